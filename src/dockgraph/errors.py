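"""Exception hierarchy for dockgraph.

Every error raised by the public API derives from :class:`DockgraphError`
so callers can catch the whole family with one clause.
"""


class DockgraphError(Exception):
    """Base class for all dockgraph errors."""


# --- structure_io ---------------------------------------------------------

class ChainNotFoundError(DockgraphError):
    """Requested chain is absent from the structure ("chain not found")."""


class MalformedRecordError(DockgraphError):
    """An ATOM/HETATM record could not be parsed ("malformed record")."""

    def __init__(self, line_number: int, line: str = ""):
        self.line_number = line_number
        super().__init__(f"malformed record at line {line_number}: {line.rstrip()!r}")


class EmptyChainError(DockgraphError):
    """Chain retained zero residues ("empty chain")."""


class EmptyResidueError(DockgraphError):
    """Residue carries no heavy atoms ("empty residue")."""


# --- graph_builder --------------------------------------------------------

class EmptyInterfaceError(DockgraphError):
    """No residue lies within the interface cutoff ("empty interface")."""


class DistanceOutOfRangeError(DockgraphError):
    """Distance outside [0, cutoff] passed to normalization ("distance out of range")."""


class InconsistentFeatureSchemaError(DockgraphError):
    """Graphs with different feature dimensions in one container."""


class CorruptContainerError(DockgraphError):
    """A required dataset or attribute is missing from an HDF5 container."""


# --- node_features --------------------------------------------------------

class UnencodableResidueError(DockgraphError):
    """Residue name outside the 20 standard amino acids ("unencodable residue")."""


class ProfileMisalignedError(DockgraphError):
    """PSSM row count does not match the chain ("profile misaligned")."""


class MalformedProfileError(DockgraphError):
    """Non-numeric or short row in a PSSM table ("malformed profile")."""


class EmbeddingProviderError(DockgraphError):
    """Embedding provider failed or is unavailable."""


class MissingFeatureError(DockgraphError):
    """A graph node has no row in a required feature source."""


# --- gnn_model / training -------------------------------------------------

class ShapeError(DockgraphError):
    """Tensor dimensions incompatible with the network specification."""


class CannotSplitError(DockgraphError):
    """Fewer than two complexes: by-complex split impossible ("cannot split")."""


class NoTrainingDataError(DockgraphError):
    """Empty training index ("no training data")."""


class UnlabeledGraphError(DockgraphError):
    """Graph without a target encountered during training ("unlabeled graph")."""


class TooManyFoldsError(DockgraphError):
    """k exceeds the number of complexes ("too many folds")."""


# --- quality_metrics ------------------------------------------------------

class NoNativeContactsError(DockgraphError):
    """Reference complex has zero cross-chain contacts ("no native contacts")."""


class DegenerateLabelsError(DockgraphError):
    """ROC requested on single-class labels ("degenerate labels")."""


class InsufficientPointsError(DockgraphError):
    """Fewer than three matched points for superposition ("insufficient points")."""


class IncompleteBackboneError(DockgraphError):
    """Backbone atoms N/CA/C/O missing for an RMSD computation."""


class NoCasesError(DockgraphError):
    """success_rate called with no complexes ("no cases")."""


# --- synthetic_data -------------------------------------------------------

class GenerationFailedError(DockgraphError):
    """Synthetic placement failed after bounded retries ("generation failed")."""
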