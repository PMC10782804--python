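"""Node feature blocks for interface graphs.

Feature layout (active blocks concatenated in this fixed order):

====================  ====  =============================================
block                 dims  content
====================  ====  =============================================
type                  20    one-hot amino-acid type (A,C,D,...,Y order)
polarity              4     one-hot {apolar, polar, positive, negative}
bsa                   1     buried surface area of the residue, Å²
charge                1     formal charge (R,K: +1; D,E: -1; H: +0.1)
cons                  1     PSSM score of the wild-type residue
pssm_ic               1     PSSM information content
pssm                  20    the full PSSM row (log-odds, A..Y order)
embedding             E     per-residue language-model embedding
====================  ====  =============================================

The four named presets reproduce the published feature sets: ``esm-pssm``
(d = 1328), ``esm`` (d = 1306), ``pssm-only`` (d = 48) and ``minimal``
(d = 26) at the production embedding width of 1280.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    EmbeddingProviderError,
    MalformedProfileError,
    MissingFeatureError,
    ProfileMisalignedError,
    UnencodableResidueError,
)
from .structure_io import (
    THREE_TO_ONE,
    Complex,
    Residue,
    normalize_residue_name,
)

#: one-letter alphabet fixing the one-hot / PSSM column order
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

POLARITY_CLASSES = ("apolar", "polar", "positive", "negative")
#: residue -> polarity class, by one-letter code
POLARITY_TABLE = {
    **{aa: "apolar" for aa in "ACFGILMPVW"},
    **{aa: "polar" for aa in "NQSTYH"},
    **{aa: "positive" for aa in "KR"},
    **{aa: "negative" for aa in "DE"},
}
#: formal charge at physiological pH; histidine gets a fractional +0.1
CHARGE_TABLE = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0, "H": 0.1}


def _one_letter(residue_name: str) -> str:
    std = normalize_residue_name(residue_name)
    if std not in THREE_TO_ONE:
        raise UnencodableResidueError(f"unencodable residue: {residue_name!r}")
    return THREE_TO_ONE[std]


def one_hot_type(residue_name: str) -> np.ndarray:
    """20-dim one-hot amino-acid type, alphabetical one-letter order."""
    vec = np.zeros(20)
    vec[_AA_INDEX[_one_letter(residue_name)]] = 1.0
    return vec


def polarity_feature(residue_name: str) -> np.ndarray:
    """4-dim one-hot over {apolar, polar, positive, negative}."""
    vec = np.zeros(4)
    vec[POLARITY_CLASSES.index(POLARITY_TABLE[_one_letter(residue_name)])] = 1.0
    return vec


def residue_charge(residue_name: str) -> float:
    """Formal side-chain charge (unitless)."""
    return CHARGE_TABLE.get(_one_letter(residue_name), 0.0)


# --- solvent accessibility --------------------------------------------------

#: Bondi van der Waals radii (Å) by element; unknown elements fall back to C
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}
_DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _atom_radii(atoms) -> np.ndarray:
    return np.array([VDW_RADII.get(a.element, _DEFAULT_RADIUS) for a in atoms])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       subset: np.ndarray | None = None,
                       n_points: int = 100, probe: float = PROBE_RADIUS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley scheme.

    ``n_points`` test points are placed on each atom's solvent sphere of
    radius ``r_vdw + probe``; a point is accessible when outside every other
    atom's solvent sphere.  ``subset`` limits which atoms are evaluated (the
    whole coordinate set always occludes).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if subset is None:
        subset = np.arange(len(coords))
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max() + probe
    out = np.zeros(len(subset))
    for k, i in enumerate(subset):
        ri = radii[i] + probe
        sphere = coords[i] + ri * pts
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        if neigh:
            nb_coords = coords[neigh]
            nb_r = radii[neigh] + probe
            d2 = ((sphere[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 > nb_r[None, :] ** 2, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[k] = 4.0 * np.pi * ri * ri * frac
    return out


def compute_bsa(cplx: Complex, residue: Residue, n_points: int = 100) -> float:
    """Buried surface area of one residue upon complex formation, Å².

    BSA = SASA(residue | own chain alone) − SASA(residue | both chains),
    clipped at zero.  Same sphere points are used in both evaluations, so
    the difference is free of quadrature noise for unoccluded residues.
    """
    own = residue.chain_id
    chain_atoms = [a for r in cplx.chains[own] for a in r.atoms]
    all_atoms = [a for r in cplx.residues() for a in r.atoms]

    def locate(atoms):
        # residue atoms are identified by object identity within the pool
        idx = [i for i, a in enumerate(atoms) if any(a is b for b in residue.atoms)]
        return np.array([a.position for a in atoms]), _atom_radii(atoms), np.array(idx)

    c1, r1, s1 = locate(chain_atoms)
    c2, r2, s2 = locate(all_atoms)
    sasa_alone = shrake_rupley_sasa(c1, r1, s1, n_points).sum()
    sasa_complex = shrake_rupley_sasa(c2, r2, s2, n_points).sum()
    return max(0.0, float(sasa_alone - sasa_complex))


# --- PSSM -------------------------------------------------------------------

@dataclass
class PssmProfile:
    """One chain's position-specific scoring matrix.

    ``scores`` rows follow the chain's residue order; columns follow
    :data:`AA_ALPHABET`.  ``information_content`` is the per-position
    conservation measure that accompanies each PSSM row.
    """

    wild_types: list[str]            # one-letter codes, length L
    scores: np.ndarray               # (L, 20) float
    information_content: np.ndarray  # (L,) float

    def __len__(self) -> int:
        return len(self.wild_types)

    def conservation(self, row: int) -> float:
        """PSSM score of the position's own (wild-type) amino acid."""
        return float(self.scores[row, _AA_INDEX[self.wild_types[row]]])


def parse_pssm(text: str) -> PssmProfile:
    """Parse a whitespace-delimited profile: ``pos wt s_A ... s_Y ic`` per row."""
    wild_types, rows, ics = [], [], []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 23:
            raise MalformedProfileError(
                f"malformed profile at line {ln}: expected 23 fields, got {len(fields)}")
        wt = fields[1].upper()
        if wt not in _AA_INDEX:
            raise MalformedProfileError(f"malformed profile at line {ln}: wild type {wt!r}")
        try:
            scores = [float(x) for x in fields[2:22]]
            ic = float(fields[22])
        except ValueError as exc:
            raise MalformedProfileError(f"malformed profile at line {ln}: {exc}") from None
        wild_types.append(wt)
        rows.append(scores)
        ics.append(ic)
    if not rows:
        raise MalformedProfileError("malformed profile: no data rows")
    return PssmProfile(wild_types, np.array(rows), np.array(ics))


def align_profile(profile: PssmProfile, chain_length: int) -> PssmProfile:
    """Guard that a profile covers a chain one-to-one."""
    if len(profile) != chain_length:
        raise ProfileMisalignedError(
            f"profile misaligned: {len(profile)} rows for chain of {chain_length} residues")
    return profile


# --- embeddings -------------------------------------------------------------

class SyntheticEmbeddingProvider:
    """Deterministic per-residue embeddings for desk-scale work.

    Each position's vector is drawn from a ``numpy`` generator seeded by a
    stable hash of ``(seed, sequence, position)``, so the provider is pure:
    identical inputs give bitwise-identical matrices, and different seeds
    give unrelated ones.  Values are standard-normal-like, matching the
    scale of real language-model representations closely enough for the
    feature pipeline and the learning sanity checks.
    """

    def __init__(self, embedding_dim: int = 1280, seed: int = 0):
        if embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")
        self.embedding_dim = embedding_dim
        self.seed = seed

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise EmbeddingProviderError("embedding provider error: empty sequence")
        rows = np.empty((len(sequence), self.embedding_dim))
        for pos in range(len(sequence)):
            digest = hashlib.blake2b(
                f"{self.seed}|{sequence}|{pos}".encode(), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            rows[pos] = rng.standard_normal(self.embedding_dim)
        return rows


class EsmEmbeddingProvider:
    """Per-residue embeddings from a published ESM-2 checkpoint.

    Optional: requires the ``fair-esm`` package and downloaded weights.
    Returns the final-layer representation for each sequence position.
    """

    def __init__(self, model_name: str = "esm2_t33_650M_UR50D"):
        try:
            import esm  # type: ignore
        except ImportError as exc:
            raise EmbeddingProviderError(
                "embedding provider error: fair-esm is not installed") from exc
        self._model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        self._model.eval()
        self._batch_converter = alphabet.get_batch_converter()
        self._layer = self._model.num_layers
        self.embedding_dim = self._model.embed_dim

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - optional path
        import torch  # type: ignore
        _, _, tokens = self._batch_converter([("seq", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._layer])
        rep = out["representations"][self._layer][0, 1:len(sequence) + 1]
        return rep.numpy().astype(float)


def embed_chain(provider, sequence: str) -> np.ndarray:
    """Run a provider on one chain sequence; validates the output shape."""
    try:
        mat = np.asarray(provider.embed(sequence), float)
    except EmbeddingProviderError:
        raise
    except Exception as exc:
        raise EmbeddingProviderError(f"embedding provider error: {exc}") from exc
    if mat.shape != (len(sequence), provider.embedding_dim) or not np.all(np.isfinite(mat)):
        raise EmbeddingProviderError(
            f"embedding provider error: bad matrix shape {mat.shape}")
    return mat


# --- feature assembly -------------------------------------------------------

@dataclass
class FeatureConfig:
    """Which feature blocks are active, and the embedding width.

    The implied node dimension is
    ``20*use_type + 4*use_polarity + use_bsa + use_charge
    + 22*use_pssm_block + embedding_dim*use_embedding``.
    """

    use_type: bool = True
    use_polarity: bool = True
    use_bsa: bool = True
    use_charge: bool = True
    use_pssm_block: bool = False
    use_embedding: bool = True
    embedding_dim: int = 1280

    PRESETS = ("esm-pssm", "esm", "pssm-only", "minimal")

    @property
    def dim(self) -> int:
        return (20 * self.use_type + 4 * self.use_polarity + self.use_bsa
                + self.use_charge + 22 * self.use_pssm_block
                + self.embedding_dim * self.use_embedding)

    @classmethod
    def preset(cls, name: str, embedding_dim: int = 1280) -> "FeatureConfig":
        base = dict(use_type=True, use_polarity=True, use_bsa=True, use_charge=True)
        if name == "esm-pssm":
            return cls(**base, use_pssm_block=True, use_embedding=True,
                       embedding_dim=embedding_dim)
        if name == "esm":
            return cls(**base, use_pssm_block=False, use_embedding=True,
                       embedding_dim=embedding_dim)
        if name == "pssm-only":
            return cls(**base, use_pssm_block=True, use_embedding=False,
                       embedding_dim=embedding_dim)
        if name == "minimal":
            return cls(**base, use_pssm_block=False, use_embedding=False,
                       embedding_dim=embedding_dim)
        raise ValueError(f"unknown preset {name!r}; expected one of {cls.PRESETS}")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "FeatureConfig":
        return cls(**json.loads(payload))


@dataclass
class FeatureSources:
    """Everything :func:`assemble_node_features` may need per complex."""

    complex: Complex
    pssms: dict[str, PssmProfile] = field(default_factory=dict)       # chain -> profile
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)   # chain -> (L, E)
    bsa_n_points: int = 100


def assemble_node_features(nodes, config: FeatureConfig,
                           sources: FeatureSources) -> np.ndarray:
    """Per-node feature matrix for the given node selection.

    ``nodes`` may be :class:`~dockgraph.structure_io.Residue` objects or
    ``(chain_id, number, insertion_code, name)`` keys resolvable against
    ``sources.complex``.  PSSM rows and embedding rows are aligned to each
    chain by residue order.
    """
    cplx = sources.complex
    chain_pos = {cid: {r.key: i for i, r in enumerate(residues)}
                 for cid, residues in cplx.chains.items()}

    resolved: list[Residue] = []
    for node in nodes:
        if isinstance(node, Residue):
            resolved.append(node)
        else:
            res = cplx.get_residue((node[0], node[1], node[2]))
            if res is None:
                raise MissingFeatureError(f"missing feature for node {node}: not in complex")
            resolved.append(res)

    if config.use_pssm_block:
        for cid, residues in cplx.chains.items():
            if cid not in sources.pssms:
                raise MissingFeatureError(f"missing feature for node: no PSSM for chain {cid}")
            align_profile(sources.pssms[cid], len(residues))
    if config.use_embedding:
        for cid, residues in cplx.chains.items():
            emb = sources.embeddings.get(cid)
            if emb is None:
                raise MissingFeatureError(
                    f"missing feature for node: no embedding for chain {cid}")
            if emb.shape != (len(residues), config.embedding_dim):
                raise MissingFeatureError(
                    f"missing feature for node: embedding for chain {cid} has shape "
                    f"{emb.shape}, expected ({len(residues)}, {config.embedding_dim})")

    rows = []
    for res in resolved:
        pos = chain_pos[res.chain_id][res.key]
        parts = []
        if config.use_type:
            parts.append(one_hot_type(res.name))
        if config.use_polarity:
            parts.append(polarity_feature(res.name))
        if config.use_bsa:
            parts.append([compute_bsa(cplx, res, sources.bsa_n_points)])
        if config.use_charge:
            parts.append([residue_charge(res.name)])
        if config.use_pssm_block:
            prof = sources.pssms[res.chain_id]
            parts.append([prof.conservation(pos)])
            parts.append([prof.information_content[pos]])
            parts.append(prof.scores[pos])
        if config.use_embedding:
            parts.append(sources.embeddings[res.chain_id][pos])
        rows.append(np.concatenate([np.asarray(p, float) for p in parts])
                    if parts else np.zeros(0))
    mat = np.array(rows, dtype=np.float32)
    if mat.shape != (len(resolved), config.dim):
        raise MissingFeatureError(
            f"assembled matrix {mat.shape} does not match config dimension {config.dim}")
    if not np.all(np.isfinite(mat)):
        raise MissingFeatureError("missing feature for node: non-finite value assembled")
    return mat
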