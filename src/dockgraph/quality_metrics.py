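"""Structural quality labels and scoring-performance metrics.

Structural side: CAPRI-convention native contacts (5 Å minimum heavy-atom
distance across the interface), fnat, Kabsch superposition, interface and
ligand RMSDs, and the DockQ composite

    DockQ = ( fnat + 1/(1 + (iRMSD/1.5)²) + 1/(1 + (LRMSD/8.5)²) ) / 3

with DockQ > 0.23 defining a near-native model.

Scoring side: interpolated ROC curves (TPR estimated at a fixed FPR grid),
the usual thresholded classification metrics plus R²/Pearson on raw
targets, and the per-complex top-k success rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr
from sklearn import metrics as _skm

from .errors import (
    DegenerateLabelsError,
    IncompleteBackboneError,
    InsufficientPointsError,
    NoCasesError,
    NoNativeContactsError,
    ShapeError,
)
from .structure_io import Complex, residue_distance_matrix

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 5.0          # Å, native-contact definition
INTERFACE_RMSD_CUTOFF = 10.0  # Å, interface-residue selection for iRMSD
NEAR_NATIVE_DOCKQ = 0.23
BACKBONE_ATOMS = ("N", "CA", "C", "O")

ResidueKey = tuple[str, int, str]


def native_contacts(cplx: Complex, contact_cutoff: float = CONTACT_CUTOFF
                    ) -> set[tuple[ResidueKey, ResidueKey]]:
    """Cross-chain residue pairs at min heavy-atom distance <= cutoff."""
    cids = cplx.chain_ids
    res_a, res_b = cplx.chains[cids[0]], cplx.chains[cids[1]]
    dmat = residue_distance_matrix(res_a, res_b)
    ii, jj = np.nonzero(dmat <= contact_cutoff)
    return {(res_a[i].key, res_b[j].key) for i, j in zip(ii, jj)}


def fnat(model: Complex, reference: Complex,
         contact_cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of the reference's cross-chain contacts present in the model.

    Contacts are keyed by (chain, number, insertion code); residues present
    in only one structure simply cannot contribute shared contacts and are
    noted with a warning.
    """
    ref_contacts = native_contacts(reference, contact_cutoff)
    if not ref_contacts:
        raise NoNativeContactsError(
            f"no native contacts in reference {reference.id!r}")
    model_keys = {r.key for r in model.residues()}
    ref_keys = {r.key for r in reference.residues()}
    if ref_keys - model_keys:
        logger.warning("%d reference residues missing from model %r",
                       len(ref_keys - model_keys), model.id)
    model_contacts = native_contacts(model, contact_cutoff)
    return len(model_contacts & ref_contacts) / len(ref_contacts)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation and translation mapping ``b`` onto ``a``.

    Returns ``(rotation, translation, rmsd)`` with the least-squares RMSD in
    Å.  The rotation has determinant +1 (reflections are corrected).
    """
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    if coords_a.shape != coords_b.shape or coords_a.ndim != 2 or coords_a.shape[1] != 3:
        raise ShapeError("shape error: matched (n, 3) coordinate sets required")
    n = len(coords_a)
    if n < 3:
        raise InsufficientPointsError(f"insufficient points: {n} < 3")
    mu_a, mu_b = coords_a.mean(axis=0), coords_b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # exact alignments warn
        rot, rssd = Rotation.align_vectors(coords_a - mu_a, coords_b - mu_b)
    rotation = rot.as_matrix()
    translation = mu_a - rotation @ mu_b
    rmsd = float(rssd / np.sqrt(n))
    return rotation, translation, rmsd


def _backbone_coords(cplx: Complex, keys: list[ResidueKey]) -> np.ndarray:
    coords = []
    for key in keys:
        res = cplx.get_residue(key)
        if res is None:
            raise IncompleteBackboneError(f"incomplete backbone: residue {key} missing")
        for name in BACKBONE_ATOMS:
            atom = res.get_atom(name)
            if atom is None:
                raise IncompleteBackboneError(
                    f"incomplete backbone: atom {name} missing in {key}")
            coords.append(atom.position)
    return np.array(coords)


def _receptor_ligand(reference: Complex) -> tuple[str, str]:
    """Receptor = longer chain, ligand = shorter (tie -> first chain)."""
    cids = reference.chain_ids
    n0, n1 = len(reference.chains[cids[0]]), len(reference.chains[cids[1]])
    return (cids[0], cids[1]) if n0 >= n1 else (cids[1], cids[0])


def dockq(model: Complex, reference: Complex) -> dict[str, float]:
    """DockQ score with its components.

    LRMSD: backbone RMSD of the ligand (shorter) chain after superposing on
    the receptor (longer) chain.  iRMSD: backbone RMSD over the reference's
    interface residues (any cross-chain heavy atom within 10 Å) after
    superposing on those same residues.  Residues shared by both structures
    enter the RMSD terms.
    """
    f = fnat(model, reference)
    receptor, ligand = _receptor_ligand(reference)
    model_keys = {r.key for r in model.residues()}

    def shared(chain_ids) -> list[ResidueKey]:
        return [r.key for cid in chain_ids for r in reference.chains[cid]
                if r.key in model_keys]

    # ligand RMSD after receptor superposition
    rec_keys = shared([receptor])
    lig_keys = shared([ligand])
    rot, trans, _ = kabsch_superpose(_backbone_coords(reference, rec_keys),
                                     _backbone_coords(model, rec_keys))
    lig_model = _backbone_coords(model, lig_keys) @ rot.T + trans
    lig_ref = _backbone_coords(reference, lig_keys)
    lrmsd = float(np.sqrt(((lig_model - lig_ref) ** 2).sum(axis=1).mean()))

    # interface RMSD after interface superposition
    cids = reference.chain_ids
    dmat = residue_distance_matrix(reference.chains[cids[0]], reference.chains[cids[1]])
    iface = [r.key for r, near in zip(reference.chains[cids[0]],
                                      dmat.min(axis=1) <= INTERFACE_RMSD_CUTOFF) if near]
    iface += [r.key for r, near in zip(reference.chains[cids[1]],
                                       dmat.min(axis=0) <= INTERFACE_RMSD_CUTOFF) if near]
    iface = [k for k in iface if k in model_keys]
    rot, trans, irmsd = kabsch_superpose(_backbone_coords(reference, iface),
                                         _backbone_coords(model, iface))

    score = (f + 1.0 / (1.0 + (irmsd / 1.5) ** 2)
             + 1.0 / (1.0 + (lrmsd / 8.5) ** 2)) / 3.0
    return {"dockq": float(score), "fnat": float(f),
            "irmsd": float(irmsd), "lrmsd": float(lrmsd)}


# --- scoring-performance metrics ----------------------------------------------

def roc_curve_interpolated(scores, labels, fpr_grid: np.ndarray | None = None
                           ) -> tuple[np.ndarray, float]:
    """Empirical ROC with TPR linearly interpolated on an FPR grid.

    Scores are swept in descending order with tied groups processed
    atomically.  Returns ``(tpr_at_grid, auc)`` where the AUC is the
    trapezoidal area over the grid (default step 0.001).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ShapeError("shape error: scores and labels differ in length")
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("degenerate labels: both classes required")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 1001)

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # collapse tied scores into atomic groups
    boundary = np.nonzero(np.diff(s))[0] + 1
    tp = np.concatenate([[0], np.add.reduceat(y == 1, np.concatenate([[0], boundary])).cumsum()])
    fp = np.concatenate([[0], np.add.reduceat(y == 0, np.concatenate([[0], boundary])).cumsum()])
    tpr = tp / n_pos
    fpr = fp / n_neg
    # vertical ROC segments duplicate FPR values; an infinitesimal tie-break
    # keeps them (numerically) vertical under linear interpolation
    fpr_adj = fpr + np.arange(len(fpr)) * 1e-12
    tpr_grid = np.interp(fpr_grid, fpr_adj, tpr)
    # integrate over the grid refined by the curve's own vertices, so the
    # trapezoidal area agrees with the exact rank-sum AUC
    x = np.union1d(fpr_grid, fpr_adj)
    auc = float(np.trapezoid(np.interp(x, fpr_adj, tpr), x))
    return tpr_grid, auc


def classification_metrics(scores, labels, score_threshold: float = 0.5,
                           targets=None) -> dict[str, float]:
    """Thresholded classification metrics plus R²/Pearson on raw targets.

    ``labels`` are the {0,1} truth; ``targets`` (default: the labels) are the
    continuous ground truth for R² and Pearson.  MCC is defined as 0 with a
    warning when a confusion-matrix marginal is empty.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape or scores.size == 0:
        raise ShapeError("shape error: scores and labels must be equal-length and nonempty")
    targets = labels.astype(float) if targets is None else np.asarray(targets, float)
    if targets.shape != scores.shape:
        raise ShapeError("shape error: targets length mismatch")
    pred = (scores > score_threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {
            "precision": float(_skm.precision_score(labels, pred, zero_division=0)),
            "recall": float(_skm.recall_score(labels, pred, zero_division=0)),
            "f1": float(_skm.f1_score(labels, pred, zero_division=0)),
            "mcc": float(_skm.matthews_corrcoef(labels, pred)),
            "accuracy": float(_skm.accuracy_score(labels, pred)),
            "r2": float(_skm.r2_score(targets, scores)),
        }
    if np.std(scores) == 0 or np.std(targets) == 0:
        out["pearson"] = float("nan")
    else:
        out["pearson"] = float(pearsonr(scores, targets)[0])
    return out


@dataclass
class QualityRecord:
    """Per-decoy bookkeeping for ranking-based evaluation."""

    graph_id: str
    complex_id: str
    fnat: float
    dockq: float
    predicted_score: float
    rank: int | None = None

    @property
    def is_near_native(self) -> bool:
        return self.dockq > NEAR_NATIVE_DOCKQ


def rank_records(records: list[QualityRecord]) -> list[QualityRecord]:
    """Assign within-complex ranks by descending score, ties by graph_id."""
    by_complex: dict[str, list[QualityRecord]] = {}
    for r in records:
        by_complex.setdefault(r.complex_id, []).append(r)
    for recs in by_complex.values():
        recs.sort(key=lambda r: (-r.predicted_score, r.graph_id))
        for i, r in enumerate(recs, start=1):
            r.rank = i
    return records


def success_rate(records: list[QualityRecord], k: int) -> float:
    """Percentage of complexes with a near-native model among top-k ranks."""
    if not records:
        raise NoCasesError("no cases")
    if any(r.rank is None for r in records):
        rank_records(records)
    complexes: dict[str, bool] = {}
    for r in records:
        hit = complexes.get(r.complex_id, False)
        complexes[r.complex_id] = hit or (r.rank <= k and r.is_near_native)
    return 100.0 * sum(complexes.values()) / len(complexes)
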