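"""Desk-scale synthetic fixtures: complexes, decoy ladders, benchmarks.

The generator produces two-chain pseudo-protein complexes whose geometry is
idealized rather than physical: a self-avoiding Cα walk with 3.8 Å steps
carries N, C, O and one pseudo side-chain atom per residue at fixed local
offsets, and chain B is grown along chain A's surface until the two chains
share a broad contact patch (by default at least eight cross-chain residue
pairs within the 5 Å contact cutoff; three is the guaranteed floor).  That is all the downstream code
paths require — residue identities, heavy-atom coordinates, and a real
interface — while remaining fully deterministic for any seed.

Decoy ladders emulate docking model sets: decoy 0 is the reference and
decoy i applies a rigid-body perturbation of chain B whose magnitude grows
linearly with i, so model quality (fnat, DockQ) degrades along the ladder.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationFailedError
from .graph_builder import (
    DEFAULT_INTERFACE_CUTOFF,
    DEFAULT_INTERNAL_CUTOFF,
    InterfaceGraph,
    build_graph,
    select_interface_nodes,
    write_graphs,
)
from .node_features import (
    AA_ALPHABET,
    FeatureConfig,
    FeatureSources,
    PssmProfile,
    SyntheticEmbeddingProvider,
    assemble_node_features,
    embed_chain,
)
from .quality_metrics import dockq as compute_dockq
from .structure_io import ONE_TO_THREE, Atom, Complex, Residue, chain_sequence, to_pdb

logger = logging.getLogger(__name__)

CA_STEP = 3.8          # Å, consecutive Cα spacing
SELF_AVOID = 4.0       # Å, min Cα distance between non-adjacent residues
MIN_CONTACTS = 8       # cross-chain residue pairs within 5 Å required (>= 3 guaranteed)


@dataclass
class DecoyLadderSpec:
    """Perturbation ladder: magnitudes increase linearly from 0 to the maxima."""

    n_decoys: int = 20
    max_translation: float = 8.0   # Å
    max_rotation: float = 60.0     # degrees
    seed: int = 0


def _ca_walk(n: int, rng: np.random.Generator, start: np.ndarray,
             direction: np.ndarray, max_tries: int = 60) -> np.ndarray | None:
    """Self-avoiding persistent random walk of n Cα positions, or None."""
    coords = [start]
    d = direction / np.linalg.norm(direction)
    for _ in range(n - 1):
        placed = False
        for _ in range(max_tries):
            step = d + 0.8 * rng.standard_normal(3)
            step = step / np.linalg.norm(step) * CA_STEP
            cand = coords[-1] + step
            prev = np.array(coords[:-1]) if len(coords) > 1 else None
            if prev is None or np.linalg.norm(prev - cand, axis=1).min() >= SELF_AVOID:
                coords.append(cand)
                d = step / CA_STEP
                placed = True
                break
        if not placed:
            return None
    return np.array(coords)


def _residue_atoms(ca: np.ndarray, prev_ca: np.ndarray | None,
                   next_ca: np.ndarray | None) -> list[tuple[str, str, np.ndarray]]:
    """Heavy atoms around one Cα with idealized local offsets.

    Offsets are chosen so consecutive residues meet at ~1.3 Å C–N spacing,
    giving the 3.0 Å internal-edge cutoff realistic sequence-neighbor edges.
    """
    fwd = (next_ca - ca) if next_ca is not None else (ca - prev_ca)
    fwd = fwd / np.linalg.norm(fwd)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(fwd @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    side = np.cross(fwd, helper)
    side /= np.linalg.norm(side)
    up = np.cross(fwd, side)
    return [
        ("N", "N", ca - 1.25 * fwd + 0.4 * side),
        ("CA", "C", ca),
        ("C", "C", ca + 1.25 * fwd + 0.4 * side),
        ("O", "O", ca + 1.25 * fwd + 0.4 * side + 1.23 * up),
        ("CB", "C", ca + 1.50 * side),
    ]


def _chain_from_walk(chain_id: str, walk: np.ndarray, names: list[str]) -> list[Residue]:
    residues = []
    for i, ca in enumerate(walk):
        prev_ca = walk[i - 1] if i > 0 else None
        next_ca = walk[i + 1] if i < len(walk) - 1 else None
        atoms = [Atom(n, e, p) for n, e, p in _residue_atoms(ca, prev_ca, next_ca)]
        residues.append(Residue(chain_id, i + 1, "", names[i], atoms))
    return residues


def generate_complex(n_res_per_chain: int, seed: int,
                     complex_id: str | None = None,
                     min_contacts: int = MIN_CONTACTS) -> tuple[str, Complex, dict[str, str]]:
    """One synthetic two-chain complex with a guaranteed interface.

    Chain B starts 5 Å off a mid-chain residue of A and is launched along a
    direction tangent to A's surface, so it skims along A and forms a broad
    contact patch rather than a single touch point.  Returns
    ``(pdb_text, complex, sequences)`` — byte-identical for a given
    (n, seed).  Raises :class:`GenerationFailedError` after bounded retries.
    """
    if n_res_per_chain < 3:
        raise ValueError("need at least 3 residues per chain")
    for attempt in range(120):
        rng = np.random.default_rng([seed, attempt])
        names_a = [ONE_TO_THREE[AA_ALPHABET[i]] for i in rng.integers(0, 20, n_res_per_chain)]
        names_b = [ONE_TO_THREE[AA_ALPHABET[i]] for i in rng.integers(0, 20, n_res_per_chain)]
        walk_a = _ca_walk(n_res_per_chain, rng, np.zeros(3), rng.standard_normal(3))
        if walk_a is None:
            continue
        # start chain B near a middle residue of A, offset outward,
        # heading tangentially so it hugs A's surface
        anchor = walk_a[n_res_per_chain // 2]
        outward = anchor - walk_a.mean(axis=0)
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        start_b = anchor + 5.0 * outward
        tangent = np.cross(outward, rng.standard_normal(3))
        tangent /= np.linalg.norm(tangent)
        walk_b = _ca_walk(n_res_per_chain, rng, start_b,
                          tangent + 0.2 * rng.standard_normal(3))
        if walk_b is None:
            continue
        cplx = Complex(complex_id or f"synth{seed}", {
            "A": _chain_from_walk("A", walk_a, names_a),
            "B": _chain_from_walk("B", walk_b, names_b),
        })
        from .structure_io import residue_distance_matrix
        dmat = residue_distance_matrix(cplx.chains["A"], cplx.chains["B"])
        if dmat.min() < 2.0:       # steric clash
            continue
        if (dmat <= 5.0).sum() < max(min_contacts, MIN_CONTACTS):
            continue
        sequences = {cid: chain_sequence(cplx, cid) for cid in cplx.chain_ids}
        return to_pdb(cplx), cplx, sequences
    raise GenerationFailedError(f"generation failed for seed {seed} (re-seed)")


def _rigid_perturbation(rng: np.random.Generator, magnitude: float,
                        max_translation: float, max_rotation: float,
                        direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation vector at a ladder fraction in [0, 1].

    The translation direction is fixed by the caller (the chain-separation
    axis), so growing magnitudes pull the chains apart gradually; only the
    rotation axis is random.
    """
    from scipy.spatial.transform import Rotation
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(magnitude * max_rotation)
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    trans = magnitude * max_translation * direction
    return rot, trans


def generate_decoys(reference: Complex, spec: DecoyLadderSpec
                    ) -> tuple[list[tuple[str, Complex]], pd.DataFrame]:
    """A decoy ladder for one reference complex, with its truth table.

    Decoy 0 is the unperturbed reference.  Decoy i rigidly moves the second
    chain with magnitude i/n of the spec maxima: a rotation pivoted at the
    interface center (axis drawn once per ladder) plus a translation along
    the chain-separation axis.  Pivoting at the interface makes contacts
    break progressively with angle — residues near the pivot hold on
    longest — so model quality degrades monotonically along the ladder.
    The table lists each decoy's fnat/DockQ computed with the quality
    metrics of this package.
    """
    from .quality_metrics import native_contacts
    cids = reference.chain_ids
    moving = cids[1]
    centroid_a = np.concatenate([r.coords() for r in reference.chains[cids[0]]]).mean(axis=0)
    centroid_b = np.concatenate([r.coords() for r in reference.chains[moving]]).mean(axis=0)
    separation = centroid_b - centroid_a
    norm = np.linalg.norm(separation)
    separation = separation / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    contact_keys = {b for _, b in native_contacts(reference)}
    contact_res = [r for r in reference.chains[moving] if r.key in contact_keys]
    pivot = (np.concatenate([r.coords() for r in contact_res]).mean(axis=0)
             if contact_res else centroid_b)
    decoys: list[tuple[str, Complex]] = []
    rows = []
    for i in range(spec.n_decoys):
        decoy_id = f"{reference.id}_d{i:03d}"
        if i == 0:
            decoy = reference.transformed(np.eye(3), np.zeros(3))
        else:
            magnitude = i / (spec.n_decoys - 1) if spec.n_decoys > 1 else 1.0
            rot, trans = _rigid_perturbation(np.random.default_rng([spec.seed, 1]),
                                             magnitude, spec.max_translation,
                                             spec.max_rotation, separation)
            # rotate about the interface pivot, then translate
            decoy = reference.transformed(rot, pivot - rot @ pivot + trans,
                                          chains={moving})
        decoy.id = decoy_id
        q = compute_dockq(decoy, reference)
        rows.append({"graph_id": decoy_id, "complex_id": reference.id,
                     "perturbation": (0.0 if i == 0 else i / max(spec.n_decoys - 1, 1)),
                     **q})
        decoys.append((decoy_id, decoy))
    return decoys, pd.DataFrame(rows)


def random_pssm(length: int, sequence: str, rng: np.random.Generator) -> PssmProfile:
    """Uniform-random toy profile aligned to a sequence (for pipeline tests)."""
    scores = rng.integers(-8, 9, size=(length, 20)).astype(float)
    ic = rng.uniform(0.0, 2.0, size=length)
    return PssmProfile(list(sequence), scores, ic)


PLANTED_BSA_CENTER = 10.0  # Å², roughly the generator's typical mean node BSA
PLANTED_BSA_SCALE = 5.0    # Å², spreads targets over most of (0, 1)


def planted_target(node_features: np.ndarray, config: FeatureConfig) -> float:
    """The planted-signal target: logistic((mean node BSA − 10 Å²) / 5 Å²).

    A smooth, bounded function of the node-feature mean, used to verify that
    the optimizer and architecture can recover a known dependence.  Buried
    surface area carries the signal because it behaves consistently across
    complexes (unlike the synthetic embeddings, which are sequence-keyed
    noise), so a correctly learned model transfers to held-out complexes.
    The center/scale match the generator's mean-BSA distribution so targets
    span most of (0, 1).
    """
    if not config.use_bsa:
        raise ValueError("planted signal requires the BSA block")
    col = 20 * config.use_type + 4 * config.use_polarity
    m = float(node_features[:, col].mean())
    return float(1.0 / (1.0 + np.exp(-(m - PLANTED_BSA_CENTER) / PLANTED_BSA_SCALE)))


@dataclass
class Benchmark:
    """Everything :func:`make_benchmark` produced, in memory and on disk."""

    graphs: list[InterfaceGraph]
    index: dict[str, list[str]]
    truth: pd.DataFrame
    config: FeatureConfig
    container_path: Path | None = None


def make_benchmark(n_complexes: int, n_decoys: int, embedding_dim: int = 16,
                   seed: int = 0, planted_signal: bool = False,
                   out_dir: str | Path | None = None,
                   n_res_per_chain: int = 30,
                   ladder: DecoyLadderSpec | None = None,
                   use_pssm: bool = False,
                   write_pdbs: bool = False) -> Benchmark:
    """Full synthetic pipeline: complexes -> decoys -> graphs -> targets.

    Targets are true fnat values unless ``planted_signal`` replaces them by
    :func:`planted_target`.  With ``out_dir`` the HDF5 container, a labels
    TSV and an index JSON are written (plus per-decoy PDB files when
    ``write_pdbs``).
    """
    config = FeatureConfig.preset("esm-pssm" if use_pssm else "esm",
                                  embedding_dim=embedding_dim)
    provider = SyntheticEmbeddingProvider(embedding_dim=embedding_dim, seed=seed)
    ladder = ladder or DecoyLadderSpec(n_decoys=n_decoys, seed=seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    graphs: list[InterfaceGraph] = []
    index: dict[str, list[str]] = {}
    tables = []
    for ci in range(n_complexes):
        cid = f"cplx{ci:03d}"
        pdb_text, reference, sequences = generate_complex(
            n_res_per_chain, seed=seed * 10007 + ci, complex_id=cid)
        spec_i = DecoyLadderSpec(n_decoys=n_decoys, seed=ladder.seed * 10007 + ci,
                                 max_translation=ladder.max_translation,
                                 max_rotation=ladder.max_rotation)
        decoys, truth = generate_decoys(reference, spec_i)
        tables.append(truth)
        embeddings = {c: embed_chain(provider, s) for c, s in sequences.items()}
        rng_pssm = np.random.default_rng([seed, ci, 7])
        pssms = ({c: random_pssm(len(s), s, rng_pssm) for c, s in sequences.items()}
                 if use_pssm else {})
        truth_by_id = truth.set_index("graph_id")
        for decoy_id, decoy in decoys:
            if write_pdbs and out_path is not None:
                (out_path / f"{decoy_id}.pdb").write_text(to_pdb(decoy))
            try:
                nodes = select_interface_nodes(decoy, DEFAULT_INTERFACE_CUTOFF)
            except Exception:
                logger.warning("skipping %s: empty interface", decoy_id)
                continue
            sources = FeatureSources(complex=decoy, pssms=pssms, embeddings=embeddings)
            feats = assemble_node_features(nodes, config, sources)
            target = (planted_target(feats, config) if planted_signal
                      else float(truth_by_id.loc[decoy_id, "fnat"]))
            g = build_graph(decoy, feats, graph_id=decoy_id,
                            interface_cutoff=DEFAULT_INTERFACE_CUTOFF,
                            internal_cutoff=DEFAULT_INTERNAL_CUTOFF,
                            target=target, complex_id=cid, nodes=nodes)
            graphs.append(g)
            index.setdefault(cid, []).append(decoy_id)
        if write_pdbs and out_path is not None:
            (out_path / f"{cid}_ref.pdb").write_text(pdb_text)

    truth_all = pd.concat(tables, ignore_index=True)
    container = None
    if out_path is not None:
        container = out_path / "graphs.h5"
        write_graphs(graphs, container, feature_config=config)
        truth_all.to_csv(out_path / "labels.tsv", sep="\t", index=False)
        (out_path / "index.json").write_text(json.dumps(index, indent=1))
    return Benchmark(graphs, index, truth_all, config, container)
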