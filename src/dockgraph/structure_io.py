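"""Reading, writing and geometric primitives for two-chain protein complexes.

The in-memory model is deliberately small: a :class:`Complex` holds exactly
two chains, each an ordered list of :class:`Residue` objects carrying heavy
atoms only.  Parsing is delegated to gemmi; on top of gemmi's object model
this module applies the contract every downstream stage relies on:

* hydrogens, waters and non-amino-acid heteroatoms are removed;
* alternate locations collapse to the highest-occupancy conformer
  (ties broken by file order);
* residues are identified by ``(chain_id, author number, insertion code)``
  and kept in author numbering — no renumbering;
* residue names outside the 20 standard amino acids are dropped with a
  warning, except selenomethionine (MSE) which is retained and reads as
  methionine in sequences and feature tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    ChainNotFoundError,
    EmptyChainError,
    EmptyResidueError,
    MalformedRecordError,
)

logger = logging.getLogger(__name__)

#: three-letter -> one-letter codes, alphabetical in the one-letter alphabet
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: accepted non-standard residue names and their standard equivalents
NONSTANDARD_TO_STANDARD = {"MSE": "MET"}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def normalize_residue_name(name: str) -> str:
    """Map a residue name to its standard three-letter equivalent.

    Returns the name unchanged for the 20 standard amino acids, applies the
    declared substitutions (MSE -> MET) otherwise, and returns the input
    verbatim when no mapping exists (callers decide whether that is fatal).
    """
    name = name.strip().upper()
    if name in THREE_TO_ONE:
        return name
    return NONSTANDARD_TO_STANDARD.get(name, name)


@dataclass(frozen=True)
class Atom:
    """A heavy atom: PDB atom name, element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), float64

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """One amino-acid residue keyed by (chain_id, number, insertion_code)."""

    chain_id: str
    number: int
    insertion_code: str  # "" when absent
    name: str            # three-letter code, possibly MSE
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates, shape (n_atoms, 3)."""
        if not self.atoms:
            raise EmptyResidueError(f"empty residue {self.key}")
        return np.array([a.position for a in self.atoms])

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Complex:
    """A two-chain complex: ordered chains of ordered residues."""

    id: str
    chains: dict[str, list[Residue]]  # insertion-ordered

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self) -> list[Residue]:
        return [r for ch in self.chains.values() for r in ch]

    def get_residue(self, key: tuple[str, int, str]) -> Residue | None:
        for r in self.chains.get(key[0], []):
            if r.key == key:
                return r
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chains: set[str] | None = None) -> "Complex":
        """Return a copy with ``x -> R x + t`` applied to the selected chains."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_chains: dict[str, list[Residue]] = {}
        for cid, residues in self.chains.items():
            move = chains is None or cid in chains
            out = []
            for res in residues:
                atoms = [
                    Atom(a.name, a.element,
                         rotation @ a.position + translation if move else a.position.copy())
                    for a in res.atoms
                ]
                out.append(Residue(res.chain_id, res.number, res.insertion_code,
                                   res.name, atoms))
            new_chains[cid] = out
        return Complex(self.id, new_chains)


def _validate_atom_lines(text: str) -> None:
    """Cheap structural check so broken ATOM records fail with a line number."""
    for i, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise MalformedRecordError(i, line)
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
            int(line[22:26])
        except ValueError:
            raise MalformedRecordError(i, line) from None


def _pick_altloc(atoms: list[tuple[str, str, float, np.ndarray]]) -> list[tuple[str, str, np.ndarray]]:
    """Collapse alternate locations: highest occupancy wins, ties -> first seen."""
    best: dict[str, tuple[float, int, str, np.ndarray]] = {}
    for order, (name, element, occ, pos) in enumerate(atoms):
        cur = best.get(name)
        if cur is None or occ > cur[0]:
            best[name] = (occ, order, element, pos)
    picked = sorted(best.items(), key=lambda kv: kv[1][1])
    return [(name, element, pos) for name, (_, _, element, pos) in picked]


def parse_pdb(text: str, chain_pair: tuple[str, str], complex_id: str = "complex") -> Complex:
    """Parse PDB text into a two-chain :class:`Complex`.

    Parameters
    ----------
    text : str
        PDB-format character stream with ATOM records for both chains.
    chain_pair : (str, str)
        The two chain identifiers to extract, in order.
    complex_id : str
        Free-text identifier stored on the result.

    Raises
    ------
    ChainNotFoundError
        If a requested chain has no retained residues.
    MalformedRecordError
        If an ATOM/HETATM record cannot be parsed (reported with line number).
    """
    if len(chain_pair) != 2:
        raise ValueError("chain_pair must name exactly two chains")
    _validate_atom_lines(text)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise MalformedRecordError(0, str(exc)) from exc
    if len(structure) == 0:
        raise ChainNotFoundError(f"chain not found: {chain_pair[0]!r} (no models)")
    model = structure[0]

    chains: dict[str, list[Residue]] = {}
    for want in chain_pair:
        gchain = None
        for ch in model:
            if ch.name == want:
                gchain = ch
                break
        if gchain is None:
            raise ChainNotFoundError(f"chain not found: {want!r}")
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip().upper()
            if name in _WATER_NAMES:
                continue
            std = normalize_residue_name(name)
            if std not in THREE_TO_ONE:
                logger.warning("dropping non-standard residue %s %s%s in chain %s",
                               name, gres.seqid.num, gres.seqid.icode.strip(), want)
                continue
            raw_atoms = []
            for ga in gres:
                element = ga.element.name.upper()
                if element in ("H", "D"):
                    continue
                raw_atoms.append((ga.name, element, float(ga.occ),
                                  np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
            picked = _pick_altloc(raw_atoms)
            if not picked:
                continue  # zero heavy atoms -> drop
            icode = gres.seqid.icode.strip()
            residues.append(Residue(
                chain_id=want, number=gres.seqid.num, insertion_code=icode,
                name=name,
                atoms=[Atom(n, e, p) for n, e, p in picked]))
        if not residues:
            raise ChainNotFoundError(f"chain not found: {want!r} (no retained residues)")
        residues.sort(key=lambda r: (r.number, r.insertion_code))
        chains[want] = residues
    return Complex(complex_id, chains)


def to_pdb(cplx: Complex) -> str:
    """Serialize a complex back to PDB text (fixed-column ATOM records)."""
    lines = []
    serial = 0
    for cid, residues in cplx.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB column convention: 1-char elements start in column 14
                field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {field} {res.name:>3s} {cid}{res.number:4d}"
                    f"{res.insertion_code or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {residues[-1].name:>3s} "
                     f"{cid}{residues[-1].number:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def chain_sequence(cplx: Complex, chain_id: str) -> str:
    """One-letter sequence of a chain, ordered by residue number then icode.

    MSE reads as ``M``; any residue that survived parsing is standard by
    construction, so the length equals the retained residue count.
    """
    if chain_id not in cplx.chains:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    residues = cplx.chains[chain_id]
    if not residues:
        raise EmptyChainError(f"empty chain {chain_id!r}")
    letters = []
    for res in residues:
        std = normalize_residue_name(res.name)
        if std not in THREE_TO_ONE:  # defensive; parse should have dropped it
            logger.warning("skipping unencodable residue %s in sequence", res.key)
            continue
        letters.append(THREE_TO_ONE[std])
    return "".join(letters)


def min_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance (Å) over all heavy-atom pairs; symmetric."""
    return float(cdist(res_a.coords(), res_b.coords()).min())


def residue_distance_matrix(residues_a: list[Residue], residues_b: list[Residue]) -> np.ndarray:
    """Matrix of min heavy-atom distances between two residue lists.

    Vectorized over all atoms at once; used by graph construction and the
    contact metrics, where per-pair calls would dominate the runtime.
    """
    coords_a = np.concatenate([r.coords() for r in residues_a])
    coords_b = np.concatenate([r.coords() for r in residues_b])
    owner_a = np.repeat(np.arange(len(residues_a)), [len(r.atoms) for r in residues_a])
    owner_b = np.repeat(np.arange(len(residues_b)), [len(r.atoms) for r in residues_b])
    d = cdist(coords_a, coords_b)
    out = np.full((len(residues_a), len(residues_b)), np.inf)
    np.minimum.at(out, (owner_a[:, None], owner_b[None, :]), d)
    return out
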