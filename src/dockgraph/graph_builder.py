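"""Interface residue graphs and their HDF5 container.

A two-chain complex becomes a graph whose nodes are the residues lying
within ``interface_cutoff`` (default 8.5 Å, minimum heavy-atom distance) of
the partner chain.  Two edge sets are kept separate because the scoring
network processes them in separate branches:

* **interface edges** join nodes of *different* chains at min heavy-atom
  distance <= ``interface_cutoff``;
* **internal edges** join nodes of the *same* chain at min heavy-atom
  distance <= ``internal_cutoff`` (default 3.0 Å).

Each undirected edge is stored once (i < j) with its raw distance in Å and
the distance normalized by the edge type's own cutoff; the model expands
edges to both directions at load time.

Containers are plain HDF5: one group per graph with datasets ``nodes``,
``node_feats``, ``edge_internal_index``, ``edge_internal_dist``,
``edge_interface_index``, ``edge_interface_dist``, a scalar ``target``
attribute when labelled, and a file-level ``feature_config`` attribute.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .errors import (
    CorruptContainerError,
    DistanceOutOfRangeError,
    EmptyInterfaceError,
    InconsistentFeatureSchemaError,
)
from .structure_io import Complex, Residue, residue_distance_matrix

logger = logging.getLogger(__name__)

DEFAULT_INTERFACE_CUTOFF = 8.5
DEFAULT_INTERNAL_CUTOFF = 3.0

NodeKey = tuple[str, int, str, str]  # (chain_id, number, insertion_code, name)


@dataclass
class InterfaceGraph:
    """One interface residue graph, ready for storage or model consumption."""

    graph_id: str
    nodes: list[NodeKey]
    node_features: np.ndarray          # (n, d) float32
    internal_index: np.ndarray         # (m1, 2) int64, i < j, same chain
    internal_dist: np.ndarray          # (m1, 2) float32: raw Å, normalized
    interface_index: np.ndarray        # (m2, 2) int64, i < j, cross chain
    interface_dist: np.ndarray         # (m2, 2) float32
    target: float | None = None
    complex_id: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_chains(self) -> np.ndarray:
        """Chain id per node (array of str)."""
        return np.array([n[0] for n in self.nodes])

    def validate(self) -> None:
        """Assert the structural invariants (same/cross chain, i<j, norm in [0,1])."""
        chains = self.node_chains()
        for idx, dist, same in ((self.internal_index, self.internal_dist, True),
                                (self.interface_index, self.interface_dist, False)):
            if len(idx) == 0:
                continue
            if not np.all(idx[:, 0] < idx[:, 1]):
                raise ValueError(f"{self.graph_id}: edges must be stored with i < j")
            same_chain = chains[idx[:, 0]] == chains[idx[:, 1]]
            if same and not same_chain.all():
                raise ValueError(f"{self.graph_id}: internal edge crosses chains")
            if not same and same_chain.any():
                raise ValueError(f"{self.graph_id}: interface edge within one chain")
            if dist[:, 1].min() < 0 or dist[:, 1].max() > 1:
                raise ValueError(f"{self.graph_id}: normalized distance outside [0,1]")


def select_interface_nodes(cplx: Complex,
                           interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF
                           ) -> list[Residue]:
    """Residues within ``interface_cutoff`` of the partner chain, both chains.

    Ordering is deterministic: chain (in complex order), then residue number,
    then insertion code.  Raises :class:`EmptyInterfaceError` when no residue
    qualifies.
    """
    cids = cplx.chain_ids
    if len(cids) != 2:
        raise ValueError("interface selection requires exactly two chains")
    res_a, res_b = cplx.chains[cids[0]], cplx.chains[cids[1]]
    dmat = residue_distance_matrix(res_a, res_b)
    keep_a = dmat.min(axis=1) <= interface_cutoff
    keep_b = dmat.min(axis=0) <= interface_cutoff
    selected = [r for r, k in zip(res_a, keep_a) if k] + \
               [r for r, k in zip(res_b, keep_b) if k]
    if not selected:
        raise EmptyInterfaceError(
            f"empty interface: no residue pair within {interface_cutoff} Å in {cplx.id!r}")
    return selected


def normalize_edge_distance(d: float, cutoff: float) -> float:
    """Linear normalization ``d / cutoff`` with a range guard on ``d``."""
    if d < 0 or d > cutoff:
        raise DistanceOutOfRangeError(f"distance out of range: {d} not in [0, {cutoff}]")
    return d / cutoff


def build_edges(cplx: Complex, nodes: list[Residue],
                internal_cutoff: float = DEFAULT_INTERNAL_CUTOFF,
                interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Edge sets over selected nodes.

    Returns ``(internal_index, internal_dist, interface_index, interface_dist)``
    with undirected pairs stored once (i < j) and distances as columns
    ``[raw Å, normalized]``.
    """
    n = len(nodes)
    dmat = residue_distance_matrix(nodes, nodes)
    chains = np.array([r.chain_id for r in nodes])
    iu, ju = np.triu_indices(n, k=1)
    same = chains[iu] == chains[ju]
    d = dmat[iu, ju]

    internal_mask = same & (d <= internal_cutoff)
    interface_mask = ~same & (d <= interface_cutoff)

    def pack(mask: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
        idx = np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)
        raw = d[mask]
        dist = np.stack([raw, raw / cutoff], axis=1).astype(np.float32)
        return idx, dist

    internal_index, internal_dist = pack(internal_mask, internal_cutoff)
    interface_index, interface_dist = pack(interface_mask, interface_cutoff)
    return internal_index, internal_dist, interface_index, interface_dist


def build_graph(cplx: Complex, node_features: np.ndarray, graph_id: str | None = None,
                interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF,
                internal_cutoff: float = DEFAULT_INTERNAL_CUTOFF,
                target: float | None = None,
                complex_id: str | None = None,
                nodes: list[Residue] | None = None) -> InterfaceGraph:
    """Assemble an :class:`InterfaceGraph` from a complex and a feature matrix.

    ``node_features`` must be row-aligned with the node selection; pass the
    ``nodes`` list returned by :func:`select_interface_nodes` when features
    were computed from it (otherwise the selection is recomputed here).
    """
    if nodes is None:
        nodes = select_interface_nodes(cplx, interface_cutoff)
    node_features = np.asarray(node_features, dtype=np.float32)
    if node_features.shape[0] != len(nodes):
        raise InconsistentFeatureSchemaError(
            f"feature matrix has {node_features.shape[0]} rows for {len(nodes)} nodes")
    internal_index, internal_dist, interface_index, interface_dist = build_edges(
        cplx, nodes, internal_cutoff, interface_cutoff)
    g = InterfaceGraph(
        graph_id=graph_id or cplx.id,
        nodes=[(r.chain_id, r.number, r.insertion_code, r.name) for r in nodes],
        node_features=node_features,
        internal_index=internal_index, internal_dist=internal_dist,
        interface_index=interface_index, interface_dist=interface_dist,
        target=target, complex_id=complex_id)
    g.validate()
    return g


# --- HDF5 container --------------------------------------------------------

_NODE_DT = h5py.string_dtype(encoding="utf-8")


def _encode_nodes(nodes: list[NodeKey]) -> np.ndarray:
    return np.array([f"{c}|{n}|{i}|{r}" for c, n, i, r in nodes], dtype=object)


def _decode_nodes(raw) -> list[NodeKey]:
    out = []
    for item in raw:
        s = item.decode() if isinstance(item, bytes) else str(item)
        c, n, i, r = s.split("|")
        out.append((c, int(n), i, r))
    return out


def write_graphs(graphs: list[InterfaceGraph], path, feature_config=None,
                 mode: str = "w") -> None:
    """Write graphs to an HDF5 container (one group per graph_id).

    All graphs in one container must share the node feature dimension; the
    serialized ``feature_config`` (any object with ``to_json`` or a plain
    string) is stored as a file attribute.  ``mode="a"`` appends, enforcing
    the schema of the existing file.
    """
    graphs = list(graphs)
    if graphs:
        dims = {g.node_features.shape[1] for g in graphs}
        if len(dims) != 1:
            raise InconsistentFeatureSchemaError(
                f"inconsistent feature schema: dimensions {sorted(dims)} in one batch")
    with h5py.File(path, mode) as f:
        existing_d = f.attrs.get("feature_dim")
        for g in graphs:
            d = g.node_features.shape[1]
            if existing_d is not None and int(existing_d) != d:
                raise InconsistentFeatureSchemaError(
                    f"inconsistent feature schema: container has d={existing_d}, got d={d}")
            existing_d = d
            grp = f.create_group(g.graph_id)
            grp.create_dataset("nodes", data=_encode_nodes(g.nodes), dtype=_NODE_DT)
            grp.create_dataset("node_feats", data=g.node_features.astype(np.float32))
            grp.create_dataset("edge_internal_index", data=g.internal_index.astype(np.int64))
            grp.create_dataset("edge_internal_dist", data=g.internal_dist.astype(np.float32))
            grp.create_dataset("edge_interface_index", data=g.interface_index.astype(np.int64))
            grp.create_dataset("edge_interface_dist", data=g.interface_dist.astype(np.float32))
            if g.target is not None:
                grp.attrs["target"] = float(g.target)
            if g.complex_id is not None:
                grp.attrs["complex_id"] = g.complex_id
        if graphs:
            f.attrs["feature_dim"] = int(existing_d)
        if feature_config is not None:
            f.attrs["feature_config"] = (feature_config.to_json()
                                         if hasattr(feature_config, "to_json")
                                         else str(feature_config))


_REQUIRED = ("nodes", "node_feats", "edge_internal_index", "edge_internal_dist",
             "edge_interface_index", "edge_interface_dist")


def read_graphs(path, graph_ids: list[str] | None = None) -> list[InterfaceGraph]:
    """Read graphs back from a container; round-trips :func:`write_graphs`."""
    out = []
    with h5py.File(path, "r") as f:
        ids = graph_ids if graph_ids is not None else list(f.keys())
        for gid in ids:
            if gid not in f:
                raise CorruptContainerError(f"corrupt container: graph {gid!r} missing")
            grp = f[gid]
            for ds in _REQUIRED:
                if ds not in grp:
                    raise CorruptContainerError(
                        f"corrupt container: dataset {ds!r} missing in {gid!r}")
            g = InterfaceGraph(
                graph_id=gid,
                nodes=_decode_nodes(grp["nodes"][...]),
                node_features=grp["node_feats"][...],
                internal_index=grp["edge_internal_index"][...],
                internal_dist=grp["edge_internal_dist"][...],
                interface_index=grp["edge_interface_index"][...],
                interface_dist=grp["edge_interface_dist"][...],
                target=float(grp.attrs["target"]) if "target" in grp.attrs else None,
                complex_id=str(grp.attrs["complex_id"]) if "complex_id" in grp.attrs else None,
            )
            out.append(g)
    return out


def read_feature_config_json(path) -> str | None:
    """The serialized feature configuration stored in a container, if any."""
    with h5py.File(path, "r") as f:
        cfg = f.attrs.get("feature_config")
    return None if cfg is None else str(cfg)


def container_index(path) -> dict[str, list[str]]:
    """DatasetIndex mapping complex_id -> graph_ids, read from group attrs."""
    index: dict[str, list[str]] = {}
    with h5py.File(path, "r") as f:
        for gid in f.keys():
            cid = str(f[gid].attrs.get("complex_id", gid))
            index.setdefault(cid, []).append(gid)
    for v in index.values():
        v.sort()
    return index
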