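"""The two-branch attention graph network that scores interface graphs.

Architecture
------------
Each graph is processed by two parallel branches that share no weights: one
message-passes over **internal** edges (within-chain contacts), the other
over **interface** edges (cross-chain contacts).  A branch is::

    conv1 (d -> 16)  ->  community pooling (max)  ->  conv2 (16 -> 32)

where a conv layer is a single-head edge-aware attention graph convolution:

    z_i   = W x_i                      (node transform, no bias)
    e'_ij = V d_ij                     (scalar edge transform, no bias)
    a_ij  = LeakyReLU( aᵀ [z_i ‖ z_j ‖ e'_ij] )
    α̂_ij  = softmax_{j ∈ N(i)} a_ij
    h_i   = ReLU( Σ_j α̂_ij z_j )       (isolated node -> zero vector)

Community pooling detects modularity-maximizing (Louvain) communities on
the internal-edge graph, per chain, and max-reduces node features within
each community; it contributes zero trainable parameters.  After conv2 each
branch is read out by an element-wise mean over its nodes (32 values); the
two read-outs concatenate to 64 and feed a dense head 64 -> 128 -> 1 (the
only place with biases).  The mean read-out — like the max, parameter-free —
was chosen because graph-level targets here are smooth functions of
node-feature averages (interface size, composition); a max read-out cannot
represent an average and measurably fails to generalize on such targets.

The trainable parameter count is therefore exactly ``32 d + 9673``:
``2 (16 d + 1 + 33)`` for the first conv pair, ``2 (512 + 1 + 65)`` for the
second, ``64·128 + 128 + 128·1 + 1`` for the head.  At the published input
widths this gives 52169 (d = 1328) and 51465 (d = 1306).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ShapeError
from .graph_builder import (
    DEFAULT_INTERFACE_CUTOFF,
    DEFAULT_INTERNAL_CUTOFF,
    InterfaceGraph,
)

LEAKY_SLOPE = 0.2
BRANCHES = ("internal", "interface")


@dataclass
class NetworkSpec:
    """Layer widths and task of the scoring network."""

    input_dim: int
    conv1_out: int = 16
    conv2_out: int = 32
    head_hidden: int = 128
    head_out: int = 1
    edge_feature_dim: int = 1
    task: str = "regression"  # or "classification"

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.edge_feature_dim != 1:
            raise ValueError("only scalar edge features are supported")

    def parameter_count_closed_form(self) -> int:
        """The closed-form identity for the trainable parameter count."""
        conv = lambda cin, cout: cin * cout + 1 + (2 * cout + 1)
        per_branch = conv(self.input_dim, self.conv1_out) + conv(self.conv1_out, self.conv2_out)
        head = (2 * self.conv2_out * self.head_hidden + self.head_hidden
                + self.head_hidden * self.head_out + self.head_out)
        return 2 * per_branch + head


def init_weights(spec: NetworkSpec, seed: int = 0) -> dict[str, Tensor]:
    """Glorot-uniform initial weights for every tensor of the network."""
    rng = np.random.default_rng(seed)

    def glorot(shape):
        fan_in, fan_out = (shape[0], shape[1]) if len(shape) == 2 else (shape[0], 1)
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    weights: dict[str, Tensor] = {}
    for branch in BRANCHES:
        for layer, (cin, cout) in (("conv1", (spec.input_dim, spec.conv1_out)),
                                   ("conv2", (spec.conv1_out, spec.conv2_out))):
            weights[f"{branch}.{layer}.W"] = glorot((cin, cout))
            weights[f"{branch}.{layer}.V"] = glorot((1, 1))
            weights[f"{branch}.{layer}.att"] = glorot((2 * cout + 1, 1))
    weights["head.fc1.W"] = glorot((2 * spec.conv2_out, spec.head_hidden))
    weights["head.fc1.b"] = Tensor(np.zeros(spec.head_hidden), requires_grad=True)
    weights["head.fc2.W"] = glorot((spec.head_hidden, spec.head_out))
    weights["head.fc2.b"] = Tensor(np.zeros(spec.head_out), requires_grad=True)
    return weights


def count_trainable_parameters(spec: NetworkSpec) -> int:
    """Exact parameter count by enumerating every instantiated weight tensor."""
    return sum(w.size for w in init_weights(spec, seed=0).values())


def conv_forward(x: Tensor, src: np.ndarray, dst: np.ndarray, edge_feats: np.ndarray,
                 W: Tensor, V: Tensor, att: Tensor, n_nodes: int) -> Tensor:
    """One edge-aware attention convolution (see module docstring).

    ``src``/``dst`` are directed edges (messages flow src -> dst); callers
    expand stored undirected edges to both orientations.  A graph with no
    edges yields all-zero outputs.
    """
    if x.shape[1] != W.shape[0]:
        raise ShapeError(f"shape error: features {x.shape[1]} vs weights {W.shape[0]}")
    z = x @ W
    if len(src) == 0:
        return Tensor(np.zeros((n_nodes, W.shape[1])))
    e = Tensor(np.asarray(edge_feats, float).reshape(-1, 1)) @ V          # (m, 1)
    cat = ad.concat([ad.take(z, dst), ad.take(z, src), e], axis=1)        # [z_i ‖ z_j ‖ e']
    raw = ad.leaky_relu((cat @ att).reshape(-1), LEAKY_SLOPE)             # (m,)
    alpha = ad.segment_softmax(raw, dst, n_nodes)
    msg = alpha.reshape(-1, 1) * ad.take(z, src)
    return ad.relu(ad.segment_sum(msg, dst, n_nodes))


# --- community pooling -------------------------------------------------------

def community_assignment(n_nodes: int, internal_index: np.ndarray,
                         node_chains: np.ndarray, seed: int = 0) -> np.ndarray:
    """Louvain communities of the internal-edge graph, detected per chain.

    Nodes without internal edges become singleton clusters.  Cluster ids are
    renumbered by each cluster's smallest node index so the assignment is
    deterministic given the seed.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(map(tuple, np.asarray(internal_index).reshape(-1, 2)))
    clusters: list[set[int]] = []
    for chain in dict.fromkeys(node_chains):  # preserve chain order
        members = [i for i in range(n_nodes) if node_chains[i] == chain]
        sub = g.subgraph(members)
        clusters.extend(nx.community.louvain_communities(sub, seed=seed))
    clusters.sort(key=min)
    assign = np.empty(n_nodes, dtype=np.int64)
    for cid, members in enumerate(clusters):
        for i in members:
            assign[i] = cid
    return assign


def community_pool(node_feats: np.ndarray | Tensor, internal_index: np.ndarray,
                   node_chains: np.ndarray, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max-pool node features over Louvain communities of the internal graph.

    Returns ``(pooled_feats, pooled_internal_edges, assignment)`` where the
    pooled edge list carries the minimum raw member-edge distance between
    (or within) clusters.  Pooling has no trainable parameters.
    """
    x = node_feats.data if isinstance(node_feats, Tensor) else np.asarray(node_feats, float)
    assign = community_assignment(len(x), internal_index, node_chains, seed)
    k = int(assign.max()) + 1 if len(assign) else 0
    pooled = ad.segment_max(Tensor(x), assign, k).data
    pooled_edges = pool_edges(internal_index, None, assign)[0]
    return pooled, pooled_edges, assign


def pool_edges(index: np.ndarray, dist: np.ndarray | None, assign: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Coarsen an edge list onto cluster ids, keeping min raw distance.

    Intra-cluster edges survive as cluster self-loops so a community keeps
    its own aggregated signal as a neighbor in the next convolution.
    """
    index = np.asarray(index).reshape(-1, 2)
    if dist is None:
        dist = np.zeros((len(index), 2), dtype=np.float32)
    best: dict[tuple[int, int], np.ndarray] = {}
    for (i, j), row in zip(index, np.asarray(dist)):
        ci, cj = int(assign[i]), int(assign[j])
        key = (min(ci, cj), max(ci, cj))
        if key not in best or row[0] < best[key][0]:
            best[key] = row
    if not best:
        return (np.zeros((0, 2), dtype=np.int64), np.zeros((0, 2), dtype=np.float32))
    keys = sorted(best)
    return (np.array(keys, dtype=np.int64),
            np.array([best[k] for k in keys], dtype=np.float32))


# --- prepared graphs & batching ----------------------------------------------

@dataclass
class PreparedGraph:
    """Model-ready view of one :class:`InterfaceGraph`.

    Undirected edges are expanded to both orientations, the community
    assignment is fixed, and both branches' pooled edge lists are
    precomputed (they depend only on topology, not on features or weights).
    """

    graph_id: str
    x: np.ndarray                       # (n, d)
    edges: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]         # src, dst, feat
    assign: np.ndarray                  # (n,) cluster ids
    n_clusters: int
    pooled_edges: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # on cluster ids
    target: float | None
    complex_id: str | None = None


def _directed(index: np.ndarray, dist: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand undirected (i<j) edges to both directions; self-loops stay single."""
    index = np.asarray(index).reshape(-1, 2)
    dist = np.asarray(dist).reshape(-1, 2)
    loops = index[:, 0] == index[:, 1]
    fwd_src, fwd_dst = index[:, 0], index[:, 1]
    rev = ~loops
    src = np.concatenate([fwd_src, index[rev, 1]])
    dst = np.concatenate([fwd_dst, index[rev, 0]])
    feat = np.concatenate([dist[:, 1], dist[rev, 1]])  # normalized distance
    return src.astype(np.int64), dst.astype(np.int64), feat.astype(float)


def prepare_graph(g: InterfaceGraph, cluster_seed: int = 0,
                  internal_cutoff: float = DEFAULT_INTERNAL_CUTOFF,
                  interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> PreparedGraph:
    chains = g.node_chains()
    assign = community_assignment(g.n_nodes, g.internal_index, chains, cluster_seed)
    n_clusters = int(assign.max()) + 1 if g.n_nodes else 0

    edges = {"internal": _directed(g.internal_index, g.internal_dist),
             "interface": _directed(g.interface_index, g.interface_dist)}
    pooled = {}
    for branch, (index, dist, cutoff) in (
            ("internal", (g.internal_index, g.internal_dist, internal_cutoff)),
            ("interface", (g.interface_index, g.interface_dist, interface_cutoff))):
        p_index, p_dist = pool_edges(index, dist, assign)
        if len(p_index):
            p_dist = p_dist.copy()
            p_dist[:, 1] = np.minimum(p_dist[:, 0] / cutoff, 1.0)
        pooled[branch] = _directed(p_index, p_dist)
    return PreparedGraph(g.graph_id, np.asarray(g.node_features, float), edges,
                         assign, n_clusters, pooled, g.target, g.complex_id)


@dataclass
class Batch:
    """Several prepared graphs concatenated with index offsets."""

    x: np.ndarray
    edges: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    assign: np.ndarray          # node -> global cluster id
    pooled_edges: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    cluster_graph: np.ndarray   # global cluster id -> graph index
    n_nodes: int
    n_clusters: int
    n_graphs: int
    targets: np.ndarray | None
    graph_ids: list[str] = field(default_factory=list)


def collate(graphs: list[PreparedGraph]) -> Batch:
    xs, assigns, cluster_graph, gids = [], [], [], []
    edges = {b: ([], [], []) for b in BRANCHES}
    pooled = {b: ([], [], []) for b in BRANCHES}
    node_off = cluster_off = 0
    targets, have_targets = [], True
    for gi, g in enumerate(graphs):
        xs.append(g.x)
        assigns.append(g.assign + cluster_off)
        cluster_graph.append(np.full(g.n_clusters, gi, dtype=np.int64))
        gids.append(g.graph_id)
        for b in BRANCHES:
            src, dst, feat = g.edges[b]
            edges[b][0].append(src + node_off)
            edges[b][1].append(dst + node_off)
            edges[b][2].append(feat)
            psrc, pdst, pfeat = g.pooled_edges[b]
            pooled[b][0].append(psrc + cluster_off)
            pooled[b][1].append(pdst + cluster_off)
            pooled[b][2].append(pfeat)
        node_off += len(g.x)
        cluster_off += g.n_clusters
        if g.target is None:
            have_targets = False
        else:
            targets.append(g.target)

    def cat(parts):
        return (np.concatenate(parts[0]), np.concatenate(parts[1]),
                np.concatenate(parts[2]))

    return Batch(
        x=np.concatenate(xs, axis=0),
        edges={b: cat(edges[b]) for b in BRANCHES},
        assign=np.concatenate(assigns),
        pooled_edges={b: cat(pooled[b]) for b in BRANCHES},
        cluster_graph=np.concatenate(cluster_graph) if cluster_graph else np.zeros(0, np.int64),
        n_nodes=node_off, n_clusters=cluster_off, n_graphs=len(graphs),
        targets=np.array(targets) if have_targets else None,
        graph_ids=gids)


# --- forward -----------------------------------------------------------------

def network_forward(batch: Batch, weights: dict[str, Tensor], spec: NetworkSpec,
                    inference: bool = False) -> Tensor:
    """Raw scores for every graph in the batch, shape ``(n_graphs,)``.

    With ``inference=True`` the regression output is clamped to [0, 1] and
    the classification output passes through the logistic function.
    """
    if batch.x.shape[1] != spec.input_dim:
        raise ShapeError(
            f"shape error: batch features {batch.x.shape[1]} vs spec {spec.input_dim}")
    x = Tensor(batch.x)
    readouts = []
    for branch in BRANCHES:
        src, dst, feat = batch.edges[branch]
        h1 = conv_forward(x, src, dst, feat,
                          weights[f"{branch}.conv1.W"], weights[f"{branch}.conv1.V"],
                          weights[f"{branch}.conv1.att"], batch.n_nodes)
        p1 = ad.segment_max(h1, batch.assign, batch.n_clusters)
        psrc, pdst, pfeat = batch.pooled_edges[branch]
        h2 = conv_forward(p1, psrc, pdst, pfeat,
                          weights[f"{branch}.conv2.W"], weights[f"{branch}.conv2.V"],
                          weights[f"{branch}.conv2.att"], batch.n_clusters)
        readouts.append(ad.segment_mean(h2, batch.cluster_graph, batch.n_graphs))
    joint = ad.concat(readouts, axis=1)                                   # (G, 64)
    hidden = ad.relu(joint @ weights["head.fc1.W"]
                     + weights["head.fc1.b"].reshape(1, -1))
    out = (hidden @ weights["head.fc2.W"]
           + weights["head.fc2.b"].reshape(1, -1)).reshape(-1)
    if inference:
        if spec.task == "regression":
            return Tensor(np.clip(out.data, 0.0, 1.0))
        return ad.sigmoid(out)
    return out


def predict(graphs: list[InterfaceGraph] | list[PreparedGraph],
            weights: dict[str, Tensor], spec: NetworkSpec,
            cluster_seed: int = 0) -> np.ndarray:
    """Inference-mode scores for a list of graphs (regression: in [0, 1])."""
    prepared = [g if isinstance(g, PreparedGraph) else prepare_graph(g, cluster_seed)
                for g in graphs]
    batch = collate(prepared)
    return network_forward(batch, weights, spec, inference=True).data


# --- checkpoints -------------------------------------------------------------

def save_checkpoint(path, weights: dict[str, Tensor], spec: NetworkSpec,
                    feature_config_json: str | None = None) -> None:
    """Persist named weight tensors plus the network spec to HDF5."""
    import h5py
    import json
    with h5py.File(path, "w") as f:
        for name, w in weights.items():
            f.create_dataset(name.replace(".", "/"), data=w.data)
        f.attrs["spec"] = json.dumps(
            {k: getattr(spec, k) for k in ("input_dim", "conv1_out", "conv2_out",
                                           "head_hidden", "head_out",
                                           "edge_feature_dim", "task")})
        if feature_config_json is not None:
            f.attrs["feature_config"] = feature_config_json


def load_checkpoint(path, expect_feature_config_json: str | None = None
                    ) -> tuple[dict[str, Tensor], NetworkSpec, str | None]:
    import h5py
    import json
    with h5py.File(path, "r") as f:
        spec = NetworkSpec(**json.loads(f.attrs["spec"]))
        fc = str(f.attrs["feature_config"]) if "feature_config" in f.attrs else None
        if expect_feature_config_json is not None and fc is not None \
                and fc != expect_feature_config_json:
            raise ShapeError("shape error: checkpoint feature config mismatches container")
        weights = {}

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                weights[name.replace("/", ".")] = Tensor(obj[...], requires_grad=True)
        f.visititems(visit)
    return weights, spec, fc
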