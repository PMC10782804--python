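# Methods

## Problem and model

Given the 3D structure of a candidate two-chain protein–protein complex,
`dockgraph` predicts its quality relative to the (unseen) native structure:
the fraction of native cross-chain residue contacts (fnat ∈ [0, 1]) in
regression mode, or the probability that an interface is biological rather
than a crystal-packing artifact in classification mode.

### Interface residue graph

A residue is a node iff its minimum heavy-atom distance to any residue of
the partner chain is ≤ 8.5 Å. Two edge sets are kept separate because they
are processed by separate network branches:

* internal edges — same-chain node pairs at min heavy-atom distance ≤ 3.0 Å;
* interface edges — cross-chain node pairs at ≤ 8.5 Å.

Each undirected edge is stored once (i < j) with its raw distance and the
distance normalized linearly by its own cutoff (d/cutoff ∈ [0, 1]); the
model expands edges to both orientations at load time. The 3.0 Å internal
cutoff and the linear normalization are package conventions (both are
config knobs); contact-based definitions all operate on heavy atoms only.
Complexes whose chains share no residue pair within 8.5 Å have no graph;
batch builders skip them with a logged warning.

### Node features

Fixed column order, inactive blocks omitted:
`[type(20) | polarity(4) | bsa(1) | charge(1) | cons(1) | pssm_ic(1) |
pssm(20) | embedding(E)]`.

* **type** — one-hot over the 20 standard amino acids, alphabetical in the
  one-letter alphabet. Selenomethionine is kept and encoded as methionine;
  other non-standard residues are dropped at parse time with a warning.
* **polarity** — one-hot over {apolar: ACFGILMPVW, polar: NQSTYH,
  positive: KR, negative: DE}. The class table is explicit and overridable.
* **bsa** — buried surface area (Å²) of the residue:
  SASA(residue | own chain alone) − SASA(residue | complex), clipped at 0.
  SASA uses the Shrake–Rupley scheme with probe 1.4 Å, Bondi radii and 100
  golden-spiral sphere points by default (a 100-vs-1000-point refinement
  check in the tests bounds the quadrature error at ~5 %; the same point set
  is used in both evaluations so unoccluded residues get exactly 0).
* **charge** — formal side-chain charge: R, K → +1; D, E → −1; H → +0.1;
  others 0.
* **cons / pssm_ic / pssm** — from a whitespace-delimited per-chain profile
  (`pos wt 20 scores ic`); `cons` is the wild-type's own PSSM score. Scores
  are fed raw (integer log-odds as floats); a standardization hook exists
  but defaults off, keeping the feature pipeline bijective with the config.
* **embedding** — per-residue language-model vectors (width configurable,
  production 1280). Two providers share one contract (pure: same input →
  same output): an optional real ESM-2 provider (`fair-esm` extra,
  final-layer representations), and the default deterministic synthetic
  provider whose row for position *i* of a sequence is standard-normal noise
  from a generator seeded by `blake2b(seed|sequence|i)`.

Presets: `esm-pssm` (d = 1328), `esm` (1306), `pssm-only` (48), `minimal`
(26) at embedding width 1280; the node dimension always satisfies
`d = 20·type + 4·polarity + bsa + charge + 22·pssm_block + E·embedding`.

### Network

Two branches with identical shapes and independent weights — one message
passes over internal edges, one over interface edges:

    conv1 (d -> 16) -> community pooling -> conv2 (16 -> 32) -> mean read-out (32)

A convolution is a single-head, edge-aware attention layer:
`z_i = W x_i` (no bias), `e'_ij = V d_ij` (1×1, no bias),
`a_ij = LeakyReLU₀.₂(aᵀ[z_i ‖ z_j ‖ e'_ij])`, attention normalized by
softmax over each destination's in-neighbors, output
`h_i = ReLU(Σ_j α̂_ij z_j)`; an isolated node outputs the zero vector.

Community pooling detects Louvain (modularity-maximizing) communities on
the internal-edge graph, per chain, with a fixed seed; node features are
max-reduced within each community, and each branch's edge list is coarsened
onto communities keeping the minimum raw member-edge distance
(renormalized by the branch cutoff, capped at 1). Intra-community edges
survive as self-loops: communities absorb most internal edges by
construction, and dropping self-loops would leave the internal branch's
second convolution with a near-empty edge set.

The two 32-dim branch read-outs concatenate and feed a dense head
64 → 128 → 1; biases exist only in the head. Regression inference clamps
the output to [0, 1] (training uses the raw output); classification applies
the logistic function. Weights initialize with Glorot-uniform ranges from a
config seed. The trainable parameter count is exactly

    2·[(16 d + 1 + 33) + (16·32 + 1 + 65)] + (64·128 + 128) + (128 + 1)
      = 32 d + 9673,

i.e. 52 169 at d = 1328 and 51 465 at d = 1306; the enumerated count of the
instantiated network must equal this closed form (tested for
d ∈ {8, 26, 48, 1306, 1328}).

**Read-out choice.** Graph-level aggregation is parameter-free, so the
count identity does not pin it. We use the element-wise *mean* over each
branch's pooled nodes: the quantities a quality scorer must express —
interface size, composition, average packing — are averages over nodes,
and in recovery experiments with a planted smooth function of mean node
features a max read-out plateaued at held-out Pearson r ≈ 0.6–0.75 (it
cannot represent a graph average), while the mean read-out reaches
r ≈ 0.82–0.96 under identical conditions. Community pooling itself remains
max aggregation.

## Training

Defaults reproduce the published protocol: MSE loss on fnat (binary
cross-entropy on {0,1} labels for the interface-class task), Adam,
learning rate 0.001, batch size 128, 20 epochs, no early stopping, no
schedule, no weight decay (all exist as config hooks, off by default).
Splits and cross-validation folds are always drawn at **complex**
granularity — no complex contributes decoys to both sides — with
determinism from a config seed (per-epoch shuffles derive from
`(seed, epoch)`). The whole stack is pure numpy (a small reverse-mode
autodiff core ships with the package), so runs are bitwise reproducible on
one platform. For the regression task, per-fold AUCs binarize the stored
fnat target at 0.23, the DockQ near-native convention applied to fnat as
the container's single scalar label.

Two desk-scale presets exist for sanity checks on small synthetic sets:
`overfit` (lr 0.01, full batch) verifies the optimizer can memorize ten
graphs; `desk_scale` (lr 0.003, batch 32, weight decay 0.01) is tuned for
a few hundred graphs, where mild L2 keeps the ~10⁴-parameter network from
memorizing sequence-keyed embedding noise instead of learning shared
structure. Neither changes the published-protocol defaults.

## Quality metrics

* **native contacts** — cross-chain residue pairs at min heavy-atom
  distance ≤ 5 Å (CAPRI convention); fnat is the fraction of reference
  contacts retained, keyed by (chain, author number, insertion code);
  residues missing from one structure are ignored with a warning.
* **DockQ** = (fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²)) / 3.
  LRMSD: backbone (N, CA, C, O) RMSD of the ligand chain after
  superposing on the receptor chain (receptor = longer chain, tie → first).
  iRMSD: backbone RMSD over the reference's interface residues (any
  cross-chain heavy atom ≤ 10 Å) after superposing on those residues.
  Superposition is least-squares with reflection correction (via
  `scipy.spatial.transform.Rotation.align_vectors`). DockQ > 0.23 defines
  near-native.
* **interpolated ROC** — descending-score sweep with tied groups processed
  atomically; TPR linearly interpolated on a fixed FPR grid (step 0.001) —
  vertical segments are preserved by an infinitesimal tie-break so the
  grid-trapezoid AUC matches the exact rank-sum AUC within 1e-3 for inputs
  ≤ 500.
* **classification suite** — precision, recall, F1, MCC (0 with a warning
  when a confusion marginal is empty), accuracy at a score threshold
  (default 0.5), plus R² = 1 − SS_res/SS_tot and Pearson r on the raw
  continuous targets.
* **success rate** — per-complex ranks by descending score (ties broken
  lexicographically by graph id); the top-k success rate is the percentage
  of complexes with ≥ 1 near-native model in ranks 1..k; non-decreasing
  in k by construction.

## Synthetic data

The generator emulates the *shape* of a docking benchmark, not its
physics. A chain is a self-avoiding persistent random walk of Cα atoms
(3.8 Å steps, ≥ 4 Å non-adjacent separation) carrying N, C, O and one
pseudo side-chain atom per residue at idealized local offsets (consecutive
C–N ≈ 1.3 Å, so sequence neighbors form internal edges at the 3 Å cutoff).
Chain B starts 5 Å off a mid-chain residue of A and is launched tangent to
A's surface so the two chains share a broad contact patch; complexes are
regenerated (bounded retries on a derived seed) until they are clash-free
(≥ 2 Å) with ≥ 8 cross-chain contacts (≥ 3 is the guaranteed minimum).
Defaults: 30 residues per chain, residue identities uniform over the 20
amino acids. Everything is deterministic in (n, seed); PDB text emission
is byte-stable.

A decoy ladder of n rungs perturbs chain B rigidly with magnitude i/(n−1):
a rotation pivoted at the interface center (axis drawn once per ladder,
max 60°) plus a translation along the chain-separation axis (max 8 Å).
Pivoting at the interface makes contacts break progressively with angle,
so fnat decays monotonically along the ladder (seed-averaged Spearman
ρ(magnitude, fnat) ≈ −0.9) and the default ladder covers both DockQ
classes. Truth tables (fnat, DockQ, iRMSD, LRMSD per decoy) are computed
with this package's own quality metrics and stored as TSV next to the
graphs container.

The planted-signal benchmark replaces fnat targets by
`logistic((mean node BSA − 10 Å²) / 5 Å²)` — a smooth function of the mean
node-feature vector used for parameter-recovery tests. BSA carries the
signal because it behaves consistently across complexes; the synthetic
embeddings are sequence-keyed noise, so a signal planted in them cannot be
distinguished from per-complex memorization at desk scale. The center and
scale match the generator's mean-BSA distribution so targets span most of
(0, 1).

**What passing these tests shows — and does not.** The synthetic world
exercises every code path (parsing, graph construction, features, training,
metrics) with exact ground truth, and shows the optimizer recovers a known
feature–target dependence on held-out complexes. It does not emulate real
docking energetics, side-chain packing, sequence-profile statistics (toy
PSSMs are uniform random), or real embedding geometry; performance numbers
on it say nothing quantitative about benchmark sets of real docked models.

## Numerical choices and degenerate inputs

* float64 throughout the network; containers store features/distances as
  float32 (round-trips are bitwise at stored precision).
* Altloc resolution: highest occupancy, ties → first in file. Residue
  identity = (chain, author number, insertion code); no renumbering.
* Empty neighborhoods: attention convolutions output zero vectors for
  isolated nodes; empty segments in pooled reductions yield zeros.
* Max-pool gradients route to the first row attaining the maximum.
* Attention softmax is max-shifted per destination for stability;
  BCE uses the softplus form.
* Edge-distance normalization rejects d outside [0, cutoff]; pooled-edge
  normalized distances are capped at 1.
* `min_heavy_atom_distance` on an empty residue, one-class ROC labels,
  < 3 superposition points, a reference without contacts, and k-fold with
  k > #complexes all raise typed errors with stable messages.

## Known limitations

* Two-chain complexes only; no mmCIF; no nucleic acids; no hydrogens.
* BSA at 100 sphere points trades ~5 % quadrature error for speed.
* Louvain communities depend on a seed; a fixed default (0) makes graph
  preparation reproducible, but different seeds can coarsen differently.
* The synthetic embedding provider matches real embeddings only in scale,
  not in information content; models trained on synthetic benchmarks do
  not transfer to real structures.
* Training is CPU-bound numpy; it is sized for desk-scale experiments
  (hundreds of graphs), not for full benchmark training.
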