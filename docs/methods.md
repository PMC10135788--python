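# Methods

## Model

`scsignet` annotates single cells with a feed-forward classifier whose
first hidden layer is sparsified by signaling-pathway structure, and
rejects cells of unknown type with a density-based anomaly detector on the
classifier's latent encodings.

**Circuit decomposition.** A pathway is a directed graph over genes.
Effectors are the nodes with no descendants (out-degree 0), receptors the
nodes with no ascendants (in-degree 0); self-loops are ignored for both
degree computations, since a gene's self-regulation says nothing about its
position in the signal flow. The effector circuit `C_e` is `{e}` plus the
reverse-reachability closure of `e` — every node with a directed path to
`e`. This closure necessarily contains every receptor connected to `e` and
handles cycles without special cases: members of a cycle upstream of `e`
are simply included. A pathway in which every node lies on a cycle has no
effector and is rejected with an error naming the pathway, rather than
silently dropped. Whether nodes that reach the effector without being
reachable from any receptor belong in the circuit is a genuine modeling
choice; we take the superset reading (all reverse-reachable nodes), which
is the more conservative mask — it can only connect more genes, never
hide one.

Circuits are named `pathwayID:effectorGene`, which keeps column identifiers
globally unique when per-pathway indicator matrices are outer-joined on the
sorted union of their gene sets. Gene matching is exact, case-sensitive
string equality; harmonizing identifier schemes (symbol vs. Ensembl) is the
caller's job, because silent fuzzy matching corrupts the mask.

**Network.** Input: one node per gene, values scaled to [−1, 1]. First
hidden layer: one node per circuit, kernel `W_S = W ⊙ I_S` where `I_S` is
the binary gene × circuit indicator. Then a dense encoding layer (default
width 128), optionally one extra dense layer, and a softmax output over
cell types. Hidden activations are ReLU. Weights are drawn Glorot-uniform
with fans computed on the full (unmasked) kernel shape and masked
immediately after drawing; biases start at zero. Training minimizes mean
categorical cross-entropy (probability floor 1e−12) with Adam (lr 1e−3,
β = 0.9/0.999, ε = 1e−8), batch size 10, at most 100 epochs. The mask is
enforced by re-projection — masked gradient entries are zeroed and
`W ← W ⊙ I_S` is re-applied after every optimizer step — which keeps
masked weights exactly zero regardless of optimizer internals (Adam's
moment terms would otherwise leak mass into masked coordinates).

Training data are split 70/30 into learning and validation subsets,
stratified by cell type. The validation loss drives early stopping: when it
has not improved for 10 consecutive epochs, training stops and the
best-validation-loss weights are restored. Parameters are float32; all
randomness flows from a single integer seed, and single-threaded runs are
bit-reproducible.

**Unknown-cell rejection.** A Local Outlier Factor model (k = 20 neighbors,
the common choice in the LOF literature) is fitted in novelty mode on the
learning split's encodings, so reference points never score themselves —
scoring the training points against their own model understates their
outlierness and would produce an overconfident threshold. The similarity
score of a cell is its negative LOF (higher = denser neighborhood; a deep
inlier scores ≈ −1). Per cell type `c`, a Tukey lower fence
`w_c = q1 − 1.5 (q3 − q1)` is computed on the validation similarity scores
of that type, with quartiles by linear interpolation (the type-7 estimator,
the default in most numerical software; documented because the fence is
sensitive to the quantile rule at small n). The unassigned threshold is the
arithmetic mean of the per-type fences. At prediction, a cell scoring
strictly below the threshold is `unassigned` — a cell exactly at the fence
is kept, favoring assignment; otherwise it gets the softmax argmax label,
with ties broken toward the lowest class index. The novelty layer never
changes which known class the network would pick; it only withholds the
label.

**Preprocessing.** UMI counts are scaled per cell to a fixed sum of 10,000;
read counts are TPM-normalized (lengths in kb), degrading to CPM with a
warning when no lengths are available, as with droplet data where length
correction is meaningless. Then natural `log1p`, then a per-gene min–max
rescale to [−1, 1]. The rescaler is fitted on the learning split only and
applied with clipping to validation and query data: training-split
statistics define the network's input domain, and clipping prevents query
outliers from stretching it (and prevents validation information leaking
into the threshold). A gene constant in training maps to 0. Matrices carry
a stage tag (`counts` → `normalized` → `scaled`) and every transform checks
it, so re-application raises instead of silently compounding. Query cells
with zero total counts are kept as all-zero profiles at prediction time
(they score like any other cell); at fit time they are an error, since a
zero-count training cell is a upstream QC failure.

**Interpretation.** For each cell group, the mean ReLU activation of every
circuit node over the group's cells, ranked descending (ties broken by
circuit id). Ranking by activation rather than by kernel weights reflects
what the group's cells actually drive through the layer; a weight-flavored
alternative (mean activation × L2 norm of the node's input weights) is
exposed as `rank_by="weight"` since "highest-weighted nodes" admits both
readings.

## Synthetic data

The generator emulates the annotator's inputs end to end. Pathways are
layered random DAGs — a receptor layer (2–3 nodes), one or two intermediate
layers, an effector layer (2–4 nodes) — with each non-receptor node drawing
1–3 parents from the previous layer, so every node lies on a
receptor→effector path and decomposition always succeeds. Counts follow a
gamma-Poisson (negative binomial) model: variance = μ + φμ² with dispersion
φ, followed by Bernoulli dropout — the standard droplet scRNA-seq noise
assumptions. Each known cell type activates a disjoint set of circuits;
genes inside an active circuit have their NB mean multiplied by the effect
size. The unknown population activates only circuits no known type uses.

Default study design: 10 pathways of 8–20 nodes, 3 known types × 300
cells, 150 unknown cells, 3 active circuits per type, effect 5×, baseline
mean 2, dispersion 0.5, dropout 0.3. Presets: `S1` (closed set, no unknown
cells), `S2` (S1 plus the unknown population), `S3_r` (S1 with one type
undersampled to r ∈ {0.2, 0.4, 0.6}). Sizes were chosen so a full fit runs
in under a second and a 2-repeat × 5-fold cross-validation in seconds,
while keeping per-gene signal-to-noise in the range where classification
is good but not trivial.

What the generator does *not* emulate: real marker-gene structure,
gene–gene correlation beyond shared circuit membership, library-size
variation, batch effects, or ambient RNA. Passing tests on this data show
the pipeline's mechanics and the recoverability of planted circuit-level
structure; they do not certify performance on real tissues.

## Known limitations

* **Open-set sensitivity depends on where the unknowns differ.** In the
  `S2` design the unknown population differs from the training types only
  through circuits that carry no class signal. Cross-entropy training has
  no incentive to preserve those directions, so the encodings compress
  exactly the information the detector would need, and at the default
  noise levels (dispersion 0.5, dropout 0.3) the fence threshold rejects
  only a minority of unknown cells — run `scripts/acceptance.py` for the
  measured rates — even though a supervised probe on the preprocessed
  genes separates the populations almost perfectly. Unknown populations
  that are globally divergent (the common real-world case, e.g. malignant
  cells in an immune reference) are far easier for this detector than
  this deliberately subtle synthetic case. The false-positive side is
  well-behaved: only a few percent of held-out known cells are rejected.
* The mean-of-fences threshold weights every type equally, so one broad
  similarity distribution can raise the threshold above tighter types'
  fences and inflate their rejection rate slightly.
* One node = one gene in pathway graphs; gene-group nodes (complexes)
  must be expanded upstream.
* No GPU path and no minibatch parallelism: the implementation targets
  masks of a few thousand genes by ~1–2 thousand circuits, where NumPy on
  one core trains in minutes.
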