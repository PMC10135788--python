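# scsignet

Signaling-circuit-informed sparse neural annotation of single cells, with
rejection of unknown cell types.

## What it does

Supervised cell-type classifiers for scRNA-seq are fast and accurate, but
two problems limit them in practice: their latent features are hard to
interpret, and they silently force every query cell into one of the trained
labels even when the cell is of a type the reference never contained.
`scsignet` addresses both by wiring prior knowledge of cell signaling into
the classifier and bolting an anomaly detector onto its latent space.

1. **Effector circuits.** Each directed signaling pathway graph is
   decomposed into *effector circuits*: for every effector gene `e` (a node
   with no descendants), the circuit `C_e` contains `e` plus every gene
   with a directed path to `e` — in particular all receptors (nodes with no
   ascendants) wired to it. Circuit membership across all pathways forms a
   binary gene × circuit indicator matrix `I_S`.
2. **Masked network.** A feed-forward classifier whose first hidden layer
   has one node per circuit and kernel `W_S = W ⊙ I_S` (Hadamard product),
   so a circuit node only sees its own genes. ReLU activations, a dense
   encoding layer, and a softmax head over cell types; trained with Adam on
   categorical cross-entropy, with a stratified 70/30 learning/validation
   split driving early stopping. The mask is re-applied after every
   optimizer step, so masked weights are exactly zero at all times.
3. **Unknown-cell rejection.** A Local Outlier Factor (LOF) model is fitted
   on the *learning* split's encodings; the similarity score of any cell is
   its negative LOF against that reference. Per cell type `c`, a Tukey
   lower fence `w_c = q1 − 1.5 (q3 − q1)` of the *validation* similarity
   scores is computed, and the unassigned threshold is the mean of the
   fences. A query scoring strictly below the threshold is labeled
   `unassigned`; otherwise it receives the softmax argmax label.
4. **Interpretation.** The signaling layer's activations are a per-circuit
   functional readout; averaging them per (observed or predicted) cell type
   ranks the circuits that characterize each population.

The preprocessing chain is per-cell count normalization (fixed-sum 10,000
for UMI data, TPM for read counts), `log1p`, and a per-gene min–max rescale
to [−1, 1] fitted on the learning split only.

## Worked example

A full round-trip on simulated data (pathways, counts and labels are
written in the same formats real runs consume — edge-list TSVs, Matrix
Market counts with sidecars, a two-column label TSV):

```sh
scsignet simulate --scenario S1 --out-dir data --seed 3
# simulated 900 cells x 154 genes, 28 circuits from 10 pathways -> data

scsignet build-mask --pathways-dir data/pathways --out-prefix mask --gmt circuits.gmt
# indicator: 154 genes x 28 circuits (226 nonzeros)

scsignet train --expression data/counts.mtx --labels data/labels.tsv \
         --mask-prefix mask --model-dir model --seed 3
# trained on 900 cells (3 types); threshold -1.2020; saved to model [0.4s]

scsignet predict --expression data/counts.mtx --model-dir model --out pred.tsv
# annotated 900 cells (32 unassigned) -> pred.tsv
```

`pred.tsv` has one row per cell: `cell_id`, `predicted_label` (a trained
type or `unassigned`), `similarity` (negative LOF; higher = more like the
reference, a deep inlier sits near −1), and one `p_<type>` probability
column per class. The threshold printed by `train` is the mean of the
per-type validation fences: cells whose similarity falls below it are not
assigned any label. `scsignet interpret` writes the top-k circuit table per
cell group, and `scsignet evaluate` runs repeated stratified k-fold
cross-validation and writes aggregate metrics and confusion matrices.

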