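# Methods

## Problem setting

Automated cell-type annotation tools for scRNA-seq disagree with each other,
and each disagrees with ground truth in its own way. `sclabelprop` treats an
ensemble of such tools as a noisy labeling source: cells on which the tools
reach a simple majority receive a *confident* label, and those labels are
spread to the remaining cells by a semi-supervised graph network trained
transductively on the dataset itself. The trained network is then explained
with DeepLIFT, giving per-gene importance scores per cell type.

## Preprocessing

Given a cells × genes count matrix:

1. remove cells expressing fewer than 200 genes (count > 0), **then** remove
   genes expressed in fewer than 3 of the surviving cells — the order
   matters and is fixed (cells first);
2. normalize each cell to 10,000 counts and apply the natural `log1p`:
   `x_i = log(1 + 10^4 · x_i / Σ_j x_ij)`; zero counts map exactly to zero;
3. project to at most 500 principal components (mean-centering only; gene
   variances are not rescaled — an open choice we resolve toward the plain
   Seurat-style recipe). The fitted components and gene means are retained
   on the embedding, because attribution later chains multipliers back
   through this linear map.

Retained cell/gene index maps are returned so externally produced
prediction tables can be subset consistently.

## Consensus voting

For `t` tools and `C` types, votes `E ∈ N^{n×C}` count the tools predicting
each type per cell (abstentions contribute nothing). With
`m_i = max(E_i) / Σ(E_i)` — the plurality share of the votes *actually
cast* — a cell is confidently labeled when `m_i ≥ 0.51` and marked `-1`
otherwise; cells with no cast votes are unconfident. Dividing by the cast
votes rather than the tool count is the literal reading of the confidence
formula; the stricter tool-count denominator is available behind
`denominator="tools"`. At any threshold above 0.5 the argmax is unique, so
no tie-break is needed. The *max consensus* baseline takes the strict
plurality and returns "unknown" on ties (including all-zero rows); every
confidently labeled cell necessarily receives the same label from max
consensus, which the tests assert by exhaustive enumeration of all 126
compositions of ≤ 5 votes over 4 types.

## EdgeConv label propagation

The network operates on the PCA coordinates. Each of `l` EdgeConv layers
builds a k-nearest-neighbor graph (Euclidean, exact ties toward the lower
node index, self-loops included) on its **input** features — the PCA
coordinates at layer 1, the previous layer's output at deeper layers (a
dynamic graph; a static mode reusing the first graph exists for ablation).
The layer computes one message per edge,

    out_i = Σ_{j ∈ N(i)} SiLU( θ · concat(x_i, x_j − x_i) + b ),

with the self-loop contributing `concat(x_i, 0)`. Widths chain
`d → e → … → e`, followed by a linear map `e → C` to class scores. Each
EdgeConv block is a single affine map plus SiLU — the minimal DGCNN-style
block; deeper per-edge MLPs were a design option we declined for parsimony.

Training: 150 epochs of Adam at learning rate 1e-4, no schedule, no weight
decay, no early stopping. Every epoch shuffles **all** cells into
minibatches of size `b` (a trailing batch of ≤ k cells merges into its
predecessor so every batch can host a k-NN graph); cross-entropy is
computed only on in-batch cells that are confident and in the training
mask, with one optimizer step per batch; batches without any labeled cell
are skipped. Unconfident cells therefore shape every graph but never touch
the loss, and the training log records exactly which cells' labels entered
the loss so tests can assert the validation mask was never consumed.

Implementation note: the network, its backpropagation and Adam are written
directly in NumPy. The model is small (tens of thousands of parameters) and
CPU-bound either way, and a transparent forward pass is what makes the
attribution below exact rather than approximate.

Hyperparameter selection masks a stratified 20% of the confident cells as
validation (per-class rounding; classes with < 2 confident cells stay whole
in training), trains each grid point once, and scores it against the
*consensus* labels on the validation mask — ground truth is never consulted.
The default grid is `b ∈ {20, 50} × k ∈ {2, 5, 10} × l ∈ {1, 2, 3} ×
e ∈ {25, 40}`, ties toward the earlier grid entry. Final reporting trains
five random initializations (seeds `base … base+4`) of the chosen
configuration on all confident cells and reports mean ± sd accuracy.
Inference scores cells in deterministic sequential batches (whole dataset
when ≤ 5000 cells, else batches of 1000) with the same dynamic-kNN forward;
argmax ties go to the lower class index.

## Neighbor-majority baseline

The nonparametric comparator works on the same PCA coordinates: cells are
partitioned once into seeded batches of ≤ 1000, a k-NN graph (no self-loop)
is built per batch once — geometry never changes, unlike the GCN's dynamic
graphs — and each epoch every still-unlabeled cell synchronously adopts the
strict plurality label of its labeled neighbors; ties defer to a later
epoch. Stopping strategies: one round; iterate until < 5% of labels change
(change measured over all cells, `-1 → label` counts); iterate until all
cells are labeled or 50 epochs. `k` and the strategy are selected on the
same validation mask as the GCN grid by hiding the validation cells and
scoring their recovery; cells still unlabeled at stopping count as
incorrect. A brute-force reimplementation that recomputes all-pairs
distances every epoch serves as the equivalence oracle in the tests.

## DeepLIFT (Rescale) attribution

Attribution explains `score(x) − score(x₀)` for each cell's predicted
class, where the reference `x₀` is the all-zero matrix in *normalized*
expression space (normalizing a zero count row is undefined, so the zeros
are declared post-normalization) pushed through the frozen pipeline: the
same gene means, the same PCA map, and the very k-NN graphs recorded from
the actual input's forward pass — graph construction is discrete structure
and is not attributed. Multipliers propagate backward by the Rescale rule:
affine operations contribute their weights; SiLU units contribute
`(SiLU(z) − SiLU(z₀)) / (z − z₀)`, falling back to the analytic derivative
when `|Δz| < 1e-7`. Because the PCA map is linear, gene-space multipliers
are PC-space multipliers times the component matrix, and the attribution of
gene g in cell i is its multiplier times `x_ig`.

Messages flowing along edges attribute part of a cell's score to its
neighbors' genes, so summation-to-delta holds exactly per batch (and per
cell in a self-loop-only configuration); both identities, the reduction to
gradient × input under identity activations, and agreement with an
independent dense multiplier-matrix implementation are asserted in the
tests at 1e-4 relative tolerance.

Per-type importance is the mean attribution over the type's cells, then the
absolute value, then division of the row by its standard deviation (rows
with zero sd are left unscaled and flagged; types with no cells are
omitted). Rankings break ties alphabetically for determinism. Marker
augmentation walks each type's ranking and appends the first `n_add = 3`
genes absent from that type's existing list, preserving the original
markers first.

## Synthetic data

The simulator produces the study conditions for everything above: 1000
cells evenly split into 4 groups over 2000 genes (desk scale). Base gene
means are Gamma(shape 0.6, rate 0.3); each group marks a `de_prob = 0.1`
fraction of genes as differentially expressed with multiplicative factors
`exp(N(0, de_facscale))` — the random sign of the log-factor gives up- and
down-regulation, and `de_facscale` is the separability dial (0.4 ≈
transcriptionally similar types, 2.0 ≈ well separated). Cell means are the
group-adjusted base means normalized to proportions and scaled to a
log-normal library size (median 5000, sdlog 0.2); counts are Poisson with
gamma overdispersion at BCV 0.2. An optional reference dataset re-draws
counts under independent per-gene batch factors (sdlog 0.5). Markers are 5
genes sampled from each group's top-10 most up-regulated.

What it does *not* emulate: dropout/zero inflation beyond gamma-Poisson,
mean-trended dispersion, trajectories, doublets, or tool errors that
correlate with expression geometry. The simulated tools (five, accuracies
0.75–0.68, 5% abstention, uniform confusion — calibrated once so that ~85%
of cells reach a 0.51 majority) err independently of where a cell sits in
PC space, which is kinder to the neighbor-majority baseline than real tools
are; passing tests therefore demonstrate the machinery and its relative
ordering under these conditions, not absolute accuracies on tissue data.

## Numerical and design choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; training, splitting, batching and simulation
  are bit-for-bit reproducible, and pipeline reruns with the same config and
  seed produce byte-identical reports (the checksum manifest excludes only
  the config echo, which records the output path).
- kNN distance ties break toward the lower node index; argmax ties toward
  the lower class index; gene-importance ties alphabetically; grid and
  sweep ties toward the earlier entry.
- Initialization is uniform Kaiming-style fan-in scaling seeded with the
  config seed, which also drives batch shuffling and the validation split.
- Degenerate inputs fail loudly: empty filters, zero-count rows before
  normalization, empty validation masks, batches smaller than k+1, labels
  outside the vocabulary.
- Test and acceptance problem sizes: unit tests run on toys (≤ 200 cells);
  the end-to-end properties run the full study conditions (1000 cells,
  2000 genes, 150 epochs, five seeds per regime); the pipeline determinism
  check uses 400 cells / 40 epochs, since determinism does not depend on
  problem size.

## Known limitations

- The EdgeConv block's hidden architecture is the minimal single-affine
  variant; richer per-edge MLPs may behave differently.
- Whether validation accuracy should be computed with minibatched or
  full-graph inference is ambiguous; we use the deterministic inference
  batching everywhere.
- The per-cell summation-to-delta identity is intentionally relaxed to a
  per-batch identity when k > 0 (neighbor attribution is assigned to the
  neighbor's genes).
- With extreme DE factors the compositional library-size normalization
  couples genes: a group's strongly up-regulated gene depresses the
  group's proportions for all other genes, so "up-regulated in the design"
  does not guarantee "higher observed mean" gene by gene.
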