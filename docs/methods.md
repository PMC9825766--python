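# Methods

## Problem and data model

A pcHi-C experiment reports candidate promoter-centered interactions as
pairs of genomic anchors with a per-interaction false-discovery rate.
`loopnet` turns these summaries into supervised training data and learns a
per-tissue classifier for PE and PP interactions. Coordinates are 0-based
half-open (BED convention) throughout; anchors are standardized to
[mid − 1000, mid + 1000) with integer-floor midpoints. Interactions are kept
only if intra-chromosomal with midpoint distance ≤ 1 Mb; the bound is
inclusive (only strictly longer-range pairs are removed). Anchors whose 2-kb
window would leave the chromosome are dropped with a logged warning rather
than padded, and duplicate standardized anchor pairs are collapsed keeping
the smallest FDR.

Labeling uses two FDR cutoffs: FDR < 0.1 → positive, FDR > 0.5 → negative
pool, in-between candidates discarded. Both cutoffs are configurable (the
stricter regimes 0.05/0.5, 0.1/0.7 and 0.1/0.9 are supported directly), as
is the negative:positive ratio (1:1 default, 1:5 for unbalanced designs).

## GC-matched negative sampling

The negative pool is usually much larger than the positive set and may
differ in base composition. Negatives are drawn so their GC histogram
matches the positives': bin edges are the deciles of the positive GC
distribution, each bin's quota is the (ratio-scaled) positive count in that
bin, sampling within bins is uniform without replacement, and any bin
shortfall is filled with the unused pool candidates nearest in GC to that
bin's positive mean. The procedure is deterministic given a seed. GC is
computed on the concatenated pair of standardized anchor sequences;
per-anchor matching is possible by supplying per-anchor GC values instead.
(The choice of pairwise GC, and Jaccard as the similarity denominator below,
are package decisions where several readings are defensible.)

## Features

* **S**: one-hot sequence per anchor, rows A/C/G/T, ambiguous bases encoded
  as all-zero rows; forward strand only; 2000 × 4 per anchor.
* **R**: coverage is converted to counts-per-million (value · 10⁶ /
  library size, with the library size taken as the track's genome-wide
  total), then averaged in 1000-bp windows slid by 50 bp: 21 values per
  anchor per track. Mean (not sum) aggregation makes constant tracks fixed
  points of the windowing, which gives a trivial oracle for testing.
* **D**: |mid₁ − mid₂| / 10⁶ ∈ [0, 1] given the distance filter. A log10
  variant can be substituted via the `scale_distance` hook.
* **aux**: per-base conservation or DNA-shape tracks are consumed as given
  (never computed from sequence) and windowed exactly like R; uncovered
  bases are imputed as 0 and counted in the log.

## Architecture

Each conv layer is convolution → batch normalization → PReLU (slope
initialized at 0.25) → dropout. A dense block has four such layers with
filters (64, 32, 16, 16) and dilation rates (1, 2, 3, 4). The two anchors
enter as input channels (sequence input 2000 × 4 × 2; read input
21 × M × 2), which keeps the printed kernel geometry valid. The sequence
block's first layer uses kernel 20 × 4, stride 10 × 4, valid padding
(2000 × 4 → 199 × 1); the read block's first layer uses kernel 3 × 1,
stride 1 × 1, valid padding (21 × M → 19 × M). Later in-block layers are
stride 1 × 1 with 'same' padding so their outputs concatenate.

Because the first layer changes the spatial geometry, the raw block input
cannot join later concatenations; dense connectivity therefore runs over
layer outputs: layer k ≥ 2 consumes concat(y₁ … y₍ₖ₋₁₎) and the block emits
concat(y₁ … y₄) with 128 channels. The channel arithmetic (in-channels of
layer k = Σ filters of layers < k) is exposed by `describe()` and asserted
in tests.

For fusion, each modality's output map (H × W × 128) is flattened to an
(H·W) × 128 single-channel grid; modality grids are stacked row-wise and a
4 × 4 convolution with stride 4 × 4 (64 filters by default) runs on the
stack, followed by global average pooling. The pooled vector is the fused
feature representation; D (when active) is concatenated to it just before
the classifier (one 256-unit ReLU layer, then a sigmoid unit). The exact
fusion reshape is not uniquely determined by the architecture's verbal
description; this grid layout is the package's documented choice, as is
channel-stacking of the two anchors (length-wise stacking is a plausible
alternative that would change the first-layer geometry).

Any nonempty subset of {S, R, D, aux} is a valid ablation; the D-only model
reduces to the classifier on the scalar distance. The aux path reuses the
read-path geometry.

The network, including backpropagation for strided/dilated convolution,
batch normalization, PReLU, dropout and the dense-block concatenation
routing, is implemented in NumPy inside the package (`loopnet.nn`) and is
verified against central finite differences in float64 (`tests/
test_network.py::test_gradients_match_finite_differences`).

## Training

Binary cross-entropy (computed from logits for stability), Adam with
initial learning rate 10⁻⁴ and exponential decay per epoch (factor 0.96
default; both configurable), batch size 64, at most 200 epochs, early
stopping when validation loss has not decreased for 5 consecutive epochs,
best-validation weights restored. Splits: 70/15/15
(train/validation/test) per target tissue; 85/15 for pretraining. The split
rounding rule gives every part but the last the floor of its share.

* **Base**: one network per tissue.
* **Multi-task** ("shared knowledge transfer"): the shared extractor is
  pretrained on interactions pooled from the source tissues and then
  *frozen*; a private extractor of identical architecture plus the
  classifier are trained on the target, the classifier consuming
  [common ‖ private] (+ D). Freezing the shared extractor during target
  training is the package's reading of shared/private disentanglement —
  joint fine-tuning of the shared part is the natural alternative.
* **Transfer**: extractor weights are copied from the pretrained network, a
  fresh classifier is attached, and all layers are fine-tuned.

The pretraining classifier head is discarded; only extractor weights
transfer. Source tissues can be all-others, a named group minus the target,
or the top-k (default 5) tissues by gene-overlap similarity.

At the problem sizes used in the tests and the acceptance script
(300–3000 interactions per tissue) the package uses a scaled-down
configuration: filters (16, 8, 8, 8), 16 fusion filters, a 64-unit hidden
layer, learning rate 10⁻³ and 12–30 epochs. These are study-size choices,
made once for the synthetic regime, where the defaults above describe the
full-size protocol.

## Evaluation

AUC is computed by the Mann–Whitney midrank formula (ties count ½) and is
tested for exact agreement with an O(n²) pairwise oracle and with
scikit-learn. AUPRC is average precision (step-wise, no interpolation).
The experiment design re-splits each tissue's data 10 times with distinct
seeds and re-trains per repeat; "mAUC" is the median AUC over the repeats.
Methods are ranked per tissue by mAUC (average ranks on ties) and compared
across tissues with a two-sided Wilcoxon rank-sum test — exact enumeration
for group sizes ≤ 10 without ties, tie-corrected normal approximation
otherwise (delegated to scipy). Cross-prediction evaluates a model trained
on one interaction type against the other type without weight updates.

## Tissue similarity

Each anchor of each positive interaction is assigned the gene with the
nearest TSS to the anchor midpoint (TSS = BED start on '+', end − 1 on '−';
ties broken by smaller coordinate, then lexicographic id). A tissue's gene
set is the union over both anchors of its positives; similarity between two
tissues is the Jaccard overlap of their gene sets (0 when both are empty).

## Synthetic study generator

`loopnet.simulate` produces every input format the pipeline consumes. The
genome is iid random sequence with configurable GC (0.5 default). Candidate
interactions draw anchor midpoints uniformly, raw anchor lengths from
{2, 3, 4, 6} kb (so standardization does real work), and distances from
uniform ranges: positives 5–300 kb and negatives 200–950 kb in `shifted`
mode, a single shared 5–950 kb range in `matched` mode (removing distance
as a label signal, the design used when negatives are distance-matched).
FDRs are Uniform(0, 0.1) for planted positives and Uniform(0.5, 1) for
negatives, so FDR labeling recovers the planted truth exactly; truth labels
are also emitted separately so dataset construction is directly assertable.

Positive anchors carry planted sequence signal: with probability
`p_shared` (0.8) an anchor receives the shared 10-mer motif — identical
across tissues, the "common feature" the shared paradigms can import — and
with probability `p_private` (0.3) a tissue-specific 10-mer. Motifs are
written at `motif_copies` = 8 random offsets within the anchor window
(shared sites in the left kilobase, private in the right, so they never
overwrite each other). The copy number emulates homotypic binding-site
clusters; a single site per anchor is too sparse a signal to be separated
from memorization noise at desk-scale sample sizes under global average
pooling. Coverage tracks are Poisson background drawn per 50-bp bin,
multiplied by `enrichment_fold` (5.0) in bins overlapping the tissue's
positive anchors.

What the generator does *not* emulate: mappability and repeat structure,
realistic motif degeneracy (planted sites are exact), correlated histone
marks, distance-decay contact frequency, or calibrated FDRs. Passing tests
therefore show that the pipeline, architecture and training paradigms
behave as designed on data with known structure — not that the model
reaches any particular accuracy on real pcHi-C data.

Because positive anchors are placed independently, a negative anchor can
overlap a planted motif region; at the default densities roughly 10–15% of
negatives acquire weak positive-like signal, which lowers the attainable
AUC ceiling slightly and is accepted as label noise.

## Numerical and degenerate-input conventions

Probabilities from `predict` are clipped to (10⁻¹², 1 − 10⁻¹²). Batch
normalization uses ε = 10⁻⁵ and momentum 0.1. Model save/load round-trips
weights (float32) and running statistics exactly; two builds from the same
config seed are bit-identical. Empty feature subsets, single-class label
vectors, pools smaller than the requested negative count, a target tissue
inside its own pretraining pool, and mismatched extractor/bundle shapes all
raise informative errors rather than degrading silently.

## Known limitations

* The NumPy training loop is single-threaded and CPU-bound; it is sized for
  thousands, not hundreds of thousands, of interactions.
* Strand information is ignored (both anchors are read on the forward
  strand).
* The fusion-grid layout and the frozen-shared multi-task variant are
  documented package choices among several defensible designs (see above).
* bigWig input requires pyBigWig; bedGraph is the text-native path.
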