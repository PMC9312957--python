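# Methods

## The problem

scATAC-seq peak calls are coarse: sparsity at the single-cell level smears
the signal so that called peaks run to 500-1,000 bp, while the functional
core of a cis-regulatory element — a transcription-factor binding site — is
~10 bp. This package trains a multi-label sequence classifier on
cell-type-resolved peak calls, then exploits the trained network twice: its
class-activation structure localizes the sub-regions of each peak that drive
the accessibility prediction (condensing peaks to candidate functional
cores), and its input sensitivity quantifies how strongly a single-nucleotide
variant shifts the predicted accessibility of its host peak, per cell type.

## Classifier

Each peak is standardized to a 1,000-bp window centered on the peak midpoint
(clamped at chromosome ends; the summit position is not available from a
plain BED, so the midpoint serves as its proxy) and one-hot encoded as a
4 x 1000 binary matrix with row order A, G, C, T. An ambiguous base becomes
an all-zero column. The label is an m-hot vector over the m cell types; a
peak accessible in two cell types carries two ones. Negative examples are
drawn from the reference genome itself: every chromosome is tiled into
consecutive 1,000-bp fragments starting at coordinate 0, any fragment
overlapping a peak by at least 1 bp is discarded, and 10,000 of the survivors
are sampled uniformly without replacement and labeled all-zero. The pool of
peaks and negatives is split 8:1:1 into train/validation/test *before*
strand doubling, so a window and its reverse complement always land in the
same partition. Both strands then enter training as independent examples.

The network is four convolutional layers (kernel width 9) with ReLU, with a
width-4 max pool and dropout after conv2 and conv4, followed by a dense layer
of 925 units (ReLU, dropout) and a final dense layer with one sigmoid unit
per cell type. Pooling uses floor division for odd lengths. For a 1,000-bp
input the spatial length of the feature map entering the dense head is

    floor((floor((1000 - 2*8) / 4) - 2*8) / 4) = 57,

i.e. 1000 -> 992 -> 984 -> 246 -> 238 -> 230 -> 57. The kernel/pool pair
(9, 4) is the unique small-integer choice that yields exactly 57, and the
flattened 320 x 57 feature map feeds the 925-unit dense layer. Default
channel widths are (160, 160, 320, 320); dropout rates are 0.2 after each
pool and 0.5 before the final dense layer.

Training minimizes binary cross-entropy averaged over batch and classes with
Adam at learning rate 5e-4 and batch size 64. Weights are initialized from
U(-1/sqrt(fan_in), +1/sqrt(fan_in)). Validation loss is evaluated after
every epoch; the returned model is the parameter snapshot with the lowest
validation loss, and training stops early after `patience` epochs without
improvement (defaults: 100 epochs maximum, patience 5). At inference the
probability for a window is the element-wise maximum over its forward and
reverse-complement predictions ("strand-max"). A transfer-learning warm
start loads all shape-compatible layers from a checkpoint trained on other
accessibility data (e.g. bulk ATAC-seq); a final layer with a different
cell-type count stays freshly initialized, and the load reports a manifest
of loaded vs. reinitialized parameters.

The network and its training loop are implemented directly in NumPy
(`scepilock.nn`): im2col convolution through BLAS matrix products, explicit
backward passes for every layer, and Adam. Explicit backpropagation is also
what the saliency module differentiates, so the same code path serves
training and interpretation, and the whole stack is deterministic for a
fixed seed in single-threaded execution.

## Peak refinement (Grad-CAM)

For a predicted-positive (window, cell type) pair, let A^k be the K
activation maps of the last convolutional stage (post-ReLU, post-pool;
length Z = 57) and y_c the pre-sigmoid class score. The per-filter
importance weights are the spatially averaged gradients

    alpha_k = (1/Z) * sum_i  d y_c / d A^k_i,

and the localization map is raw = ReLU(sum_k alpha_k A^k), a length-Z
vector. The gradient is taken at the logit rather than the probability:
through the sigmoid the gradient is scaled by p(1-p), which vanishes for
confidently predicted peaks and would suppress exactly the maps of interest.
Maps are computed on whichever strand wins the strand-max prediction
(positivity threshold 0.5) and reported on the forward genome frame
(reverse-strand maps are flipped).

The raw map is upscaled to per-base resolution piecewise-constantly: base j
gets raw[floor(j*Z/L)], so bins cover 17 or 18 bp (mean 1000/57 ≈ 17.5,
about one TF binding site). Key regions are the bins whose raw score
reaches the 80th percentile (linear interpolation between order statistics)
of all per-bin scores pooled across the predicted-positive peaks of that
cell type; adjacent kept bins merge into maximal intervals, and the
remainder of each window is its non-key complement. Two refinements of the
bare percentile rule:

* a bin whose raw score is exactly 0 is never key — rectification has
  already judged it to carry no positive evidence, and when most of a cell
  type's map mass is rectified away the pooled 80th percentile is itself 0,
  which would otherwise promote entire peaks;
* ties at a positive cutoff keep all tied bins.

Per-peak (rather than pooled) cutoffs are available behind a flag. The
export step writes one BED per cell type (score column: mean raw score of
the region rescaled to [0, 1000]) plus a condensation summary with
per-cell-type rows, an "overall" row (cell-type totals summed), and a
"union" row (key regions and peak windows deduplicated across cell types —
the union ratio can exceed the per-cell-type 20% because different cell
types keep different bins of a shared peak).

To test whether key regions capture functional sequence, mean per-base
scores of an external track (e.g. cross-species conservation) are compared
between key and non-key regions with a one-sided Welch t-test
(alternative: key > non-key). Bases missing from the track read as 0; the
fraction of regions with mean exactly 0 is reported alongside. If both
region sets are constant and equal the test is defined as p = 0.5.

## Variant impact

A single-nucleotide variant is scored inside the standardized window of its
host peak (when several windows contain it, the peak with the nearest
midpoint wins, ties to the leftmost; a variant outside all peaks is skipped
unless a variant-centered window is requested). The wild-type and mutant
windows differ at exactly one base; both are scored with strand-max
probabilities, and the delta score per cell type is |p_WT - p_mut|. Variants
are ranked by their maximum delta over cell types, ties broken by
coordinate. Only SNVs are supported; indels are rejected on ingest, and the
claimed reference allele is verified against the genome. VCF positions
(1-based) are converted to the internal 0-based convention on ingest.

## Synthetic benchmark

The generator builds a fully self-contained study so that every module is
testable without downloads. A background genome is drawn i.i.d. with a
global GC fraction (default 0.41, human-like), default 4 chromosomes of
6 Mb. Non-overlapping 1,000-bp peaks sit on a grid with >= 1,000-bp gaps —
the gaps guarantee non-overlap by construction and leave every other genome
tile eligible for negative sampling. Each cell type owns one distinct
high-information PWM motif (width 10 bp, the eukaryotic mean TF-site length;
consensus probability 0.97 per column; consensus sequences pairwise Hamming
distance >= 5). Each positive peak carries two sampled instances per
labeled cell type, placed uniformly at random, non-overlapping, strictly
inside the peak; 20% of peaks gain a second cell type (shared multi-hot
labels). Labels derive exactly from placements: label[c] = 1 iff the peak
holds an instance of a motif assigned to c. The default scale is 2,000
positive peaks per cell type and 3 cell types — 6,000 peaks plus 10,000
negatives.

Disrupting variants substitute, at a PWM column with information content
above 1 bit whose planted base is the consensus, the lowest-probability base
of that column (ties resolved in A < C < G < T order) — a substitution that
measurably changes the motif's log-odds. Neutral variants fall inside peaks
but at least 2 motif-widths away from any placement. The score track is
Normal(0.8, sd) over planted motif bases and Normal(0.2, sd) elsewhere,
clipped to [0, 1] — a conservation-like functionality proxy with known
effect direction.

What the generator does not emulate: read-level data, fragment files, peak
callers and their boundary noise, sequence composition beyond global GC,
overlapping peaks, motif grammar (cooperativity, spacing constraints), or
label noise. Passing the end-to-end suite therefore demonstrates that the
implementation learns and localizes planted signal correctly under clean
conditions; it does not certify performance on real scATAC-seq data.

## Test-suite problem sizes

The end-to-end suite trains a width-reduced configuration — conv channels
(16, 16, 32, 32), first dense layer 128 — at the full 1,000-bp input length
on the full default study (6,000 peaks, 10,000 negatives), with a 10-epoch
cap (patience 3, seed 1). These widths are a deliberate desk-scale choice:
three planted motifs need far fewer than 320 filters, and the structural
constants of the default architecture (57, 925) are asserted separately on
the default configuration. With this setup the held-out per-cell-type AUROC
exceeds 0.9 and AUPR exceeds 0.7 within the epoch cap; key regions at the
80th percentile recover over 60% of planted motif bases with >2-fold
enrichment over non-key regions; and the max delta score separates
disrupting from neutral variants with AUROC >= 0.8. Unit tests use a
miniature study (40-kb chromosomes, 200-bp peaks) and a correspondingly
small network.

## Numerical choices and edge cases

* float32 parameters and activations; losses and probabilities accumulate in
  float64.
* Sigmoid and binary cross-entropy use numerically stable formulations
  (no exp overflow for large |logit|).
* Max pooling drops the remainder positions of a length not divisible by
  the pool width (floor semantics), matching the printed 230/4 -> 57.
* Determinism: every random draw (genome, placements, splits, negative
  sampling, init, shuffling, dropout) flows from an explicit integer seed
  through numpy Generators; identical seeds give identical histories in
  single-threaded execution.
* Degenerate inputs: single-class metric inputs raise (AUROC/AUPR) or
  return the documented convention (F1 = 0 with no predicted positives);
  empty region sets, empty map sets, and empty test sets raise with
  explicit messages rather than returning silent defaults.
* Identical-coordinate peaks from different per-cell-type BEDs merge into
  one multi-hot row; overlapping-but-unequal peaks stay separate rows.

## Known limitations

* The conv channel widths, kernel/pool sizes and dropout rates of the
  original architecture are not printed in the sources available here; the
  chosen values reproduce the published structural constraints (feature map
  57, dense 925) but may differ from the original in detail.
* Whether negatives were sampled before or after the train/val/test split
  in the original pipeline is unstated; here they are pooled before
  splitting so all partitions contain negatives.
* Training on CPU in NumPy is practical at desk scale (reduced widths,
  ~10^4 examples) but not at the scale of full atlases; the architecture is
  identical, only throughput differs.
* Grad-CAM resolution is bounded by the 17.5-bp bin width; sub-bin
  localization is out of scope, as are Grad-CAM++/FullGrad variants.
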