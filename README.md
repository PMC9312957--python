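# scepilock

Cell-type-specific analysis of scATAC-seq peaks from DNA sequence alone:

1. **Multi-label accessibility classifier** — a convolutional network maps a
   1,000-bp one-hot DNA window to per-cell-type accessibility probabilities.
2. **Peak refinement (weakly supervised object detection)** — Grad-CAM over
   the last convolutional layer condenses coarse peaks to the short "key
   regions" that drive each positive prediction, sharpening fuzzy peak
   boundaries toward the underlying cis-regulatory elements.
3. **Variant impact quantification** — for a single-nucleotide variant, the
   absolute change in predicted accessibility between the wild-type and
   mutant window (the *delta score*) ranks variants by cell-type-specific
   regulatory impact.

It is aimed at groups who have cell-type-resolved peak calls (e.g. from
SnapATAC or ArchR) plus a reference genome, and want finer functional
localization and variant prioritization without any additional assays.

## Model

A peak, standardized to a 1,000-bp window and one-hot encoded (4 × 1000,
rows A, G, C, T), passes through four convolutional layers (kernel 9, ReLU)
with width-4 max-pooling and dropout after the second and fourth, then a
925-unit dense layer and a final dense layer with one sigmoid unit per cell
type. The spatial length of the last convolutional feature map is

    Z = floor((floor((1000 − 2·8)/4) − 2·8)/4) = 57.

Training: binary cross-entropy, Adam (lr 5·10⁻⁴, batch 64), both strands as
independent examples, early stopping on validation loss; 10,000 peak-free
reference-genome fragments serve as all-negative examples. Inference takes
the element-wise max over the forward and reverse-complement predictions.

For a predicted-positive (peak, cell type) pair, Grad-CAM weights the last
conv feature maps A^k by spatially averaged class-score gradients
α_k = (1/Z)·Σᵢ ∂y_c/∂A^k_i and rectifies the weighted sum,
ReLU(Σ_k α_k A^k) — a 57-bin map upscaled to per-base resolution
(17–18 bp/bin). Bins at or above the 80th percentile of the pooled scores
of a cell type form its key regions. The delta score of an SNV is
|p_WT − p_mut| per cell type, scored inside the host peak's window.

The network, backpropagation, and Adam are implemented in NumPy
(`scepilock.nn`); file I/O uses pyfaidx and plain-text BED/TSV/bedGraph;
metrics come from scikit-learn. See `docs/methods.md` for assumptions,
parameter choices, and limitations.

## Worked example

The package ships a synthetic benchmark generator whose ground truth (motif
placements, labels, disrupting vs. neutral variants) is known exactly. The
snippet below generates the default study — 3 cell types with one distinct
10-bp motif each, 2,000 positive 1,000-bp peaks per type on a 4 × 6 Mb
genome, 10,000 reference negatives — trains a width-reduced classifier, and
scores 200 variants (~15 min on one CPU):

```python
from scepilock import (SyntheticSpec, generate_dataset, load_genome,
                       ModelConfig, build_model, train, evaluate_model,
                       load_variants, score_variants, rank_variants)
from scepilock import seqdata as sd

spec = SyntheticSpec(seed=1)
ds = generate_dataset(spec, "quickstart", n_disrupting=100, n_neutral=100)

genome = load_genome(ds.fasta)
examples = sd.encode_peaks(ds.truth.peaks, ds.truth.peak_labels, genome, length=1000)
negatives = sd.sample_negatives(genome, [e.source for e in examples],
                                n=10000, length=1000, seed=1)
examples += sd.encode_negatives(negatives, genome, spec.n_cell_types)
split = sd.split_dataset(examples, seed=1)

config = ModelConfig(n_cell_types=3, conv_channels=(16, 16, 32, 32),
                     dense1_units=128, seed=1, max_epochs=10, patience=3)
model, history = train(build_model(config), split)

report = evaluate_model(model, split.test, spec.cell_type_names)
print(report.to_dataframe().to_string(index=False))

variants = load_variants(ds.variant_tsv, genome)
records = score_variants(model, variants, ds.truth.peaks, genome)
print(rank_variants(records, spec.cell_type_names).head(5).to_string(index=False))
```

Output (variant table truncated to the top five rows, annotated with the
generator's truth column):

```
trained for 10 epochs; best validation loss 0.0695
cell_type    auroc     aupr       f1  n_pos  n_neg
      ct0 0.998720 0.992942 0.957684  225.0 1375.0
      ct1 0.980861 0.922818 0.820388  227.0 1373.0
      ct2 0.998609 0.992400 0.950226  221.0 1379.0
    micro 0.994467 0.972730 0.911742  673.0 4127.0
    macro 0.992730 0.969387 0.909433    NaN    NaN
chrom     pos ref alt  max_delta argmax_cell_type      truth
 chr2 4002074   G   A   0.812334              ct0 disrupting
 chr4  338798   G   A   0.758568              ct0 disrupting
 chr3 2782177   G   A   0.685669              ct0 disrupting
 chr4 1800460   A   C   0.652445              ct2 disrupting
 chr3 1454767   A   C   0.635516              ct2 disrupting
```

Reading: each cell type's peaks are recognized on held-out windows with
AUROC ≥ 0.9; AUPR is lower where positives are scarcer relative to the
pooled negatives. In the variant ranking, planted motif-disrupting alleles
rise to the top with delta scores orders of magnitude above the neutral
background, and the cell type attaining the maximum delta identifies whose
regulatory element the variant breaks.

The same pipeline is scriptable end to end:

```sh
scepilock synth --seed 1 --out ds/
scepilock prepare --fasta ds/genome.fa --bed ds/peaks.bed --labels ds/labels.tsv \
                  --neg-n 10000 --length 1000 --seed 1 --out prep/
scepilock train --data prep/ --out run/ --conv-channels 16,16,32,32 --dense1 128 --seed 1
scepilock evaluate --ckpt run/model.ckpt.npz --data prep/
scepilock refine --ckpt run/model.ckpt.npz --bed ds/peaks.bed --fasta ds/genome.fa \
                 --percentile 80 --out-dir refined/
scepilock score-variants --ckpt run/model.ckpt.npz --vcf ds/variants.tsv \
                 --bed ds/peaks.bed --fasta ds/genome.fa --out ranked.tsv
```

`scepilock refine` writes per-cell-type key-region BEDs plus a condensation
summary; `scepilock conservation` compares an external per-base score track
(e.g. PhastCons in bedGraph form) between key and non-key regions with a
one-sided Welch t-test.

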