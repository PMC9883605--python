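# Methods

## Problem and approach

Nanopore selective sequencing ("adaptive sampling") decides in real time,
from the first fraction of a read's raw current signal, whether the strand
should continue to be sequenced or be ejected from the pore. `squigclass`
implements the signal-space approach to that decision: a one-dimensional
residual convolutional network classifies a short normalized prefix of the
squiggle as target vs. non-target species, with no basecalling and no
reference alignment.

The package covers the complete workflow — SLOW5 signal I/O, robust
preprocessing, a pore-model squiggle simulator, the classifier, a
cross-validated training protocol, and read-level evaluation — so that the
whole pipeline can be exercised end to end on synthetic data with
controlled ground truth.

## Preprocessing

A read qualifies if it has at least `min_read_samples` raw samples
(default 4500). Qualified reads are processed in this order:

1. **Trim** the first `trim_samples` samples (default 1500, ≈160 bases at
   ~9 samples/base) — a deliberate overestimate of the adaptor/stall/
   barcode region.
2. **Convert to picoamperes**: `pA = (range / digitisation) × (raw + offset)`.
3. **Segment.** Training uses `segments_per_read_train` (default 4)
   windows of `segment_length` samples (default 3000) whose starts are
   drawn independently and uniformly (with replacement — overlaps are
   allowed) from the trimmed signal; inference uses exactly the first
   window, the only part available in a real-time setting.
4. **Normalize** each segment with the MAD-based modified z-score
   `z_i = 0.6745 (x_i − median(x)) / MAD(x)`,
   `MAD = median(|x_i − median(x)|)`. The even-length median is the
   midpoint of the two central order statistics. Segments with `MAD = 0`
   (constant signal) cannot be normalized and are discarded and counted.
5. **Clamp outliers** to `±mad_threshold` (3, 5 or 10 modified-z units;
   default 5). Clamping (winsorizing) rather than deleting samples keeps
   the fixed segment length the network requires; the threshold is applied
   on the modified-z scale, the natural units of the score.

Normalization is per segment, not per read, so each classifier input is
scale- and offset-free regardless of drift along the read.

## Classifier

Input: one normalized segment (length `input_length`). Architecture:

- 1D convolution, 20 channels, kernel 19, stride 3 → batch norm → ReLU →
  max pool (2);
- `n_stages` (default 4) residual stages of `blocks_per_stage` (default 2)
  bottleneck blocks (1–k–1 convolution triplet, k = 3), channel widths
  `floor(20 × 1.5^stage)` = 20→30→45→67, stride-2 downsampling at the
  entry of every stage after the first, 1×1 projection skips where shape
  changes;
- dropout (rate 0.10) after every activation inside the blocks; inactive
  at inference;
- global mean pooling → a single sigmoid unit.

The loss is binary cross-entropy (the canonical likelihood for a single
sigmoid output). The network, its backward pass, and Adam are implemented
directly in NumPy (float32, im2col convolutions on BLAS matmuls), which
keeps the whole package importable on a plain scientific-Python stack and
fast enough on one CPU at the problem sizes used here; gradients are
verified against finite differences in the test suite.

The decision threshold is fixed at probability ≥ 0.5 → target species
(the symmetric choice for a balanced binary problem); exactly 0.5 calls
positive.

## Training protocol

Splits are stratified by class and made at read level; all segments of a
read stay on one side of any boundary, preventing sibling-segment leakage.
Two split styles are provided: a single 7:3 train/validation split, and
stratified k-fold cross-validation (default 5 folds) in which the
validation sets partition the reads. The cross-validation harness uses the
classic disjoint folds; 7:3 is the single-split path.

Each fold trains for at most `max_epochs` (default 200) on batches of
`batch_reads` reads' worth of segments (default 1000 reads → 4000
segments; smaller effective batches are configurable for CPU runs and are
recorded in the run log). Validation binary accuracy is the monitored
metric for both schedules: the learning rate is multiplied by `lr_factor`
(0.5) after `lr_patience_epochs` (20) epochs without an improvement
greater than 1e−4, and training stops after `early_stop_patience_epochs`
(30) such epochs. The weights of the best-validation epoch are restored
when the fold finishes, and the fold with the highest best-validation
accuracy is selected (ties → lowest fold index). The monitored metric is
computed on validation data (the natural regularization target; the
protocol leaves this open).

Adam's initial step size is configurable (`initial_lr`); the full-size
default is 1e−3. The scaled CPU-size network trains with 3e−3 — chosen
via the capacity check below, where 1e−3 converges too slowly for a
200-step budget on so small a network.

## Squiggle simulator

The simulator generates reads from a k-mer pore model so the pipeline can
be validated with controlled ground truth:

- **Pore model** (`k = 6`): one expected level per k-mer in the 60–130 pA
  band. Levels follow a random position-weight construction — each k-mer
  position contributes a base-specific random offset, plus a small
  k-mer-specific residual, affinely mapped onto the band. This mirrors the
  approximately additive chemistry of real pores and, because successive
  k-mers overlap in k−1 bases, gives every model a characteristic
  level-transition texture. That texture is what survives per-segment
  normalization and lets a classifier separate species; tables with fully
  independent per-k-mer levels contain no such learnable structure.
- **Signal**: per k-mer, `max(1, round(N(dwell_mean, dwell_sd)))` samples
  at `level + N(0, level_sd)`; defaults dwell 9 ± 1 samples/base
  (450 bases/s at 4 kHz ≈ 8–10 samples/base) and level noise 1.5 pA.
- **Adaptor**: a 1500-sample block of broadband noise (mean 70 pA,
  sd 15 pA), distinct from genomic signal, so trimming is meaningful.
- **Digitization**: `raw = round(pA × digitisation / range − offset)`
  clipped to int16 — the exact inverse of the pA conversion, so noise-free
  signals are recovered within half an ADC step (±0.085 pA at the default
  1400 pA / 8192 levels).

Defaults (400-base reads → ≈1500 + 3600 samples) make simulated reads
qualify under the 4500-sample rule.

What the simulator does **not** emulate: event warping and skipped/stuck
events, long-range current drift, homopolymer dwell behaviour, real
flowcell noise spectra, or genuine genome k-mer composition biases
(simulated genomes are uniform random). Passing the synthetic controls
therefore demonstrates that the pipeline's machinery is correct and that
the classifier learns signal texture, not that any particular real-data
accuracy will be achieved.

## Control experiments and problem sizes

Two end-to-end controls anchor the package (sizes chosen to keep a full
run in minutes on one CPU):

- **Separable control**: two species from distinct random 6-mer pore
  models and genomes; 1000 training + 500 test reads per class;
  1000-sample segments; a scaled 2-stage network; 5-fold CV with at most
  20 epochs per fold (early stopping patience 3, LR patience 2, batches
  of 64 reads). The best fold must classify held-out reads — first
  segment only — at ≥ 90% accuracy.
- **Null control**: identical in every respect except both "species" share
  one genome and one pore model. Test accuracy must stay inside
  0.5 ± 3σ of a fair binomial at n = 1000, i.e. [0.43, 0.57]: any
  systematic deviation would indicate leakage or a bookkeeping bug.

`scripts/acceptance.py` reruns both controls from scratch and reports the
measured quantities.

## Numerical choices and edge cases

- Even-length median: midpoint of the central order statistics; MAD = 0
  segments are discarded and counted.
- Plateau/early-stop improvement threshold: 1e−4 in binary accuracy.
- Batch norm: momentum 0.9, eps 1e−5; inference uses running statistics,
  so inference is deterministic and batch-size equivariant.
- Dropout uses an explicitly reseedable generator; training runs are
  bit-reproducible given the config seed.
- Weight init: He-normal, seeded; identical seeds give identical models.
- Capacity sanity check: the scaled 2-stage network must overfit 64
  labelled segments to ≥ 95% training accuracy within 200 steps.
- The SLOW5 dialect is the ASCII single-read-group subset with the
  canonical primary columns; labels travel in a separate two-column
  manifest since SLOW5 has no label field. Signal indexing is 0-based
  with half-open intervals.

## Known limitations

- No FAST5/POD5/BLOW5 input; no live ReadUntil integration.
- Binary (two-species) classification only.
- The NumPy engine targets CPU-scale problems; it is not intended for
  full-size (20000 reads × 3000 samples, 200 epochs) training runs, for
  which a GPU deep-learning framework would be the right tool.
- Intra-species discrimination (e.g. chromosome vs chromosome) is known
  to be much harder for this architecture family and is out of scope.
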