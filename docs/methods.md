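# Methods

## Signal model and normalization

A nanopore read is a raw current trace plus an event table assigning each
basecalled nucleotide a contiguous slice of samples. Event segmentation is
an input (an event-aware basecaller upstream, or the simulator); squigstr
neither basecalls nor resquiggles.

Per read, samples are normalized as `(x − median) / (1.4826 · MAD)` and
clipped to [−5, 5]. Median/MAD was chosen over mean/sd because single-read
traces carry heavy-tailed artifacts (stalls, current spikes) that would
otherwise set the scale; the 1.4826 factor makes the scale estimate
consistent with a normal sd, and the clip range matches the 50-bin image
height below. The (center, scale) pair is recorded in the event table for
audit. A constant trace (MAD = 0) yields all zeros plus a degenerate flag
rather than an error, so a single broken read cannot abort a run.

Each event's normalized samples are histogrammed into 50 half-open bins of
width 0.2 over [−5, 5] (values exactly at +5 fall in the top bin); the
per-bin *fraction* of the event's samples is scaled by 255 and rounded.
Fraction scaling (rather than per-event max-rescaling) preserves dwell
spread: an event whose samples scatter over many bins is visibly dimmer per
bin than a tight one. Rounding means a bin-vector sums to 255 ± a small
rounding slack (at most one count per occupied bin).

## Repeat images

For unit length R, the bin-vectors of events `j … j+R−1` form the center
channel of the image anchored at base `j`; the windows at `j−R` and `j+R`
are the other two channels (50 × R × 3, uint8). The window is
**anchor-leading**: an R-wide window has no center base for even R, so the
anchor is defined as the window's first base, isolated in one function
(`build_image`) should the convention need flipping. Anchors whose neighbor
windows would fall off the read produce no image; at prediction time such
bases default to *not in repeat*, which is correct whenever the read's ends
lie in flanking sequence and conservative (an undercount) when a read ends
inside a repeat.

## Training labels

Given primary alignments (secondary/supplementary ignored) and refined STR
regions of the motif group being trained, each read base gets one of four
labels or is excluded:

- aligned (match or mismatch) inside a group region → *in repeat*;
- a 1-bp insertion whose two aligned neighbors sit inside a region →
  *insertion in repeat*; the read base following a 1-bp deletion inside a
  region → *deletion in repeat* (multi-bp deletions mark the flanking base
  the same way; insertions longer than 1 bp are excluded, as only the 1-bp
  classes are defined);
- clipped bases, large insertions, bases aligned to regions of *other*
  motif groups, and aligned bases closer than 1.5× a region's length to
  that region → excluded (`NO_LABEL`); the margin keeps ambiguous
  near-boundary windows out of both training and evaluation;
- everything else → *not in repeat*.

Exclusion applies to training and evaluation only; prediction classifies
every base. Consequence for data design: reads must extend beyond 1.5× the
region length into the flanks, or no *not-in-repeat* examples exist
(`generate_training_set` warns in that case).

Per chromosome, at most 100 regions are sampled (seeded) when more are
available; unsampled same-group regions are excluded rather than labeled
*not in repeat*, so they cannot poison the negative class. Class balance is
handled by sampling, not loss weights: non-repeat images are split into
⌈N_nonrep/N_rep⌉ disjoint chunks of roughly repeat-set size, and each
training epoch consumes the full repeat set plus one chunk, cycling.

## Classifier

Architecture (heights act on the 50 signal bins; widths on the R unit
positions): conv 32×(4×1) same-padded + ReLU, max-pool 2×1 with ceiling,
conv 64×(3×1) same-padded + ReLU, max-pool 2×1 ceiling, flatten, dense 512
+ ReLU, dense 4 + softmax. The height trace is 50 → 25 → 13 regardless of
R, so the flatten width is 13·64·R = 832·R. Filters are one column wide on
purpose: convolution mixes signal bins within a unit position, never across
positions, until the dense layers — the cross-channel self-similarity is
what the input encoding already expresses. Ceiling pooling is forced by the
25 → 13 trace; max (not average) pooling and a ReLU 512-unit layer without
dropout are choices where the design was open, kept isolated in
`ModelSpec`/`ConvNet`.

The network is implemented directly on NumPy arrays (im2col-style strided
convolution, explicit backprop, Adam). At these sizes (≤ 5 × 10⁶
parameters dominated by the first dense layer) single-threaded BLAS matmuls
train thousands of images per second; determinism follows from seeding the
single `Generator` that drives initialization, validation split and batch
shuffling.

Training: Adam on softmax cross-entropy, batch size 512, learning rate
0.005 before epoch n, 0.001 before 10n, 0.0005 before 100n, 0.0001 after
(n = 5 by default, n = 1 supported); the schedule is interpreted in epochs,
with a config switch (`schedule_unit="step"`) to reinterpret it in
optimizer steps. Default budget is 500 epochs; the test suite and the
packaged examples use 5–30 epochs on a few thousand images, which the
separable synthetic regime saturates. Ties in the output argmax resolve to
the lowest class index. Single-class training sets are rejected; a
non-finite loss aborts with epoch/step diagnostics.

## Per-read counting and genotyping

Per read, maximal runs of in-repeat classes (*in repeat* plus both indel
classes, with no length adjustment — a knob `indel_adjust` is reserved) are
kept when ≥ 3R bases long; kept runs separated by < R bases are merged, gap
included (`count_merged_gaps` flips this). Merged length / R rounded
half-up is the read's count; with several segments overlapping a locus the
longest wins. Counts below 3 units never arise by construction.

Allele calling fits a 1-D Gaussian mixture to the integer counts for each
component number k in 3…7 (clipped to the number of distinct values, and
floored at the distinct count when fewer than 3 — one distinct value skips
the fit entirely and reports that value). Each k is fitted 20 times from
seeded `random_from_data` initializations and the single fit with the best
(lowest) AIC wins. Two numerical choices matter here:

- **Variance floor.** `reg_covar = 0.25` (component sd ≥ 0.5 repeat units).
  Counts are integers and per-read counting noise has sd ≳ 1, so a
  component narrower than half a unit models discretization, not an allele;
  without the floor, AIC rewards k = 6–7 fits that place near-delta
  components on single histogram bins, splitting a true cluster so its
  rounded mean drifts and the minor allele's weight fragments.
- **Peak aggregation.** Components whose means lie within the
  heterozygosity separation (2 counts) are merged into peaks
  (weight-averaged mean, summed weight) before ranking, because the mixture
  may still shard one allele across components. Allele 1 is the
  highest-weight peak's rounded mean; allele 2 is the next peak down the
  ranking with weight ≥ 0.2 and mean separation ≥ 2. Supporting reads per
  allele are those within ±2 counts of the allele.

The reporting thresholds (min 10 reads, weight 0.2, separation 2, support
window ±2) are explicit config defaults standing in for peak-calling rules
the upstream literature leaves unspecified. Below 10 reads only the
histogram is returned with a low-coverage flag — mixture fits on a handful
of integers are not trustworthy.

Telomere mode drops the requirement of a second flank: per read anchored at
the subtelomeric flank with mapping quality ≥ 20, the count is the merged
in-repeat run extending from the anchor toward the read end, divided by R.
Reads ending inside the repeat contribute lower bounds; the cohort summary
is the median and sd across reads, the median being robust to exactly those
truncated reads.

## Motif groups and region refinement

A motif group is the closure of a unit under cyclic rotation and reverse
complement, represented by its lexicographic minimum; all 60 non-homopolymer
trinucleotides fall into 10 groups of 6. Homopolymers are excluded
throughout (unit length ≥ 2): self-similarity between adjacent "units" is
vacuous at period 1 and the pore's dwell ambiguity makes homopolymer length
unreadable from this representation.

Tandem-repeat-finder records are refined by semi-global alignment (match
+1, mismatch −1, gap −1, free end gaps on both sequences) of the record
sequence against its unit tiled to the record length plus one unit of
slack. Because free end gaps make boundary matches score-ambiguous, the
traceback's matched positions are completed by marking every query position
consistent with a phase the traceback realized; blocks separated by ≤ R
unmatched bases (config knob) are then merged, and blocks ≥ 3R (≥ 12 for
dinucleotides) become regions. An opt-in filter drops regions within 500 bp
of another region, for benchmark designs where adjacent similar repeats
cannot be unambiguously merged.

## Simulator

The simulator realizes the premise that a k-mer's current is a
distribution: a pore model maps each k-mer (k = 6 default) to a Gaussian
(mean, sd), means uniform in [−4, 4] and sds in [0.15, 0.5]; each event
draws its dwell from 3 + a geometric tail (mean 9 samples — the ~450 Hz
sample / ~50 bases·s⁻¹ translocation regime), then that many Normal
samples. Signals are generated directly in normalized units; a device-unit
mode (offset 100, scale 20) exercises the normalizer. Locus datasets draw
each read's allele by fraction, jitter its count (Normal, rounded, floor
3), optionally inject 1-bp indels inside the array and truncate reads
inside it, and emit exact-by-construction SAM records against the
flank+array reference (the repeat-length difference becomes a single indel
at the array's 3′ end), so tests stay hermetic; a FASTQ export exists for
running a real aligner externally.

The **separable preset** places the unit-interior k-mers' means in
[2.5, 4] and all other k-mers in [−4, 0.5], guaranteeing ≥ 2 normalized
units of separation. This is the regime the packaged accuracy figures refer
to: it makes the 4-class problem nearly separable (a logistic regression on
raw pixels exceeds 0.9, which the tests check as an oracle), so passing
tests demonstrate that the chain — binning, windows, labels, training,
merging, mixture — is wired correctly, *not* that real pores, where repeat
and flank k-mer currents overlap and basecalled events misalign, would
yield the same accuracy. The simulator also omits homopolymer compression,
systematic miscalls and modified-base effects.

## Problem sizes in the packaged checks

The test suite and examples run one simulated locus of 100 reads (alleles
18/40, 60/40 read fractions, count jitter sd 1, 120 bp flanks), ≤ 5,000
training images and 30 epochs; genotype-recovery checks use 20 seeded
mixtures of ≥ 40 reads with allele gaps ≥ 4; the telomere check uses 20
reads of an 800 ± 100-copy hexamer array. These sizes saturate the
separable regime's accuracy; larger runs change runtimes, not conclusions,
in this regime.

## Known limitations

- Boundary anchors bias merged runs slightly outward (windows straddling a
  repeat edge are classified from mixed evidence the margin rule excluded
  from training), so per-read counts and called alleles can sit +1 from
  truth; the ±1 tolerance in the packaged checks reflects this.
- Two arrays separated by a few bases merge into one call by design (gap
  < R); the tool does not detect internal polymorphisms or mutations.
- Homopolymer repeats are out of scope; unit lengths above 6 need a newly
  trained model.
- Real-data performance depends on event segmentation quality from the
  upstream basecaller, which the simulator idealizes (exactly one event per
  base).
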