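# Methods

This note documents the model, the conventions and the deliberate design
choices behind `epig4nn`, in the order the pipeline runs.

## Coordinates and formats

All internal coordinates are 0-based half-open, the native convention of
BED and bedGraph; FASTA access converts on fetch. Sequences are upper-cased
on load and every character outside {A,C,G,T} collapses to N; N matches no
motif grammar and encodes as the zero vector, so unknown bases are inert
everywhere downstream. Signal tracks are piecewise-constant run lists per
chromosome; any position query is defined, returning 0 where no run covers
it. bigWig is out of scope — signal enters as bedGraph text.

## PQS discovery

Three motif grammars are scanned (see README for the patterns). Scanning
uses conventional regex semantics — leftmost match wins, quantifiers are
greedy, matches of one class never overlap each other — because census
numbers are only reproducible once these semantics are pinned down. The
minus strand is scanned on the reverse complement and coordinates are
mapped back to forward-strand intervals; G-counts are taken on the motif
strand, where the G-runs live, and every motif must carry ≥ 12 guanines
(three stacked tetrads).

Redundancy across classes and strands is then resolved 5'-first: per
chromosome, motifs are swept in ascending start order and one survives only
if it starts at least one nucleotide after the end of the last survivor
(`start ≥ kept_end + 1` on half-open intervals, so directly adjacent motifs
are *not* separated). Overlapping sequences are never merged. Where two
classes match at the same start, precedence is canonical > bulged >
irregular, then '+' before '−', then the longer match; the precedence order
is a fixed convention of this implementation (each motif must carry exactly
one class, and nothing in the grammar makes the tie self-resolving). The
sweep interpretation means that in a chain A–B–C where B overlaps both
neighbours but A and C are separated, A and C both survive; a stricter
one-survivor-per-connected-component reading would drop C. The sweep is
what "first encountered from the 5' end" describes operationally, and the
test oracle replays the same rule independently.

## Scoring, labeling, encoding

A motif's experimental score is the per-base mean of the G4 bedGraph over
its interval, uncovered positions counting as 0; motifs on chromosomes
without signal score exactly 0. Labels come from an upper-percentile cut:
the threshold is the (100 − p)-th percentile of all scores and the
comparison is strict, so ties at the threshold are negative. With the
heavily zero-inflated score distributions of G4 ChIP data this selects the
top-ranked nonzero scores; because percentile ranks are invariant under
monotone transforms, normalizing scores before labeling changes nothing and
is therefore optional.

Tracks are min–max normalized to [0,1] genome-wide with uncovered positions
treated as 0. Since a bedGraph does not declare chromosome extents, the
minimum is taken as 0 unless a genome is bound and the track fully covers
it; a constant fully-covering track degenerates to all zeros. An optional
upper-percentile clip (off by default) maps outliers above the chosen
per-base percentile to 1.0, for tracks with a few extreme spikes.

Windows: the motif is centered in a fixed-width window (default 1000 nt,
i.e. motif plus immediate genomic flanks), the 5' flank on the motif strand
taking the ceiling half when the flank length is odd; chromosome edges pad
with N. Minus-strand motifs are encoded on the motif strand (the window
sequence is reverse-complemented and the track channel reversed to stay
positionally aligned), so the network always sees G-rich motifs in a
consistent orientation. Whether the original orientation convention or the
anchor choice matters in practice is untested here; both were genuinely
open choices and are isolated in `window_span`/`build_window`. A coverage
filter optionally drops motifs whose full window is not continuously
covered by every supplied track (windows hanging off a chromosome edge are
dropped by the same rule).

## The classifier

Input is (width × channels), channels-first internally: 4 one-hot sequence
rows plus optionally 1 track row. The architecture is:

* stem: width-1 convolution to 32 channels (a per-position embedding; the
  towers supply all spatial context);
* K towers × 4 pre-activation residual blocks; block =
  [BN → ReLU → conv(W_k, dilation D_k, 32 ch)] × 2 + identity; stride 1 and
  same padding everywhere, so positional resolution is never lost (the
  per-nucleotide pseudo-tracks depend on this);
* skip-to-penultimate: each block's output goes through a width-1
  convolution to 32 channels and all twelve projections are summed — every
  block gets a two-hop gradient path to the loss;
* head: ReLU → global average pooling over positions → one affine logit →
  sigmoid. This is the smallest head consistent with a single "ultimate
  logit"; it is configurable.

Defaults: K = 3, W = [11, 11, 15], D = [1, 4, 10], 32 kernels, width 1000.
The receptive field of the default stack is ~1500 nt, so distal flank
content can influence the logit (asserted in tests by perturbation).
The 4- and 5-channel variants differ only in the stem's input fan-in,
which keeps the sequence-only baseline an exact architectural control.

The network is implemented directly on numpy: convolutions as im2col matrix
products (the input gradient of a stride-1 same-padded convolution is again
such a convolution with the kernel flipped and channel axes swapped),
standard batch-norm (momentum 0.99, eps 1e-3; evaluation mode uses running
statistics, making inference deterministic and batch-composition
invariant), hand-written backpropagation validated against central finite
differences to ~1e-7, and Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e-7).
Initialization is He/variance-scaling from a recorded seed; two builds from
the same configuration are bit-identical.

## Training

Chromosome holdout: test = {chr1, 3, 5, 7, 9}, train = the 19 others.
Because no validation set is otherwise defined, one training chromosome
(default chr22, the smallest autosome) is carved out for validation —
this preserves the train/test firewall; with a validation chromosome
designated an epoch then visits 18 chromosomes. An epoch walks training
chromosomes in ascending name order; one chromosome's samples, shuffled
with the run seed and batched at 64, form one iteration (genome-scale
datasets do not fit in memory at once, and the fixed order keeps runs
reproducible — two runs with the same seed produce loss histories equal to
1e-6). The loss is class-weighted binary cross-entropy with
w_c = N/(2·n_c) computed once on the full training set (at 5% prevalence
that is ≈ (0.53, 10.0); note that the weight pair some G4 literature
prints, 0.35/35.69, is not reproducible from this formula at that
prevalence — the formula, not the printed pair, is implemented). The epoch
count is free (default 10) because the checkpoint with the best validation
AUPRC is what is returned; a single-class validation chromosome yields an
undefined (NaN) AUPRC and never captures the checkpoint.

## Evaluation

AUROC is computed as the threshold sweep whose area equals the
Mann–Whitney statistic (ties ½); AUPRC uses step-wise (non-interpolated)
summation, the standard for imbalanced genomics evaluation — linear PR
interpolation is optimistic at low prevalence. Both are cross-checked in
the tests against brute-force oracles (all-pairs comparison; threshold
enumeration). Peak-set agreement is the fraction of peaks in A with ≥ 1 bp
overlap with any peak in B (the minimal defensible criterion; reciprocal
overlap would need a parameter nothing here constrains). Stratified
evaluation assigns each motif to the first stratum it overlaps by ≥ 1 bp in
the given priority order (promoter > enhancer > random, since promoters and
enhancers overlap but results are reported disjointly); empty or
single-class strata report NaN rather than raising.

## Profiles and pseudo-tracks

Metagene profiles center windows on interval midpoints (floor), columns
−H..+H inclusive; "6000-nt vicinity" means halfwidth 3000 and "250-nt
vicinity" halfwidth 125. Windows are forward-strand oriented — profiles
aggregate both strands and the tested tracks are strand-symmetric. The
background reference is the length-weighted genome-wide mean of the track
over covered positions; note that planted or real peaks contribute to this
mean, so "background" is the global level, not the off-peak floor.
Heatmap-style rankings sort per-locus profiles by mean intensity (stable
sort, descending). The prediction pseudo-track evaluates the model on the
window centered at every position of a region (N-padded at edges); a
stride > 1 evaluates every stride-th position and step-holds values in
between, a documented approximation for desk-scale runtime — stride 1 is
the faithful mode and equals batch prediction on the corresponding samples.

## Synthetic studies

The generator builds fixtures with the statistical structure the pipeline
assumes, with exact planted ground truth. Background sequence is sampled
with a G/C "cooldown": runs of at most two G (or C) and no further G (C)
for at least four bases after a run ends, with A/T-only four-base margins
at segment boundaries. This provably excludes all three grammars from background on
both strands *and* blocks any extension of a planted motif into its flanks
(canonical would need a GGG in the flank; bulged and irregular would need a
G within three bases of the motif edge). Motif samplers use A/T-only loops
and spacers — so the reverse complement of a planted motif region is
G-free and cannot fire the opposite strand — and are shaped so the class
the scanner's precedence assigns is the planted class: bulged samples carry
at least two broken runs (no four-GGG canonical sub-match exists), and
irregular samples use exactly two-base spacers (the bulged grammar cannot
bridge them). The realized GC content sits somewhat below the nominal
parameter as a consequence; matching the human genome's composition is a
non-goal. Every assembled genome is verified by running the scanner and
asserting found ≡ planted (intervals, classes, strands).

G4 scores are zero-inflated by construction: positives draw a constant run
in U(0.6, 1.0) over the motif; 20% of negatives draw a small value below
the noise floor (default 0.05) and the rest score exactly 0 — so
upper-percentile labeling at the planted prevalence recovers the planted
labels (exactly when the positive count is integral at the chosen
percentile and the floor stays below the threshold). The epigenetic track
carries |N(0, 0.05)| noise everywhere plus a peak on each positive motif
(default Gaussian, height 0.8, width 300 nt — height comfortably above
noise so that learnability tests probe the model, not the fixture), and
covers every chromosome fully so coverage filtering is the identity on
fixtures. Sequence-identical discordant pairs duplicate the *entire
encoding window* (not just the motif) at two loci, one member positive and
one negative: their 4-channel matrices are bit-identical and only the track
channel (and label) differs, which is the cleanest possible probe that a
sequence-only model carries no information about them.

What the fixtures do not emulate: real chromatin's correlation structure
(peaks co-occur with GC content, promoters, each other), mapping artifacts,
label noise from antibody efficiency, and hg19's motif density (~2.1 M PQS
genome-wide). Passing the desk-scale tests therefore shows the machinery is
correct and that epigenetically-determined labels are learnable by the
architecture — not that real-data AUPRC values transfer.

## Desk-scale problem sizes

The package's own test and acceptance runs use a reduced setting chosen to
exercise every stage at laptop scale: 4000 planted PQS on 8 × 46-kb
chromosomes, 250-nt windows, a reduced model (K = 2, W = [7, 7],
D = [1, 4], 4 blocks per tower), 5 training epochs for the hybrid model and
2 for the sequence-only baseline (the latter only needs to demonstrate
chance performance on the discordant pairs). Under these conditions the
hybrid model reaches held-out AUPRC ≈ 0.89 and the sequence-only model sits
at AUROC 0.5 on the discordant-pair subset — reproducing, at fixture scale,
the qualitative ordering that epigenetics-aware models dominate the
sequence-only baseline when folding is chromatin-determined.

## Known limitations

* One epigenetic channel at a time; multi-mark stacking is out of scope.
* The stem/head details, batch-norm constants and initialization scheme are
  this implementation's choices; they are configurable but untested against
  alternatives.
* `predict_track` is O(region × width) at stride 1; use the stride for
  long regions.
* The numpy network trains at small-batch BLAS speed — fine for fixture
  scale; genome-scale training is possible but slow (hours, not minutes).
* liftOver, bigWig input and figure rendering are delegated to external
  tooling.
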