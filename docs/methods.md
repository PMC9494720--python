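# Methods

`gaitnirs` implements a pipeline for decoding walking intention — the
intended step length and walking speed — from multichannel fNIRS
hemoglobin signals recorded *before* movement onset. This note records
the model, its assumptions, the numerical choices, and what the
synthetic validation does and does not establish.

## Signals and the pre-movement window

The pipeline analyses two hemoglobin quantities per trial: total
hemoglobin (totalHb) and the difference between oxygenated and
deoxygenated hemoglobin (oxyHb − deoxyHb), each a 22-channel time
series sampled every 0.13 s (≈7.7 Hz). Only the 180 samples (~23 s)
immediately preceding movement onset are used, so every feature is a
property of motion intention rather than of movement-related
hemodynamics or motion artifacts.

Six gait states — small/mid/large step (SP, MP, LP) crossed with
low/mid/high speed (LD, MD, HD), of which six combinations were walked
(SP-LD, SP-MD, MP-LD, MP-MD, MP-HD, LP-MD) — collapse into three
classes along either dimension. Along walking speed: LD = {SP-LD,
MP-LD}, MD = {SP-MD, MP-MD, LP-MD}, HD = {MP-HD}; the step-length
grouping is the analogue. Classes are imbalanced (one class per
dimension holds three of the six states), so the majority-prediction
baseline is 0.5, not 1/3; no reweighting is applied by default (a
balanced mode can be added at the SVM if needed).

## Preprocessing

**Zero-drift removal.** The baseline is estimated with a mathematical
morphology filter: erosion/dilation are sliding minima/maxima over a
flat structuring element, edges replicated, and the baseline is the
average of the close∘open and open∘close compositions (balancing the
downward bias of opening against the upward bias of closing). The
structuring element defaults to 31 samples (~4 s): long enough that
in-band oscillations faster than ~0.25 Hz pass untouched, short enough
to track slow drift. The residual operator is *not* exactly
idempotent — the open/close average is not a projection — and a second
application changes the residual by up to a few percent; this is a
property of the filter class, not an implementation artifact.

An important consequence, measured on synthetic signals: content whose
period is much longer than the structuring element (subbands 1–2,
periods 170–500+ samples) is partially absorbed into the baseline. In a
23 s window, sub-0.06 Hz oscillations and true zero drift are not
separable by any local filter; the filter therefore attenuates the
lowest subbands' slopes.

**Normalization.** Each channel's drift-free window is rescaled to
[−1, 1] via `2(x − min)/(max − min) − 1`, to reduce between-subject
amplitude differences. The window used for min/max is the 180-sample
analysis window, not the whole trial: nothing outside the window feeds
later stages, so trial-wide scaling would only inject movement-period
amplitude into a pre-movement feature. Constant channels are rejected
rather than silently mapped.

**Spectra.** For band-structure exploration, a one-sided untapered
(rectangular-window) periodogram is provided; bin powers sum to the
signal variance (Parseval).

## Subband slope features

A level-7 wavelet packet decomposition splits 0–3.85 Hz into 128
terminal subbands of 0.0300 Hz; the six lowest tile the 0–0.18 Hz range
where hemodynamic power concentrates (pd1 … pd6). Terminal nodes are
taken in frequency order (Gray-code corrected) — tree-path order would
scramble the band indexing. Each leaf is reconstructed to the original
time grid by zeroing all other leaves; since the transform is linear,
the 128 reconstructions sum to the input exactly (verified to 1e−8).

The default wavelet is db4: orthogonal, short support (8 taps), a
reasonable compromise between frequency selectivity and edge spread in
a 180-sample window. Boundary extension is symmetric. Periodized
extension would make the basis orthonormal (leaf coefficient energies
then sum exactly to signal energy) but breaks perfect reconstruction at
non-dyadic lengths in the leaf-wise reconstruction path; linear-
extrapolation extension amplifies noise into the lowest bands. All
modes remain configurable.

The feature of a (subband, channel) cell is the one-sample first
difference of the reconstructed subband averaged over the 8 samples
(~1 s) before onset — the simplest rate-of-change estimator at that
sampling rate. A 6 × 22 matrix per trial and signal kind results.

**Band-dependent sensitivity.** With only ~1.4 coefficients per leaf of
genuine signal at 180 samples, leaf reconstructions overlap spectrally,
and boundary handling dominates the window end where slopes are read.
Measured on synthetic inputs, the end-of-window slope response is
several times larger in subbands 2, 5 and 6 than in 1, 3 and 4 for any
broadband input, and the morphology filter further attenuates subbands
1–2 (see above). Cells therefore compete on unequal footing in the
global extreme-value masks below. This is an intrinsic property of the
method at this window length; it means detectable class effects are
easiest to plant — and, in real data, presumably to find — in the upper
subbands.

## Feature-selection cascade

For one class of one dimension with at least two constituent states,
per training subject:

* **M1** — elementwise mean of the constituent-state matrices;
* **M2** — |coefficient of variation| (sample sd, n−1, over the
  constituent states; a zero-mean cell has undefined CV and is assigned
  +∞ so it can never count as stable);
* **M3** — indicator of the bottom 50 % of M2 (66 of 132 cells):
  stability across the constituent states;
* **M4/M5** — indicators of the top/bottom 20 % of M1 (26 cells each):
  clear activation/inhibition. Rank thresholds use floor counts; ties
  break by ascending (band, channel) index for determinism;
* **M6 = M3∧M4**, **M7 = M3∧M5** — *key channels*;
* **M8/M9** — per-region counts of key channels over the 22 overlapping
  three-channel spatial regions (6 bands × 22 regions, entries 0–3).

Classes with a single constituent state (HD, LP) cannot support a CV
and contribute no candidates; they still serve as comparison classes in
the ANOVA stage. Across the n training subjects, a (band, region,
polarity) cell flagged by at least ⌈0.6·n⌉ subjects (12 of 20 at the
reference size) becomes a feature region; its key-channel count is the
modal nonzero per-subject count, ties resolved toward the smaller count
(a maximum rule is available as a switch).

Feature regions in adjacent subbands of the same spectral half (pd1–pd3
vs pd4–pd6; the 0.09 Hz boundary is never crossed) merge into one
feature vector, printed in the region/subband notation
`Re4: pd1(1) + pd2(1)`. Evaluating a feature on a subject's matrix
takes, per constituent band, the mean of the key-count largest (top) or
smallest (bottom) values among the region's three channels, then
averages over the constituent bands (per-band concatenation is
available as an alternative mode).

Finally, for every merged feature, a one-way ANOVA (equivalently a
squared two-sample t) is run on the per-subject class-level values for
each pair of the dimension's three classes; the feature is retained iff
any pairwise p < 0.05. Degenerate pairs (zero variance, equal means)
count as p = 1. No multiple-testing correction is applied; false
positives are tolerated here because the downstream subset search can
discard them, as the zero-effect experiments confirm (dozens of
chance-retained features yield only prior-level accuracy).

## Adaptive GA + SVM classification

Candidate features of both signal kinds form one pool. A chromosome is
a bitmask over the pool; its fitness is the mean leave-one-subject-out
accuracy of an RBF-kernel SVM (C = 1, gamma = 1/n_features, one-vs-one,
features standardized with training-fold statistics only) over the
training cohort, each subject contributing one instance per gait state.

The GA is generational with fitness-proportional selection, single-
point crossover, bit-flip mutation and elitism of one (so the best-so-
far trace is non-decreasing). Crossover and mutation probabilities
adapt to population fitness: for a pairing with larger fitness f′,

    pc = pc1 − (pc1 − pc2)(f′ − f_avg)/(f_max − f_avg)  if f′ ≥ f_avg,
    pc = pc1 otherwise,

and analogously for pm. Critical values default to pc1/pc2 = 0.9/0.6
and pm1/pm2 = 0.1/0.01 — classic adaptive-GA settings, configurable —
and a degenerate population (f_max = f_avg) receives the upper values.
Freshly crossed offspring have no fitness of their own yet, so the
larger parent fitness serves as the mutation candidate's fitness proxy;
evaluating children pre-mutation would double the evaluation budget for
no observed benefit. Fitness values are cached by bitmask and only
cache misses consume the budget, which counts evaluations by default
(20 000 at the reference size; a generations interpretation is a config
switch). Empty masks score zero and are repaired on creation. All
randomness flows from one seeded generator; runs are bit-reproducible.

The best mask is then trained once on the full training cohort and
scored on held-out subjects, one instance per (subject, state) — 66
instances for the reference 11-subject test cohort — with a 3 × 3
confusion matrix. If the candidate pool is empty the majority training
class is predicted, which *is* the class-prior baseline.

## Synthetic cohorts

Real recordings of this protocol are not available, so validation uses
synthetic cohorts emulating the data's statistical structure. Per
channel: a constant offset and a random-walk drift (amplitude scale 2.0
background-sd units — drift comparable to or larger than the signal, as
in raw optical recordings); an oscillatory background of 24 sinusoids
with frequencies uniform in 0.005–0.18 Hz, 1/f-weighted amplitudes and
random phases, normalized to unit variance (this defines the signal
unit); and white noise (sd 0.3). Defaults mirror the study shape: 31
subjects, six states, 22 channels, 0.13 s sampling, 300 pre-onset
samples (~39 s rest).

Class effects are injected as a sinusoid at the target subband's centre
frequency, phase-locked to cross zero at movement onset so that its
per-sample slope at onset equals exactly the prescribed class offset —
a constant-amplitude carrier rather than a growing envelope, because an
envelope's derivative mixes into the onset slope and makes the injected
effect size ill-defined. Effects scale per subject by a factor drawn
from Normal(1, 0.3), truncated at zero.

The canonical validation effects (used by the acceptance script, the
test suite and the README example) place one effect per dimension in
subbands 5–6 of a single channel — channel 15 of totalHb for walking
speed, channel 8 of oxyHb−deoxyHb for step length — with slope ±0.15
units/sample, opposite signs in the two multi-state classes and zero in
the single-state class. Spanning two adjacent bands exercises the
band-merging rule; the upper-subband placement follows the measured
band-dependent sensitivity discussed above. At these conditions the
injected (band, region) cell is recovered in the selected features in
20 of 20 reseeded 6-subject cohorts.

What the generator does *not* emulate: optical forward physics and
Beer–Lambert conversion, spatially correlated physiology across
channels, Mayer waves or respiration as distinct processes, motion
artifacts, and any realistic relationship between the two signal kinds
(they are generated independently). Passing tests therefore establish
that the pipeline recovers the class structure it is designed to
detect, under noise of plausible spectral shape — not that it would
achieve any particular accuracy on real cortical recordings.

## Problem sizes used in validation

The shipped experiments use 6 training + 6 test subjects, a GA budget
of 2 000 evaluations with population 30, 20 reseeded cohorts for the
recovery rate, and 100 label permutations for the no-information null.
These sizes make the full validation reproducible on a laptop in a few
minutes while leaving all statistical conclusions clear-cut: effect
cohorts score far above the null's 97.5th percentile, zero-effect
cohorts sit inside 99 % binomial bounds of the 0.5 prior.

## Known limitations

* Selection and classification assume every subject contributes every
  state; missing trials are not handled.
* The 60 % frequency rule is "≥" at the reference cohort size (12/20 is
  exactly 60 %, which the source procedure counts as selecting).
* With 180-sample windows the six subbands are far from ideally
  separated; subband indices should be read as filter outputs, not as
  sharp spectral claims.
* LOSO fitness on 6 subjects is noisy; GA selections on small cohorts
  vary across seeds even when the injected effect is always found.
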