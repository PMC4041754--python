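# Methods

This note documents the models behind `charstream`: what the synthetic EEG
generator emulates, how the decoding stack is built, which parameters
matter, and where the design was genuinely open.

## Paradigm model

The 30-symbol alphabet (A–Z plus `<SPACE> <DEL> <UNDO> <END>`) is split
into three consecutive groups of 9/10/11 symbols (A–I, J–S, T–Z+commands).
The three streams run at a common within-group SOA with phase offsets of
0, SOA/3 and 2·SOA/3, which (a) yields a pooled stimulus rate three times
the group rate and (b) guarantees that no two stimuli share an onset. One
*iteration* presents every symbol of a group exactly once; one *trial* is
the stimulation period for selecting one symbol. Because group sizes
differ, the cross-group neighbourhood of a fixed symbol rotates across
iterations — a property of the original design that the schedule generator
reproduces and the tests check.

Pseudo-random conditions draw an independent permutation per group per
iteration, with one constraint the sources leave open: the last symbol of
iteration k never reopens iteration k+1, so the same sound is never played
twice back to back. Condition C uses the fixed alphabetical order.

Stimulus duration (200–250 ms) is carried as metadata only; all decoding
is onset-based.

**Iteration budgets.** Dynamic stopping needs per-group maxima. These are
derived from a shared stimulation-time budget — the time the smallest
group needs for 15 iterations — giving maxima of 15/13/12 iterations for
group sizes 9/10/11, with a common floor of 5. Larger groups therefore get
fewer maximal repetitions, reproducing the stated 12–15 range.

## Synthetic EEG

ERP components are Gaussian bumps parameterized by peak latency, FWHM,
signed peak amplitude (µV) and a named scalp topography (max-abs
normalized). Defaults:

* **Common auditory response** (every stimulus): N1 (−1 µV, 100 ms,
  fronto-central) and P2 (+0.8 µV, 200 ms, central).
* **Oddball target (conditions A/B)**: N200 (−2 µV, 200 ms,
  fronto-central) and P300 (+4 µV, 400 ms, centro-parietal).
* **Sequential target (condition C)**: a slow central negativity peaking
  at −50 ms with 200 ms FWHM and −3 µV — the user knows when the target
  comes, so discriminative activity precedes it — plus a weak late frontal
  "confirmation" positivity (+0.8 µV at 600 ms). The late component is the
  only response feature specific to the target itself (see below).
* **Neighbour spillover (condition C)**: the same-group neighbours of a
  target evoke the anticipatory negativity at gain 0.5 by default
  (distance-1 neighbours), emulating the observed target-like responses of
  pre-/post-target stimuli.

Trial-to-trial variability has three parts: per-event latency jitter
(Gaussian, default 15 ms oddball / 50 ms sequential — anticipatory
components are temporally sloppier), per-event multiplicative amplitude
jitter (15%), and *anticipation mistiming*: a common latency shift of all
discriminative components, drawn uniformly within ±100 ms per iteration
for condition C. The shift is uniform and bounded because the predecessor
stimulus re-anchors the user's timing within one SOA, and it is coherent
within an iteration because anticipation runs early or late as a whole.

Background noise is 1/f^β (spectrally shaped white noise, β = 1 by
default) at 4 µV RMS per channel; against 3–4 µV components this gives the
mid-range single-trial separability of a usable ERP-BCI session (binary
balanced accuracies of roughly 0.65–0.8 on the default test montage of 16
EEG + 2 EOG channels at 100 Hz; a 63-channel montage and 1 kHz sampling
are available). Eye artifacts are slow frontal/EOG-dominant bumps, a
configurable fraction of which is time-locked to within ±300 ms of target
onsets.

Every additive term is logged separately; `signal = erp + artifacts +
noise` holds exactly (and is preserved by filtering and projection, which
are applied to each part), so tests can verify perfect ground-truth
bookkeeping.

**What the generator does not emulate:** biophysical head modelling and
volume conduction, non-stationary or non-Gaussian background activity,
muscle artifacts, inter-subject component topography variation, and any
acoustic property of the three voices. Passing tests therefore demonstrate
the correctness and internal consistency of the decoding stack under the
stated response model, not performance on real recordings.

### The confusion fixture

The tests that compare the sequential meta-classifier against the standard
pipeline use a deliberately adversarial profile (`confusion_profile`):
attention spillover at full gain over same-group distances 1 and 2, larger
anticipation mistiming (±150 ms per iteration), and a flatter noise
spectrum (β = 0.4, 5.5 µV RMS). Under these conditions the target and its
neighbours are nearly indistinguishable from their own epochs: the
spillover run has no amplitude gradient the per-epoch classifier could
read, mistiming blurs the temporal template, and the one target-specific
feature — the weak late positivity — contributes only ~7% of the maximum
signed-r² lobe, below the 20% selection floor of the interval heuristic,
so the standard pipeline's features never include it. The balanced 1/1
pre-/post-target contrast classifiers select their own intervals on their
own contrast and recover it, which is exactly the design rationale for the
sub-classifier bank: contrast-specific features that a single compromise
classifier misses. The fixture's parameters were chosen so that the
generator reproduces the qualitative phenomenon reported for the paradigm
— neighbour confusion that harms the per-epoch decision but is recoverable
from the sequential structure — not any quantitative accuracy.

## Preprocessing

Pipeline order is fixed: causal band-pass → (projection) → epoching →
rejection. The band-pass is Chebyshev II, 0.2 Hz high-pass (order 4) then
25 Hz low-pass (order 8), 40 dB stop-band attenuation, applied
forward-only with no group-delay compensation (an online system cannot
compensate). 40 dB bounds the residual DC leakage of the equiripple stop
band at 1% while keeping the pass band flat down to ~0.5 Hz, where the
slow anticipatory activity lives.

Epochs span [−1000, +1000) ms (start-inclusive, end-exclusive; 0 ms = the
onset marker sample). No baseline correction is applied by default: in the
sequential condition class-discriminative activity precedes the stimulus
and a pre-stimulus baseline would erase it. A baseline interval can be
passed for the oddball conditions.

Min–max rejection removes an epoch iff max−min over the window exceeds a
threshold on any monitored channel (default 70 µV on fronto-central sites;
a liberal 150 µV preset exists). Rejection changes membership only, never
content.

The ocular cleaner is a least-squares regression of every EEG channel on
the EOG reference channels, fit on the *filtered continuous calibration
signal* only and applied as a fixed channels × channels operator to any
later data. The projection stage accepts any such operator, so an
ICA-based cleaner can be plugged in; the regression backend is the
package's own default, not a reimplementation of any specific ICA method.

## Features and discriminants

The signed-r² map is the signed squared point-biserial correlation per
(channel, time point). The interval heuristic smooths the channel-summed
absolute map with a 30 ms moving average and greedily takes up to n ∈ [3,5]
peaks (earliest on ties), growing each interval while the score stays
above 20% of the global maximum, clipped to 30–150 ms, with a one-sample
guard between intervals. Smoothing width, length bounds and floor are not
fixed by the sources; they are exposed as arguments and frozen at these
defaults.

Dense LDA uses the analytic Ledoit–Wolf shrinkage intensity on the pooled
within-class covariance (deterministic, no inner CV); the bias places the
boundary at the midpoint of the projected class means — with a 1/29 class
ratio the speller ranks rather than thresholds, so no resampling or prior
correction is applied. Sparse LDA is realized as ℓ1-penalized optimal
scoring: a Lasso regression of recoded class labels whose OLS limit is
proportional to the LDA direction. All accuracies are *balanced* (mean of
per-class recalls), so chance is 0.5 regardless of class ratios; this is
also what makes a 65% gate meaningful for 1/29 problems.

Cross-validation is always trial-blocked (epochs of one trial never
straddle folds) and re-runs interval selection inside every training fold.
If a blocked split would leave a fold without one of the classes, trials
are re-dealt round-robin by target share.

## The sequential meta-classifier

Nine discriminants are trained with the identical automated procedure on
the slices listed in the README; each records its trial-blocked 5-fold CV
balanced accuracy and passes the gate only if strictly above 65%. A
*family* (global / groupwise / pretarget / posttarget / spatial) is active
if any member passes; group-resolved families evaluate each epoch with the
classifier of the epoch's own stream, and missing or gated-out members
contribute the neutral value 0.

Three choices the sources leave open are resolved as follows:

* **Output standardization.** Member outputs are z-scored by the mean and
  SD of their *out-of-fold background* (class-2) outputs. Background
  scaling makes the scores of different stream classifiers commensurable
  (background ≡ N(0,1) everywhere), and out-of-fold statistics make the
  scale honest about generalization. Zero is then a natural padding value.
* **Stacked training.** The meta discriminant is trained on the bank's
  out-of-fold outputs, not its in-sample outputs (standard stacked
  generalization). In-sample outputs are optimistically separated, and a
  meta classifier trained on them learns weights that do not transfer;
  this mattered substantially in simulation.
* **Boundary handling.** Positions outside the trial contribute 0 after
  standardization, keeping the feature dimension fixed at
  n_families × (2m + 1).

Model selection over m ∈ {0…9} × {dense, sparse} uses trial-blocked 5-fold
CV, scored by the speller's own target metric: the rank-1 rate of the
30-class decision on held-out trials, with mean target rank and then
smaller m / dense LDA as tie-breaks. Binary balanced accuracy is kept in
the CV table (and available as the selection metric), and the reported
binary accuracy of the final model comes from nested CV at the meta level
(inner selection, outer evaluation; the bank itself is fit once on all
calibration data — retraining nine sub-classifiers per outer fold was
judged not worth the cost, and the out-of-fold outputs already remove the
bank's in-sample optimism).

With m = 0 and only the global family active, the meta classifier is a
positive monotone transform of the standard pipeline's score, so its
30-class ranking ties the standard ranking exactly — the degenerate case
the tests pin down.

## Decisions, stopping, metrics

Per-symbol evidence is the *mean* of the symbol's per-occurrence outputs
(not the sum), so unequal occurrence counts under dynamic stopping do not
bias the decision. Ranking sorts by score, ties broken alphabetically.

The dynamic stopping rule is reconstructed as a significance test, the
exact online statistic being unavailable: after each completed iteration
(never before 5), a one-sided Welch t-test compares the current best
symbol's outputs against the pooled outputs of all other symbols;
stimulation stops at p < α/29 (α = 0.05, Bonferroni-corrected because the
best of 30 candidates is chosen post hoc — without the correction the rule
stops spuriously early on pure noise) or at the per-group iteration
ceiling, whichever comes first. Epochs beyond a group's ceiling are never
used.

Wolpaw's ITR is computed from rank-1 decisions only, disregarding the
rank information of incorrect decisions. B(P) is convex with its minimum
of exactly 0 at P = 1/N; below-chance accuracies are not treated
specially. The selection rate in the copy-spelling simulation is derived
from the stimulation time actually used per letter (last used onset plus
one SOA); inter-trial pauses are not charged.

## Problem sizes

The test suite and simulations run at desk scale: 16 + 2 channels at
100 Hz, 6–15 calibration trials of 6–14 iterations, and 20 paired
generator seeds for the meta-vs-standard comparison with 30 test trials
per seed. The full 63-channel, 1 kHz mode is exercised only through the
configuration surface. All randomness flows from explicit integer seeds
(experiment drivers spawn per-stage seeds from one master seed), and equal
config + seed reproduces results bit for bit.

## Known limitations

* The generator's linear additive response model cannot express every
  mechanism by which sequential context helps real decoding; in purely
  linear-Gaussian regimes a well-regularized per-epoch classifier can in
  principle read the same information from its ±1 s window, and the meta
  classifier's advantage then rests on estimation efficiency and on
  contrast-specific interval selection, as described above.
* The ocular projection is a regression cleaner, not an ICA component
  classifier; it removes exactly the subspace spanned by the EOG
  references.
* The dynamic stopping statistic is a reconstruction; absolute
  selections-per-minute figures depend on it and on the uncharged
  inter-trial pauses.
* Group-resolved sub-classifiers require calibration targets in every
  stream; the calibration-target sampler deals targets round-robin across
  streams for this reason.
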