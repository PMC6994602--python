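# Methods

This note documents the models, estimators and numerical choices behind
`ecogface`, what the synthetic generator does and does not emulate, and
the decisions taken where the design was genuinely open.

## Signal model and preprocessing

Input is a continuous multichannel voltage recording (μV) with
electrode positions in MNI space; the y coordinate indexes the
posterior (negative) to anterior axis of the temporal cortex. The chain
runs in a fixed order — downsample to 1 kHz, notch, channel QC, common
average reference, epoch, artifact rejection, time–frequency power —
because later stages depend on the statistics of earlier ones (e.g. the
common average must be computed over QC-passed channels only; a
regression test guards the order).

* **Notch**: zero-phase 4th-order Butterworth band-stops at 57–63,
  117–123 and 177–183 Hz. The filter family and order are
  implementation choices (only the stopbands are prescribed);
  attenuation at the stopband centre exceeds 20 dB while a 10 Hz
  passband tone changes by <1 %.
* **Resampling**: polyphase when the rate ratio reduces to a small
  rational, Fourier otherwise (the clinical 1525.88 Hz → 1000 Hz ratio
  does not). Duration is preserved to within one sample.
* **Channel QC**: a channel is rejected when its variance is >5× or
  <1/5× the across-channel *mean* variance, or when its count of
  first-difference jumps >100 μV exceeds 3× the mean count. The mean
  (not median) matches the rule's usual formulation; note that with few
  channels a single extreme channel inflates the mean and weakens the
  rule — the thresholds are configurable.
* **Epochs**: [−200, 700) ms around onset, half-open at sample
  resolution ([start, end) everywhere in the package), baseline-corrected
  by the [−200, 0) ms mean. Trials with any sample >100 μV in magnitude
  are flagged and excluded. Response blocks (catch trials) never enter
  analysis.
* **Band power**: per frequency (1 Hz steps, skipping bins inside the
  notch stopbands — so the HFB band spans 70–116 and 124–176 Hz; 177 Hz
  itself falls in the third-harmonic stopband), power is the squared
  magnitude of the convolution with a complex Morlet wavelet (7 cycles
  at ≥70 Hz, 5 below), converted to dB and rescaled by subtracting the
  per-trial/channel/frequency mean dB over [−100, 0) ms. Because the
  rescale is subtraction in log space, the baseline-window mean is 0 dB
  exactly before smoothing, and an amplitude doubling of an in-band
  carrier raises the plateau by 10·log₁₀ 4 ≈ 6.02 dB (verified against
  that closed form). Frequencies are then averaged within the band and
  smoothed with a 50 ms FWHM Gaussian (reflection at edges). Wavelets
  are truncated at ±5σ or the epoch length; at θ-band frequencies the
  wavelet is longer than the 900 ms epoch, so low-band estimates are
  edge-dominated and should be read qualitatively — the main analyses
  use HFB, where 7 cycles at 70 Hz span only 100 ms. An optional
  post-rescale rejection of trials with |z| > 8 (across-trial z at each
  channel/time) is off by default and intended for the semi-simulation
  path.

## Site classification

Activity: for each of the 11 categories, each trial's mean response in
[150, 500) ms is compared to the same trial's baseline mean ([−100, 0)
ms) with a sign-flip permutation test on the mean difference; FDR
(Benjamini–Hochberg, q = 0.05) is applied across sites within each
category, and a site is *active* if any category survives. Applying FDR
per category and taking the union across categories means the
site-level false-positive rate compounds over the 11 families; the
calibration test bounds the realized rate empirically.

Selectivity: one-sided label-shuffle tests of pooled faces (or human
faces alone) versus pooled non-faces on the windowed means, FDR across
sites; selective flags are granted to active sites only. *Task-active*
= active and neither selective flag. The selectivity *score* is the
windowed mean human-face response minus the pooled non-face response
(dB) — the quantity is not given a formula in the literature this
follows; the contrast that defines the human-face-selective class is the
natural choice and is what the gradient and contribution analyses use.

Permutation p-values use the (k+1)/(N+1) estimator, so p ∈
[1/(N+1), 1]; for n ≤ 10 an exhaustive enumeration path replaces Monte
Carlo and the two agree within binomial error. Each (site, contrast)
test draws from an independent RNG stream keyed by a stable hash of the
site name, and null statistics are computed from sorted per-trial
values, so classification is exactly invariant to channel and trial
ordering. Defaults are 50,000/10,000 permutations for
activity/selectivity in the API; the bundled demo configuration reduces
them to 5,000/1,000 for desk-scale runtime.

## Decoding relevance

Epoch features are the concatenated per-site band-power time courses in
[150, 500) ms (350 samples per site at 1 kHz under the package's
half-open windows). Non-face trials (7 subcategories) are subsampled
once per model to the human-face count, as evenly as possible across
subcategories (sizes differing by ≤1). Classification is a soft-margin
SVM on the precomputed linear kernel; performance is balanced accuracy
(mean of the two class sensitivities) averaged over 5 stratified outer
folds, with C chosen in 4 stratified inner folds from
{0.01, 0.1, 1, 10, 100} (ties toward the smaller, more regularized C).
Stratification is not strictly prescribed upstream but keeps class
balance per fold, which balanced accuracy needs. Significance comes
from label permutations re-run through the same CV structure.

Model variants are pure site-set ablations sharing all other
parameters. The random-subset ensemble (499 models of the
face-ablated model's size, each with ≥1 face site) shares one non-face
subsample and one fold structure so only the site sets differ; the
reported statistic is the Spearman correlation between model accuracy
and the proportion of face sites included. For large ensembles the
inner C search can be disabled (fixed C = 1), trading a small accuracy
bias that is constant across models for a ~20× speedup.

**Sparse multiple kernel learning (model IV).** One linear kernel per
site (trace-normalized to the epoch count so high-variance sites do not
dominate — switchable), combined with non-negative weights constrained
to the probability simplex. The weights are learned by projected
gradient descent on the SVM max-margin objective J(d) = Σα − ½ aᵀK a
(a = y ⊙ α), whose gradient in the m-th weight is −½ aᵀK_m a; each step
re-fits the SVM on the combined kernel, takes a normalized gradient
step with backtracking halving (12 halvings max), and projects onto the
simplex (Euclidean projection, which produces exact zeros — the
sparsity mechanism). Convergence is declared when the weight change is
<1e−4 or after 200 iterations; non-convergence is flagged on the result
rather than raised. Contributions are fold-averaged weights
renormalized to sum to 1; sparsity is the fraction of non-null
contributions, computed per fold and averaged. Kernel additivity (the
sum of per-site kernels equals the all-site kernel) ties model IV's
search space to model I's feature space exactly.

## Response onset latency

Detection runs on the *unsmoothed* band power. Each trial is divided by
its peak in [0, 600) ms (trials with non-positive peaks are excluded);
bins are [t, t+30) ms starting at stimulus onset and advancing 2 ms
(the bin alignment is a package convention — only width and overlap are
prescribed); the onset is the start time of the earliest run of ≥25
consecutive bins whose means all strictly exceed baseline mean + 1 SD,
with the run start constrained to [0, 500] ms but allowed to complete
later in the epoch. A site's ROL is the median over detected trials and
is valid only when ≥50 % of trials are detected.

The threshold estimator was a genuinely open design point. Estimating
mean and SD over time of the *trial-averaged* baseline trace makes the
SD shrink like 1/√n_trials, so with a few tens of trials the threshold
collapses onto the baseline mean and single-trial noise triggers false
early onsets. The default therefore pools per-trial baseline statistics
(each trial's baseline mean and SD, averaged across trials), which
keeps the threshold on the scale of single-trial noise — the scale a
trial-level detector must exceed; the averaged-trace and fully
per-trial variants remain available via `ROLParams.baseline_estimator`.

Gradients are Spearman correlations of site ROL (and selectivity)
against y, either absolute or after subtracting each subject's most
selective site's ROL and y (rank-invariant within a subject; it removes
subject timing offsets when pooling). Face/task-active comparisons
match each face site to its nearest task-active site within 2 mm in y
(greedy nearest-neighbour; one task site may serve several face sites)
and use a paired Wilcoxon signed-rank test, with p = 1 returned for
all-zero differences.

Absolute ROL values are method-dependent (threshold crossings move
earlier as amplitude grows — the ramp sweep shows this directly); only
relative comparisons and gradients are interpreted.

## Ramp-injection semi-simulation

`inject_ramp` adds to every condition-A trial a ramp rising linearly
over [0, 500] ms and holding afterwards, scaled so its terminal
amplitude equals SNR_in × std(X̄_B), the standard deviation over time
of the trial-averaged condition-B trace — hence
X_A,eff = X_A + SNR_in·std(X̄_B). The nominal ramp slope (3 amplitude
units per window) has no effect on a purely linear ramp once the
terminal amplitude is calibrated; it is retained so alternative ramp
shapes can be calibrated consistently, and the "amplitude units per
window" reading is a package decision (the source quantity is
unitless). The injected terminal amplitude is affine in SNR_in with
slope std(X̄_B) (regression over the 2→10 grid gives R² > 0.999
noiseless), B trials are never modified, and SNR_in = 0 is an exact
identity.

## Synthetic generator: scope and limits

The generator reproduces the *statistical structure* the analyses rely
on: AR(1) background noise (coefficient 0.97, ~1/f² at low frequency,
15 μV RMS) plus an optional 60 Hz sinusoid to exercise the notch;
planted bursts of band-limited noise (72–170 Hz, clear of the notch
bands) whose amplitude is calibrated against the background's own power
in the band so that a nominal x dB effect produces an x dB band-power
step (the [150, 500) ms *window mean* realizes ~80 % of the plateau
because of envelope ramps and smoothing); latency and selectivity
gradients linear in y; and a task design with 11 categories, 300 ms
stimuli, 400 ms ISI and interleaved response blocks. The standard
design (25 images × 2 presentations) yields 550 stimuli, 50 per
category.

It does not emulate: spatial correlation between channels beyond the
common reference, evoked (phase-locked) potentials, eye movements or
behaviour, interictal pathology, cortical geometry, or realistic
between-subject variability. Passing tests therefore demonstrate
correctness of the estimators under the planted-effect model, not
performance claims about patient data. `simulate_band_power` plants the
same effects directly in dB space (smoothed Gaussian noise, default
SD 1 dB, 20 ms correlation) for fast statistical tests that do not need
the voltage-level chain.

## Problem sizes and defaults

The bundled demonstration scenario uses 20 sites (6 face-selective,
8 task-active responding to every category, 6 noise-only), the full
550-stimulus design, 5,000/1,000 permutations for site classification,
nested CV for models I/II/IIIa, and fixed-C CV for the 499-model
ensemble and model IV; the acceptance script runs it end-to-end in
about two minutes on one CPU. Test fixtures are smaller (8–30 sites,
6–25 trials per category) and chosen so each planted effect is
recoverable with comfortable margin at those sizes.

## Known limitations

* Low-frequency band estimates on 900 ms epochs are wavelet-truncated
  (see above); a longer epoch window is the remedy if θ/α results are
  of primary interest.
* The MKL objective is non-convex in (d, α) jointly under the
  alternating scheme; different seeds can settle on different sparse
  supports when sites carry redundant signal. Contributions are
  reported fold-averaged for stability, and interpretation should stay
  at the level of "where the model put weight", not effect magnitude.
* The union-over-categories activity rule compounds FDR families, as
  noted; a single omnibus test per site would be stricter.
* The two-proportion z-test is the classical pooled-variance form
  without continuity correction (a corrected variant is available); for
  the very small counts involved an exact test would differ.
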