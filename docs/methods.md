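# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `ocutremor`, in the spirit of a
statistical package's model documentation. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The generative model of synthetic gaze

A synthetic session emulates a two-target flicker-detection task recorded
monocularly at 1 kHz. Gaze alternates between two targets separated by 19°
of visual angle (targets 1.4° wide; both angles follow from the screen
geometry via θ = atan(size/distance): 2.5 cm and 35 cm at 1 m). Fixation
durations are exponential with mean 600 ms (floored at 100 ms — values in
the few-hundred-ms range typical of target fixation); saccades are 60 ms
raised-cosine ramps with a small Gaussian landing error.

Within a fixation the position is the superposition of

* **ocular drift** — a 2-D Gaussian random walk with diffusion constant
  `drift_diffusion` (default 0.01 deg²/s, in the range of published drift
  diffusion estimates); displacement variance grows linearly with lag, a
  contract the test suite checks;
* **microtremor** — a circular oscillation of amplitude `tremor_amp`
  (default 0.01°, ~36 arcsec, at the upper end of reported microtremor
  amplitudes so the oscillation is resolvable at realistic noise) at
  `tremor_freq`, drawn uniformly on [70, 150] Hz per participant. The
  oscillator phase carries diffusion (`tremor_phase_jitter`, default
  0.3 rad/√ms), giving the rhythm a finite spectral linewidth (~15 Hz)
  rather than the infinite coherence of a mathematical sinusoid. This
  matters for the reversal statistic: a perfectly coherent tone re-peaks at
  every odd half-period (in particular at 1.5 periods, where the angle hits
  exactly π on the 1 ms lag grid), whereas a physiological, decohering
  rhythm yields a single maximum at the half-period followed by decay —
  the shape the analysis presumes. A "linear" waveform option oscillates
  along a random axis instead;
* **white measurement noise** (`noise_sd`, default 0.002°). The default
  corresponds to a low-noise research eye-tracker after filtering; it is
  deliberately small enough that tremor velocity dominates noise velocity,
  which is the regime in which microtremor is measurable at all;
* **microsaccades** — Poisson events (1/s) of ~0.25° with 10 ms
  raised-cosine profiles, labelled SACC; **blinks** — optional BLINK spans
  carrying missing positions (NaN), as real tracker exports do.

Ground-truth FIX/SACC/BLINK labels are attached per sample, standing in for
the tracker's proprietary event detector, which is treated as an input
throughout and never reimplemented.

**The tremor→CFFT link.** Each participant's latent CFFT follows
`cfft = 0.7·tremor_freq − 19 + N(0, 5)` Hz, mapping the tremor band onto
CFFTs of roughly 30–86 Hz. The link is linear because only a monotone
relationship is asserted by the science; the coefficients were chosen once
so the cohort reproduces the qualitative detection profile (nearly everyone
resolves 30 Hz flicker, about half resolve 60 Hz after the guessing floor).
A linear link on a uniform band cannot *also* produce a genuinely
above-chance group at 120 Hz; in the default cohort the group passing the
criterion at 120 Hz is dominated by lucky guessing. This is a known
limitation of the generator, not of the analysis.

**Trial responses.** A trial at flicker frequency f is answered correctly
with probability `1/3 + (2/3)·logistic(slope·(cfft − f))` — a logistic
detection curve floored at the 1/3 chance of guessing among left/right/not
sure; otherwise the wrong side or "not sure" is chosen uniformly. The
2-of-3 criterion then passes a pure guesser with probability 7/27 ≈ 0.26,
which puts an irreducible floor of label noise under every downstream
group statistic: roughly a quarter of the truly below-threshold
participants are labelled as detectors at any frequency.

## Feature extraction

**Velocities.** One-step forward differences at the 1 ms step. The unit
variant divides by the Euclidean norm (zero-norm samples invalid); the
fixational variant keeps only pairs with both endpoints labelled FIX.
Blink-adjacent samples are invalid everywhere.

**Reversal statistic.** φ(t, t+τ) is the angle between one-step velocities
at t and t+τ (not between displacements aggregated over τ), computed over
all valid pairs; the cosine is clipped to [−1, 1] before arccos. By
default the statistic runs on the fixational variant, where microtremor
lives; peak lags break ties toward the smaller lag.

**Spectra.** Because validity masks puncture the series, one FFT over the
whole recording is undefined. Spectra are computed per contiguous valid
segment of ≥ 256 samples (mean-subtracted; optional Hann taper, off by
default), interpolated as unit-mass densities onto a common 0.5 Hz grid
over [0, 500] Hz, averaged with segment-length weights, and renormalized
to unit mass. The DC bin is excluded: velocity means vanish in fixation
and residual DC would distort the cumulative curve near zero. The 0.5 Hz
grid matches the resolution at which separating frequencies are reported.

**EMD / Hilbert-Huang.** Sifting uses cubic-spline envelopes through local
maxima/minima with mirror extension of the two outermost extrema per side;
a sift is accepted when the normalized squared change between consecutive
sifts falls below 0.2 *and* the extrema/zero-crossing counts differ by at
most one (hard cap 100 sifts). Extraction stops when the residual is
monotone or has fewer than three extrema; a candidate without enough
extrema to build envelopes is folded back into the residual trend rather
than emitted as an IMF. The instantaneous frequency is the centred
difference of the unwrapped analytic-signal phase divided by 2π·Δt;
the first and last 5% of samples are excluded from all IF/IA summaries
(Hilbert edge effects), and negative IF samples (non-IMF-like local
behaviour) are excluded from the histograms and counted. IF cdfs use the
same 0.5 Hz bins on [0, 500] Hz; IF samples are pooled across a
recording's valid segments before binning. IMFs S1–S3 enter the feature
set; deeper IMFs are computed but not used as features.

## Group statistics

For each of the 16 feature families (4 cumulative spectra, 12 IF cdfs) and
each detection threshold (60, 120 Hz), `find_f_star` scans the 0.5 Hz grid
for the frequency maximizing |mean(P>) − mean(P<)| and reports the
Mann–Whitney U test there (midranks for ties; exact null when
min(n) ≤ 8 without ties, tie-corrected normal approximation otherwise).
A `min_p` mode selects by the smallest p instead — kept because the two
selection rules are both defensible readings of "best separating
frequency"; the mean-difference rule is the default. Ties break toward the
smallest frequency. **Caveat stated with every result:** f* is selected on
the same data the test is run on, and no multiplicity correction is
applied across the grid or the families; p-values are descriptive.
Selection is per threshold; a joint-selection option is not provided.

## Classification

The classifier predicts "detected at threshold" (positive class) from the
four cumulative-spectrum features at their f*. Evaluation is a nested
stratified 5-fold CV: inner 5-fold CV on each outer training set selects
the feature-family combination (all 15 non-empty subsets) and the tree
hyperparameters over max_depth {2,3,4,5,None}, max_features {all, sqrt},
min_samples_split {2,4,8}, min_samples_leaf {1,2,4} (Gini impurity;
balanced accuracy as the selection score because classes are imbalanced —
plain accuracy by flag). SMOTE (in-package: uniform interpolation toward
one of the k = 5 nearest minority neighbours, k reduced when the minority
is small) balances classes strictly inside training folds; test folds keep
their natural ratio, asserted by fold bookkeeping. Confusion counts are
pooled over the outer test folds; accuracy, sensitivity, specificity and
precision are reported at full precision and rounded to two decimals for
display only.

## Problem sizes used by the test suite

The synthetic study conditions are: 81 participants, 30 s recordings at
1 kHz, 9 trials each. The reversal-peak checks use one 60 s recording with
a 150 Hz tremor (the most demanding frequency: half-period 3.33 ms against
a 1 ms lag grid). The classifier parameter-recovery checks use the full
81-participant cohort at the default 30 s duration with a noiseless link
and a steep (slope 2 /Hz) detection curve — "strong link" conditions —
against a label-shuffled control; spectrum features only, since the tree
consumes the four velocity-component families. In the recovery experiment
the inner CV scores candidates by plain accuracy — the quantity the
experiment measures — rather than the package's balanced-accuracy default,
which targets the imbalanced-cohort setting; across cohort seeds the two
selection scores give statistically indistinguishable pooled accuracy. Oracle tests (isotropic
directions, tones, chirps, white noise, enumeration of rank tests) run at
a few thousand to 10⁵ samples.

What passing these tests shows — and does not. The suite demonstrates
that each stage recovers known structure from data generated under the
model's own assumptions (tones, random walks, logistic responders), and
that the pipeline's statistics behave correctly under the null. It does
not demonstrate that real gaze recordings carry a microtremor signature
this strong: real tracker noise, nonstationarity, head motion and the
tracker's event-detection errors are outside the generator.

## Degenerate inputs and numerical conventions

Zero-norm velocities, all-zero IMFs, constant signals, empty groups and
incomplete trial protocols all raise typed errors naming the offending
entity; missing data propagate as validity masks, never as zeros. Lags
must be multiples of the sampling step. Cumulative curves are interpolated
linearly between grid points. All randomness flows through
`numpy.random.Generator` objects seeded from a single configuration seed;
per-participant child generators make cohort simulation reproducible
independent of cohort size.
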