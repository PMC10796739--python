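# Methods

## The problem

Wrist-worn accelerometers record everything an arm does; only a fraction of
it is *goal-directed movement* (GDM) — purposeful reaching with a hand
trajectory toward a target. Impairment markers computed from GDM periods
track upper-limb function more specifically than whole-recording activity
summaries, but GDM periods must first be found. The package implements the
complete chain: signal conditioning, windowed GDM detection with
leave-one-subject-out (LOSO) evaluation, and downstream subject-level
analyses — driven by a synthetic cohort generator, since suitable labelled
clinical recordings are not redistributable.

## The synthetic cohort

The generator emulates a scripted activities-of-daily-living session
recorded from both wrists at 100 Hz, with labels on a 2.5 s grid.

**Subjects.** `make_cohort(n_stroke, n_control, seed)` draws a latent
impairment θ ~ Uniform(0.3, 0.9) per stroke subject and maps it to a
Fugl-Meyer upper-extremity score, FMA = round(66 − 48·θ + N(0, 4)) clipped
to [10, 66]. The slope was calibrated once, with a large-n run, so a
typical stroke group matches the FMA ≈ 37, SD ≈ 8–9 profile of moderately
impaired cohorts; controls have θ = 0 and FMA = 66. Each subject has an
affected side (for controls the non-dominant arm plays this role during
unimanual tasks).

**Task scripts.** Each subject's script contains mandatory repetitions
(two bimanual, two unimanual, one passive segment of 5–10 s each — every
participant performs every motor task, as in scripted protocols) and is
filled to 120 s with segments drawn as task-free 65 %, passive 15 %,
bimanual 10 %, unimanual 10 % (5–20 s each). Task-free time dominating the
recording gives a GDM *window* share of ~0.25–0.35, the imbalance regime
of real ADL monitoring. Durations are free parameters of the generator;
120 s per subject keeps a full 30-subject LOSO run around half a minute
while leaving ~250 windows per subject.

**Signals.**

* *GDM (active wrist of unimanual/bimanual segments):* trains of
  minimum-jerk reaches — along-track position s(τ) = d(10τ³ − 15τ⁴ + 6τ⁵),
  acceleration its analytic second derivative, direction uniform on the
  sphere, d ~ U(0.2, 0.6) m scaled by (1 − 0.5·θ), duration U(0.5, 1.5) s,
  inter-reach holds U(0.1, 0.4) s. Impairment adds (i) Poisson(3θ)
  corrective sub-movements per reach (1–3 cm, 0.3–0.5 s) and (ii) 4–6 Hz
  action tremor with amplitude θ·(0.1 + 0.5·min(envelope, 1.5)) m/s²,
  where the envelope is the smoothed magnitude of the reach acceleration.
  Net effect, by construction: lower amplitude statistics (RMS, median,
  max) and more zero crossings with rising impairment. Corrective
  movements are deliberately small and slow — fast blips would have
  min-jerk accelerations ∝ d/T² large enough to *raise* RMS and invert
  the clinical direction of the contrast; similarly, tremor is
  envelope-modulated because a constant tremor floor raises the magnitude
  median during holds, again against the clinical direction.
* *Passive segments* (both wrists): gait-like swing, a 1.8–2.2 Hz
  sinusoid of amplitude 1–2 m/s² along a random direction. This is the
  hard negative class: periodic, high-energy, non-goal-directed.
* *Task-free segments*, and the passive wrist of unimanual segments
  (which is also labelled task-free, per the labelling convention):
  coloured noise (white noise low-passed at 3 Hz, 0.15 m/s² RMS).
* *Everything* rides on a 9.81 m/s² gravity vector whose orientation
  performs a slow random walk, plus 0.05 m/s² white sensor noise. Gravity
  is included so the 0.1 Hz high-pass demonstrably removes it.

**What the generator does not emulate:** posture-dependent gravity
artefacts correlated with task, sensor saturation and calibration error,
idiosyncratic compensatory movement strategies, within-subject variation
over days, and any overlap between classes beyond the passive/GDM
spectral proximity. Detection scores on this cohort are therefore upper
bounds: the synthetic GDM/non-GDM contrast is cleaner than in real
recordings (the LOSO AUC here is ≈ 0.99 where real-data studies report
≈ 0.9). Passing the recovery tests shows the *pipeline* is correct and
leak-free, not that real-world accuracy would be this high.

## Conditioning

Band-pass 0.1–12 Hz, 4th-order Butterworth, applied forward–backward
(`sosfiltfilt`): offline analysis allows zero-phase filtering, which keeps
the labels aligned with the signal; the effective amplitude response is
the squared designed response, which is what the filter tests check. The
0.1 Hz edge implies ~10 s transients; property checks therefore exclude
generous edges (the data itself is never trimmed). Decimation to 25 Hz
keeps every 4th sample — the 12 Hz low-pass sits below the 12.5 Hz target
Nyquist, so no extra anti-alias filter is needed, and the filter-then-
decimate order is preserved. Velocity is the cumulative trapezoid of
acceleration from zero initial velocity, re-filtered with the same
band-pass (which removes integration drift). Velocity is kept in physical
m/s; no attempt is made to match any particular integration scaling used
elsewhere.

## Windows and labels

3 s windows (75 samples) with 70 % overlap. The fractional hop
75·0.3 = 22.5 floors to 22 samples (overlap 70.7 %) — denser windows lose
no data. A window is GDM when ≥ 1/3 of its samples are GDM ("one third"
read inclusively); per-sample GDM truth is: bimanual, or unimanual on the
active side. Fractional window lengths floor to whole samples (2.5 s at
25 Hz → 62), so the window size is a genuine config parameter.
Normalization is per channel (mean/SD pooled over all training-window
samples, population SDs so the training set standardizes exactly);
whether acceleration and velocity should be normalized jointly is
unstated in the source protocols — per-channel is used.

## Detection and evaluation

The reference backend is gradient-boosted trees (XGBoost, `hist`,
depth 4, learning rate 0.1, ≤ 300 rounds) over a per-window summary
representation: the 28-feature descriptor computed window-wise on the
normalized windows. Trees over summary features are the standard shallow
baseline for multivariate time-series windows and are deterministic given
a seed, which the evaluation and acceptance runs rely on. A convolutional
backend could sit behind the same interface but is intentionally not
included. Class weights are each class's *other*-class training
proportion (proportions rather than count ratios; equivalent up to loss
scale). Early stopping (20 rounds, validation AUC) and threshold
selection both use only the validation split; the threshold maximizes
√(TPR·TNR) over the exact candidate grid (unique scores plus midpoints),
ties toward the lower threshold.

LOSO: one split per subject; ceil(10 %) of the remaining subjects (≥ 1),
drawn subject-wise by a seeded RNG, form the validation set. The
normalizer, class weights, model and threshold are all refitted per
split, so nothing is ever estimated from the held-out subject. Split
metrics (rank-based AUC with tie averaging, balanced accuracy =
(sensitivity + specificity)/2, F1) are aggregated as unweighted means;
pooled per-window metrics are reported alongside. Splits whose test
subject has a single window class report threshold metrics only (AUC
NaN, excluded from the mean with a warning).

## The 28-feature descriptor

For acceleration and velocity separately: Pearson correlations of the
three axis pairs; the number, mean length and length entropy of
*zero-crossing segments* (maximal same-sign runs, pooled over the three
axes — pooling rather than per-axis averaging is a documented choice);
and min, max, median, RMS, dominant frequency over energy, skewness,
excess kurtosis and entropy of the per-sample magnitude.

Estimator conventions that the underlying protocols leave open, fixed
here once:

* crossing-length entropy: Shannon entropy of the exact empirical
  run-length distribution, natural log;
* magnitude entropy: 100-bin histogram over the epoch's own range,
  base-2 log (epoch entropies then sit just under log₂100 ≈ 6.64,
  consistent with reported values near 6.5);
* dominant frequency over energy: plain |FFT|² periodogram, DC excluded
  from the arg-max but included in the energy sum, value in Hz per unit
  energy;
* kurtosis is *excess* kurtosis (reported group tables contain negative
  values, impossible for raw kurtosis);
* zeros inherit the previous nonzero sign (leading zeros the next one;
  an all-zero axis is one full-length run), so runs partition the series;
* zero-variance input: skewness, kurtosis, correlation and entropy are 0
  by convention.

A vectorized batch path computes the descriptor for thousands of windows
at once and is tested for exact agreement with the per-epoch reference
implementation. Because features are recomputed per LOSO split on
normalized windows, this path is what keeps a full cohort evaluation
under a minute.

## Downstream analyses

Window predictions (each subject predicted exactly once, by the model
from its own held-out split) are converted to per-sample masks by
majority vote over the covering windows (an "any covering window" rule is
available as a config flag). Each subject's masked samples from both
wrists are concatenated into one epoch — crossing runs do not span the
concatenation boundaries in any meaningful sense, a negligible edge
effect at these epoch lengths — and summarized with the same descriptor;
subjects with fewer than 8 masked samples are logged and excluded.

* **Classification** (stroke vs control, stroke positive): elastic-net
  logistic regression, LOSO over subjects, features standardized within
  each training fold, hyperparameters (mixing ∈ {0.1, 0.5, 0.9},
  10-point logarithmic C grid) by 3-fold inner CV. Reported: balanced
  accuracy, sensitivity, specificity, mean |coefficient| per feature.
* **FMA regression** (stroke subjects only): elastic-net linear
  regression, same protocol (30-point alpha grid); reported as MAE and
  explained variance 1 − Var(residual)/Var(FMA) on held-out predictions,
  floored at −1.
* **Group statistics**: per feature, group means and sample SDs, pooled-SD
  Cohen's d (stroke − control; negative where stroke is lower) and the
  matching pooled-variance two-sided t-test. With printed two-decimal
  group summaries and n = (20, 10) this convention reproduces published
  effect-size tables to ±0.02 except where the printed inputs are
  themselves rounding-dominated (SDs of order 0.01–0.2, or values below
  ~1e-4).

Both analyses are run for two feature sources — detected GDM periods and
the entire recording — because the comparison (GDM features carry more
group information) is itself a result the pipeline must be able to
produce.

## Problem sizes and determinism

Default conditions: 30 subjects (20 stroke, 10 control), two wrists,
120 s per session at 100 Hz raw → ~8,000 windows per cohort; a full LOSO
evaluation plus downstream analyses takes under a minute on one CPU.
All randomness flows through seeds: per-session seeds are derived via
`SeedSequence([cohort_seed, subject, side])`, so any stream is
reproducible independently of cohort size; the gbt backend is
deterministic given its seed (single-threaded training), and repeated
`run_all` calls produce byte-identical reports.

## Known limitations

* The detector operates near ceiling on the synthetic cohort; relative
  comparisons (GDM-period vs entire-recording features, contrast
  directions) are meaningful, absolute numbers are not forecasts for
  real data.
* The sample-level GDM mask inherits 3 s window smearing: detected
  periods include quiet samples near true bursts, which dilutes
  amplitude-based group contrasts relative to ground-truth masks.
* Velocity features depend on the documented integration scaling;
  magnitudes are not comparable across different scaling conventions.
* No gyroscope, orientation tracking or sensor fusion: the simulator and
  pipeline are accelerometer-only by design.
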