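# gdmwear

Detection of upper-limb **goal-directed movements (GDM)** from wrist-worn
tri-axial accelerometers, and subject-level impairment markers derived from
the detected movement periods.

Purposeful reach-and-grasp movements are the atomic components of upper-limb
function; stroke degrades their amplitude and smoothness. Simple activity
counts cannot separate purposeful from incidental arm motion, so this
package implements the full analysis chain used in wearable stroke
monitoring studies:

1. **Synthetic cohort** (`gdmwear.synthcohort`) — a labelled two-wrist
   activities-of-daily-living simulator: 20 "stroke" subjects with latent
   impairment `θ ~ U(0.3, 0.9)` and Fugl-Meyer scores
   `FMA = 66 − 48·θ + ε` (giving the usual FMA ≈ 37 ± 8 stroke cohort), and
   10 controls. GDM segments are trains of minimum-jerk reaches,
   `s(τ) = d(10τ³ − 15τ⁴ + 6τ⁵)`, with impairment-graded amplitude loss,
   4–6 Hz action tremor and corrective sub-movements; passive segments are
   1.8–2.2 Hz gait swing; task-free segments are low-amplitude coloured
   noise; gravity (9.81 m/s², slowly drifting orientation) rides on
   everything.
2. **Preprocessing** (`gdmwear.preprocess`) — zero-phase 4th-order
   Butterworth band-pass 0.1–12 Hz, decimation to 25 Hz, velocity by
   trapezoidal integration followed by the same band-pass.
3. **Windowing** (`gdmwear.segmentation`) — 3 s windows with 70 % overlap
   (hop 22 samples); a window is GDM when ≥ 1/3 of its samples are GDM
   (bimanual, or unimanual on the active side). Per-channel normalization
   is fitted on training data only.
4. **Detection** (`gdmwear.detector`) — gradient-boosted trees over a
   28-feature window descriptor, class-weighted (each class by the other's
   training share), early-stopped on a validation split, with the operating
   threshold chosen by maximizing √(TPR·TNR) on validation scores.
5. **Evaluation** (`gdmwear.evaluation`) — leave-one-subject-out
   cross-validation (10 % of training subjects held out for validation per
   split): AUC, balanced accuracy, sensitivity, specificity, F1, plus
   per-task accuracy tables.
6. **Downstream markers** (`gdmwear.downstream`) — the 28-feature
   descriptor over the detected GDM periods of both wrists per subject
   (correlation of axis pairs; number, mean length and length entropy of
   zero-crossing segments; min / max / median / RMS / dominant frequency
   over energy / skewness / kurtosis / entropy of the magnitude, for
   acceleration and velocity), then elastic-net logistic classification of
   stroke vs control, elastic-net regression of the FMA score, and
   per-feature group statistics with pooled-SD Cohen's d,
   `d = (m₁ − m₂) / s_p`, `s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)`.

## Worked example

```python
from gdmwear.config import PipelineConfig
from gdmwear.pipeline import run_all

loso, downstream = run_all(PipelineConfig(), "reports", seed=1)
print({k: round(v, 3) for k, v in loso.mean.items()})
print(round(downstream.classification["gdm_periods"].balanced_accuracy, 2),
      round(downstream.classification["entire_recording"].balanced_accuracy, 2))
print(round(downstream.regression["gdm_periods"].mae, 2))
```

prints (seed 1, default 30-subject cohort):

```
{'auc': 0.998, 'balanced_accuracy': 0.979, 'sensitivity': 0.976, 'specificity': 0.983, 'f1': 0.967}
1.0 0.8
4.21
```

The first line is the mean LOSO window-level detection performance — on
this synthetic cohort the GDM/non-GDM contrast is cleaner than in real
recordings, so the detector sits near ceiling. The second line shows that
classifying stroke vs control from features of *detected GDM periods*
(balanced accuracy 1.0) beats using the entire recording (0.8): the
impairment signal lives in the goal-directed segments. The third line is
the LOSO elastic-net error of the predicted FMA score in points (the
simulated stroke group has FMA SD ≈ 10, so the model clearly beats a
mean predictor). `reports/` receives the LOSO report, the downstream
report, the per-task accuracy table and a group-statistics CSV sorted by
|Cohen's d|.

The same pipeline is scriptable from the shell:

```bash
gdmwear simulate --n-stroke 20 --n-control 10 --seed 1 --out cohort/
gdmwear preprocess --in cohort/S01_left.csv --out S01_left_kin.csv
gdmwear run-all --seed 1 --out reports/
gdmwear init-config --out pipeline.yaml   # all defaults, editable
```

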