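# strokefall

Pre-impact fall detection for people with chronic stroke, rebuilt as a
reusable, tested analysis pipeline over synthetic wearable-IMU data.

## The problem

Wearable airbag systems must decide, from body-worn inertial sensors, that a
fall is underway *before* the body hits the ground — early enough (a lead
time `t_l`, at least 75 ms for the actuator) to inflate. Detection models
for such devices are typically trained on movement data from neurologically
healthy adults. Stroke changes movement kinematics (slower gait, asymmetry,
weaker compensatory stepping), so a control-trained model may silently
under-detect falls in exactly the population that needs the device most.

This package implements the full analysis needed to study that question:

1. **Synthetic cohort generator** (`strokefall.synthetic_data`) — 3 IMUs
   (left hip, right hip, lower back; ±16 g accelerometer, ±2000 deg/s
   gyroscope, 500 Hz) recording laboratory sessions of lateral falls,
   anterior–posterior (AP) falls, near-falls, and activities of daily
   living (ADLs), with parametric cohort differences and a fall phase
   model: instability → descent → impact → rest.
2. **Preprocessing** (`strokefall.preprocessing`) — fourth-order 0.1–50 Hz
   Butterworth band-pass (zero-phase) on accelerometer channels; impact
   detection `t_p` = peak acceleration-vector magnitude; evaluation windows
   of `w` = 250 frames (500 ms) at lead time `t_l`:

   ```
   t_s = t_p − t_l − w        t_e = t_p − t_l
   ```

   Non-fall windows are drawn uniformly from the latter half of the event
   region; defective events are excluded.
3. **Feature extraction** (`strokefall.feature_extraction`) — 7 statistics
   (min, median, max, IQR, SD, skew, kurtosis) × 18 channels = **126
   features** per window.
4. **Evaluation** (`strokefall.evaluation`) — two identical AdaBoost
   ensembles (50 estimators, learning rate 1): a *stroke-trained* model
   under leave-one-subject-out (LOSO) cross-validation and a
   *control-trained* model tested on the same held-out stroke subjects;
   severity-stratified leave-one-group-out (LOGO) over 5-subject subgroups
   with k = 0…5 unstable ambulators; lead-time sweeps over
   {50, 100, 150, 200, 300, 400, 500} ms; recall / precision / F1 / AUC.
5. **Statistics** (`strokefall.statistics`) — two-tailed paired t tests per
   metric per fall family (all / lateral / AP), Holm–Bonferroni step-down
   (`P_k < α/(m+1−k)`) within each family.

## Worked example

```python
from strokefall.studies import cohort_comparison, planted_ap_effect_config
from strokefall.synthetic_data import generate_cohort_dataset

dataset = generate_cohort_dataset(
    planted_ap_effect_config(seed=1, ap_scale=0.45, noise_sd_g=0.35, jitter=0.25)
)
comp = cohort_comparison(dataset, lead_time_ms=75.0, seed=1)
recall = comp.table[comp.table.metric == "recall"]
print(recall[["family", "mean_diff", "t", "p", "significant_holm"]])
```

prints (stroke-trained minus control-trained recall, one pair per held-out
stroke subject):

```
    family  mean_diff       t       p  significant_holm
0      all     0.4167  5.9161  0.0006              True
1  lateral     0.0417  1.0000  0.3506             False
2       ap     0.8333  9.3541  0.0000              True
```

The generator planted a stroke-specific AP-fall signature (subtler
pre-impact motion) while keeping lateral falls cohort-identical, and the
pipeline recovers exactly that structure: a Holm-significant recall
advantage for the stroke-trained model overall (+0.42) that is driven by
AP falls (+0.83) while the lateral difference is small and not
significant. The numbered scripts under `analysis/` run the same
experiments end to end — dataset composition audit, window validation,
cohort comparison, non-fall composition grid, severity-stratified LOGO,
lead-time sweep, and null calibration — writing their tables under
`results/`.

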