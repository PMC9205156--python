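# Methods

This note documents the models, conventions, and design choices behind
`strokefall`, and what its synthetic experiments do and do not establish.

## Synthetic recordings

Real pre-impact fall data from stroke and control cohorts are not publicly
deposited, so the package generates its own. A recording is an 18-channel
series at 500 Hz — three sensors (left hip, right hip, lower back), each
with a 3-axis accelerometer (g, clipped to ±16) and gyroscope (deg/s,
clipped to ±2000) — containing a randomized sequence of events separated by
quiet stance.

**Fall phase model.** A fall is synthesized as four phases:

* *instability* — angular velocity about the fall axis (roll for lateral,
  pitch for AP) grows as `growth · t` with a 25% oscillatory modulation;
  the gravity vector rotates with the integrated angle (capped at 65°).
  Default duration 450 ms (control), growth 600 deg/s².
* *descent* — acceleration magnitude ramps from 1 g toward a floor
  `1 − 0.85·s` (s = signature scale, so a vivid fall approaches free
  fall at 0.15 g) while rotation continues from the instability's end
  angle; default 280 ms.
* *impact* — a 20–60 ms half-sine spike on the fall-axis accelerometer
  with the configured peak (default 6.5 g), attenuated 10%/20% at the
  contralateral hip / lower back; the spike's centre frame is the
  ground-truth impact.
* *rest* — static 1 g lying on the fall side (~300 ms).

Near-falls share the instability model (at 0.8× scale) but end in a
compensatory gyro burst proportional to the subject's `comp_gain` and a
return to gait; they never dip below ~0.6 g or spike. ADLs cover walking
(gait-frequency oscillation with left/right asymmetry), sitting, lying
(static, magnitude exactly 1 g without noise), sit-to-stand, and jumping —
the jump's sub-1 g flight phase and ~4 g landing spike make it a deliberate
hard negative.

**Noise model.** White Gaussian noise per channel (default 0.05 g / 2
deg/s) plus slow accelerometer baseline wander — three random sinusoids at
0.05–0.5 Hz with total amplitude ~0.03 g per channel — standing in for bias
instability and postural sway. The wander matters: without it, the
band-pass filter's slow compensation lobes around impact (see below) are
the dominant low-frequency content and become an artifactual classification
cue.

**Cohorts.** Subject parameters are drawn per cohort: gait speed
N(1.22, 0.19) m/s for control and N(0.88, 0.29) for stroke, with per-subject
lognormal jitter (8% default) on all kinematic parameters. Stroke means are
shifted multiplicatively: slower gait frequency (×0.75), stronger asymmetry
(×4), longer instability (×1.5), slower growth (×0.8), weaker compensation
(×0.6). The first `n_unstable` stroke subjects (default 5 of 20) are
labelled unstable ambulators and receive further shifts. These magnitudes
are free generator parameters chosen to be directionally consistent with
reported post-stroke movement differences (postural stability, trunk
control, compensatory stepping); they estimate nothing.

`null_cohorts=true` draws both cohorts from the control distribution while
keeping labels — the basis of the null-calibration study. The
`ap_signature_scale` / `lat_signature_scale` parameters scale the
instability growth and descent depth of one fall direction only, which is
how the planted-effect studies make stroke AP falls *subtler* (harder to
see pre-impact) rather than merely weaker copies of control falls.

**Determinism.** One master seed; each subject's stream derives from
(seed, cohort, subject index), so a subject's recording is invariant to
changes in the other cohort's size. Identical config + seed reproduces
identical bytes.

**Session composition.** The default study configuration generates 20
stroke + 15 control subjects with per-cohort event totals 327/112/259/156
(stroke lateral/AP/ADL/near) and 283/120/303/243 (control) — 842 falls and
961 non-falls — distributed as evenly as possible over subjects (every
subject performs each requested subtype at least twice).

## Preprocessing

Accelerometer channels are filtered with a fourth-order Butterworth
band-pass, 0.1–50 Hz, applied zero-phase (forward–backward), because the
analysis is offline; a deployed device would have to filter causally
(single-pass, with group delay), which `scipy.signal.sosfilt` on the same
design provides if deployment realism is wanted. Gyroscope channels pass
through raw. "Fourth-order"
is read as the design order passed to `scipy.signal.butter` (the band-pass
transfer function is order 8). Injected missing stretches are bridged by
linear interpolation for the filter pass and re-inserted afterwards so
missingness stays local to the defective event.

Impact time `t_p` is the frame of maximum 3-axis acceleration-vector
magnitude, maximized over the three sensors, within the event region, with
ties resolved to the earliest frame (the identification rule is not
otherwise pinned down; a pelvis-worn array sees the impact in any fall
direction). On default synthetic falls this recovers the generator's
ground truth within 50 ms in >95% of events.

Windows are 250 frames (500 ms), half-open `[t_s, t_e)`, 0-based, with
`t_e = t_p − lead` and lead times converted at 500 Hz by ceiling
(75 ms → 38 frames) so the realized lead is never shorter than requested.
Non-fall windows end uniformly within the latter half of the event region
(re-drawn up to 10 times, then clipped, when the region is barely longer
than the window). Events flagged defective, windows leaving the recording,
and windows containing missing samples are excluded and counted.

**Zero-phase filtering is acausal.** The impact spike and any sustained
post-impact orientation change are low-frequency-rich; `filtfilt` spreads
their compensation lobes symmetrically ±seconds around the event. Real
offline pipelines with zero-phase filters share this property. It means
"pre-impact" windows are not perfectly insulated from post-impact signal —
which is why the confined-signal probe generator (below) keeps the
post-impact rest phase upright and uses a modest 4 g spike.

## Features and models

Each window yields 7 statistics per channel (126 features): min, median,
max, interquartile range (linear-interpolation percentiles), sample SD
(n−1), Fisher–Pearson skew, and excess kurtosis, with skew = kurtosis = 0
on zero-variance channels. The conventions are centralized in
`feature_extraction.channel_statistics`. Columns are named
`{location}_{modality}_{axis}_{stat}` and ordered lexicographically.

Classification uses scikit-learn's `AdaBoostClassifier` (decision-tree
base learners, 50 estimators, learning rate 1) behind a narrow interface;
ROC/AUC are computed from the ensemble's continuous decision score, never
from hard labels. Schemes: LOSO over the stroke cohort; a control-trained
model fit once on all controls and tested per stroke subject (iteration
ids match LOSO so metrics pair 1:1); and severity-stratified LOGO, where
for each 5-subject stroke subgroup the stroke-trained model is fit on the
subjects outside the subgroup. Subgroups with exactly k unstable
ambulators are enumerated exhaustively and sampled without replacement only
beyond `max_groups` (100); with 5 unstable / 15 stable the feasible counts
at k = 4 and 5 are 75 and 1. Subject-level train/test disjointness is
asserted in every scheme.

**Undefined metrics.** Precision is undefined when a model predicts no
falls, AUC when a test subject lacks one class, F1 when a component is;
such iterations are flagged, excluded from means/SDs, and removed
pairwise-complete before paired tests. Counts are retained in the reports.

## Paired statistics

Per-metric paired t tests (two-tailed, df = n−1) compare the two models
over identical test units, Holm–Bonferroni-corrected across the three
fall-type families (all/lateral/AP; m = 3) at α = 0.05: sort P values
ascending, reject while `P_k < α/(m+1−k)`, stop at the first failure. The
step-down stop is essential — an ascending scan that *begins* rejecting at
the first satisfied inequality would not control the family-wise error
rate. Edge cases: all-zero differences give P = 1; differences that are
identical and non-zero leave t unbounded, so `paired_ttest` raises and the
comparison table reports that family as untested (P = NaN,
`degenerate=True`), shrinking the Holm family — a conservative choice that
arises in practice when a planted effect is strong enough that every
held-out subject shows the identical discrete recall difference. Families
with fewer than two complete pairs are handled the same way. Ties among P
values sort stably.

## Study conditions

Replicated studies run on small fixed cohorts so hundreds of end-to-end
replicates fit in minutes on one CPU; the full 35-subject session is used
for composition accounting. Sizes are stated in
`strokefall.studies`:

* **Null calibration** — 5 control + 6 stroke subjects, 10 events each,
  drawn from one common, deliberately hard distribution (80 ms descent so
  the window is dominated by instability that near-falls share, 0.5 g
  noise, 30% parameter jitter): per-subject recall genuinely varies, so
  the paired t tests are exercised on non-degenerate differences. 200
  replicates; the family-wise rejection rate of the recall family should
  not exceed α (0.05) up to Monte-Carlo noise.
* **Effect recovery** — cohorts identical except stroke AP falls carry a
  0.35× pre-impact signature. The control-trained model, trained on vivid
  AP falls, scores subtle ones below its threshold; the stroke-trained
  model learns them. Measured as the fraction of 25 replicates in which
  stroke-trained mean recall exceeds control-trained.
* **Severity trend** — unstable ambulators carry a further 0.55× AP *and*
  lateral signature; LOGO recall of the control-trained model is expected
  to fall as k grows (Spearman ρ ≤ 0 over k = 0…4 with 10 stroke / 4
  unstable subjects).
* **Confined-signal sweep** — instability 40 ms, descent 50 ms (intense
  growth), 4 g spike, upright rest, walking-only ADLs: all pre-impact
  information lives in the final ~100 ms and long-lead windows show plain
  gait that the negatives share. Mean AUC curves are averaged over 3
  generated datasets; AUC at 50 ms lead should be at least AUC at 500 ms.

## What the synthetic experiments do and do not show

Passing these suites demonstrates that the *pipeline* is correct and well
calibrated: windows and counts are exact, AUC equals the Mann–Whitney
concordance, Holm matches a brute-force step-down, the comparison rejects
at ≤ α under a true null, and planted cohort structure of the kind the
analysis is designed to detect is recovered with the right directionality.
They do not validate the generator as a biomechanical model — waveforms
are stylized templates, real stroke kinematic differences are not
estimated, and the published performance numbers from the original cohorts
(e.g., recall 0.905 vs 0.800) are not reproducible without the
non-deposited recordings; on synthetic cohorts those contrasts are
reproduced directionally only.

## Known limitations

* The fall templates have discontinuous orientation at the rest/stance
  boundary and no translation kinematics; "realism" is limited to the
  features the pipeline consumes.
* The severity label is assigned by the generator; the clinical criteria
  that defined unstable ambulators are out of scope, and the surrogate
  (exaggerated signature scales) encodes the hypothesis, not patient data.
* AdaBoost is the only classifier exercised; the interface admits others
  but none are tested.
* Per-iteration AUC on single-subject test sets with few falls is coarse
  (granularity ~1/(falls × non-falls)); replicated studies average over
  seeds for this reason.
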