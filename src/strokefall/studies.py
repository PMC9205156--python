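"""Named study conditions and end-to-end experiment runners.

This module pins down, once, the generator configurations under which the
analysis' claims are checked, and provides the runners that execute the
full pipeline (simulate → filter/window → features → cohort-dependent
models → paired statistics) under each:

* :func:`cohort_comparison` — the headline control- vs stroke-trained
  comparison across the all/lateral/AP fall families with Holm-corrected
  paired t tests;
* :func:`null_calibration_study` — the same comparison on cohorts drawn
  from one common distribution, replicated to measure the family-wise
  false-rejection rate of the recall family;
* :func:`effect_recovery_study` — cohorts identical except for a planted,
  subtler pre-impact signature of stroke AP falls; measures how often the
  stroke-trained model's mean recall exceeds the control-trained model's;
* :func:`severity_trend_study` — unstable ambulators carry an exaggerated
  (subtler still) signature; measures the rank correlation between the
  number of unstable ambulators in a LOGO test subgroup and the
  control-trained model's mean recall;
* :func:`confined_signal_sweep` — fall signatures confined to the final
  ~100 ms before impact, so short lead times must beat long ones.

Replicated studies use small cohorts and event counts (stated in each
config) so that many seeded replicates are practical on one CPU; the full
Table-1-style session composition is exercised by
:func:`strokefall.synthetic_data.study_composition_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .evaluation import (
    DEFAULT_LEAD_GRID_MS,
    DEFAULT_LEAD_TIME_MS,
    EvaluationReport,
    LeadTimeSweepResult,
    lead_time_sweep,
    run_control_trained,
    run_logo_severity,
    run_loso_stroke,
)
from .feature_extraction import build_feature_matrix
from .preprocessing import PreprocessedDataset, preprocess_dataset
from .statistics import compare_models
from .synthetic_data import (
    CohortSpec,
    Dataset,
    DatasetConfig,
    KinematicParams,
    generate_cohort_dataset,
)

FAMILIES = ("all", "lateral", "ap")
_FAMILY_SUBTYPE = {"all": None, "lateral": "lateral_fall", "ap": "ap_fall"}


# ---------------------------------------------------------------------------
# named generator configurations (the study conditions)
# ---------------------------------------------------------------------------


def null_calibration_config(seed: int) -> DatasetConfig:
    """Both cohorts drawn from one common distribution: 5 control + 6
    stroke subjects, 10 events each (3 lateral, 2 AP, 3 ADL, 2 near-fall).

    The common kinematics are deliberately hard (80 ms descent so the
    pre-impact window is dominated by instability that near-falls share,
    0.5 g channel noise, 30% between-subject parameter jitter): per-subject
    recall then genuinely varies and the paired t tests are exercised on
    non-degenerate differences rather than on all-ones metrics.
    """
    base = replace(
        KinematicParams(), descent_duration_ms=80.0, noise_sd_g=0.5, noise_sd_dps=30.0
    )
    spec = CohortSpec(gait_speed_mean=1.22, gait_speed_sd=0.19, base=base, jitter=0.3)
    return DatasetConfig(
        n_control=5,
        n_stroke=6,
        n_unstable=0,
        event_counts={
            "stroke": {"lateral_fall": 18, "ap_fall": 12, "adl": 18, "near_fall": 12},
            "control": {"lateral_fall": 15, "ap_fall": 10, "adl": 15, "near_fall": 10},
        },
        control=spec,
        stroke=spec,
        null_cohorts=True,
        seed=seed,
    )


def planted_ap_effect_config(
    seed: int,
    ap_scale: float = 0.35,
    noise_sd_g: float = 0.05,
    jitter: float = 0.08,
) -> DatasetConfig:
    """Cohorts identical except stroke AP falls carry a subtler pre-impact
    signature (growth rate and descent depth scaled by ``ap_scale``);
    lateral-fall kinematics are generated cohort-identical.  6 control + 8
    stroke subjects, 11 events each (3 lateral, 3 AP, 3 ADL, 2 near-fall).

    ``noise_sd_g``/``jitter`` harden the condition (more channel noise,
    more between-subject spread) so per-subject recall varies; the
    defaults keep the clean planted-effect condition used for effect
    recovery.
    """
    base = replace(
        KinematicParams(), noise_sd_g=noise_sd_g, noise_sd_dps=noise_sd_g * 60.0
    )
    stroke = CohortSpec(
        gait_speed_mean=1.22,
        gait_speed_sd=0.19,
        base=replace(base, ap_signature_scale=ap_scale),
        jitter=jitter,
    )
    return DatasetConfig(
        n_control=6,
        n_stroke=8,
        n_unstable=0,
        event_counts={
            "stroke": {"lateral_fall": 24, "ap_fall": 24, "adl": 24, "near_fall": 16},
            "control": {"lateral_fall": 18, "ap_fall": 18, "adl": 18, "near_fall": 12},
        },
        control=CohortSpec(gait_speed_mean=1.22, gait_speed_sd=0.19, base=base, jitter=jitter),
        stroke=stroke,
        seed=seed,
    )


def severity_effect_config(seed: int) -> DatasetConfig:
    """Planted-AP-effect cohorts where unstable ambulators carry an
    exaggerated effect: their AP and lateral fall signatures are a further
    0.55x subtler.  6 control + 10 stroke subjects (4 unstable)."""
    base = planted_ap_effect_config(seed)
    return replace(
        base,
        n_stroke=10,
        n_unstable=4,
        event_counts={
            "stroke": {"lateral_fall": 30, "ap_fall": 30, "adl": 30, "near_fall": 20},
            "control": {"lateral_fall": 18, "ap_fall": 18, "adl": 18, "near_fall": 12},
        },
        unstable_multipliers={"ap_signature_scale": 0.55, "lat_signature_scale": 0.55},
    )


def confined_signal_config(seed: int) -> DatasetConfig:
    """Fall pre-impact information confined to roughly the final 100 ms:
    instability 40 ms, descent 50 ms, with an intense growth rate so the
    short window still carries signal.  5 control + 6 stroke subjects."""
    confined = replace(
        KinematicParams(),
        instab_duration_ms=40.0,
        descent_duration_ms=50.0,
        instab_growth_dps2=6000.0,
        impact_peak_g=4.0,
        rest_upright=True,
    )
    spec = CohortSpec(gait_speed_mean=1.22, gait_speed_sd=0.19, base=confined)
    return DatasetConfig(
        n_control=5,
        n_stroke=6,
        n_unstable=0,
        event_counts={
            "stroke": {"lateral_fall": 12, "ap_fall": 18, "adl": 24, "near_fall": 12},
            "control": {"lateral_fall": 10, "ap_fall": 15, "adl": 20, "near_fall": 10},
        },
        control=spec,
        stroke=spec,
        # walking-only ADLs: at long leads the pre-impact window shows
        # plain gait, which must dominate the non-falls for the sweep to
        # reflect where the fall information lives rather than the ease of
        # rejecting static postures
        adl_kinds=("walk",),
        seed=seed,
    )


def high_separability_config(seed: int) -> DatasetConfig:
    """Near-noiseless, vivid-signature cohorts for separability checks."""
    quiet = replace(KinematicParams(), noise_sd_g=0.005, noise_sd_dps=0.2)
    spec = CohortSpec(gait_speed_mean=1.22, gait_speed_sd=0.19, base=quiet, jitter=0.03)
    return DatasetConfig(
        n_control=4,
        n_stroke=6,
        n_unstable=0,
        event_counts={
            "stroke": {"lateral_fall": 18, "ap_fall": 12, "adl": 18, "near_fall": 12},
            "control": {"lateral_fall": 12, "ap_fall": 8, "adl": 12, "near_fall": 8},
        },
        control=spec,
        stroke=spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------


def family_matrix(matrix: pd.DataFrame, family: str) -> pd.DataFrame:
    """Rows for one fall-type family: that family's falls plus all non-falls."""
    subtype = _FAMILY_SUBTYPE[family]
    if subtype is None:
        return matrix
    keep = (matrix["activity_class"] == "non_fall") | (matrix["subtype"] == subtype)
    return matrix[keep]


@dataclass
class CohortComparison:
    """Paired control- vs stroke-trained reports per fall family + statistics."""

    control_reports: dict[str, EvaluationReport]
    stroke_reports: dict[str, EvaluationReport]
    table: pd.DataFrame  # compare_models output (stroke minus control)


def cohort_comparison(
    dataset: Dataset | PreprocessedDataset,
    lead_time_ms: float = DEFAULT_LEAD_TIME_MS,
    nonfall_filter: str = "both",
    seed: int = 0,
    families: tuple[str, ...] = FAMILIES,
) -> CohortComparison:
    """Control- vs stroke-trained comparison across fall-type families.

    One feature matrix is built per cohort at the given lead time; for each
    family, the stroke-trained model runs LOSO over the stroke cohort and
    the control-trained model (fit on all controls) is tested on the same
    held-out subjects, giving paired per-iteration metrics.  The paired t
    tests are Holm-corrected across the families per metric; ``mean_diff``
    is stroke-trained minus control-trained.
    """
    pre = dataset if isinstance(dataset, PreprocessedDataset) else preprocess_dataset(dataset)
    matrix = build_feature_matrix(pre, lead_time_ms, nonfall_filter, seed)
    stroke_m = matrix[matrix["cohort"] == "stroke"]
    control_m = matrix[matrix["cohort"] == "control"]
    control_reports, stroke_reports = {}, {}
    for fam in families:
        stroke_fam = family_matrix(stroke_m, fam)
        control_fam = family_matrix(control_m, fam)
        stroke_reports[fam] = run_loso_stroke(stroke_fam, seed)
        control_reports[fam] = run_control_trained(control_fam, stroke_fam, seed)
    table = compare_models(stroke_reports, control_reports)
    return CohortComparison(control_reports, stroke_reports, table)


def null_calibration_study(
    n_replicates: int = 200, seed: int = 0, alpha: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """Family-wise false-rejection rate of the recall family under the null.

    Each replicate draws both cohorts from one common distribution, runs
    the full cohort comparison, and records whether any of the three
    Holm-corrected recall tests rejects.  Returns (rejection rate,
    per-replicate frame with the mean recall difference and the reject
    flag).
    """
    rows = []
    for r in range(n_replicates):
        rep_seed = seed * 1_000_003 + r
        dataset = generate_cohort_dataset(null_calibration_config(rep_seed))
        comp = cohort_comparison(dataset, seed=rep_seed)
        recall = comp.table[comp.table["metric"] == "recall"]
        rows.append(
            {
                "replicate": r,
                "mean_recall_diff_all": float(
                    recall.loc[recall["family"] == "all", "mean_diff"].iloc[0]
                ),
                "any_holm_rejection": bool(recall["significant_holm"].any()),
            }
        )
    frame = pd.DataFrame(rows)
    return float(frame["any_holm_rejection"].mean()), frame


def effect_recovery_study(n_seeds: int = 25, seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Fraction of planted-AP-effect replicates in which the stroke-trained
    model's mean recall (all falls) exceeds the control-trained model's."""
    rows = []
    for r in range(n_seeds):
        rep_seed = seed * 1_000_003 + r
        dataset = generate_cohort_dataset(planted_ap_effect_config(rep_seed))
        matrix = build_feature_matrix(dataset, DEFAULT_LEAD_TIME_MS, "both", rep_seed)
        stroke_m = matrix[matrix["cohort"] == "stroke"]
        control_m = matrix[matrix["cohort"] == "control"]
        loso = run_loso_stroke(stroke_m, rep_seed)
        ctrl = run_control_trained(control_m, stroke_m, rep_seed)
        rows.append(
            {
                "replicate": r,
                "stroke_trained_recall": loso.mean("recall"),
                "control_trained_recall": ctrl.mean("recall"),
            }
        )
    frame = pd.DataFrame(rows)
    frac = float((frame["stroke_trained_recall"] > frame["control_trained_recall"]).mean())
    return frac, frame


def severity_trend_study(
    n_seeds: int = 3, seed: int = 0, ks: tuple[int, ...] = (0, 1, 2, 3, 4), max_groups: int = 8
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between the unstable-ambulator count k of
    a LOGO test subgroup and the control-trained model's mean recall,
    aggregated over seeds.  Negative correlation = the control-trained
    model degrades as impairment severity in the test set grows."""
    rows = []
    for r in range(n_seeds):
        rep_seed = seed * 1_000_003 + r
        dataset = generate_cohort_dataset(severity_effect_config(rep_seed))
        matrix = build_feature_matrix(dataset, DEFAULT_LEAD_TIME_MS, "both", rep_seed)
        stroke_m = matrix[matrix["cohort"] == "stroke"]
        control_m = matrix[matrix["cohort"] == "control"]
        logo = run_logo_severity(
            control_m, stroke_m, dataset.profiles, rep_seed, ks=ks, max_groups=max_groups
        )
        for k, (ctrl_rep, stroke_rep) in logo.items():
            rows.append(
                {
                    "replicate": r,
                    "k_unstable": k,
                    "control_trained_recall": ctrl_rep.mean("recall"),
                    "stroke_trained_recall": stroke_rep.mean("recall"),
                }
            )
    frame = pd.DataFrame(rows)
    per_k = frame.groupby("k_unstable")["control_trained_recall"].mean()
    rho = float(scipy_stats.spearmanr(per_k.index.to_numpy(), per_k.to_numpy()).statistic)
    return rho, frame


def confined_signal_sweep(
    seed: int = 0,
    grid: tuple[float, ...] = DEFAULT_LEAD_GRID_MS,
    n_seeds: int = 3,
) -> dict[str, LeadTimeSweepResult]:
    """Lead-time sweep (AP falls vs all non-falls) on the confined-signal
    generator, where only short lead times can see the pre-impact signal.

    Per-iteration AUC on the small test sets is coarse, so the sweep is
    replicated over ``n_seeds`` generated datasets and the mean AUC curves
    are averaged before comparing lead times.
    """
    curves: dict[str, list[np.ndarray]] = {}
    for r in range(n_seeds):
        rep_seed = seed * 1_000_003 + r
        dataset = generate_cohort_dataset(confined_signal_config(rep_seed))
        sweeps = lead_time_sweep(
            dataset, fall_subtype="ap", nonfall_filter="both", grid=grid, seed=rep_seed
        )
        for name, res in sweeps.items():
            curves.setdefault(name, []).append(np.asarray(res.mean_auc))
    return {
        name: LeadTimeSweepResult(
            name,
            [float(g) for g in grid],
            np.nanmean(np.vstack(reps), axis=0).tolist(),
            [False] * len(grid),
        )
        for name, reps in curves.items()
    }
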