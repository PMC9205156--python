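"""Paired model comparison with family-wise error control.

Per-iteration performance metrics from two models evaluated on identical
test units form paired distributions; each metric is compared with a
classical two-tailed paired t test.  Because each metric is tested across
the three fall-type families (all / lateral / AP falls), the three P values
are corrected with the Holm-Bonferroni step-down at family-wise level
alpha = 0.05: sort P ascending and reject sequentially while

    P_k < alpha / (m + 1 - k),

stopping at the first failure.  (The sequential stop is what guarantees the
family-wise error bound; an ascending scan that starts rejecting at the
first *satisfied* inequality would not control it.)

Pairs with an undefined member (a flagged per-iteration metric) are dropped
pairwise-complete before testing, mirroring the evaluation module's
undefined-metric convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluation import METRICS, EvaluationReport

DEFAULT_ALPHA = 0.05


class StatisticsError(ValueError):
    pass


class DegenerateVarianceError(StatisticsError):
    """Non-zero mean difference with exactly zero variance."""


class InsufficientPairsError(StatisticsError):
    """Fewer than two complete pairs remain after pairwise deletion."""


@dataclass
class PairedComparison:
    metric: str
    n_pairs: int
    mean_diff: float
    t: float
    df: int
    p: float


def paired_ttest(
    values_a: Sequence[float], values_b: Sequence[float], metric: str = ""
) -> PairedComparison:
    """Two-tailed paired t test on ``a - b`` after pairwise-complete deletion."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise StatisticsError("paired sequences must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise InsufficientPairsError(f"need >= 2 complete pairs, have {n}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(metric, n, 0.0, 0.0, n - 1, 1.0)
        raise DegenerateVarianceError(
            "all paired differences identical and non-zero; t is unbounded"
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedComparison(metric, n, mean, float(t), n - 1, p)


@dataclass
class HolmResult:
    m: int
    alpha: float
    #: P values sorted ascending with their original indices.
    sorted_p: list[float]
    order: list[int]
    #: per-rank thresholds alpha / (m + 1 - k), k = 1..m.
    thresholds: list[float]
    #: rejection flags in the *original* input order.
    reject: list[bool]

    def reject_sorted(self) -> list[bool]:
        return [self.reject[i] for i in self.order]


def holm_bonferroni(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA) -> HolmResult:
    """Holm step-down: reject while P_(k) < alpha/(m+1-k), stop at the
    first failure; flags are mapped back to the input order.  Ties are
    ordered stably (original order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise StatisticsError("need at least one P value")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise StatisticsError("P values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = [alpha / (m + 1 - k) for k in range(1, m + 1)]
    reject = [False] * m
    for rank, idx in enumerate(order):
        if p[idx] < thresholds[rank]:
            reject[idx] = True
        else:
            break
    return HolmResult(
        m=m,
        alpha=alpha,
        sorted_p=[float(p[i]) for i in order],
        order=[int(i) for i in order],
        thresholds=thresholds,
        reject=reject,
    )


def compare_models(
    reports_a: Mapping[str, EvaluationReport] | EvaluationReport,
    reports_b: Mapping[str, EvaluationReport] | EvaluationReport,
    metrics: Sequence[str] = METRICS,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-metric paired comparison of two models across fall-type families.

    ``reports_a`` / ``reports_b`` map family name (e.g. ``all``,
    ``lateral``, ``ap``) to paired :class:`EvaluationReport` objects with
    identical iteration ids.  For each metric, one paired t test per family
    is run and Holm-corrected across the families (m = number of families).
    Returns one row per (family, metric) with raw and corrected flags.
    """
    if isinstance(reports_a, EvaluationReport):
        reports_a = {"all": reports_a}
    if isinstance(reports_b, EvaluationReport):
        reports_b = {"all": reports_b}
    if set(reports_a) != set(reports_b):
        raise StatisticsError("family sets differ between the two models")
    families = list(reports_a)
    for fam in families:
        ids_a = reports_a[fam].iteration_ids()
        ids_b = reports_b[fam].iteration_ids()
        if ids_a != ids_b:
            raise StatisticsError(f"family {fam!r}: iteration ids do not pair")

    rows = []
    for metric in metrics:
        comps: list[PairedComparison | None] = []
        for fam in families:
            try:
                comps.append(
                    paired_ttest(
                        reports_a[fam].values(metric), reports_b[fam].values(metric), metric
                    )
                )
            except (DegenerateVarianceError, InsufficientPairsError):
                # constant non-zero difference (t unbounded) or too few
                # complete pairs: no valid test exists; drop the family
                # from the Holm family (m shrinks) and report it untested.
                comps.append(None)
        valid = [i for i, c in enumerate(comps) if c is not None]
        holm = holm_bonferroni([comps[i].p for i in valid], alpha) if valid else None
        # holm.reject/order index into the `valid` list; rank of each valid test
        rank_of = {} if holm is None else {valid[j]: r for r, j in enumerate(holm.order)}
        for i, (fam, comp) in enumerate(zip(families, comps)):
            if comp is None:
                rows.append(
                    {
                        "family": fam,
                        "metric": metric,
                        "n_pairs": 0,
                        "mean_diff": float("nan"),
                        "t": float("nan"),
                        "df": 0,
                        "p": float("nan"),
                        "holm_threshold": float("nan"),
                        "significant_raw": False,
                        "significant_holm": False,
                        "degenerate": True,
                    }
                )
                continue
            rows.append(
                {
                    "family": fam,
                    "metric": metric,
                    "n_pairs": comp.n_pairs,
                    "mean_diff": comp.mean_diff,
                    "t": comp.t,
                    "df": comp.df,
                    "p": comp.p,
                    "holm_threshold": holm.thresholds[rank_of[i]],
                    "significant_raw": comp.p < alpha,
                    "significant_holm": holm.reject[valid.index(i)],
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows)
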