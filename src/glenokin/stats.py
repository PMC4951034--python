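"""Group-level statistics on per-shoulder looseness metrics.

Follows the study's statistical protocol: two-group comparisons use a
Student t-test when both groups pass a normality screen (Shapiro-Wilk at
alpha = 0.05, configurable) and a Mann-Whitney U test otherwise (exact for
small combined samples without ties); comparisons of three or more groups
use a Kruskal-Wallis omnibus test gated in front of pairwise Dunn post-hoc
tests.  Dunn z-statistics use pooled mean ranks with the usual tie
correction; p-values are unadjusted by default, with optional
Bonferroni/Holm adjustment.

The intra-observer repeatability harness summarises repeated measurements
of the same frame by their extreme-value spread (max - min) per quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import METRIC_NAMES, KinematicSample

__all__ = [
    "ComparisonResult",
    "compare_two_groups",
    "compare_many_groups",
    "dunn_pairwise",
    "repeatability_spread",
    "two_group_rejection_rate",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test outcome."""

    metric: str
    test: str  # student_t | mann_whitney | kruskal_wallis | dunn
    groups: tuple
    statistic: float
    p_value: float
    normality: dict | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _check_group(values, name) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError(f"group {name!r} needs at least 3 values")
    return arr


def compare_two_groups(
    values_a,
    values_b,
    metric: str = "value",
    groups: tuple = ("a", "b"),
    normality_alpha: float = 0.05,
    exact_limit: int = 20,
) -> ComparisonResult:
    """Two-sided two-group comparison with a normality screen.

    Both groups pass Shapiro-Wilk at ``normality_alpha`` -> two-sample
    Student t-test; otherwise Mann-Whitney U, exact when the pooled sample
    is small (combined n <= ``exact_limit``) and tie-free, else the normal
    approximation with tie correction.
    """
    a = _check_group(values_a, groups[0])
    b = _check_group(values_b, groups[1])
    norm = {}
    for name, arr in ((groups[0], a), (groups[1], b)):
        if np.ptp(arr) == 0:
            norm[name] = False  # constant sample: Shapiro undefined
        else:
            norm[name] = bool(sps.shapiro(arr).pvalue > normality_alpha)
    if all(norm.values()):
        res = sps.ttest_ind(a, b)
        return ComparisonResult(
            metric, "student_t", groups, float(res.statistic), float(res.pvalue), norm
        )
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_limit and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        metric, "mann_whitney", groups, float(res.statistic), float(res.pvalue), norm
    )


def dunn_pairwise(
    samples: dict[str, np.ndarray], metric: str = "value", p_adjust: str | None = None
) -> list[ComparisonResult]:
    """All pairwise Dunn tests on pooled ranks with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` over tie groups; two-sided normal p-values.
    """
    labels = list(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in labels]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, arr in zip(labels, arrays):
        mean_ranks[g] = ranks[start : start + len(arr)].mean()
        start += len(arr)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    results = []
    pvals = []
    pairs = []
    for i in range(len(labels)):
        for k in range(i + 1, len(labels)):
            gi, gk = labels[i], labels[k]
            ni, nk = len(samples[gi]), len(samples[gk])
            se = np.sqrt(var_factor * (1.0 / ni + 1.0 / nk))
            z = (mean_ranks[gi] - mean_ranks[gk]) / se if se > 0 else 0.0
            p = float(2.0 * sps.norm.sf(abs(z)))
            pairs.append(((gi, gk), float(z)))
            pvals.append(min(p, 1.0))
    if p_adjust is not None:
        from statsmodels.stats.multitest import multipletests

        pvals = list(multipletests(pvals, method=p_adjust)[1])
    for ((pair, z), p) in zip(pairs, pvals):
        results.append(ComparisonResult(metric, "dunn", pair, z, float(p)))
    return results


def compare_many_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    alpha: float = 0.05,
    p_adjust: str | None = None,
) -> list[ComparisonResult]:
    """Kruskal-Wallis omnibus over >= 3 groups, with Dunn post-hoc pairwise
    comparisons appended only when the omnibus is significant at ``alpha``
    (gatekeeping).

    ``table`` must hold one row per shoulder with a group label column and
    the metric column.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) < 3:
        raise ValueError(
            "need at least 3 groups for Kruskal-Wallis; use compare_two_groups"
        )
    samples = {g: table.loc[table[group_col] == g, metric].to_numpy(float) for g in groups}
    for g, arr in samples.items():
        _check_group(arr, g)
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0  # all observations identical: no evidence of any difference
    else:
        h, p = sps.kruskal(*samples.values())
    results = [
        ComparisonResult(metric, "kruskal_wallis", tuple(groups), float(h), float(p))
    ]
    if p < alpha:
        results.extend(dunn_pairwise(samples, metric=metric, p_adjust=p_adjust))
    return results


def compare_all_metrics(
    table: pd.DataFrame,
    metrics: tuple = METRIC_NAMES,
    group_col: str = "group",
    alpha: float = 0.05,
    p_adjust: str | None = None,
) -> pd.DataFrame:
    """Run :func:`compare_many_groups` for each metric; tidy table out."""
    rows = []
    for metric in metrics:
        for res in compare_many_groups(
            table, metric, group_col=group_col, alpha=alpha, p_adjust=p_adjust
        ):
            rows.append(
                {
                    "metric": res.metric,
                    "test": res.test,
                    "groups": "|".join(res.groups),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def repeatability_spread(repeated_samples: list[KinematicSample]) -> dict[str, float]:
    """Extreme-value spread (max - min) of repeated measurements of one
    frame, for the head-centre coordinates, the subacromial width and the
    abduction angle."""
    if len(repeated_samples) < 2:
        raise ValueError("need at least 2 repeats")
    out = {}
    for attr in ("x_mm", "y_mm", "wss_mm", "abduction_deg"):
        vals = np.array([getattr(s, attr) for s in repeated_samples])
        out[attr] = float(vals.max() - vals.min())
    return out


def two_group_rejection_rate(
    n_sim: int = 2000,
    n_per_group: int = 6,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo type-I error of :func:`compare_two_groups` under the null
    (both groups drawn from one normal distribution)."""
    if rng is None:
        rng = np.random.default_rng(0)
    rejections = 0
    for _ in range(n_sim):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        if compare_two_groups(a, b).p_value < alpha:
            rejections += 1
    return rejections / n_sim
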