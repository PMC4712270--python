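"""Group-comparison layer: normality gate, omnibus test, post-hoc pairs.

The design follows the standard two-branch convention of biomedical group
comparisons: each group's values are screened with a normality test
(Lilliefors-corrected Kolmogorov-Smirnov by default, since the Gaussian
parameters are estimated from the data; Shapiro-Wilk available); if no group
rejects at alpha, one-way ANOVA with all-pairs pooled t-tests and Bonferroni
adjustment is used, otherwise Kruskal-Wallis with Dunn's all-pairs z-tests
(mid-ranks, tie correction) and Bonferroni-style adjustment.  Significance is
flagged at adjusted p < alpha (default 0.05), with the conventional star
grades (* < 0.05, ** < 0.01, *** < 0.001) for figure-style reports.

The gate is conservative: a single non-Gaussian group sends the whole metric
to the rank branch, and groups too small to test (n < 3) or with zero
variance force the rank branch with a warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import ParameterError, ValidationError
from .morphometry import percent_of_control

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    group_a: str
    group_b: str
    raw_p: float
    adjusted_p: float
    significant: bool


@dataclass
class StatReport:
    branch: str  # "parametric" | "rank"
    normality_p: dict[str, float]
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairResult]
    means: dict[str, float]
    sems: dict[str, float]
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)


def _groups(table: pd.DataFrame, value_col: str, group_col: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for g, sub in table.groupby(group_col, sort=False):
        vals = np.asarray(sub[value_col], dtype=float)
        if len(vals) == 0:
            raise ValidationError(f"group {g!r} is empty")
        out[str(g)] = vals
    if len(out) < 2:
        raise ValidationError("at least two groups are required")
    return out


def normality_gate(
    table: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "ks",
    value_col: str = "value",
    group_col: str = "group",
) -> tuple[str, dict[str, float], list[str]]:
    """Decide the analysis branch from per-group normality tests.

    Returns ``(branch, normality_p, warnings)`` with branch ``"parametric"``
    iff every group passes (p >= alpha) and no group forces the fallback.
    """
    if method not in ("ks", "shapiro"):
        raise ParameterError(f"gate method must be 'ks' or 'shapiro', got {method!r}")
    groups = _groups(table, value_col, group_col)
    pvals: dict[str, float] = {}
    warnings: list[str] = []
    forced = False
    min_n = 4 if method == "ks" else 3  # Lilliefors table minimum is n = 4
    for g, vals in groups.items():
        if len(vals) < min_n:
            warnings.append(f"group {g!r}: n={len(vals)} < {min_n}, forcing rank branch")
            forced = True
            pvals[g] = float("nan")
            continue
        if np.ptp(vals) == 0:
            warnings.append(f"group {g!r}: degenerate (constant) values, forcing rank branch")
            forced = True
            pvals[g] = 0.0
            continue
        if method == "ks":
            _, p = lilliefors(vals, dist="norm")
        else:
            _, p = stats.shapiro(vals)
        pvals[g] = float(p)
    for w in warnings:
        logger.warning(w)
    branch = "rank" if forced or any(p < alpha for p in pvals.values() if not np.isnan(p)) \
        else "parametric"
    return branch, pvals, warnings


def _bonferroni(p: float, n_pairs: int) -> float:
    return min(1.0, p * n_pairs)


def _dunn_pairs(groups: dict[str, np.ndarray], n_pairs: int) -> list[PairResult]:
    """Dunn's all-pairs z-tests on pooled mid-ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),
    T = sum over tie groups of (t^3 - t); two-sided normal p, Bonferroni-style
    adjustment over all pairs.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_ranks = {}
    i = 0
    for g in labels:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[i:i + n].mean())
        i += n
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        if se == 0:
            raw = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            raw = float(2.0 * stats.norm.sf(abs(z)))
        out.append((a, b, raw))
    return [
        PairResult(a, b, raw, _bonferroni(raw, n_pairs), False) for a, b, raw in out
    ]


def omnibus_and_posthoc(
    table: pd.DataFrame,
    branch: str,
    alpha: float = 0.05,
    value_col: str = "value",
    group_col: str = "group",
    normality_p: dict[str, float] | None = None,
) -> StatReport:
    """Omnibus test plus all-pairs post hoc on the chosen branch.

    Parametric branch: one-way ANOVA; pairwise two-sample pooled-variance
    t-tests, Bonferroni-adjusted over all C(k, 2) pairs.  Rank branch:
    Kruskal-Wallis with tie correction; Dunn's z-tests, same adjustment.
    A group of n=1 on the parametric branch forces the rank branch with a
    warning.  Means and SEMs per group are always reported.
    """
    groups = _groups(table, value_col, group_col)
    warnings: list[str] = []
    if branch == "parametric" and any(len(v) < 2 for v in groups.values()):
        warnings.append("a group has n=1; forcing rank branch")
        logger.warning(warnings[-1])
        branch = "rank"
    if branch not in ("parametric", "rank"):
        raise ParameterError(f"branch must be 'parametric' or 'rank', got {branch!r}")

    samples = list(groups.values())
    labels = list(groups)
    n_pairs = len(labels) * (len(labels) - 1) // 2

    if branch == "parametric":
        f_stat, omni_p = stats.f_oneway(*samples)
        pairwise = []
        for a, b in itertools.combinations(labels, 2):
            _, raw = stats.ttest_ind(groups[a], groups[b], equal_var=True)
            pairwise.append(PairResult(a, b, float(raw), _bonferroni(float(raw), n_pairs), False))
        omnibus_stat, omnibus_p = float(f_stat), float(omni_p)
    else:
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            omnibus_stat, omnibus_p = 0.0, 1.0  # all values identical: no effect
        else:
            h, p = stats.kruskal(*samples)
            omnibus_stat, omnibus_p = float(h), float(p)
        pairwise = _dunn_pairs(groups, n_pairs)

    for pr in pairwise:
        pr.significant = pr.adjusted_p < alpha
    means = {g: float(v.mean()) for g, v in groups.items()}
    sems = {g: float(stats.sem(v)) if len(v) > 1 else float("nan") for g, v in groups.items()}
    return StatReport(
        branch=branch,
        normality_p=dict(normality_p or {}),
        omnibus_stat=omnibus_stat,
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        means=means,
        sems=sems,
        alpha=alpha,
        warnings=warnings,
    )


def analyze(
    table: pd.DataFrame,
    alpha: float = 0.05,
    gate_method: str = "ks",
    value_col: str = "value",
    group_col: str = "group",
) -> StatReport:
    """Convenience wrapper: gate, then omnibus + post hoc on the chosen branch."""
    branch, pvals, warns = normality_gate(
        table, alpha=alpha, method=gate_method, value_col=value_col, group_col=group_col
    )
    report = omnibus_and_posthoc(
        table, branch, alpha=alpha, value_col=value_col, group_col=group_col,
        normality_p=pvals,
    )
    report.warnings = warns + report.warnings
    return report


def stars(p: float) -> str:
    """Conventional significance grades: *** < 0.001, ** < 0.01, * < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report_figure_table(
    stat: StatReport,
    table: pd.DataFrame,
    control_group: str,
    value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Percent-of-control group summary with star annotations vs control.

    One row per group: mean and SEM in percent-of-control units plus the
    star grade of the control-vs-group adjusted p (empty for the control
    itself and for non-significant comparisons).
    """
    norm = percent_of_control(table, control_group, value_col=value_col, group_col=group_col)
    vs_control = {
        (pr.group_b if pr.group_a == control_group else pr.group_a): pr.adjusted_p
        for pr in stat.pairwise
        if control_group in (pr.group_a, pr.group_b)
    }
    rows = []
    for g, sub in norm.groupby(group_col, sort=False):
        vals = np.asarray(sub["value_pct"], dtype=float)
        rows.append(
            {
                group_col: g,
                "mean_pct": float(vals.mean()),
                "sem_pct": float(stats.sem(vals)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
                "stars": "" if g == control_group else stars(vs_control.get(g, 1.0)),
            }
        )
    return pd.DataFrame(rows)
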