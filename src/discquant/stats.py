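"""Cohort-level summaries and group comparisons.

Covers the statistics used on per-disc and per-vial measurements: eclosion
rates, fold decreases, tumor-bearing fractions, mean +/- SD condition
summaries, Kruskal-Wallis with Dunn's post-hoc z tests (Bonferroni family
adjustment), and one-way ANOVA with Dunnett's comparisons against a control
group. Dunnett family-wise adjusted p-values come from a seeded Monte-Carlo
sample of the max-|t| null, which handles balanced and unbalanced designs
uniformly.

Significance stars follow the convention ****<0.0001, ***<0.001, **<0.01,
*<0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EclosionRecord",
    "ConditionSummary",
    "KruskalResult",
    "GroupComparison",
    "eclosion_rate",
    "fold_decrease",
    "tumor_bearing_fraction",
    "summarize_condition",
    "kruskal_wallis",
    "dunn_posthoc",
    "anova_dunnett",
    "stars",
]


@dataclass(frozen=True)
class EclosionRecord:
    """Larvae selected into a vial and adults counted after eclosion."""

    genotype: str
    n_larvae: int
    n_adults: int

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        if not (0 <= self.n_adults <= self.n_larvae):
            raise ValueError("n_adults must lie in [0, n_larvae]")


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p: float
    degenerate: bool = False


@dataclass
class GroupComparison:
    """A global test plus per-pair post-hoc comparisons.

    ``comparisons`` has columns group1, group2, statistic, p_raw, p_adj,
    stars; p_adj is the family-adjusted p-value.
    """

    test: str
    statistic: float
    pvalue: float
    comparisons: pd.DataFrame


def stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def eclosion_rate(rec: EclosionRecord) -> float:
    """Percent of selected larvae that emerged as adults."""
    return 100.0 * rec.n_adults / rec.n_larvae


def fold_decrease(baseline_percent: float, treated_percent: float) -> float:
    """Baseline over treated, e.g. 46% -> 5% tumor volume is a 9.2-fold decrease."""
    if treated_percent <= 0:
        raise ValueError("treated value must be > 0 for a fold decrease")
    return baseline_percent / treated_percent


def tumor_bearing_fraction(n_with_tumor: int, n_hosts: int) -> float:
    """Percent of transplantation hosts with a visible tumor."""
    if n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    if not (0 <= n_with_tumor <= n_hosts):
        raise ValueError("n_with_tumor must lie in [0, n_hosts]")
    return 100.0 * n_with_tumor / n_hosts


def summarize_condition(values: Sequence[float], condition: str) -> ConditionSummary:
    """Mean and sample SD (ddof=1; SD = 0 for a single observation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty value list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ConditionSummary(condition=condition, n=int(arr.size), mean=float(arr.mean()), sd=sd)


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups)
        values = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        values = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least two groups")
    if any(v.size == 0 for v in values):
        raise ValueError("every group needs at least one value")
    return labels, values


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal-Wallis H with tie correction and chi-square p (k-1 df).

    ``groups`` is a mapping label -> values or a sequence of value arrays.
    When every pooled value is identical the test is degenerate; H = 0 and
    p = 1 are reported with the ``degenerate`` flag set.
    """
    _, values = _as_groups(groups)
    pooled = np.concatenate(values)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return KruskalResult(h=0.0, p=1.0, degenerate=True)
    h, p = sps.kruskal(*values)
    return KruskalResult(h=float(h), p=float(p), degenerate=False)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    mode: str = "all-pairs",
    control: str | None = None,
) -> GroupComparison:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) over tied value groups; two-sided normal
    p-values, Bonferroni-adjusted over the selected comparison family
    (all pairs, or each group versus ``control``).
    """
    labels, values = _as_groups(groups)
    if mode not in ("all-pairs", "vs-control"):
        raise ValueError("mode must be 'all-pairs' or 'vs-control'")
    if mode == "vs-control":
        if control not in labels:
            raise KeyError(f"unknown control label {control!r}; groups: {labels}")

    global_res = kruskal_wallis(dict(zip(labels, values)))
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [v.size for v in values]
    mean_ranks, start = {}, 0
    for lab, n in zip(labels, sizes):
        mean_ranks[lab] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    if mode == "all-pairs":
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        pairs = [(control, lab) for lab in labels if lab != control]

    n_of = dict(zip(labels, sizes))
    rows = []
    m = len(pairs)
    for a, b in pairs:
        denom = np.sqrt(var_factor * (1.0 / n_of[a] + 1.0 / n_of[b]))
        z = 0.0 if denom == 0 else (mean_ranks[a] - mean_ranks[b]) / denom
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p_raw)
        rows.append((a, b, float(z), p_raw, p_adj, stars(p_adj)))
    comps = pd.DataFrame(
        rows, columns=["group1", "group2", "statistic", "p_raw", "p_adj", "stars"]
    )
    return GroupComparison(
        test=f"Kruskal-Wallis + Dunn ({mode})",
        statistic=global_res.h,
        pvalue=global_res.p,
        comparisons=comps,
    )


@lru_cache(maxsize=32)
def _dunnett_max_t_null(
    n_control: int, n_treatments: tuple[int, ...], df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo sample of max_j |T_j| under the Dunnett null.

    T_j = (Xbar_j - Xbar_0) / (S sqrt(1/n_j + 1/n_0)) with group means drawn
    from their null sampling distributions and a shared pooled S^2 ~
    chi2_df / df, reproducing the many-to-one correlation structure for any
    (un)balanced design.
    """
    rng = np.random.default_rng(seed)
    m0 = rng.normal(0.0, 1.0 / np.sqrt(n_control), size=n_draws)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    max_t = np.zeros(n_draws)
    for nj in n_treatments:
        mj = rng.normal(0.0, 1.0 / np.sqrt(nj), size=n_draws)
        tj = np.abs(mj - m0) / (s * np.sqrt(1.0 / nj + 1.0 / n_control))
        np.maximum(max_t, tj, out=max_t)
    return np.sort(max_t)


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> GroupComparison:
    """One-way ANOVA plus Dunnett's many-to-one comparisons.

    The global test is the ordinary one-way ANOVA F. Each treatment is
    compared to ``control`` with a pooled-variance t statistic; the
    family-wise adjusted p-value is the Monte-Carlo tail probability
    P(max_j |T_j| >= |t_obs|) under the joint null (``n_draws`` seeded
    draws; see :func:`_dunnett_max_t_null`).
    """
    labels, values = _as_groups(groups)
    if control not in labels:
        raise KeyError(f"control group {control!r} not found; groups: {labels}")
    if any(v.size < 2 for v in values):
        raise ValueError("every group needs at least two values for ANOVA")

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, f_p = sps.f_oneway(*values)
    if not np.isfinite(f_stat):  # zero variance everywhere: no evidence of effect
        f_stat, f_p = 0.0, 1.0
    n_total = sum(v.size for v in values)
    k = len(values)
    df = n_total - k
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    pooled_var = ss_within / df

    ctrl = values[labels.index(control)]
    treatments = [(lab, v) for lab, v in zip(labels, values) if lab != control]
    null = _dunnett_max_t_null(
        ctrl.size, tuple(v.size for _, v in treatments), df, n_draws, seed
    )

    rows = []
    for lab, v in treatments:
        se = np.sqrt(pooled_var * (1.0 / v.size + 1.0 / ctrl.size))
        t = 0.0 if se == 0 else float((v.mean() - ctrl.mean()) / se)
        p_raw = float(2.0 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
        # (r+1)/(M+1) estimator keeps p in (0, 1] and monotone in |t|
        exceed = null.size - np.searchsorted(null, abs(t), side="left")
        p_adj = float((exceed + 1) / (null.size + 1))
        rows.append((control, lab, t, p_raw, min(1.0, p_adj), stars(p_adj)))
    comps = pd.DataFrame(
        rows, columns=["group1", "group2", "statistic", "p_raw", "p_adj", "stars"]
    )
    return GroupComparison(
        test="one-way ANOVA + Dunnett (Monte-Carlo)",
        statistic=float(f_stat),
        pvalue=float(f_p),
        comparisons=comps,
    )
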