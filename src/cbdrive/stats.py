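"""Inferential layer: ANOVAs with partial eta squared, paired t with
Cohen's d, and Tukey HSD / Bonferroni post-hoc comparisons.

The default unit of analysis throughout the pipeline is the participant
(per-participant cell means), which keeps designs balanced; the factorial
ANOVA therefore uses the classical balanced-design sum-of-squares
decomposition (identical to Type I/II/III on balanced data). Partial eta
squared is SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "anova_oneway",
    "anova_factorial",
    "paired_t",
    "posthoc",
]


@dataclass(frozen=True)
class StatResult:
    """One reported contrast: statistic, df, p and effect size."""

    statistic: float
    df1: float
    df2: float | None
    p: float
    effect_size: float
    method: str

    def __str__(self) -> str:  # renders in the conventional reporting style
        if self.df2 is not None:
            head = f"F({self.df1:g},{self.df2:g}) = {self.statistic:.3f}"
            eff = f"eta_p^2 = {self.effect_size:.3f}"
        else:
            head = f"t({self.df1:g}) = {self.statistic:.3f}"
            eff = f"d = {self.effect_size:.2f}"
        p = "p < .001" if self.p < 0.001 else f"p = {self.p:.3f}"
        return f"{head}, {p}, {eff} [{self.method}]"


def anova_oneway(groups: Sequence[Sequence[float]]) -> StatResult:
    """Classical between-groups one-way ANOVA.

    Returns F, (df1, df2), p and partial eta squared. Each group needs at
    least 2 values. All values identical yields F = 0, eta = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("anova_oneway needs at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    df1 = len(gs) - 1
    df2 = allv.size - len(gs)
    if ss_within == 0.0 and ss_between == 0.0:
        return StatResult(0.0, df1, df2, 1.0, 0.0, "one-way ANOVA")
    f = (ss_between / df1) / (ss_within / df2) if ss_within > 0 else np.inf
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eta = ss_between / (ss_between + ss_within)
    return StatResult(float(f), df1, df2, p, float(eta), "one-way ANOVA")


def anova_factorial(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, StatResult]:
    """Balanced two-way ANOVA with interaction.

    ``values`` carry one observation per row; ``factor_a`` / ``factor_b``
    are the two categorical labels. The design must be fully crossed and
    balanced (equal cell sizes >= 2); the balanced decomposition
    SS_A + SS_B + SS_AB + SS_error = SS_total is used, so the result
    coincides with Type I/II/III sums of squares.

    Returns StatResults keyed ``factor_a``, ``factor_b``, ``interaction``.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (y.size == a.size == b.size):
        raise ValueError("values and factor labels must have equal length")
    la, lb = np.unique(a), np.unique(b)
    if la.size < 2 or lb.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    cell_n = None
    cell_means = np.empty((la.size, lb.size))
    ss_error = 0.0
    for i, ai in enumerate(la):
        for j, bj in enumerate(lb):
            cell = y[(a == ai) & (b == bj)]
            if cell.size == 0:
                raise ValueError(f"empty cell ({ai!r}, {bj!r}): balanced designs only")
            if cell_n is None:
                cell_n = cell.size
            elif cell.size != cell_n:
                raise ValueError("unbalanced design: cell sizes differ")
            cell_means[i, j] = cell.mean()
            ss_error += float(((cell - cell.mean()) ** 2).sum())
    if cell_n < 2:
        raise ValueError("need at least 2 observations per cell")
    n = cell_n
    grand = cell_means.mean()
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)
    ss_a = n * lb.size * float(((a_means - grand) ** 2).sum())
    ss_b = n * la.size * float(((b_means - grand) ** 2).sum())
    inter = cell_means - a_means[:, None] - b_means[None, :] + grand
    ss_ab = n * float((inter**2).sum())
    df_a = la.size - 1
    df_b = lb.size - 1
    df_ab = df_a * df_b
    df_err = la.size * lb.size * (n - 1)
    ms_err = ss_error / df_err

    def _res(ss: float, df: int, label: str) -> StatResult:
        if ms_err == 0.0:
            f = 0.0 if ss == 0.0 else np.inf
        else:
            f = (ss / df) / ms_err
        p = float(sps.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0
        eta = ss / (ss + ss_error) if (ss + ss_error) > 0 else 0.0
        return StatResult(float(f), df, df_err, p, float(eta), f"factorial ANOVA: {label}")

    return {
        "factor_a": _res(ss_a, df_a, "main effect A"),
        "factor_b": _res(ss_b, df_b, "main effect B"),
        "interaction": _res(ss_ab, df_ab, "interaction"),
    }


def paired_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Paired t-test with Cohen's d = mean(diff) / SD(diff).

    Zero-variance differences (all diffs identical) are a degenerate input
    and raise, except the all-zero case which returns t = 0, d = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired_t needs two equal-length samples with n >= 2")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if float(np.abs(d).max()) == 0.0:
            return StatResult(0.0, a.size - 1, None, 1.0, 0.0, "paired t")
        raise ValueError("paired_t: differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * sps.t.sf(abs(t), a.size - 1))
    return StatResult(t, a.size - 1, None, p, float(d.mean() / sd), "paired t")


def posthoc(groups: Sequence[Sequence[float]], method: str = "tukey_hsd") -> list[dict]:
    """All pairwise comparisons with multiplicity adjustment.

    ``tukey_hsd`` uses the studentised-range distribution with the pooled
    within-group variance; ``bonferroni`` multiplies the raw two-sample
    t-test p by the number of comparisons, capped at 1.

    Returns one record per pair (i, j) with the mean difference and the
    adjusted p-value.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("posthoc needs at least 2 groups")
    m = len(gs) * (len(gs) - 1) // 2
    out: list[dict] = []
    if method == "tukey_hsd":
        res = sps.tukey_hsd(*gs)
        for i, j in itertools.combinations(range(len(gs)), 2):
            out.append(
                {
                    "i": i,
                    "j": j,
                    "mean_diff": float(gs[i].mean() - gs[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "method": "tukey_hsd",
                }
            )
    elif method == "bonferroni":
        for i, j in itertools.combinations(range(len(gs)), 2):
            _, p = sps.ttest_ind(gs[i], gs[j])
            out.append(
                {
                    "i": i,
                    "j": j,
                    "mean_diff": float(gs[i].mean() - gs[j].mean()),
                    "p_adj": float(min(1.0, p * m)),
                    "method": "bonferroni",
                }
            )
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return out
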