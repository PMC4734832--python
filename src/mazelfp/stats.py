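"""Fixed-effects ANOVA and Bonferroni-corrected pairwise follow-ups.

Implemented from sums-of-squares first principles (only the F-distribution
tail comes from scipy) so the pipeline's statistics are self-contained and
oracle-testable against an independent implementation. One-way ANOVA
compares theta-band summaries across task phases or scrub percentages across
sessions; the balanced two-way ANOVA compares behavioral scores across
training session x rat group. Significant omnibus tests are followed by all
pairwise pooled-variance t tests with Bonferroni adjustment
``p_adj = min(m p, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "EffectResult",
    "PairwiseResult",
    "PairwiseComparison",
    "one_way_anova",
    "two_way_anova",
    "bonferroni_pairwise",
]


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[int, int]
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class PairwiseResult:
    comparisons: list[PairwiseComparison]
    n_comparisons: int
    alpha: float


def _f_test(ss_num: float, df_num: int, ss_den: float, df_den: int) -> EffectResult:
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    if ms_den == 0.0:
        # Degenerate zero within-cell variance: F pinned at 0 or infinity.
        if ms_num == 0.0:
            return EffectResult(F=0.0, df_num=df_num, df_den=df_den, p=1.0)
        return EffectResult(F=np.inf, df_num=df_num, df_den=df_den, p=0.0)
    F = ms_num / ms_den
    return EffectResult(F=F, df_num=df_num, df_den=df_den, p=float(sps.f.sf(F, df_num, df_den)))


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA over >= 2 groups of >= 2 values each."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    n_total = sum(g.size for g in groups)
    eff = _f_test(ss_between, len(groups) - 1, ss_within, n_total - len(groups))
    return AnovaResult(effects={"group": eff})


def two_way_anova(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
) -> AnovaResult:
    """Balanced complete two-way fixed-effects ANOVA with interaction.

    Rejects unbalanced or incomplete designs explicitly; the factorial
    sums-of-squares decomposition below is only orthogonal when every
    (a, b) cell holds the same number of replicates (>= 2).
    """
    y = np.asarray(values, dtype=float).ravel()
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    if a_levels.size < 2 or b_levels.size < 2:
        raise ValueError("both factors need at least 2 levels")
    cells = {}
    for ai in a_levels:
        for bi in b_levels:
            cells[(ai, bi)] = y[(fa == ai) & (fb == bi)]
    sizes = {k: v.size for k, v in cells.items()}
    n_rep = next(iter(sizes.values()))
    if len(set(sizes.values())) != 1 or n_rep < 2:
        raise ValueError(
            f"design is unbalanced or incomplete (cell sizes {sorted(set(sizes.values()))}); "
            "a balanced complete design with >= 2 replicates per cell is required"
        )
    grand = y.mean()
    a_means = {ai: y[fa == ai].mean() for ai in a_levels}
    b_means = {bi: y[fb == bi].mean() for bi in b_levels}
    cell_means = {k: v.mean() for k, v in cells.items()}

    n_a, n_b = a_levels.size, b_levels.size
    ss_a = n_rep * n_b * sum((m - grand) ** 2 for m in a_means.values())
    ss_b = n_rep * n_a * sum((m - grand) ** 2 for m in b_means.values())
    ss_cells = n_rep * sum((m - grand) ** 2 for m in cell_means.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((v - cell_means[k]) ** 2).sum() for k, v in cells.items())
    df_err = y.size - n_a * n_b
    return AnovaResult(
        effects={
            "a": _f_test(ss_a, n_a - 1, ss_err, df_err),
            "b": _f_test(ss_b, n_b - 1, ss_err, df_err),
            "interaction": _f_test(max(ss_ab, 0.0), (n_a - 1) * (n_b - 1), ss_err, df_err),
        }
    )


def bonferroni_pairwise(groups: list[np.ndarray], alpha: float = 0.05) -> PairwiseResult:
    """All pairwise pooled-variance t tests with Bonferroni adjustment."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise comparisons")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    m = k * (k - 1) // 2
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            t, p = sps.ttest_ind(groups[i], groups[j], equal_var=True)
            p_adj = min(m * float(p), 1.0)
            comparisons.append(
                PairwiseComparison(
                    pair=(i, j), t=float(t), p_raw=float(p),
                    p_adjusted=p_adj, significant=p_adj < alpha,
                )
            )
    return PairwiseResult(comparisons=comparisons, n_comparisons=m, alpha=alpha)
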