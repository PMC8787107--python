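"""Demographic and clinical group comparisons.

Covers the usual cohort-description table: one-way ANOVA across three or
more groups with Scheffé post hoc contrasts, a pooled-variance two-sample t
recomputable from printed summary statistics (mean ± SD, n), and a Pearson
chi-square test for categorical (e.g., sex) distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ContractError, DegenerateInputError

__all__ = [
    "GroupSummary",
    "pooled_t_from_summary",
    "pooled_t_from_raw",
    "one_way_anova",
    "scheffe_posthoc",
    "chi_square_test",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ContractError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ContractError(f"group {self.label!r}: sd must be >= 0")


def pooled_t_from_summary(
    g1: GroupSummary, g2: GroupSummary
) -> tuple[float, int, float]:
    """Student's pooled-variance two-sample t from summary statistics.

    Returns (t, df, two-sided p) with
    ``t = (m1 - m2) / (s_p sqrt(1/n1 + 1/n2))`` and
    ``s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1 + n2 - 2)``.
    """
    df = g1.n + g2.n - 2
    pooled_var = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = np.sqrt(pooled_var * (1 / g1.n + 1 / g2.n))
    if se == 0:
        if g1.mean == g2.mean:
            raise DegenerateInputError(
                "both SDs are zero and means equal: t is undefined"
            )
        return float(np.inf) * np.sign(g1.mean - g2.mean), df, 0.0
    t = (g1.mean - g2.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pooled_t_from_raw(x1: np.ndarray, x2: np.ndarray) -> tuple[float, int, float]:
    """Pooled t from raw samples (collapses to summaries internally)."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return pooled_t_from_summary(
        GroupSummary("g1", len(x1), float(x1.mean()), float(x1.std(ddof=1))),
        GroupSummary("g2", len(x2), float(x2.mean()), float(x2.std(ddof=1))),
    )


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ContractError("ANOVA needs >= 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ContractError(f"group {i} has n < 2")
    return groups


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA: returns (F, df_between, df_within, p)."""
    groups = _check_groups(groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    f, p = sps.f_oneway(*groups)
    if not np.isfinite(f):  # all values identical within and between groups
        f, p = 0.0, 1.0
    return float(f), k - 1, n_total - k, float(p)


def scheffe_posthoc(
    groups: list[np.ndarray], pair: tuple[int, int]
) -> tuple[float, float]:
    """Scheffé contrast between two groups after a one-way ANOVA.

    The pairwise mean difference is tested against the ANOVA's within-group
    mean square; the statistic ``(m_i - m_j)^2 / (MSW (1/n_i + 1/n_j) (k-1))``
    follows an F(k-1, N-k) law under the null, making the procedure valid for
    any post hoc contrast.
    """
    groups = _check_groups(groups)
    i, j = pair
    k = len(groups)
    if not (0 <= i < k and 0 <= j < k and i != j):
        raise ContractError(f"invalid group pair {pair}")
    n_total = sum(len(g) for g in groups)
    grand = [g - g.mean() for g in groups]
    ssw = sum(float(np.sum(g**2)) for g in grand)
    df_within = n_total - k
    msw = ssw / df_within
    gi, gj = groups[i], groups[j]
    diff = gi.mean() - gj.mean()
    if msw == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.inf), 0.0
    f_stat = diff**2 / (msw * (1 / len(gi) + 1 / len(gj)) * (k - 1))
    p = sps.f.sf(f_stat, k - 1, df_within)
    return float(f_stat), float(p)


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns (chi2, df, p) for an r x c table of nonnegative integer counts.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ContractError("contingency table must be at least 2 x 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ContractError("contingency table must hold nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ContractError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
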