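"""Demographic group comparisons: summary-data t-tests and 2x2 chi-square.

Pooled-variance (Student) two-sample t-tests on group summaries and the
uncorrected Pearson chi-square on a 2x2 contingency table, the conventions
used for cohort characteristics tables; a Welch option and the Yates
correction are available as flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    """Sample size, mean and standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class ContingencyTable2x2:
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")


def t_from_summary(g1: GroupSummary, g2: GroupSummary,
                   welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries.

    Pooled-variance Student t by default (df = n1 + n2 - 2); Welch with the
    flag.  Two identical degenerate groups give t = 0, p = 1 by convention.
    Returns (t, df, p_two_tailed).
    """
    if g1.sd == 0 and g2.sd == 0 and g1.mean == g2.mean:
        return 0.0, float(g1.n + g2.n - 2), 1.0
    t, p = stats.ttest_ind_from_stats(g1.mean, g1.sd, g1.n,
                                      g2.mean, g2.sd, g2.n,
                                      equal_var=not welch)
    if welch:
        v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
        df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    else:
        df = float(g1.n + g2.n - 2)
    return float(t), float(df), float(p)


def chi2_2x2(table: ContingencyTable2x2, yates: bool = False
             ) -> tuple[float, float, float]:
    """Pearson chi-square on a 2x2 table (df = 1), Yates off by default.

    A zero row or column marginal leaves the statistic undefined and raises.
    Returns (chi2, df, p).
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=yates)
    return float(chi2), float(df), float(p)


def summaries_from_samples(x1: np.ndarray, x2: np.ndarray) -> tuple[GroupSummary, GroupSummary]:
    """Group summaries (ddof = 1) from raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return (GroupSummary(len(x1), float(x1.mean()), float(x1.std(ddof=1))),
            GroupSummary(len(x2), float(x2.mean()), float(x2.std(ddof=1))))


def cohort_table(manifest_table: pd.DataFrame,
                 group_col: str = "group_label",
                 continuous: tuple[str, ...] = ("age", "duration"),
                 categorical: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Characteristics table: per-variable test statistic, df and p."""
    groups = sorted(manifest_table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    rows = []
    for var in continuous:
        g1, g2 = (summaries_from_samples(
            manifest_table.loc[manifest_table[group_col] == groups[0], var],
            manifest_table.loc[manifest_table[group_col] == groups[1], var]))
        t, df, p = t_from_summary(g1, g2)
        rows.append({"variable": var, "test": "t",
                     f"{groups[0]}": f"{g1.mean:.2f} +/- {g1.sd:.2f}",
                     f"{groups[1]}": f"{g2.mean:.2f} +/- {g2.sd:.2f}",
                     "statistic": t, "df": df, "p": p})
    for var in categorical:
        levels = sorted(manifest_table[var].unique())
        if len(levels) != 2:
            raise ValueError(f"{var}: chi-square table needs exactly 2 levels")
        counts = np.array([
            [(manifest_table[(manifest_table[group_col] == g) &
                             (manifest_table[var] == lv)]).shape[0]
             for lv in levels] for g in groups])
        chi2, df, p = chi2_2x2(ContingencyTable2x2(counts))
        rows.append({"variable": var, "test": "chi2",
                     f"{groups[0]}": "/".join(str(c) for c in counts[0]),
                     f"{groups[1]}": "/".join(str(c) for c in counts[1]),
                     "statistic": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)
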