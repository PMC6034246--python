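"""Genotype-phenotype comparison (workflow step 5) and summary-statistic tests.

Carriers of a flagged allele set are compared with non-carriers on clinical
variables.  Continuous variables default to the Mann-Whitney U test (exact
distribution for small tie-free samples, normal approximation with tie
correction otherwise); categorical variables use the two-sided Fisher exact
test.  A Student t test (pooled or Welch) from raw values or from published
summary statistics is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import MitoburdenError

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"
EXACT = "exact"


@dataclass(frozen=True)
class GroupComparison:
    """One variable compared between carrier (+) and non-carrier (-) groups."""

    variable: str
    n_plus: int
    n_minus: int
    summary_plus: str
    summary_minus: str
    statistic: float
    p_value: float
    method: str


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Exact U distribution when feasible (min n <= 8, no ties), else
    normal approximation with tie correction and continuity correction."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), MANN_WHITNEY


def compare_phenotype(
    values_plus: Sequence[float],
    values_minus: Sequence[float],
    kind: str = "continuous",
    variable: str = "",
    rule: str = "mann_whitney",
) -> GroupComparison:
    """Compare one phenotype between carriers and non-carriers.

    ``kind='continuous'``: Mann-Whitney U by default, Student t when
    ``rule='t_test'``.  ``kind='categorical'``: ``values_*`` are event
    indicators (0/1) and the 2x2 event table is tested with Fisher's exact
    test.
    """
    x = np.asarray(values_plus, float)
    y = np.asarray(values_minus, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise MitoburdenError(f"{variable or 'variable'}: a group has no observed values")
    if kind == "continuous":
        if rule == "t_test":
            res = stats.ttest_ind(x, y)
            stat, p, method = float(res.statistic), float(res.pvalue), T_TEST
        else:
            stat, p, method = _mann_whitney(x, y)
        s_plus = f"{x.mean():.2f} ± {x.std(ddof=1):.2f}" if len(x) > 1 else f"{x.mean():.2f}"
        s_minus = f"{y.mean():.2f} ± {y.std(ddof=1):.2f}" if len(y) > 1 else f"{y.mean():.2f}"
    elif kind == "categorical":
        k_plus, k_minus = int(x.sum()), int(y.sum())
        table = [[k_plus, len(x) - k_plus], [k_minus, len(y) - k_minus]]
        stat_, p = stats.fisher_exact(table, alternative="two-sided")
        stat, p, method = float(stat_), float(p), EXACT
        s_plus = f"{k_plus} ({100 * k_plus / len(x):.2f}%)"
        s_minus = f"{k_minus} ({100 * k_minus / len(y):.2f}%)"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return GroupComparison(variable, len(x), len(y), s_plus, s_minus, stat, p, method)


def ttest_from_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    variant: str = "pooled",
) -> float:
    """Two-sided t-test P-value from published summary statistics."""
    if n1 < 2 or n2 < 2:
        raise MitoburdenError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise MitoburdenError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return float(res.pvalue)


#: Phenotype-table columns treated as categorical in carrier comparisons.
CATEGORICAL_PHENOTYPES = ("diabetes",)


def phenotype_comparison_table(
    phenotypes: pd.DataFrame,
    carriers: set[str],
    samples: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Carrier vs non-carrier comparison for every phenotype column.

    ``phenotypes`` is indexed by sample ID.  ``samples`` restricts the
    comparison (e.g. to the case cohort, as in a within-cases analysis);
    carriers outside ``samples`` are ignored.
    """
    df = phenotypes if samples is None else phenotypes.loc[[s for s in samples if s in phenotypes.index]]
    in_plus = df.index.isin(carriers)
    if variables is None:
        variables = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for var in variables:
        kind = "categorical" if var in CATEGORICAL_PHENOTYPES else "continuous"
        cmp = compare_phenotype(
            df.loc[in_plus, var], df.loc[~in_plus, var], kind=kind, variable=var
        )
        rows.append(
            {
                "variable": var,
                "n_plus": cmp.n_plus,
                "n_minus": cmp.n_minus,
                "carriers": cmp.summary_plus,
                "non_carriers": cmp.summary_minus,
                "p_value": cmp.p_value,
                "method": cmp.method,
            }
        )
    return pd.DataFrame(rows)
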