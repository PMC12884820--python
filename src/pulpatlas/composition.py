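"""Cell-type composition shifts across conditions.

Cross-tabulates subtype x condition cell counts, attaches binomial Wald
confidence intervals to the per-condition proportions, tests the full table
with an overall Pearson chi-square, and runs pairwise two-sided Fisher's
exact tests (subtype versus not-subtype between two conditions) with
Benjamini-Hochberg adjustment, Haldane-Anscombe-corrected odds ratios, and
significance stars. Delta-proportion matrices report percentage-point
changes joined with the stars.

The two-sided Fisher p follows the point-probability convention (sum of
hypergeometric probabilities of all margin-fixed tables at most as probable
as the observed one) and is evaluated in exact integer arithmetic — all
tables share the denominator C(N, n), so point probabilities are compared
and summed as integer numerators before a single float division.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CellAnnotations
from .de_enrichment import bh_adjust

__all__ = [
    "CompositionTable",
    "FisherTable",
    "count_table",
    "proportion_wald_ci",
    "overall_chisq",
    "fisher_exact_p",
    "pairwise_fisher",
    "delta_proportion",
    "stars",
]


@dataclass
class CompositionTable:
    """Subtype x condition counts with per-condition proportions and
    (after :func:`proportion_wald_ci`) Wald CI bounds."""

    counts: pd.DataFrame  # subtypes x conditions, integers
    proportions: pd.DataFrame
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        col_sums = self.proportions.sum(axis=0)
        nonzero = self.counts.sum(axis=0) > 0
        if not np.allclose(col_sums[nonzero], 1.0, atol=1e-9):
            raise ValueError("proportion columns must sum to 1")


@dataclass
class FisherTable:
    table: pd.DataFrame  # subtype, contrast, a,b,c,d, odds_ratio, CI, p, p_adj, stars


def stars(p: float) -> str:
    """Printed significance thresholds: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def count_table(ann: CellAnnotations, subtype_col: str = "cluster") -> CompositionTable:
    """Cross-tabulate subtype x condition with per-condition proportions."""
    if len(ann.table) == 0:
        raise ValueError("annotations are empty")
    counts = pd.crosstab(ann.table[subtype_col], ann.table["condition"])
    counts = counts.reindex(columns=[c for c in ann.conditions if c in counts.columns])
    totals = counts.sum(axis=0)
    proportions = counts / totals
    return CompositionTable(counts=counts, proportions=proportions)


def proportion_wald_ci(tab: CompositionTable, level: float = 0.95) -> CompositionTable:
    """Binomial Wald CIs p_hat +/- z*sqrt(p_hat(1-p_hat)/n), clipped to [0,1].

    Degenerate at boundary proportions (k = 0 or k = n gives a zero-width
    interval), retained because that is the stated convention; columns with
    n = 0 get missing CIs with a warning."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0,1)")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    n = tab.counts.sum(axis=0)
    if (n == 0).any():
        warnings.warn(f"conditions with zero cells: {list(n.index[n == 0])}")
    p = tab.proportions
    se = np.sqrt(p * (1 - p) / n.replace(0, np.nan))
    low = (p - z * se).clip(lower=0.0, upper=1.0)
    high = (p + z * se).clip(lower=0.0, upper=1.0)
    return CompositionTable(
        counts=tab.counts, proportions=tab.proportions, ci_low=low, ci_high=high
    )


def overall_chisq(tab: CompositionTable) -> tuple[float, int, float]:
    """Pearson chi-square on the full subtype x condition table; zero rows
    or columns are dropped with a warning before testing."""
    counts = tab.counts.copy()
    zero_rows = counts.index[counts.sum(axis=1) == 0]
    zero_cols = counts.columns[counts.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping zero rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        counts = counts.drop(index=zero_rows, columns=zero_cols)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table")
    res = stats.chi2_contingency(counts.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability method in exact integer arithmetic: over all tables
    with the observed margins, sum the hypergeometric probabilities that do
    not exceed the observed table's, comparing integer numerators over the
    common denominator C(N, a+b)."""
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    r1, r2 = a + b, c + d  # row margins
    c1 = a + c  # first column margin
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs:
            total += num
    return float(min(total / comb(n, c1), 1.0))


def _odds_ratio_ci(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> tuple[float, float, float, bool]:
    """Wald OR CI on the log scale; Haldane-Anscombe 0.5 added to every cell
    when any cell is zero (and only then)."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
    else:
        a2, b2, c2, d2 = float(a), float(b), float(c), float(d)
    oratio = (a2 * d2) / (b2 * c2)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    return (
        float(oratio),
        float(np.exp(np.log(oratio) - z * se)),
        float(np.exp(np.log(oratio) + z * se)),
        corrected,
    )


def pairwise_fisher(
    tab: CompositionTable,
    contrasts: list[tuple[str, str]],
    level: float = 0.95,
) -> FisherTable:
    """Per subtype and contrast: 2x2 (subtype vs not-subtype across the two
    conditions), two-sided Fisher p, BH adjustment across all (subtype,
    contrast) tests jointly, Haldane-Anscombe odds ratios with Wald CIs, and
    stars on the adjusted p."""
    for c1, c2 in contrasts:
        for c in (c1, c2):
            if c not in tab.counts.columns:
                raise ValueError(f"contrast condition {c!r} absent from table")
        if c1 == c2:
            raise ValueError(f"contrast conditions must differ: {c1!r}")
    rows = []
    for c1, c2 in contrasts:
        n1 = int(tab.counts[c1].sum())
        n2 = int(tab.counts[c2].sum())
        for subtype in tab.counts.index:
            a = int(tab.counts.loc[subtype, c1])  # subtype in condition 1
            b = n1 - a
            c = int(tab.counts.loc[subtype, c2])
            d = n2 - c
            p = fisher_exact_p(a, b, c, d)
            oratio, lo, hi, corrected = _odds_ratio_ci(a, b, c, d, level)
            rows.append(
                {
                    "subtype": subtype,
                    "contrast": f"{c1}_vs_{c2}",
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": oratio,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                    "ha_corrected": corrected,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["stars"] = [stars(p) for p in df["p_adj"]]
    return FisherTable(table=df)


def delta_proportion(
    tab: CompositionTable,
    contrast: tuple[str, str],
    fisher: FisherTable | None = None,
) -> pd.DataFrame:
    """Percentage-point change per subtype, numerator minus denominator
    condition, joined with the Fisher stars when supplied."""
    num, den = contrast
    for c in contrast:
        if c not in tab.proportions.columns:
            raise ValueError(f"condition {c!r} absent from table")
    delta = 100.0 * (tab.proportions[num] - tab.proportions[den])
    out = pd.DataFrame({"subtype": tab.counts.index, "delta_pct": delta.to_numpy()})
    if fisher is not None:
        key = f"{num}_vs_{den}"
        sub = fisher.table[fisher.table["contrast"] == key].set_index("subtype")
        out["stars"] = [
            sub["stars"].get(s, "") for s in out["subtype"]
        ]
    else:
        out["stars"] = ""
    return out
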