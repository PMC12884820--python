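"""Differential expression and over-representation analysis.

DE uses the two-sided Wilcoxon rank-sum test on log-normalized expression
with the conventional reporting thresholds (|log2FC| > 0.25 and a minimum
expression fraction of 0.1 in either group) and Benjamini-Hochberg FDR
adjustment. For small groups (min(n_A, n_B) <= 10) the exact permutation
distribution of the rank sum is computed by dynamic programming, which
remains valid under ties; otherwise the normal approximation with tie
correction is used.

Over-representation of a query gene list in named gene sets is the
upper-tail hypergeometric test against a finite universe, BH-adjusted across
sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CellAnnotations, CellMatrix, GeneSetCollection

__all__ = [
    "DETable",
    "EnrichmentTable",
    "bh_adjust",
    "exact_ranksum_p",
    "wilcoxon_de",
    "ora",
    "volcano_table",
]

EXACT_MAX_GROUP = 10  # exact rank-sum enumeration engaged below this size


@dataclass
class DETable:
    """Filtered DE results plus the unfiltered table for volcano export."""

    table: pd.DataFrame  # rows pass |log2fc| and min_frac thresholds
    all_results: pd.DataFrame  # every pre-filter-passing gene, BH-adjusted

    COLUMNS = (
        "gene",
        "log2fc",
        "frac_in_group1",
        "frac_in_group2",
        "p",
        "p_adj",
        "direction",
    )


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # set, count, gene_ratio, bg_ratio, p, p_adj, overlap


def bh_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p, valid under ties.

    Enumerates the permutation distribution of the group-A rank sum by
    subset-sum dynamic programming over the doubled mid-ranks (integers) and
    returns P(|S - E[S]| >= |S_obs - E[S]|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_a, n_b = len(x), len(y)
    n = n_a + n_b
    ranks2 = np.round(2 * stats.rankdata(np.concatenate([x, y]))).astype(int)
    s_obs = int(ranks2[:n_a].sum())
    mu2 = n_a * (n + 1)  # E[2*ranksum]
    dev = abs(s_obs - mu2)

    s_max = int(ranks2.sum())
    dp = np.zeros((n_a + 1, s_max + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] += dp[:-1, : s_max + 1 - r]
    counts = dp[n_a]
    sums = np.arange(s_max + 1)
    hits = counts[np.abs(sums - mu2) >= dev].sum()
    return float(hits / comb(n, n_a))


def _group_stats(
    m: CellMatrix, mask: np.ndarray, gene_sel: np.ndarray | slice = slice(None)
) -> tuple[np.ndarray, np.ndarray]:
    """(fraction of cells with count > 0, mean of expm1(lognorm)) per gene."""
    counts = m.counts[mask][:, gene_sel]
    frac = np.asarray((counts > 0).mean(axis=0)).ravel()
    ln = m.require_lognorm()[mask][:, gene_sel]
    expm1_mean = np.asarray(ln.expm1().mean(axis=0)).ravel()
    return frac, expm1_mean


def wilcoxon_de(
    m: CellMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    lfc_threshold: float = 0.25,
    min_frac: float = 0.1,
) -> DETable:
    """Two-sided Wilcoxon rank-sum DE between two disjoint cell groups.

    ``cells_a``/``cells_b`` are boolean masks or integer indices over the
    matrix rows. Genes are pre-filtered to an expression fraction (share of
    cells with count > 0) of at least ``min_frac`` in either group; p-values
    are BH-adjusted across tested genes; reported rows additionally satisfy
    |log2fc| > ``lfc_threshold`` with
    log2fc = log2((mean_A expm1(lognorm) + 1) / (mean_B expm1(lognorm) + 1)).
    """
    mask_a = np.zeros(m.n_cells, dtype=bool)
    mask_b = np.zeros(m.n_cells, dtype=bool)
    mask_a[np.asarray(cells_a)] = True
    mask_b[np.asarray(cells_b)] = True
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both cell groups must be non-empty")
    if (mask_a & mask_b).any():
        raise ValueError("cell groups overlap")

    frac_a, mean_a = _group_stats(m, mask_a)
    frac_b, mean_b = _group_stats(m, mask_b)
    keep = np.flatnonzero((frac_a >= min_frac) | (frac_b >= min_frac))
    if keep.size == 0:
        return DETable(
            table=pd.DataFrame(columns=list(DETable.COLUMNS)),
            all_results=pd.DataFrame(columns=list(DETable.COLUMNS)),
        )

    log2fc = np.log2((mean_a[keep] + 1.0) / (mean_b[keep] + 1.0))
    X = m.require_lognorm()
    a = X[mask_a][:, keep].toarray()
    b = X[mask_b][:, keep].toarray()
    n_a, n_b = a.shape[0], b.shape[0]
    if min(n_a, n_b) <= EXACT_MAX_GROUP:
        pvals = np.array(
            [exact_ranksum_p(a[:, j], b[:, j]) for j in range(keep.size)]
        )
    else:
        flat = (np.ptp(a, axis=0) == 0) & (np.ptp(b, axis=0) == 0) & (
            a[0] == b[0]
        )
        pvals = np.ones(keep.size)
        var = ~flat
        if var.any():
            res = stats.mannwhitneyu(
                a[:, var],
                b[:, var],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
                axis=0,
            )
            pvals[var] = res.pvalue
    p_adj = bh_adjust(pvals)

    out = pd.DataFrame(
        {
            "gene": m.gene_ids[keep],
            "log2fc": log2fc,
            "frac_in_group1": frac_a[keep],
            "frac_in_group2": frac_b[keep],
            "p": pvals,
            "p_adj": p_adj,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    )
    filtered = out[np.abs(out["log2fc"]) > lfc_threshold].reset_index(drop=True)
    return DETable(table=filtered, all_results=out)


def wilcoxon_de_groups(
    m: CellMatrix,
    ann: CellAnnotations,
    *,
    group_a: dict,
    group_b: dict,
    lfc_threshold: float = 0.25,
    min_frac: float = 0.1,
) -> DETable:
    """Convenience selector: groups given as annotation filters, e.g.
    ``group_a={'condition': 'Early'}``."""
    mask_a = ann.mask(**group_a)
    mask_b = ann.mask(**group_b)
    return wilcoxon_de(
        m,
        np.flatnonzero(mask_a),
        np.flatnonzero(mask_b),
        lfc_threshold=lfc_threshold,
        min_frac=min_frac,
    )


def ora(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> EnrichmentTable:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= k) with k the query/set overlap inside the universe,
    population |universe|, successes |set ∩ universe|, draws |query|;
    BH-adjusted across sets.
    """
    uni = set(universe)
    outside = [g for g in query if g not in uni]
    if outside:
        raise ValueError(f"query gene(s) outside universe: {outside[:10]}")
    q = set(query)
    M, n_draw = len(uni), len(q)
    rows = []
    for name, genes in sets.sets.items():
        in_uni = uni & set(genes)
        overlap = sorted(q & in_uni)
        k = len(overlap)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, M, len(in_uni), n_draw))
        rows.append(
            {
                "set": name,
                "count": k,
                "gene_ratio": k / n_draw if n_draw else 0.0,
                "bg_ratio": len(in_uni) / M if M else 0.0,
                "p": min(p, 1.0),
                "overlap": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return EnrichmentTable(
        table=df[["set", "count", "gene_ratio", "bg_ratio", "p", "p_adj", "overlap"]]
    )


def volcano_table(all_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready volcano columns from unfiltered DE results.

    Adjusted p of 0 is replaced by the smallest positive float before the
    log so -log10 stays finite.
    """
    p_adj = all_results["p_adj"].to_numpy(dtype=float)
    tiny = np.finfo(float).tiny
    neg_log10 = -np.log10(np.where(p_adj <= 0, tiny, p_adj))
    return pd.DataFrame(
        {
            "gene": all_results["gene"],
            "log2fc": all_results["log2fc"],
            "neg_log10_p_adj": neg_log10,
            "significant": p_adj < alpha,
        }
    )
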