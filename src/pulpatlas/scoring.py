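"""Gene-set activity scoring and cluster-program comparison.

Two per-cell scores are provided: the control-binned *module score* (mean
log-normalized expression of the set minus the mean over expression-matched
control genes drawn from abundance bins) and the *recovery-curve AUC* (area
under the cumulative count of set members along the per-cell expression
ranking, truncated at a top fraction and normalized to its maximum).

Cluster-level views follow: per-cluster means with optional z-scoring across
clusters, specificity contrasts (z-score difference between a canonical and a
comparator program), Pearson cross-correlation of cluster-average profiles
between two labelings, and Kruskal-Wallis / pairwise Wilcoxon comparisons of
scores across conditions.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CellAnnotations, CellMatrix, GeneSetCollection, select_hvg
from .de_enrichment import bh_adjust

logger = logging.getLogger("pulpatlas")

__all__ = [
    "ScoreTable",
    "SpecificityTable",
    "ProgramCorrelation",
    "module_score",
    "auc_score",
    "score_sets",
    "cluster_score_summary",
    "specificity_contrast",
    "program_correlation",
    "score_condition_test",
]


@dataclass
class ScoreTable:
    """Scores indexed by cell id or cluster name, one column per gene set."""

    values: pd.DataFrame
    method: str  # 'module' or 'auc'
    zscored: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("module", "auc"):
            raise ValueError("method must be 'module' or 'auc'")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")
        if self.method == "auc" and not self.zscored:
            v = self.values.to_numpy(dtype=float)
            if v.min() < 0 or v.max() > 1:
                raise ValueError("AUC scores must lie in [0,1]")


@dataclass
class SpecificityTable:
    """Per-cluster z-score difference between two programs."""

    table: pd.DataFrame  # columns: cluster, contrast, score, n_cells


@dataclass
class ProgramCorrelation:
    """Pearson r between cluster-average profiles of two labelings."""

    r: pd.DataFrame  # rows: clusters of A, columns: clusters of B
    genes: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _set_seed(seed: int, genes: list[str]) -> int:
    """Seed for a gene set's control draw, stable under argument position."""
    digest = zlib.crc32("\t".join(sorted(genes)).encode())
    return (seed * 1_000_003 + digest) % (2**31)


def module_score(
    m: CellMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Control-binned module score per cell.

    Genes are placed into ``n_bins`` equal-frequency bins of average
    log-normalized expression; for each set gene ``n_ctrl`` control genes are
    sampled from its bin without replacement (with replacement when the bin is
    smaller), and the score is the per-cell mean over the set minus the mean
    over the pooled controls. The control draw is seeded from ``seed`` and the
    set's (sorted) content, so a set scores identically wherever it appears.
    """
    X = m.require_lognorm()
    present = [g for g in gene_set if g in set(m.gene_ids)]
    missing = [g for g in gene_set if g not in set(m.gene_ids)]
    if not present:
        raise KeyError(f"no gene of the set is present in the matrix: {missing[:10]}")
    if missing:
        warnings.warn(f"{len(missing)} set gene(s) absent from matrix", stacklevel=2)

    gene_mean = np.asarray(X.mean(axis=0)).ravel()
    # equal-frequency bins on average expression (ties share a bin)
    order = np.argsort(gene_mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(m.n_genes) * n_bins) // m.n_genes, n_bins - 1
    )

    set_idx = m.gene_index(present)
    rng = np.random.default_rng(_set_seed(seed, present))
    ctrl_idx: list[np.ndarray] = []
    set_pos = set(set_idx.tolist())
    for g in set_idx:
        pool = np.flatnonzero(bins == bins[g])
        pool = pool[[p not in set_pos for p in pool]]
        if pool.size == 0:  # degenerate bin made solely of set genes
            pool = np.flatnonzero(bins == bins[g])
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)

    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=m.cell_ids, name="module_score")


def auc_score(
    m: CellMatrix, gene_set: list[str], threshold: float = 0.05
) -> pd.Series:
    """Recovery-curve AUC per cell.

    Genes are ranked per cell by log-normalized expression, descending, ties
    broken by stable gene order. With K = ceil(threshold * n_genes) and
    hits(k) the number of set genes among the top k, the score is
    sum_{k<=K} hits(k) / sum_{k<=K} min(k, |S|) — 1 when the set fills the
    top ranks, 0 when no set gene enters the top K.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    X = m.require_lognorm()
    set_idx = m.gene_index([g for g in gene_set if g in set(m.gene_ids)], missing="drop")
    if set_idx.size == 0:
        raise KeyError("no gene of the set is present in the matrix")
    G = m.n_genes
    K = int(np.ceil(threshold * G))
    s = set_idx.size
    denom = float(np.minimum(np.arange(1, K + 1), s).sum())

    dense = X.toarray()
    # stable descending sort: sort on -value keeps original gene order on ties
    order = np.argsort(-dense, axis=1, kind="stable")[:, :K]
    is_set = np.zeros(G, dtype=bool)
    is_set[set_idx] = True
    hits = np.cumsum(is_set[order], axis=1)
    auc = hits.sum(axis=1) / denom
    return pd.Series(auc, index=m.cell_ids, name="auc")


def score_sets(
    m: CellMatrix,
    gsc: GeneSetCollection,
    method: str = "module",
    *,
    n_bins: int = 25,
    n_ctrl: int = 100,
    auc_threshold: float = 0.05,
    seed: int = 0,
) -> ScoreTable:
    """Score every set of a collection; returns a cells x sets ScoreTable."""
    cols = {}
    for name, genes in gsc.sets.items():
        if method == "module":
            cols[name] = module_score(m, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        elif method == "auc":
            cols[name] = auc_score(m, genes, threshold=auc_threshold)
        else:
            raise ValueError("method must be 'module' or 'auc'")
    return ScoreTable(values=pd.DataFrame(cols), method=method)


def _zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        v = out[c].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[c] = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    return out


def cluster_score_summary(
    scores: pd.Series | pd.DataFrame,
    ann: CellAnnotations,
    zscore: bool = False,
    method: str = "module",
) -> ScoreTable:
    """Mean score per (cluster, set); optionally z-score each set column
    across clusters (sd-0 columns become all zeros)."""
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    missing = set(ann.cell_ids) - set(df.index)
    if missing:
        raise ValueError(f"scores missing for {len(missing)} annotated cells")
    df = df.loc[ann.cell_ids]
    grouped = df.groupby(ann.cluster, sort=True).mean()
    empty = [c for c in ann.clusters() if c not in grouped.index]
    if empty:
        logger.warning("clusters with no cells excluded: %s", empty)
    if zscore:
        grouped = _zscore_columns(grouped)
    return ScoreTable(values=grouped, method=method, zscored=zscore)


def specificity_contrast(
    m: CellMatrix,
    ann: CellAnnotations,
    canonical: list[str],
    comparator: list[str],
    contrast_name: str = "contrast",
    *,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SpecificityTable:
    """Per-cluster specificity: z-scored module score of the canonical
    program minus the comparator's, exactly antisymmetric under swapping."""
    if sorted(set(canonical)) == sorted(set(comparator)):
        warnings.warn("canonical and comparator sets are identical; contrast is 0")
    s_can = module_score(m, canonical, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    s_cmp = module_score(m, comparator, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    both = pd.DataFrame({"canonical": s_can, "comparator": s_cmp})
    summary = cluster_score_summary(both, ann, zscore=True).values
    n_cells = pd.Series(ann.cluster).value_counts()
    table = pd.DataFrame(
        {
            "cluster": summary.index,
            "contrast": contrast_name,
            "score": (summary["canonical"] - summary["comparator"]).to_numpy(),
            "n_cells": [int(n_cells.get(c, 0)) for c in summary.index],
        }
    )
    return SpecificityTable(table=table)


def program_correlation(
    mA: CellMatrix,
    annA: CellAnnotations,
    mB: CellMatrix,
    annB: CellAnnotations,
    n_genes: int = 1000,
) -> ProgramCorrelation:
    """Pearson r between cluster-average log-normalized profiles of two
    labelings over a harmonized high-variance gene universe.

    HVGs are selected in each matrix separately, intersected, and truncated
    to ``n_genes`` by the sum of the two within-matrix ranks.
    """
    shared = [g for g in mA.gene_ids if g in set(mB.gene_ids)]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared genes; need >= 50")
    kA = min(mA.n_genes, max(n_genes * 2, 50))
    kB = min(mB.n_genes, max(n_genes * 2, 50))
    hvA = select_hvg(mA, kA)
    hvB = select_hvg(mB, kB)
    rankA = {g: i for i, g in enumerate(hvA)}
    rankB = {g: i for i, g in enumerate(hvB)}
    common = [g for g in hvA if g in rankB]
    if len(common) < 50:
        raise ValueError(f"only {len(common)} shared high-variance genes; need >= 50")
    common.sort(key=lambda g: rankA[g] + rankB[g])
    genes = common[:n_genes]

    def cluster_means(m: CellMatrix, ann: CellAnnotations) -> pd.DataFrame:
        X = m.require_lognorm()[:, m.gene_index(genes)]
        df = pd.DataFrame(X.toarray(), index=ann.cell_ids)
        return df.groupby(ann.cluster, sort=True).mean()

    profA = cluster_means(mA, annA)
    profB = cluster_means(mB, annB)
    r = np.corrcoef(profA.to_numpy(), profB.to_numpy())[: len(profA), len(profA):]
    return ProgramCorrelation(
        r=pd.DataFrame(r, index=profA.index, columns=profB.index), genes=genes
    )


def score_condition_test(
    scores: pd.Series | pd.DataFrame, ann: CellAnnotations
) -> pd.DataFrame:
    """Kruskal-Wallis across conditions plus BH-adjusted pairwise Wilcoxon
    rank-sum tests, per gene set.

    The pairwise test uses the normal approximation with tie correction and
    no continuity correction, so with two conditions the Kruskal-Wallis
    chi-square(1) p and the squared-z Wilcoxon p coincide.
    """
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    df = df.loc[ann.cell_ids]
    conds = [
        c for c in ann.conditions if (ann.condition == c).sum() >= 2
    ]
    skipped = set(ann.conditions) - set(conds)
    if skipped:
        warnings.warn(f"conditions with < 2 cells excluded: {sorted(skipped)}")
    if len(conds) < 2:
        raise ValueError("need at least two conditions with >= 2 cells")
    rows = []
    for set_name in df.columns:
        groups = [df.loc[ann.condition == c, set_name].to_numpy() for c in conds]
        if np.ptp(np.concatenate(groups)) == 0:
            h, p_kw = 0.0, 1.0
        else:
            h, p_kw = stats.kruskal(*groups)
        pair_ps, pair_names = [], []
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
                    p = 1.0
                else:
                    p = stats.mannwhitneyu(
                        groups[i],
                        groups[j],
                        alternative="two-sided",
                        method="asymptotic",
                        use_continuity=False,
                    ).pvalue
                pair_ps.append(float(p))
                pair_names.append(f"{conds[i]}_vs_{conds[j]}")
        p_adj = bh_adjust(pair_ps)
        for name, p, pa in zip(pair_names, pair_ps, p_adj):
            rows.append(
                {
                    "set": set_name,
                    "kw_H": float(h),
                    "kw_p": float(p_kw),
                    "pair": name,
                    "wilcoxon_p": p,
                    "wilcoxon_p_adj": pa,
                }
            )
    return pd.DataFrame(rows)
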