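"""Ligand-receptor cell-cell communication inference.

For every (sender cluster, receiver cluster, ligand-receptor pair) within a
condition, a communication probability is computed from cluster-level ligand
and receptor expression through a saturating mass-action form

    prob = L*R / (Kh + L*R),          L, R >= 0, Kh > 0,

where L and R are cluster summaries (trimean by default, mean optionally) of
log-normalized expression, with multi-subunit genes combined by geometric
mean. Significance comes from a cluster-label permutation null within the
condition, with the +1/(n+1) correction so p is never exactly zero; clusters
with fewer than ``min_cells`` cells in the condition are excluded before
inference. This is a self-contained reimplementation of the widely used
permutation-test design for communication inference; it preserves
monotonicity and boundedness but makes no claim of bit-compatibility with
any particular tool.

Cross-condition views: per-pair summed-probability deltas ranked by change,
delta strength matrices with node gain/loss bookkeeping, and stratified
bootstrap confidence intervals for the global network metrics (number of
significant interactions, total communication strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, CellAnnotations, CellMatrix, LRDatabase

__all__ = [
    "CommNetwork",
    "BootstrapSummary",
    "cluster_expression",
    "communication_probability",
    "infer_network",
    "network_summaries",
    "NetworkSummaries",
    "pair_condition_delta",
    "delta_network",
    "bootstrap_metrics",
]


@dataclass
class CommNetwork:
    """Per-condition communication network.

    ``edges`` has one row per (sender, receiver, pair) among clusters that
    passed the min_cells filter, with columns prob, p, significant, pathway.
    ``counts``/``strength`` are sender x receiver matrices over significant
    edges only.
    """

    condition: str
    clusters: list[str]
    edges: pd.DataFrame
    counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    strength: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None or self.strength is None:
            sig = self.edges[self.edges["significant"]]
            counts = np.zeros((len(self.clusters), len(self.clusters)))
            strength = np.zeros_like(counts)
            pos = {c: i for i, c in enumerate(self.clusters)}
            for r in sig.itertuples():
                counts[pos[r.sender], pos[r.receiver]] += 1
                strength[pos[r.sender], pos[r.receiver]] += r.prob
            self.counts = pd.DataFrame(
                counts, index=self.clusters, columns=self.clusters
            )
            self.strength = pd.DataFrame(
                strength, index=self.clusters, columns=self.clusters
            )

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]].reset_index(drop=True)


@dataclass
class NetworkSummaries:
    n_interactions: int
    total_strength: float
    counts: pd.DataFrame
    strength: pd.DataFrame
    pathway_strength: pd.Series


@dataclass
class BootstrapSummary:
    metric: str  # 'n_interactions' or 'total_strength'
    point: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("percentile CI must bracket the point estimate")


def communication_probability(
    L: float | np.ndarray, R: float | np.ndarray, kh: float = 0.5
) -> float | np.ndarray:
    """Saturating communication probability L*R / (Kh + L*R) in [0, 1)."""
    if kh <= 0:
        raise ValueError("Kh must be positive")
    lr = np.asarray(L, dtype=float) * np.asarray(R, dtype=float)
    out = lr / (kh + lr)
    return float(out) if out.ndim == 0 else out


def _estimate(values: np.ndarray, estimator: str) -> np.ndarray:
    """Column-wise cluster summary of a cells x genes dense block."""
    if estimator == "mean":
        return values.mean(axis=0)
    if estimator == "trimean":
        q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], axis=0)
        return (q1 + 2.0 * q2 + q3) / 4.0
    raise ValueError("estimator must be 'mean' or 'trimean'")


def _geometric_mean(expr: np.ndarray, idx: list[int]) -> np.ndarray:
    """Geometric mean across subunit columns; zero if any subunit is silent."""
    sub = expr[:, idx]
    return np.prod(sub, axis=1) ** (1.0 / len(idx))


def cluster_expression(
    m: CellMatrix,
    ann: CellAnnotations,
    genes: list[str],
    cluster: str,
    condition: str,
    estimator: str = "trimean",
) -> float:
    """Cluster-level expression of a (possibly multi-subunit) gene group:
    per-gene trimean (Q1 + 2*median + Q3)/4 or mean of log-normalized
    expression over the (cluster, condition) cells, combined across genes by
    geometric mean."""
    mask = ann.mask(cluster=cluster, condition=condition)
    if not mask.any():
        raise ValueError(f"no cells for cluster {cluster!r} in {condition!r}")
    idx = m.gene_index(genes)
    block = m.require_lognorm()[mask][:, idx].toarray()
    per_gene = _estimate(block, estimator)
    return float(np.prod(per_gene) ** (1.0 / len(idx)))


class _CommCore:
    """Shared machinery over a dense (condition cells) x (LR genes) block."""

    def __init__(self, m: CellMatrix, lrdb: LRDatabase):
        self.genes = lrdb.genes()
        self.gene_pos = {g: i for i, g in enumerate(self.genes)}
        self.gene_idx = m.gene_index(self.genes)
        self.lig_idx = [
            [self.gene_pos[g] for g in p.ligand_genes] for p in lrdb.pairs
        ]
        self.rec_idx = [
            [self.gene_pos[g] for g in p.receptor_genes] for p in lrdb.pairs
        ]
        self.pairs = lrdb.pairs

    def probs(
        self,
        block: np.ndarray,
        labels: np.ndarray,
        n_clusters: int,
        estimator: str,
        kh: float,
    ) -> np.ndarray:
        """(n_pairs, n_clusters, n_clusters) probability array."""
        expr = np.empty((n_clusters, block.shape[1]))
        for k in range(n_clusters):
            expr[k] = _estimate(block[labels == k], estimator)
        out = np.empty((len(self.pairs), n_clusters, n_clusters))
        for i in range(len(self.pairs)):
            L = _geometric_mean(expr, self.lig_idx[i])
            R = _geometric_mean(expr, self.rec_idx[i])
            lr = np.outer(L, R)
            out[i] = lr / (kh + lr)
        return out


def _infer_edges(
    core: _CommCore,
    block: np.ndarray,
    labels: np.ndarray,
    clusters: list[str],
    cfg: AnalysisConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_cl = len(clusters)
    obs = core.probs(block, labels, n_cl, cfg.estimator, cfg.kh)
    exceed = np.zeros_like(obs)
    for _ in range(cfg.n_perm):
        perm = rng.permutation(labels)
        exceed += core.probs(block, perm, n_cl, cfg.estimator, cfg.kh) >= obs
    pvals = (1.0 + exceed) / (1.0 + cfg.n_perm)
    rows = []
    for i, pair in enumerate(core.pairs):
        for s in range(n_cl):
            for r in range(n_cl):
                rows.append(
                    (
                        clusters[s],
                        clusters[r],
                        pair.pair_name,
                        pair.pathway,
                        obs[i, s, r],
                        pvals[i, s, r],
                    )
                )
    edges = pd.DataFrame(
        rows, columns=["sender", "receiver", "pair", "pathway", "prob", "p"]
    )
    edges["significant"] = edges["p"] < cfg.alpha
    return edges


def _condition_block(
    m: CellMatrix,
    ann: CellAnnotations,
    core: _CommCore,
    condition: str,
    min_cells: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if condition not in ann.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_mask = ann.mask(condition=condition)
    clusters_all = sorted(set(ann.cluster[cond_mask]))
    sizes = {c: int((ann.cluster[cond_mask] == c).sum()) for c in clusters_all}
    clusters = [c for c in clusters_all if sizes[c] >= min_cells]
    if not clusters:
        raise ValueError(
            f"no cluster reaches min_cells={min_cells} in {condition!r}"
        )
    keep = cond_mask & np.isin(ann.cluster, clusters)
    labels = np.searchsorted(np.array(clusters), ann.cluster[keep])
    block = m.require_lognorm()[keep][:, core.gene_idx].toarray()
    return block, labels, clusters


def infer_network(
    m: CellMatrix,
    ann: CellAnnotations,
    lrdb: LRDatabase,
    condition: str,
    cfg: AnalysisConfig,
    seed: int | np.random.Generator | None = None,
) -> CommNetwork:
    """Infer the communication network of one condition.

    Clusters below ``cfg.min_cells`` cells in the condition are excluded; the
    permutation null relabels cluster assignments within the condition
    ``cfg.n_perm`` times; p = (1 + #{prob_perm >= prob_obs}) / (1 + n_perm).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    core = _CommCore(m, lrdb)
    block, labels, clusters = _condition_block(m, ann, core, condition, cfg.min_cells)
    edges = _infer_edges(core, block, labels, clusters, cfg, rng)
    return CommNetwork(condition=condition, clusters=clusters, edges=edges)


def network_summaries(net: CommNetwork) -> NetworkSummaries:
    """Global scalars and matrices over the significant edges."""
    sig = net.significant_edges()
    pathway = (
        sig.groupby("pathway")["prob"].sum().sort_values(ascending=False)
        if len(sig)
        else pd.Series(dtype=float)
    )
    return NetworkSummaries(
        n_interactions=int(len(sig)),
        total_strength=float(sig["prob"].sum()),
        counts=net.counts,
        strength=net.strength,
        pathway_strength=pathway,
    )


def pair_condition_delta(
    nets: dict[str, CommNetwork],
    cond_from: str,
    cond_to: str,
    mode: str = "pair",
) -> pd.DataFrame:
    """Per-pair (or per sender/receiver/pair triple) summed significant-edge
    probability in each condition with delta = to - from, sorted ascending.

    Pairs significant in neither condition are excluded. The most-decreasing
    entries head the table (rank 1 = largest decline)."""
    if mode not in ("pair", "triple"):
        raise ValueError("mode must be 'pair' or 'triple'")
    for cond in (cond_from, cond_to):
        if cond not in nets:
            raise ValueError(f"no network for condition {cond!r}")
    keys = ["pair"] if mode == "pair" else ["sender", "receiver", "pair"]

    def summed(net: CommNetwork) -> pd.Series:
        sig = net.significant_edges()
        if not len(sig):
            return pd.Series(dtype=float)
        return sig.groupby(keys)["prob"].sum()

    s_from = summed(nets[cond_from])
    s_to = summed(nets[cond_to])
    idx = s_from.index.union(s_to.index)
    if len(idx) == 0:
        return pd.DataFrame(
            columns=keys + [f"prob_{cond_from}", f"prob_{cond_to}", "delta", "rank"]
        )
    df = pd.DataFrame(
        {
            f"prob_{cond_from}": s_from.reindex(idx, fill_value=0.0),
            f"prob_{cond_to}": s_to.reindex(idx, fill_value=0.0),
        }
    )
    df["delta"] = df[f"prob_{cond_to}"] - df[f"prob_{cond_from}"]
    df = df.sort_values("delta", kind="stable").reset_index()
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def delta_network(
    net_from: CommNetwork, net_to: CommNetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta strength matrix (to - from) over the union of cluster universes
    plus per-node gained/lost significant-edge bookkeeping.

    A node's net change counts both outgoing and incoming significant edges,
    so a gained self-edge contributes +2 to its cluster."""
    clusters = sorted(set(net_from.clusters) | set(net_to.clusters))
    s_from = net_from.strength.reindex(index=clusters, columns=clusters, fill_value=0.0)
    s_to = net_to.strength.reindex(index=clusters, columns=clusters, fill_value=0.0)
    delta = s_to - s_from

    def edge_keys(net: CommNetwork) -> set[tuple[str, str, str]]:
        sig = net.significant_edges()
        return set(zip(sig["sender"], sig["receiver"], sig["pair"]))

    from_keys, to_keys = edge_keys(net_from), edge_keys(net_to)
    gained = to_keys - from_keys
    lost = from_keys - to_keys
    rows = []
    for c in clusters:
        g = sum((s == c) + (r == c) for s, r, _ in gained)
        l = sum((s == c) + (r == c) for s, r, _ in lost)
        rows.append({"cluster": c, "gained": int(g), "lost": int(l), "net": int(g - l)})
    return delta, pd.DataFrame(rows)


def bootstrap_metrics(
    m: CellMatrix,
    ann: CellAnnotations,
    lrdb: LRDatabase,
    condition: str,
    cfg: AnalysisConfig,
    seed: int | np.random.Generator | None = None,
) -> dict[str, BootstrapSummary]:
    """Percentile bootstrap CIs for n_interactions and total_strength.

    Cells are resampled with replacement within each cluster of the
    condition (stratified, original stratum sizes), so composition is held
    fixed and only expression uncertainty propagates; the full inference
    including the permutation test is recomputed per resample."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    core = _CommCore(m, lrdb)
    block, labels, clusters = _condition_block(m, ann, core, condition, cfg.min_cells)
    point_edges = _infer_edges(core, block, labels, clusters, cfg, rng)
    sig = point_edges[point_edges["significant"]]
    point = {
        "n_interactions": float(len(sig)),
        "total_strength": float(sig["prob"].sum()),
    }

    strata = [np.flatnonzero(labels == k) for k in range(len(clusters))]
    boot = {k: np.empty(cfg.n_boot) for k in point}
    for b in range(cfg.n_boot):
        take = np.concatenate(
            [rng.choice(s, size=s.size, replace=True) for s in strata]
        )
        lab = np.concatenate(
            [np.full(s.size, k) for k, s in enumerate(strata)]
        )
        edges = _infer_edges(core, block[take], lab, clusters, cfg, rng)
        sig_b = edges[edges["significant"]]
        boot["n_interactions"][b] = len(sig_b)
        boot["total_strength"][b] = sig_b["prob"].sum()

    out = {}
    for metric, values in boot.items():
        low, high = np.quantile(values, [0.025, 0.975])
        out[metric] = BootstrapSummary(
            metric=metric,
            point=point[metric],
            ci_low=float(min(low, point[metric])),
            ci_high=float(max(high, point[metric])),
            n_boot=cfg.n_boot,
        )
    return out
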