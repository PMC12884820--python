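"""Synthetic three-condition single-cell atlas generator.

The generator emulates the structure of a disease-progression atlas: an
ordered set of conditions (by default Healthy, Early, Advanced), clusters with
planted marker programs, condition-dependent cluster proportions, and
condition-dependent ligand-receptor gene activity. Counts follow a negative
binomial with a shared size (dispersion) parameter and per-cell lognormal
library-size variation — the minimal count model consistent with scRNA-seq
overdispersion; no zero inflation is added because NB zeros suffice at the
simulated depths.

Every simulation also emits a :class:`GroundTruth` record (planted markers,
proportions, LR activity, and the analytic per-cluster mean expression
matrix), which downstream parameter-recovery tests treat as the oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .core_io import (
    CellAnnotations,
    CellMatrix,
    GeneSetCollection,
    LRDatabase,
    LRPair,
)

__all__ = [
    "ClusterSpec",
    "LRProgramEntry",
    "SimConfig",
    "GroundTruth",
    "simulate_atlas",
    "null_config",
    "build_config",
    "demo_config",
    "fixture_gene_sets",
    "fixture_lr_db",
]

DEFAULT_CONDITIONS = ("Healthy", "Early", "Advanced")


@dataclass
class ClusterSpec:
    name: str
    proportions: dict[str, float]  # condition -> proportion
    marker_genes: list[str] = field(default_factory=list)
    marker_log2fc: float = 0.0


@dataclass
class LRProgramEntry:
    pair_name: str
    ligand_genes: tuple[str, ...]
    receptor_genes: tuple[str, ...]
    sender: str
    receiver: str
    activity: dict[str, float]  # condition -> multiplier (1 = no effect)
    pathway: str = "Misc"


@dataclass
class SimConfig:
    n_genes: int
    conditions: list[tuple[str, int]]  # (name, n_cells) in biological order
    clusters: list[ClusterSpec]
    lr_program: list[LRProgramEntry] = field(default_factory=list)
    baseline_mean_log: tuple[float, float] = (-1.5, 1.0)  # lognormal (mu, sigma)
    mean_overrides: dict[str, float] = field(default_factory=dict)
    dispersion: float = 2.0  # NB size parameter, shared across genes
    libsize_sigma: float = 0.3
    fixed_counts: bool = False  # exact planted composition instead of multinomial
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("cluster names not unique")
        cond_names = [c for c, _ in self.conditions]
        for cond in cond_names:
            s = sum(c.proportions.get(cond, 0.0) for c in self.clusters)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"cluster proportions for {cond!r} sum to {s}")
        seen: set[str] = set()
        for c in self.clusters:
            overlap = seen & set(c.marker_genes)
            if overlap:
                raise ValueError(f"marker genes shared across clusters: {overlap}")
            seen |= set(c.marker_genes)
        for e in self.lr_program:
            if min(e.activity.values(), default=1.0) < 0:
                raise ValueError(f"negative activity multiplier in {e.pair_name}")
        all_genes = set(self.gene_ids())
        for c in self.clusters:
            bad = set(c.marker_genes) - all_genes
            if bad:
                raise ValueError(f"marker genes out of range: {sorted(bad)[:5]}")
        for e in self.lr_program:
            bad = (set(e.ligand_genes) | set(e.receptor_genes)) - all_genes
            if bad:
                raise ValueError(f"LR genes out of range: {sorted(bad)[:5]}")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def condition_names(self) -> list[str]:
        return [c for c, _ in self.conditions]


@dataclass
class GroundTruth:
    """Planted structure of a simulation, the parameter-recovery oracle."""

    labels: pd.DataFrame  # cell_id, cluster, condition, sample_id
    planted_markers: dict[str, list[str]]  # cluster -> marker genes
    planted_proportions: dict[str, dict[str, float]]  # condition -> cluster -> p
    planted_lr: dict[str, LRProgramEntry]  # pair_name -> entry
    expected_means: dict[str, np.ndarray]  # condition -> clusters x genes
    cluster_order: list[str]
    gene_ids: list[str]
    dispersion: float
    libsize_sigma: float

    def expected_mean(self, condition: str, cluster: str) -> np.ndarray:
        return self.expected_means[condition][self.cluster_order.index(cluster)]

    def expected_lognorm_means(
        self,
        condition: str,
        cluster: str,
        genes: list[str],
        scale_factor: float = 10_000.0,
        n_quad: int = 21,
        tail: float = 1e-10,
    ) -> np.ndarray:
        """Exact numerical E[ln(1 + sf * X / T)] for the listed genes.

        X ~ NB(mean L*m_g, size r); the per-cell total T is approximated by
        its conditional mean L * sum_g m_g (it concentrates over thousands of
        genes); the lognormal library factor L is integrated by Gauss-Hermite
        quadrature.
        """
        m = self.expected_mean(condition, cluster)
        gidx = [self.gene_ids.index(g) for g in genes]
        total0 = float(m.sum())
        r = self.dispersion
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        weights = weights / np.sqrt(np.pi)
        sigma = self.libsize_sigma
        out = np.zeros(len(gidx))
        for node, w in zip(nodes, weights):
            L = np.exp(sigma * np.sqrt(2.0) * node - sigma**2 / 2.0)
            T = L * total0
            for j, g in enumerate(gidx):
                mu = L * m[g]
                if mu == 0:
                    continue
                p = r / (r + mu)
                xmax = int(stats.nbinom.ppf(1 - tail, r, p)) + 1
                xs = np.arange(xmax + 1)
                pmf = stats.nbinom.pmf(xs, r, p)
                out[j] += w * float(pmf @ np.log1p(scale_factor * xs / T))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.to_dict(orient="list"),
            "planted_markers": self.planted_markers,
            "planted_proportions": self.planted_proportions,
            "planted_lr": {
                k: {
                    "ligand_genes": list(v.ligand_genes),
                    "receptor_genes": list(v.receptor_genes),
                    "sender": v.sender,
                    "receiver": v.receiver,
                    "activity": v.activity,
                    "pathway": v.pathway,
                }
                for k, v in self.planted_lr.items()
            },
            "expected_means": {k: v.tolist() for k, v in self.expected_means.items()},
            "cluster_order": self.cluster_order,
            "gene_ids": self.gene_ids,
            "dispersion": self.dispersion,
            "libsize_sigma": self.libsize_sigma,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _baseline_means(cfg: SimConfig) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed % (2**31), 11])
    mu, sigma = cfg.baseline_mean_log
    base = rng.lognormal(mu, sigma, cfg.n_genes)
    if cfg.mean_overrides:
        ids = cfg.gene_ids()
        pos = {g: i for i, g in enumerate(ids)}
        for g, v in cfg.mean_overrides.items():
            base[pos[g]] = v
    return base


def _expected_means(cfg: SimConfig) -> dict[str, np.ndarray]:
    """clusters x genes mean matrix per condition (library factor excluded)."""
    base = _baseline_means(cfg)
    ids = cfg.gene_ids()
    pos = {g: i for i, g in enumerate(ids)}
    cluster_idx = {c.name: k for k, c in enumerate(cfg.clusters)}
    out: dict[str, np.ndarray] = {}
    for cond in cfg.condition_names():
        m = np.tile(base, (len(cfg.clusters), 1))
        for k, c in enumerate(cfg.clusters):
            if c.marker_genes and c.marker_log2fc != 0.0:
                m[k, [pos[g] for g in c.marker_genes]] *= 2.0**c.marker_log2fc
        for e in cfg.lr_program:
            a = e.activity.get(cond, 1.0)
            if a != 1.0:
                m[cluster_idx[e.sender], [pos[g] for g in e.ligand_genes]] *= a
                m[cluster_idx[e.receiver], [pos[g] for g in e.receptor_genes]] *= a
        out[cond] = m
    return out


def _fixed_cluster_counts(props: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells to planted proportions."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def simulate_atlas(
    cfg: SimConfig,
) -> tuple[CellMatrix, CellAnnotations, GroundTruth]:
    """Draw a synthetic atlas; fully determined by ``cfg.seed``.

    counts[c, g] ~ NB(mean = L_c * m[k(c), g, cond(c)], size = dispersion)
    with L_c lognormal(0, libsize_sigma) normalized to mean 1. Cells are
    assigned to clusters by a per-condition multinomial draw over the planted
    proportions, or deterministically (largest remainder) when
    ``cfg.fixed_counts`` is set.
    """
    rng = np.random.default_rng([cfg.seed % (2**31), 29])
    expected = _expected_means(cfg)
    cluster_names = [c.name for c in cfg.clusters]
    r = cfg.dispersion

    blocks: list[sp.csr_matrix] = []
    rows: list[dict[str, str]] = []
    cell_counter = 0
    for cond, n_cells in cfg.conditions:
        props = np.array([c.proportions.get(cond, 0.0) for c in cfg.clusters])
        if cfg.fixed_counts:
            per_cluster = _fixed_cluster_counts(props, n_cells)
            assign = np.repeat(np.arange(len(cfg.clusters)), per_cluster)
        else:
            assign = rng.choice(len(cfg.clusters), size=n_cells, p=props)
        L = rng.lognormal(0.0, cfg.libsize_sigma, n_cells)
        L /= np.exp(cfg.libsize_sigma**2 / 2.0)  # analytic mean-1 normalization
        mean = expected[cond][assign] * L[:, None]
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
        blocks.append(sp.csr_matrix(counts))
        for k in assign:
            rows.append(
                {
                    "cell_id": f"cell{cell_counter:06d}",
                    "cluster": cluster_names[k],
                    "condition": cond,
                    "sample_id": f"{cond}_s1",
                }
            )
            cell_counter += 1

    counts = sp.vstack(blocks).tocsr()
    labels = pd.DataFrame(rows)
    m = CellMatrix(
        counts=counts,
        gene_ids=np.array(cfg.gene_ids(), dtype=object),
        cell_ids=labels["cell_id"].to_numpy(),
    )
    ann = CellAnnotations(labels.copy(), conditions=cfg.condition_names())
    gt = GroundTruth(
        labels=labels,
        planted_markers={
            c.name: list(c.marker_genes) for c in cfg.clusters if c.marker_genes
        },
        planted_proportions={
            cond: {c.name: c.proportions.get(cond, 0.0) for c in cfg.clusters}
            for cond in cfg.condition_names()
        },
        planted_lr={e.pair_name: e for e in cfg.lr_program},
        expected_means=expected,
        cluster_order=cluster_names,
        gene_ids=cfg.gene_ids(),
        dispersion=cfg.dispersion,
        libsize_sigma=cfg.libsize_sigma,
    )
    return m, ann, gt


# ---------------------------------------------------------------------------
# config builders
# ---------------------------------------------------------------------------


def build_config(
    n_genes: int,
    conditions: list[tuple[str, int]],
    n_clusters: int,
    *,
    markers_per_cluster: int = 0,
    marker_log2fc: float = 0.0,
    marker_base_mean: float | None = None,
    proportions: dict[str, list[float]] | None = None,
    lr_edges: list[tuple[str, str, dict[str, float], str]] | None = None,
    lr_base_mean: float = 0.5,
    dispersion: float = 2.0,
    libsize_sigma: float = 0.3,
    fixed_counts: bool = False,
    seed: int = 0,
) -> SimConfig:
    """Assemble a SimConfig with disjoint marker and LR gene blocks.

    ``lr_edges`` entries are (sender, receiver, activity-per-condition,
    pathway); each edge gets a dedicated ligand gene and receptor gene whose
    baseline mean is pinned to ``lr_base_mean`` so planted effect sizes are
    controlled. Cluster names are C01, C02, ...
    """
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    cond_names = [c for c, _ in conditions]
    cluster_names = [f"C{k + 1:02d}" for k in range(n_clusters)]
    lr_edges = lr_edges or []
    needed = n_clusters * markers_per_cluster + 2 * len(lr_edges)
    if needed > n_genes:
        raise ValueError(f"{n_genes} genes cannot host {needed} planted genes")

    cursor = 0
    clusters = []
    marker_overrides: dict[str, float] = {}
    for k, name in enumerate(cluster_names):
        markers = gene_ids[cursor : cursor + markers_per_cluster]
        cursor += markers_per_cluster
        if marker_base_mean is not None:
            marker_overrides.update({g: marker_base_mean for g in markers})
        if proportions is None:
            props = {cond: 1.0 / n_clusters for cond in cond_names}
        else:
            props = {cond: proportions[cond][k] for cond in cond_names}
        clusters.append(
            ClusterSpec(
                name=name,
                proportions=props,
                marker_genes=markers,
                marker_log2fc=marker_log2fc if markers else 0.0,
            )
        )

    program, overrides = [], dict(marker_overrides)
    for i, (sender, receiver, activity, pathway) in enumerate(lr_edges):
        lig, rec = gene_ids[cursor], gene_ids[cursor + 1]
        cursor += 2
        overrides[lig] = lr_base_mean
        overrides[rec] = lr_base_mean
        program.append(
            LRProgramEntry(
                pair_name=f"P{i + 1:03d}",
                ligand_genes=(lig,),
                receptor_genes=(rec,),
                sender=sender,
                receiver=receiver,
                activity={cond: activity.get(cond, 1.0) for cond in cond_names},
                pathway=pathway,
            )
        )

    return SimConfig(
        n_genes=n_genes,
        conditions=conditions,
        clusters=clusters,
        lr_program=program,
        mean_overrides=overrides,
        dispersion=dispersion,
        libsize_sigma=libsize_sigma,
        fixed_counts=fixed_counts,
        seed=seed,
    )


def null_config(
    n_clusters: int, n_cells: int, n_pairs: int, seed: int
) -> SimConfig:
    """Global null: no marker effects, uniform proportions, all LR
    multipliers 1. Used for type-I-error calibration."""
    if min(n_clusters, n_cells, n_pairs) <= 0:
        raise ValueError("arguments must be positive")
    cluster_names = [f"C{k + 1:02d}" for k in range(n_clusters)]
    rng = np.random.default_rng([seed % (2**31), 5])
    edges = []
    for _ in range(n_pairs):
        s, t = rng.choice(n_clusters, size=2)
        edges.append((cluster_names[s], cluster_names[t], {}, "Null"))
    return build_config(
        n_genes=max(200, 2 * n_pairs + 50),
        conditions=[(c, n_cells) for c in DEFAULT_CONDITIONS],
        n_clusters=n_clusters,
        lr_edges=edges,
        seed=seed,
    )


def demo_config(
    seed: int = 0, n_cells_per_condition: int = 700, n_genes: int = 1500
) -> SimConfig:
    """Demo atlas: 8 clusters, 30 LR pairs with progressive activity loss,
    marker programs, and a planted subtype proportion shift.

    Twelve pairs are active (multiplier 5) in Healthy: six collapse already
    at the Early stage and six decline gradually (5 -> 2.5 -> 1), emulating
    progressive loss of stromal signaling, so significant-edge counts and
    total strength fall monotonically across conditions; cluster C01 shrinks
    from 30% to 10% of cells while C02 expands.
    """
    n_clusters = 8
    conds = [(c, n_cells_per_condition) for c in DEFAULT_CONDITIONS]
    cluster_names = [f"C{k + 1:02d}" for k in range(n_clusters)]
    rng = np.random.default_rng([seed % (2**31), 7])
    edges: list[tuple[str, str, dict[str, float], str]] = []
    for i in range(30):
        s, t = rng.choice(n_clusters, size=2, replace=False)
        if i < 6:  # lost at the early stage
            act = {"Healthy": 5.0, "Early": 1.0, "Advanced": 1.0}
            pathway = "ECM"
        elif i < 12:  # gradual decline
            act = {"Healthy": 5.0, "Early": 2.5, "Advanced": 1.0}
            pathway = "Laminin"
        else:
            act = {}
            pathway = "Misc"
        edges.append((cluster_names[s], cluster_names[t], act, pathway))
    shifts = {"C01": (0.30, 0.20, 0.10), "C02": (0.10, 0.20, 0.30)}
    props: dict[str, list[float]] = {}
    for j, cond in enumerate(DEFAULT_CONDITIONS):
        taken = sum(v[j] for v in shifts.values())
        rest = (1.0 - taken) / (n_clusters - len(shifts))
        props[cond] = [
            shifts[c][j] if c in shifts else rest for c in cluster_names
        ]
    return build_config(
        n_genes=n_genes,
        conditions=conds,
        n_clusters=n_clusters,
        markers_per_cluster=20,
        marker_log2fc=2.0,
        proportions=props,
        lr_edges=edges,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# companion fixtures
# ---------------------------------------------------------------------------


def fixture_gene_sets(
    cfg: SimConfig, n_decoys: int = 5, decoy_size: int | None = None
) -> GeneSetCollection:
    """One canonical '<cluster>_markers' set per marked cluster plus random
    decoy sets of matched size drawn from non-planted genes."""
    sets: dict[str, list[str]] = {}
    planted: set[str] = set()
    sizes = []
    for c in cfg.clusters:
        if c.marker_genes:
            sets[f"{c.name}_markers"] = list(c.marker_genes)
            planted |= set(c.marker_genes)
            sizes.append(len(c.marker_genes))
    for e in cfg.lr_program:
        planted |= set(e.ligand_genes) | set(e.receptor_genes)
    pool = [g for g in cfg.gene_ids() if g not in planted]
    size = decoy_size or (sizes[0] if sizes else 20)
    rng = np.random.default_rng([cfg.seed % (2**31), 13])
    for i in range(n_decoys):
        sets[f"decoy_{i + 1}"] = list(rng.choice(pool, size=size, replace=False))
    return GeneSetCollection(sets)


def fixture_lr_db(cfg: SimConfig) -> LRDatabase:
    """LR pair table covering every simulated pair, planted or not, with the
    planted pathway labels."""
    return LRDatabase(
        [
            LRPair(
                pair_name=e.pair_name,
                ligand_genes=e.ligand_genes,
                receptor_genes=e.receptor_genes,
                pathway=e.pathway,
            )
            for e in cfg.lr_program
        ]
    )
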