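"""Data model and file formats for the cross-condition single-cell pipeline.

The in-memory containers are deliberately thin: a sparse cells-by-genes count
matrix with an optional log-normalized layer (:class:`CellMatrix`), a per-cell
annotation table (:class:`CellAnnotations`), a named gene-set collection, a
ligand-receptor pair table, and the analysis configuration. On disk the matrix
travels as Matrix Market coordinate format (stored genes-by-cells, the common
exchange convention, with the orientation recorded in a sidecar JSON), gene
sets as GMT, ligand-receptor pairs as CSV.

Two preprocessing transforms live here because every downstream stage consumes
their output: library-size log-normalization (``ln(1 + sf * x / total)``) and
highly-variable-gene selection by standardized variance after removing the
mean-variance trend.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("pulpatlas")

__all__ = [
    "CellMatrix",
    "CellAnnotations",
    "GeneSetCollection",
    "LRPair",
    "LRDatabase",
    "AnalysisConfig",
    "FormatError",
    "IntegrityError",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_gmt",
    "write_gmt",
    "read_lr_csv",
    "write_lr_csv",
    "read_config",
    "write_config",
    "log_normalize",
    "select_hvg",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Companion files disagree (e.g. barcodes missing from annotations)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Sparse cells-by-genes counts with an optional log-normalized layer.

    ``counts`` holds raw non-negative integer UMI counts (CSR, cells in rows).
    ``lognorm`` is present once :func:`log_normalize` has been applied and
    holds ``ln(1 + scale_factor * counts / cell_total)`` with the same
    sparsity pattern.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    lognorm: sp.csr_matrix | None = None
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != n_cells {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts must be integral")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str], *, missing: str = "error") -> np.ndarray:
        """Column indices of ``genes``; ``missing`` in {'error','drop'}."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx, absent = [], []
        for g in genes:
            if g in lookup:
                idx.append(lookup[g])
            else:
                absent.append(g)
        if absent and missing == "error":
            raise KeyError(f"genes absent from matrix: {absent[:10]}")
        return np.asarray(idx, dtype=int)

    def require_lognorm(self) -> sp.csr_matrix:
        if self.lognorm is None:
            raise ValueError("log-normalized layer missing; run log_normalize first")
        return self.lognorm


@dataclass
class CellAnnotations:
    """Per-cell cluster, ordered condition, and sample labels."""

    table: pd.DataFrame  # columns: cell_id, cluster, condition, sample_id
    conditions: list[str] = field(default_factory=list)  # ordered

    REQUIRED = ("cell_id", "cluster", "condition", "sample_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if not self.conditions:
            # preserve first-appearance order
            self.conditions = list(dict.fromkeys(self.table["condition"]))
        extra = set(self.table["condition"]) - set(self.conditions)
        if extra:
            raise ValueError(f"conditions outside declared order: {sorted(extra)}")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy()

    @property
    def cluster(self) -> np.ndarray:
        return self.table["cluster"].to_numpy()

    @property
    def condition(self) -> np.ndarray:
        return self.table["condition"].to_numpy()

    def clusters(self) -> list[str]:
        return sorted(set(self.table["cluster"]))

    def mask(self, *, cluster=None, condition=None) -> np.ndarray:
        m = np.ones(len(self.table), dtype=bool)
        if cluster is not None:
            m &= self.table["cluster"].to_numpy() == cluster
        if condition is not None:
            m &= self.table["condition"].to_numpy() == condition
        return m

    def check_against(self, m: CellMatrix) -> None:
        if len(self.table) != m.n_cells or not np.array_equal(
            self.cell_ids, m.cell_ids
        ):
            raise IntegrityError("annotation rows do not match matrix cell_ids")


@dataclass
class GeneSetCollection:
    """Named gene sets (unique names, each non-empty after de-duplication)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.sets.items():
            dedup = list(dict.fromkeys(genes))
            if not dedup:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = dedup
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class LRPair:
    pair_name: str
    ligand_genes: tuple[str, ...]
    receptor_genes: tuple[str, ...]
    pathway: str

    def __post_init__(self) -> None:
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError(f"pair {self.pair_name!r} has an empty gene list")


@dataclass
class LRDatabase:
    """Ligand-receptor pair table; pairs aggregate to pathways."""

    pairs: list[LRPair]

    def __post_init__(self) -> None:
        names = [p.pair_name for p in self.pairs]
        if len(set(names)) != len(names):
            raise ValueError("pair_name values are not unique")

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend(p.ligand_genes)
            out.extend(p.receptor_genes)
        return list(dict.fromkeys(out))

    def pathway_of(self) -> dict[str, str]:
        return {p.pair_name: p.pathway for p in self.pairs}


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline with their field defaults.

    scale_factor : library-size normalization target (counts per cell).
    n_hvg        : number of highly variable genes to select.
    alpha        : significance level for permutation and exact tests.
    min_cells    : minimum cells per cluster/condition for communication.
    n_perm       : label permutations for the communication null.
    n_boot       : bootstrap resamples for network-metric CIs.
    lfc_threshold: |log2 fold-change| cutoff for reported DE genes.
    min_frac     : minimum expression fraction in either DE group.
    auc_threshold: top-fraction of the ranking used by the recovery-curve AUC.
    kh           : half-saturation constant of the communication probability.
    estimator    : cluster expression estimator, 'trimean' or 'mean'.
    """

    scale_factor: float = 10_000.0
    n_hvg: int = 1000
    alpha: float = 0.05
    min_cells: int = 5
    n_perm: int = 100
    n_boot: int = 500
    lfc_threshold: float = 0.25
    min_frac: float = 0.1
    auc_threshold: float = 0.05
    kh: float = 0.5
    estimator: str = "trimean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        for name in ("n_hvg", "min_cells", "n_perm", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 < self.auc_threshold < 1:
            raise ValueError("auc_threshold must lie in (0,1)")
        if self.estimator not in ("trimean", "mean"):
            raise ValueError("estimator must be 'trimean' or 'mean'")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SIDECAR = "bundle.json"


def write_mtx_bundle(
    out_dir: str | Path, m: CellMatrix, ann: CellAnnotations
) -> Path:
    """Serialize a matrix + annotations as matrix.mtx / features.tsv /
    barcodes.tsv / annotations.tsv with an orientation sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann.check_against(m)
    # genes x cells on disk, the common exchange convention
    scipy.io.mmwrite(str(out / "matrix.mtx"), m.counts.T.tocoo(), field="integer")
    pd.Series(m.gene_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    ann.table[list(CellAnnotations.REQUIRED)].to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    (out / _SIDECAR).write_text(
        json.dumps({"orientation": "genes_x_cells", "conditions": ann.conditions})
    )
    return out


def read_mtx_bundle(dir_path: str | Path) -> tuple[CellMatrix, CellAnnotations]:
    """Read a matrix.mtx + features/barcodes/annotations bundle.

    The matrix is re-oriented to cells-by-genes according to the sidecar (or
    genes-by-cells is assumed when no sidecar is present). Barcodes missing
    from ``annotations.tsv`` raise :class:`IntegrityError` naming them.
    """
    d = Path(dir_path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "annotations.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(d / fname)
    try:
        mat = scipy.io.mmread(str(d / "matrix.mtx"))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"malformed Matrix Market file: {exc}") from exc
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()

    orientation = "genes_x_cells"
    conditions: list[str] = []
    sidecar = d / _SIDECAR
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        orientation = meta.get("orientation", orientation)
        conditions = meta.get("conditions", [])
    if orientation == "genes_x_cells":
        mat = mat.T
    elif orientation != "cells_x_genes":
        raise FormatError(f"unknown orientation {orientation!r}")
    counts = sp.csr_matrix(mat)
    if counts.shape != (len(cells), len(genes)):
        raise IntegrityError(
            f"matrix shape {counts.shape} does not match "
            f"{len(cells)} barcodes x {len(genes)} features"
        )

    ann_df = pd.read_csv(d / "annotations.tsv", sep="\t", dtype=str)
    missing = sorted(set(cells) - set(ann_df["cell_id"]))
    if missing:
        raise IntegrityError(
            f"{len(missing)} barcode(s) absent from annotations.tsv: {missing[:10]}"
        )
    ann_df = ann_df.set_index("cell_id").loc[list(cells)].reset_index()
    m = CellMatrix(counts=counts, gene_ids=genes, cell_ids=cells)
    ann = CellAnnotations(ann_df, conditions=conditions)
    return m, ann


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, gsc: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_lr_csv(path: str | Path) -> LRDatabase:
    """Read the LR pair table; multi-gene subunit fields are '&'-joined."""
    df = pd.read_csv(path, dtype=str)
    need = {"pair_name", "ligand_genes", "receptor_genes", "pathway"}
    if not need <= set(df.columns):
        raise FormatError(f"LR CSV missing columns: {sorted(need - set(df.columns))}")
    pairs = [
        LRPair(
            pair_name=r.pair_name,
            ligand_genes=tuple(r.ligand_genes.split("&")),
            receptor_genes=tuple(r.receptor_genes.split("&")),
            pathway=r.pathway,
        )
        for r in df.itertuples()
    ]
    return LRDatabase(pairs)


def write_lr_csv(path: str | Path, db: LRDatabase) -> None:
    rows = [
        {
            "pair_name": p.pair_name,
            "ligand_genes": "&".join(p.ligand_genes),
            "receptor_genes": "&".join(p.receptor_genes),
            "pathway": p.pathway,
        }
        for p in db.pairs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    """Read a flat YAML mapping mirroring AnalysisConfig field names."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


def write_config(path: str | Path, cfg: AnalysisConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def log_normalize(m: CellMatrix, scale_factor: float = 10_000.0) -> CellMatrix:
    """Attach the log-normalized layer ln(1 + sf * x / cell_total).

    The inverse transform expm1(lognorm) sums to ``scale_factor`` per cell, a
    property tests rely on. Cells with zero total are an error (QC filtering
    is upstream of this package), reported by cell id.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total count: {list(m.cell_ids[zero[:10]])}"
        )
    ln = m.counts.astype(np.float64).tocsr(copy=True)
    # scale each row then log1p; sparsity pattern is preserved
    row_scale = scale_factor / totals
    ln.data *= np.repeat(row_scale, np.diff(ln.indptr))
    np.log1p(ln.data, out=ln.data)
    return CellMatrix(
        counts=m.counts,
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        lognorm=ln,
        scale_factor=scale_factor,
    )


def select_hvg(m: CellMatrix, n: int) -> list[str]:
    """Highly variable genes by standardized variance (VST-style).

    A degree-2 polynomial of log10(variance) on log10(mean) is fit over genes
    with positive mean on the raw counts; counts are standardized against the
    trend-predicted standard deviation, clipped at sqrt(n_cells), and the n
    genes with the largest variance of the clipped values are returned, ties
    broken by gene_id order.
    """
    if n > m.n_genes:
        raise ValueError(f"requested {n} HVGs but matrix has {m.n_genes} genes")
    X = m.counts.tocsc().astype(np.float64)
    n_cells = m.n_cells
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)

    std_var = np.zeros(m.n_genes)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 3:
        coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=2)
        exp_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[ok])))
        clip_max = np.sqrt(n_cells)
        idx_ok = np.flatnonzero(ok)
        for j, g in enumerate(idx_ok):
            col = X.data[X.indptr[g] : X.indptr[g + 1]]
            z_nz = (col - mean[g]) / exp_sd[j]
            z0 = -mean[g] / exp_sd[j]  # z-score of the zero entries
            z_nz = np.minimum(z_nz, clip_max)
            n_zero = n_cells - col.size
            total = z_nz.sum() + n_zero * z0
            total_sq = (z_nz**2).sum() + n_zero * z0**2
            mu = total / n_cells
            std_var[g] = (total_sq - n_cells * mu**2) / max(n_cells - 1, 1)
    # stable sort on (-std_var, gene_id) -> deterministic tie-break
    order = sorted(range(m.n_genes), key=lambda g: (-std_var[g], str(m.gene_ids[g])))
    return [str(m.gene_ids[g]) for g in order[:n]]
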