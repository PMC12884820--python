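import numpy as np
import pytest
import scipy.sparse as sp

from pulpatlas.core_io import CellAnnotations, CellMatrix, log_normalize
from pulpatlas.synthetic_data import build_config, simulate_atlas


def toy_matrix(values, gene_ids=None, cell_ids=None, lognorm=False):
    """CellMatrix from a dense array; optionally treat values as the
    log-normalized layer directly (counts set to ceil(values))."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    if lognorm:
        m = CellMatrix(
            counts=sp.csr_matrix(np.ceil(values).astype(int)),
            gene_ids=gene_ids,
            cell_ids=cell_ids,
        )
        m.lognorm = sp.csr_matrix(values)
        return m
    return CellMatrix(
        counts=sp.csr_matrix(values.astype(int)), gene_ids=gene_ids, cell_ids=cell_ids
    )


def annotations(clusters, conditions=None, cell_ids=None):
    import pandas as pd

    n = len(clusters)
    conditions = conditions if conditions is not None else ["X"] * n
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    return CellAnnotations(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "cluster": clusters,
                "condition": conditions,
                "sample_id": ["s1"] * n,
            }
        )
    )


@pytest.fixture(scope="session")
def small_atlas():
    """Two-condition atlas with planted markers and one planted LR edge."""
    cfg = build_config(
        300,
        [("Healthy", 400), ("Advanced", 400)],
        4,
        markers_per_cluster=10,
        marker_log2fc=2.0,
        lr_edges=[("C01", "C02", {"Healthy": 6.0, "Advanced": 1.0}, "ECM")]
        + [("C03", "C04", {}, "Misc"), ("C02", "C03", {}, "Misc")],
        seed=7,
    )
    m, ann, gt = simulate_atlas(cfg)
    return log_normalize(m), ann, gt, cfg


@pytest.fixture(scope="session")
def null_atlas():
    """Single-condition no-signal atlas for null-behaviour checks."""
    cfg = build_config(500, [("Healthy", 500)], 5, seed=11)
    m, ann, gt = simulate_atlas(cfg)
    return log_normalize(m), ann, gt, cfg
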