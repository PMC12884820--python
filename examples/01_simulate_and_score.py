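"""Simulate a small disease-progression atlas and score gene programs.

Builds a two-condition atlas with planted cluster markers, computes the
control-binned module score and the recovery-curve AUC for each cluster's
marker program, and prints the cluster-level z-scored summaries. The planted
cluster should attain the maximum of its own program's column.
"""

from pulpatlas import build_config, fixture_gene_sets, log_normalize, simulate_atlas
from pulpatlas.scoring import cluster_score_summary, score_sets

cfg = build_config(
    n_genes=400,
    conditions=[("Healthy", 300), ("Advanced", 300)],
    n_clusters=3,
    markers_per_cluster=15,
    marker_log2fc=2.0,
    marker_base_mean=0.5,
    seed=1,
)
matrix, ann, truth = simulate_atlas(cfg)
matrix = log_normalize(matrix)  # ln(1 + 10^4 x / total)
gene_sets = fixture_gene_sets(cfg, n_decoys=2)

for method in ("module", "auc"):
    per_cell = score_sets(matrix, gene_sets, method, seed=1)
    summary = cluster_score_summary(per_cell.values, ann, zscore=True, method=method)
    print(f"\n{method} scores, z-scored across clusters (rows = clusters):")
    print(summary.values.round(2).to_string())

print(
    "\nEach '<cluster>_markers' column peaks (z > 0) in its own cluster; the"
    "\ndecoy columns carry no cluster structure, so their z-scores are noise."
)
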