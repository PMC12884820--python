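"""Ligand-receptor communication inference with a permutation null.

Plants one active edge (C01 -> C02, activity x6 in Healthy, baseline in
Advanced) among null decoy pairs, infers per-condition networks, ranks
pairs by their change in summed probability, and attaches bootstrap CIs to
the global metrics. The planted edge should be the strongest significant
edge in Healthy and the top-declining pair Healthy -> Advanced.
"""

from pulpatlas import build_config, fixture_lr_db, log_normalize, simulate_atlas
from pulpatlas.core_io import AnalysisConfig
from pulpatlas.communication import (
    bootstrap_metrics,
    infer_network,
    network_summaries,
    pair_condition_delta,
)

edges = [("C01", "C02", {"Healthy": 6.0, "Advanced": 1.0}, "ECM")]
edges += [("C03", "C04", {}, "Misc"), ("C02", "C04", {}, "Misc")]
cfg = build_config(
    n_genes=300,
    conditions=[("Healthy", 600), ("Advanced", 600)],
    n_clusters=4,
    lr_edges=edges,
    seed=3,
)
matrix, ann, truth = simulate_atlas(cfg)
matrix = log_normalize(matrix)
lrdb = fixture_lr_db(cfg)
acfg = AnalysisConfig(n_perm=100, n_boot=100, seed=3)

nets = {c: infer_network(matrix, ann, lrdb, c, acfg) for c in ("Healthy", "Advanced")}
for cond, net in nets.items():
    s = network_summaries(net)
    print(
        f"{cond}: {s.n_interactions} significant edges, "
        f"total strength {s.total_strength:.2f}"
    )
top = nets["Healthy"].significant_edges().nlargest(1, "prob").iloc[0]
print(
    f"strongest Healthy edge: {top['sender']} -> {top['receiver']} "
    f"({top['pair']}, prob={top['prob']:.3f}, p={top['p']:.3f})"
)

delta = pair_condition_delta(nets, "Healthy", "Advanced")
print("\nPairs ranked by delta (Advanced - Healthy), most decreasing first:")
print(delta.round(3).to_string(index=False))

boot = bootstrap_metrics(matrix, ann, lrdb, "Healthy", acfg)
for name, s in boot.items():
    print(f"Healthy {name}: {s.point:.2f}  95% CI [{s.ci_low:.2f}, {s.ci_high:.2f}]")
print(
    "\nThe planted pair P001 heads the declining list; CIs come from"
    "\nstratified resampling of cells with the permutation test recomputed."
)
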