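"""End-to-end orchestration of the cross-condition comparison workflow.

A run lives in a directory with a fixed layout::

    run_dir/
      run.yaml          # root seed, analysis parameters, contrasts
      inputs/           # MTX bundle + gene_sets.gmt + lr_pairs.csv (+ truth)
      scores/           # module/AUC cluster tables, specificity, tests
      de/               # per-contrast DE, volcano, enrichment tables
      comm/             # per-condition edge lists, summaries, deltas, boots
      composition/      # proportions, chi-square, Fisher, delta matrices
      report.json       # machine-readable summary + file manifest

Stages are plain functions over the run directory so the command-line
subcommands and :func:`run_pipeline` are the same code path; re-running a
stage with the same root seed reproduces its outputs exactly. All
randomness flows from the root seed through named substreams, one per
stage, so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communication as comm
from . import composition as compo
from . import de_enrichment as de
from . import scoring
from .core_io import (
    AnalysisConfig,
    CellAnnotations,
    CellMatrix,
    GeneSetCollection,
    LRDatabase,
    log_normalize,
    read_gmt,
    read_lr_csv,
    read_mtx_bundle,
    select_hvg,
    write_gmt,
    write_lr_csv,
    write_mtx_bundle,
)
from .synthetic_data import (
    demo_config,
    fixture_gene_sets,
    fixture_lr_db,
    null_config,
    simulate_atlas,
)

logger = logging.getLogger("pulpatlas")

__all__ = [
    "PipelineError",
    "ReportBundle",
    "run_pipeline",
    "stage_seed",
    "STAGES",
]

PRESETS = {
    "demo": demo_config,
    "demo-small": lambda seed: demo_config(seed, n_cells_per_condition=250, n_genes=400),
    "null": lambda seed: null_config(8, 500, 20, seed),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class ReportBundle:
    metadata: dict
    manifest: list[str]
    summary: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "manifest": self.manifest,
                "summary": self.summary,
            },
            indent=1,
            sort_keys=True,
        )


def stage_seed(root_seed: int, stage: str) -> int:
    """Named substream seed below 2**31, stable across runs."""
    return (root_seed * 2_654_435_761 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# run-directory helpers
# ---------------------------------------------------------------------------


def _run_meta(run_dir: Path) -> dict:
    return yaml.safe_load((run_dir / "run.yaml").read_text())


def _analysis_config(meta: dict) -> AnalysisConfig:
    return AnalysisConfig(**meta.get("analysis", {}), seed=meta["seed"])


def _contrasts(meta: dict, conditions: list[str]) -> list[tuple[str, str]]:
    """Condition contrasts as (later, earlier) pairs. Defaults to the
    consecutive pairs plus first-vs-last."""
    spec = meta.get("contrasts")
    if spec:
        out = []
        for s in spec:
            later, earlier = s.split(":")
            for c in (later, earlier):
                if c not in conditions:
                    raise ValueError(f"unknown condition {c!r} in contrast {s!r}")
            out.append((later, earlier))
        return out
    out = [(conditions[i + 1], conditions[i]) for i in range(len(conditions) - 1)]
    if len(conditions) > 2:
        out.append((conditions[-1], conditions[0]))
    return out


def _load_inputs(
    run_dir: Path, acfg: AnalysisConfig
) -> tuple[CellMatrix, CellAnnotations, GeneSetCollection | None, LRDatabase | None]:
    m, ann = read_mtx_bundle(run_dir / "inputs")
    m = log_normalize(m, acfg.scale_factor)
    gmt = run_dir / "inputs" / "gene_sets.gmt"
    lr = run_dir / "inputs" / "lr_pairs.csv"
    gsc = read_gmt(gmt) if gmt.exists() else None
    lrdb = read_lr_csv(lr) if lr.exists() else None
    return m, ann, gsc, lrdb


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(
    run_dir: Path,
    seed: int,
    preset: str = "demo",
    analysis: dict | None = None,
    contrasts: list[str] | None = None,
) -> list[str]:
    """Materialize a synthetic atlas bundle plus fixtures under inputs/."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg = PRESETS[preset](stage_seed(seed, "simulate"))
    m, ann, gt = simulate_atlas(cfg)
    inputs = run_dir / "inputs"
    write_mtx_bundle(inputs, m, ann)
    write_gmt(inputs / "gene_sets.gmt", fixture_gene_sets(cfg))
    write_lr_csv(inputs / "lr_pairs.csv", fixture_lr_db(cfg))
    gt.to_json(inputs / "ground_truth.json")
    meta = {
        "seed": seed,
        "preset": preset,
        "analysis": analysis or {},
        "contrasts": contrasts,
        "subtype_col": "cluster",
    }
    (run_dir / "run.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return [
        str(inputs / f)
        for f in (
            "matrix.mtx",
            "features.tsv",
            "barcodes.tsv",
            "annotations.tsv",
            "gene_sets.gmt",
            "lr_pairs.csv",
            "ground_truth.json",
        )
    ]


def stage_normalize(run_dir: Path) -> list[str]:
    """Log-normalize and export the highly-variable-gene list."""
    meta = _run_meta(run_dir)
    acfg = _analysis_config(meta)
    m, _, _, _ = _load_inputs(run_dir, acfg)
    out = run_dir / "scores"
    out.mkdir(exist_ok=True)
    hvg = select_hvg(m, min(acfg.n_hvg, m.n_genes))
    (out / "hvg.txt").write_text("\n".join(hvg) + "\n")
    return [str(out / "hvg.txt")]


def stage_score(run_dir: Path) -> list[str]:
    """Module and AUC scores per set, cluster summaries (z-scored),
    a specificity contrast between the first two sets, and condition tests."""
    meta = _run_meta(run_dir)
    acfg = _analysis_config(meta)
    m, ann, gsc, _ = _load_inputs(run_dir, acfg)
    if gsc is None:
        raise ValueError("inputs/gene_sets.gmt is required for scoring")
    out = run_dir / "scores"
    out.mkdir(exist_ok=True)
    seed = stage_seed(acfg.seed, "score")
    files = []
    per_cell = {}
    for method in ("module", "auc"):
        tbl = scoring.score_sets(
            m, gsc, method, auc_threshold=acfg.auc_threshold, seed=seed
        )
        per_cell[method] = tbl.values
        summary = scoring.cluster_score_summary(
            tbl.values, ann, zscore=True, method=method
        )
        path = out / f"cluster_{method}_z.tsv"
        summary.values.to_csv(path, sep="\t")
        files.append(str(path))
    names = gsc.names()
    if len(names) >= 2:
        spec = scoring.specificity_contrast(
            m,
            ann,
            gsc[names[0]],
            gsc[names[1]],
            contrast_name=f"{names[0]}_vs_{names[1]}",
            seed=seed,
        )
        path = out / "specificity.tsv"
        spec.table.to_csv(path, sep="\t", index=False)
        files.append(str(path))
    tests = scoring.score_condition_test(per_cell["module"], ann)
    path = out / "condition_tests.tsv"
    tests.to_csv(path, sep="\t", index=False)
    files.append(str(path))
    return files


def stage_de(run_dir: Path) -> list[str]:
    """Wilcoxon DE + volcano table per condition contrast."""
    meta = _run_meta(run_dir)
    acfg = _analysis_config(meta)
    m, ann, _, _ = _load_inputs(run_dir, acfg)
    contrasts = _contrasts(meta, ann.conditions)
    out = run_dir / "de"
    out.mkdir(exist_ok=True)
    files = []
    for later, earlier in contrasts:
        res = de.wilcoxon_de_groups(
            m,
            ann,
            group_a={"condition": later},
            group_b={"condition": earlier},
            lfc_threshold=acfg.lfc_threshold,
            min_frac=acfg.min_frac,
        )
        tag = f"{later}_vs_{earlier}"
        p1 = out / f"de_{tag}.tsv"
        res.table.to_csv(p1, sep="\t", index=False)
        p2 = out / f"volcano_{tag}.tsv"
        de.volcano_table(res.all_results, acfg.alpha).to_csv(p2, sep="\t", index=False)
        files += [str(p1), str(p2)]
    return files


def stage_enrich(run_dir: Path) -> list[str]:
    """Hypergeometric ORA of each contrast's significant up-genes."""
    meta = _run_meta(run_dir)
    acfg = _analysis_config(meta)
    m, ann, gsc, _ = _load_inputs(run_dir, acfg)
    if gsc is None:
        raise ValueError("inputs/gene_sets.gmt is required for enrichment")
    contrasts = _contrasts(meta, ann.conditions)
    out = run_dir / "de"
    out.mkdir(exist_ok=True)
    universe = [str(g) for g in m.gene_ids]
    files = []
    for later, earlier in contrasts:
        tag = f"{later}_vs_{earlier}"
        de_path = out / f"de_{tag}.tsv"
        if not de_path.exists():
            raise FileNotFoundError(f"run the de stage first: {de_path}")
        tbl = pd.read_csv(de_path, sep="\t")
        up = tbl[(tbl["direction"] == "up") & (tbl["p_adj"] < acfg.alpha)][
            "gene"
        ].tolist()
        enr = de.ora(up, universe, gsc) if up else de.EnrichmentTable(
            table=pd.DataFrame(
                columns=["set", "count", "gene_ratio", "bg_ratio", "p", "p_adj", "overlap"]
            )
        )
        path = out / f"enrichment_{tag}.tsv"
        enr.table.to_csv(path, sep="\t", index=False)
        files.append(str(path))
    return files


def stage_communicate(run_dir: Path) -> list[str]:
    """Per-condition network inference: edge lists + summary JSON."""
    meta = _run_meta(run_dir)
    acfg = _analysis_config(meta)
    m, ann, _, lrdb = _load_inputs(run_dir, acfg)
    if lrdb is None:
        raise ValueError("inputs/lr_pairs.csv is required for communication")
    out = run_dir / "comm"
    out.mkdir(exist_ok=True)
    files = []
    for cond in ann.conditions:
        net = comm.infer_network(
            m, ann, lrdb, cond, acfg, seed=stage_seed(acfg.seed, f"communicate:{cond}")
        )
        path = out / f"edges_{cond}.tsv"
        net.edges.to_csv(path, sep="\t", index=False)
        s = comm.network_summaries(net)
        summary = {
            "condition": cond,
            "clusters": net.clusters,
            "n_interactions": s.n_interactions,
            "total_strength": s.total_strength,
            "pathway_strength": {k: float(v) for k, v in s.pathway_strength.items()},
        }
        spath = out / f"summary_{cond}.json"
        spath.write_text(json.dumps(summary, indent=1, sort_keys=True))
        cpath = out / f"counts_{cond}.csv"
        net.counts.to_csv(cpath)
        files += [str(path), str(spath), str(cpath)]
    return files


def _read_network(run_dir: Path, cond: str) -> comm.CommNetwork:
    path = run_dir / "comm" / f"edges_{cond}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"run the communicate stage first: {path}")
    edges = pd.read_csv(path, sep="\t")
    clusters = sorted(set(edges["sender"]) | set(edges["receiver"]))
    return comm.CommNetwork(condition=cond, clusters=clusters, edges=edges)


def stage_delta(run_dir: Path) -> list[str]:
    """Cross-condition delta tables and matrices from stored edge lists."""
    meta = _run_meta(run_dir)
    _, ann = read_mtx_bundle(run_dir / "inputs")
    contrasts = _contrasts(meta, ann.conditions)
    nets = {c: _read_network(run_dir, c) for c in ann.conditions}
    out = run_dir / "comm"
    files = []
    for later, earlier in contrasts:
        tag = f"{later}_vs_{earlier}"
        d = comm.pair_condition_delta(nets, earlier, later, mode="pair")
        p1 = out / f"delta_pairs_{tag}.tsv"
        d.to_csv(p1, sep="\t", index=False)
        dmat, nodes = comm.delta_network(nets[earlier], nets[later])
        p2 = out / f"delta_strength_{tag}.csv"
        dmat.to_csv(p2)
        p3 = out / f"delta_nodes_{tag}.tsv"
        nodes.to_csv(p3, sep="\t", index=False)
        files += [str(p1), str(p2), str(p3)]
    return files


def stage_bootstrap(run_dir: Path) -> list[str]:
    """Bootstrap CIs for the global network metrics, per condition."""
    meta = _run_meta(run_dir)
    acfg = _analysis_config(meta)
    m, ann, _, lrdb = _load_inputs(run_dir, acfg)
    if lrdb is None:
        raise ValueError("inputs/lr_pairs.csv is required for bootstrap")
    out = run_dir / "comm"
    out.mkdir(exist_ok=True)
    rows = []
    for cond in ann.conditions:
        res = comm.bootstrap_metrics(
            m, ann, lrdb, cond, acfg, seed=stage_seed(acfg.seed, f"bootstrap:{cond}")
        )
        for metric, s in res.items():
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "point": s.point,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "n_boot": s.n_boot,
                }
            )
    path = out / "bootstrap.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [str(path)]


def stage_compose(run_dir: Path) -> list[str]:
    """Composition suite: proportions + Wald CIs, chi-square, pairwise
    Fisher, delta-proportion matrices."""
    meta = _run_meta(run_dir)
    _, ann = read_mtx_bundle(run_dir / "inputs")
    contrasts = _contrasts(meta, ann.conditions)
    out = run_dir / "composition"
    out.mkdir(exist_ok=True)
    tab = compo.proportion_wald_ci(compo.count_table(ann, meta.get("subtype_col", "cluster")))
    files = []
    p = out / "proportions.tsv"
    merged = pd.concat(
        {
            "count": tab.counts,
            "proportion": tab.proportions,
            "ci_low": tab.ci_low,
            "ci_high": tab.ci_high,
        },
        axis=1,
    )
    merged.to_csv(p, sep="\t")
    files.append(str(p))
    stat, dof, pval = compo.overall_chisq(tab)
    (out / "chisq.json").write_text(
        json.dumps({"statistic": stat, "df": dof, "p": pval})
    )
    files.append(str(out / "chisq.json"))
    fisher = compo.pairwise_fisher(tab, contrasts)
    p = out / "fisher.tsv"
    fisher.table.to_csv(p, sep="\t", index=False)
    files.append(str(p))
    for later, earlier in contrasts:
        d = compo.delta_proportion(tab, (later, earlier), fisher)
        p = out / f"delta_proportion_{later}_vs_{earlier}.csv"
        d.to_csv(p, index=False)
        files.append(str(p))
    return files


def stage_report(run_dir: Path, manifest: list[str] | None = None) -> ReportBundle:
    """Aggregate stage outputs into report.json."""
    meta = _run_meta(run_dir)
    _, ann = read_mtx_bundle(run_dir / "inputs")
    contrasts = _contrasts(meta, ann.conditions)
    summary: dict = {"conditions": ann.conditions, "networks": {}, "top_delta": {}}
    for cond in ann.conditions:
        spath = run_dir / "comm" / f"summary_{cond}.json"
        if spath.exists():
            summary["networks"][cond] = json.loads(spath.read_text())
    for later, earlier in contrasts:
        tag = f"{later}_vs_{earlier}"
        dpath = run_dir / "comm" / f"delta_pairs_{tag}.tsv"
        if dpath.exists():
            d = pd.read_csv(dpath, sep="\t")
            summary["top_delta"][tag] = {
                "decreasing": d.head(5).to_dict(orient="records"),
                "increasing": d.tail(5).iloc[::-1].to_dict(orient="records"),
            }
    chisq = run_dir / "composition" / "chisq.json"
    if chisq.exists():
        summary["composition_chisq"] = json.loads(chisq.read_text())
    fisher = run_dir / "composition" / "fisher.tsv"
    if fisher.exists():
        ft = pd.read_csv(fisher, sep="\t", keep_default_na=False)
        summary["composition_fisher"] = ft[
            ["subtype", "contrast", "odds_ratio", "p_adj", "stars"]
        ].to_dict(orient="records")
    boot = run_dir / "comm" / "bootstrap.tsv"
    if boot.exists():
        summary["bootstrap"] = pd.read_csv(boot, sep="\t").to_dict(orient="records")
    if manifest is None:
        manifest = sorted(
            str(p)
            for p in run_dir.rglob("*")
            if p.is_file() and p.name != "report.json"
        )
    import pulpatlas

    bundle = ReportBundle(
        metadata={
            "seed": meta["seed"],
            "preset": meta.get("preset"),
            "analysis": meta.get("analysis", {}),
            "contrasts": [f"{a}_vs_{b}" for a, b in contrasts],
            "version": pulpatlas.__version__,
        },
        manifest=manifest,
        summary=summary,
    )
    (run_dir / "report.json").write_text(bundle.to_json())
    return bundle


STAGES = {
    "normalize": stage_normalize,
    "score": stage_score,
    "de": stage_de,
    "enrich": stage_enrich,
    "communicate": stage_communicate,
    "delta": stage_delta,
    "bootstrap": stage_bootstrap,
    "compose": stage_compose,
}


def run_pipeline(cfg_path: str | Path | dict, out_dir: str | Path) -> ReportBundle:
    """Execute the full workflow from a flat YAML config (or dict).

    Config keys: ``seed`` (root seed), ``preset`` or ``bundle`` (data
    source), ``analysis`` (AnalysisConfig overrides), ``contrasts``
    (["Later:Earlier", ...]), ``subtype_col``. Any stage error aborts with
    the stage name; partial outputs stay behind next to a FAILED marker.
    """
    cfg = (
        dict(cfg_path)
        if isinstance(cfg_path, dict)
        else yaml.safe_load(Path(cfg_path).read_text())
    )
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: list[str] = []

    def run_stage(name, fn, *args, **kw):
        t0 = time.time()
        try:
            result = fn(*args, **kw)
        except Exception as exc:
            (run_dir / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
        return result

    if "bundle" in cfg:
        inputs = run_dir / "inputs"
        if not inputs.exists():
            import shutil

            shutil.copytree(cfg["bundle"], inputs)
        (run_dir / "run.yaml").write_text(
            yaml.safe_dump(
                {
                    "seed": seed,
                    "preset": None,
                    "analysis": cfg.get("analysis", {}),
                    "contrasts": cfg.get("contrasts"),
                    "subtype_col": cfg.get("subtype_col", "cluster"),
                },
                sort_keys=False,
            )
        )
        manifest += sorted(str(p) for p in inputs.rglob("*") if p.is_file())
    else:
        manifest += run_stage(
            "simulate",
            stage_simulate,
            run_dir,
            seed,
            cfg.get("preset", "demo"),
            cfg.get("analysis", {}),
            cfg.get("contrasts"),
        )
    for name, fn in STAGES.items():
        manifest += run_stage(name, fn, run_dir)
    bundle = run_stage("report", stage_report, run_dir, manifest)
    if (run_dir / "FAILED").exists():
        (run_dir / "FAILED").unlink()
    return bundle
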