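import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulpatlas.core_io import GeneSetCollection, log_normalize
from pulpatlas.scoring import (
    auc_score,
    cluster_score_summary,
    module_score,
    program_correlation,
    score_condition_test,
    score_sets,
    specificity_contrast,
)
from pulpatlas.synthetic_data import (
    build_config,
    fixture_gene_sets,
    simulate_atlas,
)

from conftest import annotations, toy_matrix


class TestAucScore:
    def test_hand_worked_recovery_curve(self):
        # G=10, K=3, set at descending ranks 2 and 4 -> hits (0,1,1), AUC 0.4
        m = toy_matrix([[10, 9, 8, 7, 6, 5, 4, 3, 2, 1]], lognorm=True)
        assert auc_score(m, ["g1", "g3"], threshold=0.3).iloc[0] == pytest.approx(0.4)

    def test_maximal_and_empty_recovery(self):
        m = toy_matrix([[10, 9, 8, 7, 6, 5, 4, 3, 2, 1]], lognorm=True)
        assert auc_score(m, ["g0", "g1"], threshold=0.3).iloc[0] == 1.0
        assert auc_score(m, ["g8", "g9"], threshold=0.3).iloc[0] == 0.0

    def test_bounded_and_tie_stable(self, small_atlas):
        m, _, gt, _ = small_atlas
        s = auc_score(m, gt.planted_markers["C01"], threshold=0.05)
        assert (s >= 0).all() and (s <= 1).all()
        pd.testing.assert_series_equal(
            s, auc_score(m, gt.planted_markers["C01"], threshold=0.05)
        )

    def test_promoting_a_set_gene_never_decreases_auc(self):
        rng = np.random.default_rng(5)
        base = rng.random((1, 20))
        m = toy_matrix(base, lognorm=True)
        s0 = auc_score(m, ["g7", "g11"], threshold=0.25).iloc[0]
        promoted = base.copy()
        promoted[0, 7] = base.max() + 1.0  # g7 to rank 1
        s1 = auc_score(toy_matrix(promoted, lognorm=True), ["g7", "g11"], 0.25).iloc[0]
        assert s1 >= s0

    def test_empty_intersection_rejected(self, small_atlas):
        m, _, _, _ = small_atlas
        with pytest.raises(KeyError):
            auc_score(m, ["NOPE1", "NOPE2"])


class TestModuleScore:
    def test_decoy_sets_have_near_zero_grand_mean(self, null_atlas):
        m, _, _, cfg = null_atlas
        rng = np.random.default_rng(0)
        means = []
        for i in range(100):
            decoy = list(rng.choice(m.gene_ids, size=15, replace=False))
            means.append(module_score(m, decoy, seed=1).mean())
        assert abs(np.mean(means)) < 0.05

    def test_marker_cluster_scores_highest(self, small_atlas):
        m, ann, gt, _ = small_atlas
        s = module_score(m, gt.planted_markers["C01"], seed=2)
        by_cluster = s.groupby(ann.cluster).mean()
        assert by_cluster.idxmax() == "C01"
        assert (by_cluster.drop("C01") < by_cluster["C01"]).all()

    def test_missing_genes_warn_but_all_missing_errors(self, small_atlas):
        m, _, gt, _ = small_atlas
        genes = gt.planted_markers["C01"]
        with pytest.warns(UserWarning, match="absent"):
            module_score(m, genes + ["NOPE"], seed=0)
        with pytest.raises(KeyError):
            module_score(m, ["NOPE"], seed=0)

    def test_deterministic_given_seed(self, small_atlas):
        m, _, gt, _ = small_atlas
        a = module_score(m, gt.planted_markers["C02"], seed=5)
        b = module_score(m, gt.planted_markers["C02"], seed=5)
        pd.testing.assert_series_equal(a, b)


class TestClusterSummary:
    def test_zscore_rules(self):
        m = toy_matrix(np.tile([[1.0, 2.0]], (6, 1)), lognorm=True)
        ann = annotations(["A", "A", "A", "B", "B", "B"])
        scores = pd.DataFrame(
            {"flat": np.ones(6), "split": [1, 1, 1, 5, 5, 5]},
            index=m.cell_ids,
        )
        out = cluster_score_summary(scores, ann, zscore=True).values
        assert (out["flat"] == 0).all()  # sd-0 column rule
        assert out["split"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["split"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_planted_set_attains_column_maximum(self, small_atlas):
        m, ann, gt, cfg = small_atlas
        gsc = fixture_gene_sets(cfg)
        tbl = score_sets(m, gsc, "module", seed=3)
        summary = cluster_score_summary(tbl.values, ann, zscore=True).values
        for cl in gt.planted_markers:
            assert summary[f"{cl}_markers"].idxmax() == cl


class TestSpecificity:
    def test_identical_sets_contrast_zero_with_warning(self, small_atlas):
        m, ann, gt, _ = small_atlas
        genes = gt.planted_markers["C01"]
        with pytest.warns(UserWarning, match="identical"):
            out = specificity_contrast(m, ann, genes, list(genes), seed=1)
        assert np.allclose(out.table["score"], 0.0)

    def test_antisymmetry_exact(self, small_atlas):
        m, ann, gt, _ = small_atlas
        a = gt.planted_markers["C01"]
        b = gt.planted_markers["C02"]
        fwd = specificity_contrast(m, ann, a, b, seed=4).table["score"].to_numpy()
        rev = specificity_contrast(m, ann, b, a, seed=4).table["score"].to_numpy()
        np.testing.assert_array_equal(fwd, -rev)

    def test_planted_programs_separate(self, small_atlas):
        m, ann, gt, _ = small_atlas
        out = specificity_contrast(
            m, ann, gt.planted_markers["C01"], gt.planted_markers["C02"], seed=4
        ).table.set_index("cluster")["score"]
        assert out["C01"] > 0 > out["C02"]


class TestProgramCorrelation:
    def test_self_correlation_diagonal_one(self, small_atlas):
        m, ann, _, _ = small_atlas
        pc = program_correlation(m, ann, m, ann, n_genes=100)
        np.testing.assert_allclose(np.diag(pc.r.to_numpy()), 1.0, atol=1e-12)

    def test_negated_profile_gives_minus_one(self):
        # identical labels; second matrix reflects every value around a
        # scalar, so each cluster-mean profile is an affine negation
        rng = np.random.default_rng(8)
        base = rng.random((120, 80)) + 0.5
        mA = toy_matrix(base, lognorm=True)
        mB = toy_matrix(3.0 - base, lognorm=True)
        ann = annotations(list(np.repeat(["A", "B", "C"], 40)))
        pc = program_correlation(mA, ann, mB, ann, n_genes=60)
        np.testing.assert_allclose(np.diag(pc.r.to_numpy()), -1.0, atol=1e-12)

    def test_shared_programs_matched_by_argmax(self):
        cfgs = [
            build_config(
                600,
                [("Healthy", 600)],
                4,
                markers_per_cluster=15,
                marker_log2fc=2.0,
                marker_base_mean=0.5,
                seed=s,
            )
            for s in (41, 42)
        ]
        sims = [simulate_atlas(c) for c in cfgs]
        (mA, aA, _), (mB, aB, _) = sims
        pc = program_correlation(
            log_normalize(mA), aA, log_normalize(mB), aB, n_genes=100
        )
        rows = pc.r.to_numpy()
        match = (np.argmax(rows, axis=1) == np.arange(rows.shape[0])).mean()
        assert match >= 0.9

    def test_insufficient_shared_genes_rejected(self):
        mA = toy_matrix(np.random.default_rng(0).random((30, 60)), lognorm=True)
        mB = toy_matrix(
            np.random.default_rng(1).random((30, 60)),
            gene_ids=[f"other{i}" for i in range(60)],
            lognorm=True,
        )
        ann = annotations(["A"] * 15 + ["B"] * 15)
        with pytest.raises(ValueError, match="shared"):
            program_correlation(mA, ann, mB, ann, n_genes=50)


class TestConditionTests:
    def test_constant_scores_give_h_zero_p_one(self):
        scores = pd.Series(np.ones(40), index=[f"c{i}" for i in range(40)])
        ann = annotations(["A"] * 40, conditions=["X"] * 20 + ["Y"] * 20)
        out = score_condition_test(scores, ann)
        assert out["kw_H"].iloc[0] == 0.0
        assert out["kw_p"].iloc[0] == 1.0

    def test_two_condition_kw_equals_squared_wilcoxon(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.normal(size=200), index=[f"c{i}" for i in range(200)])
        ann = annotations(
            ["A"] * 200,
            conditions=["X"] * 100 + ["Y"] * 100,
            cell_ids=list(scores.index),
        )
        out = score_condition_test(scores, ann)
        assert out["kw_p"].iloc[0] == pytest.approx(
            out["wilcoxon_p"].iloc[0], abs=1e-6
        )

    def test_planted_condition_shift_detected(self):
        # one lognorm-unit shift between conditions, 300 cells each
        rng = np.random.default_rng(10)
        low = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            s = np.concatenate([r.normal(0, 1, 300), r.normal(1, 1, 300)])
            ann = annotations(
                ["A"] * 600, conditions=["X"] * 300 + ["Y"] * 300
            )
            out = score_condition_test(
                pd.Series(s, index=[f"c{i}" for i in range(600)]), ann
            )
            low += out["kw_p"].iloc[0] < 1e-6
        assert low == 20

    def test_tiny_condition_excluded_with_warning(self):
        scores = pd.Series(
            np.arange(41, dtype=float), index=[f"c{i}" for i in range(41)]
        )
        ann = annotations(
            ["A"] * 41, conditions=["X"] * 20 + ["Y"] * 20 + ["Z"]
        )
        with pytest.warns(UserWarning, match="Z"):
            out = score_condition_test(scores, ann)
        assert set(p.split("_vs_")[0] for p in out["pair"]) <= {"X", "Y"}
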