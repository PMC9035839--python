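import numpy as np
import pytest

from nnan.attention_predictor import PredictorNet, Model, TrainConfig
from nnan.core_data import BipartiteAssociations
from nnan.evaluation import (
    PipelineConfig,
    auprc,
    auroc,
    embedding_profiles,
    feature_importance,
    make_cv_plan,
    neighbor_check,
    rank_candidates,
    run_cv,
    run_round,
    top_l_experiment,
)
from nnan.drug_similarity import fingerprint_similarity_matrix
from ._oracles import auprc_step_integration, auroc_pair_counting


class TestMakeCVPlan:
    def _assoc(self, m, n, edges):
        return BipartiteAssociations(
            [f"d{i}" for i in range(m)], [f"m{i}" for i in range(n)], set(edges)
        )

    def test_ten_positives_split_two_each(self):
        edges = {(i, 0) for i in range(10)}
        plan = make_cv_plan(self._assoc(10, 2, edges), seed=0)
        assert [len(f) for f in plan.positive_folds] == [2, 2, 2, 2, 2]

    def test_folds_partition_samples(self, small_synth):
        plan = make_cv_plan(small_synth.assoc, seed=3)
        all_pos = [p for f in plan.positive_folds for p in f]
        all_neg = [p for f in plan.negative_folds for p in f]
        assert sorted(all_pos) == sorted(small_synth.assoc.edges)
        assert sorted(all_neg) == sorted(small_synth.assoc.negatives())
        assert len(set(all_pos)) == len(all_pos)
        assert len(set(all_neg)) == len(all_neg)

    def test_negative_ratio_all_on_toy(self):
        # 3x2 universe with 2 positives -> 4 negatives total across folds
        plan = make_cv_plan(
            self._assoc(3, 2, {(0, 0), (1, 1)}),
            negative_ratio="all",
            seed=0,
            n_folds=2,
        )
        assert sum(len(f) for f in plan.negative_folds) == 4

    def test_too_few_positives(self):
        with pytest.raises(ValueError):
            make_cv_plan(self._assoc(3, 2, {(0, 0)}), n_folds=5)

    def test_plan_invariant_to_edge_insertion_order(self, small_synth):
        a = make_cv_plan(small_synth.assoc, seed=1)
        reordered = BipartiteAssociations(
            small_synth.assoc.drug_ids,
            small_synth.assoc.microbe_ids,
            set(reversed(sorted(small_synth.assoc.edges))),
        )
        b = make_cv_plan(reordered, seed=1)
        assert a.positive_folds == b.positive_folds
        assert a.negative_folds == b.negative_folds


class TestMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_reversed_scores(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_hand_case_six_samples(self):
        scores = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
        labels = [1, 0, 1, 1, 0, 0]
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels), abs=0
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [0, 0])

    def test_matches_brute_force_on_random_cases(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 51))
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties
            scores = np.round(rng.random(n), 1)
            assert auroc(scores, labels) == pytest.approx(
                auroc_pair_counting(scores, labels), abs=1e-12
            )
            assert auprc(scores, labels) == pytest.approx(
                auprc_step_integration(scores, labels), abs=1e-12
            )


class TestProfiles:
    def test_all_zero_embedding(self):
        pos, unl = embedding_profiles(np.zeros((4, 3)), [1, 0, 1, 0])
        assert np.all(pos == 0) and np.all(unl == 0)

    def test_single_positive_row(self):
        E = np.array([[0.1, 0.2], [0.5, 0.6], [0.7, 0.8]])
        pos, unl = embedding_profiles(E, [1, 0, 0])
        assert np.array_equal(pos, E[0])
        assert np.array_equal(unl, E[1:].mean(axis=0))

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            embedding_profiles(np.zeros((2, 2)), [1, 1])


class TestFeatureImportance:
    def test_constant_matrix(self):
        assert np.allclose(feature_importance(np.full((5, 3), 0.7)), 0.7)

    def test_single_row(self):
        row = np.array([[0.1, 0.9, 0.4]])
        assert np.array_equal(feature_importance(row), row[0])

    def test_hand_mean(self):
        M = np.array([[0.0, 0.4, 1.0, 0.2], [1.0, 0.6, 0.0, 0.2], [0.5, 0.5, 0.5, 0.2]])
        assert feature_importance(M).tolist() == [0.5, 0.5, 0.5, pytest.approx(0.2)]


class TestPipeline:
    def test_run_cv_reports_sane_metrics(
        self, small_synth, small_synth_sims, fast_pipeline_config
    ):
        dsim, msim = small_synth_sims
        rep = run_cv(dsim, msim, small_synth.assoc, fast_pipeline_config)
        assert len(rep.fold_auroc) == 5
        assert all(0 <= v <= 1 for v in rep.fold_auroc + rep.fold_auprc)
        assert rep.mean_auroc > 0.7  # planted structure is learnable
        assert 0 <= rep.pooled_auroc <= 1

    def test_round_ignores_association_table_edges(
        self, small_synth, small_synth_sims, fast_pipeline_config
    ):
        """Structure comes from the explicit training positives only."""
        dsim, msim = small_synth_sims
        plan = make_cv_plan(small_synth.assoc, seed=0)
        tr_p, tr_y, te_p, te_y = plan.round_inputs(0)
        pruned = BipartiteAssociations(
            small_synth.assoc.drug_ids,
            small_synth.assoc.microbe_ids,
            small_synth.assoc.edges - set(plan.positive_folds[0]),
        )
        r1 = run_round(
            dsim, msim, small_synth.assoc, tr_p, tr_y, te_p, te_y,
            fast_pipeline_config,
        )
        r2 = run_round(
            dsim, msim, pruned, tr_p, tr_y, te_p, te_y, fast_pipeline_config
        )
        assert r1.auroc == r2.auroc and r1.auprc == r2.auprc

    def test_top_l_full_length_equals_unmasked(
        self, small_synth, small_synth_sims, fast_pipeline_config
    ):
        dsim, msim = small_synth_sims
        full = max(small_synth.assoc.n_drugs, small_synth.assoc.n_microbes)
        curve = top_l_experiment(
            [full], dsim, msim, small_synth.assoc, fast_pipeline_config
        )
        rep = run_cv(dsim, msim, small_synth.assoc, fast_pipeline_config)
        assert curve[0][1] == pytest.approx(rep.mean_auroc, abs=1e-12)

    def test_top_l_clamps_oversized_l(
        self, small_synth, small_synth_sims, fast_pipeline_config, caplog
    ):
        dsim, msim = small_synth_sims
        full = max(small_synth.assoc.n_drugs, small_synth.assoc.n_microbes)
        with caplog.at_level("WARNING", logger="nnan"):
            curve = top_l_experiment(
                [full + 100], dsim, msim, small_synth.assoc, fast_pipeline_config
            )
        assert curve[0][0] == full
        assert any("clamped" in r.message for r in caplog.records)


class TestNeighborCheck:
    def _setup(self):
        bits = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0, 0],
                [1, 1, 1, 1, 0, 0],
                [0, 0, 0, 0, 1, 1],
            ],
            dtype=np.uint8,
        )
        sim = fingerprint_similarity_matrix(["d0", "d1", "d2", "d3"], bits)
        return sim

    def test_no_other_associated_drugs(self):
        sim = self._setup()
        assoc = BipartiteAssociations(
            ["d0", "d1", "d2", "d3"], ["m0"], edges={(0, 0)}
        )
        table, flagged = neighbor_check("d0", "m0", 3, sim, assoc)
        assert flagged == 0
        assert len(table) == 3

    def test_all_top_neighbors_associated(self):
        sim = self._setup()
        assoc = BipartiteAssociations(
            ["d0", "d1", "d2", "d3"], ["m0"],
            edges={(0, 0), (1, 0), (2, 0), (3, 0)},
        )
        _, flagged = neighbor_check("d0", "m0", 3, sim, assoc)
        assert flagged == 3

    def test_table_sorted_by_similarity(self):
        sim = self._setup()
        assoc = BipartiteAssociations(["d0", "d1", "d2", "d3"], ["m0"], {(0, 0)})
        table, _ = neighbor_check("d0", "m0", 3, sim, assoc)
        sims = [row[2] for row in table]
        assert sims == sorted(sims, reverse=True)

    def test_unknown_ids(self):
        sim = self._setup()
        assoc = BipartiteAssociations(["d0", "d1", "d2", "d3"], ["m0"], {(0, 0)})
        with pytest.raises(KeyError):
            neighbor_check("dX", "m0", 3, sim, assoc)
        with pytest.raises(KeyError):
            neighbor_check("d0", "mX", 3, sim, assoc)


class TestRankCandidates:
    def _constant_model(self, g):
        net = PredictorNet(
            W1=np.zeros((g, 4)), b1=np.zeros(4), W2=np.zeros((4, 2)), b2=np.zeros(2)
        )
        return Model(attention=None, predictor=net, config=TrainConfig())

    def test_tie_break_by_drug_id(self, small_synth, small_synth_sims):
        dsim, msim = small_synth_sims
        g = small_synth.assoc.n_drugs + small_synth.assoc.n_microbes
        model = self._constant_model(g)
        ranked = rank_candidates(
            small_synth.microbe_ids[0], model, dsim, msim, small_synth.assoc,
            exclude_known=False,
        )
        assert [r[0] for r in ranked] == sorted(small_synth.assoc.drug_ids)
        assert all(s == 0.5 for _, s in ranked)

    def test_exclude_known_removes_degree_entries(
        self, small_synth, small_synth_sims
    ):
        dsim, msim = small_synth_sims
        g = small_synth.assoc.n_drugs + small_synth.assoc.n_microbes
        model = self._constant_model(g)
        b = 0
        deg = len(small_synth.assoc.drugs_of_microbe(b))
        ranked = rank_candidates(
            small_synth.microbe_ids[b], model, dsim, msim, small_synth.assoc,
            exclude_known=True,
        )
        assert len(ranked) == small_synth.assoc.n_drugs - deg

    def test_unknown_microbe(self, small_synth, small_synth_sims):
        dsim, msim = small_synth_sims
        model = self._constant_model(
            small_synth.assoc.n_drugs + small_synth.assoc.n_microbes
        )
        with pytest.raises(KeyError):
            rank_candidates("nope", model, dsim, msim, small_synth.assoc)
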