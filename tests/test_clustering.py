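import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igsa import (
    GeneSetScoreMatrix,
    PhenotypeTable,
    SegmentationConfig,
    SimilarityConfig,
    accumulate_cluster,
    baseline_similarity,
    count_signs,
    double_cluster,
    make_start_seed,
    segment_trace,
    simulate_trace,
    smic,
)
from igsa.clustering import ClusteringResult
from oracles import greedy_order_literal, smic_grid_max, smic_mle_scalar

MLE = SimilarityConfig("smic_mle")

sign_vectors = st.lists(st.sampled_from([-1.0, 0.0, 1.0]), min_size=1, max_size=40)


class TestCountSigns:
    def test_mixed_signs(self):
        u = np.array([1.0, 1.0, -1.0, -1.0, 1.0])
        v = np.array([1.0, -1.0, -1.0, 1.0, 1.0])
        pair = count_signs(u, v)
        assert (pair.n_cgs, pair.n_dgs, pair.n_tied) == (3, 2, 0)

    def test_identical_nonzero_vectors_all_cgs(self):
        u = np.array([0.5, -0.2, 1.0])
        pair = count_signs(u, u)
        assert (pair.n_cgs, pair.n_dgs, pair.n_tied) == (3, 0, 0)

    def test_zero_vector_all_tied(self):
        pair = count_signs(np.array([1.0, -1.0, 2.0]), np.zeros(3))
        assert (pair.n_cgs, pair.n_dgs, pair.n_tied) == (0, 0, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_signs(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=100)
    @given(u=sign_vectors)
    def test_counts_partition_length(self, u):
        v = list(reversed(u))
        pair = count_signs(np.array(u), np.array(v))
        assert pair.n_cgs + pair.n_dgs + pair.n_tied == len(u)


class TestSmic:
    def test_fixed_theta_hand_value(self):
        u = np.array([1.0, 1.0, 1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, 1.0, -1.0, 1.0])  # 3 CGS, 2 DGS
        cfg = SimilarityConfig("smic_fixed", theta=0.8)
        assert smic(u, v, cfg) == pytest.approx(3 * 0.8 + 2 * 0.2)

    def test_identical_vectors_score_full_length(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        assert smic(u, u, MLE) == 4.0

    def test_opposite_vectors_score_half_length(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        assert smic(u, -u, MLE) == 2.0

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            SimilarityConfig("smic_fixed", theta=0.3)

    @settings(deadline=None, max_examples=200)
    @given(u=sign_vectors, seed=st.integers(0, 10_000))
    def test_mle_matches_grid_max_symmetric_and_bounded(self, u, seed):
        rng = np.random.default_rng(seed)
        v = rng.choice([-1.0, 0.0, 1.0], size=len(u))
        u = np.array(u)
        pair = count_signs(u, v)
        value = smic(u, v, MLE)
        assert value == pytest.approx(smic_grid_max(pair.n_cgs, pair.n_dgs), abs=1e-9)
        assert smic(v, u, MLE) == value
        assert 0.0 <= value <= len(u)
        assert (value == len(u)) == (pair.n_cgs == len(u))

    @settings(deadline=None, max_examples=100)
    @given(u=sign_vectors)
    def test_flipping_dgs_to_cgs_never_decreases(self, u):
        u = np.array(u)
        v = -u  # every nonzero position is DGS
        base = smic(u, v, MLE)
        for k in range(len(u)):
            if u[k] != 0:
                w = v.copy()
                w[k] = u[k]  # one DGS becomes CGS
                assert smic(u, w, MLE) >= base
                break


class TestBaselineSimilarity:
    def test_identical_vectors(self):
        u = np.array([0.0, 1.0, 2.0])
        assert baseline_similarity(u, u, SimilarityConfig("euclidean")) == 0.0
        assert baseline_similarity(u, u, SimilarityConfig("pearson")) == pytest.approx(1.0)

    def test_negated_vector_pearson(self):
        u = np.array([0.0, 1.0, 2.0])
        assert baseline_similarity(u, -u, SimilarityConfig("pearson")) == pytest.approx(-1.0)

    def test_monotone_transform_spearman(self):
        u = np.array([0.0, 1.0, 2.0])
        v = np.array([0.0, 2.0, 4.0])
        assert baseline_similarity(u, v, SimilarityConfig("spearman")) == pytest.approx(1.0)

    def test_zero_variance_returns_zero_with_warning(self, caplog):
        u = np.ones(4)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert baseline_similarity(u, v, SimilarityConfig("pearson")) == 0.0

    def test_euclidean_is_negated_distance(self):
        u = np.array([0.0, 3.0])
        v = np.array([4.0, 0.0])
        assert baseline_similarity(u, v, SimilarityConfig("euclidean")) == -5.0


class TestMakeStartSeed:
    def _scores(self, values, samples, groups):
        pheno = PhenotypeTable(group_of=dict(zip(samples, groups)))
        sm = GeneSetScoreMatrix(
            [f"S{i}" for i in range(values.shape[0])], samples, values,
            {f"S{i}": 1 for i in range(values.shape[0])},
        )
        return sm, pheno

    def test_single_control_seed_is_its_column(self):
        values = np.array([[0.5, -0.5], [0.2, 0.3]])
        sm, pheno = self._scores(values, ["c", "x"], ["control", "case"])
        np.testing.assert_allclose(make_start_seed(sm, pheno), values[:, 0])

    def test_symmetric_controls_give_zero_seed(self):
        values = np.array([[0.5, -0.5, 1.0], [0.2, -0.2, 1.0]])
        sm, pheno = self._scores(values, ["c1", "c2", "x"], ["control", "control", "case"])
        np.testing.assert_allclose(make_start_seed(sm, pheno), np.zeros(2))

    def test_genesets_mode_zero_vector_of_sample_length(self):
        values = np.zeros((3, 12))
        sm, pheno = self._scores(
            values, [f"s{i}" for i in range(12)], ["control"] + ["case"] * 11
        )
        seed = make_start_seed(sm, pheno, mode="genesets")
        assert seed.shape == (12,)
        assert not seed.any()

    def test_no_controls_rejected_in_samples_mode(self):
        values = np.zeros((2, 2))
        pheno = PhenotypeTable(group_of={"a": "case", "b": "control"})
        sm = GeneSetScoreMatrix(["S0", "S1"], ["a", "x"], values, {"S0": 1, "S1": 1})
        with pytest.raises(ValueError, match="control"):
            make_start_seed(sm, pheno)


class TestAccumulateCluster:
    def test_single_candidate(self):
        seed = np.array([1.0, -1.0])
        vec = np.array([1.0, 1.0])
        res = accumulate_cluster({"only": vec}, seed, MLE)
        assert res.ordered_ids == ["only"]
        assert res.trace == [smic(vec, seed, MLE)]

    def test_matches_literal_steps_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n_cand = rng.integers(1, 7)
            length = rng.integers(2, 9)
            vectors = {
                f"s{chr(97 + i)}": rng.choice([-1.0, 0.0, 1.0], size=length)
                for i in range(n_cand)
            }
            seed = rng.choice([-1.0, 0.0, 1.0], size=length)
            res = accumulate_cluster(vectors, seed, MLE)
            order, trace = greedy_order_literal(vectors, seed, smic_mle_scalar)
            assert res.ordered_ids == order
            np.testing.assert_allclose(res.trace, trace, atol=1e-9)

    def test_output_is_permutation_and_rerun_identical(self):
        rng = np.random.default_rng(8)
        vectors = {f"v{i}": rng.normal(size=12) for i in range(9)}
        seed = rng.normal(size=12)
        a = accumulate_cluster(vectors, seed, MLE)
        b = accumulate_cluster(vectors, seed, MLE)
        assert sorted(a.ordered_ids) == sorted(vectors)
        assert a.ordered_ids == b.ordered_ids
        assert a.trace == b.trace

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            accumulate_cluster({"a": np.ones(3)}, np.ones(4), MLE)

    def test_zero_seed_ties_broken_lexicographically(self):
        vectors = {"b": np.array([1.0, 1.0]), "a": np.array([-1.0, -1.0])}
        res = accumulate_cluster(vectors, np.zeros(2), MLE)
        assert res.ordered_ids[0] == "a"


class TestSegmentTrace:
    def _result(self, trace):
        ids = [f"s{i:03d}" for i in range(len(trace))]
        return ClusteringResult(ids, list(trace), np.zeros(1))

    def test_strictly_linear_trace_one_class(self):
        res = segment_trace(self._result(2.0 + 0.5 * np.arange(20)))
        assert set(res.class_of.values()) == {1}

    @pytest.mark.parametrize("n", [12, 20, 30])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_arc_boundary_within_one_rank(self, n, seed):
        trace, truth = simulate_trace("two_arc", n, seed=seed)
        res = segment_trace(self._result(trace))
        classes = [res.class_of[s] for s in res.ordered_ids]
        assert max(classes) == 2
        boundary = classes.index(2)  # 0-based first rank of class 2
        assert abs(boundary - truth.junction) <= 1

    def test_min_class_size_dominates(self):
        trace, _ = simulate_trace("two_arc", 20, seed=0)
        res = segment_trace(self._result(trace), SegmentationConfig(min_class_size=20))
        assert set(res.class_of.values()) == {1}

    def test_short_trace_single_class(self):
        res = segment_trace(self._result([1.0, 2.0]))
        assert set(res.class_of.values()) == {1}

    def test_classes_contiguous_in_rank_order(self):
        trace, _ = simulate_trace("two_arc", 30, seed=5)
        res = segment_trace(self._result(trace))
        classes = [res.class_of[s] for s in res.ordered_ids]
        assert classes == sorted(classes)
        assert classes[0] == 1


class TestDoubleCluster:
    def _inputs(self):
        rng = np.random.default_rng(17)
        samples = ["c1", "c2"] + [f"x{i}" for i in range(6)]
        groups = ["control"] * 2 + ["case"] * 6
        values = rng.normal(size=(5, 8))
        pheno = PhenotypeTable(group_of=dict(zip(samples, groups)))
        sm = GeneSetScoreMatrix(
            [f"S{i}" for i in range(5)], samples, values, {f"S{i}": 5 for i in range(5)}
        )
        return sm, pheno

    def test_singletons(self):
        pheno = PhenotypeTable(group_of={"c": "control", "x": "case"})
        sm = GeneSetScoreMatrix(["S"], ["c", "x"], np.array([[0.1, -0.4]]), {"S": 1})
        sample_order, set_order, marker = double_cluster(sm, pheno, ["S"])
        assert sample_order == ["x"] and set_order == ["S"]
        assert marker.shape == (1, 1) and marker[0, 0] == np.False_

    def test_marker_matches_direct_indexing(self):
        sm, pheno = self._inputs()
        sample_order, set_order, marker = double_cluster(sm, pheno, sm.set_names)
        for i, name in enumerate(set_order):
            for j, sample in enumerate(sample_order):
                direct = sm.scores[sm.set_names.index(name), sm.sample_ids.index(sample)]
                assert marker[i, j] == (direct > 0)

    def test_input_sample_order_does_not_change_result(self):
        sm, pheno = self._inputs()
        base = double_cluster(sm, pheno, sm.set_names)
        rng = np.random.default_rng(23)
        for _ in range(10):
            perm = rng.permutation(len(sm.sample_ids))
            shuffled = GeneSetScoreMatrix(
                sm.set_names,
                [sm.sample_ids[k] for k in perm],
                sm.scores[:, perm],
                sm.support,
            )
            got = double_cluster(shuffled, pheno, sm.set_names)
            assert got[0] == base[0] and got[1] == base[1]
            np.testing.assert_array_equal(got[2], base[2])

    def test_unknown_set_rejected(self):
        sm, pheno = self._inputs()
        with pytest.raises(KeyError):
            double_cluster(sm, pheno, ["nope"])
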