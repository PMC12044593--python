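"""Unit and property tests for the core elimination machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import acfsa
from acfsa.core import (ResponseTable, chi_squared_scores, confidence_ellipse,
                        eliminate_lowest, fit_cluster_gaussians, fit_pca,
                        kmeans_cluster, match_cluster_labels, project)
from acfsa.errors import ValidationError

from oracles import best_matching_agreement, kmeans_min_inertia


def make_table(values, sensors=None, analytes=None):
    values = np.asarray(values, float)
    n, p = values.shape
    sensors = sensors or [f"s{i}" for i in range(p)]
    analytes = analytes or [f"A{i}" for i in range(n)]
    return ResponseTable.from_arrays(values, sensors, analytes, [1] * n)


# ---------------------------------------------------------------------------
# PCA


class TestPCA:
    def test_single_varying_column_explains_everything(self):
        X = np.column_stack([np.full(6, 0.2), np.linspace(-1, 1, 6),
                             np.full(6, -0.1)])
        model = fit_pca(X)
        assert np.allclose(model.explained_variance_ratio, [1.0, 0.0])

    def test_mean_row_projects_to_origin(self, paper_table):
        model = fit_pca(paper_table)
        coords = project(model, paper_table.values.mean(axis=0))
        assert np.allclose(coords, [0.0, 0.0], atol=1e-10)

    def test_two_sensor_ratios_match_eigendecomposition(self, rng):
        X = rng.normal(size=(20, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
        model = fit_pca(X)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=1)))[::-1]
        assert np.allclose(model.explained_variance, evals)
        assert np.allclose(model.explained_variance_ratio, evals / evals.sum())
        assert np.isclose(model.explained_variance_ratio.sum(), 1.0)

    def test_projected_variance_equals_eigenvalues(self, paper_table):
        model = fit_pca(paper_table)
        coords = project(model, paper_table.values)
        assert np.allclose(coords.var(axis=0, ddof=1),
                           model.explained_variance)

    def test_translation_invariance(self, rng):
        X = rng.normal(size=(12, 5))
        shifted = X + rng.normal(size=5)
        c1 = project(fit_pca(X), X)
        c2 = project(fit_pca(shifted), shifted)
        # loadings sign is fixed deterministically, so coords match exactly
        assert np.allclose(np.abs(c1), np.abs(c2), atol=1e-8)

    def test_loadings_orthonormal(self, paper_table):
        L = fit_pca(paper_table).loadings
        assert np.allclose(L @ L.T, np.eye(2), atol=1e-10)

    def test_ratios_non_increasing(self, paper_table):
        r = fit_pca(paper_table).explained_variance_ratio
        assert r[0] >= r[1] >= 0 and r.sum() <= 1 + 1e-12

    def test_single_sensor_degenerate_second_axis(self, rng):
        X = rng.normal(size=(10, 1))
        model = fit_pca(X)
        assert model.degenerate
        coords = project(model, X)
        assert np.allclose(coords[:, 1], 0.0)
        assert np.allclose(model.explained_variance_ratio, [1.0, 0.0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_pca(np.zeros((2, 4)))

    def test_dimension_mismatch_rejected(self, paper_table):
        model = fit_pca(paper_table)
        with pytest.raises(ValidationError):
            project(model, np.zeros(model.n_sensors + 1))


# ---------------------------------------------------------------------------
# k-means


class TestKMeans:
    def test_separated_groups_recover_means(self, rng):
        g1 = rng.normal(0, 0.01, size=(10, 2))
        g2 = rng.normal(0, 0.01, size=(10, 2)) + [10, 10]
        pts = np.vstack([g1, g2])
        model = kmeans_cluster(pts, 2, seed=0)
        centers = model.centers[np.argsort(model.centers[:, 0])]
        assert np.allclose(centers, [g1.mean(axis=0), g2.mean(axis=0)],
                           atol=1e-8)

    def test_k_equals_n_gives_zero_inertia(self, rng):
        pts = rng.normal(size=(5, 2))
        assert kmeans_cluster(pts, 5, seed=0).inertia == pytest.approx(0.0)

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 2), (8, 3)])
    def test_inertia_matches_bruteforce(self, n, k):
        rng = np.random.default_rng(10 * n + k)
        pts = rng.normal(size=(n, 2))
        model = kmeans_cluster(pts, k, seed=0, n_restarts=50)
        assert model.inertia == pytest.approx(kmeans_min_inertia(pts, k),
                                              rel=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_cluster(np.zeros((3, 2)), 4)


# ---------------------------------------------------------------------------
# Label matching


class TestLabelMatching:
    def test_diagonal_dominant_identity(self):
        assignments = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        truth = ["A", "A", "B", "B", "B", "C", "C", "C", "A"]
        mapping = match_cluster_labels(assignments, truth)
        assert mapping == {0: "A", 1: "B", 2: "C"}

    def test_reversed_renaming_recovered(self):
        truth = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        assignments = [2] * 3 + [1] * 3 + [0] * 3
        mapping = match_cluster_labels(assignments, truth)
        assert mapping == {2: "A", 1: "B", 0: "C"}
        relabeled = [mapping[c] for c in assignments]
        assert relabeled == truth

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_agreement_matches_exhaustive_permutations(self, k):
        rng = np.random.default_rng(k)
        for _ in range(10):
            truth = [f"L{t}" for t in rng.integers(0, k, size=5 * k)]
            assignments = rng.integers(0, k, size=5 * k)
            # make sure all clusters and labels occur
            assignments[:k] = np.arange(k)
            truth[:k] = [f"L{t}" for t in range(k)]
            mapping = match_cluster_labels(assignments, truth)
            agree = sum(mapping[c] == t for c, t in zip(assignments, truth))
            assert agree == best_matching_agreement(assignments, truth)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            match_cluster_labels([0, 1, 2], ["A", "B", "A"])


# ---------------------------------------------------------------------------
# Confidence ellipses


class TestConfidenceEllipse:
    def test_isotropic_semi_axes(self):
        # four points whose sample covariance is exactly (2a²/3)·I
        a = 3.0
        pts = np.array([[a, 0], [-a, 0], [0, a], [0, -a]], float)
        sigma = np.sqrt(2 * a**2 / 3)
        ell = confidence_ellipse(pts, level=0.95)
        assert np.allclose(ell.semi_axes, 2.4477 * sigma, rtol=1e-4)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        ell = confidence_ellipse(pts)
        assert ell.degenerate
        assert ell.semi_axes[1] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            confidence_ellipse(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# Chi-squared scores


class TestChiSquared:
    def test_toy_table_statistic(self):
        table = make_table([[0.1], [0.1], [0.9], [0.9]])
        scores = chi_squared_scores(table, ["A", "A", "B", "B"])
        # 2 occupied bins × 2 labels, perfect association: N·(min(r,c)−1)
        assert scores["s0"] == pytest.approx(4.0)

    def test_constant_sensor_scores_zero_with_warning(self):
        table = make_table([[0.5], [0.5], [0.5], [0.5]])
        with pytest.warns(UserWarning, match="constant"):
            scores = chi_squared_scores(table, ["A", "A", "B", "B"])
        assert scores["s0"] == 0.0

    def test_affine_rescaling_invariance(self, paper_table):
        labels = paper_table.analyte_labels
        base = chi_squared_scores(paper_table, labels)
        rescaled = ResponseTable(paper_table.data * 7.5 - 1.3)
        assert chi_squared_scores(rescaled, labels) == pytest.approx(base)

    def test_scores_nonnegative(self, paper_table):
        scores = chi_squared_scores(paper_table, paper_table.analyte_labels)
        assert all(v >= 0 for v in scores.values())

    def test_label_length_mismatch_rejected(self, paper_table):
        with pytest.raises(ValidationError):
            chi_squared_scores(paper_table, ["A"])


class TestEliminateLowest:
    def test_minimum_selected(self):
        assert eliminate_lowest({"s1": 4.0, "s2": 0.0}) == "s2"

    def test_tie_broken_lexicographically(self):
        assert eliminate_lowest({"b": 1.0, "a": 1.0, "c": 1.0}) == "a"

    def test_single_sensor_rejected(self):
        with pytest.raises(ValidationError):
            eliminate_lowest({"only": 1.0})


# ---------------------------------------------------------------------------
# ARI


class TestARI:
    def test_identical_partitions(self):
        assert acfsa.adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_label_permutation_invariance(self):
        assert acfsa.adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_partial_overlap_value(self):
        from oracles import ari_pair_counting
        a, b = [0, 0, 1, 1], [0, 1, 1, 1]
        assert acfsa.adjusted_rand_index(a, b) == pytest.approx(
            ari_pair_counting(a, b))

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=12),
           st.data())
    def test_matches_pair_counting_and_symmetry(self, a, data):
        from oracles import ari_pair_counting
        b = data.draw(st.lists(st.integers(0, 3), min_size=len(a),
                               max_size=len(a)))
        val = acfsa.adjusted_rand_index(a, b)
        assert val == pytest.approx(ari_pair_counting(a, b), abs=1e-12)
        assert val == pytest.approx(acfsa.adjusted_rand_index(b, a))
        assert -1.0 < val <= 1.0 + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            acfsa.adjusted_rand_index([0, 1], [0, 1, 2])


# ---------------------------------------------------------------------------
# Binarization


class TestBinarize:
    def test_sign_mapping(self):
        table = make_table([[0.3, -0.2, 0.0]])
        out = acfsa.binarize_responses(table)
        assert out.values.tolist() == [[1.0, -1.0, 1.0]]

    def test_dead_band(self):
        table = make_table([[0.05, -0.05, -0.2]])
        out = acfsa.binarize_responses(table, dead_band=0.1)
        assert out.values.tolist() == [[1.0, 1.0, -1.0]]

    def test_identical_sign_profiles_become_indistinguishable(self):
        # two quenching-type analytes with different magnitudes collapse
        # onto the same ±1 fingerprint, losing separability
        values = np.array([[-0.5, -0.1, -0.3],
                           [-0.1, -0.4, -0.05],
                           [0.2, 0.3, -0.2],
                           [0.4, 0.1, -0.1]])
        table = ResponseTable.from_arrays(
            values, ["s0", "s1", "s2"],
            ["Cu2+", "Hg2+", "Ni2+", "Pb2+"], [1, 1, 1, 1])
        out = acfsa.binarize_responses(table)
        cu = out.data.loc[("Cu2+", 1)].to_numpy()
        hg = out.data.loc[("Hg2+", 1)].to_numpy()
        assert np.array_equal(cu, hg)

    @given(st.lists(st.floats(-0.99, 0.99, allow_nan=False), min_size=1,
                    max_size=8))
    def test_output_always_plus_minus_one(self, row):
        out = acfsa.binarize_responses(make_table([row]))
        assert set(np.unique(out.values)) <= {-1.0, 1.0}


# ---------------------------------------------------------------------------
# The elimination loop


class TestRunACFSA:
    def test_trace_counts_and_nesting(self, paper_trace):
        assert paper_trace.n_eliminations == 28
        assert len(paper_trace.records) == 29
        prev = None
        for rec in paper_trace.records:
            if prev is not None:
                assert set(rec.sensors) < set(prev.sensors)
                assert len(rec.sensors) == len(prev.sensors) - 1
            prev = rec

    def test_eliminated_sensor_has_min_score(self, paper_trace):
        for rec in paper_trace.records:
            if rec.eliminated is not None:
                assert rec.chi2_scores[rec.eliminated] == min(
                    rec.chi2_scores.values())

    def test_trace_reproducible(self, paper_table, fast_config):
        stop = acfsa.StoppingCondition(min_sensors=25)
        t1 = acfsa.run_acfsa(paper_table, stop, fast_config)
        t2 = acfsa.run_acfsa(paper_table, stop, fast_config)
        for r1, r2 in zip(t1.records, t2.records):
            assert r1.sensors == r2.sensors
            assert r1.ari == r2.ari
            assert r1.error == r2.error
            assert r1.chi2_scores == r2.chi2_scores

    def test_random_strategy_seeded(self, paper_table):
        cfg = acfsa.ACFSAConfig(strategy="random", random_seed=7, n_mc=2000)
        stop = acfsa.StoppingCondition(min_sensors=27)
        t1 = acfsa.run_acfsa(paper_table, stop, cfg)
        t2 = acfsa.run_acfsa(paper_table, stop, cfg)
        assert [r.eliminated for r in t1.records] == \
               [r.eliminated for r in t2.records]

    def test_performance_stopping_selects_smallest_satisfying_set(
            self, paper_table, fast_config):
        stop = acfsa.StoppingCondition(min_ari=1.0)
        trace = acfsa.run_acfsa(paper_table, stop, fast_config)
        assert trace.status == "performance"
        assert trace.selected is not None
        assert trace.selected.ari == 1.0
        # nothing smaller satisfies
        smaller = [r for r in trace.records
                   if r.n_sensors < trace.selected.n_sensors]
        assert all(r.ari < 1.0 for r in smaller)

    def test_unreachable_condition_reports_exhausted(self):
        # interleaved analytes on a line: contiguous k-means clusters can
        # never match the truth, so ARI = 1 is unattainable
        vals = np.column_stack([np.arange(6.0), np.arange(6.0)])
        table = ResponseTable.from_arrays(
            vals, ["s0", "s1"], ["A", "B"] * 3, [1, 1, 2, 2, 3, 3])
        trace = acfsa.run_acfsa(table, acfsa.StoppingCondition(min_ari=1.0),
                                acfsa.ACFSAConfig(n_mc=1000))
        assert trace.status == "exhausted"
        assert trace.selected is None
        assert trace.records[-1].n_sensors == 1

    def test_chi2_selection_never_worse_than_random_baseline(self):
        """The chi-squared ranking reaches a perfect, low-error classifier
        with at most as many sensors as seeded random elimination."""
        def smallest_good_set(trace):
            good = [r.n_sensors for r in trace.records
                    if r.ari == 1.0 and r.error < 0.01]
            return min(good) if good else np.inf

        stop = acfsa.StoppingCondition(min_sensors=1)
        for seed in range(8):
            table = acfsa.generate_response_table(acfsa.paper_like_spec(seed))
            chi2 = acfsa.run_acfsa(table, stop, acfsa.ACFSAConfig(
                kmeans_seed=seed, mc_seed=seed, n_mc=2000))
            rand = acfsa.run_acfsa(table, stop, acfsa.ACFSAConfig(
                kmeans_seed=seed, mc_seed=seed, n_mc=2000,
                strategy="random", random_seed=seed))
            assert smallest_good_set(rand) >= smallest_good_set(chi2)

    def test_stopping_condition_validation(self):
        with pytest.raises(ValidationError):
            acfsa.StoppingCondition()
        with pytest.raises(ValidationError):
            acfsa.StoppingCondition(min_sensors=0)
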