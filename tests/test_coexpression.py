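"""Weighted co-expression core: adjacency, TOM, modules, eigengenes, stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statusflow.coexpression import (
    CoexpressionConfig,
    CoexpressionModel,
    adjacency_matrix,
    detect_modules,
    eigengene_network,
    module_eigengenes,
    node_statistics,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)
from statusflow.datasets import SynthCohortConfig, simulate_cohort


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Triple-loop oracle for the topological overlap similarity."""
    n = a.shape[0]
    out = np.eye(n)
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_perfect_anticorrelation_gives_one(self):
        X = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        a = adjacency_matrix(X, soft_power=6)
        assert a[0, 1] == pytest.approx(1.0)

    def test_hand_computed_sixth_power(self):
        # cor((1,2,3,4),(1,2,2,4)) = 4.5/sqrt(5*4.75) ~ 0.92338; ^6 ~ 0.6198
        X = np.array([[1.0, 2, 3, 4], [1.0, 2, 2, 4]])
        a = adjacency_matrix(X, soft_power=6)
        assert a[0, 1] == pytest.approx(0.6198, abs=1e-3)

    def test_independent_noise_vanishes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 2000))
        a = adjacency_matrix(X, soft_power=6)
        off = a[~np.eye(4, dtype=bool)]
        assert np.all(off < 1e-3)

    def test_zero_variance_row_warns_and_drops(self):
        X = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        with pytest.warns(UserWarning, match="zero-variance"):
            a = adjacency_matrix(X, soft_power=2)
        assert a[0, 1] == 0.0 and a[0, 2] == 0.0 and a[0, 0] == 1.0

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency_matrix(np.eye(3), soft_power=0.5)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 8))
        a = adjacency_matrix(X, soft_power=3)
        assert np.allclose(a, a.T, atol=1e-12)
        assert np.all((a >= 0) & (a <= 1))


class TestTOM:
    def test_clique_overlap_is_one(self):
        a = np.ones((3, 3))
        t = tom_similarity(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_half_adjacency_direct_formula(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(a)
        # (0.25 + 0.5) / (1.0 + 1 - 0.5)
        assert t[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(8, 8))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom_similarity(a), tom_brute_force(a), atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            tom_similarity(np.ones((3, 4)))

    def test_bounds(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (10, 10))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(a)
        assert np.all((t >= 0) & (t <= 1)) and np.allclose(t, t.T, atol=1e-12)


class TestModuleDetection:
    @staticmethod
    def _two_block_expression(seed=0):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.standard_normal((2, 30))
        X = np.vstack([np.outer(rng.uniform(0.5, 1, 20), f1),
                       np.outer(rng.uniform(0.5, 1, 20), f2)])
        return X

    def test_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        X = self._two_block_expression()
        tom = tom_similarity(adjacency_matrix(X, 6))
        labels = detect_modules(tom, CoexpressionConfig(min_module_size=5))
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_pure_noise_goes_grey(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 30))
        tom = tom_similarity(adjacency_matrix(X, 6))
        labels = detect_modules(tom, CoexpressionConfig(min_module_size=30))
        assert (labels == 0).mean() > 0.5

    def test_permutation_invariance_up_to_relabeling(self):
        from sklearn.metrics import adjusted_rand_score

        X = self._two_block_expression(seed=5)
        tom = tom_similarity(adjacency_matrix(X, 6))
        cfg = CoexpressionConfig(min_module_size=5)
        labels = detect_modules(tom, cfg)
        rng = np.random.default_rng(2)
        perm = rng.permutation(X.shape[0])
        labels_p = detect_modules(tom[np.ix_(perm, perm)], cfg)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_too_few_proteins_all_grey(self):
        tom = np.eye(5)
        labels = detect_modules(tom, CoexpressionConfig(min_module_size=30))
        assert np.all(labels == 0)


class TestEigengenes:
    def test_identical_profiles_give_common_profile(self):
        profile = np.array([1.0, 3, 2, 5, 4, 6])
        X = np.tile(profile, (5, 1))
        e = module_eigengenes(X, np.ones(5, dtype=int))[1].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(e @ z), 1.0, atol=1e-12)
        assert e @ z > 0  # sign oriented with the members

    def test_noiseless_factor_recovery(self):
        cfg = SynthCohortConfig(n_proteins=20, planted_modules=((10, 0.8, 0.9),),
                                noise_sd=0.0, seed=8, n_replicas=1)
        (study,) = simulate_cohort(cfg)
        labels = np.array([1] * 10 + [0] * 10)
        e = module_eigengenes(study, labels)[1].to_numpy()
        member = study.expression.to_numpy()[0]
        assert abs(np.corrcoef(e, member)[0, 1]) > 0.999

    def test_sign_flips_with_negated_members(self):
        rng = np.random.default_rng(4)
        X = np.outer(rng.uniform(0.5, 1, 6), rng.standard_normal(12))
        labels = np.ones(6, dtype=int)
        e = module_eigengenes(X, labels)[1].to_numpy()
        e_neg = module_eigengenes(-X, labels)[1].to_numpy()
        assert np.allclose(e, -e_neg, atol=1e-10)

    def test_unit_norm(self, planted_fit):
        for q in planted_fit.eigengenes.columns:
            assert np.linalg.norm(planted_fit.eigengenes[q]) == pytest.approx(1.0)


class TestNodeStatistics:
    def test_profile_proportional_to_trait_has_ps_one(self):
        S = np.array([0.0, 1, -1, 0, 1, -1, 0, 1])
        X = np.vstack([2.5 * S + 1.0])
        e = pd.DataFrame({1: S / np.linalg.norm(S)})
        ps, _, _ = node_statistics(X, S, e, np.array([1]), soft_power=6)
        assert ps[0] == pytest.approx(1.0)

    def test_orthogonal_profile_has_ps_zero(self):
        S = np.array([1.0, -1, 1, -1])
        X = np.vstack([[1.0, 1, -1, -1]])
        e = pd.DataFrame({1: S / 2})
        ps, _, _ = node_statistics(X, S, e, np.array([1]), soft_power=6)
        assert ps[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_rejected(self):
        X = np.random.default_rng(0).standard_normal((3, 6))
        e = pd.DataFrame({1: np.ones(6)})
        with pytest.raises(ValueError):
            node_statistics(X, np.zeros(6), e, np.array([1, 1, 1]), 6)

    def test_module_significance_is_mean_member_ps(self, planted_fit):
        labels = planted_fit.labels
        ps = planted_fit.significance
        for q, sig in planted_fit.module_significance.items():
            assert sig == pytest.approx(ps[labels == q].mean())


class TestEigengeneNetwork:
    def test_identical_and_anticorrelated(self):
        e = np.random.default_rng(0).standard_normal(10)
        E = pd.DataFrame({1: e, 2: e, 3: -e})
        A, diss = eigengene_network(E)
        assert A[0, 1] == pytest.approx(1.0) and diss[0, 1] == pytest.approx(0.0)
        assert A[0, 2] == pytest.approx(0.0) and diss[0, 2] == pytest.approx(2.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_adjacency_dissimilarity_identity(self, seed):
        rng = np.random.default_rng(seed)
        E = pd.DataFrame(rng.standard_normal((12, 3)))
        A, diss = eigengene_network(E)
        assert np.allclose(A, 1.0 - diss / 2.0, atol=1e-12)

    def test_single_eigengene_rejected(self):
        with pytest.raises(ValueError):
            eigengene_network(pd.DataFrame({1: np.arange(5.0)}))


class TestScaleFree:
    def test_preferential_attachment_degrees_fit_power_law(self):
        import networkx as nx

        g = nx.barabasi_albert_graph(2000, 2, seed=1)
        k = np.array([d for _, d in g.degree()], dtype=float)
        r2, slope = scale_free_fit(k)
        assert r2 >= 0.85 and slope < 0

    def test_single_candidate_returned(self, planted_cohort):
        power, table, _ = pick_soft_threshold(planted_cohort[0],
                                              candidate_powers=[1])
        assert power == 1.0 and len(table) == 1

    def test_powers_below_one_rejected(self, planted_cohort):
        with pytest.raises(ValueError):
            pick_soft_threshold(planted_cohort[0], candidate_powers=[0.5, 2])


class TestCandidateSelection:
    def test_planted_drivers_recovered(self, planted_cohort, planted_fit):
        cand = planted_fit.select_candidates()
        truth = set(planted_cohort[0].module_truth[1])
        recovered = len(set(cand.protein_id) & truth) / len(truth)
        assert recovered >= 0.9

    def test_threshold_one_empty(self, planted_fit):
        with pytest.warns(UserWarning, match="empty"):
            cand = planted_fit.select_candidates(ps_threshold=1.0,
                                                 mm_threshold=1.0)
        assert cand.empty

    def test_zero_thresholds_return_all_module_members(self, planted_fit):
        cand = planted_fit.select_candidates(ps_threshold=0.0, mm_threshold=0.0)
        n_members = int((planted_fit.labels != 0).sum())
        assert len(cand) == n_members
        assert (cand.ps.diff().dropna() <= 1e-15).all()  # sorted descending

    def test_summary_mentions_modules(self, planted_fit):
        text = planted_fit.summary()
        assert "soft power" in text and "module" in text
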