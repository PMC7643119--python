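"""Graph Laplacian machinery and singularity geometry."""

import numpy as np
import pytest

from statusflow.datasets import (
    ManifoldSampleConfig,
    SynthCohortConfig,
    simulate_cohort,
    simulate_intersecting_manifolds,
)
from statusflow.manifold import (
    Embedding,
    KernelSpec,
    effective_potential,
    eigengene_form,
    eigenmap_embedding,
    fit_potential_constant,
    gaussian_kl,
    graph_laplacian,
    incidence_angle,
    kernel_matrix,
    pointcloud_laplacian,
    singular_geometry,
    singular_laplacian_prediction,
    smoothness_functional,
)


class TestKernels:
    def test_gaussian_self_similarity_and_unit_distance(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        W = kernel_matrix(X, KernelSpec(family="gaussian", h=1.0))
        assert W[0, 0] == pytest.approx(1.0)
        assert W[0, 1] == pytest.approx(np.exp(-1.0))

    def test_sigma_parameterization(self):
        X = np.array([[0.0], [1.0]])
        W = kernel_matrix(X, KernelSpec(family="gaussian", h=None, sigma=0.5))
        assert W[0, 1] == pytest.approx(np.exp(-1.0 / (2 * 0.25)))

    def test_rational_quadratic_self_similarity(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        W = kernel_matrix(X, KernelSpec(family="rational_quadratic", offset=2.0))
        assert W[0, 1] == pytest.approx(1.0)

    def test_all_families_symmetric(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 3))
        for spec in (KernelSpec("gaussian", h=0.7),
                     KernelSpec("sigmoid", offset=0.1),
                     KernelSpec("rational_quadratic", offset=1.3)):
            W = kernel_matrix(X, spec)
            assert np.allclose(W, W.T, atol=1e-12)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.zeros((2, 2)), KernelSpec(family="cubic"))


class TestLaplacian:
    def test_two_node_spectrum(self):
        g = graph_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(g.laplacian, [[1, -1], [-1, 1]])
        vals = np.linalg.eigvalsh(g.laplacian)
        assert np.allclose(vals, [0.0, 2.0])

    def test_constant_null_space_and_psd(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 1, (7, 7))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        g = graph_laplacian(W)
        assert np.allclose(g.laplacian @ np.ones(7), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(g.laplacian).min() > -1e-10

    def test_quadratic_form_matches_pair_sum(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 1, (6, 6))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        g = graph_laplacian(W)
        f = rng.standard_normal(6)
        brute = sum(
            W[i, j] * (f[i] - f[j]) ** 2
            for i in range(6) for j in range(i + 1, 6)
        )
        assert f @ g.laplacian @ f == pytest.approx(brute)
        assert smoothness_functional(f, g) == pytest.approx(brute)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            graph_laplacian(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_smoothness_examples(self):
        g = graph_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert smoothness_functional(np.array([3.0, 3.0]), g) == 0.0
        # single unordered pair: w (f_0 - f_1)^2 = 1
        assert smoothness_functional(np.array([0.0, 1.0]), g) == pytest.approx(1.0)
        f = np.array([0.2, -1.4])
        assert smoothness_functional(3 * f, g) == pytest.approx(
            9 * smoothness_functional(f, g)
        )


class TestEigenmaps:
    @staticmethod
    def _path_graph(n=4):
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        return graph_laplacian(W)

    def test_path_fiedler_vector_monotone(self):
        emb = eigenmap_embedding(self._path_graph(), k=2)
        fiedler = emb.coordinates[:, 0]
        diffs = np.diff(fiedler)
        assert np.all(diffs > 0) or np.all(diffs < 0)
        assert emb.eigenvalues[0] > 1e-8  # trivial mode excluded

    def test_coordinates_degree_orthonormal(self):
        g = self._path_graph(6)
        emb = eigenmap_embedding(g, k=3)
        D = np.diag(g.degree)
        gram = emb.coordinates.T @ D @ emb.coordinates
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        W = rng.uniform(0.1, 1, (8, 8))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        emb = eigenmap_embedding(graph_laplacian(W), k=2)
        perm = rng.permutation(8)
        emb_p = eigenmap_embedding(graph_laplacian(W[np.ix_(perm, perm)]), k=2)
        assert np.allclose(emb.eigenvalues, emb_p.eigenvalues, atol=1e-10)
        for j in range(2):
            r = np.corrcoef(emb.coordinates[perm, j], emb_p.coordinates[:, j])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8

    def test_isolated_node_errors_with_hint(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="bandwidth"):
            eigenmap_embedding(graph_laplacian(W), k=1)


class TestEigengeneForm:
    def test_single_candidate_is_rank_one(self):
        rng = np.random.default_rng(0)
        S = np.tile([0.0, 1.0, -1.0], 4)
        x = rng.standard_normal(12)
        score = eigengene_form(x[None, :], S, soft_power=6)
        z = (x - x.mean()) / x.std()
        assert abs(np.corrcoef(score, z)[0, 1]) == pytest.approx(1.0)

    def test_invariant_to_candidate_order(self):
        rng = np.random.default_rng(1)
        S = np.tile([0.0, 1.0, -1.0], 4)
        X = rng.standard_normal((5, 12))
        a = eigengene_form(X, S, 6)
        b = eigengene_form(X[::-1], S, 6)
        assert np.allclose(a, b, atol=1e-10)

    def test_noiseless_factor_recovered(self):
        cfg = SynthCohortConfig(n_proteins=12, planted_modules=((8, 0.9, 0.9),),
                                noise_sd=0.0, seed=2, n_replicas=1)
        (study,) = simulate_cohort(cfg)
        X = study.expression.to_numpy()[:8]
        score = eigengene_form(X, study.status_trait, 6)
        member = X[0]
        assert abs(np.corrcoef(score, member)[0, 1]) > 0.999

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError):
            eigengene_form(np.random.default_rng(0).standard_normal((2, 6)),
                           np.zeros(6), 6)


class TestIncidenceAngleAndKL:
    def test_angle_examples(self):
        assert incidence_angle([1, 0], [1, 0]) == pytest.approx(0.0)
        assert incidence_angle([1, 0], [0, 1]) == pytest.approx(0.5)
        assert incidence_angle([1, 0], [1, 1]) == pytest.approx(0.25)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            incidence_angle([0, 0], [1, 0])

    def test_kl_examples(self):
        assert gaussian_kl((0.0, 1.0), (0.0, 1.0)) == pytest.approx(0.0)
        assert gaussian_kl((1.0, 1.0), (0.0, 1.0)) == pytest.approx(0.5)

    def test_kl_asymmetry(self):
        p, q = (0.0, 1.0), (0.0, 4.0)
        assert gaussian_kl(p, q) != pytest.approx(gaussian_kl(q, p))

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kl((np.zeros(2), np.zeros((2, 2))), (np.zeros(2), np.eye(2)))


class TestSingularGeometry:
    def test_theta_recovered_on_synthetic_sheets(self, sheet_cloud):
        geom = singular_geometry(np.array([0.1, 0.0, 0.3]), sheet_cloud,
                                 h=0.01, d=2)
        assert abs(geom.theta - np.pi / 4) < 0.05
        assert np.linalg.norm(geom.n1) == pytest.approx(1.0)
        assert np.linalg.norm(geom.n2) == pytest.approx(1.0)
        assert geom.D1 >= 0 and geom.D2 >= 0
        # true scaled radius: 0.1 / sqrt(0.01) = 1
        assert geom.r == pytest.approx(1.0, abs=0.15)

    def test_point_on_intersection_has_zero_radius(self, sheet_cloud):
        geom = singular_geometry(np.array([0.0, 0.0, 0.3]), sheet_cloud,
                                 h=0.01, d=2)
        assert geom.r < 0.15
        assert np.linalg.norm(geom.x0 - [0, 0, 0.3]) < 0.05


class TestSingularPrediction:
    def test_orthogonal_sheets_drop_second_term(self):
        from statusflow.manifold import SingularityModel

        m = SingularityModel(
            x0=np.zeros(3), x1=np.zeros(3), x2=np.zeros(3),
            n1=np.array([1.0, 0, 0]), n2=np.array([0, 1.0, 0]),
            theta=np.pi / 2, D1=0, D2=0, r=1.0, p_x0=1.0, d=2, h=1.0,
        )
        with_second = singular_laplacian_prediction(m, dn1_f=1.0, dn2_f=5.0)
        without = singular_laplacian_prediction(m, dn1_f=1.0, dn2_f=0.0)
        assert with_second == pytest.approx(without)

    def test_zero_radius_gives_zero(self):
        from statusflow.manifold import SingularityModel

        m = SingularityModel(
            x0=np.zeros(3), x1=np.zeros(3), x2=np.zeros(3),
            n1=np.array([1.0, 0, 0]), n2=np.array([0, 1.0, 0]),
            theta=np.pi / 4, D1=0, D2=0, r=0.0, p_x0=1.0, d=2, h=1.0,
        )
        assert singular_laplacian_prediction(m, 1.0, 1.0) == 0.0

    def test_direct_evaluation(self):
        from statusflow.manifold import SingularityModel

        m = SingularityModel(
            x0=np.zeros(3), x1=np.zeros(3), x2=np.zeros(3),
            n1=np.array([1.0, 0, 0]), n2=np.array([0, 1.0, 0]),
            theta=np.pi / 4, D1=0, D2=0, r=1.0, p_x0=1.0, d=2, h=1.0,
        )
        # pi^{2/2} * 1 * exp(-sin^2(pi/4)) * 1 * 1 = pi e^{-1/2}
        assert singular_laplacian_prediction(m, 1.0, 0.0) == pytest.approx(
            np.pi * np.exp(-0.5), rel=1e-12
        )

    def test_edge_type_drops_other_sheet(self):
        from statusflow.manifold import SingularityModel

        m = SingularityModel(
            x0=np.zeros(3), x1=np.zeros(3), x2=np.zeros(3),
            n1=np.array([1.0, 0, 0]), n2=np.array([0, 1.0, 0]),
            theta=np.pi / 4, D1=0, D2=0, r=1.0, p_x0=1.0, d=2, h=1.0,
            singularity_type="edge",
        )
        assert singular_laplacian_prediction(m, 1.0, 7.0) == pytest.approx(
            singular_laplacian_prediction(m, 1.0, 0.0)
        )


def _sheet_field(cloud):
    """Continuous field, linear on each sheet in the off-intersection coord."""
    bc, ba = cloud.sheet_basis("c"), cloud.sheet_basis("a")
    s_c = cloud.coords @ bc[:, 0]
    s_a = cloud.coords @ ba[:, 0]
    return np.where(cloud.sheet_label == "c", s_c, s_a)


class TestPointcloudLaplacian:
    def test_constant_field_is_zero(self, sheet_cloud):
        f = np.ones(len(sheet_cloud.coords))
        q = np.array([[0.2, 0.0, 0.1]])
        out = pointcloud_laplacian(sheet_cloud.coords, f, q, np.array([1.0]),
                                   h=0.02, d=2)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_field_interior_cancellation(self):
        # far from the intersection the first-order term cancels as n grows
        rng = np.random.default_rng(0)
        vals = []
        for n in (1000, 16000):
            pts = np.column_stack([
                rng.uniform(-1, 1, n), np.zeros(n), rng.uniform(-1, 1, n)
            ])
            f = pts[:, 0]
            q = np.array([[0.5, 0.0, 0.0]])
            out = pointcloud_laplacian(pts, f, q, np.array([0.5]), h=0.01, d=2)
            vals.append(abs(out[0]))
        assert vals[1] < vals[0]
        assert vals[1] < 0.5

    def test_inverse_sqrt_h_singular_scaling(self):
        cfg = ManifoldSampleConfig(dihedral_angle=np.pi / 4, n_points=5000,
                                   seed=2)
        cloud = simulate_intersecting_manifolds(cfg)
        f = _sheet_field(cloud)
        bc = cloud.sheet_basis("c")
        hs = np.array([0.08, 0.04, 0.02, 0.01])
        vals = []
        for h in hs:
            ts = np.linspace(-0.5, 0.5, 9)
            q = np.array([[np.sqrt(h), 0.0, t] for t in ts])  # fixed r = 1
            fq = q @ bc[:, 0]
            vals.append(pointcloud_laplacian(cloud.coords, f, q, fq, h, 2).mean())
        slope = np.polyfit(np.log(hs), np.log(np.abs(vals)), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_empirical_profile_matches_prediction_shape(self):
        # correlation across query radii between the empirical Laplacian and
        # the r e^{-r^2 sin^2 theta} profile of the leading-order prediction
        cfg = ManifoldSampleConfig(dihedral_angle=np.pi / 4, n_points=5000,
                                   seed=2)
        cloud = simulate_intersecting_manifolds(cfg)
        f = _sheet_field(cloud)
        bc = cloud.sheet_basis("c")
        h = 0.005
        r_values = np.linspace(0.2, 2.5, 25)
        q = np.outer(r_values * np.sqrt(h), bc[:, 0])
        fq = q @ bc[:, 0]
        emp = pointcloud_laplacian(cloud.coords, f, q, fq, h, 2)
        geom = singular_geometry(q[len(q) // 2], cloud, h=h, d=2)
        pred = np.array([
            singular_laplacian_prediction(geom, dn1_f=1.0, dn2_f=1.0, r=r)
            for r in r_values
        ])
        assert abs(np.corrcoef(emp, pred)[0, 1]) >= 0.8


class TestEffectivePotential:
    def test_zero_cases(self):
        assert effective_potential(0.0, C=2.0, h=1.0) == 0.0
        assert effective_potential(1.3, C=0.0, h=1.0) == 0.0

    def test_extremum_location_and_magnitude(self):
        C, h = -2.0, 0.5
        r = np.linspace(0, 3, 100_001)
        vals = effective_potential(r, C, h)
        k = np.argmax(np.abs(vals))
        assert r[k] == pytest.approx(1 / np.sqrt(2), abs=1e-3)
        assert abs(vals[k]) == pytest.approx(
            abs(C) * np.exp(-0.5) / np.sqrt(2 * h), rel=1e-6
        )

    def test_constant_fit_recovers_truth(self):
        rng = np.random.default_rng(1)
        r = np.linspace(0.1, 2, 30)
        y = effective_potential(r, C=1.7, h=0.3) + rng.normal(0, 1e-3, r.size)
        assert fit_potential_constant(r, y, h=0.3) == pytest.approx(1.7, abs=0.01)
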