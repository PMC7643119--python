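"""Graph-Laplacian geometry of the status manifolds.

The disease-status space is modelled as Riemannian manifolds (one per
status) meeting at singularities; each status transition corresponds to a
locus where the point-cloud graph Laplacian blows up like 1/sqrt(h).

This module provides

* the kernel families used to weight the sample graph (gaussian with
  bandwidth h, ``w_ij = exp(-||x_i - x_j||^2 / h)``; sigmoid; rational
  quadratic);
* the unnormalized graph Laplacian ``L = D - W``, the smoothness functional
  ``S(f) = 1/2 f^T L f`` and the Laplacian-eigenmap embedding solving the
  generalized problem ``L f = lambda D f``;
* the empirical point-cloud Laplacian and its analytic leading-order
  prediction near an intersection-type singularity,

      L_h f(x) ~ (1/sqrt(h)) pi^{d/2} r e^{-r^2 sin^2 theta} p(x0)
                 (dn1 f1(x0) + cos(theta) dn2 f2(x0)),

  with r = ||x - x0|| / sqrt(h), theta the incidence angle of the two
  sheets, and p the sampling density at the nearest singular point x0;
* the lumped 1-D effective potential profile ``(1/sqrt(h)) C r e^{-r^2}``
  that the dynamics stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, subspace_angles
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .datasets import PointCloud

__all__ = [
    "KernelSpec",
    "ManifoldGraph",
    "Embedding",
    "SingularityModel",
    "kernel_matrix",
    "graph_laplacian",
    "smoothness_functional",
    "eigenmap_embedding",
    "eigengene_form",
    "incidence_angle",
    "gaussian_kl",
    "singular_geometry",
    "singular_laplacian_prediction",
    "pointcloud_laplacian",
    "kernel_density",
    "effective_potential",
    "fit_potential_constant",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters for the sample/point graph.

    ``gaussian`` uses bandwidth ``h`` (``w = exp(-dist^2/h)``); passing
    ``sigma`` instead sets ``h = 2 sigma^2``. ``sigmoid`` is
    ``tanh(x_i . x_j / n_features + offset)``; ``rational_quadratic`` is
    ``1 - dist^2 / (dist^2 + offset)``.
    """

    family: str = "gaussian"
    h: float | None = 1.0
    sigma: float | None = None
    offset: float = 1.0

    def bandwidth(self) -> float:
        if self.sigma is not None:
            if self.sigma <= 0:
                raise ValueError("sigma must be > 0")
            return 2.0 * self.sigma**2
        if self.h is None or self.h <= 0:
            raise ValueError("bandwidth h must be > 0")
        return float(self.h)

    def validate(self) -> None:
        if self.family not in {"gaussian", "sigmoid", "rational_quadratic"}:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            self.bandwidth()
        if self.family == "rational_quadratic" and self.offset <= 0:
            raise ValueError("rational_quadratic needs offset > 0")


def _sq_dists(X: np.ndarray) -> np.ndarray:
    g = X @ X.T
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2 * g
    return np.maximum(d2, 0.0)


def kernel_matrix(coords: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Symmetric edge-weight matrix W for the chosen kernel family."""
    spec.validate()
    X = np.asarray(coords, dtype=float)
    if spec.family == "gaussian":
        W = np.exp(-_sq_dists(X) / spec.bandwidth())
    elif spec.family == "sigmoid":
        W = np.tanh(X @ X.T / X.shape[1] + spec.offset)
    else:  # rational quadratic
        d2 = _sq_dists(X)
        W = 1.0 - d2 / (d2 + spec.offset)
    return 0.5 * (W + W.T)


@dataclass
class ManifoldGraph:
    """Weighted sample graph with its unnormalized Laplacian L = D - W."""

    weights: np.ndarray
    kernel: KernelSpec | None = None
    degree: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if (W < 0).any():
            raise ValueError("edge weights must be nonnegative")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        self.weights = W
        self.degree = W.sum(axis=1)
        self.laplacian = np.diag(self.degree) - W


def graph_laplacian(W: np.ndarray, kernel: KernelSpec | None = None) -> ManifoldGraph:
    return ManifoldGraph(weights=np.asarray(W, dtype=float), kernel=kernel)


def smoothness_functional(f: np.ndarray, graph: ManifoldGraph) -> float:
    """Graph smoothness ``S(f) = sum_{i~j} w_ij (f_i - f_j)^2`` over
    unordered pairs, i.e. ``f^T L f`` -- equivalently half the sum over
    ordered pairs."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != graph.laplacian.shape[0]:
        raise ValueError("f must be defined on every node")
    return float(f @ graph.laplacian @ f)


@dataclass
class Embedding:
    """Bottom nontrivial generalized eigenpairs of L f = lambda D f."""

    eigenvalues: np.ndarray
    coordinates: np.ndarray  # nodes x k, D-orthonormal

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def eigenmap_embedding(graph: ManifoldGraph, k: int) -> Embedding:
    """Laplacian-eigenmap coordinates: the k bottom nontrivial solutions of
    the generalized problem ``L f = lambda D f``, D-orthonormal.

    Each successive coordinate minimizes the weighted squared-difference
    objective subject to D-orthogonality to the previous ones.
    """
    n = graph.laplacian.shape[0]
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < number of nodes")
    if (graph.degree <= 0).any():
        raise ValueError(
            "graph has isolated nodes; increase the kernel bandwidth"
        )
    n_comp, _ = connected_components(graph.weights > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"graph has {n_comp} connected components; the bottom "
            "eigenvectors are component indicators",
            stacklevel=2,
        )
    vals, vecs = eigh(graph.laplacian, np.diag(graph.degree))
    # drop trivial (near-zero) constant modes, one per component
    nontrivial = slice(n_comp, n_comp + k)
    return Embedding(eigenvalues=vals[nontrivial], coordinates=vecs[:, nontrivial])


def eigengene_form(
    expression: np.ndarray,
    status_trait: np.ndarray,
    soft_power: float,
    spec: KernelSpec | None = None,
) -> np.ndarray:
    """Per-sample scalar field built from candidate-protein eigengenes.

    The candidate expression rows are weighted by their protein significance
    ``|cor(x_i, S)|^xi``, the leading right-singular vector of that weighted,
    standardized matrix gives a per-sample score, and the score is passed
    through a status-centered gaussian kernel phi_S (distance to the mean
    score of the control samples) to give one value per node.
    """
    from .coexpression import _cor_with_vector

    X = np.asarray(expression, dtype=float)
    S = np.asarray(status_trait, dtype=float)
    if np.ptp(S) == 0:
        raise ValueError("status trait is constant")
    ps = np.abs(_cor_with_vector(X, S)) ** soft_power
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(ps[:, None] * Z, full_matrices=False)
    score = vt[0]
    if _cor_with_vector(Z, score).mean() < 0:
        score = -score
    if spec is None:
        return score
    spec.validate()
    center = score[S == 0].mean() if (S == 0).any() else score.mean()
    return np.exp(-((score - center) ** 2) / spec.bandwidth())


def incidence_angle(A: np.ndarray, B: np.ndarray) -> float:
    """Normalized incidence angle ``arccos(A.B / |A||B|) / pi`` in [0, 1]."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise ValueError("incidence angle of a zero vector is undefined")
    c = np.clip(A @ B / (na * nb), -1.0, 1.0)
    return float(np.arccos(c) / np.pi)


def gaussian_kl(p_params, q_params) -> float:
    """Closed-form KL divergence between two (multivariate) Gaussians.

    Parameters are ``(mean, covariance)``; scalars are promoted to 1-D.
    """
    mu_p, S_p = p_params
    mu_q, S_q = q_params
    mu_p = np.atleast_1d(np.asarray(mu_p, dtype=float))
    mu_q = np.atleast_1d(np.asarray(mu_q, dtype=float))
    S_p = np.atleast_2d(np.asarray(S_p, dtype=float))
    S_q = np.atleast_2d(np.asarray(S_q, dtype=float))
    k = mu_p.size
    sign_q, logdet_q = np.linalg.slogdet(S_q)
    sign_p, logdet_p = np.linalg.slogdet(S_p)
    if sign_q <= 0 or sign_p <= 0:
        raise ValueError("covariances must be positive definite")
    Sq_inv = np.linalg.inv(S_q)
    diff = mu_q - mu_p
    kl = 0.5 * (
        np.trace(Sq_inv @ S_p) + diff @ Sq_inv @ diff - k + logdet_q - logdet_p
    )
    return float(max(kl, 0.0))


# ---------------------------------------------------------------------------
# singularity geometry
# ---------------------------------------------------------------------------


@dataclass
class SingularityModel:
    """Local geometry of a point near a manifold-intersection singularity."""

    x0: np.ndarray            # nearest point of the estimated intersection
    x1: np.ndarray            # tangent-space projection onto the own sheet
    x2: np.ndarray            # tangent-space projection onto the other sheet
    n1: np.ndarray            # unit direction x0 - x1
    n2: np.ndarray            # unit direction x0 - x2
    theta: float              # incidence angle, radians
    D1: float                 # KL distance between status groups along n1
    D2: float                 # KL distance along n2
    r: float                  # scaled radius ||x - x0|| / sqrt(h)
    p_x0: float               # kernel density at x0
    d: int                    # intrinsic dimension
    h: float                  # bandwidth
    C: float | None = None    # lumped potential constant, if fitted
    singularity_type: str = "intersection"

    def phi1(self, r: float | np.ndarray | None = None):
        """Scalar profile Phi_1(r) = pi^{d/2} r exp(-r^2 sin^2 theta) p(x0)."""
        rr = self.r if r is None else r
        return np.pi ** (self.d / 2) * rr * np.exp(
            -np.square(rr) * np.sin(self.theta) ** 2
        ) * self.p_x0

    def phi2(self, r: float | np.ndarray | None = None):
        """Phi_2 = cos(theta) Phi_1."""
        return np.cos(self.theta) * self.phi1(r)


def _local_tangent(points: np.ndarray, d: int) -> np.ndarray:
    """Orthonormal tangent basis (columns) by local PCA (mean-centered)."""
    Y = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    return vt[:d].T


def _common_subspace(U: np.ndarray, V: np.ndarray, cos_tol: float = 0.99) -> np.ndarray:
    """Orthonormal basis of the near-common directions of two subspaces
    (principal vectors whose principal angle is close to zero)."""
    A, s, _ = np.linalg.svd(U.T @ V)
    keep = s > cos_tol
    if not keep.any():
        return np.zeros((U.shape[0], 0))
    W, _ = np.linalg.qr(U @ A[:, keep])
    return W


def estimate_intersection_set(
    cloud: PointCloud, k_neighbors: int = 15
) -> np.ndarray:
    """Indices of points whose k-NN neighbourhood contains both sheet labels."""
    tree = cKDTree(cloud.coords)
    _, nbr = tree.query(cloud.coords, k=k_neighbors + 1)
    labels = np.asarray(cloud.sheet_label)
    mixed = np.array(
        [len(set(labels[row])) > 1 for row in nbr]
    )
    return np.flatnonzero(mixed)


def singular_geometry(
    x: np.ndarray,
    cloud: PointCloud,
    h: float,
    d: int | None = None,
    k_neighbors: int = 30,
    theta_source: str = "geometry",
    theta_fixed: float | None = None,
) -> SingularityModel:
    """Estimate the singularity geometry around query point ``x``.

    ``x0`` is the nearest point of the estimated intersection set (points
    whose neighbourhoods mix both sheet labels); tangent spaces of each sheet
    at x0 come from local PCA; ``theta`` is the dihedral angle between them
    (largest principal angle between the tangent subspaces) unless another
    ``theta_source`` (``kl`` or ``fixed``) is requested; D1/D2 are Gaussian
    KL distances between the two status groups projected on n1/n2.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    x = np.asarray(x, dtype=float)
    labels = np.asarray(cloud.sheet_label)
    if d is None:
        d = cloud.config.intrinsic_dim if cloud.config is not None else 2
    inter = estimate_intersection_set(cloud)
    if inter.size == 0:
        raise ValueError("no intersection points found; both sheets must be sampled")
    dists = np.linalg.norm(cloud.coords[inter] - x, axis=1)
    x0 = cloud.coords[inter[np.argmin(dists)]]

    bases = {}
    for lab in ("c", "a"):
        pts = cloud.coords[labels == lab]
        if len(pts) < max(d + 2, k_neighbors // 2):
            raise ValueError(f"too few points on sheet {lab!r} for local PCA")
        tree = cKDTree(pts)
        kk = min(k_neighbors, len(pts))
        _, nbr = tree.query(x0, k=kk)
        bases[lab] = _local_tangent(pts[np.atleast_1d(nbr)], d)

    # refine x0: project onto the affine subspace through the centroid of the
    # intersection set, spanned by the sheets' common tangent directions.
    # The centroid of the whole mixed-neighbourhood set is unbiased for an
    # affine intersection (sheet offsets average out along both sheets).
    m = cloud.coords[inter].mean(axis=0)
    W = _common_subspace(bases["c"], bases["a"])
    x0 = m + W @ (W.T @ (x - m)) if W.shape[1] else m

    def _project(basis: np.ndarray) -> np.ndarray:
        return x0 + basis @ (basis.T @ (x - x0))

    x1, x2 = _project(bases["c"]), _project(bases["a"])

    def _unit_dir(xi: np.ndarray) -> np.ndarray:
        v = x0 - xi
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            return np.zeros_like(v)
        return v / nrm

    n1, n2 = _unit_dir(x1), _unit_dir(x2)

    if theta_source == "geometry":
        theta = float(np.max(subspace_angles(bases["c"], bases["a"])))
    elif theta_source == "fixed":
        if theta_fixed is None:
            raise ValueError("theta_source='fixed' requires theta_fixed")
        theta = float(theta_fixed)
    elif theta_source == "kl":
        proj_c = cloud.coords[labels == "c"] @ (n1 if n1.any() else bases["c"][:, 0])
        proj_a = cloud.coords[labels == "a"] @ (n1 if n1.any() else bases["c"][:, 0])
        kl = gaussian_kl(
            (proj_c.mean(), np.var(proj_c, ddof=1)),
            (proj_a.mean(), np.var(proj_a, ddof=1)),
        )
        theta = float(np.pi * (1 - np.exp(-kl)))  # map divergence into (0, pi)
    else:
        raise ValueError(f"unknown theta_source {theta_source!r}")

    def _kl_along(direction: np.ndarray) -> float:
        if not direction.any():
            direction = bases["c"][:, 0]
        pc = cloud.coords[labels == "c"] @ direction
        pa = cloud.coords[labels == "a"] @ direction
        vc, va = np.var(pc, ddof=1), np.var(pa, ddof=1)
        if vc <= 0 or va <= 0:
            return 0.0
        return gaussian_kl((pc.mean(), vc), (pa.mean(), va))

    r = float(np.linalg.norm(x - x0) / np.sqrt(h))
    p_x0 = kernel_density(x0, cloud.coords[labels == "a"], h, d)
    return SingularityModel(
        x0=x0, x1=x1, x2=x2, n1=n1, n2=n2, theta=theta,
        D1=_kl_along(n1), D2=_kl_along(n2), r=r, p_x0=p_x0, d=d, h=h,
    )


def kernel_density(x: np.ndarray, points: np.ndarray, h: float, d: int) -> float:
    """Gaussian kernel density estimate with the Laplacian's normalization,
    ``(1 / (n (pi h)^{d/2})) sum_j exp(-||x - x_j||^2 / h)``."""
    x = np.asarray(x, dtype=float)
    pts = np.asarray(points, dtype=float)
    w = np.exp(-np.sum((pts - x) ** 2, axis=1) / h)
    return float(w.sum() / (len(pts) * (np.pi * h) ** (d / 2)))


def singular_laplacian_prediction(
    model: SingularityModel,
    dn1_f: float,
    dn2_f: float,
    h: float | None = None,
    r: float | np.ndarray | None = None,
):
    """Leading-order graph Laplacian near an intersection-type singularity:

    ``(1/sqrt(h)) pi^{d/2} r exp(-r^2 sin^2 theta) p(x0)
    (dn1_f + cos(theta) dn2_f)``.

    For an edge-type singularity (the manifold sharply changes direction and
    only one sheet contributes), the second term is dropped.
    """
    h = model.h if h is None else h
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    second = 0.0 if model.singularity_type == "edge" else np.cos(model.theta) * dn2_f
    return (1.0 / np.sqrt(h)) * model.phi1(r) * (dn1_f + second)


def pointcloud_laplacian(
    cloud_coords: np.ndarray,
    f_values: np.ndarray,
    query_points: np.ndarray,
    f_query: np.ndarray,
    h: float,
    d: int,
) -> np.ndarray:
    """Empirical point-cloud Laplacian at the query points,

    ``L_{n,h} f(x) = (1/(n h (pi h)^{d/2})) sum_j
    exp(-||x - x_j||^2 / h) (f(x) - f(x_j))``

    (positive-semidefinite sign convention). Queries whose gaussian
    neighbourhood is numerically empty get value 0 with a warning.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    pts = np.asarray(cloud_coords, dtype=float)
    f = np.asarray(f_values, dtype=float)
    Q = np.atleast_2d(np.asarray(query_points, dtype=float))
    fq = np.atleast_1d(np.asarray(f_query, dtype=float))
    n = len(pts)
    norm = 1.0 / (n * h * (np.pi * h) ** (d / 2))
    out = np.empty(len(Q))
    empty = 0
    for i, (q, fx) in enumerate(zip(Q, fq)):
        w = np.exp(-np.sum((pts - q) ** 2, axis=1) / h)
        if w.sum() < 1e-300:
            empty += 1
            out[i] = 0.0
            continue
        out[i] = norm * np.sum(w * (fx - f))
    if empty:
        warnings.warn(
            f"{empty} query points had empty neighbourhoods at h={h}", stacklevel=2
        )
    return out


def effective_potential(r, C: float, h: float):
    """The lumped 1-D profile ``(1/sqrt(h)) C r exp(-r^2)``."""
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    r = np.asarray(r, dtype=float)
    val = (1.0 / np.sqrt(h)) * C * r * np.exp(-(r**2))
    return float(val) if val.ndim == 0 else val


def fit_potential_constant(r_values, laplacian_values, h: float) -> float:
    """Least-squares C so that ``(1/sqrt(h)) C r e^{-r^2}`` matches the
    empirical Laplacian values along the reaction coordinate."""
    r = np.asarray(r_values, dtype=float)
    y = np.asarray(laplacian_values, dtype=float)
    basis = (1.0 / np.sqrt(h)) * r * np.exp(-(r**2))
    denom = basis @ basis
    if denom == 0:
        raise ValueError("degenerate design: all r e^{-r^2} values are zero")
    return float((basis @ y) / denom)
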