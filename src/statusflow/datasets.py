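"""Synthetic proteomic cohorts and intersecting-manifold point clouds.

Every downstream stage of the package (co-expression modules, manifold
geometry, status dynamics) is exercised on data from this module, so the
generators carry the exact statistical structure those stages assume:

* cohorts are latent-factor models -- each planted module is generated as
  ``x_i = a_i * E + noise`` around a factor ``E`` correlated with the
  disease-status trait ``S`` at a configured level, giving ground truth for
  eigengenes, protein significance and preservation;
* point clouds are sampled on two affine sheets meeting along a lower
  dimensional subspace at a known dihedral angle, giving an analytic oracle
  for every geometric quantity estimated near the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_CODES",
    "DEFAULT_GROUPS",
    "SynthCohortConfig",
    "ExpressionStudy",
    "ManifoldSampleConfig",
    "PointCloud",
    "simulate_cohort",
    "simulate_intersecting_manifolds",
    "simulate_trajectories",
]

#: Disease-status phases coded as the quantitative trait S.
STATUS_CODES = {"control": 0.0, "active": 1.0, "quiescent": -1.0}

#: The five patient groups of the study design: healthy controls plus
#: active/quiescent phases of Crohn's disease and ulcerative colitis.
DEFAULT_GROUPS: tuple[tuple[str, str], ...] = (
    ("CTRL", "control"),
    ("CD", "active"),
    ("CD", "quiescent"),
    ("UC", "active"),
    ("UC", "quiescent"),
)


@dataclass(frozen=True)
class SynthCohortConfig:
    """Configuration of a synthetic proteomic cohort.

    Parameters
    ----------
    n_proteins
        Total number of protein profiles (rows).
    groups
        ``(disease, status)`` labels; status must be one of
        ``control``, ``active``, ``quiescent``.
    samples_per_group
        Biopsies per group (the study design uses 8).
    n_replicas
        Number of independently sampled replica cohorts sharing the same
        planted module memberships.
    planted_modules
        Each entry is ``(size, factor_status_correlation, within_module_r2)``:
        the module size, the sample correlation of the module factor with the
        status trait, and the fraction of each member's variance explained by
        the factor.
    noise_sd
        Scale of all residual noise. At 0 planted modules are exactly rank 1
        and background proteins are flat.
    seed
        Seed of the single generator driving the whole cohort.
    """

    n_proteins: int = 500
    groups: Sequence[tuple[str, str]] = DEFAULT_GROUPS
    samples_per_group: int = 8
    n_replicas: int = 2
    planted_modules: Sequence[tuple[int, float, float]] = ((60, 0.8, 0.5),)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        sizes = [m[0] for m in self.planted_modules]
        if any(s < 3 for s in sizes):
            raise ValueError("every planted module needs size >= 3")
        if sum(sizes) > self.n_proteins:
            raise ValueError("planted module sizes exceed n_proteins")
        for _, rho, r2 in self.planted_modules:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("factor_status_correlation must be in [-1, 1]")
            if not 0.0 < r2 < 1.0 or r2 == 0.0:
                raise ValueError("within_module_r2 must be in (0, 1)")
        for _, status in self.groups:
            if status not in STATUS_CODES:
                raise ValueError(f"unknown status label {status!r}")


@dataclass
class ExpressionStudy:
    """A proteins x samples expression matrix with its sample annotation.

    ``status_trait`` holds the quantitative status coding
    (0 control, 1 active, -1 quiescent) per sample.
    """

    expression: pd.DataFrame
    status_trait: np.ndarray
    sample_meta: pd.DataFrame
    module_truth: dict[int, list[str]] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def validate(self) -> None:
        if self.expression.isna().any().any():
            raise ValueError("expression contains missing values")
        if self.expression.shape[1] != len(self.sample_meta):
            raise ValueError("sample count mismatch between matrix and metadata")
        allowed = set(STATUS_CODES.values())
        if not set(np.unique(self.status_trait)) <= allowed:
            raise ValueError("status_trait must take values in {0, 1, -1}")

    def to_tsv(self, expression_path, meta_path) -> None:
        df = self.expression.copy()
        df.insert(0, "protein_id", df.index)
        df.to_csv(expression_path, sep="\t", index=False)
        self.sample_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expression_path, meta_path) -> "ExpressionStudy":
        df = pd.read_csv(expression_path, sep="\t")
        df = df.set_index("protein_id")
        meta = pd.read_csv(meta_path, sep="\t")
        trait = meta["status"].map(STATUS_CODES).to_numpy(dtype=float)
        return cls(expression=df, status_trait=trait, sample_meta=meta)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _factor_with_exact_correlation(
    trait: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance factor whose sample correlation with ``trait`` is exactly rho."""
    s = _standardize(trait)
    g = rng.standard_normal(trait.size)
    g = g - s * (g @ s) / (s @ s)  # residualize against the trait
    g = _standardize(g)
    f = rho * s + np.sqrt(max(0.0, 1.0 - rho**2)) * g
    return f


def simulate_cohort(config: SynthCohortConfig) -> list[ExpressionStudy]:
    """Generate one :class:`ExpressionStudy` per replica cohort.

    Module memberships and factor loadings are shared across replicas
    (preservation ground truth); factors and noise are drawn independently,
    so the replicas are independent samples of the same generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = len(config.groups) * config.samples_per_group

    protein_ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    meta_rows = []
    trait = np.empty(n_samples)
    col = 0
    for disease, status in config.groups:
        for k in range(config.samples_per_group):
            meta_rows.append(
                {
                    "sample_id": f"{disease}_{status}_{k}",
                    "disease": disease,
                    "status": status,
                }
            )
            trait[col] = STATUS_CODES[status]
            col += 1
    sizes = [m[0] for m in config.planted_modules]
    bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    module_truth = {
        q + 1: protein_ids[bounds[q] : bounds[q + 1]]
        for q in range(len(sizes))
    }
    # loadings shared across replicas so intramodular connectivity is preserved
    loadings = [rng.uniform(0.5, 1.0, size=s) for s in sizes]

    studies = []
    for rep in range(config.n_replicas):
        X = rng.standard_normal((config.n_proteins, n_samples)) * config.noise_sd
        for q, (size, rho, r2) in enumerate(config.planted_modules):
            factor = _factor_with_exact_correlation(trait, rho, rng)
            a = loadings[q]
            # member noise scaled so var explained by the factor is r2 when
            # noise_sd == 1, and exactly rank 1 when noise_sd == 0
            resid_scale = a * np.sqrt((1.0 - r2) / r2) * config.noise_sd
            eps = rng.standard_normal((size, n_samples))
            block = a[:, None] * factor[None, :] + resid_scale[:, None] * eps
            X[bounds[q] : bounds[q + 1], :] = block
        meta = pd.DataFrame(meta_rows)
        meta.insert(1, "replica", rep + 1)
        expr = pd.DataFrame(X, index=protein_ids, columns=meta["sample_id"])
        study = ExpressionStudy(
            expression=expr,
            status_trait=trait.copy(),
            sample_meta=meta,
            module_truth={q: list(v) for q, v in module_truth.items()},
        )
        study.validate()
        studies.append(study)
    return studies


# ---------------------------------------------------------------------------
# intersecting manifolds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifoldSampleConfig:
    """Two d-dimensional affine sheets in R^D meeting at a dihedral angle.

    The sheets share a (d-1)-dimensional intersection subspace. Defaults are
    desk scale (d=2 sheets in R^3); the study-scale geometry (8-manifolds in
    R^20) is reachable by configuration.
    """

    intrinsic_dim: int = 2
    ambient_dim: int = 3
    dihedral_angle: float = np.pi / 4
    n_points: int = 1000
    density: str = "uniform"
    near_cut: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.intrinsic_dim < self.ambient_dim:
            raise ValueError("need 1 <= intrinsic_dim < ambient_dim")
        if not 0.0 < self.dihedral_angle <= np.pi / 2:
            raise ValueError("dihedral_angle must lie in (0, pi/2]")
        if self.density != "uniform":
            raise ValueError("only uniform sheet sampling is implemented")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass
class PointCloud:
    """Points on the two sheets with their sheet label (c = control, a = active)."""

    coords: np.ndarray
    sheet_label: np.ndarray
    is_near_intersection: np.ndarray
    config: ManifoldSampleConfig | None = None

    def sheet_basis(self, label: str) -> np.ndarray:
        """Orthonormal basis (columns) of the labelled sheet's subspace."""
        if self.config is None:
            raise ValueError("cloud has no generating configuration attached")
        return _sheet_basis(self.config, label)

    def nearest_intersection_point(self, x: np.ndarray) -> np.ndarray:
        """Analytic nearest point of the sheet intersection (test oracle)."""
        if self.config is None:
            raise ValueError("cloud has no generating configuration attached")
        d, D = self.config.intrinsic_dim, self.config.ambient_dim
        out = np.zeros(D)
        out[2 : d + 1] = np.asarray(x)[2 : d + 1]
        return out

    def to_tsv(self, path) -> None:
        D = self.coords.shape[1]
        df = pd.DataFrame(self.coords, columns=[f"x{i+1}" for i in range(D)])
        df["sheet_label"] = self.sheet_label
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PointCloud":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("sheet_label").to_numpy()
        coords = df.to_numpy(dtype=float)
        return cls(coords=coords, sheet_label=labels,
                   is_near_intersection=np.zeros(len(labels), dtype=bool))


def _sheet_basis(config: ManifoldSampleConfig, label: str) -> np.ndarray:
    """Sheet subspaces: intersection = span(e3..e_{d+1}); sheet c adds e1,
    sheet a adds cos(theta) e1 + sin(theta) e2."""
    d, D = config.intrinsic_dim, config.ambient_dim
    theta = config.dihedral_angle
    basis = np.zeros((D, d))
    if label == "c":
        basis[0, 0] = 1.0
    elif label == "a":
        basis[0, 0] = np.cos(theta)
        basis[1, 0] = np.sin(theta)
    else:
        raise ValueError(f"unknown sheet label {label!r}")
    for k in range(1, d):
        basis[k + 1, k] = 1.0
    return basis


def simulate_intersecting_manifolds(config: ManifoldSampleConfig) -> PointCloud:
    """Sample ``n_points`` per sheet uniformly from [-1, 1]^d sheet coordinates.

    The first sheet coordinate is the signed distance from the intersection
    subspace, so ``|s_1| < near_cut`` flags points near the singularity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.intrinsic_dim
    coords, labels, near = [], [], []
    for label in ("c", "a"):
        basis = _sheet_basis(config, label)
        local = rng.uniform(-1.0, 1.0, size=(config.n_points, d))
        coords.append(local @ basis.T)
        labels.extend([label] * config.n_points)
        near.append(np.abs(local[:, 0]) < config.near_cut)
    return PointCloud(
        coords=np.vstack(coords),
        sheet_label=np.asarray(labels),
        is_near_intersection=np.concatenate(near),
        config=config,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def simulate_trajectories(
    force_field,
    n_traj: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 20.0,
    dt: float = 0.05,
    x_range: tuple[float, float] = (-1.5, 1.5),
    v_range: tuple[float, float] = (-0.5, 0.5),
):
    """Integrate ``n_traj`` orbits from random initial conditions and add
    Gaussian observation noise of the stated standard deviation.

    Returns a list of :class:`statusflow.dynamics.Orbit`.
    """
    from .dynamics import integrate_orbit

    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t_eval = np.arange(0.0, t_max + dt / 2, dt)
    orbits = []
    for _ in range(n_traj):
        y0 = np.array(
            [rng.uniform(*x_range), rng.uniform(*v_range)]
        )
        orbit = integrate_orbit(force_field, y0, (0.0, t_max), t_eval=t_eval)
        if noise_sd > 0:
            orbit.states = orbit.states + rng.normal(
                0.0, noise_sd, size=orbit.states.shape
            )
        orbits.append(orbit)
    return orbits
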