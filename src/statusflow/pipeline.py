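"""End-to-end orchestration: cohort simulation -> co-expression modules ->
manifold singularity geometry -> status dynamics -> compensatory control.

Each stage consumes the artifacts of the previous one: candidate proteins
flow from the co-expression stage into the manifold stage; the fitted
potential constant, bandwidth and incidence angle flow into the dynamics
stage; the equilibria flow into the control stage. Reports are plain JSON,
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .coexpression import CoexpressionConfig, CoexpressionModel
from .control import ControlProblem, iterative_rescue
from .datasets import (
    ManifoldSampleConfig,
    SynthCohortConfig,
    simulate_cohort,
    simulate_intersecting_manifolds,
)
from .dynamics import ForceField, find_equilibria
from .manifold import (
    fit_potential_constant,
    pointcloud_laplacian,
    singular_geometry,
)
from .preservation import ModulePreservation

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage parameters of the full pipeline."""

    seed: int = 0
    output_dir: str | None = None
    cohort: SynthCohortConfig = field(default_factory=SynthCohortConfig)
    coexpression: CoexpressionConfig = field(
        default_factory=lambda: CoexpressionConfig(min_module_size=20)
    )
    manifold_cloud: ManifoldSampleConfig = field(
        default_factory=lambda: ManifoldSampleConfig(n_points=1500)
    )
    manifold_bandwidth: float = 0.02
    preservation_permutations: int = 50
    ps_threshold: float = 0.005
    mm_threshold: float = 0.5
    eta: float = 0.1
    run_control: bool = True
    rescue_start: tuple[float, float] = (-0.45, 0.0)
    max_rescue_iterations: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = SynthCohortConfig(**raw.pop("cohort"))
        if "coexpression" in raw:
            kwargs["coexpression"] = CoexpressionConfig(**raw.pop("coexpression"))
        if "manifold_cloud" in raw:
            kwargs["manifold_cloud"] = ManifoldSampleConfig(**raw.pop("manifold_cloud"))
        if "rescue_start" in raw:
            raw["rescue_start"] = tuple(raw["rescue_start"])
        kwargs.update(raw)
        return cls(**kwargs)


def _stage_simulate(config: PipelineConfig, report: dict):
    cohort_cfg = SynthCohortConfig(
        **{**asdict(config.cohort), "seed": config.cohort.seed + config.seed}
    )
    studies = simulate_cohort(cohort_cfg)
    report["simulate"] = {
        "n_proteins": cohort_cfg.n_proteins,
        "n_samples": studies[0].n_samples,
        "n_replicas": len(studies),
        "planted_modules": [list(m) for m in cohort_cfg.planted_modules],
    }
    return studies


def _stage_coexpress(config: PipelineConfig, studies, report: dict):
    model = CoexpressionModel(studies[0], config.coexpression)
    results = model.fit()
    preserved = set(results.module_significance)
    preservation = None
    if len(studies) > 1 and results.module_significance:
        preservation = ModulePreservation(
            studies[0], studies[1], results.labels,
            soft_power=config.coexpression.soft_power,
        ).fit(n_permutations=max(50, config.preservation_permutations),
              seed=config.seed + 1)
        preserved = {q for q, z in preservation.zsummary.items() if z > 10}
    candidates = results.select_candidates(
        ps_threshold=config.ps_threshold,
        mm_threshold=config.mm_threshold,
        preserved_modules=preserved,
    )
    report["coexpress"] = {
        "soft_power": results.soft_power,
        "n_modules": len(results.module_significance),
        "module_sizes": {
            str(q): int((results.labels == q).sum())
            for q in results.module_significance
        },
        "preserved_modules": sorted(int(q) for q in preserved),
        "zsummary": (
            {str(q): z for q, z in preservation.zsummary.items()}
            if preservation is not None else None
        ),
        "n_candidates": int(len(candidates)),
    }
    return results, candidates


def _stage_manifold(config: PipelineConfig, report: dict):
    cloud_cfg = ManifoldSampleConfig(
        **{**asdict(config.manifold_cloud),
           "seed": config.manifold_cloud.seed + config.seed}
    )
    cloud = simulate_intersecting_manifolds(cloud_cfg)
    h = config.manifold_bandwidth
    d = cloud_cfg.intrinsic_dim
    theta = cloud_cfg.dihedral_angle

    # sheet-dependent scalar field with unit normal derivatives at the
    # intersection: the reaction-coordinate function the Laplacian sees
    basis_c = cloud.sheet_basis("c")
    basis_a = cloud.sheet_basis("a")
    s_c = cloud.coords @ basis_c[:, 0]
    s_a = cloud.coords @ basis_a[:, 0]
    f = np.where(cloud.sheet_label == "c", s_c, s_a)

    r_values = np.linspace(0.3, 2.0, 12)
    queries = np.outer(r_values * np.sqrt(h), basis_c[:, 0])
    f_q = queries @ basis_c[:, 0]
    emp = pointcloud_laplacian(cloud.coords, f, queries, f_q, h, d)
    C = fit_potential_constant(r_values, emp, h)
    geom = singular_geometry(queries[len(queries) // 2], cloud, h, d=d)
    report["manifold"] = {
        "h": h,
        "intrinsic_dim": d,
        "theta_true": theta,
        "theta_estimated": geom.theta,
        "kl_D1": geom.D1,
        "kl_D2": geom.D2,
        "C_fitted": C,
        "density_x0": geom.p_x0,
    }
    return C, geom


def _stage_dynamics(config: PipelineConfig, C: float, report: dict):
    field_ = ForceField.default_calibrated(
        eta=config.eta, amplitude_scale=max(abs(C), 1e-6)
    )
    eq = find_equilibria(field_)
    report["dynamics"] = {
        "eta": config.eta,
        "amplitude_scale": max(abs(C), 1e-6),
        "n_stable": len(eq.stable),
        "x_D": eq.x_D,
        "x_C": eq.x_C,
        "basin_boundary": eq.basin_boundary,
    }
    return field_, eq


def _stage_control(config: PipelineConfig, field_, eq, report: dict):
    problem = ControlProblem(
        target=eq.y_C, max_iterations=config.max_rescue_iterations
    )
    rescue = iterative_rescue(field_, np.asarray(config.rescue_start), problem,
                              equilibria=eq)
    report["control"] = {
        "success": rescue.success,
        "n_iterations": rescue.n_iterations,
        "final_distance": rescue.final_distance,
        "total_perturbation": rescue.total_perturbation.tolist(),
    }
    return rescue


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    The report records the package version, the seed, and one summary block
    per executed stage; it is JSON-serializable and, for a fixed
    configuration and seed, deterministic.
    """
    report: dict = {"version": __version__, "seed": config.seed, "stages": []}
    try:
        studies = _stage_simulate(config, report)
        report["stages"].append("simulate")
        _results, _candidates = _stage_coexpress(config, studies, report)
        report["stages"].append("coexpress")
        C, _geom = _stage_manifold(config, report)
        report["stages"].append("manifold")
        field_, eq = _stage_dynamics(config, C, report)
        report["stages"].append("dynamics")
        if config.run_control:
            _stage_control(config, field_, eq, report)
            report["stages"].append("control")
        report["status"] = "ok"
    except Exception as exc:  # noqa: BLE001 - report which stage failed
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        if config.output_dir is not None:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
    return report
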