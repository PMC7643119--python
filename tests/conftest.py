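import numpy as np
import pytest

from statusflow.coexpression import CoexpressionConfig, CoexpressionModel
from statusflow.datasets import (
    ManifoldSampleConfig,
    SynthCohortConfig,
    simulate_cohort,
    simulate_intersecting_manifolds,
)
from statusflow.dynamics import ForceField, find_equilibria


@pytest.fixture(scope="session")
def planted_cohort():
    """Two replica cohorts, 500 proteins, one planted 60-protein module
    (status correlation 0.8, within-module r2 0.5)."""
    cfg = SynthCohortConfig(
        n_proteins=500, planted_modules=((60, 0.8, 0.5),), seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_fit(planted_cohort):
    return CoexpressionModel(planted_cohort[0], CoexpressionConfig()).fit()


@pytest.fixture(scope="session")
def sheet_cloud():
    """Desk-scale intersecting sheets: d=2, D=3, dihedral angle pi/4."""
    cfg = ManifoldSampleConfig(dihedral_angle=np.pi / 4, n_points=2000, seed=1)
    return simulate_intersecting_manifolds(cfg)


@pytest.fixture(scope="session")
def calibrated_field():
    return ForceField.default_calibrated()


@pytest.fixture(scope="session")
def calibrated_equilibria(calibrated_field):
    return find_equilibria(calibrated_field)
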