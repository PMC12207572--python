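import numpy as np
import pytest

import polorient as po

# A reduced focal grid keeps every field computation fast while sampling the
# doughnut structure well (~25 px across the central features). All physical
# parameters match the instrument defaults (375 nm, NA 1.30 in water).
TEST_OBJECTIVE = po.ObjectiveConfig(
    grid_points=65,
    grid_extent_nm=800.0,
    aperture_quadrature_points=96,
)


@pytest.fixture(scope="session")
def objective() -> po.ObjectiveConfig:
    return TEST_OBJECTIVE


@pytest.fixture(scope="session")
def az_field(objective) -> po.VectorField:
    return po.focal_field("azimuthal", objective)


@pytest.fixture(scope="session")
def rad_field(objective) -> po.VectorField:
    return po.focal_field("radial", objective)


@pytest.fixture(scope="session")
def lin_field(objective) -> po.VectorField:
    return po.focal_field("linear", objective)


@pytest.fixture(scope="session")
def curve(az_field, rad_field) -> po.RatioCurve:
    return po.ratio_curve(az_field, rad_field)


def grid_summed_excitation(field: po.VectorField, theta_deg: float, phi_deg: float) -> float:
    """Independent oracle: element-wise |E·mu|^2 summed over the grid."""
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    mu = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    amp = field.ex * mu[0] + field.ey * mu[1] + field.ez * mu[2]
    return float((np.abs(amp) ** 2).sum())


def phi_averaged_excitation(field: po.VectorField, theta_deg: float, n_phi: int = 360) -> float:
    """Independent oracle: explicit uniform average over in-plane azimuths."""
    phis = np.arange(n_phi) * (360.0 / n_phi)
    return float(np.mean([grid_summed_excitation(field, theta_deg, p) for p in phis]))
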