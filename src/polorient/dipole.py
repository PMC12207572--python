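"""Excitation response of a fixed transition dipole scanned by a focused beam.

The excitation rate of a dipole μ in field E is ∝ |E·μ|² (linear regime).
For a membrane probe the in-plane azimuth φ is isotropic, so the quantity
that matters is the φ-averaged, grid-integrated excitation. Averaging
|E·μ|² over φ kills the cross terms and leaves a quadratic form in
(sin θ, cos θ):

    ⟨I(θ)⟩_φ = a · sin²θ + b · cos²θ

with ``a = ½ Σ(|Ex|² + |Ey|²)`` and ``b = Σ|Ez|²`` summed over the scan
grid. These two beam moments fully characterize a polarization mode for
ensemble-orientation work; the explicit per-φ pattern path is retained for
single-molecule pattern rendering and as an independent numerical check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .optics import ObjectiveConfig, VectorField

__all__ = [
    "DipoleOrientation",
    "ExcitationPattern",
    "BeamMoments",
    "excitation_pattern",
    "integrated_excitation",
    "beam_moments",
    "collection_efficiency",
    "write_pattern_tiff",
]

logger = logging.getLogger(__name__)

PHI_AVERAGED = "phi-averaged"


@dataclass(frozen=True)
class DipoleOrientation:
    """Transition-dipole direction: polar tilt θ from the membrane normal
    (optical axis), in-plane azimuth φ."""

    theta_deg: float
    phi_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ValueError(f"theta_deg must be in [0, 90], got {self.theta_deg}")
        if not 0.0 <= self.phi_deg < 360.0:
            raise ValueError(f"phi_deg must be in [0, 360), got {self.phi_deg}")

    def unit_vector(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        ph = np.deg2rad(self.phi_deg)
        return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


@dataclass
class ExcitationPattern:
    """Excitation rate versus beam offset — the image a scanned single
    molecule produces (up to emission factors)."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    rate: np.ndarray
    mode: str
    orientation: DipoleOrientation | str

    def __post_init__(self) -> None:
        if self.rate.shape != (self.y_nm.size, self.x_nm.size):
            raise ValueError("rate array does not match the grid")
        if np.any(self.rate < 0):
            raise ValueError("excitation rates must be non-negative")

    def total(self) -> float:
        return float(self.rate.sum())


@dataclass(frozen=True)
class BeamMoments:
    """Grid-summed transverse and longitudinal second moments of a field."""

    transverse_moment: float
    longitudinal_moment: float
    mode: str

    def __post_init__(self) -> None:
        if self.transverse_moment < 0 or self.longitudinal_moment < 0:
            raise ValueError("beam moments must be non-negative")

    def integrated_excitation(self, theta_deg: float | np.ndarray):
        """⟨I(θ)⟩_φ = a sin²θ + b cos²θ."""
        th = np.deg2rad(theta_deg)
        return (
            self.transverse_moment * np.sin(th) ** 2
            + self.longitudinal_moment * np.cos(th) ** 2
        )


def excitation_pattern(fld: VectorField, orientation: DipoleOrientation) -> ExcitationPattern:
    """Rate |E(offset)·μ|² at every beam offset for a fixed dipole."""
    if not fld.is_normalized:
        logger.warning(
            "excitation_pattern called with an unnormalized %s field; "
            "absolute rates will not be comparable across modes",
            fld.mode,
        )
    mu = orientation.unit_vector()
    amp = fld.ex * mu[0] + fld.ey * mu[1] + fld.ez * mu[2]
    return ExcitationPattern(
        x_nm=fld.x_nm,
        y_nm=fld.y_nm,
        rate=np.abs(amp) ** 2,
        mode=fld.mode,
        orientation=orientation,
    )


def beam_moments(fld: VectorField) -> BeamMoments:
    """Transverse moment a = ½ Σ(|Ex|²+|Ey|²) and longitudinal b = Σ|Ez|²."""
    if not fld.is_normalized:
        logger.warning("beam_moments called with an unnormalized %s field", fld.mode)
    a = 0.5 * float(fld.transverse_intensity().sum())
    b = float(fld.longitudinal_intensity().sum())
    return BeamMoments(transverse_moment=a, longitudinal_moment=b, mode=fld.mode)


def integrated_excitation(fld: VectorField, theta_deg: float | np.ndarray):
    """φ-averaged, grid-summed excitation of a dipole tilted at θ.

    Equals the quadratic form of :func:`beam_moments`; for the azimuthal mode
    the longitudinal moment vanishes, so an axial dipole (θ = 0) is dark.
    """
    return beam_moments(fld).integrated_excitation(theta_deg)


# ---------------------------------------------------------------------------
# emission-side collection weighting (optional; cancels in same-θ ratios)

_COLLECTION_MODELS = ("constant", "high_na_weighting")


def _collected_power_coefficients(theta_max_rad: float) -> tuple[float, float]:
    """Closed-form pieces of the power a dipole radiates into the NA cone.

    dP/dΩ ∝ sin²Ψ with Ψ the angle between dipole and emission direction.
    Integrating over the cone of half-angle α about the axis, the azimuthal
    integral is analytic and leaves P(θ) = c_t·sin²θ + c_z·cos²θ with

        c_t = 2π(1-cosα) - π ∫₀^α sin³Θ dΘ
        c_z = 2π(1-cosα) - 2π ∫₀^α cos²Θ sinΘ dΘ
    """
    ca = np.cos(theta_max_rad)
    int_sin3 = 2.0 / 3.0 - ca + ca**3 / 3.0
    int_cos2sin = (1.0 - ca**3) / 3.0
    base = 2.0 * np.pi * (1.0 - ca)
    c_t = base - np.pi * int_sin3
    c_z = base - 2.0 * np.pi * int_cos2sin
    return float(c_t), float(c_z)


@lru_cache(maxsize=32)
def _collection_norm(theta_max_rad: float) -> float:
    c_t, c_z = _collected_power_coefficients(theta_max_rad)
    return max(c_t, c_z)


def collection_efficiency(
    theta_deg: float | np.ndarray,
    config: ObjectiveConfig | None = None,
    model: str = "constant",
):
    """Fraction of a dipole's emission collected by the objective, normalized
    to its maximum over θ.

    ``constant`` returns 1 for every tilt (the default downstream: for a
    ratio of two excitation modes at one θ the emission factor cancels).
    ``high_na_weighting`` integrates the classical sin²Ψ dipole radiation
    pattern over the collection cone.
    """
    if model not in _COLLECTION_MODELS:
        raise ValueError(f"unknown collection model {model!r}; expected one of {_COLLECTION_MODELS}")
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 90):
        raise ValueError("theta_deg must lie in [0, 90]")
    if model == "constant":
        out = np.ones_like(theta)
        return float(out) if np.isscalar(theta_deg) else out
    config = config or ObjectiveConfig()
    c_t, c_z = _collected_power_coefficients(config.theta_max_rad)
    th = np.deg2rad(theta)
    power = c_t * np.sin(th) ** 2 + c_z * np.cos(th) ** 2
    eta = power / _collection_norm(config.theta_max_rad)
    return float(eta) if np.isscalar(theta_deg) else eta


def write_pattern_tiff(pattern: ExcitationPattern, path: str | Path) -> Path:
    """Write a pattern as 32-bit float TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, pattern.rate.astype(np.float32))
    if isinstance(pattern.orientation, DipoleOrientation):
        orient = {"theta_deg": pattern.orientation.theta_deg, "phi_deg": pattern.orientation.phi_deg}
    else:
        orient = {"marker": str(pattern.orientation)}
    meta = {"mode": pattern.mode, "orientation": orient}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path
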