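"""Tilt-angle inference from azimuthal/radial intensity ratios.

The theoretical ratio of grid-integrated, φ-averaged excitation under the
two doughnut modes is

    R(θ) = I_A(θ) / I_R(θ) = a_A sin²θ / (a_R sin²θ + b_R cos²θ)

which is 0 at θ = 0 (the azimuthal beam has no longitudinal field to couple
to an axial dipole), strictly increasing on (0, 90°], and capped at
a_A / a_R. A measured phase-wise ratio therefore maps to a unique
*effective* tilt — the single angle whose theoretical ratio equals the
ensemble ratio. The closed-form inverse is

    θ = arctan √( b_R·R / (a_A − a_R·R) ).

Angle utilities for comparing with molecular-dynamics conformer
distributions (folding 0–180° tilts into the 0–90° quadrant and
probability-weighted conformer averaging) live here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .dipole import beam_moments
from .optics import VectorField

__all__ = [
    "RatioCurve",
    "OrientationEstimate",
    "AngleDistribution",
    "ConformerWeights",
    "ratio_curve",
    "invert_ratio",
    "fold_angle",
    "average_conformer_orientation",
]

PHASE_LABELS = ("Lo", "Ld", "other")


@dataclass
class RatioCurve:
    """Tabulated theoretical I_A/I_R versus tilt θ with its quadratic-form
    coefficients (a_A, a_R, b_R)."""

    theta_grid_deg: np.ndarray
    ratio: np.ndarray
    coefficients: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.theta_grid_deg = np.asarray(self.theta_grid_deg, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.theta_grid_deg.shape != self.ratio.shape:
            raise ValueError("theta grid and ratio must have the same length")
        if np.any(np.diff(self.theta_grid_deg) <= 0):
            raise ValueError("theta grid must be strictly increasing")
        if self.theta_grid_deg[0] < 0 or self.theta_grid_deg[-1] > 90:
            raise ValueError("theta grid must lie within [0, 90]")
        if np.any(~np.isfinite(self.ratio)):
            raise ValueError("ratio must be finite everywhere (longitudinal moment > 0)")
        if np.any(np.diff(self.ratio) <= 0):
            raise ValueError("ratio must be strictly increasing in θ")
        if self.coefficients is not None:
            a_a, a_r, b_r = self.coefficients
            if b_r <= 0:
                raise ValueError("radial longitudinal moment b_R must be positive")

    def ratio_at(self, theta_deg: float | np.ndarray):
        """Evaluate R(θ): closed form when coefficients are known, monotone
        PCHIP interpolation of the table otherwise."""
        if self.coefficients is not None:
            a_a, a_r, b_r = self.coefficients
            th = np.deg2rad(theta_deg)
            s2, c2 = np.sin(th) ** 2, np.cos(th) ** 2
            return a_a * s2 / (a_r * s2 + b_r * c2)
        return PchipInterpolator(self.theta_grid_deg, self.ratio)(theta_deg)

    @property
    def max_ratio(self) -> float:
        if self.coefficients is not None:
            a_a, a_r, _ = self.coefficients
            return a_a / a_r
        return float(self.ratio[-1])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"theta_deg": self.theta_grid_deg, "ratio": self.ratio}).to_csv(
            path, index=False
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatioCurve":
        df = pd.read_csv(path)
        return cls(
            theta_grid_deg=df["theta_deg"].to_numpy(),
            ratio=df["ratio"].to_numpy(),
            coefficients=None,
        )


@dataclass(frozen=True)
class OrientationEstimate:
    """Recovered effective mean tilt for one lipid phase."""

    theta_deg: float
    phase_label: str
    measured_ratio: float
    method_tag: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ValueError("theta_deg must be in [0, 90]")
        if self.phase_label not in PHASE_LABELS:
            raise ValueError(f"phase_label must be one of {PHASE_LABELS}")

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.theta_deg,
            "phase_label": self.phase_label,
            "measured_ratio": self.measured_ratio,
            "method_tag": self.method_tag,
            "angle_convention": "tilt from membrane normal (optical axis)",
        }


@dataclass
class AngleDistribution:
    """Discrete probability distribution over tilt angles."""

    angle_grid_deg: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.angle_grid_deg = np.asarray(self.angle_grid_deg, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.angle_grid_deg.shape != self.probability.shape:
            raise ValueError("grid and probability must share a shape")
        if np.any(self.probability < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probability.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")

    def mean(self, fold: bool = False) -> float:
        angles = self.angle_grid_deg
        if fold:
            angles = np.array([fold_angle(a) for a in angles])
        return float(np.sum(self.probability * angles))


@dataclass(frozen=True)
class ConformerWeights:
    """Population weights of the two membrane conformers of the probe.

    Equal populations by default; the single-component-membrane literature
    value is 0.51/0.49.
    """

    w_i: float = 0.5
    w_ii: float = 0.5

    def __post_init__(self) -> None:
        if self.w_i < 0 or self.w_ii < 0:
            raise ValueError("conformer weights must be non-negative")
        if abs(self.w_i + self.w_ii - 1.0) > 1e-9:
            raise ValueError("conformer weights must sum to 1")


def ratio_curve(
    azimuthal: VectorField,
    radial: VectorField,
    theta_grid_deg: np.ndarray | None = None,
) -> RatioCurve:
    """Build the theoretical I_A/I_R(θ) curve from a normalized field pair."""
    if azimuthal.mode != "azimuthal" or radial.mode != "radial":
        raise ValueError("expected an (azimuthal, radial) field pair, in that order")
    if not (azimuthal.is_normalized and radial.is_normalized):
        raise ValueError("fields must be normalized to equal mean intensity first")
    if abs(azimuthal.mean_intensity() - radial.mean_intensity()) > 1e-9 * max(
        azimuthal.mean_intensity(), radial.mean_intensity()
    ):
        raise ValueError("fields are tagged normalized but their mean intensities differ")

    mom_a = beam_moments(azimuthal)
    mom_r = beam_moments(radial)
    if mom_r.longitudinal_moment <= 0:
        raise ValueError(
            "radial longitudinal moment is zero: the ratio curve is undefined at θ = 0"
        )
    if theta_grid_deg is None:
        theta_grid_deg = np.arange(0.0, 91.0)
    theta_grid_deg = np.asarray(theta_grid_deg, dtype=float)
    coeffs = (
        mom_a.transverse_moment,
        mom_r.transverse_moment,
        mom_r.longitudinal_moment,
    )
    th = np.deg2rad(theta_grid_deg)
    s2, c2 = np.sin(th) ** 2, np.cos(th) ** 2
    ratio = coeffs[0] * s2 / (coeffs[1] * s2 + coeffs[2] * c2)
    return RatioCurve(theta_grid_deg=theta_grid_deg, ratio=ratio, coefficients=coeffs)


def invert_ratio(
    curve: RatioCurve,
    measured_ratio: float,
    phase_label: str = "other",
) -> OrientationEstimate:
    """Solve ratio(θ) = measured ratio for the effective tilt θ.

    Uses the closed-form inverse when the curve carries its quadratic-form
    coefficients, monotone interpolation otherwise.
    """
    if measured_ratio < 0:
        raise ValueError(f"measured ratio must be non-negative, got {measured_ratio}")
    rmax = curve.max_ratio
    if measured_ratio > rmax * (1.0 + 1e-12):
        raise ValueError(
            f"measured ratio {measured_ratio:.6g} exceeds the curve maximum "
            f"{rmax:.6g}; check that both images share the equal-mean-intensity "
            "normalization"
        )
    if curve.coefficients is not None:
        a_a, a_r, b_r = curve.coefficients
        denom = a_a - a_r * measured_ratio
        if denom <= 0:
            theta = 90.0
        else:
            theta = float(
                np.rad2deg(np.arctan(np.sqrt(b_r * measured_ratio / denom)))
            )
        tag = "closed_form"
    else:
        inv = PchipInterpolator(curve.ratio, curve.theta_grid_deg)
        theta = float(np.clip(inv(min(measured_ratio, rmax)), 0.0, 90.0))
        tag = "monotone_interpolation"
    return OrientationEstimate(
        theta_deg=theta,
        phase_label=phase_label,
        measured_ratio=float(measured_ratio),
        method_tag=tag,
    )


def fold_angle(theta_deg: float) -> float:
    """Fold a tilt from [0°, 180°] into [0°, 90°] (θ ↦ 180° − θ above 90°).

    Tilt distributions from molecular-dynamics trajectories span 0–180°; a
    dipole at θ and 180° − θ is the same physical absorber, so folding
    preserves the meaning while matching the first-quadrant convention used
    by the ratio analysis.
    """
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError(f"theta_deg must be in [0, 180], got {theta_deg}")
    return float(theta_deg) if theta_deg <= 90.0 else 180.0 - float(theta_deg)


def average_conformer_orientation(
    dist_i: AngleDistribution,
    dist_ii: AngleDistribution,
    weights: ConformerWeights | None = None,
    fold: bool = False,
) -> float:
    """Probability-weighted mean tilt per conformer, combined by population.

    Each conformer's distribution is reduced to its probability-weighted
    mean angle (after optional per-value folding into [0°, 90°]); the two
    means are then combined with the conformer population weights.
    """
    weights = weights or ConformerWeights()
    return weights.w_i * dist_i.mean(fold=fold) + weights.w_ii * dist_ii.mean(fold=fold)


def write_estimates_json(
    estimates: list[OrientationEstimate],
    path: str | Path,
    extra: dict | None = None,
) -> Path:
    """Write estimates as a JSON record with provenance fields."""
    from . import __version__

    path = Path(path)
    payload = {
        "version": __version__,
        "estimates": [e.to_dict() for e in estimates],
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path
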