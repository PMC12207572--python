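"""Emission spectra, generalized polarization, and orientation-conditioned
spectral models.

Laurdan's emission reports on the hydration/dipolar relaxation of its local
environment: an ordered, dehydrated phase peaks near 425 nm, a fluid phase
near 475 nm. Generalized polarization condenses this into

    GP = (I_blue − I_red) / (I_blue + I_red)

with each band intensity averaged over a configurable window. The spectral
model couples orientation to emission: probes lying more in the membrane
plane experience stronger dipolar relaxation, so their band red-shifts by
``orientation_redshift_nm_per_sin2theta · sin²θ``. Weighting the θ-resolved
spectra by a polarization mode's excitation efficiency then yields the
population spectrum that a given beam actually probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dipole import BeamMoments
from .orientation import AngleDistribution

__all__ = [
    "EmissionSpectrum",
    "GPConfig",
    "SpectralModelParams",
    "generalized_polarization",
    "model_spectrum",
    "population_spectrum",
]

PHASES = ("Lo", "Ld")


@dataclass
class EmissionSpectrum:
    """Wavelength-indexed emission intensity with phase/polarization labels."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    phase: str | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(self.intensity < 0) or np.any(~np.isfinite(self.intensity)):
            raise ValueError("intensity must be non-negative and finite")

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelength_nm[int(np.argmax(self.intensity))])

    def scaled(self, factor: float) -> "EmissionSpectrum":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return EmissionSpectrum(
            wavelength_nm=self.wavelength_nm.copy(),
            intensity=self.intensity * factor,
            phase=self.phase,
            mode=self.mode,
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, phase: str | None = None, mode: str | None = None
    ) -> "EmissionSpectrum":
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "intensity"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
            phase=phase,
            mode=mode,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "intensity": self.intensity}
        ).to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class GPConfig:
    """Band definition for generalized polarization (standard Laurdan
    convention: blue 440 nm, red 490 nm, ±5 nm rectangular windows)."""

    lambda_blue_nm: float = 440.0
    lambda_red_nm: float = 490.0
    band_halfwidth_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda_blue_nm >= self.lambda_red_nm:
            raise ValueError("blue band must sit below the red band")
        if self.band_halfwidth_nm < 0:
            raise ValueError("band halfwidth must be non-negative")

def _band_mean(s: EmissionSpectrum, center: float, halfwidth: float) -> float:
    lo, hi = center - halfwidth, center + halfwidth
    if lo < s.wavelength_nm[0] or hi > s.wavelength_nm[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] nm lies outside the spectrum grid "
            f"[{s.wavelength_nm[0]}, {s.wavelength_nm[-1]}] nm"
        )
    sel = (s.wavelength_nm >= lo) & (s.wavelength_nm <= hi)
    if not sel.any():
        raise ValueError(f"no spectral samples inside the band [{lo}, {hi}] nm")
    return float(s.intensity[sel].mean())


def generalized_polarization(
    s: EmissionSpectrum, cfg: GPConfig | None = None, *, swap_bands: bool = False
) -> float:
    """GP = (I_blue − I_red)/(I_blue + I_red) with band-window means.

    ``swap_bands=True`` exchanges the roles of the two windows, which by
    construction negates the statistic.
    """
    cfg = cfg or GPConfig()
    blue_c, red_c = cfg.lambda_blue_nm, cfg.lambda_red_nm
    if swap_bands:
        blue_c, red_c = red_c, blue_c
    i_blue = _band_mean(s, blue_c, cfg.band_halfwidth_nm)
    i_red = _band_mean(s, red_c, cfg.band_halfwidth_nm)
    total = i_blue + i_red
    if total <= 0:
        raise ValueError("both band intensities are zero: GP undefined")
    return (i_blue - i_red) / total


@dataclass(frozen=True)
class SpectralModelParams:
    """Single-band emission model per phase with an optional tilt-dependent
    red shift (nm per sin²θ); positive values shift in-plane probes redward."""

    peak_lo_nm: float = 425.0
    peak_ld_nm: float = 475.0
    bandwidth_lo_nm: float = 50.0
    bandwidth_ld_nm: float = 60.0
    orientation_redshift_nm_per_sin2theta: float = 0.0
    lineshape: str = "gaussian"

    def __post_init__(self) -> None:
        for peak in (self.peak_lo_nm, self.peak_ld_nm):
            if not 380.0 <= peak <= 600.0:
                raise ValueError(f"peak {peak} nm outside the plausible 380–600 nm range")
        if self.bandwidth_lo_nm <= 0 or self.bandwidth_ld_nm <= 0:
            raise ValueError("bandwidths must be positive")
        if self.lineshape not in ("gaussian", "lognormal"):
            raise ValueError("lineshape must be 'gaussian' or 'lognormal'")

    def peak(self, phase: str) -> float:
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        return self.peak_lo_nm if phase == "Lo" else self.peak_ld_nm

    def bandwidth(self, phase: str) -> float:
        return self.bandwidth_lo_nm if phase == "Lo" else self.bandwidth_ld_nm


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _lineshape(grid: np.ndarray, center: float, fwhm: float, kind: str) -> np.ndarray:
    if kind == "gaussian":
        sigma = fwhm * _FWHM_TO_SIGMA
        return np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    # log-normal in wavelength: Gaussian in ln(λ), peaked exactly at `center`,
    # with log-width chosen so the FWHM matches the Gaussian's for small widths
    sigma_g = fwhm * _FWHM_TO_SIGMA / center
    out = np.zeros_like(grid)
    pos = grid > 0
    out[pos] = np.exp(-0.5 * ((np.log(grid[pos]) - np.log(center)) / sigma_g) ** 2)
    return out / out.max()


def model_spectrum(
    phase: str,
    theta_deg: float | None,
    params: SpectralModelParams | None = None,
    wavelength_grid_nm: np.ndarray | None = None,
) -> EmissionSpectrum:
    """Unit-peak single-band spectrum for a phase, optionally red-shifted by
    the probe tilt: center = phase peak + redshift·sin²θ."""
    params = params or SpectralModelParams()
    if wavelength_grid_nm is None:
        wavelength_grid_nm = np.arange(380.0, 601.0, 1.0)
    wavelength_grid_nm = np.asarray(wavelength_grid_nm, dtype=float)
    center = params.peak(phase)
    if theta_deg is not None:
        if not 0.0 <= theta_deg <= 90.0:
            raise ValueError("theta_deg must be in [0, 90]")
        center += params.orientation_redshift_nm_per_sin2theta * np.sin(np.deg2rad(theta_deg)) ** 2
    if center < wavelength_grid_nm[0] or center > wavelength_grid_nm[-1]:
        raise ValueError(
            f"band center {center:.1f} nm lies outside the wavelength grid "
            f"[{wavelength_grid_nm[0]}, {wavelength_grid_nm[-1]}] nm"
        )
    intensity = _lineshape(wavelength_grid_nm, center, params.bandwidth(phase), params.lineshape)
    return EmissionSpectrum(
        wavelength_nm=wavelength_grid_nm, intensity=intensity, phase=phase, mode=None
    )


def population_spectrum(
    dist: AngleDistribution,
    moments: BeamMoments,
    phase: str,
    params: SpectralModelParams | None = None,
    wavelength_grid_nm: np.ndarray | None = None,
) -> EmissionSpectrum:
    """Excitation-weighted mixture spectrum of an orientation population.

    Each tilt θ contributes its model spectrum weighted by p(θ) times the
    mode's excitation efficiency a·sin²θ + b·cos²θ, so an azimuthal beam
    (a only) over-weights in-plane (red-shifted) probes relative to a radial
    beam. Output normalized to unit peak.
    """
    params = params or SpectralModelParams()
    if wavelength_grid_nm is None:
        wavelength_grid_nm = np.arange(380.0, 601.0, 1.0)
    weights = dist.probability * moments.integrated_excitation(dist.angle_grid_deg)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"the {moments.mode} mode cannot excite this orientation population "
            "(zero total weight); the population spectrum is undefined"
        )
    weights = weights / total
    mix = np.zeros_like(np.asarray(wavelength_grid_nm, dtype=float))
    for theta, w in zip(dist.angle_grid_deg, weights):
        if w == 0.0:
            continue
        mix += w * model_spectrum(phase, float(theta), params, wavelength_grid_nm).intensity
    mix /= mix.max()
    return EmissionSpectrum(
        wavelength_nm=np.asarray(wavelength_grid_nm, dtype=float),
        intensity=mix,
        phase=phase,
        mode=moments.mode,
    )
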