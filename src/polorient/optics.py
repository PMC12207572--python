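"""Vectorial focal fields of cylindrical vector beams under high-NA focusing.

Implements Richards–Wolf-type angular-spectrum focusing for azimuthally,
radially, and linearly polarized input beams through an aplanatic objective
into a homogeneous medium. The focal-plane (z = 0) electric field is computed
as a superposition of plane waves over the aperture cone, with the standard
``sqrt(cos θ)`` aplanatic apodization. For the cylindrically symmetric modes
the integrals reduce to Bessel transforms:

* radial input:    ``E_ρ ∝ ∫ P(θ) √cosθ sinθ cosθ J₁(kρ sinθ) dθ``,
  ``E_z ∝ i ∫ P(θ) √cosθ sin²θ J₀(kρ sinθ) dθ``
* azimuthal input: ``E_φ ∝ ∫ P(θ) √cosθ sinθ J₁(kρ sinθ) dθ``, ``E_z ≡ 0``
* linear (x) input: the usual I₀/I₁/I₂ diffraction integrals.

The azimuthal mode therefore carries no longitudinal field anywhere, while
the radial mode focuses to a strong longitudinal spike on the optical axis —
the contrast that makes the pair orientation-sensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import j0, j1, jv

__all__ = [
    "MODES",
    "REFERENCE_MEAN_INTENSITY",
    "ObjectiveConfig",
    "VectorField",
    "focal_field",
    "normalize_equal_mean_intensity",
    "write_field_tiff",
    "read_field_tiff",
    "write_intensity_tiff",
]

MODES = ("azimuthal", "radial", "linear")

#: Common grid-window-averaged intensity all fields are normalized to
#: (arbitrary units). Downstream intensity *ratios* are invariant to it.
REFERENCE_MEAN_INTENSITY = 1.0

NORMALIZED_TAG = "mean_intensity"
RAW_TAG = "raw"


@dataclass(frozen=True)
class ObjectiveConfig:
    """Objective / excitation geometry.

    Parameters
    ----------
    wavelength_nm
        Excitation wavelength in vacuum (nm).
    numerical_aperture
        Objective NA; must be below the sample refractive index.
    refractive_index_sample
        Index of the immersion/sample medium (water-like buffer).
    filling_factor
        Ratio of input beam waist to pupil radius. ``None`` (default) models
        a uniform annular amplitude for the doughnut modes and a uniform
        pupil for the linear mode.
    grid_extent_nm
        Half-width of the focal-plane sampling window.
    grid_points
        Samples per axis; must be odd so the optical axis is a grid point.
    aperture_quadrature_points
        Gauss–Legendre nodes over the focusing angle.
    """

    wavelength_nm: float = 375.0
    numerical_aperture: float = 1.30
    refractive_index_sample: float = 1.33
    filling_factor: float | None = None
    grid_extent_nm: float = 1000.0
    grid_points: int = 257
    aperture_quadrature_points: int = 128

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if not self.numerical_aperture > 0:
            raise ValueError("numerical_aperture must be positive")
        if self.numerical_aperture >= self.refractive_index_sample:
            raise ValueError(
                "numerical_aperture must be smaller than the sample refractive "
                f"index (got NA={self.numerical_aperture} ≥ "
                f"n={self.refractive_index_sample}): the focusing cone is "
                "undefined otherwise"
            )
        if self.grid_points < 3 or self.grid_points % 2 == 0:
            raise ValueError("grid_points must be odd and ≥ 3 so the optical axis is sampled")
        if self.grid_extent_nm <= 0:
            raise ValueError("grid_extent_nm must be positive")
        if self.aperture_quadrature_points < 4:
            raise ValueError("aperture_quadrature_points must be ≥ 4")
        if self.filling_factor is not None and self.filling_factor <= 0:
            raise ValueError("filling_factor must be positive when given")

    @property
    def theta_max_rad(self) -> float:
        """Half-angle of the focusing cone."""
        return float(np.arcsin(self.numerical_aperture / self.refractive_index_sample))

    @property
    def wavenumber_per_nm(self) -> float:
        """Wavenumber in the sample medium, rad/nm."""
        return 2.0 * np.pi * self.refractive_index_sample / self.wavelength_nm

    def axes_nm(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(-self.grid_extent_nm, self.grid_extent_nm, self.grid_points)
        return x, x.copy()


@dataclass
class VectorField:
    """Complex focal-plane electric field on a Cartesian grid.

    Components are stored as 2D complex arrays indexed ``[row, col]`` with
    ``row`` ↔ y and ``col`` ↔ x; ``x_nm``/``y_nm`` give the grid coordinates.
    """

    x_nm: np.ndarray
    y_nm: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    mode: str
    config: ObjectiveConfig
    normalization_tag: str = RAW_TAG
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (self.y_nm.size, self.x_nm.size)
        for name in ("ex", "ey", "ez"):
            comp = getattr(self, name)
            if comp.shape != shape:
                raise ValueError(f"component {name} has shape {comp.shape}, expected {shape}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ex.shape

    @property
    def axis_index(self) -> tuple[int, int]:
        """(row, col) of the on-axis grid point."""
        return int(np.argmin(np.abs(self.y_nm))), int(np.argmin(np.abs(self.x_nm)))

    def intensity(self) -> np.ndarray:
        """Total intensity |Ex|² + |Ey|² + |Ez|² per grid point."""
        return (
            np.abs(self.ex) ** 2 + np.abs(self.ey) ** 2 + np.abs(self.ez) ** 2
        )

    def longitudinal_intensity(self) -> np.ndarray:
        return np.abs(self.ez) ** 2

    def transverse_intensity(self) -> np.ndarray:
        return np.abs(self.ex) ** 2 + np.abs(self.ey) ** 2

    def mean_intensity(self) -> float:
        return float(self.intensity().mean())

    def scaled(self, factor: float, tag: str | None = None) -> "VectorField":
        """Return a copy with every component multiplied by ``factor``."""
        return replace(
            self,
            ex=self.ex * factor,
            ey=self.ey * factor,
            ez=self.ez * factor,
            normalization_tag=tag if tag is not None else self.normalization_tag,
        )

    @property
    def is_normalized(self) -> bool:
        return self.normalization_tag == NORMALIZED_TAG

    def component_stack(self) -> np.ndarray:
        """Stack components to shape (rows, cols, 3) for vectorized dot products."""
        return np.stack([self.ex, self.ey, self.ez], axis=-1)


def _pupil_amplitude(mode: str, config: ObjectiveConfig, theta: np.ndarray) -> np.ndarray:
    if config.filling_factor is None:
        return np.ones_like(theta)
    r = np.sin(theta) / (config.filling_factor * np.sin(config.theta_max_rad))
    if mode in ("azimuthal", "radial"):
        # doughnut (LG01-like) input: zero on axis, Gaussian envelope
        return r * np.exp(-(r**2))
    return np.exp(-(r**2))


def _aperture_nodes(config: ObjectiveConfig, n_points: int | None = None):
    n = n_points or config.aperture_quadrature_points
    nodes, weights = np.polynomial.legendre.leggauss(n)
    theta = 0.5 * config.theta_max_rad * (nodes + 1.0)
    w = 0.5 * config.theta_max_rad * weights
    return theta, w


def focal_field(
    mode: str,
    config: ObjectiveConfig | None = None,
    *,
    normalize: bool = True,
    quadrature_points: int | None = None,
) -> VectorField:
    """Compute the focal-plane (z = 0) field for one polarization mode.

    The returned field is normalized so its grid-window-averaged intensity
    equals :data:`REFERENCE_MEAN_INTENSITY` (identical across modes), unless
    ``normalize=False``.
    """
    config = config or ObjectiveConfig()
    if mode not in MODES:
        raise ValueError(f"unknown polarization mode {mode!r}; expected one of {MODES}")

    x, y = config.axes_nm()
    X, Y = np.meshgrid(x, y)
    R = np.hypot(X, Y)
    PHI = np.arctan2(Y, X)
    k = config.wavenumber_per_nm

    theta, w = _aperture_nodes(config, quadrature_points)
    st, ct = np.sin(theta), np.cos(theta)
    apo = np.sqrt(ct) * _pupil_amplitude(mode, config, theta)

    kr = k * R.ravel()[:, None] * st[None, :]
    shape = R.shape

    if mode == "azimuthal":
        e_phi = (j1(kr) @ (w * apo * st)).reshape(shape)
        ex = (-e_phi * np.sin(PHI)).astype(complex)
        ey = (e_phi * np.cos(PHI)).astype(complex)
        ez = np.zeros(shape, dtype=complex)
    elif mode == "radial":
        e_rho = (j1(kr) @ (w * apo * st * ct)).reshape(shape)
        e_z = (j0(kr) @ (w * apo * st * st)).reshape(shape)
        ex = (e_rho * np.cos(PHI)).astype(complex)
        ey = (e_rho * np.sin(PHI)).astype(complex)
        ez = 1j * e_z
    else:  # linear, x-polarized
        i0 = (j0(kr) @ (w * apo * st * (1.0 + ct))).reshape(shape)
        i1 = (j1(kr) @ (w * apo * st * st)).reshape(shape)
        i2 = (jv(2, kr) @ (w * apo * st * (1.0 - ct))).reshape(shape)
        ex = (i0 + i2 * np.cos(2.0 * PHI)).astype(complex)
        ey = (i2 * np.sin(2.0 * PHI)).astype(complex)
        ez = -2j * i1 * np.cos(PHI)

    fld = VectorField(x_nm=x, y_nm=y, ex=ex, ey=ey, ez=ez, mode=mode, config=config)
    if normalize:
        (fld,) = normalize_equal_mean_intensity([fld])
    return fld


def normalize_equal_mean_intensity(
    fields: list[VectorField],
    reference: float = REFERENCE_MEAN_INTENSITY,
) -> list[VectorField]:
    """Rescale each field so its window-mean intensity equals ``reference``.

    This encodes the experimental condition that the average excitation
    intensity in the focal plane is identical for every polarization mode, so
    phase-wise intensity ratios compare field *structure*, not beam power.
    """
    if not fields:
        raise ValueError("need at least one field")
    shape = fields[0].shape
    for fld in fields:
        if fld.shape != shape:
            raise ValueError("all fields must share a common grid")
    out = []
    for fld in fields:
        mean = fld.mean_intensity()
        if mean <= 0.0 or not np.isfinite(mean):
            raise ValueError(f"cannot normalize a zero/non-finite-intensity field ({fld.mode})")
        out.append(fld.scaled(np.sqrt(reference / mean), tag=NORMALIZED_TAG))
    return out


# ---------------------------------------------------------------------------
# export helpers


def write_field_tiff(fld: VectorField, path: str | Path) -> Path:
    """Write the complex field as 6 float32 TIFF planes + a JSON sidecar.

    Plane order: Ex.re, Ex.im, Ey.re, Ey.im, Ez.re, Ez.im.
    """
    import tifffile

    path = Path(path)
    planes = np.stack(
        [
            fld.ex.real, fld.ex.imag,
            fld.ey.real, fld.ey.imag,
            fld.ez.real, fld.ez.imag,
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, planes)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "mode": fld.mode,
        "normalization_tag": fld.normalization_tag,
        "grid_extent_nm": fld.config.grid_extent_nm,
        "grid_points": fld.config.grid_points,
        "wavelength_nm": fld.config.wavelength_nm,
        "numerical_aperture": fld.config.numerical_aperture,
        "refractive_index_sample": fld.config.refractive_index_sample,
        "plane_order": ["ex.re", "ex.im", "ey.re", "ey.im", "ez.re", "ez.im"],
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_field_tiff(path: str | Path) -> VectorField:
    """Read a field written by :func:`write_field_tiff`."""
    import tifffile

    path = Path(path)
    planes = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = ObjectiveConfig(
        wavelength_nm=meta["wavelength_nm"],
        numerical_aperture=meta["numerical_aperture"],
        refractive_index_sample=meta["refractive_index_sample"],
        grid_extent_nm=meta["grid_extent_nm"],
        grid_points=meta["grid_points"],
    )
    x, y = config.axes_nm()
    return VectorField(
        x_nm=x,
        y_nm=y,
        ex=planes[0] + 1j * planes[1],
        ey=planes[2] + 1j * planes[3],
        ez=planes[4] + 1j * planes[5],
        mode=meta["mode"],
        config=config,
        normalization_tag=meta["normalization_tag"],
    )


def write_intensity_tiff(fld: VectorField, path: str | Path) -> Path:
    """Write the total intensity map as 32-bit float TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, fld.intensity().astype(np.float32))
    return path
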