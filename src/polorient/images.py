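"""Segmentation and phase-wise quantification of paired polarization scans.

A phase-separated supported bilayer imaged under azimuthal and radial
excitation gives two pixel-registered scans. The liquid-ordered (Lo) domains
appear as darker patches within the brighter liquid-disordered (Ld)
background; the default segmentation Otsu-thresholds the radial-excitation
image (both phases bright there, most stable contrast) and cleans speckle
with a morphological opening. Phase-wise mean intensities under each mode
give the two ratios I_A/I_R that the orientation inversion consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import profile_line
from skimage.morphology import disk, opening

__all__ = [
    "BACKGROUND",
    "LO",
    "LD",
    "ScanImage",
    "PhaseMask",
    "PhaseStats",
    "LineProfile",
    "difference_image",
    "segment_phases",
    "phase_mean_intensities",
    "line_profile",
]

# mask label values
BACKGROUND = 0
LO = 1
LD = 2

SEGMENTATION_METHODS = ("otsu_single", "otsu_difference", "manual_roi")


@dataclass
class ScanImage:
    """One raster scan: per-pixel intensity plus acquisition metadata."""

    pixels: np.ndarray
    pixel_size_nm: float
    polarization: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_size_nm: float,
        polarization: str | None = None,
    ) -> "ScanImage":
        """Read a single-page grayscale TIFF (8/16-bit integer or float)."""
        import tifffile

        pixels = tifffile.imread(Path(path))
        if pixels.ndim != 2:
            raise ValueError(f"{path}: expected a single-page grayscale TIFF")
        return cls(
            pixels=pixels.astype(float),
            pixel_size_nm=pixel_size_nm,
            polarization=polarization,
            meta={"source": str(path)},
        )

    def to_tiff(self, path: str | Path) -> Path:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.pixels.astype(np.float32))
        return path


@dataclass
class PhaseMask:
    """Per-pixel phase labels (Lo/Ld/background) with provenance."""

    labels: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (BACKGROUND, LO, LD)).all():
            raise ValueError("labels must be background/Lo/Ld")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self, label: int) -> int:
        return int((self.labels == label).sum())

    def swapped(self) -> "PhaseMask":
        """Exchange the Lo/Ld semantics, keeping geometry."""
        out = self.labels.copy()
        out[self.labels == LO] = LD
        out[self.labels == LD] = LO
        return PhaseMask(labels=out, provenance=self.provenance + "+swapped")

    def to_tiff(self, path: str | Path) -> Path:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.labels.astype(np.uint8))
        return path

    @classmethod
    def from_tiff(cls, path: str | Path, provenance: str = "manual_roi") -> "PhaseMask":
        import tifffile

        return cls(labels=tifffile.imread(Path(path)).astype(np.uint8), provenance=provenance)


@dataclass(frozen=True)
class PhaseStats:
    """Phase-wise mean intensities under both modes and their ratios."""

    i_a_lo: float
    i_a_ld: float
    i_r_lo: float
    i_r_ld: float
    ratio_lo: float
    ratio_ld: float
    n_lo: int
    n_ld: int

    def to_dict(self) -> dict:
        return {
            "I_A_Lo": self.i_a_lo,
            "I_A_Ld": self.i_a_ld,
            "I_R_Lo": self.i_r_lo,
            "I_R_Ld": self.i_r_ld,
            "ratio_Lo": self.ratio_lo,
            "ratio_Ld": self.ratio_ld,
            "n_pixels_Lo": self.n_lo,
            "n_pixels_Ld": self.n_ld,
        }


def _check_pair(a: ScanImage, b: ScanImage) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if abs(a.pixel_size_nm - b.pixel_size_nm) > 1e-9:
        raise ValueError("pixel sizes differ between the paired images")


def difference_image(a: ScanImage, b: ScanImage, normalize: bool = False) -> np.ndarray:
    """Signed pixel-wise difference a − b.

    With ``normalize=True`` each image is first scaled to unit mean so the
    difference highlights structural contrast rather than power imbalance.
    """
    _check_pair(a, b)
    pa, pb = a.pixels, b.pixels
    if normalize:
        if pa.mean() <= 0 or pb.mean() <= 0:
            raise ValueError("cannot mean-normalize a zero-intensity image")
        pa = pa / pa.mean()
        pb = pb / pb.mean()
    return pa - pb


def align_integer_shift(a: ScanImage, b: ScanImage, max_shift_px: int = 5) -> tuple[int, int]:
    """Estimate an integer (row, col) shift of b relative to a by exhaustive
    cross-correlation over a small window. Images from one raster scan are
    normally pixel-registered; this exists behind a flag for drifted pairs."""
    _check_pair(a, b)
    best, best_shift = -np.inf, (0, 0)
    pa = a.pixels - a.pixels.mean()
    pb = b.pixels - b.pixels.mean()
    for dr in range(-max_shift_px, max_shift_px + 1):
        for dc in range(-max_shift_px, max_shift_px + 1):
            shifted = np.roll(np.roll(pb, dr, axis=0), dc, axis=1)
            score = float((pa * shifted).sum())
            if score > best:
                best, best_shift = score, (dr, dc)
    return best_shift


def segment_phases(
    a: ScanImage,
    r: ScanImage,
    method: str = "otsu_single",
    opening_radius_px: int = 2,
    background_percentile: float | None = None,
    manual_mask: PhaseMask | None = None,
) -> PhaseMask:
    """Two-class phase segmentation of a registered image pair.

    ``otsu_single`` thresholds the radial-excitation image; ``otsu_difference``
    thresholds the mean-normalized difference (azimuthal − radial), where Lo
    is strongly negative. Lo is the darker class in either driving image. A
    binary opening (disk radius ``opening_radius_px``) removes speckle.
    ``manual_roi`` bypasses thresholding and returns the supplied mask.
    """
    _check_pair(a, r)
    if method not in SEGMENTATION_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {SEGMENTATION_METHODS}")

    if method == "manual_roi":
        if manual_mask is None:
            raise ValueError("manual_roi requires manual_mask")
        if manual_mask.shape != a.shape:
            raise ValueError("manual mask shape does not match the images")
        return PhaseMask(labels=manual_mask.labels.copy(), provenance="manual_roi")

    driving = r.pixels if method == "otsu_single" else difference_image(a, r, normalize=True)
    if np.ptp(driving) == 0:
        raise ValueError(
            "driving image is constant: no threshold separates two phases "
            "(is this really a phase-separated membrane scan?)"
        )
    thr = threshold_otsu(driving)
    lo = driving < thr
    if opening_radius_px > 0:
        lo = opening(lo, disk(opening_radius_px))
    labels = np.where(lo, LO, LD).astype(np.uint8)

    if background_percentile is not None:
        floor = np.percentile(r.pixels, background_percentile)
        labels[r.pixels <= floor] = BACKGROUND

    if (labels == LO).sum() == 0 or (labels == LD).sum() == 0:
        raise ValueError(
            "degenerate segmentation: one phase class is empty after "
            "thresholding/opening; adjust the method or supply a manual mask"
        )
    return PhaseMask(labels=labels, provenance=method)


def phase_mean_intensities(a: ScanImage, r: ScanImage, mask: PhaseMask) -> PhaseStats:
    """Per-phase arithmetic mean intensity of each image and the two
    azimuthal/radial ratios; background pixels are excluded."""
    _check_pair(a, r)
    if mask.shape != a.shape:
        raise ValueError("mask shape does not match the images")
    out: dict[int, tuple[float, float, int]] = {}
    for label in (LO, LD):
        sel = mask.labels == label
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"phase label {label} has no pixels; cannot compute statistics")
        out[label] = (float(a.pixels[sel].mean()), float(r.pixels[sel].mean()), n)
    (ia_lo, ir_lo, n_lo), (ia_ld, ir_ld, n_ld) = out[LO], out[LD]
    if ir_lo <= 0 or ir_ld <= 0:
        raise ValueError("zero radial mean intensity: the I_A/I_R ratio is undefined")
    return PhaseStats(
        i_a_lo=ia_lo,
        i_a_ld=ia_ld,
        i_r_lo=ir_lo,
        i_r_ld=ir_ld,
        ratio_lo=ia_lo / ir_lo,
        ratio_ld=ia_ld / ir_ld,
        n_lo=n_lo,
        n_ld=n_ld,
    )


@dataclass
class LineProfile:
    """Averaged intensity along a sampled segment."""

    position_nm: np.ndarray
    intensity: np.ndarray

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame({"position_nm": self.position_nm, "intensity": self.intensity}).to_csv(
            path, index=False
        )
        return path


def line_profile(
    img: ScanImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 1,
) -> LineProfile:
    """Intensity profile along a segment from ``start`` to ``end`` (row, col),
    averaged over ``width_px`` perpendicular pixels, positions in nm."""
    rows, cols = img.shape
    for name, (rr, cc) in (("start", start), ("end", end)):
        if not (0 <= rr <= rows - 1 and 0 <= cc <= cols - 1):
            raise ValueError(f"{name} point {(rr, cc)} lies outside the image {img.shape}")
    values = profile_line(
        img.pixels, start, end, linewidth=width_px, order=1, mode="reflect", reduce_func=np.mean
    )
    length_px = float(np.hypot(end[0] - start[0], end[1] - start[1]))
    step_nm = (length_px / (values.size - 1)) * img.pixel_size_nm if values.size > 1 else 0.0
    position_nm = np.arange(values.size) * step_nm
    return LineProfile(position_nm=position_nm, intensity=values)
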