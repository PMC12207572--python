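"""Run configuration: YAML blocks mirroring the module-level dataclasses.

A config file looks like::

    objective:
      wavelength_nm: 375
      numerical_aperture: 1.30
      refractive_index_sample: 1.33
      grid_extent_nm: 1000
      grid_points: 257
      aperture_quadrature_points: 128
    gp:
      lambda_blue_nm: 440
      lambda_red_nm: 490
      band_halfwidth_nm: 5
    segmentation:
      method: otsu_single
      opening_radius_px: 2
    simulation:
      shape: [256, 256]
      lo_theta_deg: 32
      ld_theta_deg: 41
      family: delta
    seed: 0
    output_dir: out

Every block validates against its module's invariants at load time, before
any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .optics import ObjectiveConfig
from .spectra import GPConfig, SpectralModelParams

__all__ = ["SegmentationParams", "SimulationParams", "RunConfig"]


@dataclass(frozen=True)
class SegmentationParams:
    method: str = "otsu_single"
    opening_radius_px: int = 2
    background_percentile: float | None = None

    def __post_init__(self) -> None:
        from .images import SEGMENTATION_METHODS

        if self.method not in SEGMENTATION_METHODS:
            raise ValueError(f"unknown segmentation method {self.method!r}")
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be non-negative")


@dataclass(frozen=True)
class SimulationParams:
    shape: tuple[int, int] = (256, 256)
    lo_theta_deg: float = 32.0
    ld_theta_deg: float = 41.0
    family: str = "delta"
    lo_spread_deg: float = 8.0
    ld_spread_deg: float = 15.0
    dye_surface_density_um2: float = 3.0e5
    brightness_lo: float = 0.04
    brightness_ld: float = 0.065
    background_counts: float = 1.0
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.family not in ("delta", "truncated_normal"):
            raise ValueError("family must be 'delta' or 'truncated_normal'")
        for th in (self.lo_theta_deg, self.ld_theta_deg):
            if not 0.0 <= th <= 90.0:
                raise ValueError("phase tilt angles must be in [0, 90]")

    def build_membrane(self, seed: int):
        from .synthetic import default_membrane

        return default_membrane(
            seed=seed,
            shape=tuple(self.shape),
            lo_theta_deg=self.lo_theta_deg,
            ld_theta_deg=self.ld_theta_deg,
            family=self.family,
            lo_spread_deg=self.lo_spread_deg,
            ld_spread_deg=self.ld_spread_deg,
            dye_surface_density_um2=self.dye_surface_density_um2,
            brightness={"Lo": self.brightness_lo, "Ld": self.brightness_ld},
            background_counts=self.background_counts,
            pixel_size_nm=self.pixel_size_nm,
        )


@dataclass
class RunConfig:
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    spectral: SpectralModelParams = field(default_factory=SpectralModelParams)
    seed: int = 0
    output_dir: Path = Path("out")
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def block(name, factory):
            data = raw.get(name) or {}
            if name == "simulation" and "shape" in data:
                data = {**data, "shape": tuple(data["shape"])}
            return factory(**data)

        return cls(
            objective=block("objective", ObjectiveConfig),
            gp=block("gp", GPConfig),
            segmentation=block("segmentation", SegmentationParams),
            simulation=block("simulation", SimulationParams),
            spectral=block("spectral", SpectralModelParams),
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "out")),
            verbosity=int(raw.get("verbosity", 1)),
        )

    def to_dict(self) -> dict:
        d = {
            "objective": asdict(self.objective),
            "gp": asdict(self.gp),
            "segmentation": asdict(self.segmentation),
            "simulation": asdict(self.simulation),
            "spectral": asdict(self.spectral),
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "verbosity": self.verbosity,
        }
        d["simulation"]["shape"] = list(d["simulation"]["shape"])
        return d

    def config_hash(self) -> str:
        """Short stable digest embedded in every output artifact."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {"version": __version__, "config_hash": self.config_hash(), "seed": self.seed}
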