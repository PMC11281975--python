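"""Configuration objects for the synthetic generator and the full pipeline.

One YAML file can drive everything; dataclass defaults encode the study
design (33 analysis years, 20 plots per species split over four topographic
categories, four injected non-consecutive drought years).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

CATEGORIES = ("SS", "NS", "PL", "VA")
SPECIES = ("PCAB", "PISY")

#: growing-season start threshold (°C) on the mean of the five preceding days
SPECIES_THRESHOLDS = {"PISY": 12.0, "PCAB": 9.0}


@dataclass
class NoiseConfig:
    """AR(1) noise settings for ring widths (lognormal) and NDVI (Gaussian)."""

    ring_ar: float = 0.3
    ring_sd: float = 0.10      # sd of log-width innovations
    ndvi_ar: float = 0.2
    ndvi_sd: float = 0.02      # sd of per-scene NDVI innovations


@dataclass
class SimulationConfig:
    seed: int = 0
    year_start: int = 1985
    year_end: int = 2017
    n_plots_per_species: int = 20
    categories: Sequence[str] = CATEGORIES
    drought_years: Sequence[int] = (1994, 2003, 2006, 2015)
    sr_anomaly: float = 2.5        # injected JJA SR excess, baseline SDs
    growth_drop: float = 0.20      # fractional ring-width loss at lag 0
    legacy: Sequence[float] = (0.10, 0.05, 0.02, 0.01)   # lags 1..4
    ndvi_drop: float = 0.05
    ndvi_rebound: float = 0.02     # lag 1-2 NDVI excess
    ndvi_trend: float = 0.002      # per-year linear drift
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    cloud_fraction: float = 0.3
    n_trees_per_plot: int = 26
    # age curve w(a) = age_amp * exp(-a / age_tau) + age_base, in mm
    age_amp: float = 2.0
    age_tau: float = 80.0
    age_base: float = 0.5
    # climate coupling of ring width to standardized JJA SR / SM anomalies
    coupling_sr: float = -0.04
    coupling_sm: float = 0.04

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        for y in self.drought_years:
            if not (self.year_start <= y <= self.year_end):
                raise ValueError(f"drought year {y} outside simulated range "
                                 f"{self.year_start}-{self.year_end}")
        ys = sorted(self.drought_years)
        for a, b in zip(ys, ys[1:]):
            if b - a < 2:
                raise ValueError(f"drought years {a} and {b} are consecutive")
        for name in ("growth_drop", "ndvi_drop", "ndvi_rebound", "cloud_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} not in [0, 1)")
        for v in self.legacy:
            if not 0.0 <= v < 1.0:
                raise ValueError(f"legacy fraction {v} not in [0, 1)")
        if isinstance(self.noise, dict):
            self.noise = NoiseConfig(**self.noise)

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Exactly one input mode: ``synthetic=True`` (inputs generated under the
    output directory) or explicit paths to RWL/scene/climate/metadata files.
    """

    seed: int = 0
    synthetic: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rwl_dir: str | None = None
    scenes_path: str | None = None
    daily_climate_path: str | None = None
    monthly_climate_path: str | None = None
    metadata_path: str | None = None
    species_thresholds: dict = field(default_factory=lambda: dict(SPECIES_THRESHOLDS))
    spline_wavelength: int = 30
    min_sample_depth: int = 5
    spei_scale: int = 4
    latitude: float = 49.5
    n_events: int = 4
    event_variable: str = "SR"       # SR (max) or SM (min)
    sea_lag: int = 4
    sea_resamples: int = 1000
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        for name in ("spline_wavelength", "spei_scale", "n_events",
                     "sea_lag", "sea_resamples", "min_sample_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.synthetic:
            missing = [n for n in ("rwl_dir", "scenes_path", "daily_climate_path",
                                   "monthly_climate_path", "metadata_path")
                       if getattr(self, n) is None]
            if missing:
                raise ValueError("data mode requires input paths; missing: "
                                 + ", ".join(missing))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
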