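"""Synthetic NDVI-by-elevation datasets with the statistical structure of
intertidal remote-sensing maps.

On a tidal flat, elevation relative to mean water level (MWL) sets
low-tide exposure and hence desiccation stress for seagrass.  The
generator emulates the structure of a multi-year NDVI map stack over such
a gradient: pixels with fixed (uniformly distributed) elevations, assigned
to 0.1-m elevation classes, whose per-class NDVI distribution moves from
unimodal-high (healthy meadow) through bimodal (patchy meadow/bare mosaic)
to unimodal-low (bare flat) with increasing elevation.  Per class the NDVI
is a two-component Gaussian mixture truncated to the NDVI range [-1, 1];
the high-state mixing weight is a monotone non-increasing function of
elevation.  This is a statistical stand-in, not a radiative-transfer
model: it exists so the potential-analysis arm of the pipeline can be
exercised, with known ground truth, without any satellite data.

An optional mechanistic mode instead drives NDVI from simulated shoot
densities of the dynamical model, with elevation mapped to the natural
mortality rate (desiccation proxy) and NDVI a saturating function of
shoot density plus observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import ModelParameters
from .ensemble import EnsembleConfig, StressClassedSamples, run_ensemble

__all__ = [
    "FieldGeneratorConfig",
    "FieldDataset",
    "generate_field_dataset",
    "link_elevation_to_mortality",
    "ElevationMortalityMap",
]

NDVI_RANGE = (-1.0, 1.0)


@dataclass(frozen=True)
class FieldGeneratorConfig:
    """Structure and mixture specification of the synthetic map stack.

    The default high/low NDVI states (0.55 +/- 0.08 dense Zostera meadow,
    0.05 +/- 0.05 bare wet sediment) are typical end-member values for
    intertidal seagrass scenes.  The high-state weight is 1 below
    ``bimodal_zone[0]``, falls linearly to 0 across the zone, and is 0
    above it, giving unimodal-high, bimodal, unimodal-low class bands.
    """

    years: tuple[int, ...] = (2007, 2009, 2011, 2013)
    pixels_per_year: int = 17672
    elevation_min: float = -0.6      # m relative to MWL
    elevation_max: float = 0.3
    class_width: float = 0.1
    high_ndvi_mean: float = 0.55
    high_ndvi_sd: float = 0.08
    low_ndvi_mean: float = 0.05
    low_ndvi_sd: float = 0.05
    bimodal_zone: tuple[float, float] = (-0.3, 0.0)
    seed: int = 0
    mode: str = "mixture"            # "mixture" | "mechanistic"
    mechanistic_replicates: int = 25
    mechanistic_burn_in_years: int = 200

    def __post_init__(self) -> None:
        if self.pixels_per_year < 1 or not self.years:
            raise ValueError("need at least one pixel and one year")
        span = self.elevation_max - self.elevation_min
        if span <= 0 or self.class_width <= 0:
            raise ValueError("elevation range and class width must be positive")
        n = span / self.class_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("class_width must divide the elevation range")
        problems = []
        for name in ("high_ndvi_mean", "low_ndvi_mean"):
            v = getattr(self, name)
            if not NDVI_RANGE[0] <= v <= NDVI_RANGE[1]:
                problems.append(f"{name}={v} outside NDVI range")
        for name in ("high_ndvi_sd", "low_ndvi_sd"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        if not self.bimodal_zone[0] < self.bimodal_zone[1]:
            problems.append(f"bimodal_zone {self.bimodal_zone} must be increasing")
        if problems:
            raise ValueError("invalid mixture spec: " + "; ".join(problems))
        if self.mode not in ("mixture", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_classes(self) -> int:
        return round((self.elevation_max - self.elevation_min) / self.class_width)

    def class_edges(self) -> np.ndarray:
        return self.elevation_min + self.class_width * np.arange(self.n_classes + 1)

    def class_midpoints(self) -> np.ndarray:
        edges = self.class_edges()
        # rounded so midpoints are stable keys (CSV round trips, selection)
        return np.round(0.5 * (edges[:-1] + edges[1:]), 10)

    def high_state_weight(self, elevation: np.ndarray | float) -> np.ndarray:
        """Mixing weight of the high-NDVI state, monotone in elevation."""
        lo, hi = self.bimodal_zone
        e = np.asarray(elevation, dtype=float)
        return np.clip((hi - e) / (hi - lo), 0.0, 1.0)

    def expected_modality(self, min_weight: float = 0.1) -> np.ndarray:
        """Configured number of modes per class (evaluated at midpoints).

        A class counts as bimodal when both mixture components carry at
        least ``min_weight`` of its pixels.
        """
        w = self.high_state_weight(self.class_midpoints())
        return np.where(np.minimum(w, 1.0 - w) >= min_weight, 2, 1)


@dataclass(frozen=True)
class FieldDataset:
    """Synthetic NDVI records: one row per (pixel, year)."""

    records: pd.DataFrame  # pixel_id, year, elevation_m, elevation_class, ndvi
    config: FieldGeneratorConfig

    def __post_init__(self) -> None:
        ndvi = self.records["ndvi"]
        if ndvi.min() < NDVI_RANGE[0] or ndvi.max() > NDVI_RANGE[1]:
            raise ValueError("NDVI outside [-1, 1]")

    def to_csv(self, path: str | Path) -> None:
        out = self.records.rename(columns={"elevation_class": "class"})
        out.to_csv(path, index=False)

    def to_samples(self) -> StressClassedSamples:
        """Pool all years per elevation class for potential analysis."""
        mids = self.config.class_midpoints()
        obs = tuple(
            self.records.loc[self.records["elevation_class"] == m, "ndvi"].to_numpy(float)
            for m in mids
        )
        return StressClassedSamples(
            class_name="elevation_m",
            class_values=mids,
            observations=obs,
            observable="ndvi",
            provenance="synthetic_field",
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a = (NDVI_RANGE[0] - mean) / sd
    b = (NDVI_RANGE[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_field_dataset(
    cfg: FieldGeneratorConfig,
    parameters: ModelParameters | None = None,
) -> FieldDataset:
    """Generate the synthetic map stack described by ``cfg``.

    Pixel elevations are drawn once, uniformly over the elevation range,
    and reused across years (a pixel keeps its position on the flat);
    NDVI is drawn independently per pixel and year, so years with the same
    mixture spec are exchangeable.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.pixels_per_year
    elevation = rng.uniform(cfg.elevation_min, cfg.elevation_max, size=n)
    edges = cfg.class_edges()
    mids = cfg.class_midpoints()
    class_idx = np.clip(np.searchsorted(edges, elevation, side="right") - 1, 0, len(mids) - 1)

    if cfg.mode == "mechanistic":
        ndvi_by_year = _mechanistic_ndvi(cfg, elevation, rng, parameters)
    else:
        w_high = cfg.high_state_weight(elevation)
        ndvi_by_year = []
        for _ in cfg.years:
            is_high = rng.random(n) < w_high
            ndvi = np.empty(n)
            k = int(is_high.sum())
            ndvi[is_high] = _truncated_normal(rng, cfg.high_ndvi_mean, cfg.high_ndvi_sd, k)
            ndvi[~is_high] = _truncated_normal(rng, cfg.low_ndvi_mean, cfg.low_ndvi_sd, n - k)
            ndvi_by_year.append(ndvi)

    frames = [
        pd.DataFrame(
            {
                "pixel_id": np.arange(n),
                "year": year,
                "elevation_m": elevation,
                "elevation_class": mids[class_idx],
                "ndvi": ndvi,
            }
        )
        for year, ndvi in zip(cfg.years, ndvi_by_year)
    ]
    return FieldDataset(records=pd.concat(frames, ignore_index=True), config=cfg)


def _mechanistic_ndvi(
    cfg: FieldGeneratorConfig,
    elevation: np.ndarray,
    rng: np.random.Generator,
    parameters: ModelParameters | None,
    *,
    noise_sd: float = 0.05,
    half_saturation_fraction: float = 0.2,
) -> list[np.ndarray]:
    """NDVI from simulated shoot densities (optional generator mode).

    Per elevation class the dynamical model is run as a small stochastic
    ensemble at the mortality mapped from the class midpoint; pixel NDVI
    values are drawn from the class's pool of yearly shoot densities
    through a saturating reflectance curve plus Gaussian noise, clipped to
    the NDVI range.  Scaled for qualitative structure, not pixel realism.
    """
    p = parameters if parameters is not None else ModelParameters()
    mids = cfg.class_midpoints()
    m_n = link_elevation_to_mortality(mids)
    samples = run_ensemble(
        p,
        EnsembleConfig(
            m_n_grid=np.sort(np.unique(m_n)),
            replicates=cfg.mechanistic_replicates,
            burn_in_years=cfg.mechanistic_burn_in_years,
            sample_years=len(cfg.years),
            seed=int(rng.integers(2**31 - 1)),
        ),
    )
    pool_by_class = {
        mid: samples.flat(int(np.searchsorted(samples.class_values, mn)))
        for mid, mn in zip(mids, m_n)
    }
    edges = cfg.class_edges()
    class_idx = np.clip(np.searchsorted(edges, elevation, side="right") - 1, 0, len(mids) - 1)
    k_half = half_saturation_fraction * p.Z_max
    out = []
    for _ in cfg.years:
        z = np.array(
            [rng.choice(pool_by_class[mids[i]]) for i in class_idx]
        )
        ndvi = cfg.low_ndvi_mean + (cfg.high_ndvi_mean - cfg.low_ndvi_mean) * z / (z + k_half)
        ndvi = ndvi + rng.normal(0.0, noise_sd, size=len(z))
        out.append(np.clip(ndvi, *NDVI_RANGE))
    return out


@dataclass(frozen=True)
class ElevationMortalityMap:
    """Piecewise-linear monotone map from elevation (m MWL) to mortality.

    The default sends the lowest flats (-0.6 m, negligible exposure) to
    the default natural mortality 0.007 day^-1 and the highest ones
    (+0.3 m, strong desiccation) to 0.15 day^-1, the top of the ensemble
    mortality gradient.
    """

    points: tuple[tuple[float, float], ...] = ((-0.6, 0.007), (0.3, 0.15))

    def __post_init__(self) -> None:
        e = np.array([q[0] for q in self.points])
        m = np.array([q[1] for q in self.points])
        if len(self.points) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("mapping needs >= 2 points with strictly increasing elevations")
        if np.any(np.diff(m) < 0) or np.any(m < 0):
            raise ValueError("mortality mapping must be non-negative and monotone non-decreasing")

    def __call__(self, elevation: np.ndarray | float) -> np.ndarray | float:
        e = np.array([q[0] for q in self.points])
        m = np.array([q[1] for q in self.points])
        out = np.interp(elevation, e, m)
        return float(out) if np.isscalar(elevation) else out


def link_elevation_to_mortality(
    elevation: np.ndarray | float,
    mapping: ElevationMortalityMap | Sequence[tuple[float, float]] | None = None,
) -> np.ndarray | float:
    """Map tidal-flat elevation to the natural seagrass mortality rate.

    Elevation controls low-tide air exposure, hence desiccation stress,
    modelled as added natural mortality.  ``mapping`` may be an
    :class:`ElevationMortalityMap` or a sequence of (elevation, m_n)
    breakpoints; it must be monotone non-decreasing.
    """
    if mapping is None:
        mapping = ElevationMortalityMap()
    elif not isinstance(mapping, ElevationMortalityMap):
        mapping = ElevationMortalityMap(points=tuple((float(a), float(b)) for a, b in mapping))
    return mapping(elevation)
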