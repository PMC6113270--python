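"""Potential analysis: attractor detection from stress-classed samples.

Treating the observable ``z`` (shoot density or NDVI) as draws from a
stochastic system ``dz = -U'(z) dt + sigma dW``, the stationary density
``Pd(z)`` maps to an effective potential ``U(z) = -log Pd(z)``: states of
high occurrence are wells of ``U`` ("attractors"), intervening lows of
occurrence are barriers ("repellors").  Per stress class the density is
estimated with a Gaussian kernel whose bandwidth is the normal-reference
bin width ``h = 1.06 * s * n**(-1/5)``, and wells/barriers are located by
automated peak search on the density with a prominence floor.

The method is diagnostic, not inferential: multimodality indicates strong
feedback-mediated dynamics (alternative basins *or* slow-fast cycles, which
dwell long in their extreme states), without distinguishing the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .ensemble import StressClassedSamples

__all__ = [
    "bin_width",
    "estimate_density",
    "find_attractors",
    "potential_landscape",
    "ClassLandscape",
    "PotentialLandscape",
]

#: Density floor keeping U = -log(Pd) finite; peak logic runs on Pd itself,
#: so the floor never moves an attractor or repellor.
DENSITY_FLOOR = 1e-12

#: Evaluation-grid size and half-width (in bandwidths) beyond the data range.
GRID_POINTS = 512
GRID_PAD_BANDWIDTHS = 3.0


def bin_width(values: Sequence[float] | np.ndarray) -> float:
    """Normal-reference bandwidth / bin width ``1.06 * s * n**(-1/5)``.

    ``s`` is the sample standard deviation (n-1 denominator).  Degenerate
    samples (fewer than two values, or zero spread) have no meaningful
    scale and raise ``ValueError``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    s = float(values.std(ddof=1))
    # ptp guards constant samples whose std is pure mean-roundoff noise
    if not s > 0 or np.ptp(values) == 0:
        raise ValueError("sample standard deviation is zero: no scale for a bin width")
    return 1.06 * s * n ** (-0.2)


def estimate_density(
    values: Sequence[float] | np.ndarray,
    grid: np.ndarray,
    h: float,
) -> np.ndarray:
    """Gaussian kernel density of ``values`` on ``grid`` with bandwidth ``h``.

    Plain kernel sum ``Pd(x) = (1/(n h)) sum_i phi((x - z_i) / h)``,
    evaluated in data blocks to bound memory for large samples.
    """
    values = np.asarray(values, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if not h > 0:
        raise ValueError(f"bandwidth must be > 0, got {h}")
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    out = np.zeros_like(grid)
    norm = 1.0 / (values.size * h * np.sqrt(2.0 * np.pi))
    for start in range(0, values.size, 8192):
        block = values[start:start + 8192]
        u = (grid[:, None] - block[None, :]) / h
        out += np.exp(-0.5 * u * u).sum(axis=1)
    return norm * out


def find_attractors(
    density: np.ndarray,
    grid: np.ndarray,
    prominence_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Attractor and repellor positions from a density on a grid.

    Attractors are local maxima of the density with topographic prominence
    of at least ``prominence_fraction * max(density)`` (suppressing
    sampling-noise peaks); repellors are the density minima between each
    adjacent attractor pair, so they strictly alternate with attractors.
    A flat or single-peak density yields zero repellors; a density with no
    qualifying peak yields two empty arrays.
    """
    density = np.asarray(density, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if density.size != grid.size or density.size < 3:
        raise ValueError("need matching density/grid arrays of length >= 3")
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    peak_idx, _ = find_peaks(density, prominence=prominence_fraction * density.max())
    attractors = grid[peak_idx]
    repellors = []
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        k = a + int(np.argmin(density[a:b + 1]))
        repellors.append(grid[k])
    return attractors, np.asarray(repellors, dtype=float)


@dataclass(frozen=True)
class ClassLandscape:
    """Potential landscape of a single stress class."""

    class_value: float
    n_obs: int
    h: float | None
    grid: np.ndarray | None
    density: np.ndarray | None
    potential: np.ndarray | None          # U = -log(max(Pd, floor))
    attractors: np.ndarray
    repellors: np.ndarray
    error: str | None = None              # set when the class was degenerate

    @property
    def ok(self) -> bool:
        return self.error is None

    @property
    def n_attractors(self) -> int:
        return int(len(self.attractors))

    def summary(self) -> dict:
        return {
            "class": self.class_value,
            "n_obs": self.n_obs,
            "h": self.h,
            "attractors": [float(a) for a in self.attractors],
            "repellors": [float(r) for r in self.repellors],
            "error": self.error,
        }


@dataclass(frozen=True)
class PotentialLandscape:
    """Per-class potential landscapes along a stress gradient."""

    class_name: str
    classes: tuple[ClassLandscape, ...]
    prominence_fraction: float

    def __iter__(self):
        return iter(self.classes)

    def attractor_counts(self) -> np.ndarray:
        return np.array([c.n_attractors for c in self.classes])

    def summary(self) -> list[dict]:
        return [c.summary() for c in self.classes]


def potential_landscape(
    samples: StressClassedSamples,
    prominence_fraction: float = 0.05,
    *,
    clip_range: tuple[float, float] | None = None,
    n_grid: int = GRID_POINTS,
) -> PotentialLandscape:
    """Run the full potential analysis per stress class.

    Per class: bandwidth from :func:`bin_width`, Gaussian KDE on a grid of
    ``n_grid`` points spanning the data padded by three bandwidths,
    ``U = -log(Pd)`` with a floor keeping it finite, then automated peak
    search.  Classes with degenerate samples are flagged (``error`` set)
    and the remaining classes are still processed.  ``clip_range`` clamps
    observations first (used for NDVI, which is bounded in [-1, 1]).
    """
    if not 0 < prominence_fraction < 1:
        raise ValueError("prominence_fraction must be in (0, 1)")
    out: list[ClassLandscape] = []
    for k, class_value in enumerate(samples.class_values):
        values = samples.flat(k)
        if clip_range is not None:
            values = np.clip(values, *clip_range)
        try:
            h = bin_width(values)
        except ValueError as err:
            out.append(
                ClassLandscape(
                    class_value=float(class_value), n_obs=values.size,
                    h=None, grid=None, density=None, potential=None,
                    attractors=np.empty(0), repellors=np.empty(0),
                    error=str(err),
                )
            )
            continue
        pad = GRID_PAD_BANDWIDTHS * h
        grid = np.linspace(values.min() - pad, values.max() + pad, n_grid)
        density = estimate_density(values, grid, h)
        potential = -np.log(np.maximum(density, DENSITY_FLOOR))
        attractors, repellors = find_attractors(density, grid, prominence_fraction)
        out.append(
            ClassLandscape(
                class_value=float(class_value), n_obs=values.size,
                h=h, grid=grid, density=density, potential=potential,
                attractors=attractors, repellors=repellors,
            )
        )
    return PotentialLandscape(
        class_name=samples.class_name,
        classes=tuple(out),
        prominence_fraction=prominence_fraction,
    )
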