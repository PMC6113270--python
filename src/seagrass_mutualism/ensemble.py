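"""Stochastic replicate ensembles over a mortality gradient.

Environmental variability enters through the seagrass carrying capacity:
replicate ``i`` carries a piecewise-constant noisy capacity
``Z_max * (1 + eps)`` with ``eps ~ Normal(0, sigma^2)`` truncated to keep
the capacity positive — one draw for the burn-in phase and an independent
redraw at the start of every sample year.  Seagrass relaxes toward its
capacity within days, so each yearly sample tracks that year's capacity
and the pooled samples of a class are effectively independent draws, the
regime the kernel-density stage assumes.  Every replicate is integrated at
every mortality value on the grid; after burn-in the shoot density is
recorded instantaneously at the end of each sample year.  The pooled
yearly samples per mortality class are the input to the potential
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ModelParameters
from .simulate import DAYS_PER_YEAR, ScenarioConfig, integrate

__all__ = ["EnsembleConfig", "StressClassedSamples", "run_ensemble", "default_mortality_grid"]


def default_mortality_grid() -> np.ndarray:
    """Mortality gradient: 61 values, 0 to 0.15 day^-1 in steps of 0.0025."""
    return np.round(np.arange(61) * 0.0025, 10)


@dataclass(frozen=True)
class EnsembleConfig:
    """Gradient, replication, noise and sampling protocol for an ensemble."""

    m_n_grid: np.ndarray = field(default_factory=default_mortality_grid)
    replicates: int = 625
    burn_in_years: int = 200
    sample_years: int = 50
    sigma: float = 0.15       # relative SD of the per-replicate Z_max draw
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        grid = np.asarray(self.m_n_grid, dtype=float)
        object.__setattr__(self, "m_n_grid", grid)
        if grid.ndim != 1 or len(grid) == 0 or not np.all(np.diff(grid) > 0) and len(grid) > 1:
            raise ValueError("m_n_grid must be a non-empty strictly increasing 1-D array")
        if np.any(grid < 0):
            raise ValueError("m_n values must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.burn_in_years < 0 or self.sample_years < 1:
            raise ValueError("burn_in_years must be >= 0 and sample_years >= 1")


@dataclass(frozen=True)
class StressClassedSamples:
    """Scalar observations grouped by a stressor class.

    ``observations[k]`` holds the samples of class ``class_values[k]``:
    a (replicates, years) array for model ensembles, or a flat 1-D array
    for field-style data.  ``flat(k)`` always returns the pooled 1-D view.
    """

    class_name: str                     # e.g. "m_n" or "elevation_m"
    class_values: np.ndarray            # ordered stressor values
    observations: tuple[np.ndarray, ...]
    observable: str = "Z"               # "Z" (shoots m^-2) or "ndvi"
    provenance: str = "model"           # "model" | "synthetic_field"
    n_failures: int = 0

    def __post_init__(self) -> None:
        if len(self.observations) != len(self.class_values):
            raise ValueError("one observation array required per class")
        for v, obs in zip(self.class_values, self.observations):
            if obs.size == 0:
                raise ValueError(f"class {v} has no observations")
            if not np.all(np.isfinite(obs)):
                raise ValueError(f"class {v} contains non-finite observations")

    def flat(self, index: int) -> np.ndarray:
        return np.asarray(self.observations[index]).ravel()

    def to_long_dataframe(self) -> pd.DataFrame:
        frames = []
        for v, obs in zip(self.class_values, self.observations):
            obs = np.asarray(obs)
            if obs.ndim == 2:
                rep, yr = np.divmod(np.arange(obs.size), obs.shape[1])
                frames.append(
                    pd.DataFrame(
                        {"class_value": v, "replicate": rep, "year": yr + 1, "value": obs.ravel()}
                    )
                )
            else:
                frames.append(pd.DataFrame({"class_value": v, "value": obs}))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)

    @staticmethod
    def read_csv(path: str | Path, class_name: str = "class_value",
                 observable: str = "Z", provenance: str = "model") -> "StressClassedSamples":
        df = pd.read_csv(path)
        if "class_value" not in df.columns or "value" not in df.columns:
            raise ValueError("expected columns 'class_value' and 'value'")
        values = np.array(sorted(df["class_value"].unique()), dtype=float)
        obs = tuple(
            df.loc[df["class_value"] == v, "value"].to_numpy(float) for v in values
        )
        return StressClassedSamples(class_name, values, obs,
                                    observable=observable, provenance=provenance)


def draw_capacity_multipliers(cfg: EnsembleConfig) -> np.ndarray:
    """Carrying-capacity multipliers ``1 + eps``, shape (replicates, 1 + years).

    Column 0 is the replicate's burn-in capacity; columns 1.. are the
    yearly redraws for the sample phase.  One independent RNG stream per
    replicate, spawned from the master seed, so serial and parallel
    execution produce identical draws.  Draws are rejected (redrawn) until
    the multiplier is positive.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    out = np.ones((cfg.replicates, 1 + cfg.sample_years))
    if cfg.sigma == 0:
        return out
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        for j in range(out.shape[1]):
            mult = 1.0 + rng.normal(0.0, cfg.sigma)
            while mult <= 0.0:
                mult = 1.0 + rng.normal(0.0, cfg.sigma)
            out[i, j] = mult
    return out


def _run_replicate(
    p: ModelParameters, m_n: float, mults: np.ndarray, cfg: EnsembleConfig
) -> np.ndarray:
    """Burn in at the base capacity, then one segment per sample year with
    that year's capacity; returns end-of-year shoot densities."""
    base = p.replace(m_n=m_n, Z_max=p.Z_max * float(mults[0]))
    if cfg.burn_in_years > 0:
        traj = integrate(
            base,
            ScenarioConfig(
                mutualism=True,
                duration_days=cfg.burn_in_years * DAYS_PER_YEAR,
                output_step_days=cfg.burn_in_years * DAYS_PER_YEAR,
                rtol=cfg.rtol, atol=cfg.atol,
            ),
        )
        state = traj.final_state
    else:
        from .simulate import default_initial_state

        state = default_initial_state(base, mutualism=True)
    zs = np.empty(cfg.sample_years)
    for y in range(cfg.sample_years):
        py = p.replace(m_n=m_n, Z_max=p.Z_max * float(mults[1 + y]))
        seg = integrate(
            py,
            ScenarioConfig(
                mutualism=True,
                duration_days=DAYS_PER_YEAR,
                output_step_days=DAYS_PER_YEAR,
                initial_state=state,
                rtol=cfg.rtol, atol=cfg.atol,
            ),
        )
        state = seg.final_state
        zs[y] = state.Z
    return zs


def run_ensemble(p: ModelParameters, cfg: EnsembleConfig) -> StressClassedSamples:
    """Integrate the replicate ensemble (mutualism on) over the mortality grid.

    Returns per-class (replicates x sample_years) shoot-density samples,
    recorded instantaneously at the end of each year after burn-in.
    Replicates whose integration fails are skipped and counted; if more
    than ``max_failure_fraction`` of runs fail, the ensemble errors out.
    """
    multipliers = draw_capacity_multipliers(cfg)
    n_runs = 0
    n_failed = 0
    per_class: list[np.ndarray] = []
    for m_n in cfg.m_n_grid:
        rows = []
        for i in range(cfg.replicates):
            n_runs += 1
            try:
                rows.append(_run_replicate(p, float(m_n), multipliers[i], cfg))
            except RuntimeError:
                n_failed += 1
                continue
        if not rows:
            raise RuntimeError(f"all replicates failed at m_n = {m_n}")
        per_class.append(np.vstack(rows))
    if n_failed > cfg.max_failure_fraction * n_runs:
        raise RuntimeError(
            f"{n_failed}/{n_runs} ensemble runs failed "
            f"(> {100 * cfg.max_failure_fraction:.0f}% tolerated)"
        )
    return StressClassedSamples(
        class_name="m_n",
        class_values=np.asarray(cfg.m_n_grid, dtype=float),
        observations=tuple(per_class),
        observable="Z",
        provenance="model",
        n_failures=n_failed,
    )
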