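"""Bifurcation scans and per-parameter sensitivity analysis.

The control parameter of primary interest is the natural seagrass mortality
``m_n``, a proxy for low-tide desiccation stress: below a critical value the
mutualism holds the system at a vegetated equilibrium, above it the system
falls into slow-fast collapse-and-recovery cycles.  ``scan_mortality``
sweeps ``m_n`` with state continuation (forward and backward, to expose
hysteresis if any); ``find_cycle_threshold`` locates the cycle onset for an
arbitrary parameter by bisection; ``sensitivity_analysis`` expresses, for
every model parameter, how far it must move from its default before cycles
appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import PARAMETER_NAMES, ModelParameters, ModelState
from .simulate import (
    DAYS_PER_YEAR,
    RegimeClassification,
    RegimeLabel,
    ScenarioConfig,
    Trajectory,
    classify_regime,
    default_initial_state,
    integrate,
)

__all__ = [
    "BifurcationResult",
    "CycleThreshold",
    "SensitivityRecord",
    "AmbiguousThresholdError",
    "scan_mortality",
    "find_cycle_threshold",
    "sensitivity_analysis",
]

# Warm-started scans re-seed vanishingly small (underflowed) shoot densities
# at this fraction of Z_max: a dormant propagule bank, numerically.
_Z_RESEED_FRACTION = 1e-12


class AmbiguousThresholdError(RuntimeError):
    """More than one regime transition inside the searched interval.

    ``brackets`` holds every (low, high) parameter bracket across which the
    cycling label flips, so the caller can pick or refine rather than the
    search guessing for them.
    """

    def __init__(self, parameter: str, brackets: list[tuple[float, float]]):
        self.parameter = parameter
        self.brackets = brackets
        super().__init__(
            f"{len(brackets)} regime transitions for {parameter!r} in the "
            f"searched interval: {brackets}"
        )


@dataclass(frozen=True)
class BifurcationResult:
    """Per-value regime classification along a parameter sweep."""

    parameter: str
    values: np.ndarray                      # in scan order
    classifications: tuple[RegimeClassification, ...]
    direction: str                          # "forward" | "backward"
    mutualism: bool
    continuation: bool

    def __post_init__(self) -> None:
        d = np.diff(self.values)
        ok = np.all(d > 0) if self.direction == "forward" else np.all(d < 0)
        if not ok:
            raise ValueError(f"values must be strictly monotone for direction={self.direction!r}")
        if len(self.classifications) != len(self.values):
            raise ValueError("one classification required per scanned value")

    @property
    def labels(self) -> list[RegimeLabel]:
        return [c.label for c in self.classifications]

    def first_value_with(self, label: RegimeLabel) -> float | None:
        """Smallest scanned parameter value carrying ``label`` (or None)."""
        hits = [v for v, c in zip(self.values, self.classifications) if c.label is label]
        return min(hits) if hits else None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter: self.values,
                "label": [c.label.value for c in self.classifications],
                "z_min": [c.z_min for c in self.classifications],
                "z_mean": [c.z_mean for c in self.classifications],
                "z_max": [c.z_max for c in self.classifications],
                "period_days": [c.period_days for c in self.classifications],
            }
        )


@dataclass(frozen=True)
class CycleThreshold:
    """Bisection-refined onset of sustained cycles for one parameter."""

    parameter: str
    value: float               # bracket midpoint
    bracket: tuple[float, float]
    default: float
    cycles_in_bracket_side: str  # "above" | "below": where cycles lie

    @property
    def percent_change(self) -> float:
        return 100.0 * abs(self.value - self.default) / self.default


@dataclass(frozen=True)
class SensitivityRecord:
    """How far one parameter must move from default before cycles appear."""

    parameter: str
    default: float
    threshold: float | None        # None: no cycle onset in search range
    percent_change: float | None

    def __post_init__(self) -> None:
        if self.percent_change is not None and self.percent_change < 0:
            raise ValueError("percent_change must be >= 0")


def _classification_at(
    p: ModelParameters,
    mutualism: bool,
    transient_years: float,
    window_years: float,
    initial_state: ModelState | None,
    output_step_days: float,
) -> tuple[RegimeClassification, Trajectory]:
    cfg = ScenarioConfig(
        mutualism=mutualism,
        duration_days=(transient_years + window_years) * DAYS_PER_YEAR,
        initial_state=initial_state,
        output_step_days=output_step_days,
    )
    traj = integrate(p, cfg)
    cls = classify_regime(traj, transient_days=transient_years * DAYS_PER_YEAR)
    return cls, traj


def scan_mortality(
    p: ModelParameters,
    lo: float = 0.0,
    hi: float = 0.35,
    n_steps: int = 150,
    direction: str = "forward",
    mutualism: bool = True,
    *,
    continuation: bool = True,
    transient_years: float = 200.0,
    window_years: float = 100.0,
    output_step_days: float = 5.0,
) -> BifurcationResult:
    """Sweep the natural mortality ``m_n`` and classify the regime per value.

    With ``continuation=True`` each value starts from the previous value's
    final state, the standard protocol for exposing alternative equilibria
    when combined with a backward sweep; ``continuation=False`` cold-starts
    every value from the sparse-colonisation state.
    """
    if not (0 <= lo < hi):
        raise ValueError("require 0 <= lo < hi")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    values = np.linspace(lo, hi, n_steps)
    if direction == "backward":
        values = values[::-1]

    state: ModelState | None = None
    out: list[RegimeClassification] = []
    for i, m_n in enumerate(values):
        pi = p.replace(m_n=float(m_n))
        try:
            cls, traj = _classification_at(
                pi, mutualism, transient_years, window_years, state, output_step_days
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"mortality scan failed at step {i} (m_n = {m_n:.6g}): {err}"
            ) from err
        out.append(cls)
        if continuation:
            z, s, om, l = traj.final_state
            state = ModelState(max(z, _Z_RESEED_FRACTION * p.Z_max), s, om, l)
        else:
            state = None
    return BifurcationResult(
        parameter="m_n",
        values=values,
        classifications=tuple(out),
        direction=direction,
        mutualism=mutualism,
        continuation=continuation,
    )


def _valid_params(p: ModelParameters, name: str, value: float) -> ModelParameters | None:
    try:
        return p.replace(**{name: value})
    except ValueError:
        return None


def find_cycle_threshold(
    p: ModelParameters,
    parameter: str,
    interval: tuple[float, float],
    tol: float = 1e-4,
    *,
    mutualism: bool = True,
    n_coarse: int = 11,
    transient_years: float = 500.0,
    window_years: float = 200.0,
    output_step_days: float = 5.0,
    _cache: dict[float, bool] | None = None,
) -> CycleThreshold | None:
    """Bisect for the parameter value at which sustained cycles first occur.

    All other parameters stay at their values in ``p`` and every trial run
    cold-starts from the sparse-colonisation state, so the result is a
    property of the attractor structure, not of continuation history.  The
    interval is first probed on a coarse grid to bracket the transition;
    exactly one cycling/non-cycling flip is then refined by bisection until
    the bracket is narrower than ``tol`` (absolute, in the parameter's
    units), and the bracket midpoint is returned.  Returns ``None`` when
    the whole interval carries a single regime; raises
    :class:`AmbiguousThresholdError` when more than one flip is found.

    Grid values at which the parameter set is invalid (e.g. ``S_min``
    pushed above ``S_max``) are treated as outside the searchable range.
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    if n_coarse < 2:
        raise ValueError("n_coarse must be >= 2")

    cache: dict[float, bool] = {} if _cache is None else _cache

    def cycles_at(value: float) -> bool | None:
        if value in cache:
            return cache[value]
        pi = _valid_params(p, parameter, value)
        if pi is None:
            return None
        cls, _ = _classification_at(
            pi, mutualism, transient_years, window_years, None, output_step_days
        )
        result = cls.label is RegimeLabel.LIMIT_CYCLE
        cache[value] = result
        return result

    if lo > 0 and hi / lo >= 10.0:
        grid = np.geomspace(lo, hi, n_coarse)
    else:
        grid = np.linspace(lo, hi, n_coarse)
    probed = [(float(v), cycles_at(float(v))) for v in grid]
    probed = [(v, c) for v, c in probed if c is not None]
    if len(probed) < 2:
        return None
    brackets = [
        (probed[i][0], probed[i + 1][0])
        for i in range(len(probed) - 1)
        if probed[i][1] != probed[i + 1][1]
    ]
    if not brackets:
        return None
    if len(brackets) > 1:
        raise AmbiguousThresholdError(parameter, brackets)

    a, b = brackets[0]
    while b - a > tol:
        mid = 0.5 * (a + b)
        if cycles_at(mid) == cycles_at(a):
            a = mid
        else:
            b = mid
    side = "above" if cycles_at(b) else "below"
    return CycleThreshold(
        parameter=parameter,
        value=0.5 * (a + b),
        bracket=(a, b),
        default=float(getattr(p, parameter)),
        cycles_in_bracket_side=side,
    )


def sensitivity_analysis(
    p: ModelParameters,
    parameters: Sequence[str] | None = None,
    search_factor: float = 100.0,
    *,
    rel_tol: float = 0.02,
    mutualism: bool = True,
    transient_years: float = 500.0,
    window_years: float = 200.0,
    output_step_days: float = 5.0,
    n_coarse_per_side: int = 7,
    progress: Callable[[str], None] | None = None,
) -> list[SensitivityRecord]:
    """Distance from default to cycle onset, parameter by parameter.

    Each parameter is searched on a multiplicative interval
    ``[default / search_factor, default * search_factor]`` (the defaults
    span many orders of magnitude, so an additive window would be
    meaningless for the small conversion factors).  Both sides of the
    default are probed on geometric grids; the side whose cycle onset lies
    closer to the default, in percent change, provides the reported
    threshold, refined by bisection to ``rel_tol * default``.  Records are
    sorted by percent change ascending; parameters with no onset in range
    report ``threshold=None`` and sort last.

    By default the natural mortality ``m_n`` is excluded (it is the scanned
    stress axis, analysed separately); pass an explicit list to include it.
    """
    if parameters is None:
        parameters = [name for name in PARAMETER_NAMES if name != "m_n"]
    records: list[SensitivityRecord] = []
    for name in parameters:
        default = float(getattr(p, name))
        if default <= 0:
            raise ValueError(f"sensitivity search needs a positive default for {name}")
        cache: dict[float, bool] = {}
        best: CycleThreshold | None = None
        factors = np.geomspace(1.0, search_factor, n_coarse_per_side + 1)
        for side_grid in (default * factors, default / factors):
            lo, hi = float(min(side_grid)), float(max(side_grid))
            if not lo < hi:  # degenerate interval (search_factor == 1)
                continue
            try:
                thr = find_cycle_threshold(
                    p, name, (lo, hi), tol=rel_tol * default,
                    mutualism=mutualism, n_coarse=len(side_grid),
                    transient_years=transient_years, window_years=window_years,
                    output_step_days=output_step_days, _cache=cache,
                )
            except AmbiguousThresholdError as err:
                # take the flip nearest the default on this side
                nearest = min(
                    err.brackets, key=lambda br: min(abs(br[0] - default), abs(br[1] - default))
                )
                thr = find_cycle_threshold(
                    p, name, nearest, tol=rel_tol * default,
                    mutualism=mutualism, n_coarse=2,
                    transient_years=transient_years, window_years=window_years,
                    output_step_days=output_step_days, _cache=cache,
                )
            if thr is not None and (best is None or thr.percent_change < best.percent_change):
                best = thr
        if best is None:
            records.append(SensitivityRecord(name, default, None, None))
        else:
            records.append(
                SensitivityRecord(name, default, best.value, best.percent_change)
            )
        if progress is not None:
            pc = records[-1].percent_change
            progress(
                f"{name}: threshold "
                + (f"{records[-1].threshold:.6g} ({pc:.1f}% change)" if pc is not None else "none in range")
            )
    records.sort(key=lambda rec: math.inf if rec.percent_change is None else rec.percent_change)
    return records
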