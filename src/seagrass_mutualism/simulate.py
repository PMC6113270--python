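"""Scenario integration and dynamical-regime classification.

The vector field is integrated with a stiff-capable adaptive solver (LSODA).
Internally the seagrass equation is integrated in log density, ``u = ln Z``:
during deep collapse phases of the slow-fast cycles shoot density decays
exponentially for years and can fall below any fixed absolute tolerance,
where a linear-space solver loses the sign of ``Z`` and with it the
recovery phase of the cycle.  In log space the collapse and recovery are
nearly linear segments, ``Z`` stays positive by construction, and the cycle
period is solver-robust.  The other three components (S, OM, L) remain in
linear space; they are bounded away from problematic magnitudes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .core import ModelParameters, ModelState

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "RegimeLabel",
    "RegimeClassification",
    "default_initial_state",
    "integrate",
    "classify_regime",
]

DAYS_PER_YEAR = 365.0


def default_initial_state(p: ModelParameters, mutualism: bool = True) -> ModelState:
    """Sparse colonisation start: 1% of carrying capacity, clean sediment.

    A single-digit *Loripes* seed population lets the bivalve equation act
    from the start when the mutualism is on; without the mutualism the run
    starts (and stays) at ``L = 0`` so the sulfide sink is absent.
    """
    return ModelState(Z=0.01 * p.Z_max, S=0.0, OM=0.0, L=1.0 if mutualism else 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """What to integrate: scenario switches, horizon, sampling and tolerances."""

    mutualism: bool = True
    duration_days: float = 20 * DAYS_PER_YEAR
    initial_state: ModelState | None = None  # None -> default_initial_state
    output_step_days: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.duration_days > 0:
            raise ValueError("duration_days must be > 0")
        if not self.output_step_days > 0:
            raise ValueError("output_step_days must be > 0")
        if self.initial_state is not None:
            ModelState(*self.initial_state).validate()

    def resolve_initial_state(self, p: ModelParameters) -> ModelState:
        if self.initial_state is None:
            return default_initial_state(p, self.mutualism)
        return ModelState(*self.initial_state)


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model states from one scenario integration."""

    times: np.ndarray            # days, strictly increasing
    states: np.ndarray           # shape (n, 4): columns Z, S, OM, L
    parameters: ModelParameters
    scenario: ScenarioConfig

    @property
    def Z(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def OM(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def L(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def final_state(self) -> ModelState:
        return ModelState(*self.states[-1])

    def after(self, t_days: float) -> "Trajectory":
        """Sub-trajectory at times >= ``t_days`` (transient removal)."""
        keep = self.times >= t_days
        if not keep.any():
            raise ValueError(f"no samples at or after t = {t_days} days")
        return Trajectory(self.times[keep], self.states[keep], self.parameters, self.scenario)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_days": self.times, "Z": self.Z, "S": self.S, "OM": self.OM, "L": self.L}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def read_csv(
        path: str | Path,
        parameters: ModelParameters | None = None,
        scenario: ScenarioConfig | None = None,
    ) -> "Trajectory":
        df = pd.read_csv(path)
        expected = ["t_days", "Z", "S", "OM", "L"]
        if list(df.columns) != expected:
            raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
        return Trajectory(
            df["t_days"].to_numpy(float),
            df[["Z", "S", "OM", "L"]].to_numpy(float),
            parameters if parameters is not None else ModelParameters(),
            scenario if scenario is not None else ScenarioConfig(duration_days=float(df["t_days"].iloc[-1]) or 1.0),
        )


def _rhs_log(t, y, p: ModelParameters, mutualism: bool, u_cap: float):
    # State is (ln Z, S, OM, L).  Scalar math: the solver calls this at every
    # internal step, so avoid ndarray temporaries beyond the return value.
    u, S, OM, L = y
    # Cap the exponent a few e-foldings above the logistic barrier ln(Z_max):
    # solver trial steps may probe far outside the invariant region, and an
    # uncapped exp would overflow every coupled term.
    Z = math.exp(min(u, u_cap)) if u > -745.0 else 0.0
    Sc = S if S > 0.0 else 0.0  # tolerate solver-level undershoot below 0
    OMc = OM if OM > 0.0 else 0.0
    Lc = L if L > 0.0 else 0.0
    if Sc <= p.S_min:
        fS = 0.0
    elif Sc >= p.S_max:
        fS = 1.0
    else:
        fS = (Sc - p.S_min) / (p.S_max - p.S_min)
    mort_rate = p.m_s * fS + p.m_n
    du = p.r * (1.0 - Z / p.Z_max) - mort_rate
    dS = p.C_om * OMc - p.C_s * Lc * Sc - p.e_s * S
    dOM = p.C_z * mort_rate * Z - p.e_m * OM
    if mutualism:
        dL = p.r_L * (Z / p.Z_max) * (1.0 - Lc / p.L_max) - p.m_L * L
    else:
        dL = 0.0
    return (du, dS, dOM, dL)


def _rhs_bare(t, y, p: ModelParameters, mutualism: bool):
    # Degenerate scenario Z(0) = 0: seagrass stays extinct, remaining
    # subsystem is linear in (S, OM, L).
    S, OM, L = y
    dS = p.C_om * max(OM, 0.0) - p.C_s * max(L, 0.0) * max(S, 0.0) - p.e_s * S
    dOM = -p.e_m * OM
    dL = -p.m_L * L if mutualism else 0.0
    return (dS, dOM, dL)


def integrate(p: ModelParameters, cfg: ScenarioConfig) -> Trajectory:
    """Integrate the model for one scenario and return the sampled trajectory.

    Raises ``RuntimeError`` naming the failing time if the solver cannot
    complete a step.
    """
    y0 = cfg.resolve_initial_state(p).validate()
    n_out = int(math.floor(cfg.duration_days / cfg.output_step_days))
    t_eval = np.linspace(0.0, n_out * cfg.output_step_days, n_out + 1)
    if t_eval[-1] < cfg.duration_days - 1e-9:
        t_eval = np.append(t_eval, cfg.duration_days)

    if y0.Z == 0.0:
        sol = solve_ivp(
            _rhs_bare, (0.0, cfg.duration_days), [y0.S, y0.OM, y0.L],
            method="LSODA", t_eval=t_eval, rtol=cfg.rtol, atol=cfg.atol,
            args=(p, cfg.mutualism),
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed near t = {sol.t[-1]:.3f} days: {sol.message}")
        states = np.column_stack(
            [np.zeros_like(sol.t), sol.y[0], sol.y[1], sol.y[2]]
        )
    else:
        u_cap = math.log(p.Z_max) + 4.0
        sol = solve_ivp(
            _rhs_log, (0.0, cfg.duration_days),
            [math.log(y0.Z), y0.S, y0.OM, y0.L],
            method="LSODA", t_eval=t_eval, rtol=cfg.rtol, atol=cfg.atol,
            args=(p, cfg.mutualism, u_cap),
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed near t = {sol.t[-1]:.3f} days: {sol.message}")
        with np.errstate(under="ignore"):
            Z = np.exp(np.minimum(sol.y[0], u_cap))
        states = np.column_stack([Z, sol.y[1], sol.y[2], sol.y[3]])
    np.clip(states, 0.0, None, out=states)
    states[0] = np.asarray(y0, float)  # exact initial condition at t = 0
    return Trajectory(sol.t.copy(), states, p, cfg)


class RegimeLabel(str, enum.Enum):
    """Qualitative long-run behaviour of the seagrass component."""

    STABLE_EQUILIBRIUM = "stable_equilibrium"
    DAMPED_OSCILLATION = "damped_oscillation"
    LIMIT_CYCLE = "limit_cycle"
    COLLAPSED = "collapsed"


@dataclass(frozen=True)
class RegimeClassification:
    """Regime label with post-transient shoot-density statistics."""

    label: RegimeLabel
    z_mean: float
    z_min: float
    z_max: float
    period_days: float | None = None  # only for limit cycles

    def __post_init__(self) -> None:
        if not (self.z_min <= self.z_mean <= self.z_max):
            raise ValueError("require z_min <= z_mean <= z_max")
        if self.period_days is not None and not self.period_days > 0:
            raise ValueError("period_days must be > 0 when present")


# Sustained vs damped oscillation: ratio of last to first post-transient
# peak-to-trough amplitude below this -> damped.
_DECAY_RATIO = 0.9
_EPS = 1e-12


def classify_regime(
    traj: Trajectory,
    transient_fraction: float | None = None,
    amplitude_tol: float = 1e-3,
    *,
    transient_days: float | None = None,
    collapse_fraction: float = 0.01,
) -> RegimeClassification:
    """Classify the post-transient seagrass dynamics of a trajectory.

    The transient window defaults to ``max(200 years, half the run)``;
    alternatively give ``transient_fraction`` (of the run length) or an
    absolute ``transient_days``.  ``amplitude_tol`` is the relative Z
    amplitude ``(max - min) / mean`` below which the run counts as steady.
    Oscillations are sustained (a limit cycle) when at least two
    post-transient peaks are present and their peak-to-trough amplitudes do
    not decay; decaying peak sequences are damped oscillations.  A steady
    run whose mean shoot density is below ``collapse_fraction * Z_max``
    is labelled collapsed.
    """
    if not amplitude_tol > 0:
        raise ValueError("amplitude_tol must be > 0")
    duration = traj.times[-1] - traj.times[0]
    if transient_days is None:
        if transient_fraction is not None:
            if not 0 <= transient_fraction < 1:
                raise ValueError("transient_fraction must be in [0, 1)")
            transient_days = traj.times[0] + transient_fraction * duration
        else:
            transient_days = traj.times[0] + max(200 * DAYS_PER_YEAR, 0.5 * duration)
    if transient_days >= traj.times[-1]:
        raise ValueError("trajectory shorter than the transient window")
    window = traj.after(transient_days)
    z = window.Z
    if not np.all(np.isfinite(z)):
        raise ValueError("trajectory contains non-finite values")
    z_min, z_max = float(z.min()), float(z.max())
    # pairwise summation can put the mean a few ulp outside [min, max]
    z_mean = float(min(max(z.mean(), z_min), z_max))
    amplitude = (z_max - z_min) / max(z_mean, _EPS)

    if amplitude <= amplitude_tol:
        if z_mean < collapse_fraction * traj.parameters.Z_max:
            return RegimeClassification(RegimeLabel.COLLAPSED, z_mean, z_min, z_max)
        return RegimeClassification(RegimeLabel.STABLE_EQUILIBRIUM, z_mean, z_min, z_max)

    # Only count oscillations on the scale of the overall excursion; slow-fast
    # plateaus carry numerical micro-wiggles that are not cycles.
    prominence = 0.1 * (z_max - z_min)
    peaks, _ = find_peaks(z, prominence=prominence)
    if len(peaks) < 2:
        # One overshoot (or slow drift) still relaxing: not sustained.
        return RegimeClassification(RegimeLabel.DAMPED_OSCILLATION, z_mean, z_min, z_max)

    # Sustained vs decaying: compare the excursion envelope of the two
    # halves of the window.  (A per-peak amplitude measure is fragile here
    # because slow-fast collapses ring, producing clusters of near-equal
    # peaks separated by shallow dips.)
    half = len(z) // 2
    first_amp = float(z[:half].max() - z[:half].min())
    last_amp = float(z[half:].max() - z[half:].min())
    if last_amp < _DECAY_RATIO * first_amp:
        return RegimeClassification(RegimeLabel.DAMPED_OSCILLATION, z_mean, z_min, z_max)
    period = _dominant_period(z, window.times)
    if period is None:  # no clear autocorrelation peak: median peak spacing
        period = float(np.median(np.diff(window.times[peaks])))
    return RegimeClassification(
        RegimeLabel.LIMIT_CYCLE, z_mean, z_min, z_max, period_days=period
    )


def _dominant_period(z: np.ndarray, times: np.ndarray) -> float | None:
    """Cycle period from the first significant autocorrelation peak.

    Robust to the fast ringing that decorates slow-fast collapses, which
    makes raw inter-peak spacings meaningless.
    """
    x = z - z.mean()
    n = len(x)
    # FFT autocorrelation, normalised to lag 0
    f = np.fft.rfft(x, 2 * n)
    ac = np.fft.irfft(f * np.conj(f))[:n]
    if ac[0] <= 0:
        return None
    ac /= ac[0]
    peaks, props = find_peaks(ac, prominence=0.05, height=0.2)
    if len(peaks) == 0:
        return None
    dt = float(np.median(np.diff(times)))
    return float(peaks[0] * dt)
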