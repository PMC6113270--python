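"""Scenario integration and regime classification."""

import math

import numpy as np
import pytest

from seagrass_mutualism import (
    ModelParameters,
    ModelState,
    RegimeLabel,
    ScenarioConfig,
    Trajectory,
    classify_regime,
    default_initial_state,
    integrate,
)
from seagrass_mutualism.simulate import DAYS_PER_YEAR


@pytest.fixture(scope="module")
def mutualism_20yr(params) -> Trajectory:
    return integrate(params, ScenarioConfig(mutualism=True, duration_days=20 * DAYS_PER_YEAR))


@pytest.fixture(scope="module")
def no_mutualism_20yr(params) -> Trajectory:
    cfg = ScenarioConfig(
        mutualism=False,
        duration_days=20 * DAYS_PER_YEAR,
        initial_state=ModelState(80.0, 0.0, 0.0, 0.0),
    )
    return integrate(params, cfg)


@pytest.fixture(scope="module")
def cycling_300yr(params) -> Trajectory:
    cfg = ScenarioConfig(mutualism=True, duration_days=300 * DAYS_PER_YEAR, output_step_days=5.0)
    return integrate(params.replace(m_n=0.03), cfg)


class TestIntegrate:
    def test_trajectory_contract(self, mutualism_20yr):
        tr = mutualism_20yr
        assert np.all(np.diff(tr.times) > 0)
        assert tuple(tr.states[0]) == tuple(default_initial_state(tr.parameters))
        assert np.all(tr.states >= 0)
        assert np.all(np.isfinite(tr.states))

    def test_no_mutualism_bed_rises_once_then_collapses(self, no_mutualism_20yr, params):
        """Without the bivalve sulfide sink the bed is transient: one
        initial rise, then sulfide-driven collapse to a sparse state."""
        z = no_mutualism_20yr.Z
        peak = z.argmax()
        assert z[peak] > 0.9 * z.max()  # single dominant maximum
        assert z[-1] < 0.05 * params.Z_max
        # sulfide ends high: the sink is gone
        assert no_mutualism_20yr.S[-1] > params.S_min

    def test_mutualism_holds_bed_at_subtoxic_equilibrium(self, mutualism_20yr, params):
        fp = params.fixed_point()
        final_5yr = mutualism_20yr.after(15 * DAYS_PER_YEAR)
        assert np.all(np.abs(final_5yr.Z - fp.Z) < 0.05 * fp.Z)
        # integrated equilibrium matches the algebraic fixed point < 0.5%
        end = mutualism_20yr.final_state
        for got, want in zip(end, fp):
            assert abs(got - want) < 0.005 * want

    def test_mutualism_keeps_sulfide_below_toxicity_onset(self, mutualism_20yr, params):
        post = mutualism_20yr.after(10 * DAYS_PER_YEAR)
        assert np.all(post.S < params.S_min)

    def test_raised_mortality_causes_recurring_collapse_and_recovery(self, cycling_300yr, params):
        post = cycling_300yr.after(150 * DAYS_PER_YEAR)
        assert post.Z.max() > 0.5 * params.Z_max
        assert post.Z.min() < 0.01 * params.Z_max
        cls = classify_regime(cycling_300yr, transient_days=150 * DAYS_PER_YEAR)
        assert cls.label is RegimeLabel.LIMIT_CYCLE
        assert cls.period_days > 0

    def test_boundedness_by_carrying_capacities(self, mutualism_20yr, cycling_300yr, params):
        for tr in (mutualism_20yr, cycling_300yr):
            assert np.all(tr.Z <= params.Z_max * (1 + 1e-6))
            assert np.all(tr.L <= params.L_max * (1 + 1e-6))

    def test_solver_tolerance_robustness(self, params):
        base = ScenarioConfig(mutualism=True, duration_days=5 * DAYS_PER_YEAR)
        tight = ScenarioConfig(mutualism=True, duration_days=5 * DAYS_PER_YEAR,
                               rtol=base.rtol / 2, atol=base.atol / 2)
        a = integrate(params, base).final_state
        b = integrate(params, tight).final_state
        for x, y in zip(a, b):
            assert abs(x - y) <= 0.001 * max(abs(y), 1e-6)

    def test_bare_start_stays_bare(self, params):
        cfg = ScenarioConfig(
            mutualism=True, duration_days=20 * DAYS_PER_YEAR,
            initial_state=ModelState(0.0, 300.0, 0.05, 10.0),
        )
        tr = integrate(params, cfg)
        assert np.all(tr.Z == 0.0)
        # with no seagrass the sediment clears: OM exported, sulfide follows
        assert tr.OM[-1] < 0.01 * 0.05
        assert tr.S[-1] < 2.0

    def test_invalid_scenarios_rejected(self, params):
        with pytest.raises(ValueError):
            ScenarioConfig(duration_days=0)
        with pytest.raises(ValueError):
            ScenarioConfig(initial_state=ModelState(-1.0, 0, 0, 0))

    def test_csv_round_trip(self, tmp_path, mutualism_20yr):
        path = tmp_path / "traj.csv"
        mutualism_20yr.to_csv(path)
        assert path.read_text().splitlines()[0] == "t_days,Z,S,OM,L"
        back = Trajectory.read_csv(path)
        np.testing.assert_allclose(back.states, mutualism_20yr.states, rtol=1e-6)


def _synthetic_trajectory(params, t, z) -> Trajectory:
    states = np.column_stack([z, np.zeros_like(z), np.zeros_like(z), np.zeros_like(z)])
    cfg = ScenarioConfig(duration_days=float(t[-1]), initial_state=ModelState(*states[0]))
    return Trajectory(np.asarray(t, float), states, params, cfg)


class TestClassifyRegime:
    def test_constant_high_density_is_stable(self, params):
        t = np.arange(0.0, 500 * DAYS_PER_YEAR, 30.0)
        cls = classify_regime(_synthetic_trajectory(params, t, np.full_like(t, 7840.0)))
        assert cls.label is RegimeLabel.STABLE_EQUILIBRIUM
        assert cls.z_min <= cls.z_mean <= cls.z_max

    def test_constant_sparse_density_is_collapsed(self, params):
        t = np.arange(0.0, 500 * DAYS_PER_YEAR, 30.0)
        cls = classify_regime(_synthetic_trajectory(params, t, np.full_like(t, 10.0)))
        assert cls.label is RegimeLabel.COLLAPSED

    def test_sustained_oscillation_with_known_period(self, params):
        t = np.arange(0.0, 600 * DAYS_PER_YEAR, 10.0)
        period = 8 * DAYS_PER_YEAR
        z = 4000.0 + 2000.0 * np.sin(2 * np.pi * t / period)
        cls = classify_regime(_synthetic_trajectory(params, t, z))
        assert cls.label is RegimeLabel.LIMIT_CYCLE
        assert cls.period_days == pytest.approx(period, rel=0.02)

    def test_decaying_oscillation_is_damped(self, params):
        t = np.arange(0.0, 600 * DAYS_PER_YEAR, 10.0)
        decay = np.exp(-t / (50 * DAYS_PER_YEAR))
        z = 4000.0 + 2000.0 * decay * np.sin(2 * np.pi * t / (8 * DAYS_PER_YEAR))
        cls = classify_regime(_synthetic_trajectory(params, t, z))
        assert cls.label is RegimeLabel.DAMPED_OSCILLATION

    def test_default_scenario_classified_stable(self, mutualism_20yr):
        cls = classify_regime(mutualism_20yr, transient_fraction=0.5)
        assert cls.label is RegimeLabel.STABLE_EQUILIBRIUM

    def test_label_invariant_to_doubling_duration(self, params):
        """Stable and cycling labels persist when the run is extended at the
        same absolute transient."""
        for m_n, expected, years in ((0.007, RegimeLabel.STABLE_EQUILIBRIUM, 20),
                                     (0.03, RegimeLabel.LIMIT_CYCLE, 300)):
            p = params.replace(m_n=m_n)
            transient = years * DAYS_PER_YEAR / 2
            for factor in (1, 2):
                cfg = ScenarioConfig(mutualism=True,
                                     duration_days=factor * years * DAYS_PER_YEAR,
                                     output_step_days=5.0)
                cls = classify_regime(integrate(p, cfg), transient_days=transient)
                assert cls.label is expected, (m_n, factor)

    def test_transient_longer_than_run_rejected(self, params, mutualism_20yr):
        with pytest.raises(ValueError):
            classify_regime(mutualism_20yr, transient_days=30 * DAYS_PER_YEAR)

    def test_non_finite_trajectory_rejected(self, params):
        t = np.arange(0.0, 500 * DAYS_PER_YEAR, 30.0)
        z = np.full_like(t, 5000.0)
        z[-1] = np.nan
        with pytest.raises(ValueError):
            classify_regime(_synthetic_trajectory(params, t, z))
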