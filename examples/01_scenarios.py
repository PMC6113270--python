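"""Three scenario runs showing what the mutualism does for bed stability.

Integrates the model (i) without the lucinid bivalves, (ii) with them at
default conditions, and (iii) with them under raised natural mortality
(a stand-in for desiccation stress), then classifies each regime.
"""

from seagrass_mutualism import (
    ModelParameters,
    ModelState,
    ScenarioConfig,
    classify_regime,
    integrate,
)
from seagrass_mutualism.simulate import DAYS_PER_YEAR

p = ModelParameters()

scenarios = {
    "no mutualism": (p, ScenarioConfig(
        mutualism=False, duration_days=20 * DAYS_PER_YEAR,
        initial_state=ModelState(80.0, 0.0, 0.0, 0.0))),
    "mutualism, default mortality": (p, ScenarioConfig(
        mutualism=True, duration_days=20 * DAYS_PER_YEAR)),
    "mutualism, raised mortality (m_n = 0.03)": (p.replace(m_n=0.03), ScenarioConfig(
        mutualism=True, duration_days=300 * DAYS_PER_YEAR, output_step_days=5.0)),
}

for name, (pi, cfg) in scenarios.items():
    traj = integrate(pi, cfg)
    cls = classify_regime(traj, transient_fraction=0.5)
    print(f"{name}:")
    print(f"  regime: {cls.label.value}")
    print(f"  peak Z over run: {traj.Z.max():7.0f} shoots/m^2 "
          f"({100 * traj.Z.max() / pi.Z_max:.0f}% of Z_max)")
    print(f"  post-transient Z: mean {cls.z_mean:7.0f}, min {cls.z_min:.3g}, "
          f"max {cls.z_max:7.0f}")
    if cls.period_days:
        print(f"  cycle period: ~{cls.period_days / 365:.0f} yr")

print(
    "\nReading: without the bivalves the bed overshoots once and collapses\n"
    "under its own sulfide load; with them it settles on a stable vegetated\n"
    "equilibrium; raising mortality pushes it into slow-fast\n"
    "collapse-and-recovery cycles."
)
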