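# seagrass-mutualism

Dynamics of a facultative mutualism between an intertidal seagrass
(*Zostera noltii*) and lucinid bivalves (*Loripes lucinalis*) whose gill
endosymbionts oxidise pore-water sulfide. The package is for theoretical
ecologists and coastal-ecosystem modellers who want to study how a
mutualistic feedback stabilises a foundation species, when that
stabilisation fails, and how the failure shows up in occupation-density
("potential") analyses of simulated or remotely sensed vegetation data.

## The model

Four coupled ODEs (time in days) track seagrass shoots `Z` (shoots m⁻²),
pore-water sulfide `S` (µmol L⁻¹), sediment organic matter `OM` (%) and
bivalve density `L` (ind m⁻²):

    dZ/dt  = r (1 − Z/Z_max) Z − [m_s · fS(S) + m_n] Z
    dS/dt  = C_om · OM − C_s · L · S − e_s · S
    dOM/dt = C_z · [m_s · fS(S) + m_n] Z − e_m · OM
    dL/dt  = r_L (Z/Z_max)(1 − L/L_max) − m_L · L

with `fS` a linear toxicity ramp, 0 below `S_min = 200 µmol L⁻¹` and 1
above `S_max = 1000 µmol L⁻¹`. Seagrass fuels sediment organic matter,
whose anaerobic decomposition produces toxic sulfide (a negative
feedback); the bivalves, sustained by seagrass, remove sulfide (the
mutualistic positive feedback, the `C_s·L·S` sink). "Without the
mutualism" means `dL/dt = 0` with `L = 0`.

Around the model the package provides:

- `simulate` — stiff-capable scenario integration (internally in log shoot
  density, so the extreme collapse phases of slow-fast cycles stay
  resolved) and automatic regime classification (stable equilibrium /
  damped oscillation / limit cycle / collapsed);
- `bifurcation` — mortality scans with forward/backward continuation,
  bisection for the cycle-onset value of any parameter, and a
  multiplicative-range sensitivity analysis over all parameters;
- `ensemble` — replicated stochastic ensembles over a mortality gradient
  with noisy carrying capacity, sampled yearly after burn-in;
- `potential` — Gaussian-kernel occupation densities per stress class
  (bandwidth `h = 1.06 · s · n^(−1/5)`), potentials `U = −log P_d`, and
  automated attractor/repellor detection;
- `field` — a seeded generator of synthetic NDVI-by-elevation map stacks
  with configurable per-class modality, so the field arm of the pipeline
  is testable without satellite data.

## A worked example

```python
import numpy as np
from seagrass_mutualism import ModelParameters
from seagrass_mutualism.bifurcation import find_cycle_threshold
from seagrass_mutualism.ensemble import EnsembleConfig, run_ensemble
from seagrass_mutualism.potential import potential_landscape

p = ModelParameters()                       # field-calibrated defaults

thr = find_cycle_threshold(p, "m_n", (0.01, 0.05), tol=1e-4)
print(f"cycles set in at m_n = {thr.value:.4f} /day")

cfg = EnsembleConfig(m_n_grid=np.array([0.007, 0.04]), replicates=60, seed=1)
samples = run_ensemble(p, cfg)
for c in potential_landscape(samples):
    print(f"m_n = {c.class_value}: attractors at {np.round(c.attractors)}")
```

prints

```
cycles set in at m_n = 0.0234 /day
m_n = 0.007: attractors at [7767.]
m_n = 0.04: attractors at [  21. 6785.]
```

Below the onset mortality (0.0234 day⁻¹, ~3.3× the natural rate of 0.007)
the bivalves hold the bed at a single vegetated attractor near carrying
capacity; above it the system falls into slow-fast collapse-and-recovery
cycles, whose long dwell times at high and near-zero density imprint two
attractors on the occupation density — the same bimodal signature usually
read as alternative stable states.

The `examples/` directory holds one short script per capability
(scenario runs, cycle onset, ensemble + potential analysis, synthetic
field data); each prints its numbers with a line on how to read them.
A thin CLI wraps the same functions:
`seagrass-mutualism simulate|bifurcate|sensitivity|ensemble|potential|synthify|reproduce`
(see `seagrass-mutualism --help`; `reproduce` chains the headline analyses
at moderate size).

## Layout

```
src/seagrass_mutualism/   core, simulate, bifurcation, ensemble,
                          potential, field, io, cli
examples/                 narrative scripts, one per capability
tests/                    pytest suite (unit, property and end-to-end)
docs/methods.md           modelling and numerical notes
```
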