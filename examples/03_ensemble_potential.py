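"""Stochastic ensemble + potential analysis: one basin or two?

Runs a reduced replicate ensemble (60 replicates; the full protocol uses
625) at one mortality below and one above the cycle onset, with 15%
carrying-capacity noise, then estimates the occupation density of shoot
densities per class and finds its attractors.
"""

import numpy as np

from seagrass_mutualism import ModelParameters
from seagrass_mutualism.ensemble import EnsembleConfig, run_ensemble
from seagrass_mutualism.potential import potential_landscape

p = ModelParameters()
cfg = EnsembleConfig(
    m_n_grid=np.array([0.007, 0.04]), replicates=60,
    burn_in_years=200, sample_years=50, sigma=0.15, seed=1,
)
print(f"integrating {cfg.replicates} replicates x {len(cfg.m_n_grid)} mortality classes ...")
samples = run_ensemble(p, cfg)

for k, m_n in enumerate(samples.class_values):
    pooled = samples.flat(k)
    print(f"m_n = {m_n}: pooled Z mean {pooled.mean():6.0f}, SD {pooled.std(ddof=1):6.0f} "
          f"(n = {pooled.size})")

landscape = potential_landscape(samples)
for c in landscape:
    att = ", ".join(f"{a:.0f}" for a in c.attractors)
    rep = ", ".join(f"{r:.0f}" for r in c.repellors) or "-"
    print(f"m_n = {c.class_value}: {c.n_attractors} attractor(s) at [{att}] "
          f"shoots/m^2, repellor(s) at [{rep}]")

print(
    "\nReading: below the cycle onset there is a single vegetated attractor\n"
    "near carrying capacity; above it the slow-fast cycles dwell at high and\n"
    "near-zero density long enough to imprint two attractors on the\n"
    "occupation density, the same signature alternative stable states leave."
)
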