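"""Synthetic NDVI maps over an elevation gradient, analysed like field data.

Generates a four-year stack of NDVI values over a tidal-flat elevation
gradient (unimodal vegetated low on the flat, bimodal mid-gradient,
unimodal bare up high), pools the years per 0.1-m elevation class, and
runs the potential analysis — the same procedure one would apply to
calibrated satellite maps.
"""

from seagrass_mutualism.field import FieldGeneratorConfig, generate_field_dataset, link_elevation_to_mortality
from seagrass_mutualism.potential import potential_landscape

cfg = FieldGeneratorConfig(seed=42)
dataset = generate_field_dataset(cfg)
print(f"generated {len(dataset.records)} NDVI records "
      f"({len(cfg.years)} years x {cfg.pixels_per_year} pixels, {cfg.n_classes} classes)")

landscape = potential_landscape(dataset.to_samples(), clip_range=(-1.0, 1.0))
print("\nelevation   m_n proxy   attractors (NDVI)")
for c in landscape:
    m_n = link_elevation_to_mortality(c.class_value)
    att = ", ".join(f"{a:+.2f}" for a in c.attractors)
    print(f"  {c.class_value:+.2f} m     {m_n:.3f}/d    {c.n_attractors}: [{att}]")

print(
    "\nReading: one high-NDVI attractor below -0.3 m (healthy meadow), two\n"
    "attractors between -0.3 and 0 m (meadow/bare mosaic under intermediate\n"
    "desiccation stress), one low-NDVI attractor above 0 m (bare flat) —\n"
    "mirroring the attractor structure the model produces along its\n"
    "mortality gradient."
)
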