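# Methods and numerical notes

## Model

The model couples seagrass shoot density `Z`, pore-water sulfide `S`,
sediment organic matter `OM` and lucinid bivalve density `L` on a tropical
intertidal flat (equations in the README). Its assumptions, in brief:
logistic seagrass growth; seagrass mortality split into a constant natural
rate `m_n` (also the proxy for desiccation stress) and a sulfide-driven
part that ramps linearly between an onset (`S_min`) and a saturation
(`S_max`) concentration; organic matter fed solely by dead seagrass and
lost at a constant export/decomposition rate; sulfide produced
proportionally to organic matter and removed by bivalve uptake plus
abiotic oxidation/outgassing; bivalve recruitment proportional to seagrass
cover (larvae arrive from the water column) saturating at a carrying
capacity, with density-independent mortality. All parameters are
non-negative; defaults are the field-calibrated values listed in
`ModelParameters`, with time in days throughout ("year" in protocols
means 365 days). The conversion `C_om` defaults to the coupled value
`0.01 / C_z` but is stored independently so sensitivity analyses can move
it alone.

Two structural facts organise everything downstream:

1. **The vegetated equilibrium is sub-toxic.** At defaults the coexistence
   equilibrium is `Z* = Z_max(1 − m_n/r) = 7840`, `OM* ≈ 0.123 %`,
   `L* ≈ 3539`, `S* ≈ 62 µmol L⁻¹ < S_min`, so the toxicity ramp is
   inactive there (`ModelParameters.fixed_point`).
2. **Cycle onset is a border collision.** Raising `m_n` (or moving any
   other parameter that raises equilibrium sulfide) pushes `S*` up to
   `S_min`; the instant the equilibrium touches the ramp corner it loses
   stability and the system jumps to large-amplitude slow-fast cycles.
   Solving `S*(m_n) = S_min` algebraically gives the onset at
   `m_n ≈ 0.0234 day⁻¹`, which the simulation-based bisection reproduces;
   the tests use this closed form as an independent oracle. The corner
   also explains which parameters can never destabilise the default state:
   `m_s`, `S_max` and (at defaults) `e_s`, `r` do not raise `S*` to
   `S_min` anywhere in a ×100 search range, so the sensitivity analysis
   genuinely reports "no threshold" for them.

## Integration

`scipy.integrate.solve_ivp` with LSODA, `rtol 1e-8` / `atol 1e-10`.
The seagrass equation is integrated in log density `u = ln Z`: during deep
collapse phases `Z` decays exponentially for years (minima below
`10⁻²⁰⁰ Z_max` are normal for these cycles), where a linear-space solver
loses the sign of `Z` and with it the recovery leg of the cycle. In log
space collapse and recovery are near-linear segments and `Z > 0` holds by
construction. The exponent is capped a few e-foldings above `ln Z_max`
(solver trial steps can probe far outside the invariant region; the
logistic term makes the cap unreachable by true dynamics), and small
solver-level undershoots of 0 in `S`, `OM`, `L` are treated as 0 inside
the right-hand side. Outputs are clipped at 0. A start with `Z(0) = 0`
exactly is integrated as the bare-sediment subsystem (seagrass extinct).

Default initial state: `Z = 0.01 Z_max`, clean sediment (`S = OM = 0`),
and a seed population `L = 1` when the mutualism is on (`L = 0` when off,
so the sulfide sink is absent). Scenario runs are solver-robust: halving
the tolerances moves a 5-year endpoint by < 0.1%.

## Regime classification

After discarding a transient window (default: the larger of 200 years and
half the run), the relative amplitude `a = (max − min)/mean` of `Z`
decides steady (`a ≤ 10⁻³`) versus oscillating. Steady runs with mean
below 1% of `Z_max` are "collapsed". Oscillating runs are "sustained"
(limit cycle) when at least two peaks with prominence ≥ 10% of the
excursion are present and the excursion envelope of the second half of the
window is at least 0.9× that of the first half; otherwise "damped".
The envelope test, rather than per-peak amplitudes, is deliberate:
slow-fast collapses ring (mixed-mode oscillations), producing clusters of
near-equal peaks separated by shallow dips that defeat peak-to-peak decay
measures. The cycle period is taken from the first significant
autocorrelation peak for the same reason. Near the onset the transition is
sharp (border collision, no slowly-growing small cycles), which keeps the
classification and the bisection stable; threshold searches still use a
long transient (500 years) because cycle periods near onset are decades.

## Bifurcation and sensitivity

`scan_mortality` sweeps `m_n` (default 150 steps over 0–0.35 day⁻¹)
with warm-start continuation, forward or backward, to expose hysteresis if
any existed (none does at defaults: forward, backward and cold-start scans
agree). Underflowed shoot densities are re-seeded at `10⁻¹² Z_max`
between continuation steps — a numerical propagule bank; without it a
warm start from an underflowed state would freeze the bare state into the
rest of the scan.

`find_cycle_threshold` probes an interval on a coarse grid (geometric when
the interval spans ≥ one decade), requires exactly one cycling/non-cycling
flip, and bisects it; multiple flips are reported as brackets rather than
resolved silently. `sensitivity_analysis` searches each parameter over
`default × [1/100, 100]`, takes the onset nearest the default in percent
change, and refines it to 2% of the default. Parameter values that violate
constructor invariants (e.g. `S_min` pushed above `S_max`) are treated as
outside the searchable range. Narrow cycling bands lying entirely between
two coarse grid points (ratio ≈ 1.9) would be missed; the reported
thresholds for all parameters with a finite result match the algebraic
`S* = S_min` crossing, so no such band affects the defaults. `m_n` is
excluded by default (it is the scanned stress axis) and can be included
explicitly.

## Stochastic ensemble

The ensemble emulates observing many seagrass patches along a stress
gradient: for each mortality value on a 61-step grid (0–0.15 day⁻¹,
step 0.0025) each of 625 replicates is integrated with a noisy carrying
capacity `Z_max(1 + ε)`, `ε ~ N(0, 0.15²)` truncated to keep the capacity
positive, and sampled instantaneously at the end of each of 50 years after
a 200-year burn-in. The noise is redrawn once per replicate for the
burn-in and independently at the start of every sample year
(piecewise-constant yearly environmental variation). The yearly redraw is
a deliberate design choice: seagrass relaxes to its capacity within days,
so each yearly sample tracks that year's capacity and the pooled class
sample is effectively 31 250 independent draws — the regime the
kernel-density stage assumes. A single static draw per replicate would
leave only 625 distinct values, each duplicated 50 times; the bandwidth
formula (computed from n = 31 250) then undersmooths and manufactures
spurious attractors (a ~17% relative prominence artifact at full scale).
Replicates use independent RNG streams spawned from one master seed, so
serial and parallel execution agree bit-for-bit; failed replicates are
skipped and counted, and more than 1% failures aborts the run.

## Potential analysis

Per stress class, the observable's density `P_d` is estimated with a plain
Gaussian kernel sum of bandwidth `h = 1.06 · s · n^(−1/5)` (sample SD `s`,
n−1 denominator) on 512 grid points spanning the data ± 3h, and the
potential is `U = −log(max(P_d, 10⁻¹²))` — the floor keeps `U` finite but
never moves an extremum because peak logic runs on `P_d`. Attractors are
density maxima with topographic prominence ≥ 5% of the density maximum
(configurable; the floor suppresses sampling-noise peaks), repellors the
minima between adjacent attractors, so the two strictly alternate.
Classes are analysed independently (no smoothing across the gradient);
degenerate classes (n < 2 or zero spread) are flagged and the rest
processed. NDVI observations are clamped to [−1, 1] first. The analysis is
diagnostic: bimodality flags strong feedback-mediated dynamics but cannot
by itself distinguish alternative stable states from slow-fast cycles —
indeed here the cycles produce the classic bistability signature.

## Synthetic field data

The generator emulates the *structure* of a calibrated multi-year NDVI map
stack over a tidal flat, not its physics: pixel elevations drawn once,
uniformly over −0.6…+0.3 m relative to mean water level, binned into nine
0.1-m classes; per class a two-component Gaussian NDVI mixture truncated
to [−1, 1], with high state 0.55 ± 0.08 (dense meadow) and low state
0.05 ± 0.05 (bare wet sediment) — typical end-member values for intertidal
seagrass scenes — and a high-state weight falling linearly from 1 to 0
across −0.3…0 m. Years are exchangeable redraws (no temporal
autocorrelation), so "four years" matches the real stack's record count
without claiming its dynamics. What passing tests show is therefore that
the potential-analysis arm recovers a known per-class modality; they say
nothing about atmospheric correction, sensor cross-calibration, spatial
autocorrelation, or real interannual change, all of which are absent by
design. An optional mechanistic mode instead drives NDVI from simulated
shoot densities through a saturating reflectance curve plus noise, with
elevation mapped monotonically to natural mortality
(−0.6 m → 0.007 day⁻¹, +0.3 m → 0.15 day⁻¹, piecewise-linear and
configurable) — the map is plumbing for cross-pipeline consistency checks,
not a calibrated desiccation model.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the protocols at the sizes
the analyses need rather than maxima: scenario runs of 20–700 years;
threshold bisections to 10⁻⁴ day⁻¹ (within 500-year transients and
200-year windows); the full 14-parameter sensitivity analysis at 2%
bisection tolerance; the full 625-replicate ensemble for the headline
attractor statistics and a 100-replicate version for the two-class
end-to-end tests (the pooled statistics are stable well below full
replication); synthetic field stacks at the full 4 × 17 672 records.

## Known limitations

- The toxicity ramp's corner makes the onset a non-smooth bifurcation;
  eigenvalue-based continuation tools expecting smooth Hopf points will
  disagree about the classification exactly at the corner.
- Regime labels come from trajectory statistics, not normal forms; a
  damped oscillation decaying by less than 10% over the post-transient
  window is indistinguishable from a cycle at that horizon (the bias on
  reported thresholds is ≪ the bisection tolerance).
- Deep-cycle minima (`Z ~ 10⁻²⁰⁰ Z_max`) are mathematically faithful to
  the ODE but ecologically absurd; any extinction floor would lengthen or
  break the recovery leg. Periods of deep cycles should be read as
  model artifacts, regime labels as robust.
- The ensemble's noise enters only through the carrying capacity;
  observation noise, demographic stochasticity and parameter noise are out
  of scope.
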