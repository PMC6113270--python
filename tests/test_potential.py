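"""Potential analysis: bandwidth, kernel density, attractor detection."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from seagrass_mutualism.ensemble import StressClassedSamples
from seagrass_mutualism.potential import (
    bin_width,
    estimate_density,
    find_attractors,
    potential_landscape,
)


def unit_sd_sample(n: int, scale: float = 1.0, rng=None) -> np.ndarray:
    """Alternating sample with sample SD (n-1 denominator) exactly ``scale``."""
    x = np.resize([1.0, -1.0], n)
    x *= scale / np.std(x, ddof=1)
    return x


class TestBinWidth:
    def test_normal_reference_formula(self):
        # 1.06 * 1 * 32**(-1/5); 32**(1/5) = 2 exactly
        assert bin_width(unit_sd_sample(32)) == pytest.approx(0.53, abs=1e-12)

    def test_ensemble_sized_sample(self):
        # 1.06 * 1200 * 31250**(-1/5) ~ 160.6 (625 replicates x 50 years)
        h = bin_width(unit_sd_sample(31250, scale=1200.0))
        assert h == pytest.approx(1.06 * 1200.0 * 31250 ** (-0.2), rel=1e-12)
        assert h == pytest.approx(160.6, abs=0.1)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 2.0, 300)
        assert bin_width(3.5 * x) == pytest.approx(3.5 * bin_width(x), rel=1e-12)

    @pytest.mark.parametrize("values", [[1.0], [2.0, 2.0, 2.0]])
    def test_degenerate_samples_rejected(self, values):
        with pytest.raises(ValueError):
            bin_width(values)


class TestEstimateDensity:
    def test_equals_naive_kernel_sum(self):
        """Oracle: the unchunked textbook sum (1/(n h)) sum phi((x-z_i)/h)."""
        rng = np.random.default_rng(1)
        values = rng.normal(0.0, 1.0, 257)
        grid = np.linspace(-4, 4, 101)
        h = 0.37
        naive = np.array(
            [
                np.exp(-0.5 * ((x - values) / h) ** 2).sum() / (len(values) * h * np.sqrt(2 * np.pi))
                for x in grid
            ]
        )
        np.testing.assert_allclose(estimate_density(values, grid, h), naive, rtol=1e-12)

    def test_agrees_with_scipy_gaussian_kde(self):
        """Independent library route: gaussian_kde with the factor chosen so
        its kernel SD equals h."""
        rng = np.random.default_rng(2)
        values = rng.normal(8000.0, 1200.0, 2000)
        grid = np.linspace(3000, 13000, 200)
        h = bin_width(values)
        kde = gaussian_kde(values, bw_method=h / values.std(ddof=1))
        np.testing.assert_allclose(estimate_density(values, grid, h), kde(grid), rtol=1e-9)

    def test_normal_sample_peaks_near_mean_and_normalizes(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8000.0, 1200.0, 20000)
        h = bin_width(values)
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 512)
        pd_grid = estimate_density(values, grid, h)
        assert abs(np.trapezoid(pd_grid, grid) - 1.0) < 0.01
        assert abs(grid[pd_grid.argmax()] - 8000.0) < 2 * h

    def test_repeated_value_gives_symmetric_kernel(self):
        values = np.full(50, 3.3)
        grid = np.linspace(1.3, 5.3, 201)  # symmetric about 3.3
        pd_grid = estimate_density(values, grid, h=0.5)
        assert grid[pd_grid.argmax()] == pytest.approx(3.3)
        np.testing.assert_allclose(pd_grid, pd_grid[::-1], rtol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.empty(0), np.linspace(0, 1, 10), 0.1)
        with pytest.raises(ValueError):
            estimate_density(np.ones(5), np.linspace(0, 1, 10), 0.0)
        with pytest.raises(ValueError):
            estimate_density(np.ones(5), np.array([0.3, 0.2, 0.1]), 0.1)


class TestFindAttractors:
    def test_unimodal_sample_single_attractor(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0.0, 1.0, 5000)
        h = bin_width(values)
        grid = np.linspace(-5, 5, 512)
        att, rep = find_attractors(estimate_density(values, grid, h), grid)
        assert len(att) == 1 and len(rep) == 0
        assert abs(att[0]) < 2 * h

    def test_two_component_mixture_recovered(self):
        """50/50 mixture of N(500, 150) and N(7500, 800): two attractors
        within 2 bandwidths of the component means, one repellor between."""
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(500.0, 150.0, 2500), rng.normal(7500.0, 800.0, 2500)]
        )
        h = bin_width(values)
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 512)
        att, rep = find_attractors(estimate_density(values, grid, h), grid)
        assert len(att) == 2 and len(rep) == 1
        assert abs(att[0] - 500.0) < 2 * h
        assert abs(att[1] - 7500.0) < 2 * h
        assert att[0] < rep[0] < att[1]

    def test_flat_density_yields_empty_result(self):
        grid = np.linspace(0, 1, 100)
        att, rep = find_attractors(np.full(100, 0.5), grid)
        assert len(att) == 0 and len(rep) == 0

    def test_extrema_match_on_potential_scale(self):
        """argmax Pd == argmin U: the log transform moves no extremum."""
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(-2, 0.5, 3000), rng.normal(2, 0.7, 2000)])
        h = bin_width(values)
        grid = np.linspace(-5, 5, 512)
        pd_grid = estimate_density(values, grid, h)
        u = -np.log(np.maximum(pd_grid, 1e-12))
        att, _ = find_attractors(pd_grid, grid)
        att_u, _ = find_attractors(np.exp(-u), grid)
        np.testing.assert_allclose(att, att_u)
        assert grid[pd_grid.argmax()] == grid[u.argmin()]


def mixture_samples(weights, n=4000, seed=0) -> StressClassedSamples:
    """Stress-classed two-component mixtures with known per-class weight."""
    rng = np.random.default_rng(seed)
    obs = []
    for w in weights:
        k = rng.binomial(n, w)
        obs.append(
            np.concatenate([rng.normal(7500.0, 800.0, k), rng.normal(500.0, 150.0, n - k)])
        )
    return StressClassedSamples(
        "stress", np.arange(len(weights), dtype=float), tuple(obs)
    )


class TestPotentialLandscape:
    def test_modality_recovery_across_stress_gradient(self):
        """Across 27 class draws (3 seeds x 9 weights) the attractor count
        matches the generating modality in >= 95% of classes."""
        weights = [1.0, 1.0, 1.0, 0.8, 0.5, 0.2, 0.0, 0.0, 0.0]
        expected = [2 if 0.1 <= w <= 0.9 else 1 for w in weights]
        hits = total = 0
        for seed in range(3):
            landscape = potential_landscape(mixture_samples(weights, seed=seed))
            for c, want in zip(landscape.classes, expected):
                hits += int(c.n_attractors == want)
                total += 1
        assert hits / total >= 0.95

    def test_alternation_and_normalization_invariants(self):
        landscape = potential_landscape(mixture_samples([0.5, 0.3], seed=1))
        for c in landscape:
            merged = np.sort(np.concatenate([c.attractors, c.repellors]))
            interleaved = np.empty_like(merged)
            interleaved[0::2] = np.sort(c.attractors)
            interleaved[1::2] = np.sort(c.repellors)
            np.testing.assert_allclose(merged, interleaved)
            assert len(c.repellors) == len(c.attractors) - 1
            assert abs(np.trapezoid(c.density, c.grid) - 1.0) < 0.01
            assert np.all(np.isfinite(c.potential))

    def test_affine_rescaling_moves_positions_not_counts(self):
        base = mixture_samples([0.5], seed=2)
        a, b = 0.25, 3000.0
        scaled = StressClassedSamples(
            "stress", base.class_values, (a * base.observations[0] + b,)
        )
        l0 = potential_landscape(base).classes[0]
        l1 = potential_landscape(scaled).classes[0]
        assert l0.n_attractors == l1.n_attractors
        np.testing.assert_allclose(l1.attractors, a * l0.attractors + b, rtol=5e-3)

    def test_sample_permutation_irrelevant(self):
        base = mixture_samples([0.4], seed=3)
        rng = np.random.default_rng(9)
        shuffled = StressClassedSamples(
            "stress", base.class_values, (rng.permutation(base.observations[0]),)
        )
        np.testing.assert_allclose(
            potential_landscape(base).classes[0].attractors,
            potential_landscape(shuffled).classes[0].attractors,
        )

    def test_degenerate_class_flagged_others_processed(self):
        good = np.random.default_rng(10).normal(0.5, 0.1, 500)
        samples = StressClassedSamples(
            "stress", np.array([0.0, 1.0]), (np.full(10, 0.3), good)
        )
        landscape = potential_landscape(samples)
        assert not landscape.classes[0].ok
        assert landscape.classes[1].ok
        assert landscape.classes[1].n_attractors == 1

    def test_clip_range_applied_before_analysis(self):
        values = np.concatenate([np.random.default_rng(11).normal(0.9, 0.2, 1000)])
        samples = StressClassedSamples("elev", np.array([0.0]), (values,), observable="ndvi")
        c = potential_landscape(samples, clip_range=(-1.0, 1.0)).classes[0]
        assert c.grid[-1] <= 1.0 + 3 * c.h + 1e-9
        assert c.attractors.max() <= 1.0
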