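"""Poisson-lognormal machinery and quasi-UMI rescue of inflated read counts."""

import numpy as np
import pytest
from scipy import integrate, stats

from molspikes.quasiumi import (
    PoilogShape,
    adjust_expected_spike_molecules,
    estimate_total_rna,
    poilog_mle,
    poilog_pmf,
    poilog_sample,
    quantile_normalize,
    tune_shape,
)
from molspikes.saturation import SaturationFit


class TestPoilogPmf:
    def test_normalizes_to_one(self):
        shape = PoilogShape(0.5, 2.0)
        total = poilog_pmf(np.arange(0, 200_000), shape).sum()
        assert abs(total - 1.0) < 1e-6

    def test_non_negative(self):
        shape = PoilogShape(-1.0, 1.5)
        assert np.all(poilog_pmf(np.arange(0, 500), shape) >= 0)

    def test_sigma_to_zero_limit_is_poisson(self):
        """As sigma -> 0 the mixture degenerates to Poisson(exp(mu))."""
        shape = PoilogShape(0.0, 1e-4)
        p0 = float(poilog_pmf(np.array([0]), shape)[0])
        assert p0 == pytest.approx(np.exp(-1.0), abs=1e-6)
        ks = np.arange(0, 15)
        assert np.allclose(poilog_pmf(ks, shape), stats.poisson.pmf(ks, 1.0), atol=1e-5)

    @pytest.mark.parametrize(
        "k,mu,sigma",
        [(0, 0.5, 2.0), (1, 0.5, 2.0), (10, 0.5, 2.0), (5, -1.0, 0.5), (0, 0.0, 0.3),
         (25, 1.0, 1.0)],
    )
    def test_against_direct_quadrature_oracle(self, k, mu, sigma):
        """Independent check: direct numerical integration of the mixture."""
        def integrand(z):
            return stats.norm.pdf(z) * stats.poisson.pmf(k, np.exp(mu + sigma * z))

        expected, _ = integrate.quad(integrand, -10, 10, limit=200)
        got = float(poilog_pmf(np.array([k]), PoilogShape(mu, sigma))[0])
        assert got == pytest.approx(expected, rel=1e-6)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            poilog_pmf(np.array([-1]), PoilogShape(0.0, 1.0))


class TestPoilogMle:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        counts = poilog_sample(5000, PoilogShape(0.5, 2.0), rng)
        fit = poilog_mle(counts)
        assert fit.mu == pytest.approx(0.5, abs=0.15)
        assert fit.sigma == pytest.approx(2.0, abs=0.15)
        assert fit.converged

    def test_poisson_input_pins_sigma_near_zero(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5.0, size=2000)
        fit = poilog_mle(counts)
        assert fit.sigma < 0.15
        assert np.exp(fit.mu) == pytest.approx(5.0, rel=0.1)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            poilog_mle([1, 2, 3])
        with pytest.raises(ValueError):
            poilog_mle([4] * 100)


class TestEstimateTotalRna:
    def test_symmetric_fraction(self):
        est = estimate_total_rna(1000, 1000, 1000.0)
        assert est.total_endogenous_molecules == pytest.approx(1000.0)
        assert est.spike_fraction == pytest.approx(0.5)

    def test_quarter_fraction(self):
        est = estimate_total_rna(1000, 3000, 1000.0)
        assert est.total_endogenous_molecules == pytest.approx(3000.0)

    def test_scale_invariance(self):
        a = estimate_total_rna(500, 1500, 800.0)
        b = estimate_total_rna(5000, 15000, 800.0)
        assert a.total_endogenous_molecules == pytest.approx(b.total_endogenous_molecules)

    def test_zero_spike_reads_errors(self):
        with pytest.raises(ValueError):
            estimate_total_rna(0, 100, 50.0)

    def test_proportional_sampling_recovers_known_total(self, rng):
        """Reads sampled proportionally from known molecule pools."""
        spike_molecules, endo_molecules = 2000, 60_000
        depth = 30_000
        p_spike = spike_molecules / (spike_molecules + endo_molecules)
        spike_reads = rng.binomial(depth, p_spike)
        est = estimate_total_rna(spike_reads, depth - spike_reads, spike_molecules)
        se = depth * np.sqrt(p_spike * (1 - p_spike))
        rel_se = 3 * se / (depth * p_spike)
        assert est.total_endogenous_molecules == pytest.approx(endo_molecules, rel=rel_se)


class TestAdjustExpectedSpikeMolecules:
    def _fit(self):
        return SaturationFit(b0=0.0, b1=30_000.0, c=np.log(1e-5))

    def test_observed_equals_predicted_identity(self):
        fit = self._fit()
        predicted = fit.predict(100_000)
        assert adjust_expected_spike_molecules(100_000, int(predicted), fit, 49_125.0) == (
            pytest.approx(49_125.0, rel=1e-4)
        )

    def test_ten_percent_over(self):
        fit = self._fit()
        predicted = fit.predict(100_000)
        adjusted = adjust_expected_spike_molecules(100_000, int(1.1 * predicted), fit, 1000.0)
        assert adjusted == pytest.approx(1100.0, rel=1e-3)

    def test_nonpositive_prediction_errors(self):
        fit = SaturationFit(b0=0.0, b1=0.0, c=0.0)
        with pytest.raises(ValueError):
            adjust_expected_spike_molecules(100, 10, fit, 1000.0)


class TestQuantileNormalize:
    def test_zeros_stay_zero_and_all_zero_input(self):
        shape = PoilogShape(0.5, 1.5)
        reads = np.array([0, 0, 0])
        assert quantile_normalize(reads, shape).tolist() == [0, 0, 0]
        reads = np.array([0, 5, 0, 17])
        out = quantile_normalize(reads, shape)
        assert out[0] == 0 and out[2] == 0 and out[1] >= 1 and out[3] >= 1

    def test_monotone_and_tie_preserving(self, rng):
        shape = PoilogShape(0.5, 1.8)
        reads = rng.poisson(20, size=400)
        out = quantile_normalize(reads, shape)
        order = np.argsort(reads)
        assert np.all(np.diff(out[order]) >= 0)
        for v in np.unique(reads[reads > 0]):
            assert len(np.unique(out[reads == v])) == 1

    def test_reproduces_target_distribution_by_construction(self, rng):
        """Reads = amplified poilog counts map back to the poilog quantiles."""
        shape = PoilogShape(0.8, 1.6)
        true_umis = poilog_sample(5000, shape, rng)
        reads = true_umis * 7  # constant amplification preserves all ranks
        quasi = quantile_normalize(reads, shape, anchor_zeros=False)
        nz_q = np.sort(quasi[quasi > 0])
        nz_t = np.sort(true_umis[true_umis > 0])
        # Kolmogorov distance between rescued and true nonzero distributions
        grid = np.arange(1, max(nz_q.max(), nz_t.max()) + 1)
        cdf_q = np.searchsorted(nz_q, grid, side="right") / len(nz_q)
        cdf_t = np.searchsorted(nz_t, grid, side="right") / len(nz_t)
        assert np.max(np.abs(cdf_q - cdf_t)) < 0.05

    def test_total_non_decreasing_in_sigma(self, rng):
        reads = rng.poisson(5.0 * poilog_sample(2000, PoilogShape(0.5, 2.0), rng))
        totals = [
            quantile_normalize(reads, PoilogShape(0.5, s)).sum()
            for s in np.linspace(1.8, 2.2, 9)
        ]
        assert all(a <= b for a, b in zip(totals, totals[1:]))


class TestTuneShape:
    def test_grid_of_one_equals_plain_normalization(self, rng):
        shape0 = PoilogShape(0.5, 1.5)
        reads = rng.poisson(10, size=300)
        chosen, quasi = tune_shape(reads, shape0, target_total=500.0, grid_points=1)
        assert chosen.sigma == shape0.sigma
        assert np.array_equal(quasi, quantile_normalize(reads, shape0))

    def test_already_optimal_returns_sigma0(self, rng):
        shape0 = PoilogShape(0.5, 1.5)
        reads = rng.poisson(10, size=300)
        target = float(quantile_normalize(reads, shape0).sum())
        chosen, _ = tune_shape(reads, shape0, target_total=target)
        assert chosen.sigma == pytest.approx(shape0.sigma)

    def test_rescue_of_inflated_cells(self):
        """End-to-end rescue: 5x-inflated reads recover true UMI totals and ranks,
        and the rescued distribution is closer to the truth than raw reads are."""
        from scipy.stats import spearmanr

        from molspikes.simulate import expression_profile, simulate_inflated_well

        rng = np.random.default_rng(42)
        rates = expression_profile(seed=42)
        for _ in range(3):
            well = simulate_inflated_well(rates, rng)
            true_umis, reads, spike_counts = (
                well["true_umis"], well["reads"], well["spike_counts"],
            )
            spike_molecules = float(spike_counts.sum())
            est = estimate_total_rna(
                int(5 * spike_molecules), int(reads.sum()), spike_molecules
            )
            shape0 = poilog_mle(spike_counts)
            shape, quasi = tune_shape(reads, shape0, est.total_endogenous_molecules)
            nz = (true_umis > 0) | (quasi > 0)
            rho = spearmanr(quasi[nz], true_umis[nz]).statistic
            assert rho >= 0.9
            assert abs(quasi.sum() - true_umis.sum()) / true_umis.sum() < 0.10

            def ks(sample):
                nz_s = np.sort(sample[sample > 0])
                nz_t = np.sort(true_umis[true_umis > 0])
                grid = np.arange(1, max(nz_s.max(), nz_t.max()) + 1)
                c1 = np.searchsorted(nz_s, grid, side="right") / len(nz_s)
                c2 = np.searchsorted(nz_t, grid, side="right") / len(nz_t)
                return np.max(np.abs(c1 - c2))

            assert ks(quasi) < ks(reads)  # rescued closer to truth than raw reads
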