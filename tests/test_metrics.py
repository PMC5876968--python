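"""Aerosol sizing statistics: Da/Dg, cumulative mass, MMAD, GSD, events."""

import numpy as np
import pytest
from scipy.stats import norm

from aerocath.metrics import (
    AerosolSummary,
    SizeDistribution,
    aerodynamic_to_geometric,
    aerosolization_rate,
    classify_aps_events,
    cumulative_mass_distribution,
    geometric_to_aerodynamic,
    gsd,
    mass_quantile_from_particles,
    mmad,
)


class TestDiameterConversion:
    def test_unit_density_identity(self):
        assert aerodynamic_to_geometric(4.0, 1.0) == pytest.approx(4.0)

    def test_pfd_hand_value(self):
        assert aerodynamic_to_geometric(4.33, 1.95) == pytest.approx(3.101, abs=1e-3)

    def test_round_trip_identity(self):
        da = 4.33
        back = geometric_to_aerodynamic(aerodynamic_to_geometric(da, 1.95), 1.95)
        assert back == pytest.approx(da, rel=1e-12)

    def test_strictly_decreasing_in_density(self):
        rhos = np.linspace(0.5, 3.0, 20)
        dgs = [aerodynamic_to_geometric(5.0, r) for r in rhos]
        assert np.all(np.diff(dgs) < 0)

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            aerodynamic_to_geometric(5.0, 0.0)


class TestCumulativeMass:
    def test_two_point_plateau(self):
        dist = SizeDistribution([1.99, 2.01, 7.99, 8.01], [0.5, 0.0, 0.5])
        d, f = cumulative_mass_distribution(dist)
        # Between the two sizes the curve holds at one half.
        assert np.interp(5.0, d, f) == pytest.approx(0.5)

    def test_non_decreasing_and_normalized(self):
        rng = np.random.default_rng(0)
        diam = np.exp(rng.normal(np.log(5), 0.5, 2000))
        dist = SizeDistribution.from_particles(diam, diam**3)
        d, f = cumulative_mass_distribution(dist)
        assert np.all(np.diff(f) >= 0)
        assert f[0] == 0.0 and f[-1] == pytest.approx(1.0)

    def test_matches_analytic_lognormal_cdf(self):
        """Equal-mass draws from a mass-weighted lognormal reproduce the
        analytic CDF to better than 0.01 everywhere."""
        rng = np.random.default_rng(1)
        med, sg = 6.0, 1.8
        diam = np.exp(rng.normal(np.log(med), np.log(sg), 100_000))
        dist = SizeDistribution.from_particles(diam, np.ones_like(diam), n_bins=200)
        d, f = cumulative_mass_distribution(dist)
        analytic = norm.cdf(np.log(d / med) / np.log(sg))
        assert np.max(np.abs(f - analytic)) < 0.01

    def test_zero_mass_rejected(self):
        dist = SizeDistribution([1.0, 2.0], [0.0])
        with pytest.raises(ValueError):
            cumulative_mass_distribution(dist)

    def test_mixture_additivity(self):
        """The curve of a pooled population is the mass-weighted mixture of
        the component curves."""
        rng = np.random.default_rng(2)
        d1 = np.exp(rng.normal(np.log(3), 0.3, 4000))
        d2 = np.exp(rng.normal(np.log(9), 0.4, 4000))
        m1, m2 = d1**3, 2.0 * d2**3
        edges = np.exp(np.linspace(np.log(0.5), np.log(40), 101))
        mk = lambda d, m: SizeDistribution(edges, np.histogram(d, edges, weights=m)[0])
        s1, s2 = mk(d1, m1), mk(d2, m2)
        _, f1 = cumulative_mass_distribution(s1)
        _, f2 = cumulative_mass_distribution(s2)
        _, f12 = cumulative_mass_distribution(
            mk(np.concatenate([d1, d2]), np.concatenate([m1, m2]))
        )
        w1 = s1.total_mass / (s1.total_mass + s2.total_mass)
        np.testing.assert_allclose(f12, w1 * f1 + (1 - w1) * f2, atol=1e-12)


class TestMMAD:
    def test_monodisperse(self):
        assert mmad(np.full(100, 5.0), np.ones(100)) == pytest.approx(5.0)

    def test_equal_mass_bins_split_at_shared_edge(self):
        dist = SizeDistribution([1.0, 2.0, 4.0], [0.5, 0.5])
        assert mmad(dist) == pytest.approx(2.0)

    def test_lognormal_mass_median_recovery(self):
        rng = np.random.default_rng(3)
        diam = np.exp(rng.normal(np.log(7.2), np.log(1.8), 100_000))
        assert mmad(diam, np.ones_like(diam)) == pytest.approx(7.2, abs=0.1)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_quantile_from_particles([1.0], [0.0], 0.5)


class TestGSD:
    def test_monodisperse_unity(self):
        g = gsd(np.full(50, 5.0), np.ones(50))
        assert g == pytest.approx(1.0)
        assert not AerosolSummary(5.0, 5.0, g).heterodisperse

    def test_lognormal_sigma_recovery(self):
        rng = np.random.default_rng(4)
        diam = np.exp(rng.normal(np.log(6.0), np.log(1.8), 100_000))
        assert gsd(diam, np.ones_like(diam)) == pytest.approx(1.8, abs=0.03)

    def test_heterodisperse_threshold(self):
        assert AerosolSummary(4.0, 6.0, 1.3).heterodisperse
        assert not AerosolSummary(4.0, 6.0, 1.2).heterodisperse

    def test_quantile_ratio_agrees_with_moment_formula(self):
        rng = np.random.default_rng(5)
        ln_d = rng.normal(np.log(6.0), np.log(1.9), 50_000)
        diam = np.exp(ln_d)
        moment = np.exp(ln_d.std())
        assert gsd(diam, np.ones_like(diam)) == pytest.approx(moment, rel=0.01)


class TestAerosolizationRate:
    def test_no_mass_change(self):
        assert aerosolization_rate(10.0, 10.0, 1.0, 1.95) == 0.0

    def test_pfd_hand_value(self):
        assert aerosolization_rate(10.0, 9.9, 1.0, 1.95) == pytest.approx(0.05128, abs=1e-4)

    def test_inverse_in_duration(self):
        full = aerosolization_rate(10.0, 9.9, 1.0, 1.95)
        half = aerosolization_rate(10.0, 9.9, 0.5, 1.95)
        assert half == pytest.approx(2 * full)

    def test_mass_gain_rejected(self):
        with pytest.raises(ValueError):
            aerosolization_rate(9.9, 10.0, 1.0, 1.95)


class TestEventClassification:
    def test_diameter_thresholds(self):
        counts = classify_aps_events([0.3, 10.0, 25.0])
        assert counts == (1, 1, 0, 1)

    def test_range_edges_belong_to_event2(self):
        counts = classify_aps_events([0.5, 20.0])
        assert counts.event2 == 2

    def test_coincidence_takes_precedence(self):
        counts = classify_aps_events([10.0, 10.0], [True, False])
        assert counts.event3 == 1 and counts.event2 == 1

    def test_partition_is_exact(self):
        rng = np.random.default_rng(6)
        d = np.exp(rng.normal(1.0, 1.5, 5000))
        coin = rng.random(5000) < 0.1
        counts = classify_aps_events(d, coin)
        assert sum(counts) == 5000

    def test_empty_input(self):
        assert classify_aps_events([]) == (0, 0, 0, 0)
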