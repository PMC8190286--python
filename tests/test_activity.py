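import numpy as np
import pytest
from scipy import integrate
from scipy.special import i0

from scavcam.activity import (
    ActivityDensity,
    CircularSample,
    activity_comparison,
    bootstrap_overlap,
    circular_sd,
    fit_circular_kde,
    kappa_for_circular_sd,
    overlap_coefficient,
    plugin_kappa,
    split_by_prior_use,
    timestamps_to_radians,
)

TWO_PI = 2 * np.pi


def vm_pdf(x, mu, kappa):
    return np.exp(kappa * np.cos(x - mu)) / (TWO_PI * i0(kappa))


def integral(density: ActivityDensity) -> float:
    v = np.append(density.density, density.density[0])
    g = np.append(density.grid, density.grid[0] + TWO_PI)
    return integrate.trapezoid(v, g)


class TestKde:
    def test_normalized_and_periodic(self, rng):
        d = fit_circular_kde(CircularSample(rng.vonmises(1.0, 3.0, 500) % TWO_PI))
        assert integral(d) == pytest.approx(1.0, abs=1e-6)
        assert (d.density >= 0).all()
        assert len(d.grid) == 512

    def test_uniform_limit(self, rng):
        theta = rng.uniform(0, TWO_PI, 20000)
        d = fit_circular_kde(CircularSample(theta))
        assert np.max(np.abs(d.density - 1 / TWO_PI)) < 0.1 / TWO_PI

    def test_point_mass_with_fixed_kappa(self):
        d = fit_circular_kde(CircularSample(np.full(5, 1.3)), kappa=4.0)
        np.testing.assert_allclose(d.density, vm_pdf(d.grid, 1.3, 4.0), rtol=1e-6)

    def test_small_sample_needs_explicit_kappa(self):
        with pytest.raises(ValueError, match="kappa"):
            fit_circular_kde(CircularSample(np.array([1.0])))
        fit_circular_kde(CircularSample(np.array([1.0])), kappa=2.0)  # ok

    def test_beats_uniform_on_concentrated_sample(self, rng):
        """Integrated squared error against the true von Mises density is
        smaller than that of the uniform density (quadrature oracle)."""
        theta = rng.vonmises(np.pi, 2.0, 5000) % TWO_PI
        d = fit_circular_kde(CircularSample(theta))
        truth = vm_pdf(d.grid, np.pi, 2.0)
        ise_kde = np.mean((d.density - truth) ** 2)
        ise_unif = np.mean((1 / TWO_PI - truth) ** 2)
        assert ise_kde < ise_unif

    def test_kappa_inversion_round_trip(self):
        for kappa in (0.5, 2.0, 50.0):
            from scipy.special import i0e, i1e

            sd = np.sqrt(-2 * np.log(i1e(kappa) / i0e(kappa)))
            assert kappa_for_circular_sd(sd) == pytest.approx(kappa, rel=1e-6)

    def test_plugin_kappa_grows_with_n(self, rng):
        theta = rng.vonmises(0.0, 2.0, 4000) % TWO_PI
        k_small = plugin_kappa(theta[:200])
        k_big = plugin_kappa(theta)
        assert k_big > k_small  # bandwidth shrinks, concentration grows


class TestOverlap:
    def test_identity(self, rng):
        d = fit_circular_kde(CircularSample(rng.vonmises(1.0, 2.0, 400) % TWO_PI))
        assert overlap_coefficient(d, d) == pytest.approx(1.0, abs=1e-9)

    def test_near_disjoint(self, rng):
        d1 = fit_circular_kde(CircularSample(rng.vonmises(0.0, 50.0, 2000) % TWO_PI), kappa=50.0)
        d2 = fit_circular_kde(CircularSample(rng.vonmises(np.pi, 50.0, 2000) % TWO_PI), kappa=50.0)
        assert overlap_coefficient(d1, d2) < 0.01

    def test_symmetric(self, rng):
        d1 = fit_circular_kde(CircularSample(rng.vonmises(0.5, 2.0, 300) % TWO_PI))
        d2 = fit_circular_kde(CircularSample(rng.vonmises(2.5, 1.0, 300) % TWO_PI))
        assert overlap_coefficient(d1, d2) == overlap_coefficient(d2, d1)

    def test_rotation_invariant(self, rng):
        a = rng.vonmises(1.0, 2.0, 800) % TWO_PI
        b = rng.vonmises(2.0, 3.0, 800) % TWO_PI
        base = overlap_coefficient(
            fit_circular_kde(CircularSample(a)), fit_circular_kde(CircularSample(b))
        )
        shift = TWO_PI * 5 / 24
        rot = overlap_coefficient(
            fit_circular_kde(CircularSample((a + shift) % TWO_PI)),
            fit_circular_kde(CircularSample((b + shift) % TWO_PI)),
        )
        assert rot == pytest.approx(base, abs=5e-3)

    def test_mismatched_grids_rejected(self, rng):
        d1 = fit_circular_kde(CircularSample(rng.vonmises(0, 2, 100) % TWO_PI), grid_size=512)
        d2 = fit_circular_kde(CircularSample(rng.vonmises(0, 2, 100) % TWO_PI), grid_size=256)
        with pytest.raises(ValueError):
            overlap_coefficient(d1, d2)

    def test_matches_quadrature_truth(self, rng):
        """Delta on two von Mises samples 2 h apart tracks the analytic
        integral-of-minimum of the true densities."""
        mu1, mu2, kappa = np.pi, np.pi + TWO_PI * 2 / 24, 2.0
        xs = np.linspace(0, TWO_PI, 20001)
        truth = integrate.trapezoid(np.minimum(vm_pdf(xs, mu1, kappa), vm_pdf(xs, mu2, kappa)), xs)
        a = rng.vonmises(mu1, kappa, 2000) % TWO_PI
        b = rng.vonmises(mu2, kappa, 2000) % TWO_PI
        delta = overlap_coefficient(
            fit_circular_kde(CircularSample(a)), fit_circular_kde(CircularSample(b))
        )
        assert delta == pytest.approx(truth, abs=0.03)


class TestBootstrap:
    def test_same_data_high_overlap(self, rng):
        a = rng.vonmises(1.0, 2.0, 300) % TWO_PI
        est = bootstrap_overlap(CircularSample(a), CircularSample(a.copy()), n_boot=150, seed=0)
        assert est.delta > 0.95
        assert est.ci_high >= est.delta
        assert est.ci_low <= est.delta <= est.ci_high

    def test_deterministic_for_seed(self, rng):
        a = rng.vonmises(0.5, 2.0, 200) % TWO_PI
        b = rng.vonmises(1.5, 2.0, 200) % TWO_PI
        e1 = bootstrap_overlap(CircularSample(a), CircularSample(b), n_boot=120, seed=9)
        e2 = bootstrap_overlap(CircularSample(a), CircularSample(b), n_boot=120, seed=9)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_low_iteration_warning(self, rng, caplog):
        a = rng.vonmises(0.5, 2.0, 50) % TWO_PI
        with caplog.at_level("WARNING", logger="scavcam.activity"):
            bootstrap_overlap(CircularSample(a), CircularSample(a), n_boot=50, seed=0)
        assert any("n_boot" in r.message for r in caplog.records)


class TestComparison:
    def test_timestamps_to_radians(self):
        import pandas as pd

        rad = timestamps_to_radians(pd.Series(pd.to_datetime(["2017-02-01 00:00", "2017-02-01 12:00", "2017-02-01 18:00"])))
        np.testing.assert_allclose(rad, [0.0, np.pi, 1.5 * np.pi])

    def test_split_is_strictly_causal(self, detections_factory):
        minutes_40d = 60 * 24 * 40
        det = detections_factory(
            [
                ("S01", "marten", minutes_40d),          # same instant as first fisher
                ("S01", "fisher", minutes_40d),
                ("S01", "marten", minutes_40d + 60),     # after first fisher
            ]
        )
        used, not_used = split_by_prior_use(det, "marten", "fisher")
        assert len(used) == 1
        assert len(not_used) == 1

    def test_three_way_comparison_ordering(self, rng):
        """Crepuscular subordinate vs nocturnal dominant: between-species
        overlap is lower than within-species overlap."""
        n = 600
        marten_a = np.concatenate(
            [rng.vonmises(TWO_PI * 6 / 24, 2.0, n // 2), rng.vonmises(TWO_PI * 18 / 24, 2.0, n // 2)]
        ) % TWO_PI
        marten_b = np.concatenate(
            [rng.vonmises(TWO_PI * 6 / 24, 2.0, n // 2), rng.vonmises(TWO_PI * 18 / 24, 2.0, n // 2)]
        ) % TWO_PI
        fisher = rng.vonmises(TWO_PI * 1 / 24, 1.5, n) % TWO_PI
        comp = activity_comparison(marten_a, marten_b, fisher, n_boot=120, seed=4)
        ov = comp["overlaps"]
        assert ov["marten_used_vs_marten_not_used"].delta > ov["marten_used_vs_fisher"].delta
        assert ov["marten_used_vs_marten_not_used"].ci_high > 0.9

    def test_empty_subset_skipped(self, rng):
        comp = activity_comparison(
            np.array([]), rng.uniform(0, TWO_PI, 100), rng.uniform(0, TWO_PI, 100), n_boot=120, seed=0
        )
        assert set(comp["overlaps"]) == {"marten_not_used_vs_fisher"}
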