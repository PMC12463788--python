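"""Noisy acquisition, thinning, combination, bootstrap, dead time."""

import numpy as np
import pytest

import tcyspect as t
from tcyspect.acquisition import (DeadTimeModel, ProjectionSet,
                                  bootstrap_resample, combine_single_isotope,
                                  expected_projections, fit_dead_time,
                                  fit_ideal_slope, linearity_limit,
                                  observed_rate, poisson_sample,
                                  thin_projections)


@pytest.fixture(scope="module")
def geom():
    return t.SystemGeometry(n_angles=6, grid_shape=16, voxel_mm=9.6)


def _make_set(counts: dict, geom, duration=20.0, isotope="Tc"):
    return ProjectionSet(windows=counts, duration_s=duration, collimator="LEHR",
                         isotope=isotope, geometry=geom,
                         provenance=[{"op": "synthetic"}])


@pytest.fixture
def small_set(geom):
    rng = np.random.default_rng(5)
    return _make_set({"140": rng.poisson(8.0, (6, 16, 16)).astype(float),
                      "226": rng.poisson(3.0, (6, 16, 16)).astype(float)}, geom)


class TestAcquire:
    def test_noise_off_equals_expectation(self, test_phantom, spectrum,
                                          collimators):
        geom = t.SystemGeometry(n_angles=6, grid_shape=64, voxel_mm=9.6)
        ps = t.acquire(test_phantom, collimators["ME"], spectrum, geom, 20.0,
                       ("140",), noise=False, isotopes=("Tc",))
        proj = t.Projector(test_phantom.attenuation_per_cm, collimators["ME"],
                           "Tc", "140", spectrum, geom)
        np.testing.assert_allclose(
            ps.windows["140"], proj.forward(test_phantom.activity_mbq["Tc"]) * 20.0)
        assert ps.isotope == "Tc"

    def test_same_seed_reproduces(self, test_phantom, spectrum, collimators):
        geom = t.SystemGeometry(n_angles=4, grid_shape=64, voxel_mm=9.6)
        a = t.acquire(test_phantom, collimators["ME"], spectrum, geom, 20.0,
                      ("140",), seed=42, isotopes=("Tc",))
        b = t.acquire(test_phantom, collimators["ME"], spectrum, geom, 20.0,
                      ("140",), seed=42, isotopes=("Tc",))
        np.testing.assert_array_equal(a.windows["140"], b.windows["140"])
        assert a.provenance[0]["seed"] == 42

    def test_noisy_requires_seed(self, test_phantom, spectrum, collimators):
        geom = t.SystemGeometry(n_angles=4, grid_shape=64, voxel_mm=9.6)
        with pytest.raises(ValueError, match="seed"):
            t.acquire(test_phantom, collimators["ME"], spectrum, geom, 20.0,
                      ("140",), noise=True)

    def test_negative_duration_rejected(self, test_phantom, spectrum, collimators):
        geom = t.SystemGeometry(n_angles=4, grid_shape=64, voxel_mm=9.6)
        with pytest.raises(ValueError, match="duration"):
            t.acquire(test_phantom, collimators["ME"], spectrum, geom, -1.0,
                      ("140",), noise=False)

    def test_poisson_sampling_is_unbiased(self, geom):
        expect = _make_set({"140": np.full((6, 16, 16), 5.0)}, geom)
        totals = [poisson_sample(expect, seed).windows["140"][0, 0, 0]
                  for seed in range(600)]
        mean = np.mean(totals)
        se = np.sqrt(5.0 / 600)
        assert abs(mean - 5.0) < 3 * se


class TestThinning:
    def test_fraction_one_is_identity(self, small_set):
        out = thin_projections(small_set, 1.0, seed=0)
        np.testing.assert_array_equal(out.windows["140"], small_set.windows["140"])

    def test_fraction_zero_is_empty(self, small_set):
        out = thin_projections(small_set, 0.0, seed=0)
        assert not out.windows["140"].any()

    def test_half_fraction_totals_within_binomial_bound(self, geom):
        big = _make_set({"140": np.full((6, 16, 16), 651.0)}, geom)  # ~1e6 total
        total = big.windows["140"].sum()
        out = thin_projections(big, 0.5, seed=1)
        kept = out.windows["140"].sum()
        sd = np.sqrt(total * 0.25)
        assert abs(kept - 0.5 * total) < 5 * sd

    def test_non_integer_counts_rejected(self, geom):
        frac = _make_set({"140": np.full((6, 16, 16), 2.5)}, geom)
        with pytest.raises(ValueError, match="integer"):
            thin_projections(frac, 0.5, seed=0)

    def test_bad_fraction_rejected(self, small_set):
        with pytest.raises(ValueError):
            thin_projections(small_set, 1.5, seed=0)


class TestCombine:
    def test_zero_set_is_identity(self, small_set, geom):
        zero = _make_set({w: np.zeros_like(a) for w, a in small_set.windows.items()},
                         geom, isotope="Y")
        dual = combine_single_isotope(small_set, zero)
        for w in small_set.windows:
            np.testing.assert_array_equal(dual.windows[w], small_set.windows[w])
        assert dual.isotope == "dual"

    def test_totals_add_exactly(self, small_set, geom):
        rng = np.random.default_rng(9)
        other = _make_set({w: rng.poisson(2.0, a.shape).astype(float)
                           for w, a in small_set.windows.items()}, geom, isotope="Y")
        dual = combine_single_isotope(small_set, other)
        for w in small_set.windows:
            assert dual.windows[w].sum() == small_set.windows[w].sum() + \
                other.windows[w].sum()

    def test_mismatched_metadata_rejected(self, small_set, geom):
        other = _make_set(small_set.windows, geom, duration=10.0)
        with pytest.raises(ValueError, match="duration"):
            combine_single_isotope(small_set, other)
        other2 = ProjectionSet(windows=small_set.windows, duration_s=20.0,
                               collimator="HE", isotope="Y", geometry=geom)
        with pytest.raises(ValueError, match="collimator"):
            combine_single_isotope(small_set, other2)


class TestBootstrap:
    def test_preserves_window_totals_exactly(self, small_set):
        for res in bootstrap_resample(small_set, 5, seed=2):
            for w in small_set.windows:
                assert res.windows[w].sum() == small_set.windows[w].sum()

    def test_three_bases_times_25_gives_75(self, small_set):
        realizations = []
        for ib in range(3):
            realizations.extend(bootstrap_resample(small_set, 25, seed=ib))
        assert len(realizations) == 75

    def test_single_bin_resample_is_identity(self, geom):
        arr = np.zeros((6, 16, 16))
        arr[0, 0, 0] = 37.0
        single = _make_set({"140": arr}, geom)
        for res in bootstrap_resample(single, 3, seed=0):
            np.testing.assert_array_equal(res.windows["140"], arr)

    def test_all_zero_window_stays_zero(self, geom):
        empty = _make_set({"140": np.zeros((6, 16, 16))}, geom)
        res = bootstrap_resample(empty, 2, seed=0)
        assert not res[0].windows["140"].any()


class TestDeadTime:
    def test_identity_without_dead_time(self):
        dt = DeadTimeModel(tau_s=0.0, intrinsic_slope_cps_per_mbq=1e4)
        assert observed_rate(1234.5, dt) == 1234.5

    def test_maximum_at_inverse_tau(self):
        tau = 2e-6
        dt = DeadTimeModel(tau_s=tau, intrinsic_slope_cps_per_mbq=1e4)
        assert observed_rate(1.0 / tau, dt) == pytest.approx(np.exp(-1) / tau)

    def test_two_percent_deviation_closed_form(self):
        tau = 1e-6
        dt = DeadTimeModel(tau_s=tau, intrinsic_slope_cps_per_mbq=1e4)
        r = -np.log(0.98) / tau
        assert 1.0 - observed_rate(r, dt) / r == pytest.approx(0.02, rel=1e-12)

    def test_limit_monotone_in_tau(self):
        slope = 25.0
        limits = [linearity_limit(DeadTimeModel(tau_s=tau,
                                                intrinsic_slope_cps_per_mbq=1e4),
                                  slope, 0.02) for tau in (1e-7, 1e-6, 1e-5)]
        assert limits[0] > limits[1] > limits[2]

    def test_zero_tau_is_unbounded(self):
        dt = DeadTimeModel(tau_s=0.0, intrinsic_slope_cps_per_mbq=1e4)
        assert linearity_limit(dt, 25.0, 0.02) == np.inf

    def test_threshold_to_zero_limit_to_zero(self):
        dt = DeadTimeModel(tau_s=1e-6, intrinsic_slope_cps_per_mbq=1e4)
        assert linearity_limit(dt, 25.0, 1e-9) < linearity_limit(dt, 25.0, 1e-3)

    def test_ideal_slope_exact_on_linear_data(self):
        a = np.linspace(0.1, 5.0, 20)
        assert fit_ideal_slope(a, 17.0 * a, 10.0) == pytest.approx(17.0, rel=1e-12)

    def test_ideal_slope_robust_to_mild_dead_time(self):
        tau = 5e-7
        dt = DeadTimeModel(tau_s=tau, intrinsic_slope_cps_per_mbq=9e4)
        a = np.linspace(0.01, 30.0, 100)
        rates = observed_rate(a * 9e4 * 2.5e-4, dt)
        # cut chosen so R*tau < 1e-3 below it -> bias < 0.1%
        slope = fit_ideal_slope(a, rates, low_activity_cut_mbq=5.0)
        assert slope == pytest.approx(9e4 * 2.5e-4, rel=0.002)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_ideal_slope(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 0.5)

    def test_tau_recovery_from_noise_free_curve(self):
        tau = 7.5e-7
        dt = DeadTimeModel(tau_s=tau, intrinsic_slope_cps_per_mbq=9e4)
        r = np.linspace(1e4, 8e5, 20)
        assert fit_dead_time(r, observed_rate(r, dt)) == pytest.approx(tau, rel=0.02)
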