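"""Crosstalk background estimators and the method-aware reconstructor."""

import numpy as np
import pytest

import tcyspect as t
from tcyspect.acquisition import ProjectionSet
from tcyspect.corrections import (CorrectionMethod, SpectSystem,
                                  calibrate_k_factor, estimate_background_dew,
                                  estimate_background_mc,
                                  estimate_background_tew, reconstruct_tc)
from tcyspect.reconstruction import OsemConfig, osem


@pytest.fixture(scope="module")
def dual_toy(spectrum, collimators):
    """Noise-free dual-isotope toy on a 32^3 grid with the ME collimator."""
    n = 32
    geom = t.SystemGeometry(n_angles=30, grid_shape=n, voxel_mm=9.6)
    me = collimators["ME"]
    c = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    body = (X ** 2 + Y ** 2 + Z ** 2) <= 12 ** 2
    hot = ((X - 4) ** 2 + Y ** 2 + Z ** 2) <= 3 ** 2
    tc_map = np.where(body, 1.0, 0.0)
    tc_map[hot] = 4.0
    y_map = np.where(body, 20.0, 0.0)
    mu = np.where(body, 0.08, 0.0)
    system = SpectSystem(mu, me, spectrum, geom)
    dur = 20.0
    wins = {}
    for w in ("125", "140", "155", "226"):
        tot = np.zeros((geom.n_angles, n, n))
        for iso, amap in (("Tc", tc_map), ("Y", y_map)):
            if sum(spectrum.window_sensitivity(iso, "ME", w)) > 0:
                tot += system.projector(iso, w).forward(amap) * dur
        wins[w] = tot
    ps = ProjectionSet(windows=wins, duration_s=dur, collimator="ME",
                       isotope="dual", geometry=geom)
    true_bg = system.projector("Y", "140").forward(y_map) * dur
    cnr_masks = (hot, body & ~hot & ((X ** 2 + Y ** 2 + Z ** 2) <= 9 ** 2))
    return {"system": system, "ps": ps, "true_bg": true_bg, "tc_map": tc_map,
            "y_map": y_map, "cnr_masks": cnr_masks, "geom": geom}


class TestDew:
    def test_scales_counts_by_k(self):
        out = estimate_background_dew(np.full((2, 4, 4), 100.0), 0.478)
        np.testing.assert_allclose(out, 47.8)

    def test_k_one_is_identity(self):
        arr = np.arange(8.0).reshape(2, 2, 2)
        np.testing.assert_array_equal(estimate_background_dew(arr, 1.0), arr)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            estimate_background_dew(np.ones((2, 2)), 0.0)

    def test_dew_consistent_simulator(self, dual_toy, collimators):
        # The simulator's 90Y model is spectrally uniform, so k * (226 window)
        # reproduces the true 140 keV crosstalk total.
        bg = estimate_background_dew(dual_toy["ps"].windows["226"],
                                     collimators["ME"].k_factor)
        # the 226 window contains only Y counts here
        assert bg.sum() == pytest.approx(dual_toy["true_bg"].sum(), rel=0.01)


class TestTew:
    def test_mean_of_windows(self):
        out = estimate_background_tew(np.full((2, 2), 10.0), np.full((2, 2), 30.0))
        np.testing.assert_allclose(out, 20.0)

    def test_zero_windows_zero_background(self):
        assert not estimate_background_tew(np.zeros((3, 3)), np.zeros((3, 3))).any()

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            estimate_background_tew(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMc:
    def test_tc_only_data_gives_zero_background(self, dual_toy):
        ps = dual_toy["ps"]
        empty = ProjectionSet(
            windows={**ps.windows, "226": np.zeros_like(ps.windows["226"])},
            duration_s=ps.duration_s, collimator=ps.collimator,
            isotope="Tc", geometry=ps.geometry)
        bg, rec = estimate_background_mc(empty, dual_toy["system"],
                                         OsemConfig(iterations=3, subsets=5))
        assert not bg.any()
        assert rec is None

    def test_noise_free_background_within_10pct(self, dual_toy):
        bg, _ = estimate_background_mc(dual_toy["ps"], dual_toy["system"],
                                       OsemConfig(iterations=10, subsets=5),
                                       cnr_masks=dual_toy["cnr_masks"])
        err = abs(bg.sum() - dual_toy["true_bg"].sum()) / dual_toy["true_bg"].sum()
        assert err < 0.10

    def test_background_linear_in_y_activity(self, dual_toy):
        cfg = OsemConfig(iterations=6, subsets=5)
        bg1, _ = estimate_background_mc(dual_toy["ps"], dual_toy["system"], cfg,
                                        cnr_masks=dual_toy["cnr_masks"])
        ps = dual_toy["ps"]
        system = dual_toy["system"]
        wins2 = {}
        for w, arr in ps.windows.items():
            extra = np.zeros_like(arr)
            if sum(system.spectrum.window_sensitivity("Y", "ME", w)) > 0:
                extra = system.projector("Y", w).forward(dual_toy["y_map"]) * \
                    ps.duration_s
            wins2[w] = arr + extra
        ps2 = ProjectionSet(windows=wins2, duration_s=ps.duration_s,
                            collimator=ps.collimator, isotope="dual",
                            geometry=ps.geometry)
        bg2, _ = estimate_background_mc(ps2, system, cfg,
                                        cnr_masks=dual_toy["cnr_masks"])
        assert bg2.sum() / bg1.sum() == pytest.approx(2.0, rel=0.02)

    def test_missing_estimation_window_rejected(self, dual_toy):
        ps = dual_toy["ps"]
        no226 = ProjectionSet(
            windows={w: a for w, a in ps.windows.items() if w != "226"},
            duration_s=ps.duration_s, collimator=ps.collimator,
            isotope="dual", geometry=ps.geometry)
        with pytest.raises(KeyError, match="226"):
            estimate_background_mc(no226, dual_toy["system"], OsemConfig())


class TestCalibrateKFactor:
    @pytest.mark.parametrize("name,k", [("LEHR", 0.478), ("ME", 0.632),
                                        ("HE", 0.745)])
    def test_reproduces_configured_k(self, spectrum, collimators, name, k):
        geom = t.SystemGeometry(n_angles=8, grid_shape=32, voxel_mm=9.6)
        assert calibrate_k_factor(spectrum, collimators[name], geom) == \
            pytest.approx(k, abs=5e-4)


class TestReconstructTc:
    def test_method_none_matches_plain_osem(self, dual_toy):
        cfg = OsemConfig(iterations=3, subsets=5)
        ps = dual_toy["ps"]
        rec = reconstruct_tc(ps, CorrectionMethod("none"), dual_toy["system"], cfg)
        proj = dual_toy["system"].projector("Tc", "140")
        ref = osem(ps.windows["140"], proj, ps.duration_s, None, cfg)
        np.testing.assert_array_equal(rec.image, ref.image)

    def test_dew_background_total_close_to_truth(self, dual_toy, collimators):
        cfg = OsemConfig(iterations=2, subsets=5)
        method = CorrectionMethod("dew", k_factor=collimators["ME"].k_factor)
        rec = reconstruct_tc(dual_toy["ps"], method, dual_toy["system"], cfg)
        assert rec.provenance["method"] == "dew"

    def test_tew_with_empty_scatter_windows_matches_primary_only_osem(
            self, dual_toy):
        cfg = OsemConfig(iterations=2, subsets=5)
        ps = dual_toy["ps"]
        empty = ProjectionSet(
            windows={"140": ps.windows["140"],
                     "125": np.zeros_like(ps.windows["125"]),
                     "155": np.zeros_like(ps.windows["155"])},
            duration_s=ps.duration_s, collimator=ps.collimator,
            isotope="dual", geometry=ps.geometry)
        rec = reconstruct_tc(empty, CorrectionMethod("tew"),
                             dual_toy["system"], cfg)
        proj = dual_toy["system"].projector("Tc", "140", include_diffuse=False)
        ref = osem(ps.windows["140"], proj, ps.duration_s, None, cfg)
        np.testing.assert_array_equal(rec.image, ref.image)

    def test_missing_required_window_named(self, dual_toy):
        ps = dual_toy["ps"]
        no125 = ProjectionSet(
            windows={w: a for w, a in ps.windows.items() if w != "125"},
            duration_s=ps.duration_s, collimator=ps.collimator,
            isotope="dual", geometry=ps.geometry)
        with pytest.raises(KeyError, match="125"):
            reconstruct_tc(no125, CorrectionMethod("tew"), dual_toy["system"],
                           OsemConfig())

    def test_dew_crc_not_worse_than_uncorrected_noise_free(self, dual_toy,
                                                           collimators):
        # On noise-free DEW-consistent data the corrected reconstruction
        # recovers at least the contrast of the uncorrected one.
        cfg = OsemConfig(iterations=8, subsets=5)
        ps = dual_toy["ps"]
        hot, core_bg = dual_toy["cnr_masks"]
        rec_none = reconstruct_tc(ps, CorrectionMethod("none"),
                                  dual_toy["system"], cfg)
        rec_dew = reconstruct_tc(
            ps, CorrectionMethod("dew", k_factor=collimators["ME"].k_factor),
            dual_toy["system"], cfg)

        def contrast(img):
            return img[hot].mean() / img[core_bg].mean()

        assert contrast(rec_dew.image) >= contrast(rec_none.image)


class TestCorrectionMethod:
    def test_dew_requires_k(self):
        with pytest.raises(ValueError, match="k-factor"):
            CorrectionMethod("dew")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            CorrectionMethod("abc")

    def test_tew_disables_scatter_model(self):
        assert CorrectionMethod("tew").include_tc_scatter_model is False
        assert CorrectionMethod("mc").include_tc_scatter_model is True
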