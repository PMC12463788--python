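"""90Y crosstalk compensation for the 140 keV technetium window.

Three estimators of the 90Y bremsstrahlung background contaminating the
99mTc photopeak window, each feeding the OSEM background term:

* **MC** — reconstruct a 90Y image from the 226 keV window (which carries no
  99mTc signal) with the 90Y system model, halting near CNR convergence, and
  forward-project it through the 90Y 140 keV model in expectation mode.
* **DEW** — scale the measured 226 keV counts by the collimator's k-factor.
* **TEW** — average the 125 and 155 keV flanking windows per bin.  Because
  this estimate already contains scattered 99mTc, the model-based 99mTc
  scatter component is excluded from the forward model in this mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .acquisition import ProjectionSet
from .physics import (CollimatorModel, Projector, SpectrumModel, SystemGeometry,
                      point_source_window_counts)
from .reconstruction import (OsemConfig, ReconVolume, cnr_stop,
                             contrast_noise_ratio, osem)

log = logging.getLogger(__name__)

METHODS = ("none", "mc", "dew", "tew")


@dataclass(frozen=True)
class CorrectionMethod:
    """Configuration of one crosstalk compensation method."""
    name: str                       # none | mc | dew | tew
    k_factor: float | None = None   # DEW only
    estimation_window: str = "226"  # 226 default, 181 optional

    def __post_init__(self) -> None:
        if self.name not in METHODS:
            raise ValueError(f"unknown method {self.name!r}; expected one of {METHODS}")
        if self.name == "dew" and (self.k_factor is None or self.k_factor <= 0):
            raise ValueError("DEW requires a positive k-factor")

    @property
    def include_tc_scatter_model(self) -> bool:
        # TEW's background absorbs the 99mTc scatter estimate, so the
        # model-based scatter component must be off.
        return self.name != "tew"

    def required_windows(self) -> tuple[str, ...]:
        if self.name in ("mc", "dew"):
            return ("140", self.estimation_window)
        if self.name == "tew":
            return ("140", "125", "155")
        return ("140",)


@dataclass
class SpectSystem:
    """Bundle of the system model shared by simulator and reconstructor."""
    attenuation: np.ndarray
    collimator: CollimatorModel
    spectrum: SpectrumModel
    geometry: SystemGeometry

    def __post_init__(self) -> None:
        self._cache: dict[tuple[str, str, bool], Projector] = {}

    def projector(self, isotope: str, window: str, *,
                  include_diffuse: bool = True) -> Projector:
        # Projectors are stateless apart from their attenuation cache, so
        # they are shared across reconstructions of the same system.
        key = (isotope, window, include_diffuse)
        if key not in self._cache:
            self._cache[key] = Projector(
                self.attenuation, self.collimator, isotope, window,
                self.spectrum, self.geometry, include_diffuse=include_diffuse)
        return self._cache[key]


def estimate_background_dew(proj_est_window: np.ndarray, k: float) -> np.ndarray:
    """Expected 90Y counts in the 140 keV window: per-bin k-factor scaling."""
    if k <= 0:
        raise ValueError("k-factor must be > 0")
    return k * np.asarray(proj_est_window, dtype=np.float64)


def estimate_background_tew(proj125: np.ndarray, proj155: np.ndarray) -> np.ndarray:
    """Non-primary counts in the 140 keV window: mean of flanking windows."""
    a = np.asarray(proj125, dtype=np.float64)
    b = np.asarray(proj155, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"window shapes differ: {a.shape} vs {b.shape}")
    return 0.5 * (a + b)


def estimate_background_mc(proj_set: ProjectionSet, system: SpectSystem,
                           config: OsemConfig, estimation_window: str = "226",
                           cnr_masks: tuple[np.ndarray, np.ndarray] | None = None
                           ) -> tuple[np.ndarray, ReconVolume | None]:
    """Model-based 90Y background: auxiliary reconstruction + reprojection.

    Reconstructs a 90Y image from the estimation window with the 90Y system
    model, halting when the CNR increase stays below 2% for three consecutive
    iterations, then forward-projects it through the 90Y 140 keV model in
    expectation (noise-free) mode.  Returns the expected 140 keV background
    counts and the auxiliary reconstruction.
    """
    if estimation_window not in proj_set.windows:
        raise KeyError(f"estimation window {estimation_window!r} missing from data")
    y_est = proj_set.windows[estimation_window]
    if y_est.sum() == 0:
        log.warning("estimation window %s is empty; returning zero background",
                    estimation_window)
        return np.zeros_like(y_est), None

    proj_y = system.projector("Y", estimation_window)
    if cnr_masks is None:
        hot_mask, bg_mask = _auto_cnr_masks(proj_set, proj_y, config)
    else:
        hot_mask, bg_mask = cnr_masks

    history: list[float] = []

    def stop_when_converged(it: int, image: np.ndarray) -> bool:
        history.append(contrast_noise_ratio(image, hot_mask, bg_mask))
        if len(history) < 4:
            return False
        return cnr_stop(np.array(history)) < len(history) - 1

    recon = osem(y_est, proj_y, proj_set.duration_s, None, config,
                 callback=stop_when_converged)
    stop_it = cnr_stop(np.array(history)) if history else recon.n_iterations - 1
    y_image = recon.snapshots[min(stop_it, recon.n_iterations - 1)]

    proj_140 = system.projector("Y", "140")
    background = proj_140.forward(y_image) * proj_set.duration_s
    return background, recon


def _auto_cnr_masks(proj_set: ProjectionSet, proj_y: Projector,
                    config: OsemConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fallback CNR masks derived from a short pilot reconstruction."""
    pilot = osem(proj_set.windows[proj_y.window], proj_y, proj_set.duration_s,
                 None, OsemConfig(iterations=2, subsets=config.subsets,
                                  floor=config.floor))
    img = pilot.image
    pos = img > 0
    hot = img >= np.quantile(img[pos], 0.90) if pos.any() else np.zeros_like(pos)
    bg = pos & ~hot
    if not hot.any() or bg.sum() < 2:
        raise ValueError("cannot derive CNR masks from pilot reconstruction")
    return hot, bg


def calibrate_k_factor(spectrum: SpectrumModel, collimator: CollimatorModel,
                       geometry: SystemGeometry) -> float:
    """k-factor from an expectation-mode 90Y point-source simulation.

    Total 140 keV counts divided by total 226 keV counts for a point source
    centred in a water cylinder.
    """
    counts = point_source_window_counts(10.0, "Y", collimator, spectrum,
                                        geometry, windows=("140", "226"))
    if counts["226"] == 0:
        raise ZeroDivisionError("no counts in the 226 keV window")
    return counts["140"] / counts["226"]


def reconstruct_tc(proj_set: ProjectionSet, method: CorrectionMethod,
                   system: SpectSystem, config: OsemConfig,
                   cnr_masks: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> ReconVolume:
    """Method-aware 99mTc reconstruction of the 140 keV window."""
    for win in method.required_windows():
        if win not in proj_set.windows:
            raise KeyError(f"method {method.name!r} requires the {win} keV window, "
                           "which is missing from the projection set")

    if method.name == "none":
        background = None
    elif method.name == "mc":
        background, _ = estimate_background_mc(
            proj_set, system, config, method.estimation_window, cnr_masks)
    elif method.name == "dew":
        background = estimate_background_dew(
            proj_set.windows[method.estimation_window], method.k_factor)
    else:  # tew
        background = estimate_background_tew(proj_set.windows["125"],
                                             proj_set.windows["155"])
    assert background is None or np.all(background >= 0)

    proj_tc = system.projector("Tc", "140",
                               include_diffuse=method.include_tc_scatter_model)
    recon = osem(proj_set.windows["140"], proj_tc, proj_set.duration_s,
                 background, config)
    recon.provenance.update({
        "method": method.name,
        "windows_used": list(method.required_windows()),
        "estimation_window": method.estimation_window if method.name in
        ("mc", "dew") else None,
    })
    return recon
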