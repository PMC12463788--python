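"""Noisy data generation and count-rate procedures.

Turns expected projections into measured data (independent Poisson counts per
bin per window), and implements the data-manipulation procedures of the
study: pseudo-list-mode binomial thinning, synthetic dual-isotope combination
of single-isotope sets, multinomial bootstrap resampling, and the
paralyzable dead-time / count-rate linearity analysis.

Every stochastic operation takes an explicit seed and records it in the
output's provenance chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import VoxelPhantom
from .physics import (CollimatorModel, Projector, SpectrumModel, SystemGeometry)


@dataclass
class ProjectionSet:
    """Per-angle, per-window count arrays with acquisition metadata."""
    windows: dict[str, np.ndarray]      # window -> (n_angles, n, n) counts
    duration_s: float
    collimator: str
    isotope: str                        # "Tc" | "Y" | "dual"
    geometry: SystemGeometry
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {w: a.shape for w, a in self.windows.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"window arrays disagree in shape: {shapes}")
        for w, a in self.windows.items():
            if np.any(a < 0):
                raise ValueError(f"negative counts in window {w}")

    def total_counts(self, window: str) -> float:
        return float(self.windows[window].sum())

    def is_integer(self) -> bool:
        return all(np.allclose(a, np.round(a)) for a in self.windows.values())

    def copy_with(self, windows: dict[str, np.ndarray], note: dict) -> "ProjectionSet":
        return replace(self, windows=windows,
                       provenance=self.provenance + [note])


def acquire(phantom: VoxelPhantom, collimator: CollimatorModel,
            spectrum: SpectrumModel, geometry: SystemGeometry,
            duration_s: float, windows: tuple[str, ...],
            seed: int | None = None, noise: bool = True,
            isotopes: tuple[str, ...] | None = None) -> ProjectionSet:
    """Simulate an acquisition of the phantom.

    Expected counts per bin are the summed forward projections of all
    isotope activity maps times the per-projection duration; with ``noise``
    each bin is an independent Poisson sample.
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if noise and seed is None:
        raise ValueError("a seed is required for a noisy acquisition")
    if isotopes is None:
        isotopes = tuple(iso for iso, amap in phantom.activity_mbq.items()
                         if amap.sum() > 0)
    expected: dict[str, np.ndarray] = {}
    for win in windows:
        tot = None
        for iso in isotopes:
            s_p, s_d = spectrum.window_sensitivity(iso, collimator.name, win)
            if s_p == 0 and s_d == 0:
                continue
            proj = Projector(phantom.attenuation_per_cm, collimator, iso, win,
                             spectrum, geometry)
            arr = proj.forward(phantom.activity_mbq[iso]) * duration_s
            tot = arr if tot is None else tot + arr
        n = geometry.grid_shape
        expected[win] = tot if tot is not None else np.zeros(
            (geometry.n_angles, n, n))

    if noise:
        rng = np.random.default_rng(seed)
        data = {w: rng.poisson(e).astype(np.float64) for w, e in expected.items()}
    else:
        data = expected
    tag = "dual" if len(isotopes) > 1 else (isotopes[0] if isotopes else "none")
    prov = [{"op": "acquire", "seed": seed, "noise": noise,
             "isotopes": list(isotopes), "duration_s": duration_s,
             "collimator": collimator.name}]
    return ProjectionSet(windows=data, duration_s=duration_s,
                         collimator=collimator.name, isotope=tag,
                         geometry=geometry, provenance=prov)


def expected_projections(phantom: VoxelPhantom, isotope: str,
                         collimator: CollimatorModel, spectrum: SpectrumModel,
                         geometry: SystemGeometry, duration_s: float,
                         windows: tuple[str, ...]) -> ProjectionSet:
    """Noise-free single-isotope expectation (convenience wrapper)."""
    return acquire(phantom, collimator, spectrum, geometry, duration_s,
                   windows, noise=False, isotopes=(isotope,))


def poisson_sample(expected: ProjectionSet, seed: int) -> ProjectionSet:
    """Draw one Poisson realization of an expectation-mode ProjectionSet."""
    rng = np.random.default_rng(seed)
    data = {w: rng.poisson(e).astype(np.float64)
            for w, e in expected.windows.items()}
    return expected.copy_with(data, {"op": "poisson_sample", "seed": seed})


def thin_projections(proj: ProjectionSet, fraction: float, seed: int) -> ProjectionSet:
    """Pseudo-list-mode thinning: keep each recorded count with ``fraction``.

    Each bin is replaced by a binomial draw, emulating an acquisition at
    proportionally lower activity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not proj.is_integer():
        raise ValueError("thinning requires integer counts (recorded events)")
    rng = np.random.default_rng(seed)
    data = {w: rng.binomial(a.astype(np.int64), fraction).astype(np.float64)
            for w, a in proj.windows.items()}
    return proj.copy_with(data, {"op": "thin", "fraction": fraction, "seed": seed})


def combine_single_isotope(proj_tc: ProjectionSet, proj_y: ProjectionSet) -> ProjectionSet:
    """Synthetic dual-isotope set: per-bin, per-window sum of two sets."""
    if proj_tc.collimator != proj_y.collimator:
        raise ValueError("collimators differ between the two sets")
    if proj_tc.geometry != proj_y.geometry:
        raise ValueError("geometries differ between the two sets")
    if proj_tc.duration_s != proj_y.duration_s:
        raise ValueError("durations differ between the two sets")
    if set(proj_tc.windows) != set(proj_y.windows):
        raise ValueError("window sets differ between the two sets")
    data = {w: proj_tc.windows[w] + proj_y.windows[w] for w in proj_tc.windows}
    return ProjectionSet(
        windows=data, duration_s=proj_tc.duration_s,
        collimator=proj_tc.collimator, isotope="dual", geometry=proj_tc.geometry,
        provenance=proj_tc.provenance + proj_y.provenance + [{"op": "combine"}])


def bootstrap_resample(proj: ProjectionSet, n_resamples: int,
                       seed: int) -> list[ProjectionSet]:
    """Multinomial bootstrap: redistribute each window's total count over
    bins with probabilities proportional to the original counts.

    Every resample preserves the per-window total exactly.
    """
    if not proj.is_integer():
        raise ValueError("bootstrap requires integer counts")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_resamples):
        data = {}
        for w, a in proj.windows.items():
            total = int(round(a.sum()))
            if total == 0:
                data[w] = np.zeros_like(a)
                continue
            p = (a / a.sum()).ravel()
            data[w] = rng.multinomial(total, p).reshape(a.shape).astype(np.float64)
        out.append(proj.copy_with(data, {"op": "bootstrap", "seed": seed,
                                         "resample": r}))
    return out


# ---------------------------------------------------------------------------
# Dead time and count-rate linearity

@dataclass(frozen=True)
class DeadTimeModel:
    """Paralyzable dead time: R_obs = R_true * exp(-R_true * tau)."""
    tau_s: float
    intrinsic_slope_cps_per_mbq: float
    extrinsic_intrinsic_ratio: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValueError("tau must be >= 0")
        if self.intrinsic_slope_cps_per_mbq <= 0:
            raise ValueError("intrinsic slope must be > 0")


def observed_rate(true_rate_cps: float | np.ndarray,
                  dead_time: DeadTimeModel) -> np.ndarray:
    """Observed count rate under the paralyzable dead-time model."""
    r = np.asarray(true_rate_cps, dtype=float)
    if np.any(r < 0):
        raise ValueError("true rate must be >= 0")
    return r * np.exp(-r * dead_time.tau_s)


def linearity_limit(dead_time: DeadTimeModel, activity_to_rate_cps_per_mbq: float,
                    threshold: float) -> float:
    """Activity (MBq) at which observed rates first deviate by ``threshold``.

    The paralyzable relative deviation 1 - R_obs/R_true = 1 - exp(-R tau)
    reaches the threshold at R = -ln(1-threshold)/tau; dividing by the
    activity-to-rate slope gives the activity limit.  Infinite when tau = 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if activity_to_rate_cps_per_mbq <= 0:
        raise ValueError("activity-to-rate slope must be > 0")
    if dead_time.tau_s == 0:
        return float("inf")
    rate = -np.log1p(-threshold) / dead_time.tau_s
    return float(rate / activity_to_rate_cps_per_mbq)


def fit_ideal_slope(activities_mbq: np.ndarray, rates_cps: np.ndarray,
                    low_activity_cut_mbq: float) -> float:
    """Ideal count-rate slope (cps/MBq) from low-activity measurements.

    Least-squares line through the origin using only points below the cut,
    where dead-time losses are assumed negligible.
    """
    a = np.asarray(activities_mbq, dtype=float)
    r = np.asarray(rates_cps, dtype=float)
    sel = a < low_activity_cut_mbq
    if np.count_nonzero(sel) < 2:
        raise ValueError(f"need >= 2 points below {low_activity_cut_mbq} MBq, "
                         f"have {int(np.count_nonzero(sel))}")
    x, y = a[sel], r[sel]
    return float(np.dot(x, y) / np.dot(x, x))


def fit_dead_time(true_rates_cps: np.ndarray, observed_rates_cps: np.ndarray) -> float:
    """Recover the paralyzable tau from (true, observed) rate pairs."""
    from scipy.optimize import curve_fit

    def model(r, tau):
        return r * np.exp(-r * tau)

    r = np.asarray(true_rates_cps, dtype=float)
    o = np.asarray(observed_rates_cps, dtype=float)
    tau0 = 1.0 / max(r.max(), 1.0)
    popt, _ = curve_fit(model, r, o, p0=[tau0])
    return float(popt[0])
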