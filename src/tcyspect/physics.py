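"""Deterministic SPECT system model.

The physics is a two-component expectation model per (isotope, collimator,
energy window): a *primary* component carrying the distance-dependent
geometric collimator response, and a *diffuse* component (object scatter,
septal penetration, bremsstrahlung haze) modeled as the primary projection
convolved with a broad stationary Gaussian.  Both components share the
attenuated rotation-based line projector, so the full operator is linear and
its exact adjoint is available for iterative reconstruction.

The 90Y bremsstrahlung continuum is spectrally smooth, so its primary/diffuse
split and blur are shared by all energy windows of a collimator; the ratio of
total 90Y counts between the 140 and 226 keV windows therefore equals the
collimator's configured k-factor for any source distribution — the property
the dual-energy-window correction relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

from .config import load_defaults

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

WINDOW_NAMES = ("125", "140", "155", "181", "226", "full")
NARROW_WINDOWS = ("125", "140", "155", "181", "226")


@dataclass(frozen=True)
class CollimatorModel:
    """Parallel-hole collimator geometry and its measured k-factor."""
    name: str
    hole_length_mm: float
    septal_thickness_mm: float
    hole_diameter_mm: float
    penetration_scale: float
    k_factor: float

    def __post_init__(self) -> None:
        for f in ("hole_length_mm", "septal_thickness_mm", "hole_diameter_mm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be > 0")

    @property
    def effective_diameter_mm(self) -> float:
        # Septal penetration folded into an effective hole diameter.
        return self.hole_diameter_mm * (1.0 + self.penetration_scale)

    @classmethod
    def from_config(cls, name: str, cfg: dict | None = None) -> "CollimatorModel":
        cfg = cfg if cfg is not None else load_defaults()
        try:
            c = cfg["collimators"][name]
        except KeyError:
            raise KeyError(f"unknown collimator {name!r}; have "
                           f"{sorted(cfg['collimators'])}") from None
        return cls(name=name, **c)


def psf_sigma(collimator: CollimatorModel, distance_mm: float | np.ndarray) -> np.ndarray:
    """Gaussian sigma (mm) of the geometric collimator response at a distance.

    FWHM(z) = d_eff * (L + z) / L with L the hole length; monotone in z and
    collimator-limited (FWHM ~ d_eff) at the face.
    """
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    fwhm = collimator.effective_diameter_mm * (collimator.hole_length_mm + d) \
        / collimator.hole_length_mm
    return fwhm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class EnergyWindowSet:
    """Named acquisition energy windows with [low, high] bounds in keV."""
    bounds_kev: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        narrow = [(self.bounds_kev[w][0], self.bounds_kev[w][1], w)
                  for w in NARROW_WINDOWS if w in self.bounds_kev]
        for lo, hi, w in narrow:
            if not lo < hi:
                raise ValueError(f"window {w}: bounds must be ascending")
        for (a_lo, a_hi, a), (b_lo, b_hi, b) in zip(narrow, narrow[1:]):
            if a_hi > b_lo:
                raise ValueError(f"windows {a} and {b} overlap")

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "EnergyWindowSet":
        cfg = cfg if cfg is not None else load_defaults()
        return cls(bounds_kev={w: tuple(b) for w, b in cfg["energy_windows_kev"].items()})

    def __contains__(self, window: str) -> bool:
        return window in self.bounds_kev


@dataclass(frozen=True)
class SpectrumModel:
    """Per (isotope, collimator, window) detection fractions and blur scales.

    ``sensitivity[(iso, coll, win)] = (primary, diffuse)`` in cps/MBq;
    ``diffuse_fwhm_mm[(iso, coll)]`` is the stationary blur of the diffuse
    component.  The 90Y entries are constructed from the collimator k-factor:
    s(140) = k * s(226), identically split, so the k-factor invariant holds by
    construction and closes the loop with the point-source calibration.
    """
    sensitivity: dict[tuple[str, str, str], tuple[float, float]]
    diffuse_fwhm_mm: dict[tuple[str, str], float]

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "SpectrumModel":
        cfg = cfg if cfg is not None else load_defaults()
        spec = cfg["spectrum"]
        sens: dict[tuple[str, str, str], tuple[float, float]] = {}
        fwhm: dict[tuple[str, str], float] = {}

        for coll, windows in spec["Tc"]["windows"].items():
            fwhm[("Tc", coll)] = float(spec["Tc"]["diffuse_fwhm_mm"][coll])
            for win, (p, d) in windows.items():
                sens[("Tc", coll, win)] = (float(p), float(d))

        y = spec["Y"]
        for coll, s226 in y["s226_cps_per_mbq"].items():
            fwhm[("Y", coll)] = float(y["diffuse_fwhm_mm"][coll])
            pf = float(y["primary_fraction"][coll])
            k = float(cfg["collimators"][coll]["k_factor"])
            totals = {"226": float(s226), "140": k * float(s226)}
            for win, rel in y["window_rel_140"].items():
                totals[win] = float(rel) * totals["140"]
            for win, tot in totals.items():
                sens[("Y", coll, win)] = (pf * tot, (1.0 - pf) * tot)

        model = cls(sensitivity=sens, diffuse_fwhm_mm=fwhm)
        for v in sens.values():
            assert v[0] >= 0 and v[1] >= 0
        return model

    def window_sensitivity(self, isotope: str, collimator: str, window: str) -> tuple[float, float]:
        try:
            return self.sensitivity[(isotope, collimator, window)]
        except KeyError:
            raise KeyError(f"no spectrum entry for isotope={isotope!r}, "
                           f"collimator={collimator!r}, window={window!r}") from None


@dataclass(frozen=True)
class SystemGeometry:
    """Acquisition geometry: circular orbit, detector bins at voxel pitch."""
    n_angles: int = 120
    rotation_radius_mm: float = 250.0
    grid_shape: int = 128
    voxel_mm: float = 4.8

    def __post_init__(self) -> None:
        if self.n_angles <= 0:
            raise ValueError("n_angles must be > 0")
        if self.grid_shape * self.voxel_mm / 2.0 > self.rotation_radius_mm + \
                self.grid_shape * self.voxel_mm:
            raise ValueError("rotation radius too small for the grid")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * 360.0 / self.n_angles


# ---------------------------------------------------------------------------
# Rotation operator (exact sparse adjoint)

_ROT_CACHE: dict[tuple[int, float], sparse.csr_matrix] = {}


def _rotation_matrix(n: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear in-plane rotation of an (n, n) grid about its centre.

    Output voxel p samples the input at rot(-angle) p, so applying the matrix
    rotates image content by +angle.  The transpose is the exact adjoint.
    """
    key = (n, round(float(angle_deg) % 360.0, 9))
    mat = _ROT_CACHE.get(key)
    if mat is not None:
        return mat
    theta = np.deg2rad(angle_deg)
    c0 = (n - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x = ii.ravel() - c0
    y = jj.ravel() - c0
    cos, sin = np.cos(theta), np.sin(theta)
    sx = cos * x + sin * y + c0
    sy = -sin * x + cos * y + c0
    i0 = np.floor(sx).astype(np.int64)
    j0 = np.floor(sy).astype(np.int64)
    fx = sx - i0
    fy = sy - j0
    rows, cols, data = [], [], []
    out_idx = np.arange(n * n)
    for di, dj, w in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                      (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
        si = i0 + di
        sj = j0 + dj
        ok = (si >= 0) & (si < n) & (sj >= 0) & (sj < n) & (w > 0)
        rows.append(out_idx[ok])
        cols.append((si * n + sj)[ok])
        data.append(w[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n)).tocsr()
    _ROT_CACHE[key] = mat
    return mat


def _apply_rotation(vol: np.ndarray, mat: sparse.csr_matrix, transpose: bool) -> np.ndarray:
    n = vol.shape[0]
    m = mat.T if transpose else mat
    return (m @ vol.reshape(n * n, -1)).reshape(vol.shape)


# ---------------------------------------------------------------------------
# Projector

class Projector:
    """Linear expectation model A for one (isotope, collimator, window).

    ``forward`` maps an activity volume (MBq per voxel) to expected count
    rates (cps) per detector bin for each projection angle; ``adjoint`` is the
    exact matrix transpose.  Rotation matrices and per-angle attenuation
    factors are cached across calls, which makes repeated application inside
    OSEM cheap.
    """

    _ATT_CACHE_LIMIT_BYTES = 512 * 1024 * 1024

    def __init__(self, attenuation: np.ndarray, collimator: CollimatorModel,
                 isotope: str, window: str, spectrum: SpectrumModel,
                 geometry: SystemGeometry, *, include_primary: bool = True,
                 include_diffuse: bool = True, windows: EnergyWindowSet | None = None):
        attenuation = np.asarray(attenuation, dtype=np.float64)
        n = geometry.grid_shape
        if attenuation.shape != (n, n, n):
            raise ValueError(f"attenuation shape {attenuation.shape} does not match "
                             f"geometry grid {(n, n, n)}")
        if windows is not None and window not in windows:
            raise KeyError(f"unknown energy window {window!r}")
        self.attenuation = attenuation
        self.collimator = collimator
        self.isotope = isotope
        self.window = window
        self.spectrum = spectrum
        self.geometry = geometry
        self.include_primary = include_primary
        self.include_diffuse = include_diffuse

        self.s_primary, self.s_diffuse = spectrum.window_sensitivity(
            isotope, collimator.name, window)
        self.diffuse_sigma_px = spectrum.diffuse_fwhm_mm[(isotope, collimator.name)] \
            * FWHM_TO_SIGMA / geometry.voxel_mm

        # Distance from each rotated x-plane to the collimator face and the
        # corresponding PSF sigma in pixels.
        x_world = (np.arange(n) - (n - 1) / 2.0) * geometry.voxel_mm
        dist = np.maximum(geometry.rotation_radius_mm - x_world, 0.0)
        self.psf_sigma_px = psf_sigma(collimator, dist) / geometry.voxel_mm

        self._att_cache: dict[int, np.ndarray] = {}
        self._att_cacheable = (geometry.n_angles * attenuation.nbytes / 2
                               < self._ATT_CACHE_LIMIT_BYTES)

    # -- helpers -----------------------------------------------------------

    def _att_factors(self, angle_idx: int) -> np.ndarray:
        att = self._att_cache.get(angle_idx)
        if att is not None:
            return att
        mat = _rotation_matrix(self.geometry.grid_shape,
                               self.geometry.angles_deg[angle_idx])
        mu = _apply_rotation(self.attenuation, mat, transpose=False)
        dx_cm = self.geometry.voxel_mm / 10.0
        # Path integral from each voxel to the detector (+x side), counting
        # half of the voxel's own attenuation.
        path = np.cumsum(mu[::-1], axis=0)[::-1] - 0.5 * mu
        att = np.exp(-path * dx_cm).astype(np.float32)
        if self._att_cacheable:
            self._att_cache[angle_idx] = att
        return att

    def _window_combine(self, proj: np.ndarray) -> np.ndarray:
        out = np.zeros_like(proj)
        if self.include_primary and self.s_primary > 0:
            out += self.s_primary * proj
        if self.include_diffuse and self.s_diffuse > 0:
            out += self.s_diffuse * gaussian_filter(
                proj, self.diffuse_sigma_px, mode="constant")
        return out

    # -- operator ----------------------------------------------------------

    def forward(self, activity: np.ndarray, angle_indices=None) -> np.ndarray:
        """Expected cps per bin; shape (n_selected_angles, n, n)."""
        n = self.geometry.grid_shape
        activity = np.asarray(activity, dtype=np.float64)
        if activity.shape != (n, n, n):
            raise ValueError(f"activity shape {activity.shape} does not match grid")
        if angle_indices is None:
            angle_indices = range(self.geometry.n_angles)
        out = np.empty((len(angle_indices), n, n), dtype=np.float64)
        for k, a in enumerate(angle_indices):
            mat = _rotation_matrix(n, self.geometry.angles_deg[a])
            rot = _apply_rotation(activity, mat, transpose=False)
            rot *= self._att_factors(a)
            proj = np.zeros((n, n), dtype=np.float64)
            for ix in range(n):
                plane = rot[ix]
                if plane.any():
                    proj += gaussian_filter(plane, self.psf_sigma_px[ix],
                                            mode="constant")
            out[k] = self._window_combine(proj)
        return out

    def adjoint(self, projections: np.ndarray, angle_indices=None) -> np.ndarray:
        """Exact transpose of :meth:`forward`."""
        n = self.geometry.grid_shape
        projections = np.asarray(projections, dtype=np.float64)
        if angle_indices is None:
            angle_indices = range(self.geometry.n_angles)
        if projections.shape != (len(angle_indices), n, n):
            raise ValueError(f"projection shape {projections.shape} does not match "
                             f"({len(angle_indices)}, {n}, {n})")
        vol = np.zeros((n, n, n), dtype=np.float64)
        rot_vol = np.empty_like(vol)
        for k, a in enumerate(angle_indices):
            w = self._window_combine(projections[k])
            att = self._att_factors(a)
            for ix in range(n):
                rot_vol[ix] = gaussian_filter(w, self.psf_sigma_px[ix],
                                              mode="constant") * att[ix]
            mat = _rotation_matrix(n, self.geometry.angles_deg[a])
            vol += _apply_rotation(rot_vol, mat, transpose=True)
        return vol


def forward_project(activity: np.ndarray, attenuation: np.ndarray,
                    collimator: CollimatorModel, isotope: str, window: str,
                    spectrum: SpectrumModel, geometry: SystemGeometry,
                    **kwargs) -> np.ndarray:
    """Functional wrapper around :class:`Projector.forward` (cps per bin)."""
    if np.asarray(activity).shape != np.asarray(attenuation).shape:
        raise ValueError("activity and attenuation grids do not match")
    proj = Projector(attenuation, collimator, isotope, window, spectrum,
                     geometry, **kwargs)
    return proj.forward(activity)


def back_project(projections: np.ndarray, attenuation: np.ndarray,
                 collimator: CollimatorModel, isotope: str, window: str,
                 spectrum: SpectrumModel, geometry: SystemGeometry,
                 **kwargs) -> np.ndarray:
    """Functional wrapper around :class:`Projector.adjoint`."""
    proj = Projector(attenuation, collimator, isotope, window, spectrum,
                     geometry, **kwargs)
    return proj.adjoint(projections)


# ---------------------------------------------------------------------------
# Point-source calibration geometry

def water_cylinder_attenuation(geometry: SystemGeometry, radius_mm: float = 100.0,
                               mu_per_cm: float | None = None) -> np.ndarray:
    """Attenuation map of a water cylinder (axis along z) centred in the FOV."""
    if mu_per_cm is None:
        mu_per_cm = load_defaults()["attenuation_per_cm"]["soft_tissue"]
    n = geometry.grid_shape
    c = (np.arange(n) - (n - 1) / 2.0) * geometry.voxel_mm
    r2 = c[:, None] ** 2 + c[None, :] ** 2
    mu = np.zeros((n, n, n))
    mu[r2 <= radius_mm ** 2, :] = mu_per_cm
    return mu


def point_source_window_counts(activity_mbq: float, isotope: str,
                               collimator: CollimatorModel, spectrum: SpectrumModel,
                               geometry: SystemGeometry, duration_s: float = 20.0,
                               windows=NARROW_WINDOWS) -> dict[str, float]:
    """Expected counts per energy window for a centred point source in water.

    Used for k-factor calibration and count-rate curves.  Expectation mode:
    no Poisson noise.
    """
    if activity_mbq < 0:
        raise ValueError("activity must be >= 0")
    n = geometry.grid_shape
    act = np.zeros((n, n, n))
    act[n // 2, n // 2, n // 2] = activity_mbq
    mu = water_cylinder_attenuation(geometry)
    counts: dict[str, float] = {}
    for win in windows:
        s_p, s_d = spectrum.window_sensitivity(isotope, collimator.name, win)
        if s_p == 0 and s_d == 0:
            counts[win] = 0.0
            continue
        proj = Projector(mu, collimator, isotope, win, spectrum, geometry)
        counts[win] = float(proj.forward(act).sum()) * duration_s
    return counts
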