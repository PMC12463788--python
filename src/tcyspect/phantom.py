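"""Digital anthropomorphic torso phantom.

Generates the voxelized stand-in for the physical torso phantom used in the
dual-isotope study: an elliptical water-filled torso containing a liver with
two spherical tumors, two lungs, and three small extrahepatic-deposition (EHD)
spheres in the background volume.  Per-isotope activity maps follow the
configured tumor-to-normal ratios, lung shunt fraction (LSF) and EHD-to-liver
activity ratios; the attenuation map assigns narrow-beam 140 keV coefficients
by material.

Compartment activities are solved analytically from the ratio configuration
(`solve_compartment_activities`) so the ground truth reproduces the configured
ratios exactly, independent of voxelisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import load_defaults

# Label map ids.  BODY is the water-filled torso interior outside all active
# compartments; it carries attenuation but never activity.
BACKGROUND, BODY, LIVER, TUMOR1, TUMOR2, LUNG, EHD1, EHD2, EHD3 = range(9)

LABEL_NAMES = {
    BACKGROUND: "background", BODY: "body", LIVER: "liver",
    TUMOR1: "tumor1", TUMOR2: "tumor2", LUNG: "lung",
    EHD1: "ehd1", EHD2: "ehd2", EHD3: "ehd3",
}

#: Compartments that can carry activity, in canonical order.
ACTIVE_COMPARTMENTS = ("liver", "tumor1", "tumor2", "lungs", "ehd1", "ehd2", "ehd3")


@dataclass(frozen=True)
class IsotopeConfig:
    """Activity configuration for one isotope column of the phantom table."""
    tn_ratio_tumor1: float
    tn_ratio_tumor2: float
    lsf_pct: float
    ehd1_liver_pct: float
    ehd2_liver_pct: float
    ehd3_liver_pct: float
    total_mbq: float

    def ehd_pcts(self) -> tuple[float, float, float]:
        return (self.ehd1_liver_pct, self.ehd2_liver_pct, self.ehd3_liver_pct)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity configuration of the digital phantom.

    ``volumes_ml['liver']`` is the whole liver compartment including the two
    tumor spheres; normal-liver volume is derived.
    """
    volumes_ml: dict[str, float]
    isotopes: dict[str, IsotopeConfig]
    grid_shape: int
    voxel_mm: float
    placement_mm: dict[str, dict]

    def __post_init__(self) -> None:
        for name, v in self.volumes_ml.items():
            if v <= 0:
                raise ValueError(f"compartment volume {name!r} must be > 0, got {v}")
        if self.volumes_ml["tumor1"] + self.volumes_ml["tumor2"] >= self.volumes_ml["liver"]:
            raise ValueError("tumor volumes must be smaller than the liver volume")
        for iso, cfg in self.isotopes.items():
            if cfg.tn_ratio_tumor1 < 0 or cfg.tn_ratio_tumor2 < 0:
                raise ValueError(f"{iso}: T/N ratios must be >= 0")
            if not (0 <= cfg.lsf_pct < 100):
                raise ValueError(f"{iso}: LSF must be in [0, 100), got {cfg.lsf_pct}")
            if any(p < 0 for p in cfg.ehd_pcts()):
                raise ValueError(f"{iso}: EHD ratios must be >= 0")
            if cfg.total_mbq < 0:
                raise ValueError(f"{iso}: total activity must be >= 0")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be > 0")

    @property
    def normal_liver_ml(self) -> float:
        return self.volumes_ml["liver"] - self.volumes_ml["tumor1"] - self.volumes_ml["tumor2"]

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_mm / 10.0) ** 3  # mm^3 -> mL via cm^3

    @classmethod
    def from_config(cls, cfg: dict | None = None, *, grid_shape: int | None = None,
                    voxel_mm: float | None = None) -> "PhantomSpec":
        """Build a spec from a config dict (packaged defaults when ``None``)."""
        cfg = cfg if cfg is not None else load_defaults()
        ph = cfg["phantom"]
        isotopes = {iso: IsotopeConfig(**vals) for iso, vals in ph["isotopes"].items()}
        return cls(
            volumes_ml=dict(ph["volumes_ml"]),
            isotopes=isotopes,
            grid_shape=grid_shape if grid_shape is not None else ph["grid"]["shape"],
            voxel_mm=voxel_mm if voxel_mm is not None else ph["grid"]["voxel_mm"],
            placement_mm=ph["placement_mm"],
        )


@dataclass(frozen=True)
class CompartmentActivities:
    """Solved activity (MBq) per compartment for one isotope."""
    isotope: str
    activity_mbq: dict[str, float]
    concentration_mbq_per_ml: dict[str, float]

    @property
    def whole_liver_mbq(self) -> float:
        a = self.activity_mbq
        return a["liver"] + a["tumor1"] + a["tumor2"]

    @property
    def total_mbq(self) -> float:
        return float(sum(self.activity_mbq.values()))


@dataclass
class VoxelPhantom:
    """Voxelized phantom: label map, per-isotope activity maps, attenuation."""
    labels: np.ndarray                      # int labels, shape (n, n, n)
    activity_mbq: dict[str, np.ndarray]     # isotope -> MBq per voxel
    attenuation_per_cm: np.ndarray          # linear attenuation at 140 keV
    voxel_mm: float
    spec: PhantomSpec
    activities: dict[str, CompartmentActivities] = field(default_factory=dict)

    def compartment_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def voxel_counts(self) -> dict[str, int]:
        out = {}
        for lab, name in LABEL_NAMES.items():
            if lab in (BACKGROUND, BODY):
                continue
            out[name] = int(np.count_nonzero(self.labels == lab))
        return out


@dataclass(frozen=True)
class TrueMetrics:
    """Ground-truth metrics derived from solved compartment activities."""
    lsf_pct: float
    tn_ratio_tumor1: float
    tn_ratio_tumor2: float
    ehd_mbq: tuple[float, float, float]
    total_mbq: float


def solve_compartment_activities(spec: PhantomSpec, isotope: str) -> CompartmentActivities:
    """Solve per-compartment activities from the ratio configuration.

    The whole-liver activity L (normal liver + both tumors) is the anchor:
    lungs carry L * LSF/(1-LSF) so that lungs/(lungs+L) = LSF, each EHD
    carries its configured percentage of L, and everything is rescaled so the
    grand total equals the configured total activity.
    """
    if isotope not in spec.isotopes:
        raise KeyError(f"unknown isotope {isotope!r}; have {sorted(spec.isotopes)}")
    iso = spec.isotopes[isotope]
    lsf = iso.lsf_pct / 100.0
    if not lsf < 1.0:
        raise ValueError(f"infeasible configuration: LSF = {iso.lsf_pct}% (lungs would "
                         "carry all activity)")
    ehd_fracs = [p / 100.0 for p in iso.ehd_pcts()]

    v_n = spec.normal_liver_ml
    v_t1 = spec.volumes_ml["tumor1"]
    v_t2 = spec.volumes_ml["tumor2"]
    # Whole-liver activity per unit normal-liver concentration.
    liver_per_cn = v_n + iso.tn_ratio_tumor1 * v_t1 + iso.tn_ratio_tumor2 * v_t2
    if liver_per_cn <= 0:
        raise ValueError("infeasible configuration: liver carries no activity")
    # Grand total per unit whole-liver activity.
    total_per_l = 1.0 + lsf / (1.0 - lsf) + sum(ehd_fracs)
    liver_total = iso.total_mbq / total_per_l
    c_n = liver_total / liver_per_cn

    act = {
        "liver": c_n * v_n,
        "tumor1": c_n * iso.tn_ratio_tumor1 * v_t1,
        "tumor2": c_n * iso.tn_ratio_tumor2 * v_t2,
        "lungs": liver_total * lsf / (1.0 - lsf),
        "ehd1": ehd_fracs[0] * liver_total,
        "ehd2": ehd_fracs[1] * liver_total,
        "ehd3": ehd_fracs[2] * liver_total,
    }
    # Exact-total rescale (guards accumulated rounding; exact by construction).
    s = sum(act.values())
    if s > 0:
        scale = iso.total_mbq / s
        act = {k: v * scale for k, v in act.items()}
    vols = {
        "liver": v_n, "tumor1": v_t1, "tumor2": v_t2,
        "lungs": spec.volumes_ml["lungs"],
        "ehd1": spec.volumes_ml["ehd1"], "ehd2": spec.volumes_ml["ehd2"],
        "ehd3": spec.volumes_ml["ehd3"],
    }
    conc = {k: act[k] / vols[k] for k in act}
    return CompartmentActivities(isotope=isotope, activity_mbq=act,
                                 concentration_mbq_per_ml=conc)


def _voxel_centers_mm(n: int, voxel_mm: float) -> np.ndarray:
    """World coordinates (mm) of voxel centres, origin at the volume centre."""
    return (np.arange(n) - (n - 1) / 2.0) * voxel_mm


def _ellipsoid_d2(shape: int, voxel_mm: float, center: np.ndarray,
                  semi_axes: np.ndarray) -> np.ndarray:
    c = _voxel_centers_mm(shape, voxel_mm)
    dx = (c[:, None, None] - center[0]) / semi_axes[0]
    dy = (c[None, :, None] - center[1]) / semi_axes[1]
    dz = (c[None, None, :] - center[2]) / semi_axes[2]
    return dx * dx + dy * dy + dz * dz


def _claim_nearest(d2: np.ndarray, n_vox: int, labels: np.ndarray,
                   allowed: np.ndarray, name: str) -> np.ndarray:
    """Indices of the ``n_vox`` voxels nearest to a compartment centre.

    Selection is over the whole grid; if any selected voxel is not in
    ``allowed`` (already claimed by another compartment, or outside the host
    region) the placement overlaps and an error is raised.
    """
    flat = np.argsort(d2, axis=None, kind="stable")[:n_vox]
    idx = np.unravel_index(flat, d2.shape)
    if not allowed[idx].all():
        bad = labels[idx][~allowed[idx]]
        names = sorted({LABEL_NAMES.get(int(b), str(b)) for b in bad})
        raise ValueError(f"compartment {name!r} overlaps {names} at this placement/grid")
    return idx


def build_phantom(spec: PhantomSpec,
                  activities: dict[str, CompartmentActivities] | None = None) -> VoxelPhantom:
    """Render the phantom onto the voxel grid.

    Compartments are placed as analytic ellipsoids/spheres; each is rendered
    by claiming the ``round(volume / voxel_volume)`` voxels nearest to its
    centre (in the ellipsoid metric), which matches nominal volumes to within
    half a voxel.  Activity is distributed uniformly over each compartment's
    voxels and rescaled to the solved compartment activity exactly.
    """
    if activities is None:
        activities = {iso: solve_compartment_activities(spec, iso) for iso in spec.isotopes}
    n = spec.grid_shape
    voxel = spec.voxel_mm
    vv = spec.voxel_volume_ml
    place = {k: {kk: np.asarray(vvv, dtype=float) for kk, vvv in v.items()}
             for k, v in spec.placement_mm.items()}

    half_fov = n * voxel / 2.0
    for name, p in place.items():
        semi = p.get("semi_axes")
        if semi is None:  # sphere: radius from its nominal volume
            r = (3.0 * spec.volumes_ml[name] * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            semi = np.array([r, r, r])
        if np.any(np.abs(p["center"]) + semi > half_fov):
            raise ValueError(f"grid too small: compartment {name!r} extends beyond the "
                             f"field of view ({2 * half_fov:.0f} mm)")

    labels = np.full((n, n, n), BACKGROUND, dtype=np.int16)

    body = place["body"]
    labels[_ellipsoid_d2(n, voxel, body["center"], body["semi_axes"]) <= 1.0] = BODY

    def sphere_radius(vol_ml: float) -> float:
        return (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    # Lungs: two equal ellipsoids sharing the configured lungs volume.
    lung_each = spec.volumes_ml["lungs"] / 2.0
    for key in ("lung_left", "lung_right"):
        p = place[key]
        d2 = _ellipsoid_d2(n, voxel, p["center"], p["semi_axes"])
        idx = _claim_nearest(d2, int(round(lung_each / vv)), labels,
                             labels == BODY, key)
        labels[idx] = LUNG

    # Whole liver, then the tumor spheres carved out of it.
    pl = place["liver"]
    d2_liver = _ellipsoid_d2(n, voxel, pl["center"], pl["semi_axes"])
    idx = _claim_nearest(d2_liver, int(round(spec.volumes_ml["liver"] / vv)),
                         labels, labels == BODY, "liver")
    labels[idx] = LIVER
    for key, lab in (("tumor1", TUMOR1), ("tumor2", TUMOR2)):
        r = sphere_radius(spec.volumes_ml[key])
        d2 = _ellipsoid_d2(n, voxel, place[key]["center"], np.array([r, r, r]))
        idx = _claim_nearest(d2, int(round(spec.volumes_ml[key] / vv)), labels,
                             labels == LIVER, key)
        labels[idx] = lab

    # EHD spheres in the background (torso water) volume.
    for key, lab in (("ehd1", EHD1), ("ehd2", EHD2), ("ehd3", EHD3)):
        r = sphere_radius(spec.volumes_ml[key])
        d2 = _ellipsoid_d2(n, voxel, place[key]["center"], np.array([r, r, r]))
        idx = _claim_nearest(d2, max(1, int(round(spec.volumes_ml[key] / vv))),
                             labels, labels == BODY, key)
        labels[idx] = lab

    comp_label = {"liver": LIVER, "tumor1": TUMOR1, "tumor2": TUMOR2,
                  "lungs": LUNG, "ehd1": EHD1, "ehd2": EHD2, "ehd3": EHD3}
    act_maps: dict[str, np.ndarray] = {}
    for iso, ca in activities.items():
        amap = np.zeros((n, n, n), dtype=np.float64)
        for comp, a in ca.activity_mbq.items():
            mask = labels == comp_label[comp]
            nvox = int(np.count_nonzero(mask))
            if a > 0 and nvox == 0:
                raise ValueError(f"compartment {comp!r} has activity but no voxels")
            if nvox:
                amap[mask] = a / nvox
        total = float(sum(ca.activity_mbq.values()))
        s = amap.sum()
        if s > 0:
            amap *= total / s
        act_maps[iso] = amap

    cfg = load_defaults()["attenuation_per_cm"]
    mu = np.zeros((n, n, n), dtype=np.float64)
    mu[labels != BACKGROUND] = cfg["soft_tissue"]
    mu[labels == LUNG] = cfg["lung"]

    return VoxelPhantom(labels=labels, activity_mbq=act_maps, attenuation_per_cm=mu,
                        voxel_mm=voxel, spec=spec, activities=dict(activities))


def true_metrics(phantom: VoxelPhantom, spec: PhantomSpec, isotope: str) -> TrueMetrics:
    """Ground-truth LSF, tumor concentration ratios and EHD activities.

    Computed from the solved compartment activities (not the voxel maps), so
    the configured ratios are reproduced to machine precision.
    """
    ca = phantom.activities.get(isotope) or solve_compartment_activities(spec, isotope)
    a = ca.activity_mbq
    c = ca.concentration_mbq_per_ml
    liver_total = ca.whole_liver_mbq
    denom = a["lungs"] + liver_total
    lsf = 100.0 * a["lungs"] / denom if denom > 0 else float("nan")
    cn = c["liver"]
    tn1 = c["tumor1"] / cn if cn > 0 else float("nan")
    tn2 = c["tumor2"] / cn if cn > 0 else float("nan")
    return TrueMetrics(
        lsf_pct=lsf, tn_ratio_tumor1=tn1, tn_ratio_tumor2=tn2,
        ehd_mbq=(a["ehd1"], a["ehd2"], a["ehd3"]),
        total_mbq=ca.total_mbq,
    )
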