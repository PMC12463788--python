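"""Quantitative evaluation: masks, CRC, LSF, noise, EHD activity readout.

Metric conventions:

* CRC = 100 * [(<a_tumor> - <a_normal>) / <a_normal>] / (T/N - 1), means over
  the tumor-sphere mask and the eroded liver-background mask.
* LSF = 100 * a_lungs / (a_lungs + a_liver), totals over the dilated lung
  mask and the (undilated) full-liver mask.
* Noise = coefficient of variation over the liver-background mask, sample
  standard deviation (N - 1).

Masks follow the study protocol: lungs and EHD masks dilated by three voxels
(3-D, 6-connected) to mitigate spill-out, liver-background eroded by three
voxels to exclude partial-volume shells, tumor masks as spheres of the
physical tumor volume centred on the centre of mass of the highest-intensity
voxels near the nominal tumor position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, center_of_mass

from . import phantom as ph
from .reconstruction import ReconVolume

_STRUCT6 = np.zeros((3, 3, 3), dtype=bool)
_STRUCT6[1, 1, :] = _STRUCT6[1, :, 1] = _STRUCT6[:, 1, 1] = True


@dataclass
class MaskSet:
    """Binary evaluation masks on the reconstruction grid."""
    liver_background: np.ndarray    # eroded normal liver
    full_liver: np.ndarray          # liver + tumors, undilated
    lungs: np.ndarray               # dilated
    tumor1: np.ndarray              # sphere of physical volume
    tumor2: np.ndarray
    ehd: tuple[np.ndarray, np.ndarray, np.ndarray]   # dilated
    voxel_mm: float

    def __post_init__(self) -> None:
        if (self.tumor1 & self.liver_background).any() or \
                (self.tumor2 & self.liver_background).any():
            raise ValueError("tumor masks overlap the liver-background mask")


@dataclass(frozen=True)
class MetricsResult:
    """Per-realization metric readout."""
    crc_tumor1_pct: float
    crc_tumor2_pct: float
    lsf_pct: float
    noise: float
    ehd_mbq: tuple[float, float, float]
    iteration: int
    realization: str = ""
    extras: dict = field(default_factory=dict)


def _sphere_mask(shape: int, voxel_mm: float, center_vox: np.ndarray,
                 volume_ml: float) -> np.ndarray:
    """Sphere of given physical volume: the N nearest voxels to the centre."""
    n_vox = max(1, int(round(volume_ml / (voxel_mm / 10.0) ** 3)))
    ax = np.arange(shape)
    d2 = ((ax[:, None, None] - center_vox[0]) ** 2
          + (ax[None, :, None] - center_vox[1]) ** 2
          + (ax[None, None, :] - center_vox[2]) ** 2)
    flat = np.argsort(d2, axis=None, kind="stable")[:n_vox]
    mask = np.zeros((shape,) * 3, dtype=bool)
    mask.ravel()[flat] = True
    return mask


def _locate_tumor(image: np.ndarray, nominal_center_vox: np.ndarray,
                  radius_vox: float) -> np.ndarray:
    """Centre of mass of the top-1% intensity voxels in a search box of twice
    the tumor diameter around the nominal centre."""
    shape = np.array(image.shape)
    half = max(2, int(np.ceil(2.0 * radius_vox)))
    lo = np.maximum(nominal_center_vox.astype(int) - half, 0)
    hi = np.minimum(nominal_center_vox.astype(int) + half + 1, shape)
    box = image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if not np.any(box > 0):
        return nominal_center_vox.astype(float)
    thresh = np.quantile(box, 0.99)
    hot = box >= thresh
    com = np.array(center_of_mass(box * hot))
    return lo + com


def build_masks(phantom: ph.VoxelPhantom, recon: ReconVolume | np.ndarray | None = None,
                dilation: int = 3) -> MaskSet:
    """Evaluation masks from the ground-truth label map and a reconstruction.

    ``recon`` (image or ReconVolume) is used only to centre the tumor-sphere
    masks on the reconstructed hot spots; when omitted the nominal (ground
    truth) tumor centres are used.
    """
    labels = phantom.labels
    if isinstance(recon, ReconVolume):
        image = recon.image
    else:
        image = recon
    if image is not None and image.shape != labels.shape:
        raise ValueError("reconstruction grid does not match the label map")

    voxel = phantom.voxel_mm
    normal_liver = labels == ph.LIVER
    liver_bg = binary_erosion(normal_liver, _STRUCT6, iterations=dilation) \
        if dilation > 0 else normal_liver
    if not liver_bg.any():
        raise ValueError("liver-background mask is empty after erosion "
                         "(grid too coarse)")
    full_liver = normal_liver | (labels == ph.TUMOR1) | (labels == ph.TUMOR2)
    lungs = labels == ph.LUNG
    if dilation > 0:
        lungs = binary_dilation(lungs, _STRUCT6, iterations=dilation)
    ehd_masks = []
    for lab in (ph.EHD1, ph.EHD2, ph.EHD3):
        m = labels == lab
        if dilation > 0:
            m = binary_dilation(m, _STRUCT6, iterations=dilation)
        ehd_masks.append(m)

    n = labels.shape[0]
    spec = phantom.spec
    tumors = {}
    for key in ("tumor1", "tumor2"):
        center_mm = np.asarray(spec.placement_mm[key]["center"], dtype=float)
        nominal_vox = center_mm / voxel + (n - 1) / 2.0
        radius_vox = (3.0 * spec.volumes_ml[key] * 1000.0 / (4 * np.pi)) ** (1 / 3) \
            / voxel
        if image is not None:
            center = _locate_tumor(image, nominal_vox, radius_vox)
        else:
            center = nominal_vox
        tumors[key] = _sphere_mask(n, voxel, center, spec.volumes_ml[key])

    liver_bg = liver_bg & ~tumors["tumor1"] & ~tumors["tumor2"]
    if not liver_bg.any():
        raise ValueError("liver-background mask is empty after tumor exclusion")
    return MaskSet(liver_background=liver_bg, full_liver=full_liver, lungs=lungs,
                   tumor1=tumors["tumor1"], tumor2=tumors["tumor2"],
                   ehd=tuple(ehd_masks), voxel_mm=voxel)


def _image_of(recon: ReconVolume | np.ndarray) -> np.ndarray:
    return recon.image if isinstance(recon, ReconVolume) else np.asarray(recon)


def crc(recon: ReconVolume | np.ndarray, masks: MaskSet, tn_ratio: float,
        tumor: str = "tumor1") -> float:
    """Contrast recovery coefficient (%) for one tumor."""
    if tn_ratio == 1.0:
        raise ValueError("CRC undefined for T/N ratio = 1")
    img = _image_of(recon)
    t_mean = img[getattr(masks, tumor)].mean()
    n_mean = img[masks.liver_background].mean()
    if n_mean == 0:
        return float("nan")
    return float(100.0 * ((t_mean - n_mean) / n_mean) / (tn_ratio - 1.0))


def lsf(recon: ReconVolume | np.ndarray, masks: MaskSet) -> float:
    """Lung shunt fraction (%): lung total over lung + full-liver total."""
    img = _image_of(recon)
    lungs = img[masks.lungs].sum()
    liver = img[masks.full_liver].sum()
    denom = lungs + liver
    if denom == 0:
        return float("nan")
    return float(100.0 * lungs / denom)


def noise(recon: ReconVolume | np.ndarray, background_mask: np.ndarray) -> float:
    """Coefficient of variation over the liver background (sample std)."""
    vals = _image_of(recon)[background_mask]
    if vals.size < 2:
        raise ValueError("noise requires >= 2 background voxels")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std(ddof=1) / mean)


def ehd_activity(recon: ReconVolume | np.ndarray, masks: MaskSet) -> tuple[float, ...]:
    """Summed activity (MBq) within each dilated EHD mask."""
    img = _image_of(recon)
    return tuple(float(img[m].sum()) for m in masks.ehd)


def matched_iteration(noise_history: np.ndarray, target_noise: float) -> int:
    """Iteration whose noise is closest to the target; ties to the earlier."""
    h = np.asarray(noise_history, dtype=float)
    if h.size == 0:
        raise ValueError("empty noise history")
    return int(np.argmin(np.abs(h - target_noise)))


def evaluate(recon: ReconVolume | np.ndarray, masks: MaskSet,
             tn1: float, tn2: float, iteration: int = -1,
             realization: str = "") -> MetricsResult:
    """Full metric readout of one reconstruction."""
    return MetricsResult(
        crc_tumor1_pct=crc(recon, masks, tn1, "tumor1") if tn1 != 1.0 else float("nan"),
        crc_tumor2_pct=crc(recon, masks, tn2, "tumor2") if tn2 != 1.0 else float("nan"),
        lsf_pct=lsf(recon, masks),
        noise=noise(recon, masks.liver_background),
        ehd_mbq=ehd_activity(recon, masks),
        iteration=iteration, realization=realization)


def aggregate_realizations(results: list[MetricsResult]) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation (N-1) per metric."""
    if len(results) < 2:
        raise ValueError("aggregation requires >= 2 realizations")
    out: dict[str, tuple[float, float]] = {}
    for name in ("crc_tumor1_pct", "crc_tumor2_pct", "lsf_pct", "noise"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1)))
    ehd = np.array([r.ehd_mbq for r in results], dtype=float)
    for j in range(ehd.shape[1]):
        out[f"ehd{j + 1}_mbq"] = (float(ehd[:, j].mean()), float(ehd[:, j].std(ddof=1)))
    return out
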