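"""Densitometric, geometric and microarchitectural indices.

Density indices are plain means of the calibrated values over compartment
masks.  BV/TV is derived densitometrically from Tb.vBMD assuming fully
mineralized compact bone at 1200 mg HA/cm^3 and marrow at 0, and Tb.Th /
Tb.Sp follow from BV/TV and the directly measured Tb.N under plate-model
assumptions -- so the identities Tb.Th*Tb.N = BV/TV and Tb.Sp*Tb.N =
1 - BV/TV hold exactly on every record.

Direct 3D distance measures:

* ``local_thickness`` -- Hildebrand maximal-sphere thickness (the diameter
  of the largest sphere containing each voxel while fitting inside the
  structure), volume-weighted;
* ``tb_n_direct`` -- trabecular number from the mean spacing between
  trabecular mid-axes (3D thinning skeleton), measured either by
  directional intercepts along the grid axes (default) or by
  sphere-fitting on the mid-axis complement;
* ``ct_th_direct`` -- maximal-sphere thickness of the pore-filled cortex
  (mineralized cortex plus intracortical pores), so pore surfaces do not
  bias the endosteal-periosteal distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import skeletonize

from .core import COMPACT_BONE_DENSITY, CalibratedVolume
from .segmentation import CompartmentMasks


@dataclass
class MorphometryRecord:
    """All indices for one scan and one region."""

    region_label: str = "global"
    tot_vbmd: float = np.nan
    ct_vbmd: float = np.nan
    tb_vbmd: float = np.nan
    bvtv: float = np.nan
    tb_n: float = np.nan
    tb_th: float = np.nan
    tb_sp: float = np.nan
    tb_1n_sd: float = np.nan
    ct_th_areal: float = np.nan
    ct_th_star: float = np.nan
    ct_ar: float = np.nan
    tb_ar: float = np.nan
    ct_pov: float = np.nan
    ct_bv: float = np.nan
    ct_po: float = np.nan

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def vbmd(vol: CalibratedVolume, mask: np.ndarray) -> float:
    """Mean calibrated density over a mask, mg HA/cm^3."""
    if not mask.any():
        raise ValueError("empty mask")
    return float(vol.data[mask].mean())


def bvtv_from_density(tb_vbmd: float) -> float:
    """Densitometric bone volume fraction, Tb.vBMD / 1200."""
    if tb_vbmd < 0:
        raise ValueError("density must be non-negative")
    f = tb_vbmd / COMPACT_BONE_DENSITY
    if f > 1.0:
        import warnings

        warnings.warn("Tb.vBMD exceeds the compact-bone density; clipping BV/TV")
        f = 1.0
    return f


def plate_model_derive(bvtv: float, tb_n: float) -> tuple[float, float]:
    """Tb.Th and Tb.Sp from BV/TV and Tb.N under plate-model assumptions."""
    if tb_n <= 0:
        raise ValueError("tb_n must be positive")
    return bvtv / tb_n, (1.0 - bvtv) / tb_n


def local_thickness(mask: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Maximal-sphere local thickness map.

    For every structure voxel, the diameter of the largest sphere that
    contains the voxel and fits entirely inside the structure, in units of
    ``spacing``.  Implemented by painting spheres from distance-ridge
    candidates in order of decreasing radius.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    dt = ndimage.distance_transform_edt(mask)
    lt = 2.0 * dt
    nz, ny, nx = mask.shape
    # a sphere at y is redundant if a neighbor's sphere contains it:
    # dt(n) >= dt(y) + |y - n|
    cand = mask.copy()
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                d = float(np.sqrt(dz * dz + dy * dy + dx * dx))
                src = (
                    slice(max(0, dz), nz + min(0, dz)),
                    slice(max(0, dy), ny + min(0, dy)),
                    slice(max(0, dx), nx + min(0, dx)),
                )
                dst = (
                    slice(max(0, -dz), nz + min(0, -dz)),
                    slice(max(0, -dy), ny + min(0, -dy)),
                    slice(max(0, -dx), nx + min(0, -dx)),
                )
                shifted = np.zeros_like(dt)
                shifted[dst] = dt[src]
                cand[dst] &= ~(shifted[dst] >= dt[dst] + d)
    centers = np.argwhere(cand)
    radii = dt[cand]
    order = np.argsort(radii)[::-1]
    for (cz, cy, cx), r in zip(centers[order], radii[order]):
        ri = int(r)
        if ri < 1:
            continue
        z0, z1 = max(0, cz - ri), min(nz, cz + ri + 1)
        y0, y1 = max(0, cy - ri), min(ny, cy + ri + 1)
        x0, x1 = max(0, cx - ri), min(nx, cx + ri + 1)
        sub = lt[z0:z1, y0:y1, x0:x1]
        if sub.size and sub.min() >= 2 * r:
            continue
        Z, Y, X = np.ogrid[z0 - cz : z1 - cz, y0 - cy : y1 - cy, x0 - cx : x1 - cx]
        ball = (Z * Z + Y * Y + X * X) <= r * r
        np.maximum(sub, np.where(ball, 2.0 * r, 0.0), out=sub)
    lt[~mask] = 0.0
    return lt * spacing


def _intercept_gaps(
    skel: np.ndarray, region: np.ndarray, window: int = 2, run_cap: int = 4
) -> np.ndarray:
    """Gaps between consecutive mid-axis crossings along the three grid
    axes, in voxels.

    The skeleton is dilated transversely to each probe axis by ``window``
    voxels so that lines passing near a mid-axis register the crossing;
    runs of consecutive skeleton voxels along the line count as a single
    crossing at their midpoint.  Runs longer than ``run_cap`` mean the
    probe runs along a mid-axis rather than across it; gaps adjoining such
    a run are discarded."""
    gaps = []
    for axis in range(3):
        # dilate only in the two transverse directions
        se = np.ones((2 * window + 1,) * 3, bool)
        idx: list = [slice(None)] * 3
        idx[axis] = [i for i in range(2 * window + 1) if i != window]
        se[tuple(idx)] = False
        dil = ndimage.binary_dilation(skel, structure=se)
        sk = np.moveaxis(dil, axis, -1)
        rg = np.moveaxis(region, axis, -1)
        n = sk.shape[-1]
        flat_sk = sk.reshape(-1, n)
        flat_rg = rg.reshape(-1, n)
        rows = np.flatnonzero(flat_sk.sum(axis=1) >= 2)
        for i in rows:
            line = flat_sk[i]
            d = np.diff(np.concatenate(([0], line.view(np.int8), [0])))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1) - 1
            lengths = ends - starts + 1
            short = lengths <= run_cap
            mids = (starts + ends) / 2.0
            for j in range(len(mids) - 1):
                if not (short[j] and short[j + 1]):
                    continue
                a, b = mids[j], mids[j + 1]
                lo, hi = int(np.ceil(a)), int(np.floor(b))
                if flat_rg[i, lo : hi + 1].all():
                    gaps.append(b - a)
    return np.asarray(gaps, dtype=float)


def tb_n_direct(
    trabecular_bone: np.ndarray,
    voxel_mm: float,
    trabecular_region: Optional[np.ndarray] = None,
    method: str = "intercept",
    trim_bounds: tuple[float, float] = (0.5, 1.6),
) -> tuple[float, float]:
    """Trabecular number and spacing heterogeneity from mid-axis distances.

    The trabecular mid-axes are extracted by 3D medial-axis thinning.
    ``method="intercept"`` measures the spacing as the distance between
    consecutive mid-axis crossings along each of the three grid axes;
    gaps outside ``trim_bounds`` times the median are discarded as
    skeletonization artifacts (a missed crossing doubles a gap; a spur
    halves one).  ``method="sphere"`` uses the volume-weighted
    maximal-sphere diameter of the mid-axis complement instead.  Returns
    ``(tb_n, tb_1n_sd)`` in 1/mm and mm.
    """
    if not trabecular_bone.any():
        raise ValueError("trabecular bone mask is empty")
    if trabecular_region is None:
        trabecular_region = np.ones_like(trabecular_bone)
    skel = skeletonize(trabecular_bone.astype(np.uint8)).astype(bool)
    if not skel.any():
        raise ValueError("degenerate trabecular mask: no skeleton")
    if method == "intercept":
        gaps = _intercept_gaps(skel, trabecular_region)
        if gaps.size == 0:
            raise ValueError("no mid-axis spacings measurable")
        med = float(np.median(gaps))
        gaps = gaps[(gaps >= trim_bounds[0] * med) & (gaps <= trim_bounds[1] * med)]
        spacing_mm = gaps * voxel_mm
        mean_sp = float(spacing_mm.mean())
        sd_sp = float(spacing_mm.std(ddof=0))
    elif method == "sphere":
        space = trabecular_region & ~skel
        lt = local_thickness(space, spacing=voxel_mm)
        vals = lt[space]
        vals = vals[vals > 0]
        mean_sp = float(vals.mean())
        sd_sp = float(vals.std(ddof=0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return 1.0 / mean_sp, sd_sp


def periosteal_perimeter(periosteal: np.ndarray, voxel_mm: float) -> float:
    """Mean per-slice periosteal contour length (marching squares), mm."""
    total = 0.0
    n = 0
    for k in range(periosteal.shape[0]):
        sl = periosteal[k].astype(float)
        if not sl.any():
            continue
        for contour in find_contours(sl, 0.5):
            total += float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))
        n += 1
    if n == 0 or total == 0:
        raise ValueError("empty periosteal mask")
    return total * voxel_mm / n


def ct_th_areal(ct_ar_mm2: float, perimeter_mm: float) -> float:
    """Annular-model cortical thickness: area / periosteal perimeter."""
    if perimeter_mm <= 0:
        raise ValueError("perimeter must be positive")
    return ct_ar_mm2 / perimeter_mm


def ct_th_direct(
    cortex_auto: np.ndarray, pores: Optional[np.ndarray], voxel_mm: float
) -> float:
    """Direct 3D cortical thickness on the pore-filled cortex (Ct.Th*)."""
    composite = cortex_auto if pores is None else (cortex_auto | pores)
    if not composite.any():
        raise ValueError("empty cortical composite")
    lt = local_thickness(composite, spacing=voxel_mm)
    return float(lt[composite].mean())


def ct_po(ct_pov_mm3: float, ct_bv_mm3: float) -> float:
    """Intracortical porosity as a normalized volumetric index, percent:
    100 * Ct.PoV / (Ct.PoV + Ct.BV)."""
    if ct_pov_mm3 < 0:
        raise ValueError("pore volume must be non-negative")
    if ct_pov_mm3 + ct_bv_mm3 <= 0:
        raise ValueError("cortical volume is zero")
    return 100.0 * ct_pov_mm3 / (ct_pov_mm3 + ct_bv_mm3)


def areas(masks: CompartmentMasks, voxel_mm: float) -> tuple[float, float]:
    """Mean per-slice cortical and trabecular (medullary) areas in mm^2.

    The cortical area includes intracortical pore space (compartment
    area); the trabecular area is the medullary region.
    """
    n = masks.periosteal.shape[0]
    ct = masks.cortex_used
    if masks.pores is not None:
        ct = ct | masks.pores
    ct_ar = float(ct.sum()) * voxel_mm**2 / n
    tb_ar = float(masks.trabecular_region.sum()) * voxel_mm**2 / n
    return ct_ar, tb_ar


def compute_morphometry(
    vol: CalibratedVolume,
    masks: CompartmentMasks,
    tb_n_method: str = "intercept",
) -> MorphometryRecord:
    """Assemble the full global morphometry record for one scan."""
    v = vol.voxel_mm
    rec = MorphometryRecord(region_label="global")
    rec.tot_vbmd = vbmd(vol, masks.periosteal)
    rec.ct_vbmd = vbmd(vol, masks.cortex_used)
    rec.tb_vbmd = vbmd(vol, masks.trabecular_region)
    rec.bvtv = bvtv_from_density(rec.tb_vbmd)
    rec.tb_n, rec.tb_1n_sd = tb_n_direct(
        masks.trabecular_bone, v, masks.trabecular_region, method=tb_n_method
    )
    rec.tb_th, rec.tb_sp = plate_model_derive(rec.bvtv, rec.tb_n)
    rec.ct_ar, rec.tb_ar = areas(masks, v)
    rec.ct_th_areal = ct_th_areal(rec.ct_ar, periosteal_perimeter(masks.periosteal, v))
    rec.ct_th_star = ct_th_direct(masks.cortex_used, masks.pores, v)
    pores = masks.pores if masks.pores is not None else np.zeros_like(masks.periosteal)
    rec.ct_pov = float(pores.sum()) * v**3
    rec.ct_bv = float(masks.cortex_used.sum()) * v**3
    rec.ct_po = ct_po(rec.ct_pov, rec.ct_bv)
    return rec
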