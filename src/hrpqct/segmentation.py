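"""Compartment and intracortical-pore segmentation.

Two cortical segmentation routes are provided, mirroring clinical HR-pQCT
practice:

* the *standard* route -- Gaussian smoothing followed by a fixed threshold
  at 16% of the grayscale range inside the periosteal contour; adequate
  for thick dense cortices but known to misbehave for thin or very porous
  ones;
* the *extended* route -- a dual-threshold autocontour in the spirit of
  Buie's method: the medullary space is recovered by connected-component
  selection of the sub-threshold interior and morphologically closed, so
  the endosteal boundary stays closed across intracortical pores.

Intracortical pores are segmented in two stages: per-slice 2D component
labeling keeps void regions that are fully enclosed by mineralized cortex
(not 4-connected to either the exterior or the medullary background), and
a 3D region growing then adds void voxels connected to those seeds along
the axial direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import CalibratedVolume, IntensityScale

_FOUR = ndimage.generate_binary_structure(2, 1)
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class CompartmentMasks:
    """Aligned binary masks for one scan."""

    periosteal: np.ndarray
    cortex_std: Optional[np.ndarray] = None
    cortex_auto: Optional[np.ndarray] = None
    trabecular_region: Optional[np.ndarray] = None
    trabecular_bone: Optional[np.ndarray] = None
    pores: Optional[np.ndarray] = None
    method_tags: dict = field(default_factory=dict)

    @property
    def cortex_used(self) -> np.ndarray:
        return self.cortex_auto if self.cortex_auto is not None else self.cortex_std


def periosteal_contour(
    vol: CalibratedVolume,
    scale: IntensityScale = IntensityScale(),
    closing_radius: int = 5,
    sigma_voxels: float = 1.0,
) -> np.ndarray:
    """Closed periosteal region per slice, by edge finding.

    Gaussian presmoothing (a contour on the noisy raw data would jitter by
    whole voxels), an initial threshold at the cortical absolute threshold,
    then one half-maximum refinement pass: the final contour sits at 50%
    of the cortical tissue density, which localizes the edge of a
    partial-volume ramp at the true surface instead of ~0.6 voxel outside
    it.  Per slice: threshold, morphological closing, largest connected
    component (which drops a fibula by size), hole fill.
    """
    sm = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma=sigma_voxels,
                                 truncate=3.0)
    se = disk(closing_radius)

    def contour_at(thr: float) -> np.ndarray:
        out = np.zeros(vol.data.shape, dtype=bool)
        for k in range(vol.n_slices):
            bw = sm[k] >= thr
            if not bw.any():
                raise ValueError(f"no voxels above threshold {thr:g} in slice {k}")
            bw = ndimage.binary_closing(bw, structure=se)
            lab, n = ndimage.label(bw, structure=_EIGHT)
            if n > 1:
                sizes = ndimage.sum_labels(bw, lab, index=np.arange(1, n + 1))
                bw = lab == (1 + int(np.argmax(sizes)))
            out[k] = ndimage.binary_fill_holes(bw)
        return out

    initial = contour_at(scale.cortical_threshold)
    tissue = float(np.median(sm[initial & (sm >= scale.cortical_threshold)]))
    half_max = 0.5 * tissue
    # the refinement can only tighten a threshold that was below half-max
    if half_max <= scale.cortical_threshold:
        return initial
    return contour_at(half_max)


def second_bone_mask(
    vol: CalibratedVolume,
    scale: IntensityScale = IntensityScale(),
    closing_radius: int = 5,
    min_area_frac: float = 0.02,
) -> np.ndarray:
    """Filled mask of the second-largest bone (fibula) per slice.

    Needed only for quadrant-axis definition at the tibia.
    """
    thr = scale.cortical_threshold
    se = disk(closing_radius)
    out = np.zeros(vol.data.shape, dtype=bool)
    for k in range(vol.n_slices):
        bw = ndimage.binary_closing(vol.data[k] >= thr, structure=se)
        lab, n = ndimage.label(bw, structure=_EIGHT)
        if n < 2:
            continue
        sizes = ndimage.sum_labels(bw, lab, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1]
        if sizes[order[1]] >= min_area_frac * sizes[order[0]]:
            out[k] = ndimage.binary_fill_holes(lab == (1 + int(order[1])))
    if not out.any():
        raise ValueError("no second bone found; use radius mode")
    return out


def cortex_standard(
    vol: CalibratedVolume,
    periosteal: np.ndarray,
    scale: IntensityScale = IntensityScale(),
    sigma_voxels: float = 1.0,
) -> np.ndarray:
    """Standard-route mineralized cortex: 3D Gaussian smoothing then a
    fixed threshold at 16% of the grayscale range, largest component."""
    sm = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma=sigma_voxels,
                                 truncate=3.0)
    bw = (sm >= scale.cortical_threshold) & periosteal
    if not bw.any():
        raise ValueError("standard cortical segmentation is empty")
    lab, n = ndimage.label(bw, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        sizes = ndimage.sum_labels(bw, lab, index=np.arange(1, n + 1))
        bw = lab == (1 + int(np.argmax(sizes)))
    return bw


def cortex_autocontour(
    vol: CalibratedVolume,
    periosteal: np.ndarray,
    scale: IntensityScale = IntensityScale(),
    sigma_voxels: float = 1.0,
    endosteal_closing_radius: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Extended-route segmentation.

    Returns ``(cortex_auto, trabecular_region)``: the mineralized cortex
    bounded by closed periosteal and endosteal surfaces, and the medullary
    (trabecular) region.  The endosteal surface is recovered by selecting
    the largest connected sub-threshold component inside the periosteal
    region (the marrow space) and closing it per slice, which bridges
    intracortical pores and trabecular contact points.
    """
    sm = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma=sigma_voxels,
                                 truncate=3.0)
    # medullary recovery works on the smoothed image; the mineralized mask
    # itself uses the raw densities so that near-voxel-scale pores survive
    mineral = (vol.data >= scale.cortical_threshold) & periosteal
    void = periosteal & ~((sm >= scale.cortical_threshold) & periosteal)
    if not mineral.any():
        raise ValueError("no mineralized tissue inside the periosteal contour")
    # medullary space: the largest connected void component (3D);
    # intracortical pores are disconnected from it by construction
    lab, n = ndimage.label(void, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        # fully dense section: no medullary cavity resolved
        return mineral, np.zeros_like(mineral)
    sizes = ndimage.sum_labels(void, lab, index=np.arange(1, n + 1))
    med = lab == (1 + int(np.argmax(sizes)))
    se = disk(endosteal_closing_radius)
    out_med = np.zeros_like(med)
    for k in range(med.shape[0]):
        m = ndimage.binary_closing(med[k], structure=se)
        m = ndimage.binary_fill_holes(m)
        out_med[k] = m & periosteal[k]
    compartment = periosteal & ~out_med
    cortex = compartment & mineral
    return cortex, out_med


def laplace_hamming(
    data: np.ndarray,
    cutoff: float = 0.4,
    laplace_weight: float = 0.5,
) -> np.ndarray:
    """Frequency-domain edge-enhancing smoothing filter.

    The transfer function is a radial Hamming low-pass window (cutoff as a
    fraction of Nyquist) multiplied by a blend of unity and the normalized
    Laplacian magnitude response ``(1-w) + w * (f/f_nyq)^2``.  The window
    smooths, the Laplacian term enhances edges.
    """
    data = np.asarray(data, dtype=np.float32)
    freqs = [np.fft.fftfreq(n) for n in data.shape]  # cycles/voxel, Nyquist 0.5
    fz, fy, fx = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f = np.sqrt(fz**2 + fy**2 + fx**2) / 0.5  # as fraction of Nyquist
    ham = np.where(f <= cutoff, 0.54 + 0.46 * np.cos(np.pi * f / cutoff), 0.0)
    lap = (1.0 - laplace_weight) + laplace_weight * np.minimum(f, 1.0) ** 2
    out = np.fft.ifftn(np.fft.fftn(data) * ham * lap).real
    return out.astype(np.float32)


def trabecular_extract(
    vol: CalibratedVolume,
    trabecular_region: np.ndarray,
    scale: IntensityScale = IntensityScale(),
    cutoff: float = 0.8,
    laplace_weight: float = 0.8,
    rescale: str = "positive",
) -> np.ndarray:
    """Extract the trabecular structure.

    Laplace-Hamming filter, rescaling of the filtered output over the
    trabecular region to the full grayscale range, then the fixed 40%
    threshold.  With ``rescale="positive"`` (default) the signed filter
    output is rectified at zero and scaled by its maximum, so the threshold
    selects voxels at >= 40% of the peak edge-enhanced response -- on
    blurred rod phantoms this reproduces the rasterized structure volume
    closely.  ``rescale="minmax"`` maps the signed range [min, max]
    linearly instead.
    """
    if not trabecular_region.any():
        raise ValueError("trabecular region is empty")
    filt = laplace_hamming(vol.data, cutoff=cutoff, laplace_weight=laplace_weight)
    vals = filt[trabecular_region]
    lo = 0.0 if rescale == "positive" else float(vals.min())
    hi = float(vals.max())
    if hi <= lo:
        # structureless region: degenerate, return empty mask
        return np.zeros_like(trabecular_region)
    rescaled = (filt - lo) / (hi - lo) * scale.full_scale_density
    return (rescaled >= scale.trabecular_threshold) & trabecular_region


def pore_segment(
    cortex_auto: np.ndarray,
    periosteal: np.ndarray,
    vol: CalibratedVolume,
    scale: IntensityScale = IntensityScale(),
    trabecular_region: Optional[np.ndarray] = None,
    sigma_voxels: float = 1.0,
    min_pore_voxels: int = 0,
    void_threshold: str = "half-tissue",
) -> np.ndarray:
    """Two-stage intracortical pore segmentation.

    Stage 1 labels void voxels inside the cortical compartment per 2D
    slice and keeps components that touch neither the exterior nor the
    medullary background (4-connectivity).  Stage 2 grows from those seeds
    through compartment void voxels with 26-connectivity, following pore
    canals along the axial direction.

    Void classification uses the raw densities (smoothing at sigma ~ 1
    voxel fills in pores whose radius is near the voxel size).  With
    ``void_threshold="half-tissue"`` (default) the pore boundary sits at
    half the cortical tissue density -- the full-width-half-maximum
    criterion, which places the interface at the 50% partial-volume level
    and is unbiased for near-voxel-scale pores; ``"cortical"`` inherits
    the fixed cortical segmentation threshold instead.
    """
    if trabecular_region is None:
        _, trabecular_region = cortex_autocontour(vol, periosteal, scale,
                                                  sigma_voxels=sigma_voxels)
    compartment = periosteal & ~trabecular_region
    if void_threshold == "half-tissue":
        thr = 0.5 * float(np.median(vol.data[cortex_auto]))
    elif void_threshold == "cortical":
        thr = scale.cortical_threshold
    else:
        raise ValueError(f"unknown void_threshold {void_threshold!r}")
    void = compartment & (vol.data < thr)
    background = ~periosteal | trabecular_region

    seeds = np.zeros_like(void)
    for k in range(void.shape[0]):
        lab, n = ndimage.label(void[k], structure=_FOUR)
        if n == 0:
            continue
        # components 4-adjacent to background are open, not pores
        bg_dil = ndimage.binary_dilation(background[k], structure=_FOUR)
        touching = np.unique(lab[bg_dil & (lab > 0)])
        keep = np.setdiff1d(np.arange(1, n + 1), touching)
        if keep.size:
            seeds[k] = np.isin(lab, keep)

    if not seeds.any():
        return seeds
    # stage 2: 3D region growing through compartment void space
    lab3, _ = ndimage.label(void, structure=np.ones((3, 3, 3), bool))
    grown_ids = np.unique(lab3[seeds])
    grown_ids = grown_ids[grown_ids > 0]
    pores = np.isin(lab3, grown_ids)
    if min_pore_voxels > 0:
        lab_p, n_p = ndimage.label(pores, structure=np.ones((3, 3, 3), bool))
        sizes = ndimage.sum_labels(pores, lab_p, index=np.arange(1, n_p + 1))
        small = np.flatnonzero(sizes < min_pore_voxels) + 1
        pores &= ~np.isin(lab_p, small)
    return pores


def segment_all(
    vol: CalibratedVolume,
    scale: IntensityScale = IntensityScale(),
    **kwargs,
) -> CompartmentMasks:
    """Run the full segmentation chain and assemble a compartment partition.

    The returned masks satisfy ``periosteal = cortex_auto | pores |
    trabecular_region`` exactly: sub-threshold compartment voxels that the
    pore segmentation does not claim (thin partial-volume shells at the
    surfaces) are absorbed into the cortical mask.
    """
    periosteal = periosteal_contour(vol, scale)
    cortex_std = cortex_standard(vol, periosteal, scale)
    cortex_auto, trab_region = cortex_autocontour(vol, periosteal, scale)
    pores = pore_segment(cortex_auto, periosteal, vol, scale,
                         trabecular_region=trab_region, **kwargs)
    compartment = periosteal & ~trab_region
    cortex_auto = (cortex_auto | (compartment & ~pores)) & ~pores
    trab_bone = trabecular_extract(vol, trab_region, scale)
    masks = CompartmentMasks(
        periosteal=periosteal,
        cortex_std=cortex_std,
        cortex_auto=cortex_auto,
        trabecular_region=trab_region,
        trabecular_bone=trab_bone,
        pores=pores,
        method_tags={"cortex": "autocontour", "pores": "2d-label+3d-grow"},
    )
    return masks
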