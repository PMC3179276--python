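"""Synthetic distal radius/tibia phantoms with voxel-counted ground truth.

The generator rasterizes an idealized peripheral-bone cross-section -- a
tapered annular cortex enclosing intracortical pores and a three-axis
trabecular rod lattice -- at 3x supersampling, then block-averages the
mineral occupancy down to the acquisition grid.  That partial-volume path
produces the fractional-density boundary voxels that the fixed-threshold
segmentation steps must cope with, which is the point of the phantom.

Ground truth (porosity, BV/TV, thicknesses) is counted on the pre-blur
label image at acquisition resolution, so recovery tests compare against
exactly the geometry that was rasterized, not against continuous formulas.

Longitudinal follow-ups are produced by re-rasterizing the same anatomy
with an axial window shift (simulated repositioning) and applying
morphological perturbations -- endocortical apposition/resorption,
trabecular thinning, pore growth -- on the supersampled label image before
the same blur/noise path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import CalibratedVolume, Side, Site

# label values on the pre-blur label image
BG, CORTEX, TRAB, PORE, MARROW, FIBULA = 0, 1, 2, 3, 4, 5
N_LABELS = 6
SUPERSAMPLE = 3
MINERALIZED = (CORTEX, TRAB, FIBULA)


@dataclass(frozen=True)
class PoreModel:
    """Intracortical pore population.

    ``axial_fraction`` of the pores are cylinders running the full axial
    length (Haversian-like); the remainder are spherical voids.
    """

    n_pores: int = 30
    pore_radius_mm: float = 0.12
    axial_fraction: float = 0.8


@dataclass(frozen=True)
class TrabecularLattice:
    """Three-axis rod lattice filling the medullary compartment."""

    spacing_mm: float = 0.55
    rod_radius_mm: float = 0.10


@dataclass(frozen=True)
class Fibula:
    """Optional second bone for quadrant-axis definition at the tibia."""

    center_offset_mm: tuple[float, float] = (10.0, 0.0)
    radius_mm: float = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    site: Site = "radius"
    side: Side = "left"
    n_slices: int = 110
    voxel_mm: float = 0.082
    outer_radius_mm: float = 7.0
    #: fractional change of the outer radius per slice (0.5 %/mm default)
    taper_per_slice: float = 0.005 * 0.082
    cortical_thickness_mm: float = 0.9
    pore_model: Optional[PoreModel] = field(default_factory=PoreModel)
    trabecular_lattice: Optional[TrabecularLattice] = field(
        default_factory=TrabecularLattice
    )
    tissue_density: float = 1100.0  # mg HA/cm^3 for cortex and rods
    noise_sd: float = 0.0  # mg HA/cm^3
    fibula: Optional[Fibula] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.voxel_mm, self.outer_radius_mm, self.cortical_thickness_mm) <= 0:
            raise ValueError("all lengths must be positive")
        if self.cortical_thickness_mm >= self.outer_radius_mm:
            raise ValueError("cortical_thickness_mm must be < outer_radius_mm")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        lat = self.trabecular_lattice
        if lat is not None and lat.spacing_mm <= 2 * lat.rod_radius_mm:
            raise ValueError("lattice spacing must exceed twice the rod radius")
        if self.taper_per_slice < 0:
            raise ValueError("taper_per_slice must be >= 0")


@dataclass
class ChangeSpec:
    """Morphological perturbation turning a baseline into a follow-up."""

    endocortical_apposition_voxels: int = 0  # negative = resorption
    trabecular_thinning_voxels: int = 0
    pore_dilation_voxels: int = 0
    axial_shift_slices: int = 0


@dataclass
class PhantomTruth:
    """Voxel-counted ground truth plus the label image it was counted on."""

    true_ct_po: float  # % pore/(pore+cortical bone)
    true_tb_n: float  # 1/mm, = 1/lattice spacing
    true_ct_th: float  # mm
    true_bvtv: float  # fraction, rods/(rods+marrow)
    true_density: float  # mg HA/cm^3 tissue density
    applied_change: str
    labels: np.ndarray  # (n_slices, ny, nx) uint8 pre-blur label image
    spec: PhantomSpec = None
    voxel_counts: dict = field(default_factory=dict)


def _slice_coords(spec: PhantomSpec, shift_slices: int = 0) -> np.ndarray:
    """Anatomical slice coordinate of each supersampled slice center."""
    n_fine = spec.n_slices * SUPERSAMPLE
    j = np.arange(n_fine)
    # fine-voxel centers expressed in acquisition-slice units
    s = (j + 0.5) / SUPERSAMPLE - 0.5
    return s + shift_slices


def _grid_axes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int, int]:
    margin = 0.8
    xmax = spec.outer_radius_mm + margin
    ymax = xmax
    if spec.fibula is not None:
        ox, oy = spec.fibula.center_offset_mm
        xmax = max(xmax, abs(ox) + spec.fibula.radius_mm + margin)
        ymax = max(ymax, abs(oy) + spec.fibula.radius_mm + margin)
    nx = 2 * int(np.ceil(xmax / spec.voxel_mm)) + 1
    ny = 2 * int(np.ceil(ymax / spec.voxel_mm)) + 1
    fine = spec.voxel_mm / SUPERSAMPLE
    # physical coordinates of supersampled voxel centers, origin at section center
    x = (np.arange(nx * SUPERSAMPLE) + 0.5) * fine - nx * spec.voxel_mm / 2
    y = (np.arange(ny * SUPERSAMPLE) + 0.5) * fine - ny * spec.voxel_mm / 2
    return x, y, nx, ny


def _lattice_dist2(u: np.ndarray, spacing: float) -> np.ndarray:
    """Squared distance to the nearest lattice plane family at half-offset."""
    d = np.mod(u - spacing / 2.0, spacing)
    d = np.minimum(d, spacing - d)
    return d * d


def _sample_pores(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample pore centers at least one acquisition voxel inside
    both cortical surfaces over every slice the pore spans."""
    pm = spec.pore_model
    if pm is None or pm.n_pores == 0:
        return [], []
    margin = spec.voxel_mm  # 1 acquisition voxel
    s_lo, s_hi = -0.5, spec.n_slices - 0.5
    R = lambda s: spec.outer_radius_mm * (1.0 - spec.taper_per_slice * s)
    r = lambda s: R(s) - spec.cortical_thickness_mm

    def radial_bounds(s0, s1):
        lo = r(min(s0, s1)) + pm.pore_radius_mm + margin
        hi = R(max(s0, s1)) - pm.pore_radius_mm - margin
        return lo, hi

    lo_all, hi_all = radial_bounds(s_lo, s_hi)
    if lo_all >= hi_all:
        raise ValueError(
            "pores cannot fit inside the cortex: pore radius plus enclosure "
            "margin exceeds the available cortical thickness"
        )
    n_axial = int(round(pm.n_pores * pm.axial_fraction))
    axial, spherical = [], []
    for _ in range(n_axial):
        theta = rng.uniform(0.0, 2 * np.pi)
        rho = rng.uniform(lo_all, hi_all)
        axial.append((rho * np.cos(theta), rho * np.sin(theta)))
    z_len_mm = spec.n_slices * spec.voxel_mm
    for _ in range(pm.n_pores - n_axial):
        for _try in range(1000):
            zc = rng.uniform(pm.pore_radius_mm, z_len_mm - pm.pore_radius_mm)
            half = pm.pore_radius_mm / spec.voxel_mm
            s0 = zc / spec.voxel_mm - 0.5 - half
            s1 = zc / spec.voxel_mm - 0.5 + half
            lo, hi = radial_bounds(max(s0, s_lo), min(s1, s_hi))
            if lo < hi:
                theta = rng.uniform(0.0, 2 * np.pi)
                rho = rng.uniform(lo, hi)
                spherical.append((rho * np.cos(theta), rho * np.sin(theta), zc))
                break
        else:
            raise ValueError("pores cannot fit inside the cortex")
    return axial, spherical


def _rasterize(spec: PhantomSpec, shift_slices: int = 0) -> np.ndarray:
    """Supersampled label volume, slice coordinates shifted for follow-ups."""
    x, y, nx, ny = _grid_axes(spec)
    X, Y = np.meshgrid(x, y)  # (ny*S, nx*S)
    rho2 = X * X + Y * Y
    s = _slice_coords(spec, shift_slices)
    n_fine = s.size
    labels = np.zeros((n_fine, y.size, x.size), dtype=np.uint8)

    rng = np.random.default_rng(spec.seed)
    axial_pores, sph_pores = _sample_pores(spec, rng)

    lat = spec.trabecular_lattice
    if lat is not None:
        dz2_xy = _lattice_dist2(X, lat.spacing_mm) + _lattice_dist2(Y, lat.spacing_mm)
        dx_y = _lattice_dist2(Y, lat.spacing_mm)  # y-part for x-rods
        dy_x = _lattice_dist2(X, lat.spacing_mm)  # x-part for y-rods
        rod_r2 = lat.rod_radius_mm**2

    fib = spec.fibula
    if fib is not None:
        fx, fy = fib.center_offset_mm
        fib_mask2d = (X - fx) ** 2 + (Y - fy) ** 2 <= fib.radius_mm**2

    pore_r2 = 0.0 if spec.pore_model is None else spec.pore_model.pore_radius_mm**2
    if axial_pores:
        ax_d2 = np.min(
            np.stack([(X - px) ** 2 + (Y - py) ** 2 for px, py in axial_pores]), axis=0
        )

    for j in range(n_fine):
        sj = s[j]
        Rj = spec.outer_radius_mm * (1.0 - spec.taper_per_slice * sj)
        rj = Rj - spec.cortical_thickness_mm
        if rj <= 0:
            raise ValueError("taper collapses the endosteal radius; shorten the stack")
        sl = labels[j]
        inner = rho2 <= rj * rj
        cortex = (rho2 <= Rj * Rj) & ~inner
        sl[cortex] = CORTEX
        sl[inner] = MARROW
        if lat is not None:
            zmm = (sj + 0.5) * spec.voxel_mm
            dz = _lattice_dist2(np.array([zmm]), lat.spacing_mm)[0]
            rods = (
                (dz2_xy <= rod_r2)
                | ((dx_y + dz) <= rod_r2)
                | ((dy_x + dz) <= rod_r2)
            )
            sl[inner & rods] = TRAB
        if axial_pores:
            sl[cortex & (ax_d2 <= pore_r2)] = PORE
        for (px, py, pz) in sph_pores:
            zmm = (sj + 0.5) * spec.voxel_mm  # anatomical axial position
            dz2 = (zmm - pz) ** 2
            if dz2 <= pore_r2:
                d2 = (X - px) ** 2 + (Y - py) ** 2
                sl[cortex & (d2 <= pore_r2 - dz2)] = PORE
        if fib is not None:
            sl[fib_mask2d] = FIBULA
    return labels


def _downsample_labels(fine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote label image and mineral occupancy fraction per
    acquisition voxel."""
    S = SUPERSAMPLE
    nz, ny, nx = (d // S for d in fine.shape)
    blocks = fine.reshape(nz, S, ny, S, nx, S)
    counts = np.empty((N_LABELS, nz, ny, nx), dtype=np.int16)
    for lab in range(N_LABELS):
        counts[lab] = (blocks == lab).sum(axis=(1, 3, 5))
    labels = counts.argmax(axis=0).astype(np.uint8)
    mineral = (counts[CORTEX] + counts[TRAB] + counts[FIBULA]).astype(np.float32)
    mineral /= S**3
    return labels, mineral


def _truth_from_labels(
    labels: np.ndarray, spec: PhantomSpec, applied_change: str
) -> PhantomTruth:
    counts = {lab: int((labels == lab).sum()) for lab in range(N_LABELS)}
    pore, ctx = counts[PORE], counts[CORTEX]
    ct_po = 100.0 * pore / (pore + ctx) if (pore + ctx) else 0.0
    trab, marrow = counts[TRAB], counts[MARROW]
    bvtv = trab / (trab + marrow) if (trab + marrow) else 0.0
    lat = spec.trabecular_lattice
    tb_n = 1.0 / lat.spacing_mm if lat is not None else 0.0
    return PhantomTruth(
        true_ct_po=ct_po,
        true_tb_n=tb_n,
        true_ct_th=spec.cortical_thickness_mm,
        true_bvtv=bvtv,
        true_density=spec.tissue_density,
        applied_change=applied_change,
        labels=labels,
        spec=spec,
        voxel_counts=counts,
    )


def _volume_from_fine(
    fine: np.ndarray, spec: PhantomSpec, noise_seed: int
) -> tuple[CalibratedVolume, np.ndarray]:
    labels, mineral = _downsample_labels(fine)
    data = mineral * spec.tissue_density
    if spec.noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)
    vol = CalibratedVolume(
        data.astype(np.float32), voxel_mm=spec.voxel_mm, site=spec.site, side=spec.side
    )
    return vol, labels


def generate_phantom(spec: PhantomSpec) -> tuple[CalibratedVolume, PhantomTruth]:
    """Generate a calibrated phantom volume and its voxel-counted truth.

    Deterministic: the same spec (including seed) yields a bit-identical
    volume.
    """
    fine = _rasterize(spec)
    vol, labels = _volume_from_fine(fine, spec, noise_seed=spec.seed + 1)
    truth = _truth_from_labels(labels, spec, applied_change="none")
    return vol, truth


def _perturb_fine(fine: np.ndarray, spec: PhantomSpec, change: ChangeSpec) -> np.ndarray:
    """Apply morphological perturbations on the supersampled label image."""
    S = SUPERSAMPLE
    out = fine.copy()
    k = change.endocortical_apposition_voxels
    if k > 0:
        interior = (out == MARROW) | (out == TRAB)
        dist = ndimage.distance_transform_edt(out != CORTEX)
        out[interior & (dist <= k * S)] = CORTEX
    elif k < 0:
        interior = (out == MARROW) | (out == TRAB)
        dist = ndimage.distance_transform_edt(~interior)
        out[(out == CORTEX) & (dist <= -k * S)] = MARROW
    k = change.trabecular_thinning_voxels
    if k > 0:
        dist = ndimage.distance_transform_edt(out == TRAB)
        out[(out == TRAB) & (dist <= k * S)] = MARROW
    k = change.pore_dilation_voxels
    if k > 0:
        dist = ndimage.distance_transform_edt(out != PORE)
        out[(out == CORTEX) & (dist <= k * S)] = PORE
    return out


def apply_change(
    vol: CalibratedVolume,
    truth: PhantomTruth,
    change: ChangeSpec,
    seed: int,
) -> tuple[CalibratedVolume, PhantomTruth]:
    """Simulate a follow-up scan of the same anatomy.

    The anatomy is re-rasterized with the scan window shifted by
    ``axial_shift_slices`` (repositioning error), morphological changes are
    applied on the supersampled label image, and the result goes through
    the same partial-volume and noise path as the baseline.  ``seed`` only
    drives the follow-up noise realization; the anatomy remains tied to the
    baseline spec's seed.
    """
    spec = truth.spec
    if spec is None:
        raise ValueError("truth must come from generate_phantom")
    if abs(change.axial_shift_slices) >= spec.n_slices / 3:
        raise ValueError("axial shift must be smaller than a third of the stack")
    fine = _rasterize(spec, shift_slices=change.axial_shift_slices)
    fine = _perturb_fine(fine, spec, change)
    vol2, labels2 = _volume_from_fine(fine, spec, noise_seed=seed)
    desc = (
        f"endo={change.endocortical_apposition_voxels} "
        f"thin={change.trabecular_thinning_voxels} "
        f"pore+={change.pore_dilation_voxels} "
        f"shift={change.axial_shift_slices}"
    )
    truth2 = _truth_from_labels(labels2, spec, applied_change=desc)
    truth2.true_ct_th = (
        spec.cortical_thickness_mm
        + change.endocortical_apposition_voxels * spec.voxel_mm
    )
    return vol2, truth2
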