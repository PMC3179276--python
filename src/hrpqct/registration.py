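"""Longitudinal common-region registration by slice-area cross-correlation.

Follow-up scans of the same limb are acquired with a repositioning error
that is, to good approximation, a pure axial offset of the scan window.
The common volume of interest (VOI) between two visits is found by
computing the periosteal cross-sectional area of every slice in each scan
and maximizing the correlation of the two area profiles over integer
offsets; all longitudinal comparisons are then restricted to the
overlapping sub-stacks.

The correlation statistic is the Pearson correlation of the mean-removed
overlapping segments, which is insensitive to a global area offset between
visits (e.g. from periosteal apposition); the raw dot product is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CalibratedVolume


@dataclass
class AreaProfile:
    """Periosteal cross-sectional area per slice, mm^2."""

    areas: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1:
            raise ValueError("area profile must be one-dimensional")
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.areas.size


@dataclass
class CommonVOI:
    """Axial overlap between a baseline and a follow-up scan.

    ``offset_slices`` is defined so that follow-up slice ``j`` images the
    anatomy of baseline slice ``j + offset_slices``.
    """

    offset_slices: int
    baseline_range: tuple[int, int]  # [start, end)
    followup_range: tuple[int, int]
    n_common: int
    correlation: float

    def __post_init__(self) -> None:
        nb = self.baseline_range[1] - self.baseline_range[0]
        nf = self.followup_range[1] - self.followup_range[0]
        if not (nb == nf == self.n_common):
            raise ValueError("VOI ranges must have equal length n_common")


def area_profile(vol: CalibratedVolume, periosteal_mask: np.ndarray) -> AreaProfile:
    """Per-slice periosteal area: voxel count times voxel area."""
    if periosteal_mask.shape != vol.data.shape:
        raise ValueError("mask must be aligned with the volume")
    counts = periosteal_mask.reshape(vol.n_slices, -1).sum(axis=1)
    return AreaProfile(areas=counts * vol.voxel_mm**2, voxel_mm=vol.voxel_mm)


def find_offset(
    a: AreaProfile,
    b: AreaProfile,
    max_shift: int = 30,
    min_overlap: int = 50,
) -> CommonVOI:
    """Optimal integer offset between two area profiles.

    Maximizes the Pearson correlation of the overlapping profile segments
    over offsets in ``[-max_shift, +max_shift]``; ties break toward the
    smaller ``|offset|``.  Offsets whose overlap is shorter than
    ``min_overlap`` slices are rejected to prevent spurious end-matching.
    """
    x, y = a.areas, b.areas
    if not x.any() or not y.any():
        raise ValueError("cannot register an all-zero area profile")
    na, nb = x.size, y.size
    if max_shift >= min(na, nb):
        raise ValueError("max_shift must be smaller than the shorter profile")
    best: tuple[float, int] | None = None
    # visit offsets in order of increasing |offset| so ties keep the smaller
    for o in sorted(range(-max_shift, max_shift + 1), key=abs):
        # follow-up slice j ~ baseline slice j + o
        lo_b = max(0, -o)
        hi_b = min(nb, na - o)
        n = hi_b - lo_b
        if n < min_overlap:
            continue
        xs = x[lo_b + o : hi_b + o]
        ys = y[lo_b:hi_b]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        if best is None or r > best[0]:
            best = (r, o)
    if best is None:
        raise ValueError(
            "no valid offset: profiles constant or overlap below min_overlap"
        )
    r, o = best
    lo_b = max(0, -o)
    hi_b = min(nb, na - o)
    return CommonVOI(
        offset_slices=o,
        baseline_range=(lo_b + o, hi_b + o),
        followup_range=(lo_b, hi_b),
        n_common=hi_b - lo_b,
        correlation=r,
    )


def crop_to_voi(
    vol: CalibratedVolume, slice_range: tuple[int, int]
) -> CalibratedVolume:
    """Axial crop of a volume to a VOI slice range."""
    lo, hi = slice_range
    if not (0 <= lo < hi <= vol.n_slices):
        raise ValueError(f"slice range {slice_range} out of bounds")
    return CalibratedVolume(
        vol.data[lo:hi].copy(),
        voxel_mm=vol.voxel_mm,
        site=vol.site,
        side=vol.side,
    )


def register_pair(
    baseline: CalibratedVolume,
    followup: CalibratedVolume,
    baseline_periosteal: np.ndarray,
    followup_periosteal: np.ndarray,
    max_shift: int = 30,
    min_overlap: int = 50,
) -> tuple[CommonVOI, CalibratedVolume, CalibratedVolume]:
    """Register a scan pair and return the VOI plus both cropped volumes."""
    voi = find_offset(
        area_profile(baseline, baseline_periosteal),
        area_profile(followup, followup_periosteal),
        max_shift=max_shift,
        min_overlap=min_overlap,
    )
    return (
        voi,
        crop_to_voi(baseline, voi.baseline_range),
        crop_to_voi(followup, voi.followup_range),
    )
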