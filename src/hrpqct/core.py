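"""Core data model and scan-geometry bookkeeping.

Calibrated HR-pQCT volumes carry density in mg HA/cm^3 on an isotropic
voxel grid (82 um in the standard in vivo protocol).  Fixed segmentation
thresholds are expressed as fractions of the scanner's positive integer
range; because the native range is device configuration rather than
physics, the mapping to absolute density is an explicit, configurable
linear scale here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Site = Literal["radius", "tibia"]
Side = Literal["left", "right"]

#: Matrix mineral density assumed for fully mineralized compact bone when
#: deriving BV/TV densitometrically (marrow taken as 0 mg HA/cm^3).
COMPACT_BONE_DENSITY = 1200.0  # mg HA/cm^3

#: Standard in vivo voxel size.
DEFAULT_VOXEL_MM = 0.082


@dataclass
class CalibratedVolume:
    """A calibrated 3D density image.

    Attributes
    ----------
    data : ndarray, shape (n_slices, ny, nx)
        Density in mg HA/cm^3.  Axis 0 is the axial (distal-proximal)
        direction; slice index increases proximally.
    voxel_mm : float
        Isotropic voxel size in mm.
    site : {"radius", "tibia"}
    side : {"left", "right"}
    """

    data: np.ndarray
    voxel_mm: float = DEFAULT_VOXEL_MM
    site: Site = "radius"
    side: Side = "left"
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density values must be finite")
        if self.slice_axis != 0:
            self.data = np.moveaxis(self.data, self.slice_axis, 0)
            self.slice_axis = 0

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def region_length_mm(self) -> float:
        return self.n_slices * self.voxel_mm


@dataclass(frozen=True)
class ScanRegionSpec:
    """Axial extent of the tomographic scan region."""

    region_length_mm: float
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_slices <= 0 or self.region_length_mm <= 0:
            raise ValueError("scan region must have positive length")


@dataclass(frozen=True)
class IntensityScale:
    """Mapping from threshold fractions of the integer grayscale range to
    absolute density.

    ``full_scale_density`` is the density corresponding to 100% of the
    positive integer range.  The standard protocol thresholds the
    Gaussian-smoothed image at 16% (cortical shell) and the
    Laplace-Hamming-filtered image at 40% (trabecular structure).
    """

    full_scale_density: float = 2000.0  # mg HA/cm^3
    cortical_threshold_frac: float = 0.16
    trabecular_threshold_frac: float = 0.40

    def __post_init__(self) -> None:
        for f in (self.cortical_threshold_frac, self.trabecular_threshold_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("threshold fractions must lie in (0, 1)")
        if self.full_scale_density <= 0:
            raise ValueError("full_scale_density must be positive")

    @property
    def cortical_threshold(self) -> float:
        """Absolute cortical threshold in mg HA/cm^3."""
        return self.cortical_threshold_frac * self.full_scale_density

    @property
    def trabecular_threshold(self) -> float:
        """Absolute trabecular threshold on the rescaled filtered image."""
        return self.trabecular_threshold_frac * self.full_scale_density


def slices_for_region(region_length_mm: float, voxel_mm: float) -> int:
    """Number of axial slices spanning a scan region.

    >>> slices_for_region(9.02, 0.082)
    110
    """
    if region_length_mm <= 0 or voxel_mm <= 0:
        raise ValueError("lengths must be positive")
    return int(round(region_length_mm / voxel_mm))


def voxel_from_fov(fov_mm: float, matrix_n: int) -> int:
    """Isotropic voxel size in micrometres from field of view and
    reconstruction matrix size.

    >>> voxel_from_fov(126, 1536)
    82
    """
    if fov_mm <= 0 or matrix_n <= 0:
        raise ValueError("fov_mm and matrix_n must be positive")
    return int(round(1000.0 * fov_mm / matrix_n))
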