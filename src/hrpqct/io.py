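"""Volume and results I/O.

Volumes are exchanged as NIfTI-1 (.nii/.nii.gz), MetaImage (.mha/.mhd) or
multi-page TIFF stacks; the first two carry the voxel size in the header,
TIFF requires explicit metadata.  Results go out as CSV (one row per
scan x region) and JSON with a schema version tag.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import CalibratedVolume
from .morphometry import MorphometryRecord

SCHEMA_VERSION = "1.0"

_VOXEL_ATOL = 1e-6


def read_volume(
    path: str | Path,
    voxel_mm: Optional[float] = None,
    site: str = "radius",
    side: str = "left",
    allow_anisotropic: bool = False,
) -> CalibratedVolume:
    """Read a calibrated volume, taking the voxel size from the header.

    TIFF stacks carry no voxel size and require ``voxel_mm``.  A header
    voxel size that contradicts an explicit ``voxel_mm`` is an error, as
    are anisotropic voxels unless ``allow_anisotropic``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        data = np.asarray(img.dataobj).T  # nibabel is (x, y, z); we use (z, y, x)
        header_voxel = tuple(float(z) for z in zooms[::-1])
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        header_voxel = tuple(float(s) for s in img.GetSpacing()[::-1])
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path))
        header_voxel = None
    else:
        raise ValueError(f"unrecognized volume format: {path.name}")

    if header_voxel is not None:
        if max(header_voxel) - min(header_voxel) > _VOXEL_ATOL and not allow_anisotropic:
            raise ValueError(f"anisotropic voxels {header_voxel} in {path.name}")
        header_iso = float(header_voxel[0])
        if voxel_mm is not None and abs(voxel_mm - header_iso) > _VOXEL_ATOL:
            raise ValueError(
                f"voxel size {voxel_mm} contradicts header {header_iso} in {path.name}"
            )
        voxel_mm = header_iso
    if voxel_mm is None:
        raise ValueError(f"{path.name} carries no voxel size; pass voxel_mm")
    return CalibratedVolume(np.asarray(data), voxel_mm=voxel_mm, site=site, side=side)


def write_volume(vol: CalibratedVolume, path: str | Path) -> Path:
    """Write a volume with its voxel size in the header (format by suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes).lower()
    v = vol.voxel_mm
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([v, v, v, 1.0])
        nib.save(nib.Nifti1Image(vol.data.T.astype(np.float32), affine), str(path))
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.data.astype(np.float32))
        img.SetSpacing((v, v, v))
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), vol.data.astype(np.float32))
    else:
        raise ValueError(f"unrecognized volume format: {path.name}")
    return path


def write_mask(mask: np.ndarray, voxel_mm: float, path: str | Path) -> Path:
    """Write a binary mask as uint8 with voxel size in the header."""
    vol = CalibratedVolume(mask.astype(np.uint8), voxel_mm=voxel_mm)
    return write_volume(vol, path)


def write_results(
    records: Sequence[MorphometryRecord | dict],
    path: str | Path,
    fmt: str = "csv",
    scan_id: str = "scan",
) -> Path:
    """Write morphometry/FE records as CSV or JSON.

    CSV gets one row per record keyed by (scan_id, region_label); JSON
    wraps the same rows with a schema version.
    """
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        d = rec.as_dict() if hasattr(rec, "as_dict") else dict(rec)
        rows.append({"scan_id": scan_id, **d})
    columns = ["scan_id"] + list(MorphometryRecord().as_dict().keys())
    df = pd.DataFrame(rows, columns=columns if rows else columns)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        payload = {"schema_version": SCHEMA_VERSION,
                   "records": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1, default=float))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_truth(truth, path: str | Path) -> Path:
    """JSON sidecar with a phantom's generator truth (labels omitted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "true_ct_po": truth.true_ct_po,
        "true_tb_n": truth.true_tb_n,
        "true_ct_th": truth.true_ct_th,
        "true_bvtv": truth.true_bvtv,
        "true_density": truth.true_density,
        "applied_change": truth.applied_change,
        "voxel_counts": truth.voxel_counts,
        "schema_version": SCHEMA_VERSION,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path
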