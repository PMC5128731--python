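"""Reading and writing CT volumes, masks and contours.

Supported inputs: NIfTI (``.nii`` / ``.nii.gz``), a directory of DICOM
files (one series, sorted by slice position), or a directory / glob of
PNG/TIFF slices (stacked in sorted filename order).  Volumes are held as
``(slice, row, col)`` arrays; NIfTI files are written with an RAS-ish
affine built from the voxel spacing, and read back by reversing the same
axis order, so lungtrace output round-trips.
"""

from __future__ import annotations

import glob
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import CTVolume

__all__ = [
    "load_volume",
    "save_volume_nifti",
    "load_mask",
    "save_mask_nifti",
    "save_mask_png_stack",
    "contours_to_csv",
    "metrics_to_csv",
]

_PNG_EXTS = (".png", ".tif", ".tiff")


def load_volume(path: str, spacing: tuple[float, float, float] | None = None) -> CTVolume:
    """Load a CT volume from NIfTI, a DICOM series directory, or an image
    stack directory/glob.  ``spacing`` overrides the stored spacing (and is
    required metadata for image stacks, defaulting to 1 mm)."""
    if os.path.isdir(path):
        files = sorted(os.listdir(path))
        if any(f.lower().endswith(_PNG_EXTS) for f in files):
            return _load_image_stack(
                [os.path.join(path, f) for f in files if f.lower().endswith(_PNG_EXTS)],
                spacing,
            )
        return _load_dicom_series(path, spacing)
    if path.endswith((".nii", ".nii.gz")):
        return _load_nifti(path, spacing)
    matched = sorted(glob.glob(path))
    if matched and matched[0].lower().endswith(_PNG_EXTS):
        return _load_image_stack(matched, spacing)
    raise ValueError(f"unrecognized volume input: {path!r}")


def _load_nifti(path: str, spacing) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 2:
        data = data[..., None]
    # our writer stores (col, row, slice) in voxel axes; reverse to
    # (slice, row, col)
    voxels = np.transpose(data, (2, 1, 0))
    if spacing is None:
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels, spacing=spacing)


def _nifti_affine(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def save_volume_nifti(path: str, volume: CTVolume) -> None:
    import nibabel as nib

    data = np.transpose(volume.voxels, (2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.float32), _nifti_affine(volume.spacing)), path)


def save_mask_nifti(
    path: str, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> None:
    """Write a (labeled or boolean) mask volume as uint8 NIfTI."""
    import nibabel as nib

    arr = np.asarray(mask)
    if arr.ndim == 2:
        arr = arr[None]
    data = np.transpose(arr.astype(np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _nifti_affine(spacing)), path)


def load_mask(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a mask volume (NIfTI or image stack); returns (array, spacing)."""
    vol = load_volume(path)
    return vol.voxels.astype(np.uint8), vol.spacing


def _load_dicom_series(path: str, spacing) -> CTVolume:
    import pydicom

    slices = []
    for f in sorted(os.listdir(path)):
        full = os.path.join(path, f)
        try:
            ds = pydicom.dcmread(full)
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {path!r}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    if spacing is None:
        first = slices[0]
        ps = getattr(first, "PixelSpacing", [1.0, 1.0])
        if len(slices) > 1:
            dz = abs(sort_key(slices[1]) - sort_key(slices[0])) or 1.0
        else:
            dz = float(getattr(first, "SliceThickness", 1.0))
        spacing = (dz, float(ps[0]), float(ps[1]))
    return CTVolume(np.stack(arrays), spacing=spacing)


def _load_image_stack(files: list[str], spacing) -> CTVolume:
    arrays = [np.asarray(iio.imread(f), dtype=float) for f in files]
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    return CTVolume(np.stack(arrays), spacing=spacing)


def save_mask_png_stack(directory: str, mask: np.ndarray, prefix: str = "slice") -> None:
    """Write each slice of a mask volume as an 8-bit PNG (labels scaled to
    be visible: 0/1/2 -> 0/127/254)."""
    os.makedirs(directory, exist_ok=True)
    arr = np.asarray(mask)
    if arr.ndim == 2:
        arr = arr[None]
    for i, sl in enumerate(arr):
        iio.imwrite(
            os.path.join(directory, f"{prefix}_{i:04d}.png"),
            (sl.astype(np.uint8) * 127).clip(0, 255).astype(np.uint8),
        )


def contours_to_csv(path: str, per_slice_contours: dict) -> None:
    """Write refined contours as CSV rows (slice, side, row, col).

    ``per_slice_contours`` maps slice index -> {side: FloatContour}.
    """
    rows = []
    for idx, sides in sorted(per_slice_contours.items()):
        for side, curve in sides.items():
            for r, c in curve.points:
                rows.append((idx, side, float(r), float(c)))
    pd.DataFrame(rows, columns=["slice", "side", "row", "col"]).to_csv(
        path, index=False
    )


def metrics_to_csv(path: str, records: list[dict]) -> None:
    pd.DataFrame(records).to_csv(path, index=False)
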