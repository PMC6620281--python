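"""Readers and writers for slices, phantoms, contours and cohort tables.

DICOM reading needs the optional ``pydicom`` dependency (install
``lsnquant[dicom]``); NIfTI and 16-bit PNG are always available.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .phantom import PhantomData
from .segmentation import Slice

__all__ = [
    "read_slice",
    "write_nifti",
    "read_nifti",
    "write_png16",
    "write_mask_png",
    "write_phantom",
    "contour_to_csv",
    "read_roi_file",
    "read_cohort_csv",
]


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    if name.endswith((".dcm", ".ima")):
        return "dicom"
    raise InputError(f"cannot infer image format from {path}")


def read_slice(path: str | os.PathLike, fmt: str | None = None,
               slice_selector: int | None = None,
               spacing: float | None = None) -> Slice:
    """Load one 2-D slice with its pixel spacing in mm.

    ``slice_selector`` picks a plane from 3-D NIfTI volumes (axis 2) or a
    file from a DICOM series directory (sorted by InstanceNumber).  PNG
    carries no physical spacing, so ``spacing`` is mandatory there.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    fmt = fmt or _infer_format(path)

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            if data.shape[2] == 1:
                data = data[:, :, 0]
            elif slice_selector is None:
                raise InputError(
                    f"volume has {data.shape[2]} slices; pass a slice "
                    f"selector in [0, {data.shape[2] - 1}]")
            else:
                data = data[:, :, slice_selector]
        sp = spacing if spacing is not None else float(zooms[0])
        return Slice(data, pixel_spacing=sp, metadata={"source": str(path)})

    if fmt == "png":
        if spacing is None:
            raise InputError("PNG carries no pixel spacing; pass spacing "
                             "explicitly (mm/pixel)")
        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3:  # collapse RGB(A)
            data = data[..., :3].mean(axis=-1)
        return Slice(data, pixel_spacing=spacing, metadata={"source": str(path)})

    if fmt == "dicom":
        try:
            import pydicom
        except ImportError as exc:
            raise InputError(
                "DICOM support requires the optional pydicom dependency "
                "(pip install lsnquant[dicom])") from exc
        if path.is_dir():
            files = sorted(p for p in path.iterdir()
                           if p.suffix.lower() in (".dcm", ".ima"))
            if not files:
                raise InputError(f"no DICOM files in {path}")
            datasets = [pydicom.dcmread(str(f)) for f in files]
            datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
            if len(datasets) > 1 and slice_selector is None:
                raise InputError(
                    f"series has {len(datasets)} slices; pass a slice "
                    f"selector in [0, {len(datasets) - 1}]")
            ds = datasets[slice_selector or 0]
        else:
            ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        data = data * slope + intercept
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            sp = float(ps[0])
        elif spacing is not None:
            sp = spacing
        else:
            raise InputError("DICOM lacks PixelSpacing; pass spacing explicitly")
        return Slice(data, pixel_spacing=sp,
                     metadata={"source": str(path),
                               "pixel_spacing_rc": (float(ps[0]), float(ps[1]))
                               if ps is not None else None})

    raise InputError(f"unknown format {fmt!r}")


def write_nifti(path: str | os.PathLike, array: np.ndarray,
                spacing: float = 1.0) -> None:
    arr = np.asarray(array, dtype=np.float64)
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((spacing,) * arr.ndim)
    nib.save(img, str(path))


def read_nifti(path: str | os.PathLike) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(float)


def write_png16(path: str | os.PathLike, array: np.ndarray) -> None:
    """Round and clip to the uint16 range; lossy for arbitrary floats."""
    arr = np.clip(np.round(np.asarray(array, dtype=float)), 0, 65535)
    iio.imwrite(path, arr.astype(np.uint16))


def write_mask_png(path: str | os.PathLike, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def write_phantom(data: PhantomData, outdir: str | os.PathLike) -> dict:
    """Write image, mask, bias and boundary ground truth; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = data.spec.pixel_spacing
    paths = {
        "image_nii": outdir / "phantom.nii",
        "image_png": outdir / "phantom.png",
        "mask_png": outdir / "true_mask.png",
        "bias_nii": outdir / "true_bias.nii",
        "boundary_csv": outdir / "true_boundary.csv",
    }
    write_nifti(paths["image_nii"], data.image, sp)
    write_png16(paths["image_png"], data.image)
    write_mask_png(paths["mask_png"], data.true_mask)
    write_nifti(paths["bias_nii"], data.true_bias, sp)
    pd.DataFrame({
        "index": np.arange(len(data.true_boundary)),
        "row": data.true_boundary[:, 0],
        "col": data.true_boundary[:, 1],
    }).to_csv(paths["boundary_csv"], index=False)
    return {k: str(v) for k, v in paths.items()}


def contour_to_csv(path: str | os.PathLike, contour) -> None:
    cum = contour.cumulative_lengths[:len(contour.points)] * contour.pixel_spacing
    pd.DataFrame({
        "index": np.arange(len(contour.points)),
        "row": contour.points[:, 0],
        "col": contour.points[:, 1],
        "cumulative_arclength_mm": cum,
    }).to_csv(path, index=False)


def read_roi_file(path: str | os.PathLike) -> list[tuple[int, int]]:
    """CSV with columns roi_id, start_index, end_index."""
    df = pd.read_csv(path)
    required = {"roi_id", "start_index", "end_index"}
    if not required.issubset(df.columns):
        raise ParameterError(
            f"ROI file must have columns {sorted(required)}, "
            f"got {list(df.columns)}")
    return [(int(r.start_index), int(r.end_index)) for r in df.itertuples()]


def read_cohort_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "fibrosis", "lsn_score"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
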