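"""Readers and writers for multispectral stacks and score maps.

Supported inputs (all bands must share one pixel grid and be pre-aligned):

* multi-page TIFF, one page per band, page order = band order;
* a directory of single-frame DICOM files, ordered by filename;
* a directory of grayscale PNG (or other imageio-readable) images, ordered
  by filename.

Integer intensities are rescaled to [0, 1] by the dtype maximum on load
(16-bit DICOM and 8-bit PNG end up on one scale); float inputs are passed
through unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .features import ImageStack

__all__ = [
    "load_stack",
    "load_tiff_stack",
    "load_dicom_dir",
    "load_image_dir",
    "write_psi_tiff",
    "write_psi_csv",
]


def _rescale(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def load_tiff_stack(path: str | Path) -> ImageStack:
    """Load a multi-page TIFF, one grayscale page per spectral band."""
    import tifffile

    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2-D pages, got shape {pages.shape}")
    return ImageStack(bands=[_rescale(p) for p in pages])


def load_dicom_dir(path: str | Path) -> ImageStack:
    """Load a directory of single-frame DICOM files, ordered by filename."""
    import pydicom

    files = sorted(Path(path).glob("*.dcm")) or sorted(Path(path).iterdir())
    bands, labels = [], []
    for f in files:
        if not f.is_file():
            continue
        ds = pydicom.dcmread(str(f))
        bands.append(_rescale(ds.pixel_array))
        labels.append(f.stem)
    if not bands:
        raise ValueError(f"no DICOM files found under {path}")
    return ImageStack(bands=bands, band_labels=labels)


def load_image_dir(path: str | Path, pattern: str = "*.png") -> ImageStack:
    """Load a directory of grayscale images (PNG by default), by filename."""
    import imageio.v3 as iio

    files = sorted(Path(path).glob(pattern))
    if not files:
        raise ValueError(f"no files matching {pattern!r} under {path}")
    bands, labels = [], []
    for f in files:
        img = iio.imread(str(f))
        if img.ndim == 3:  # collapse an RGB(A) read of a gray image
            img = img[..., :3].mean(axis=-1)
        bands.append(_rescale(img))
        labels.append(f.stem)
    return ImageStack(bands=bands, band_labels=labels)


def load_stack(path: str | Path, fmt: str = "auto") -> ImageStack:
    """Dispatch on ``fmt`` in {'tiff', 'dicom', 'png', 'auto'}."""
    path = Path(path)
    if fmt == "auto":
        if path.is_file():
            fmt = "tiff"
        elif any(path.glob("*.dcm")):
            fmt = "dicom"
        else:
            fmt = "png"
    if fmt == "tiff":
        return load_tiff_stack(path)
    if fmt == "dicom":
        return load_dicom_dir(path)
    if fmt == "png":
        return load_image_dir(path)
    raise ValueError(f"unknown stack format {fmt!r}")


def write_psi_tiff(path: str | Path, psi_grid: np.ndarray) -> None:
    """Write a score map as a 32-bit float single-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(psi_grid, dtype=np.float32))


def write_psi_csv(path: str | Path, psi_grid: np.ndarray) -> None:
    """Write a score map as CSV rows (row, col, psi)."""
    import pandas as pd

    H, W = psi_grid.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pd.DataFrame(
        {"row": rr.ravel(), "col": cc.ravel(), "psi": np.asarray(psi_grid).ravel()}
    ).to_csv(path, index=False)
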