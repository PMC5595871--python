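"""Gradient-orientation features for multispectral image stacks.

Each spectral slice is converted to a per-pixel unit gradient-orientation
field, and the orientations in a small window around every pixel are
concatenated into that pixel's representative feature vector for the slice.
Orientation (rather than intensity) makes the features invariant to the
band-to-band illumination and absorption gain that dominates raw
multispectral intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStack",
    "OrientationField",
    "FeatureMatrix",
    "compute_orientation",
    "extract_window_features",
    "build_feature_matrix",
]

#: gradient magnitudes below this are treated as "no orientation"
GRAD_EPS = 1e-12


@dataclass
class ImageStack:
    """An aligned multispectral sequence: s bands on one H x W pixel grid.

    Intensities are float arrays rescaled to [0, 1]; use the readers in
    :mod:`msinc.io` to load TIFF/DICOM/PNG data with the rescaling applied.
    """

    bands: list[np.ndarray]
    band_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bands) < 2:
            raise ValueError("an ImageStack needs at least 2 spectral bands")
        shapes = {b.shape for b in self.bands}
        if len(shapes) != 1:
            raise ValueError(f"bands differ in shape: {sorted(shapes)}")
        self.bands = [np.asarray(b, dtype=np.float64) for b in self.bands]
        if not self.band_labels:
            self.band_labels = [f"band-{k}" for k in range(len(self.bands))]
        if len(self.band_labels) != len(self.bands):
            raise ValueError("band_labels length must match number of bands")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands[0].shape


@dataclass
class OrientationField:
    """Per-pixel unit gradient direction, stored as (cos θ, sin θ) channels.

    ``valid`` is False where the gradient magnitude vanishes; there both
    channels are exactly 0, a neutral encoding for "no orientation".
    """

    cos: np.ndarray
    sin: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.cos.shape


@dataclass
class FeatureMatrix:
    """The d x n observation matrix X with per-spectrum row blocks.

    Rows ``block_bounds[j][0]:block_bounds[j][1]`` hold x_ij for spectrum j;
    column i corresponds to flat pixel index ``pixel_index[i]`` on the
    ``grid_shape`` raster (the map needed to fold per-pixel scores back into
    an image).
    """

    values: np.ndarray
    block_bounds: list[tuple[int, int]]
    grid_shape: tuple[int, int] | None = None
    pixel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("X must be 2-D (d x n)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("X contains non-finite entries")
        d = self.values.shape[0]
        covered = sorted(self.block_bounds)
        if covered[0][0] != 0 or covered[-1][1] != d:
            raise ValueError("block_bounds must cover all d rows")
        for (a0, a1), (b0, b1) in zip(covered, covered[1:]):
            if a1 != b0:
                raise ValueError("block_bounds must be contiguous and disjoint")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def s(self) -> int:
        return len(self.block_bounds)

    @property
    def d_js(self) -> np.ndarray:
        return np.array([b - a for a, b in self.block_bounds], dtype=np.int64)

    def block(self, j: int) -> np.ndarray:
        """The d_j x n feature block of spectrum j (a view, not a copy)."""
        a, b = self.block_bounds[j]
        return self.values[a:b]


def compute_orientation(image: np.ndarray) -> OrientationField:
    """Unit gradient orientation of a 2-D image.

    Gradients are central differences with reflective border padding, so the
    field covers every pixel of the grid.  Pixels with gradient magnitude
    below ``GRAD_EPS`` (flat patches, and borders of locally symmetric
    patterns) are flagged invalid and encoded (0, 0).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D with H, W >= 3")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    p = np.pad(image, 1, mode="reflect")
    gx = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])   # d/d(col)
    gy = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])   # d/d(row)
    mag = np.hypot(gx, gy)
    valid = mag >= GRAD_EPS
    safe = np.where(valid, mag, 1.0)
    cos = np.where(valid, gx / safe, 0.0)
    sin = np.where(valid, gy / safe, 0.0)
    return OrientationField(cos=cos, sin=sin, valid=valid)


def extract_window_features(fld: OrientationField, window: int) -> np.ndarray:
    """Concatenate the (cos θ, sin θ) pairs of a w x w window at every pixel.

    Returns an (H, W, 2 w^2) array; the last axis lists the window positions
    in row-major order, each contributing its (cos, sin) pair.  Borders use
    reflective padding so every pixel yields a full-length vector.
    """
    w = int(window)
    if w % 2 == 0:
        raise ValueError("window size must be odd")
    H, W = fld.shape
    if not (3 <= w <= min(H, W)):
        raise ValueError("window must satisfy 3 <= w <= min(H, W)")
    half = w // 2
    out = np.empty((H, W, 2 * w * w), dtype=np.float64)
    for k, chan in enumerate((fld.cos, fld.sin)):
        p = np.pad(chan, half, mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(p, (w, w))
        out[..., k::2] = win.reshape(H, W, w * w)
    return out


def build_feature_matrix(
    stack: ImageStack,
    window: int = 7,
    mask: np.ndarray | None = None,
    center: bool = True,
) -> FeatureMatrix:
    """Assemble the d x n observation matrix from an image stack.

    Every band contributes a block of 2*window^2 rows; columns are pixels
    (optionally restricted to a boolean region-of-interest ``mask``).  Each
    row is mean-centered across pixels by default: the latent prior of the
    downstream model is zero-mean with no intercept, so the linear
    reconstruction x_ij = P_j z_i is only attainable for centered features.
    """
    H, W = stack.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError("mask shape must match the image grid")
        if not mask.any():
            raise ValueError("mask selects zero pixels")
        cols = np.flatnonzero(mask.ravel())
    else:
        cols = np.arange(H * W)

    blocks = []
    bounds = []
    row = 0
    for band in stack.bands:
        feats = extract_window_features(compute_orientation(band), window)
        block = feats.reshape(H * W, -1)[cols].T  # d_j x n
        if center:
            block = block - block.mean(axis=1, keepdims=True)
        blocks.append(block)
        bounds.append((row, row + block.shape[0]))
        row += block.shape[0]

    return FeatureMatrix(
        values=np.vstack(blocks),
        block_bounds=bounds,
        grid_shape=(H, W),
        pixel_index=cols,
    )
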