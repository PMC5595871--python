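"""Ground-truthed synthetic inputs at two levels.

``generate_views`` draws raw multi-view feature matrices directly from the
generative model (shared latent per pixel, plus planted multi-latent
"anomalous" pixels), so the sampler can be validated against known
projections and labels.  ``generate_msi_stack`` builds an image-level
phantom: a smooth band-coherent background with elliptical lesions whose
texture decouples across the longer-wavelength bands, instantiating
spectral inconsistency the way early pigment-epithelium changes appear
only in red/infrared slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .features import FeatureMatrix, ImageStack

__all__ = ["GenerativeParams", "generate_views", "generate_msi_stack"]


@dataclass
class GenerativeParams:
    """Ground truth behind a synthetic feature matrix.

    ``latent_vectors[i]`` holds the latent vectors of pixel i (one row for
    consistent pixels, two for anomalous ones); ``view_assignment[i, j]``
    indexes the row used by view j.  ``weights[i]`` are the per-pixel
    mixture weights that assigned the views of anomalous pixels.
    """

    true_P: list[np.ndarray]
    sigma: float
    r: float
    latent_vectors: list[np.ndarray]
    view_assignment: np.ndarray
    weights: list[np.ndarray]
    anomaly_labels: np.ndarray

    def __post_init__(self) -> None:
        for i, lab in enumerate(self.anomaly_labels):
            used = len(np.unique(self.view_assignment[i]))
            if bool(lab) != (used > 1):
                raise ValueError(
                    f"pixel {i}: label {bool(lab)} inconsistent with "
                    f"{used} latent vector(s) in use"
                )


def generate_views(
    n: int,
    s: int,
    d_j: int,
    l: int,
    anomaly_rate: float = 0.0,
    sigma: float = 50.0,
    r: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, GenerativeParams]:
    """Draw a d x n multi-view feature matrix from the generative model.

    Projection entries are i.i.d. standard normal; latents z ~ N(0,
    I/(sigma r)); observations x_ij = P_j z_{i, m(j)} + eps with eps ~
    N(0, I/sigma).  A fraction ``anomaly_rate`` of pixels draws a second
    independent latent vector and assigns each view to one of the two
    uniformly, re-drawing until both are actually used.
    """
    if not 0 <= anomaly_rate < 1:
        raise ValueError("anomaly_rate must lie in [0, 1)")
    if min(n, s, d_j, l) < 1 or s < 2:
        raise ValueError("need n, d_j, l >= 1 and s >= 2")
    if 0 < anomaly_rate and anomaly_rate * n < 1:
        warnings.warn(
            "anomaly_rate * n < 1: the drawn sample may contain no anomalies",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    true_P = [rng.standard_normal((d_j, l)) for _ in range(s)]

    n_anom = int(round(anomaly_rate * n))
    anom_idx = rng.choice(n, size=n_anom, replace=False)
    labels = np.zeros(n, dtype=bool)
    labels[anom_idx] = True

    z_std = 1.0 / np.sqrt(sigma * r)
    latents: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    assign = np.zeros((n, s), dtype=np.int64)
    X = np.empty((s * d_j, n))
    for i in range(n):
        if labels[i]:
            Z = rng.normal(0.0, z_std, size=(2, l))
            w = np.full(2, 0.5)
            while True:
                a = rng.integers(0, 2, size=s)
                if len(np.unique(a)) == 2:
                    break
        else:
            Z = rng.normal(0.0, z_std, size=(1, l))
            w = np.ones(1)
            a = np.zeros(s, dtype=np.int64)
        latents.append(Z)
        weights.append(w)
        assign[i] = a
        for j in range(s):
            mean = true_P[j] @ Z[a[j]]
            X[j * d_j:(j + 1) * d_j, i] = mean + rng.normal(
                0.0, 1.0 / np.sqrt(sigma), size=d_j
            )

    fm = FeatureMatrix(
        values=X,
        block_bounds=[(j * d_j, (j + 1) * d_j) for j in range(s)],
    )
    params = GenerativeParams(
        true_P=true_P,
        sigma=sigma,
        r=r,
        latent_vectors=latents,
        view_assignment=assign,
        weights=weights,
        anomaly_labels=labels,
    )
    return fm, params


def _smooth_field(rng: np.random.Generator, H: int, W: int, scale: float) -> np.ndarray:
    """Zero-mean unit-variance low-frequency Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal((H, W)), scale)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_msi_stack(
    H: int = 64,
    W: int = 64,
    s: int = 5,
    n_lesions: int = 3,
    lesion_radius: float = 7.0,
    contrast_flip_band: int | None = None,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Multispectral phantom with spectrally incoherent lesions.

    The background is one smooth Gaussian field shared by all bands with a
    band-specific gain (consistent tissue: orientation identical across
    bands).  Each lesion is an ellipse inside which, for every band index
    >= ``contrast_flip_band`` (default s // 2), the texture is re-drawn
    independently per band — structure visible only at the longer
    wavelengths, and incoherent among them.  Lesions overflowing the frame
    are clipped.  Returns the stack and the boolean lesion mask.
    """
    if min(H, W) < 32:
        raise ValueError("H and W must be >= 32")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    if contrast_flip_band is None:
        contrast_flip_band = s // 2
    rng = np.random.default_rng(seed)

    background = _smooth_field(rng, H, W, scale=6.0)
    gains = rng.uniform(0.6, 1.4, size=s)
    bands = [0.5 + 0.12 * g * background for g in gains]

    mask = np.zeros((H, W), dtype=bool)
    rr, cc = np.mgrid[0:H, 0:W]
    for _ in range(n_lesions):
        cy = rng.uniform(lesion_radius, H - lesion_radius)
        cx = rng.uniform(lesion_radius, W - lesion_radius)
        ry = lesion_radius * rng.uniform(0.6, 1.2)
        rx = lesion_radius * rng.uniform(0.6, 1.2)
        theta = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask |= (u / ry) ** 2 + (v / rx) ** 2 <= 1.0

    for j in range(contrast_flip_band, s):
        lesion_tex = _smooth_field(rng, H, W, scale=2.0)
        bands[j] = np.where(mask, 0.5 + 0.12 * gains[j] * lesion_tex, bands[j])

    # slight per-band sensor noise; keeps bands non-identical without
    # breaking the orientation coherence of the background
    bands = [
        np.clip(band + rng.normal(0.0, 0.004, size=(H, W)), 0.0, 1.0)
        for band in bands
    ]
    labels = [f"synth-band-{k}" for k in range(s)]
    return ImageStack(bands=bands, band_labels=labels), mask
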