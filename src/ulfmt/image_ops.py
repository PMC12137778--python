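"""Image-domain utilities: coil combination and magnitude denoising."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_nl_means

__all__ = ["MagnitudeImage", "rss_combine", "nlm_denoise"]


@dataclass
class MagnitudeImage:
    """Non-negative 3D intensity volume with voxel sizes in mm."""

    data: np.ndarray
    voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("magnitude intensities must be non-negative")
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")


def rss_combine(per_coil: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares combination of per-coil complex images.

    ``per_coil`` has shape (n_coils, ...); the result drops the coil axis.
    Permutation-invariant in coil order and linear in a global scale factor.
    """
    per_coil = np.asarray(per_coil)
    if per_coil.ndim < 2 or per_coil.shape[0] < 1:
        raise ValueError("expected a stack of at least one coil image")
    return np.sqrt(np.sum(np.abs(per_coil) ** 2, axis=0))


def nlm_denoise(
    img: np.ndarray | MagnitudeImage,
    patch_radius: int = 1,
    search_radius: int = 3,
    smoothing: float = 0.05,
) -> np.ndarray:
    """Non-local-means denoising of a magnitude volume.

    ``smoothing`` is the filtering strength ``h`` in the units of the image;
    0 disables the filter (identity). Output is never negative, and a
    constant image passes through unchanged (every patch is identical, so
    the weighted average reproduces the value).
    """
    data = img.data if isinstance(img, MagnitudeImage) else np.asarray(img, dtype=float)
    if patch_radius < 0 or search_radius < 0:
        raise ValueError("radii must be >= 0")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if smoothing == 0:
        return data.copy()
    out = denoise_nl_means(
        data,
        patch_size=2 * patch_radius + 1,
        patch_distance=search_radius,
        h=smoothing,
        fast_mode=True,
        preserve_range=True,
    )
    return np.clip(out, 0.0, None)
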