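"""Shared image-conditioning operators used by both imaging pipelines.

All operators are deterministic, shape-preserving functions of plain
``numpy`` arrays.  Physical units enter only through ``voxel_size``:
Gaussian scales are given in micrometres and converted to per-axis voxel
sigmas, which is how anisotropic stacks (z coarser than x/y) are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, white_tophat
from skimage.segmentation import morphological_chan_vese

__all__ = [
    "ImageStack3D",
    "match_histogram",
    "blob_enhance",
    "dog_enhance",
    "subtract_background",
    "otsu_threshold",
    "refine_active_contour",
    "sigma_um_to_voxels",
    "mask_volume",
]


@dataclass
class ImageStack3D:
    """Multi-channel intensity image with physical voxel size.

    Parameters
    ----------
    channels : dict
        Mapping channel name -> intensity array (all the same shape).
        Arrays may be 3D (z, y, x) or 2D (y, x).
    voxel_size : tuple of float
        Physical size of one voxel per axis, in micrometres, in the same
        axis order as the arrays (e.g. ``(0.297, 0.1154, 0.1154)`` for an
        anisotropic confocal stack).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        ndim = next(iter(shapes.__iter__())).__len__()
        if len(self.voxel_size) != ndim:
            raise ValueError("voxel_size length must match array ndim")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


def sigma_um_to_voxels(sigma_um: float, voxel_size: tuple[float, ...]) -> tuple[float, ...]:
    """Convert an isotropic physical scale to per-axis voxel sigmas."""
    if sigma_um <= 0:
        raise ValueError("sigma must be positive")
    return tuple(sigma_um / v for v in voxel_size)


def mask_volume(mask: np.ndarray, voxel_size: tuple[float, ...]) -> float:
    """Physical volume (µm³, or area in µm² for 2D) of a binary mask."""
    return float(np.count_nonzero(mask)) * float(np.prod(voxel_size))


def match_histogram(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Monotone intensity remapping of ``image`` onto ``reference``'s histogram.

    Normalising every acquisition to one reference image removes
    session-to-session intensity drift before a global threshold is applied.
    Raises if the reference is constant (the mapping is undefined).
    """
    if image.size == 0 or reference.size == 0:
        raise ValueError("empty image")
    if np.ptp(reference) == 0:
        raise ValueError("constant-valued reference: histogram mapping undefined")
    return exposure.match_histograms(np.asarray(image, dtype=float), np.asarray(reference, dtype=float))


def blob_enhance(
    channel: np.ndarray,
    sigma_um: float,
    voxel_size: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Gaussian smoothing at a physical scale, to raise blob SNR before Otsu.

    ``voxel_size=None`` interprets ``sigma_um`` directly in pixels.
    Edge mode is reflective so borders are not darkened (a darkened rim
    would bias the subsequent threshold).
    """
    if voxel_size is None:
        voxel_size = (1.0,) * channel.ndim
    sigma = sigma_um_to_voxels(sigma_um, voxel_size)
    return ndi.gaussian_filter(np.asarray(channel, dtype=float), sigma=sigma, mode="reflect")


def dog_enhance(
    channel: np.ndarray,
    sigma_small: float,
    sigma_large: float,
    voxel_size: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Difference-of-Gaussians band-pass: keeps cell-body-scale features,
    suppresses both pixel noise and slowly varying background."""
    if not sigma_small < sigma_large:
        raise ValueError(f"need sigma_small < sigma_large, got {sigma_small} >= {sigma_large}")
    lo = blob_enhance(channel, sigma_small, voxel_size)
    hi = blob_enhance(channel, sigma_large, voxel_size)
    return lo - hi


def subtract_background(channel: np.ndarray, disk_radius: int) -> np.ndarray:
    """Remove broad background with a disk-shaped morphological opening.

    The opening (an estimate of everything wider than the disk) is
    subtracted from the input — the white top-hat.  Features smaller than
    the disk are preserved; output is non-negative and pixelwise <= input.
    2D only.
    """
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("background subtraction is defined for 2D images")
    if 2 * disk_radius + 1 > min(channel.shape):
        raise ValueError("structuring disk larger than image")
    return white_tophat(channel, footprint=disk(disk_radius))


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> tuple[float, np.ndarray]:
    """Otsu threshold plus the resulting foreground mask.

    The threshold maximises between-class variance of a 256-bin histogram
    over the channel's min–max range; a voxel is foreground iff its
    intensity is *strictly greater* than the threshold.  Both choices are
    fixed so that results are bit-reproducible.
    """
    channel = np.asarray(channel)
    if np.ptp(channel) == 0:
        raise ValueError("constant channel: Otsu threshold undefined")
    thr = float(threshold_otsu(channel, nbins=nbins))
    return thr, channel > thr


def refine_active_contour(
    channel: np.ndarray,
    init_mask: np.ndarray,
    iterations: int = 35,
    smoothing: int = 1,
) -> np.ndarray:
    """Refine an initial mask with region-based (edge-free) active contours.

    Runs the morphological Chan–Vese evolution for a fixed iteration
    budget starting from ``init_mask``; the budget also bounds how far any
    boundary can travel (one voxel per iteration), so components cannot
    stray arbitrarily from the initialisation.  ``iterations=0`` returns
    the initial mask unchanged.
    """
    init_mask = np.asarray(init_mask, dtype=bool)
    if init_mask.shape != channel.shape:
        raise ValueError("init_mask shape must match channel")
    if not init_mask.any():
        raise ValueError("empty initial mask")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return init_mask.copy()
    out = morphological_chan_vese(
        np.asarray(channel, dtype=float),
        num_iter=iterations,
        init_level_set=init_mask.astype(np.int8),
        smoothing=smoothing,
    )
    return out.astype(bool)
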