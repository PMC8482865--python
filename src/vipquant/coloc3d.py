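"""3D puncta-on-process colocalization with soma removal.

The statistic: segment the cytosolic cell label, remove the somas so only
neurite processes remain, segment the puncta channel after histogram
normalisation to a reference image, AND the two masks, and count 3D
connected components — putative puncta on processes — normalised by the
physical volume of the processes (puncta per µm³).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import stats
from .preproc import (
    ImageStack3D,
    blob_enhance,
    mask_volume,
    match_histogram,
    otsu_threshold,
    refine_active_contour,
)

__all__ = [
    "ColocResult",
    "segment_somas",
    "make_process_mask",
    "segment_puncta",
    "count_colocalized",
    "quantify_stack",
    "compare_coloc_groups",
]

log = logging.getLogger(__name__)

_STRUCTURES = {6: ndi.generate_binary_structure(3, 1),
               18: ndi.generate_binary_structure(3, 2),
               26: ndi.generate_binary_structure(3, 3)}


def _structure(connectivity: int, ndim: int) -> np.ndarray:
    if ndim == 3:
        try:
            return _STRUCTURES[connectivity]
        except KeyError:
            raise ValueError("3D connectivity must be 6, 18 or 26") from None
    return ndi.generate_binary_structure(ndim, ndim)


@dataclass
class ColocResult:
    """Colocalized-puncta count and process-volume-normalised density."""

    n_colocalized: int
    process_volume: float      # µm³
    density: float             # puncta per µm³
    layer_label: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.process_volume <= 0:
            raise ValueError("process volume must be positive")
        if self.n_colocalized < 0:
            raise ValueError("count must be >= 0")
        if not np.isclose(self.density, self.n_colocalized / self.process_volume):
            raise ValueError("density inconsistent with count / volume")

    def to_dict(self) -> dict:
        return {
            "n_colocalized": self.n_colocalized,
            "process_volume_um3": self.process_volume,
            "density_per_um3": self.density,
            "layer": self.layer_label,
            "group": self.group_label,
        }


def segment_somas(
    cell_channel: np.ndarray,
    voxel_size: tuple[float, ...],
    sigma_um: float = 1.5,
    ac_iterations: int = 10,
    ac_smoothing: int = 1,
    min_volume_um3: float = 300.0,
) -> np.ndarray:
    """Mask of soma-scale bright bodies in the cell channel.

    Blob enhancement at a soma scale suppresses the thin processes, Otsu
    picks out the bright bodies, active contours sharpen the boundary on
    the raw channel, and a volume floor (default 300 µm³, well above any
    process fragment) keeps only soma-sized components.  Returns an empty
    mask when nothing survives the floor.
    """
    cell_channel = np.asarray(cell_channel, dtype=float)
    smoothed = blob_enhance(cell_channel, sigma_um, voxel_size)
    _, init = otsu_threshold(smoothed)
    if not init.any():
        return init
    voxel_vol = float(np.prod(voxel_size))
    labels, n = ndi.label(init, structure=_structure(26, init.ndim))
    counts = np.bincount(labels.ravel())
    refined = np.zeros_like(init)
    pad = ac_iterations + 3
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        # a component can only grow one voxel per iteration, so anything far
        # below the floor cannot reach it and is skipped outright
        if counts[lab] * voxel_vol < min_volume_um3 / 16.0:
            continue
        crop_sl = tuple(
            slice(max(0, s.start - pad), min(dim, s.stop + pad))
            for s, dim in zip(sl, init.shape)
        )
        piece = refine_active_contour(
            cell_channel[crop_sl], labels[crop_sl] == lab,
            iterations=ac_iterations, smoothing=ac_smoothing,
        ) if ac_iterations > 0 else labels[crop_sl] == lab
        refined[crop_sl] |= piece
    if not refined.any():
        return refined
    labels, n = ndi.label(refined, structure=_structure(26, refined.ndim))
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts * voxel_vol >= min_volume_um3)
    keep = keep[keep > 0]
    if keep.size == 0:
        log.info("no component above the soma volume floor; returning empty mask")
        return np.zeros_like(refined)
    return np.isin(labels, keep)


def make_process_mask(
    cell_channel: np.ndarray,
    soma_mask: np.ndarray,
    voxel_size: tuple[float, ...],
    smooth_sigma_um: float = 0.0,
) -> np.ndarray:
    """Otsu mask of the cell channel with soma voxels removed.

    The somas are removed from the data first: the Otsu threshold is
    computed on the soma-excluded voxels only, so that bright soma mass
    cannot pull the threshold above the process intensity.  An optional
    Gaussian smoothing (off by default: it thickens thin tubes and biases
    the volume upward) is available for very noisy data.  Raises if
    nothing remains — there would be no process volume to normalise by.
    """
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if soma_mask.shape != cell_channel.shape:
        raise ValueError("soma mask shape must match the channel")
    chan = blob_enhance(cell_channel, smooth_sigma_um, voxel_size) \
        if smooth_sigma_um > 0 else np.asarray(cell_channel, dtype=float)
    remaining = chan[~soma_mask]
    thr, _ = otsu_threshold(remaining)
    mask = (chan > thr) & ~soma_mask
    if not mask.any():
        raise ValueError("no process voxels remain after soma removal")
    return mask


def segment_puncta(
    puncta_channel: np.ndarray,
    reference: np.ndarray,
    voxel_size: tuple[float, ...],
    min_voxels: int = 2,
    smooth_sigma_um: float = 0.15,
    connectivity: int = 26,
) -> np.ndarray:
    """Histogram-match the puncta channel to the reference, then Otsu.

    Components smaller than ``min_voxels`` are dropped as noise.  The
    small pre-threshold smoothing plays the same stabilising role as in
    :func:`make_process_mask`.
    """
    matched = match_histogram(puncta_channel, reference)
    if smooth_sigma_um > 0:
        matched = blob_enhance(matched, smooth_sigma_um, voxel_size)
    _, mask = otsu_threshold(matched)
    if min_voxels > 1 and mask.any():
        labels, _ = ndi.label(mask, structure=_structure(connectivity, mask.ndim))
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        mask[np.isin(labels, small)] = False
    return mask


def count_colocalized(
    process_mask: np.ndarray,
    puncta_mask: np.ndarray,
    voxel_size: tuple[float, ...],
    connectivity: int = 26,
    layer_label: str = "",
    group_label: str = "",
) -> ColocResult:
    """AND the masks and count 3D connected components.

    Each component of ``process_mask & puncta_mask`` counts as one
    putative punctum on a process; the density is this count divided by
    the process volume (voxel count × voxel volume, µm³).
    """
    if process_mask.shape != puncta_mask.shape:
        raise ValueError("mask shapes differ")
    volume = mask_volume(process_mask, voxel_size)
    if volume == 0:
        raise ValueError("process volume is zero")
    overlap = np.asarray(process_mask, bool) & np.asarray(puncta_mask, bool)
    _, n = ndi.label(overlap, structure=_structure(connectivity, overlap.ndim))
    return ColocResult(
        n_colocalized=int(n),
        process_volume=volume,
        density=float(n) / volume,
        layer_label=layer_label,
        group_label=group_label,
    )


def quantify_stack(
    stack: ImageStack3D,
    reference: np.ndarray,
    cell_channel: str = "cell",
    puncta_channel: str = "puncta",
    soma_sigma_um: float = 1.5,
    soma_min_volume_um3: float = 300.0,
    ac_iterations: int = 10,
    process_smooth_sigma_um: float = 0.0,
    puncta_smooth_sigma_um: float = 0.15,
    min_punctum_voxels: int = 2,
    connectivity: int = 26,
    layer_label: str = "",
    group_label: str = "",
) -> ColocResult:
    """Full pipeline on one stack: soma removal, puncta segmentation,
    AND + connected components, volume normalisation."""
    cell = stack.channel(cell_channel)
    somas = segment_somas(cell, stack.voxel_size, sigma_um=soma_sigma_um,
                          ac_iterations=ac_iterations,
                          min_volume_um3=soma_min_volume_um3)
    processes = make_process_mask(cell, somas, stack.voxel_size,
                                  smooth_sigma_um=process_smooth_sigma_um)
    puncta = segment_puncta(stack.channel(puncta_channel), reference,
                            stack.voxel_size, min_voxels=min_punctum_voxels,
                            smooth_sigma_um=puncta_smooth_sigma_um,
                            connectivity=connectivity)
    return count_colocalized(processes, puncta, stack.voxel_size,
                             connectivity=connectivity,
                             layer_label=layer_label, group_label=group_label)


def compare_coloc_groups(results_a, results_b) -> stats.TestResult:
    """Two-sided Mann–Whitney U on the two groups' densities.

    Returns the test result with group medians recorded in ``extra``.
    """
    if len(results_a) < 1 or len(results_b) < 1:
        raise ValueError("each group needs at least one result")
    dens_a = [r.density for r in results_a]
    dens_b = [r.density for r in results_b]
    res = stats.mann_whitney_u(dens_a, dens_b)
    res.extra = {**(res.extra or {}),
                 "median_a": float(np.median(dens_a)),
                 "median_b": float(np.median(dens_b))}
    return res
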