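"""Disk formats: channel-major multi-page TIFF for images, JSON + mask
TIFFs for ground truth, long-format CSV for sweeps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys_ppr import SweepSet
from .preproc import ImageStack3D
from .synthetic_data import GroundTruth

__all__ = [
    "write_stack", "read_stack",
    "write_ground_truth", "write_sweeps", "read_sweeps",
]


def write_stack(path, stack: ImageStack3D) -> None:
    """Write a multi-channel stack as a channel-major TIFF; channel names
    and voxel size go into the image description."""
    data = np.stack([stack.channels[c] for c in stack.channels], axis=0)
    desc = json.dumps({
        "channels": list(stack.channels),
        "voxel_size_um": list(stack.voxel_size),
    })
    tifffile.imwrite(path, data.astype(np.float32), description=desc)


def read_stack(path, channel_names=None, voxel_size=None) -> ImageStack3D:
    """Read a channel-major TIFF back into an :class:`ImageStack3D`.

    Metadata written by :func:`write_stack` is used when present;
    otherwise ``channel_names`` and ``voxel_size`` must be given.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    names = channel_names or meta.get("channels")
    vs = voxel_size or meta.get("voxel_size_um")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if vs is None:
        raise ValueError("voxel size not in file metadata; pass voxel_size=")
    if len(names) != data.shape[0]:
        raise ValueError("channel name count does not match first axis")
    return ImageStack3D(
        channels={n: data[i].astype(float) for i, n in enumerate(names)},
        voxel_size=tuple(float(v) for v in vs),
    )


def write_ground_truth(outdir, truth: GroundTruth, prefix: str = "truth") -> None:
    """Ground truth as JSON (scalars, labels, centers) plus mask TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {}
    for key in ("true_on_process_count", "true_process_volume", "true_labels", "true_amps"):
        val = getattr(truth, key)
        if val is not None:
            payload[key] = val if not isinstance(val, tuple) else list(val)
    for key in ("on_centers", "off_centers", "cell_centers",
                "true_cr_means", "true_elfn1_means"):
        val = getattr(truth, key)
        if val is not None:
            payload[key] = np.asarray(val).tolist()
    (outdir / f"{prefix}.json").write_text(json.dumps(payload, indent=1))
    for key in ("process_mask_true", "soma_mask_true"):
        mask = getattr(truth, key)
        if mask is not None:
            tifffile.imwrite(outdir / f"{prefix}_{key}.tif", mask.astype(np.uint8))


def write_sweeps(path, sweeps: SweepSet) -> None:
    sweeps.to_frame().to_csv(path, index=False)


def read_sweeps(path, stim_times, holding_potential: float = -70.0) -> SweepSet:
    return SweepSet.from_frame(pd.read_csv(path), stim_times, holding_potential)
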