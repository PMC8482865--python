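"""Ground-truthed synthetic inputs for the three quantification pipelines.

Three generators emulate the data each pipeline consumes:

* :func:`generate_coloc_stack` — a two-channel anisotropic confocal stack:
  tubular neurite processes plus brighter ellipsoidal somas in the cell
  channel, Gaussian-profile puncta on and off the processes in the puncta
  channel, with additive Gaussian noise over a detector baseline.
* :func:`generate_ish_image` — a multi-channel 2D section: labelled cell
  bodies, a transcript channel whose per-cell level follows a two-component
  (positive/negative) mixture, and a second transcript channel whose mean
  depends on genotype and class.
* :func:`generate_sweeps` — averagable voltage-clamp sweeps containing two
  stereotyped evoked inward currents at a fixed inter-stimulus interval,
  the second summating on the decay of the first.

Every generator records its ground truth (masks, counts, labels,
amplitudes) so downstream estimates can be scored against it, and is
bit-reproducible for a fixed seed.  A single integer seed fans out to
independent substreams for geometry, class assignment and noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .preproc import ImageStack3D

__all__ = [
    "PlacementError",
    "ColocSimParams",
    "IshSimParams",
    "SweepSimParams",
    "GroundTruth",
    "generate_coloc_stack",
    "generate_ish_image",
    "generate_sweeps",
    "sample_cr_intensities",
    "synaptic_transient",
]


class PlacementError(RuntimeError):
    """Requested objects cannot be placed in the given geometry."""


@dataclass
class GroundTruth:
    """Generator-side truth; consumed only by tests and benchmarks."""

    true_on_process_count: int | None = None
    true_process_volume: float | None = None
    on_centers: np.ndarray | None = None
    off_centers: np.ndarray | None = None
    process_mask_true: np.ndarray | None = None
    soma_mask_true: np.ndarray | None = None
    true_labels: list[str] | None = None
    cell_centers: np.ndarray | None = None
    cell_radius_px: float | None = None
    true_cr_means: np.ndarray | None = None
    true_elfn1_means: np.ndarray | None = None
    true_amps: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# 3D colocalization stack
# ---------------------------------------------------------------------------

@dataclass
class ColocSimParams:
    """Geometry and signal model for the two-channel 3D stack.

    Voxels are anisotropic (z coarser than x/y, as in confocal stacks);
    all object sizes are in micrometres and are converted per axis.
    ``snr`` is the ratio of object peak amplitude to noise sigma in each
    channel; ``numpy.inf`` gives noise-free images.
    """

    shape: tuple[int, int, int] = (64, 192, 192)
    voxel_size: tuple[float, float, float] = (0.297, 0.1154, 0.1154)
    n_processes: int = 5
    process_radius: float = 0.4
    n_somas: int = 1
    soma_radii: tuple[float, float, float] = (4.0, 5.0, 5.0)
    puncta_on_density: float = 0.5
    puncta_off_count: int = 60
    puncta_on_soma_count: int = 0
    puncta_radius: float = 0.25
    min_separation: float = 1.5
    snr: float = 20.0
    process_amp: float = 100.0
    soma_amp: float = 200.0
    puncta_amp: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("stack too small")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        for name in ("n_processes", "n_somas", "puncta_off_count", "puncta_on_soma_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.puncta_on_density < 0:
            raise ValueError("puncta_on_density must be >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def _random_walk_path(rng, shape, voxel_size, n_steps, step_um, wobble):
    """Random-walk centreline through the volume, reflected at the borders.
    Returns voxel index array (n, 3)."""
    extent = np.array(shape) * np.array(voxel_size)
    pos = rng.uniform(0.1, 0.9, size=3) * extent
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = np.empty((n_steps, 3))
    for i in range(n_steps):
        pts[i] = pos
        direction = direction + wobble * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + step_um * direction
        # reflect at volume boundary
        for ax in range(3):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                direction[ax] = -direction[ax]
            elif pos[ax] > extent[ax]:
                pos[ax] = 2 * extent[ax] - pos[ax]
                direction[ax] = -direction[ax]
    idx = np.round(pts / np.array(voxel_size)).astype(int)
    return np.clip(idx, 0, np.array(shape) - 1)


def _tube_mask(path_voxels: np.ndarray, shape, voxel_size, radius: float) -> np.ndarray:
    """Inflate a set of centreline voxels to a tube of physical radius via
    an anisotropy-aware Euclidean distance transform."""
    seed = np.zeros(shape, dtype=bool)
    seed[tuple(path_voxels.T)] = True
    dist = ndi.distance_transform_edt(~seed, sampling=voxel_size)
    return dist <= radius


def _ellipsoid_mask(shape, voxel_size, center_um, radii_um) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, v, c, r in zip(grids, voxel_size, center_um, radii_um):
        acc = acc + ((g * v - c) / r) ** 2
    return acc <= 1.0


def _pick_separated(rng, candidates_um: np.ndarray, n: int, min_sep: float,
                    what: str, avoid=()) -> np.ndarray:
    """Greedily pick n points (physical coords) >= min_sep apart from each
    other and from every point in ``avoid``."""
    if len(candidates_um) == 0 and n > 0:
        raise PlacementError(f"no eligible voxels to place {what}")
    order = rng.permutation(len(candidates_um))
    taken: list[np.ndarray] = [np.asarray(q) for q in avoid]
    chosen: list[np.ndarray] = []
    for i in order:
        p = candidates_um[i]
        if all(np.linalg.norm(p - q) >= min_sep for q in taken):
            taken.append(p)
            chosen.append(p)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise PlacementError(
            f"could only place {len(chosen)}/{n} {what} at separation {min_sep} µm"
        )
    return np.asarray(chosen).reshape(n, 3)


def _render_puncta(shape, voxel_size, centers_vox, amp, radius_um) -> np.ndarray:
    """Sum of Gaussian-profile puncta (sigma = radius, per-axis in voxels),
    each scaled to peak amplitude ``amp``."""
    img = np.zeros(shape, dtype=float)
    if len(centers_vox) == 0:
        return img
    img[tuple(np.asarray(centers_vox).T)] += 1.0
    sigma = tuple(radius_um / v for v in voxel_size)
    img = ndi.gaussian_filter(img, sigma=sigma, mode="constant")
    peak = 1.0
    for s in sigma:
        peak /= np.sqrt(2 * np.pi) * s
    return img * (amp / peak)


def generate_coloc_stack(params: ColocSimParams) -> tuple[ImageStack3D, GroundTruth]:
    """Render a two-channel stack with known puncta-on-process truth.

    Channel ``"cell"`` holds processes and (brighter) somas; channel
    ``"puncta"`` holds the puncta.  Exactly ``round(density * volume)``
    puncta are centred on process voxels that are outside every soma —
    the same definition of "on a process" the measurement pipeline uses
    after soma removal — plus ``puncta_off_count`` away from the
    processes and, optionally, ``puncta_on_soma_count`` on soma voxels.
    """
    p = params
    ss = np.random.SeedSequence(p.seed)
    rng_geom, rng_pl, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    shape, vs = p.shape, p.voxel_size
    extent = np.array(shape) * np.array(vs)
    voxel_vol = float(np.prod(vs))

    # neurite tubes
    process_mask = np.zeros(shape, dtype=bool)
    if p.n_processes > 0:
        step = 2.0 * min(vs)
        n_steps = int(1.2 * extent.max() / step)
        paths = [
            _random_walk_path(rng_geom, shape, vs, n_steps, step, wobble=0.15)
            for _ in range(p.n_processes)
        ]
        process_mask = _tube_mask(np.vstack(paths), shape, vs, p.process_radius)

    # somas: ellipsoids placed with a margin so they fit, brighter than tubes
    soma_mask = np.zeros(shape, dtype=bool)
    radii = np.asarray(p.soma_radii, dtype=float)
    if p.n_somas > 0:
        if np.any(2 * radii >= extent):
            raise PlacementError("soma does not fit in the stack")
        centers = []
        for _ in range(200 * p.n_somas):
            c = rng_geom.uniform(radii, extent - radii)
            if all(np.linalg.norm((c - o) / radii) >= 2.6 for o in centers):
                centers.append(c)
                if len(centers) == p.n_somas:
                    break
        if len(centers) < p.n_somas:
            raise PlacementError("cannot place requested somas without overlap")
        for c in centers:
            soma_mask |= _ellipsoid_mask(shape, vs, c, radii)

    on_region = process_mask & ~soma_mask
    true_volume = float(np.count_nonzero(on_region)) * voxel_vol
    n_on = int(round(p.puncta_on_density * true_volume))

    coords_um = lambda mask: np.argwhere(mask) * np.array(vs)  # noqa: E731
    on_centers = (
        _pick_separated(rng_pl, coords_um(on_region), n_on, p.min_separation, "on-process puncta")
        if n_on else np.empty((0, 3))
    )
    if p.puncta_off_count:
        # keep off-puncta clear of the tubes so they cannot touch the mask
        dist = ndi.distance_transform_edt(~process_mask, sampling=vs) if process_mask.any() \
            else np.full(shape, np.inf)
        off_region = (dist > p.process_radius + 2 * p.puncta_radius) & ~soma_mask
        off_centers = _pick_separated(
            rng_pl, coords_um(off_region), p.puncta_off_count, p.min_separation,
            "off-process puncta", avoid=on_centers,
        )
    else:
        off_centers = np.empty((0, 3))
    if p.puncta_on_soma_count:
        # keep on-soma puncta wholly inside the soma: a punctum straddling
        # the boundary would be neither clearly on nor off the soma
        depth = ndi.distance_transform_edt(soma_mask, sampling=vs)
        soma_only = (depth > 2 * p.puncta_radius) & ~process_mask
        soma_centers = _pick_separated(
            rng_pl, coords_um(soma_only), p.puncta_on_soma_count, p.min_separation,
            "on-soma puncta", avoid=np.vstack([on_centers, off_centers]) if len(on_centers) or len(off_centers) else (),
        )
        off_centers = np.vstack([off_centers, soma_centers])

    all_centers = np.vstack([on_centers, off_centers])
    centers_vox = np.round(all_centers / np.array(vs)).astype(int) if len(all_centers) else all_centers

    ch_cell = p.process_amp * process_mask.astype(float)
    ch_cell[soma_mask] = p.soma_amp
    ch_puncta = _render_puncta(shape, vs, centers_vox, p.puncta_amp, p.puncta_radius)

    if np.isfinite(p.snr):
        sigma1 = p.process_amp / p.snr
        sigma2 = p.puncta_amp / p.snr
        # detector baseline keeps the clipped-noise floor out of the histogram
        ch_cell = ch_cell + 5 * sigma1 + rng_noise.normal(0, sigma1, shape)
        ch_puncta = ch_puncta + 5 * sigma2 + rng_noise.normal(0, sigma2, shape)
    ch_cell = np.clip(ch_cell, 0, None)
    ch_puncta = np.clip(ch_puncta, 0, None)

    stack = ImageStack3D(
        channels={"cell": ch_cell, "puncta": ch_puncta},
        voxel_size=vs,
        meta={"seed": p.seed, "snr": p.snr},
    )
    truth = GroundTruth(
        true_on_process_count=int(len(on_centers)),
        true_process_volume=true_volume,
        on_centers=np.asarray(on_centers),
        off_centers=np.asarray(off_centers),
        process_mask_true=process_mask,
        soma_mask_true=soma_mask,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# 2D multiplexed ISH section
# ---------------------------------------------------------------------------

@dataclass
class IshSimParams:
    """Population structure for a synthetic multiplexed ISH section.

    Per-cell CR intensity follows a two-component mixture with mixing
    weight ``cr_pos_fraction`` (≈80 % of VIP cells are CR-positive in
    cortex, which is also the classifier's default prior).  The Elfn1
    channel mean depends on ``(genotype, cr_class)``; the default table
    encodes a conditional-knockout that halves Elfn1 in CR-negative
    (multipolar) cells.
    """

    image_shape: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.5
    n_cells: int = 12
    cell_radius_um: float = 4.0
    cr_pos_fraction: float = 0.8
    cr_intensity_means: tuple[float, float] = (30.0, 120.0)
    cr_intensity_sd: float = 8.0
    elfn1_means_by_group: dict = field(default_factory=lambda: {
        ("control", "cr_pos"): 40.0,
        ("control", "cr_neg"): 80.0,
        ("cko", "cr_pos"): 40.0,
        ("cko", "cr_neg"): 40.0,
    })
    elfn1_sd: float = 8.0
    genotype: str = "control"
    cell_amp: float = 120.0
    noise_sigma: float = 4.0
    layer_boundaries: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cr_pos_fraction <= 1.0:
            raise ValueError("cr_pos_fraction must be in [0, 1]")
        low, high = self.cr_intensity_means
        if not high > low:
            raise ValueError("high CR mean must exceed low CR mean")
        if list(self.layer_boundaries) != sorted(set(self.layer_boundaries)):
            raise ValueError("layer boundaries must be strictly increasing")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def sample_cr_intensities(params: IshSimParams) -> tuple[np.ndarray, list[str]]:
    """Draw per-cell CR mean intensities from the two-component mixture.

    Returns ``(means, labels)`` where labels are ``"cr_pos"``/``"cr_neg"``.
    This is the population model underlying :func:`generate_ish_image`,
    exposed separately so classifier behaviour can be studied on large
    populations without rendering pixels.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_class, rng_int = (np.random.default_rng(s) for s in ss.spawn(2))
    low, high = params.cr_intensity_means
    pos = rng_class.random(params.n_cells) < params.cr_pos_fraction
    means = np.where(pos, high, low) + rng_int.normal(0, params.cr_intensity_sd, params.n_cells)
    labels = ["cr_pos" if f else "cr_neg" for f in pos]
    return np.clip(means, 0, None), labels


def generate_ish_image(params: IshSimParams) -> tuple[ImageStack3D, GroundTruth]:
    """Render a four-channel 2D section with known per-cell truth.

    Channels: ``"cell"`` (cytosolic label, uniform disks), ``"cr"`` and
    ``"elfn1"`` (transcript signal constant within each cell at that
    cell's true mean), ``"dapi"`` (nuclei).  Cells are non-overlapping
    disks placed with a margin from the border.
    """
    p = params
    # substreams 0-1 are consumed by sample_cr_intensities (same seed)
    ss = np.random.SeedSequence(p.seed)
    _, _, s_elfn1, s_place, s_noise = ss.spawn(5)
    rng_elfn1 = np.random.default_rng(s_elfn1)
    rng_place = np.random.default_rng(s_place)
    rng_noise = np.random.default_rng(s_noise)
    h, w = p.image_shape
    r_px = p.cell_radius_um / p.pixel_size_um
    margin = r_px + 2

    cr_means, labels = sample_cr_intensities(p)
    elfn1_means = np.clip(
        np.array([p.elfn1_means_by_group[(p.genotype, lab)] for lab in labels])
        + rng_elfn1.normal(0, p.elfn1_sd, p.n_cells),
        0, None,
    )

    centers: list[np.ndarray] = []
    max_tries = 400 * max(1, p.n_cells)
    for _ in range(max_tries):
        c = rng_place.uniform([margin, margin], [h - margin, w - margin])
        if all(np.linalg.norm(c - o) >= 2.4 * r_px for o in centers):
            centers.append(c)
            if len(centers) == p.n_cells:
                break
    if len(centers) < p.n_cells:
        raise PlacementError(f"cannot place {p.n_cells} non-overlapping cells")
    centers = np.asarray(centers).reshape(p.n_cells, 2)

    yy, xx = np.mgrid[0:h, 0:w]
    ch_cell = np.zeros((h, w))
    ch_cr = np.zeros((h, w))
    ch_elfn1 = np.zeros((h, w))
    ch_dapi = np.zeros((h, w))
    for i, c in enumerate(centers):
        d2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
        inside = d2 <= r_px**2
        ch_cell[inside] = p.cell_amp
        ch_cr[inside] = cr_means[i]
        ch_elfn1[inside] = elfn1_means[i]
        ch_dapi[d2 <= (0.6 * r_px) ** 2] = 100.0

    baseline = 3 * p.noise_sigma
    chans = {}
    for name, img in (("cell", ch_cell), ("cr", ch_cr), ("elfn1", ch_elfn1), ("dapi", ch_dapi)):
        noisy = img + baseline + rng_noise.normal(0, p.noise_sigma, (h, w)) \
            if p.noise_sigma > 0 else img
        chans[name] = np.clip(noisy, 0, None)

    stack = ImageStack3D(
        channels=chans,
        voxel_size=(p.pixel_size_um, p.pixel_size_um),
        meta={"seed": p.seed, "genotype": p.genotype,
              "layer_boundaries": list(p.layer_boundaries)},
    )
    truth = GroundTruth(
        true_labels=labels,
        cell_centers=centers,
        cell_radius_px=r_px,
        true_cr_means=cr_means,
        true_elfn1_means=elfn1_means,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Evoked-current sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepSimParams:
    """Paired-stimulus voltage-clamp sweep model.

    Two stimuli at 50 Hz (20 ms inter-stimulus interval) evoke inward
    (negative) currents with difference-of-exponentials kinetics; twelve
    sweeps per recording is the standard 2-minute acquisition.
    """

    n_sweeps: int = 12
    sampling_rate: float = 10_000.0
    duration: float = 0.25
    stim_times: tuple[float, float] = (0.1, 0.12)
    amp1: float = -100.0
    amp2: float = -120.0
    tau_rise: float = 0.0005
    tau_decay: float = 0.005
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        t1, t2 = self.stim_times
        if not t2 > t1:
            raise ValueError("stim_times must be strictly increasing")
        if self.n_sweeps < 1:
            raise ValueError("need at least one sweep")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if t2 + 0.02 > self.duration:
            raise ValueError("duration too short for the second response")


def synaptic_transient(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials waveform, normalised to unit peak, zero
    for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return out / peak


def generate_sweeps(params: SweepSimParams):
    """Simulate evoked-current sweeps with known amplitude pair.

    The second transient is added on top of the decaying first, so its
    true amplitude is defined relative to the extrapolated decay — the
    same convention the measurement uses for its summation correction.
    Returns ``(SweepSet, GroundTruth)``.
    """
    from .ephys_ppr import SweepSet  # local import to avoid a cycle

    p = params
    isi = p.stim_times[1] - p.stim_times[0]
    if p.tau_decay >= 10 * isi:
        warnings.warn(
            "decay constant is >= 10x the inter-stimulus interval; "
            "summation makes the second amplitude ill-defined",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    n = int(round(p.duration * p.sampling_rate))
    t = np.arange(n) / p.sampling_rate
    clean = (
        p.amp1 * synaptic_transient(t - p.stim_times[0], p.tau_rise, p.tau_decay)
        + p.amp2 * synaptic_transient(t - p.stim_times[1], p.tau_rise, p.tau_decay)
    )
    noise = rng.normal(0, p.noise_sigma, (p.n_sweeps, n)) if p.noise_sigma > 0 \
        else np.zeros((p.n_sweeps, n))
    sweeps = SweepSet(
        time=t,
        sweeps=clean[None, :] + noise,
        sampling_rate=p.sampling_rate,
        stim_times=p.stim_times,
    )
    truth = GroundTruth(true_amps=(p.amp1, p.amp2))
    return sweeps, truth
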