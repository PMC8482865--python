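# Methods

`vipquant` implements three quantification pipelines used in studies of
cortical VIP interneurons — 3D puncta-on-process colocalization,
per-cell multiplexed ISH intensity quantification, and paired-pulse
ratio (PPR) analysis of evoked synaptic currents — together with the
group statistics that connect them and a synthetic-data module that
generates ground-truthed inputs for all three. This note records the
models, the parameters that matter, and the design choices made where
the procedures were genuinely open.

## 3D colocalization (`coloc3d`)

The statistic is the density of putative presynaptic mGluR7 puncta on
tdTomato-labelled VIP neurite processes: puncta are a terminal-level
proxy for trans-synaptic Elfn1 function, and somatic signal must not
count.

Pipeline on a two-channel stack (cell label, puncta label):

1. **Soma segmentation** — Gaussian blob enhancement at a soma scale
   (`soma_sigma_um`, default 1.5 µm) suppresses the thin processes;
   Otsu thresholding picks the bright bodies; morphological Chan–Vese
   active contours (default 10 iterations, smoothing 1) sharpen each
   component's boundary on the raw channel; components below a volume
   floor (`soma_min_volume_um3`, default 300 µm³ — well above any
   process fragment, below any realistic soma) are discarded.
   Active-contour refinement runs per component on a padded crop: a
   front moves at most one voxel per iteration, so a margin of
   `iterations + 3` voxels loses nothing and makes the 3D evolution
   tractable.
2. **Process mask** — Otsu threshold of the cell channel computed on
   the *soma-excluded* voxels, with soma voxels then removed from the
   mask. Excluding the somas from the histogram is essential: a bright
   soma occupying a few percent of the stack otherwise pulls the Otsu
   split between soma and process intensity and the processes are lost.
   No pre-smoothing by default — smoothing thickens tubes a fraction of
   a micrometre wide and inflates the reference volume by tens of
   percent.
3. **Puncta mask** — the puncta channel is histogram-matched to a
   reference image (monotone intensity remapping; removes
   session-to-session drift; the reference is an explicit input), then
   lightly smoothed (`puncta_smooth_sigma_um`, default 0.15 µm) and
   Otsu-thresholded; components smaller than `min_punctum_voxels`
   (default 2) are dropped. The small matched filter is a deliberate
   addition: puncta occupy ~0.1 % of the voxels, and raw Otsu on such a
   histogram locks onto the noise mode (the threshold falls inside the
   background and the mask floods). With the filter the pipeline
   recovers ~98 % of rendered puncta at snr 10.
4. **Counting** — the process and puncta masks are combined with a
   logical AND and 3D connected components (26-neighbourhood by
   default, configurable) are counted; the count is divided by the
   process volume (voxel count x voxel volume, µm³). Two puncta merged
   by the AND mask count once, by construction.

Group comparison of densities uses the two-sided Mann–Whitney U test.

## ISH quantification (`ish_quant`)

Per-cell transcript levels in 2D sections with a cytosolic cell label
(VIP-tdTomato), two transcript channels (CR/Calb2 and Elfn1) and a
nuclear channel used only for drawing region/layer ROIs.

1. **Cell segmentation** — difference-of-Gaussians enhancement
   (defaults 1 and 4 px), Otsu for an initial mask, per-component
   active-contour refinement on a padded crop of the raw channel,
   then an area filter (20–400 µm²) for plausible cell bodies.
2. **Intensity measurement** — each transcript channel is cleaned by
   disk-based background subtraction (white top-hat, default radius
   10 px) and averaged over each cell's own pixels. Note the top-hat's
   background estimate under noise sits ~3 sigma below the local mean
   (an erosion is a local minimum), so measured means carry a small
   common positive offset; ratios between groups are compressed toward
   1 accordingly, which is visible in the effect-recovery tests
   (measured ~1.8x for a true 2x).
3. **Region/layer assignment** — each cell is labelled by the first
   layer polygon (ordered pia to white matter) that covers its
   centroid; boundary ties therefore resolve to the pia-proximal layer;
   cells outside all polygons are "unassigned".
4. **CR classification** — prior-matched thresholding: within one
   image, the threshold is the empirical `1 - prior` quantile (linear
   interpolation) of per-cell CR means, default prior 0.8 (the
   literature fraction of CR-positive VIP cells), and a cell is
   positive iff its mean exceeds it. When interpolation or ties leave
   the positive fraction short of the prior, the k-th largest mean
   (k = ceil(prior·n)) becomes the effective cut with ties included, so
   the achieved fraction is the closest attainable from above. The
   threshold is computed per image by default; pooling across images is
   a flag.
5. **Group comparison** — two-sided Mann–Whitney U on per-image mean
   intensities (the section is the statistical unit by default;
   per-cell mode available), optionally restricted by CR class and
   layer.

## PPR analysis (`ephys_ppr`)

Recordings are sets of voltage-clamp sweeps (12 per recording is the
standard 2-minute acquisition at Vh = −70 mV) with two stimuli at 50 Hz
(20 ms inter-stimulus interval). The sweeps are averaged pointwise and
both EPSC amplitudes measured on the mean trace:

- Baseline: mean over 50 ms before stimulus 1. The first millisecond
  after each stimulus is blanked as artifact; the peak search window is
  1–15 ms post-stimulus.
- A light boxcar smoothing (0.3 ms) suppresses the upward bias of
  picking an extremum in noise. It attenuates both responses by an
  identical factor (a moving average of an exponential is a scaled
  exponential), so the ratio is unaffected.
- **Summation correction** (default on): a mono-exponential is fitted
  (log-linear least squares) to the first response's decay from 6 ms
  after stimulus 1 to the second stimulus, and subtracted from the
  trace before the second extremum is taken. The 6 ms start leaves the
  rise component at exp(−12) of its peak, so the fit is exact on
  noise-free difference-of-exponentials responses and the identity
  ratio is recovered to ~1e-7. A flag disables the correction
  (uncorrected peak-minus-baseline is also provided since published
  conventions vary).
- PPR = amp2/amp1 with amplitudes as positive magnitudes; release
  probability is classed low (PPR > 1, facilitating), high (PPR < 1,
  depressing) or moderate (|PPR − 1| <= 0.1, configurable band).
- QC gate: a recording fails iff access resistance > 40 MΩ or
  whole-cell capacitance < 4 pF.

Index windows are selected with half-sample tolerance so that the same
nominal offset after either stimulus selects congruent samples; naive
floating-point comparisons otherwise shift one window by one sample and
bias the ratio by ~1.5 %.

## Statistics (`stats`)

Implemented from first principles so each can be validated against an
independent oracle (permutation enumeration, hand computation, scipy):

- **Mann–Whitney U** with midranks. Exact p when `n_a*n_b <= 400` and
  no ties, from the standard counting recurrence for the null
  distribution of U; otherwise the normal approximation with tie and
  continuity correction. Two-sided p is the doubled smaller tail,
  capped at 1. Identical samples give p = 1.
- **t tests**: two-tailed paired Student's t, and Welch's unequal-
  variance t with Welch–Satterthwaite df for unpaired comparisons.
  Zero-variance degeneracies resolve to p = 1 when means agree and
  raise otherwise (never NaN).
- **One-way ANOVA** with Bonferroni-corrected pairwise t tests
  (raw p multiplied by the number of pairs, capped at 1).
- **Candidate filter** for differential-expression tables:
  |log2ratio| >= 0.5 and p <= 0.01, both bounds inclusive; the p-value
  column is selectable because published tables carry both raw and
  adjusted p.

## Synthetic data (`synthetic_data`)

The generators produce the statistical structure each pipeline assumes,
with ground truth recorded for scoring. One integer seed fans out into
independent substreams per stage, and all generators are
bit-reproducible.

- **Colocalization stacks** (default 64 x 192 x 192 voxels at the
  anisotropic voxel size 0.297 x 0.1154 x 0.1154 µm): neurite processes
  are random-walk tubes (radius 0.4 µm) rendered with an
  anisotropy-aware distance transform; somas are ellipsoids (radii
  4 x 5 x 5 µm, ~420 µm³) brighter than the processes; puncta are
  Gaussian spots (sigma 0.25 µm) with exactly `round(density x volume)`
  centred on process-not-soma voxels — the same "on process" definition
  the pipeline measures after soma removal — plus a fixed number off
  the processes (and optionally wholly inside somas, for the
  soma-removal property). Noise is Gaussian over a detector baseline of
  5 sigma (so clipping at zero does not distort the histogram), with
  snr = peak amplitude / sigma. Puncta centres keep a minimum mutual
  separation of 1.5 µm across all classes: at the rendered spot size
  two closer puncta can merge above threshold even without noise, and
  the generator's contract is that noise-free objects are individually
  resolvable. Somas are placed with surfaces more than one soma-blur
  scale apart for the same reason.
- **ISH sections** (default 192 x 192 px at 0.5 µm/px, 12 cells of
  radius 4 µm): non-overlapping disks; each cell's CR mean is drawn
  from a two-component mixture (80 % positive at 120 a.u., 20 %
  negative at 30 a.u., sd 8) and painted uniformly inside the cell; the
  Elfn1 mean is set by (genotype, CR class) — the default table gives
  CR-negative (multipolar) cells high Elfn1 in controls and halves it
  in the conditional knockout, the effect the study design targets.
  Gaussian pixel noise (sigma 4) over a small baseline.
  `sample_cr_intensities` exposes the population model without
  rendering pixels, for classifier studies at large n.
- **Sweeps** (default 12 sweeps, 10 kHz, 250 ms): each sweep is the sum
  of two difference-of-exponentials transients (rise 0.5 ms, decay
  5 ms) at 100 and 120 ms, scaled to the injected amplitudes (inward =
  negative), plus white noise (default 5 pA). The second transient
  rides on the decay of the first, so the injected second amplitude is
  defined relative to the extrapolated decay — matching the
  measurement's summation-correction convention. A decay constant
  >= 10x the inter-stimulus interval triggers a warning (the second
  amplitude becomes ill-defined under such summation).

### What the generators do not emulate

No point-spread function or optical sectioning, no tissue
autofluorescence or structured background, no cell-to-cell morphological
variability (cells are disks, somas ellipsoids), no spot-level
transcript granularity in the ISH channels, no stimulus artifacts or
series-resistance dynamics in the sweeps. Passing the end-to-end tests
therefore demonstrates that the pipelines measure what they claim on
data with the assumed structure — not that segmentation would survive
every pathology of real tissue.

## Problem sizes in the validation suite

The validation suite runs the colocalization grid at 128³ voxels over
three true densities (0.2, 0.45, 0.75 puncta/µm³ — the top of the range
is set by what 1.5 µm-separated puncta can pack onto the rendered
tubes) and three snr levels (5, 10, 20); the soma-removal property on
ten 48 x 128 x 128 stacks; the ISH effect recovery on 50 independent
two-arm cohorts of 18 sections each; Welch's type-I error on 10,000
null simulations; and exact Mann–Whitney against full enumeration for
all size pairs up to 7 per side.

## Known limitations

- Otsu thresholding needs a usable bimodal histogram; at snr well below
  10 the process volume estimate degrades sharply (visible at snr 5 in
  the grid test), which mirrors the method's real-data requirements.
- Morphological background subtraction under noise leaves a small
  common positive offset in per-cell means (erosion tracks the noise
  floor), compressing between-group ratios toward 1.
- The prior-matched CR classifier fixes the positive *fraction*; it is
  only as accurate as the separation of the two intensity modes, and is
  undefined when all cells have identical means.
- The PPR summation correction assumes a mono-exponential decay between
  the pulses; strongly non-exponential decays would bias amp2.
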