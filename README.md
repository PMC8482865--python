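# vipquant

Quantification pipelines for studies of cortical VIP interneurons and
their synapses, for researchers who need the custom measurements such
studies rely on as tested, scriptable code rather than one-off analysis
scripts:

- **3D puncta-on-process colocalization** (`vipquant.coloc3d`): count
  presynaptic mGluR7 immunopuncta on fluorescently labelled neurite
  processes in anisotropic confocal stacks, after removing cell somas,
  normalised by process volume (puncta/µm³). Somas are segmented by
  blob enhancement → Otsu thresholding → active contours and removed;
  puncta are segmented on a histogram-matched channel; the masks are
  combined with a logical AND and 3D connected components are counted.
- **Per-cell ISH quantification** (`vipquant.ish_quant`): segment cell
  bodies in 2D multiplexed in situ hybridisation sections
  (difference-of-Gaussians → Otsu → active contours), measure per-cell
  transcript intensities after disk-based background subtraction,
  assign cells to cortical layers, and classify cells as CR⁺ by
  prior-matched thresholding — the per-image intensity threshold is set
  so that ~80 % of VIP cells (the literature prior) come out positive.
- **Paired-pulse ratio** (`vipquant.ephys_ppr`): average evoked-current
  sweeps, measure both EPSC amplitudes (with mono-exponential
  summation correction of the second), and compute PPR = amp₂/amp₁.
  PPR > 1 (facilitation) indicates low presynaptic release
  probability, PPR < 1 high; recordings failing the quality gate
  (access resistance > 40 MΩ or capacitance < 4 pF) are excluded.
- **Statistics** (`vipquant.stats`): Mann–Whitney U (exact p by null
  enumeration for small samples), paired and Welch t tests, one-way
  ANOVA with Bonferroni post hoc, and the candidate-gene filter
  (|log2ratio| ≥ 0.5, p ≤ 0.01) for differential-expression tables.
- **Synthetic data** (`vipquant.synthetic_data`): ground-truthed
  generators for all three data types — tubes + somas + puncta stacks,
  two-component CR mixtures with genotype-dependent Elfn1 means, and
  paired evoked-current sweeps — so every pipeline is testable
  end-to-end without any imaging data.

## Worked example

```python
from vipquant.synthetic_data import ColocSimParams, generate_coloc_stack
from vipquant.coloc3d import quantify_stack

stack, truth = generate_coloc_stack(ColocSimParams(seed=42))
reference, _ = generate_coloc_stack(ColocSimParams(seed=7))
result = quantify_stack(stack, reference.channel("puncta"))
print(result.to_dict())
print(truth.true_on_process_count, truth.true_process_volume)
```

prints

```
{'n_colocalized': 36, 'process_volume_um3': 73.5864312546,
 'density_per_um3': 0.4892206264962684, 'layer': '', 'group': ''}
36 72.73210880628
```

The pipeline found 36 colocalized puncta on 73.6 µm³ of segmented
process — the generator placed exactly 36 puncta on 72.7 µm³ of true
process, so the density (0.489/µm³ measured vs 0.495/µm³ true) is
recovered to ~1 %. The same stack run through the command line:

```sh
vipquant simulate coloc3d --out sim --seed 42
vipquant coloc3d --stack sim/stack.tif --reference ref/stack.tif --out result.json
```

Electrophysiology, equally brief:

```python
from vipquant.synthetic_data import SweepSimParams, generate_sweeps
from vipquant.ephys_ppr import ppr_from_sweeps

sweeps, _ = generate_sweeps(SweepSimParams(amp1=-95.0, amp2=-138.0,
                                           noise_sigma=4.0, seed=42))
print(ppr_from_sweeps(sweeps))
```

```
PPRResult(amp1=95.8184748402286, amp2=138.272068011142,
          ppr=1.443062710418864, release_class='low')
```

The injected amplitude ratio 138/95 = 1.453 is measured as 1.443 from
twelve noisy sweeps, and the synapse is classed as facilitating (low
release probability).

Batch processing over a manifest CSV (`path,reference,group,layer`)
with `vipquant batch --manifest manifest.csv --out results/` writes a
per-stack density table and the two-sided Mann–Whitney comparison of
the groups. All tunable parameters (segmentation scales, iteration
counts, windows, priors) live in one validated YAML config; see
`vipquant.config.RunConfig`.

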