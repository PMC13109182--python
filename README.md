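# quando

Per-cell quantification of where DNA-damage foci sit relative to chromatin
compaction, using only a DNA counterstain. Given dual-color confocal images
— channel 1 a damage/protein marker (e.g. γ-H2AX), channel 2 a DNA
counterstain (e.g. DAPI) — the package computes, for every nucleus:

1. **DNA density** — the counterstain intensity normalized to its in-nucleus
   maximum, averaged over the damage regions (high = damage in compact
   chromatin, low = damage in open chromatin), and
2. **Colocalization fraction f₁/f₂** — image cross-correlation spectroscopy
   (ICCS): the ratio of the cross-correlation amplitude to the
   autocorrelation amplitude, ranging from 1 (complete colocalization)
   through 0 (independence) to −1 (repulsion). No object segmentation of
   the marker channel is required.

A synthetic-scene simulator with tunable ground truth (heterochromatin
blobs, damage foci, placement probability `p_het`, PSF blur, Poisson noise)
makes the whole pipeline testable without external data.

## Modules

| module               | contents |
|----------------------|----------|
| `quando.preprocess`  | isodata thresholding, nucleus count masks, rolling-ball background subtraction, damage masks, focus counting |
| `quando.density`     | per-nucleus intensity normalization and damage-ROI DNA density |
| `quando.iccs`        | masked spatial auto/cross-correlation, Gaussian amplitude fits with zero-lag handling, f₁/f₂, iterative per-cell extraction |
| `quando.synthetic`   | ground-truth nucleus and field simulator |
| `quando.pipeline`    | batch runner, YAML config, CSV outputs, group summaries |
| `quando.validation`  | simulate-and-analyze batches for validation studies |

## CLI

```bash
# simulate a synthetic field (TIFF channels + ground-truth CSV)
quando simulate --out sim/ --n-cells 10 --p-het 1.0 --seed 7

# run the analysis (per-cell results.csv + summary.csv)
quando run --ch1 sim/ch1_damage.tif --ch2 sim/ch2_dna.tif \
    --out analysis/ --foci-threshold 100 --min-area 2000

# group summary of a results table
quando summarize --results analysis/results.csv --group-by image_id
```

`quando run` also accepts `--config cfg.yaml` (see `quando.pipeline.RunConfig`
for all keys: rolling-ball radius, damage threshold, segmentation filters,
correlation window, fit constants, QC bounds). The damage threshold is a
per-experiment constant chosen by the user and held fixed across images of
the same experiment.

## Library use

```python
from quando import RunConfig, analyze_pair, SceneParams, simulate_field

ch1, ch2, truth = simulate_field(10, params=SceneParams(p_het=1.0), seed=0)
table = analyze_pair(ch1, ch2, RunConfig(foci_threshold=100, min_area_px=2000))
print(table[["cell_id", "n_foci", "dna_density", "f1", "valid"]])
```

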