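# wspdrop

Droplet deposition analysis on scanned water-sensitive paper (WSP).

WSP cards stain dark where spray droplets land. `wspdrop` segments those
stains from 8-bit grayscale scans with three interchangeable methods,
repairs bright glare holes inside stains by morphological closing, and
reports the standard deposition metrics:

* **coverage** — stained fraction of the card, in percent;
* **droplet count / density** — connected stains per cm² of card;
* **PA group** — sparse / medium / dense classification by total droplet
  pixel area (sparse ≤ 12,000 < medium ≤ 40,000 < dense < 90,000 px).

Segmentation methods:

| method | threshold |
| --- | --- |
| `fixed` | constant gray level 153 (normalized 0.60 on [0, 255]) |
| `otsu` | exhaustive search maximizing between-class variance σ²(k) |
| `genetic-otsu` | seeded genetic algorithm over the 8-bit threshold space with σ²(k) as fitness, polished by a final ±1 hill climb |

Droplets are the **dark** class: a pixel is droplet foreground when its
gray value is strictly below the threshold. Mask PNGs use droplet = 255.

A synthetic-scan generator (`wspdrop.synthetic`) renders WSP-like images —
light paper, dark elliptical stains with log-normal radii, optional glare
holes, Gaussian noise — with exact, alias-free ground truth, so the whole
pipeline is benchmarkable without any field data.

## CLI

```bash
# generate a seeded synthetic panel with ground truth
wspdrop simulate --out sim/ --seed 7 --n 10 --group sparse

# analyze scans (files or directories) with one or more methods
wspdrop analyze sim/ -m fixed -m otsu -m genetic-otsu --seed 7 --out results/

# benchmark methods against a reference CSV
wspdrop evaluate sim/ --reference reference.csv -m otsu --out eval/
```

Every run writes a `manifest.json` with all parameters so it can be
reproduced exactly. Stochastic paths (`genetic-otsu`, `simulate`) require
an explicit `--seed`; there is no wall-clock fallback. Exit codes:
0 success, 1 usage error, 2 data error.

The reference CSV for `evaluate` has columns
`image_id,true_coverage_pct,true_density,pa_group`, where `image_id`
matches the scan file stem.

## Library

```python
from wspdrop import (
    GAConfig, SyntheticSpec, analyze_image, generate_wsp,
)

img, truth = generate_wsp(SyntheticSpec(seed=1, n_droplets=15, noise_sigma=5.0))
report = analyze_image(img, "genetic_otsu", ga_config=GAConfig(seed=1))
print(report.coverage_pct, report.droplet_count, report.density_per_cm2)
```

## Notes on conventions

* RGB scans default to the **red** channel: WSP is yellow with blue
  stains, so red is bright on paper and dark on stains. Use `--channel`
  to override.
* Density is reported as droplets per cm² (a dimensionally meaningful
  unit), alongside the raw count.
* Coverage is computed after hole closing and size filtering
  (`--min-area`, default 2 px) on the repaired mask.
* Missing DPI metadata falls back to 96 DPI with a logged warning.
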