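# phenokit

Classical image-analysis pipelines for plant phenotyping: measure seeds,
tomatoes, wheat ears and heads, maize kernel rows, canopies, and flag-leaf
angles from single photographs, with reference-object scale calibration and
a synthetic-scene generator that provides exact ground truth for validating
every stage.

It is written for plant scientists and breeders who photograph samples with
a phone or fixed camera against a plain background — seeds on a black tray
with a coin for scale, a wheat ear between black sheets, a field plot
marked with a white rectangle — and want counts, sizes, shapes, and angles
without training or deploying a neural network. Detections can also come
from any external detector (point/box CSVs) through a small backend
contract, so learned models slot in front of the same measurement code.

## What it computes

| Pipeline | Traits |
| --- | --- |
| `seed` | count, length, width, perimeter, area, aspect ratio (px and mm via coin) |
| `tomato` | count, width, diameter, perimeter, area (wrapped-hue HSV segmentation, coin check) |
| `spikelet` | spikelet count, per-spikelet angle to the rachis tangent, ear-axis fit, skeleton |
| `canopy` | area, length, width, compactness, green ratio |
| `corn` | visible kernel count, row count, kernels per row (PCA + 1-D K-means) |
| `leaf_angle` | flag-leaf to stem angle from keypoints A/B/C(+L) |
| `wheat_head` | head count, head length/width, density (heads/m²), optional yield |

The core quantitative conventions: threshold `t* = argmax_t ω₀(t)ω₁(t)(μ₀(t)−μ₁(t))²`
on the 8-bit luminance histogram; compactness `4πA/P²`; length/width from
the minimum-area rotated rectangle; scale `mm/px = d_coin / 2r`; touching
objects resolved by convex-hull solidity gating plus marker-controlled
watershed of the Euclidean distance transform with a neck-depth validity
test; spikelet axes by seeded RANSAC with total-least-squares refit; rachis
by BIC-selected polynomial regression in a PCA-rotated frame; kernel rows
by silhouette-selected 1-D K-means. Details and the reasoning behind each
choice are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic seed tray (50 elliptical seeds, a 25 mm coin of radius
100 px, black background) and run the seed pipeline:

```python
from phenokit.synth import SeedTraySpec, gen_seed_tray
from phenokit import run_seed_pheno

image, truth = gen_seed_tray(SeedTraySpec(n_seeds=50, seed=1))
result = run_seed_pheno(image)
print(result.traits["count"])                      # 50
print(round(result.calibration.mm_per_px, 4))      # 0.125
print(round(result.traits["mean"]["length_px"], 1))   # 32.1
print(round(result.traits["mean"]["length_mm"], 2))   # 4.01
```

The pipeline found all 50 seeds; the coin-derived scale 0.125 mm/px matches
the generative truth (coin diameter 25 mm over 200 px); the mean seed
length 32.1 px (4.01 mm) agrees with the generated mean major axis of
32.1 px. `result.records` holds one trait record per seed,
`result.to_json()` a fully reproducible result document, and
`result.records_frame()` a pandas table.

The same works from the shell:

```sh
phenokit synth seed_tray --seed 1 --out scene/
phenokit seed scene/image.png --coin-mm 25 --out results/
```

which writes `results/result.json`, `results/traits.csv`, and an
`overlay.png` with instance boundaries.

## Scope

Everything here is classical and deterministic; no trained weights ship
with the package. The synthetic scenes validate the measurement chain
(exact-rasterized shapes, controlled difficulty), not robustness to field
imagery — that is the role of pluggable detection backends. Color
calibration, lens-distortion correction, 3-D reconstruction, and
multi-image workflows are out of scope.
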