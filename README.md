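# cropseg

Semi-automated crop-plot segmentation from UAS imagery for experimental
agriculture.

Breeding and agronomy trials plant cereals in grids of hundreds of small
rectangular plots (microplots) separated by narrow soil or plough-line
divisions. Extracting per-plot statistics (canopy height, vigour indices,
emergence) from drone orthomosaics or photogrammetric DSMs first requires a
polygon for every plot — usually a manual digitization job. `cropseg`
automates it by detecting the straight *divisions* between plots instead of
the plants themselves, so it works across phenology, from emergence (bare
plough lines) to senescence, with essentially two parameters: an edge
smoothing scale σ and a minimum plot area in m².

The chain: AOI mask → Canny or phase-congruency edge primitives → field
major/minor axis orientation from the AOI's minimum rotated rectangle →
standard Hough transform constrained to normal angles near each axis
(`x cos θ + y sin θ = r`) → lines rendered and merged → connected components
of the line-free interior → area filter → map-coordinate plot polygons →
optional boundary refinement (morphological Chan–Vese or Otsu). Accuracy
against a validation layer is scored pixel-wise:

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F_beta    = (1 + β²) · precision · recall / (β² · precision + recall)

with β = 1 by default. See `docs/methods.md` for the full model description
and design rationale.

## Worked example

No survey imagery ships with the package, so generate a synthetic trial field
(a rotated 6×10 grid of 1.5 m × 3.0 m oat plots with known ground truth),
segment it, and score the result:

```bash
cropseg synth --out-dir demo --rows 6 --cols 10 --angle 17 --seed 1
cropseg segment --image demo/scene.tif --aoi demo/aoi.geojson \
                --out demo/plots.geojson --min-area 3.5
cropseg eval --pred demo/plots.geojson --truth demo/truth.geojson \
             --image demo/scene.tif --aoi demo/aoi.geojson
```

The segment step prints

```
wrote 60 segments to demo/plots.geojson
```

— all 60 plots recovered, one polygon each — and the eval step reports (excerpt)

```
  "f_beta_pct": 96.84,
  "precision_pct": 100.0,
  "recall_pct": 93.88,
```

Precision 1.0 means no segment pixel strays outside a true plot; recall ~0.94
reflects the one-to-two-pixel inward bias of boundaries that sit on the
division edges; F1 ≈ 0.97 overall. Named presets reproducing published
per-site parameter sets are available via `--preset`
(`cae_tatws_cn`, `cae_tatws_pc`, `cae_gwyn8`, `cae_gwyn7_dual`,
`cae_rasus4_dsm`), e.g. dual-axis Canny with σ = 4 (threshold 6) along the
major axis and σ = 40 along the minor for emergence-stage fields. Every run
writes a JSON run log with the fully resolved configuration; runs are
byte-deterministic.

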