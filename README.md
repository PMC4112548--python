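# spindlequant

Quantification of mitotic spindle orientation dynamics and astral
microtubule organization in neural stem and progenitor cells of the
developing neocortex — with a ground-truthed synthetic microscopy
generator, because the measurements are defined on multi-channel confocal
stacks for which no public accession exists.

The package is aimed at quantitative cell biologists studying spindle
orientation control in pseudostratified neuroepithelia: it turns
multi-channel 3D stacks (DNA / tubulin / cortical-marker / reporter) into
per-cell and per-tissue numbers, and it can fabricate realistic-geometry
inputs whose every generative parameter is known, so every measurement is
testable as a parameter-recovery problem.

## What it measures

- **Chromosome-plate orientation** (`plate_orientation`): the signed
  deviation θ of the plate's main axis from the local apico-basal axis
  (0° = perpendicular to the ventricular surface; ±90° = parallel).  The
  per-cell summary is the *maximal amplitude of deviations*
  max θ(t) − min θ(t) over the metaphase → anaphase-onset window, plus the
  six-bin colour classification of whole tracks (blue > 30° … dark red
  < −30°).
- **Astral microtubule census** (`astral_census`): the soma is split into
  apical / central / basal regions by the planes through the apical-most
  and basal-most peri/centromeric heterochromatin foci (the brightest DNA
  puncta on the plate); astrals emanating from the two spindle poles that
  reach within δ_cortex (default 1 µm) of the cell periphery are counted
  per region.  Central astrals are only countable in "Side" views (spindle
  axis mostly along the optical axis); "Front" views report them as not
  assessed.  Basal progenitors, which lack apical polarity, get an
  orientation census instead (apically / basally / centrally oriented, ±45°
  sectors).
- **Cortical marker profile** (`cortical_profile`): intensity along the
  one-pixel soma contour on a single central optical section, cytoplasmic
  background subtracted (median of the eroded interior), resampled by
  linear interpolation to 100 equidistant positions on the normalized
  perimeter, starting at the apical midpoint and proceeding clockwise —
  the assay used for cortical LGN distribution.
- **Spindle-integrity metrics** (`spindle_metrics`): main-spindle-region
  area (mean of the two central-most sections), mean intensity normalized
  to the whole image, per-pixel SD normalized to the region mean, and the
  soma diameter along the pole–pole axis.
- **Division symmetry** (`division_symmetry`): whether the prospective
  cleavage plane (≈ the anaphase plate angle) bisects or bypasses the
  cadherin-negative apical membrane domain, and the percentage of
  asymmetric (bypass) divisions.
- **Tissue censuses** (`tissue_census`): marker fractions by zone
  (resident APs = Pax6+ Tbr2−, newborn BPs = Tbr2+), mitoses per 100 µm of
  apical surface (VZ / SVZ / all), neurons per 100 µm of pial surface,
  apoptotic cells per 10,000 µm².
- **Statistics** (`stats`): mean ± SEM, Student's t / Mann–Whitney U,
  one-way ANOVA + Tukey HSD, Kruskal–Wallis + Dunn's multiple comparison
  (rank-based z with tie correction, Bonferroni family adjustment).

The synthetic generator (`synthetic`) also implements the guy-rope
anchoring model as a mean-reverting (Ornstein–Uhlenbeck) angle process,
dθ = −k·n_polar·θ·dt + σ·dW: more polar astral anchors mean a stiffer
restoring force and smaller orientation fluctuations.

## Worked example

Render one Side-view mitotic cell with a known 5 / 7 / 9 census and
measure it back:

```python
import numpy as np
from spindlequant import side_view_cell, make_mitotic_cell
from spindlequant.pipeline import measure_cell

rng = np.random.default_rng(42)
spec = side_view_cell(rng, n_apical=5, n_basal=7, n_central=9)
stack, gt = make_mitotic_cell(spec, seed=42)
row = measure_cell(stack)
print(gt.census)          # {'apical': 5, 'basal': 7, 'central': 9}
print(row["view"],        # side
      row["astral_apical"],   # 5
      row["astral_basal"],    # 7
      row["astral_central"])  # 9
print(round(row["spindle_area_um2"], 1))   # 46.8
```

The detected census equals the generative one exactly; the main spindle
region of this cell covers 46.8 µm² at the 0.09 × 0.09 µm pixel size.  A
small two-group pipeline run shows the anchoring model end to end — cells
built with the proliferating-type astral complement hold their spindle
steadier than neurogenic-type cells:

```python
from spindlequant.pipeline import RunConfig, run_cell_pipeline

cfg = RunConfig(seed=7, groups=[{"name": "proliferating_ap", "n": 3},
                                {"name": "neurogenic_ap", "n": 3}])
df = run_cell_pipeline(cfg)
print(df.groupby("group")[["astral_apical", "astral_basal",
                           "track_amplitude_deg"]].mean().round(2))
#                   astral_apical  astral_basal  track_amplitude_deg
# neurogenic_ap              2.67           4.0                21.94
# proliferating_ap           5.33           7.0                12.49
```

The same operations are available from the shell:

```bash
spindlequant simulate cell --seed 3 --out out/cell
spindlequant measure census --stack out/cell/stack.tif
spindlequant simulate tissue --seed 4 --out out/tissue
spindlequant tissue counts --nuclei out/tissue/nuclei.csv --apical-length 200
spindlequant stats compare --csv values.csv --group-col group --value-col value
```

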