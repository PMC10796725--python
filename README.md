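# endograin

Tools for relating the inner structure of the rice grain to its Glycemic
Index (GI). Rice endosperm is packed with compound starch granules; how
tightly they pack — the porosity of the grain section, the size and shape
of the granules, the extent of the chalky versus crystalline endosperm —
varies strongly between varieties and is a candidate driver of how fast
the starch digests. `endograin` implements the complete computational
chain for such a study:

* **morphometry** — segmentation of calibrated FESEM micrographs of grain
  sections into granule instances, true pores and perspective shadows;
  per-granule area (pixel count × pixel size²), perimeter, moment-ellipse
  eccentricity (0 = circle), isoperimetric circularity 4πA/P² (1 = circle)
  and equivalent circular diameter d = 2√(A/π); field porosity
  100 · pore / (pore + shadow + granule) pixels; and per-variety
  aggregation weighted by the chalky fraction of the endosperm.
* **glycemia** — the in-vivo GI from capillary blood-glucose curves
  sampled at −5, 0, 15, 30, 45, 60, 90, 120 min: trapezoidal incremental
  area under the curve above the fasting baseline (area below baseline
  disregarded, crossing segments split at the interpolated crossing),
  GI = 100 · IAUC(test) / mean IAUC(glucose reference) per subject,
  study GI as the subject mean, classed ≤ 55 low / 56–69 medium / ≥ 70 high.
* **stats_explore** — pairwise-complete Pearson correlations and PCA with
  unit-variance scaling (autoscaling) on variety-level feature tables.
* **synthetic_data** — seeded, ground-truthed generators for both input
  kinds: anisotropic-Voronoi endosperm fields with programmed porosity and
  rendered shadows, and glycemic trials whose noise-free GI equals the
  programmed value exactly.
* packaged per-variety tables (`endograin.tables`) covering 54 varieties:
  the 25-variety GI panel with biochemistry, and 29 further varieties
  characterised by FESEM only.

## Worked example

```python
>>> from endograin import morphometry as M, glycemia as G
>>> from endograin.synthetic_data import MicrographParams, generate_micrograph
>>> micro, truth = generate_micrograph(MicrographParams(target_porosity_pct=5.0), seed=42)
>>> labels = M.classify_voids(micro, M.segment_micrograph(micro))
>>> round(truth.achieved_porosity_pct, 2), round(labels.porosity(), 2)
(5.0, 5.01)
>>> M.equivalent_diameter(43.02)   # mean granule area in um^2 -> diameter in um
7.4
>>> G.classify_gi(92.31)
'high'
```

The generated field realises its programmed 5.0 % porosity exactly (pore
pixels over analysed area, before noise); the full pipeline — Otsu
segmentation, watershed splitting, pore/shadow discrimination — recovers
5.01 %. A 43.02 µm² mean granule corresponds to a 7.40 µm equivalent
circular diameter, and a study GI of 92.31 is a high-GI food.

The `analysis/` scripts run the study steps end to end and write their
tables under `results/`:

```sh
python analysis/01_simulate_micrographs.py     # ground-truthed fields
python analysis/02_porosity_recovery.py        # recovery MAE ~0.22 points
python analysis/03_gi_trial_simulation.py      # bias +0.6 GI units / 200 trials
python analysis/04_reproduce_printed_tables.py # diameters, GI classes, correlations
python analysis/05_structure_gi_exploration.py # PCA scores/loadings
```

There is also a CLI: `endograin simulate|segment|morphometry|gi|correlate|pca|reproduce`
(see `endograin --help`).

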