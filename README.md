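# macromigr

Quantitative image analysis for macrophage migration on extracellular-matrix
(ECM) substrates. Macrophages plated on fibronectin (FN) spread and migrate
slowly but persistently; on laminin (LAM 111) they stay rounded and migrate
fast but meander, intermittently elongating and snapping back in
single-frame "slingshot" recoils. This package implements the measurement
layer needed to quantify that contrast from time-lapse movies, confocal
z-stacks and adhesion-assay images — plus a synthetic-data generator with
known ground truth so every measurement can be validated end to end.

## What it computes

- **Tracking** (`trackio`): Laplacian-of-Gaussian spot detection with
  sub-pixel localisation, two-pass linear-assignment (LAP) linking with gap
  closing (link/gap distance ≤ 70.0, gaps ≤ 10 frames), and track filters
  (duration ≥ 20 frames, mean speed ≥ 2.00, displacement ≥ 8.00, in
  calibrated units).
- **Motility** (`motility`): velocity v = T_path / Δt in µm/min, and
  persistence d/T — net displacement over accumulated path length, 1 for
  perfectly straight migration.
- **Shape** (`morpho`): circularity C = 4πA/P² from a sub-pixel contour,
  elongation (second-moment axis ratio), per-frame shape change
  s_n = |C_n − C_{n+1}| over a 5-h window (31 frames at 10 min/frame), and
  slingshot events (s_n ≥ 0.4, inclusive), reported as events per cell.
- **Intensity** (`quant`): ventral fraction f = I₀ / Σ_z I_z of a confocal
  z-stack (z = 0 the coverslip-proximal slice; a myosin-II localisation
  proxy), in-mask intensity statistics, five-position coating uniformity,
  blot densitometry ratios, and the adhesion ratio (post-wash count /
  pre-wash count).
- **Statistics** (`report`): superplot summaries (per-run mean ± SEM,
  per-condition grand mean of run means) and group comparisons —
  Kruskal–Wallis with Dunn's multiple-comparison post-hoc (Holm-adjusted),
  Mann–Whitney, Welch's t, one-way ANOVA.
- **Synthetic data** (`simkit`): a two-mode persistent random walk with
  Bernoulli slingshot events, rendered to 16-bit TIFF movies, plus z-stack
  and pre/post-wash field simulators. Presets `FN_LIKE` and `LAM_LIKE`
  reproduce the qualitative substrate contrast with known ground truth.

## Worked example

```python
from macromigr import report

bundle = report.run_pipeline(report.DEMO_CONFIG)  # 3 runs x 20 cells/condition
print(bundle["summaries"]["mean_speed_um_min"].conditions)
print(bundle["summaries"]["persistence"].conditions)
for metric, st in bundle["stats"].items():
    print(metric, "p =", f"{st['p']:.3g}")
```

prints

```
condition  grand_mean  n_runs  n_cells
       FN    0.299886       3       60
      LAM    0.958285       3       60
condition  grand_mean  n_runs  n_cells
       FN    0.468493       3       60
      LAM    0.146430       3       60
mean_speed_um_min p = 3.43e-21
persistence p = 1.13e-16
mean_shape_change p = 3.56e-21
slingshot_count p = 2.87e-24
```

Laminin-like cells migrate ~3× faster (0.96 vs 0.30 µm/min) but far less
persistently (0.15 vs 0.47), change shape more, and show slingshot events —
the qualitative fingerprint the measurement layer is designed to resolve,
here recovered from simulated data at high significance (Mann–Whitney).

The same pipeline runs from a shell:

```sh
macromigr simulate --preset lam_like --n-cells 20 --movie demo.tif
macromigr track --movie demo.tif --out tracks.csv
macromigr metrics --tracks tracks.csv --out metrics.csv
macromigr run --config experiment.yaml --out results/
```

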