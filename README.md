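# mesotrack

Quantitative analysis of single-cell migration and shape for live-imaged
mesoderm in the gastrulating mouse embryo — and for any comparable 3-D
time-lapse tracking experiment.

During mouse gastrulation, epiblast cells delaminate at the primitive
streak and migrate either anteriorly (embryonic mesoderm) or proximally
(extra-embryonic mesoderm). The two populations behave very differently:
embryonic cells follow meandering but directional paths, while
extra-embryonic cells move tortuously with little net displacement, are
larger, more stretched, and carry fewer filopodia. `mesotrack` implements
the measurement pipeline needed to quantify these phenotypes from
manually segmented image data:

- **Trajectory metrics** per cell, from centroid tracks in µm/minutes:
  net displacement `D_net = ‖x(t_N) − x(t_0)‖`, travel (path)
  displacement `D_trav = Σᵢ ‖x(tᵢ₊₁) − x(tᵢ)‖`, straightness
  `S = D_net / D_trav ∈ [0, 1]`, and mean speed as the duration-weighted
  mean of the instantaneous slopes of the piecewise-linear path-length
  curve (identically `D_trav / (t_N − t_0)`).
- **Drift correction** of whole-embryo translation using an
  embryo-contour reference track: `x'(t) = x(t) − (ref(t) − ref(t₀))`,
  with optional user-supplied per-frame rotations.
- **Pair coupling** for annotated daughter / proximity / collision
  pairs: angle between whole-window net-displacement vectors, symmetric
  min/max net and travel displacement ratios, mean and final
  inter-centroid distance over common timepoints.
- **Morphometry** of segmented masks on anisotropic voxel grids: volume
  (voxel counting), surface area (level-0.5 isosurface triangulation),
  cell stretch as the long/short axis ratio of the equal-second-moment
  ellipse of the Z projection, plus filopodium polyline lengths and
  counts per cell per timepoint.
- **Group statistics** with a normality-gated test choice: Welch's
  t-test when both samples pass Shapiro–Wilk at α = 0.05, otherwise the
  two-sided Mann–Whitney–Wilcoxon; everything reported as mean ± SEM
  (sd/√n). An independent exact Mann–Whitney oracle by full enumeration
  backs the implementation for small tie-free samples.
- **Synthetic data** with known ground truth: persistent random walks
  (von Mises–Fisher heading concentration κ, lognormal speeds), daughter
  pairs with correlated headings, rasterized ellipsoid masks, and
  Poisson filopodia — so the whole pipeline is testable at desk scale.

## Worked example

Simulate a cohort shaped like the tracked experiment (34 embryonic vs 17
extra-embryonic cells, 20-min frames, ~160 min), compute per-cell
metrics, and compare the groups:

```sh
mesotrack simulate --seed 1 --out sim --division-rate 0.2
mesotrack track-metrics --tracks sim/tracks.csv --out track_summaries.tsv
mesotrack pair-metrics  --tracks sim/tracks.csv --pairs sim/pairs.csv --out pair_summaries.tsv
mesotrack compare-table --table track_summaries.tsv \
    --value-cols straightness,mean_speed_um_min --out comparisons.tsv
```

`track_summaries.tsv` holds one row per cell:

```
embryo_id  cell_id         region     n_points  duration_min  net_displacement_um  travel_displacement_um  straightness  mean_speed_um_min
sim        embryonic_000   embryonic  9         160           74.03749444          92.15062563             0.8034399542  0.5759414102
sim        embryonic_001   embryonic  9         160           80.33098848          101.4745261             0.791636991   0.6342157879
```

and `comparisons.tsv` the group table (mean ± SEM per region, the test
the normality gate selected, and its two-sided p):

```
metric             group_a    group_b          n_a  n_b  mean_a        sem_a          mean_b        sem_b          test_used     statistic    p_value
straightness       embryonic  extra_embryonic  34   17   0.7875900553  0.01958561987  0.4134011873  0.03315393668  mann_whitney  562          5.182854477e-08
mean_speed_um_min  embryonic  extra_embryonic  34   17   0.6660168832  0.01001934842  0.4515424241  0.01346099155  t_test        12.78116179  1.834600925e-14
```

Read: simulated embryonic cells are straighter (0.79 ± 0.02 vs
0.41 ± 0.03, Mann–Whitney p ≈ 5·10⁻⁸) and faster (0.67 ± 0.01 vs
0.45 ± 0.01 µm/min, Welch p ≈ 2·10⁻¹⁴) than extra-embryonic cells —
recovering the generating parameters (speeds 0.67 and 0.44 µm/min,
heading concentrations κ = 5 vs 0.3). The daughter-pair aggregates show
the expected coupling (mean angle ≈ 14°, net ratio ≈ 0.84, mean
inter-cell distance ≈ 9 µm for this seed).

The same stages run against real exports: a track CSV (columns
`embryo_id, cell_id, region, t_min, x_um, y_um, z_um`; foreign column
names remappable via a dialect), a pair annotation CSV, multi-page TIFF
label volumes, and a filopodia polyline CSV. `mesotrack run --config
config.yaml` executes all stages and writes a deterministic TSV report
bundle with a run log.

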