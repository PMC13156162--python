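# pellet-morph

Quantitative morphometrics for filamentous fungal pellet populations in
submerged culture, built around *Aspergillus niger*-style coagulative
pellets.  The package covers both scales on which such cultures are
described:

* **Macromorphology** — 2D population images of a dish: pellet segmentation,
  area-equivalent circular diameters (d = 2·√(A/π)), pellet number
  concentration (mL⁻¹), dispersed-mycelium fraction, and binned size
  distributions q₀/Q₀ (50 µm bins) with median and interquartile range.
* **Micromorphology** — 3D binary voxel volumes of single pellets (e.g. from
  micro-computed tomography): radial solid-fraction profiles (50 µm core
  sphere + 15 µm shells), porosity against the convex-hull envelope,
  skeletonisation of the hyphal network with tip/branch-point census, total
  hyphal length and average branch length (ABL), hyphal diameter from the
  distance transform, volume-equivalent diameter, and DBSCAN clustering of
  spore coordinates.
* **Inner-architecture classes** — a deterministic rule cascade assigning
  each pellet class I (one centred spore agglomerate), II (multiple attached
  agglomerates), III (loose entanglement of mature pellets/fragments,
  irregular shape or hollow centre) or the provisional class IV
  (shear-broken fragments).
* **Population statistics** — Mann–Whitney U comparison of diameter
  distributions (exact for small tie-free samples), histogram-intersection
  overlap coefficient, surface-to-volume ratio of the population
  (S/V = 6·Σd²/Σd³ under the sphere assumption) and its Spearman association
  with substrate uptake.
* **Growth kinetics** — µ (log-linear regression of CDW), R_s, q_s
  (trapezoidal mean biomass), Y_x/s and ΔCDW_max from CDW/glucose batch
  time series, via a statsmodels-style `GrowthKineticsModel(series).fit()`.

Because raw microscopy and tomography data of such studies are rarely
deposited, the package ships a first-class synthetic generator (`phantom`):
off-lattice pellets grown from spore agglomerates by persistent-random-walk
tips with lateral branching (expected inter-branch spacing equal to a target
ABL), planar-cut breakage and hull-contact fusion events, voxelization to
binary volumes, and projection rendering of whole populations.  Every
generated pellet carries its exact ground truth (graph, counts, lengths,
class), so each analysis stage is testable end to end.

## Worked example

Grow a synthetic pellet, rasterise it and recover its micromorphology:

```python
from pelletmorph.phantom import census_pellet_spec, grow_pellet, voxelize
from pelletmorph import tomo3d

pellet = grow_pellet(census_pellet_spec(0))   # ground truth: 5 tips, 3 branch points
vol = voxelize(pellet, voxel_size=1.0)
m = tomo3d.compute_metrics(vol, spore_points=pellet.spore_points)
print(m.n_tips, m.n_branch_points, round(m.total_hyphal_length, 6))
```

prints `5 3 0.000235`: the skeleton census equals the ground-truth census
exactly and the measured total hyphal length (2.35×10⁻⁴ m) is within 2% of
the true 2.4×10⁻⁴ m laid down by the generator.

Fit batch growth kinetics to a noisy synthetic cultivation (true µ = 0.15 h⁻¹,
Y_x/s = 0.65 g g⁻¹, 8 g L⁻¹ initial glucose):

```python
from pelletmorph.phantom import simulate_growth_series
from pelletmorph.kinetics import GrowthKineticsModel

series = simulate_growth_series(mu=0.15, y_xs=0.65, noise=0.02, seed=1)
print(GrowthKineticsModel(series).fit(mu_window=(6, 12)).summary())
```

```
Growth kinetics (replicate synthetic)
mu estimator: log-linear least-squares regression
-------------------------------------------------------
Specific growth rate mu [1/h]        0.1519  window 6-12 h
Substrate uptake rate R_s [g/L/h]    0.5055  window 0-16 h
Specific uptake rate q_s [g/g/h]     0.2035
Biomass yield Y_x/s [g/g]            0.6477
Max CDW increase dCDW_max [g/L]      5.2382
```

µ and Y_x/s land within 2% of the generating values; the uptake window
(0–16 h) was auto-detected as the period until glucose depletion.

A full pipeline run (simulation → 2D/3D analysis → classification → stats),
comparing a breakage-dominated "high-shear" arm with a fusion-dominated
"low-shear" arm:

```
pellet-morph pipeline --seed 1 --out run1
```

writes `run1/report.json` plus per-arm population and region tables.  The
report shows the expected directional physics: the high-shear arm ends with
more, smaller pellets (class IV fragments appear), the low-shear arm with
fewer, larger, multi-cluster class III pellets.

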