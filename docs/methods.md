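# Methods

This note documents the models, estimators and numerical choices behind
pellet-morph, what the synthetic data emulate, and where the declared
defaults come from.

## The growth model behind the synthetic pellets

Coagulative *A. niger* pellets form from spore agglomerates whose number is
set in culture by the spore-to-microparticle (talcum) ratio.  The generator
models one pellet as:

1. **Seeding.** `n_agglomerates` Gaussian clusters of spores
   (`agglomerate_spread` between clusters, `spore_spread` within).  Talcum
   particles are not modelled as distinct objects; their biological effect is
   folded entirely into `n_agglomerates`.
2. **Apical extension.** Each spore emits `germ_tubes_per_spore` tips (with a
   30° minimum angular separation between sibling tubes).  Tips advance in
   2 µm steps at `tip_speed` (default 40 µm h⁻¹, giving realistic pellet
   radii over hour-scale runs) as a persistent random walk:
   d ← normalize(d + σ·ξ) with σ = 0.9·(1 − persistence).
3. **Lateral branching.** The distance to the next branch event is drawn as
   `min_branch_spacing + Exp(target_branch_length − min_branch_spacing)`.
   The expectation equals `target_branch_length` exactly, while the
   refractory floor (default 10 µm) guarantees no ground-truth edge shorter
   than the skeleton prune length — without it, branch events falling inside
   the pruning radius would make an exact skeleton census impossible by
   construction, not by implementation error.  Daughters leave at 45–85° off
   the parent axis.
4. **Self-avoidance.** A step that would bring a tip within
   `avoidance_clearance` (6 µm, i.e. two hyphal diameters) of a non-adjacent
   hypha is deflected, or the tip is arrested.  This mimics negative
   autotropism and, practically, keeps distinct tubes resolvable after
   voxelization.  It is disabled in the dense reference phantom, where
   hyphal crowding is the point.

Edge lengths, tip/branch-point counts, spore positions and class labels are
recorded exactly from the generated graph.  Two census conventions coexist:
`true_tips`/`true_branch_points` count biological apices and branch events,
while `SyntheticPellet.census()` counts degree-1 and degree-≥3 nodes of the
degree-2-suppressed graph — the quantity a topological skeleton can actually
recover (a root with two germ tubes is invisible to a skeleton; a root with
three is a junction).

**Breakage** is a planar cut: polylines are split exactly at their plane
crossings (length is conserved to machine precision) and everything left on
one side forms one class IV fragment, keeping the spores on its side.  A
stress-field fracture model is deliberately out of scope: the observable
consequences (fragment counts, diameter shifts) do not require one.
**Fusion** translates one pellet along the line of centres until the hulls
interpenetrate by `overlap` µm and unions the graphs; cluster counts and
lengths are additive and the product is class III.

**Population simulation** works on lightweight records (diameter, class,
cluster count) rather than full graphs.  Diameters are lognormal
(median 609 µm for the low-talcum seed regime, 234 µm for the high-talcum
regime; geometric CV 0.33 reproduces seed-culture interquartile ranges).
Breakage events pick pellets with probability ∝ d², split the volume at a
uniform 25–50% fraction (d³ conserved) and flag fragments class IV; fusion
merges two pellets volume-additively into class III with summed clusters.
Per step, `max(1, round(rate·n))` events fire, so a breakage-dominated
schedule strictly increases the count and pushes the median down, and a
fusion schedule does the reverse — the directional behaviour of high- vs
low-shear reactors.

What the generator does **not** emulate: hydrodynamics and shear-stress
fields, oxygen/substrate gradients inside pellets, spore swelling, hyphal
death and vacuolation, talcum as a distinct voxel phase, and imaging
artifacts beyond Gaussian noise.  Tests passing on phantoms therefore
validate the measurement chain, not these biological processes.

## 2D analysis

Global Otsu threshold on the (inverted) intensity, hole filling, 8-connected
labelling and a distance-transform watershed with seed maxima at least 60 µm
apart to split touching pellets.  Regions with area-equivalent diameter
below `dispersed_cutoff` (default 50 µm — a declared default, the
pellet-vs-dispersed criterion of the lineage method is not published) count
as dispersed mycelium; border-touching regions are excluded from size
statistics but reported.  Median and IQR use linear-interpolation empirical
quantiles (numpy default, type 7) on raw diameters so results are
reproducible bit for bit; q₀/Q₀ use half-open 50 µm bins from zero.

## 3D analysis

* **Radial profile**: mass centre = unweighted centroid of solid voxels;
  regions are the 50 µm core sphere and half-open 15 µm shells out to the
  farthest solid voxel; each fraction is solid/total voxel count within the
  grid.  The volume-weighted mean of shell fractions equals the global solid
  fraction by construction.
* **Envelope**: convex hull of solid voxels, evaluated as voxel centres
  inside the hull united with the solid itself (the hull of voxel centres is
  inscribed, so boundary voxels may fall marginally outside).  Chosen over a
  bounding sphere because irregular class III shapes would otherwise
  overestimate porosity; degenerate (collinear/coplanar) solids fall back to
  the bounding sphere and are flagged.  Porosity = 1 − solid/envelope;
  volume-equivalent diameter = (6·V_env/π)^(1/3); sphericity =
  π^(1/3)·(6V)^(2/3)/A on the continuous hull.
* **Skeleton**: `skimage.morphology.skeletonize` (3D thinning), then a
  hand-built graph: voxels with ≠2 neighbours cluster into nodes
  (26-connectivity), degree-2 runs become edges.  Edge length is measured by
  chords over 3-voxel windows — per-voxel 1/√2/√3 step sums overestimate
  oblique runs by the staircase effect; 3-voxel chords remove most of that
  bias while following curvature.  Spur edges shorter than `prune_length`
  (6 µm = two hyphal diameters) are removed, short junction–junction edges
  and self-loops are contracted (thinning splits some junctions into
  multi-node clusters), and each terminal edge is lengthened by the distance
  transform value at its endpoint, compensating the ~1 tube radius that
  thinning erodes from every free end.  Thinning is orientation-dependent at
  the percent level: the census is strictly invariant under 90° rotations,
  lengths agree to a few percent.
* **ABL** is the mean edge length (branch point to branch point or tip).
  Note that in any finitely grown tree the observed mean is below the
  branch-placement target: inter-branch distances are censored by the growth
  horizon.  Tests therefore validate the tree ABL against an independent 1D
  simulation of the same placement law, not against the raw target.
* **Hyphal diameter**: 2 × mean Euclidean distance transform along skeleton
  voxels, excluding voxels within 6 µm of a junction (there the EDT reads
  the junction blob).  Tip regions bias the estimate slightly downward on
  small phantoms with many ends.
* **Spore clustering**: `sklearn.cluster.DBSCAN` with eps = 10 µm and
  min_pts = 3 (spores are 3–4 µm contact assemblies; the parameters are
  declared defaults).  The sklearn convention — a core point has ≥ min_pts
  points within eps including itself — is adopted; tests verify equivalence
  with a brute-force eps-connectivity/core-point oracle, treating border
  points that neighbour several clusters as legitimately ambiguous.
* Spore *detection* from real grayscale volumes is out of scope; the module
  takes coordinates (phantom ground truth or an external detector).

## Classification

Rule cascade (all thresholds configurable in `ClassRule`): class IV if
fragment-flagged (from the simulator event log when available, shape
heuristics otherwise — the source is recorded); else class III if envelope
sphericity < 0.6 or the centre solid fraction < 0.05 (a loosely entangled
centre); else class I if the pellet holds ≤ 3 spore clusters, class II
otherwise.  The defaults are calibrated on constructed archetypes: compact
single/multi-cluster pellets classify I/II with total accuracy, fused pairs
read III through their hollow mass centre.  They are declared choices — the
underlying indicators (centre solid fraction, cluster count) are reported in
the literature, printed cutoffs are not.  A genuinely ambiguous regime
exists: a young pellet of several widely spaced agglomerates has a hollow
mass centre and will read III until growth fills its interior.

## Kinetics

µ is the least-squares slope of ln CDW over the stated window (a regression
rather than a two-point difference; the choice is recorded in the result
metadata).  R_s is the endpoint glucose difference over the uptake window
(auto-detected from the first sample to the first sample below 0.1 g L⁻¹,
overridable); q_s divides R_s by the trapezoidal time-average CDW, so
q_s·X̄ = R_s identically.  Y_x/s = (max CDW − CDW₀)/consumed glucose.
Because ΔCDW_max takes a maximum, plateau noise biases it upward; averaging
biological replicates before fitting (standard practice for batch series)
suppresses the bias, and the tests fit the mean curve of two noisy
replicates.  Talcum carried in the biomass is not subtracted — it cannot be
separated quantitatively and its share of dry weight is small.

## Population statistics

Mann–Whitney U uses midranks for ties; the p-value is exact (full
enumeration) when both samples have ≤ 12 observations and no ties, otherwise
the normal approximation with tie and continuity corrections (both via
scipy, with the method pinned explicitly).  The overlap coefficient is the
histogram intersection Σ min(q₀ᵃ, q₀ᵇ) on common 50 µm bins — the standard
OVC variant; a density-overlap alternative would differ only in smoothing.
S/V treats pellets as spheres (the quantity is defined from diameters, which
implies the same); class III irregularity is knowingly ignored here.
Spearman (not Pearson) correlation is used for the S/V–uptake association:
with four conditions only a monotone claim is defensible.

## Problem sizes and tolerances

Default test/acceptance scales: 50 phantom pellets (~180 µm across, 1 µm
voxels) for the skeleton census; n = 200 populations for median recovery
(5% tolerance ≈ 3 standard errors of a lognormal sample median at this n);
one ~250 µm dense phantom for porosity (tolerance 0.02); 11-point growth
series (2 h sampling over 20 h).  These sizes keep a full run in tens of
seconds while leaving every tolerance dominated by method error, not sample
noise.  Seeded `numpy.random.default_rng` generators drive all randomness;
child seeds derive from the user seed by SHA-256 so stages are independently
reproducible.

## Known limitations

* Skeleton length error grows with curvature and voxel size; at 1 µm voxels
  and 1.5 µm tube radius the aggregate error is ~1–2%, single pellets up to
  ~7%.  The census can miss a tip/branch pair (sub-2% of pellets at the
  census-phantom scale) when a daughter branches at a shallow angle right at
  the refractory floor.
* The 2D watershed merges pellets whose centres are closer than the seed
  distance (60 µm); the projection renderer avoids overlap, real dishes may
  not.
* `binarize` assumes the solid phase is the brighter one.
* Class III detection rests on the centre solid fraction for near-spherical
  fusions; sphericity only triggers for grossly irregular shapes.
* The population simulator conserves pellet volume under events but does not
  grow pellets between timepoints; growth enters only through the sampled
  diameter law per timepoint.
* In dense volumes (hyphae allowed to overlap), thinning of merged tubes
  produces spurious junctions and short edges, deflating the apparent ABL
  well below the generative branch spacing; skeleton-census guarantees hold
  only for collision-free (self-avoiding) phantoms, which is exactly why the
  census phantom enables avoidance and the dense porosity phantom does not.
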