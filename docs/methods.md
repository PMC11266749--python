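# Methods

This note records the models, estimators, parameter choices and known
limitations behind `granulefish`, in the order the pipeline runs.

## Coordinate and unit conventions

All arrays are `(z, y, x)` with 0-based indices. Positions are fractional
pixels in x/y and fractional slices in z; every distance threshold is in
those mixed units (2 px in-plane, 2 slices axially, and so on). Physical
pixel pitch and z-step are carried as metadata on `ImageStack` but never
enter a threshold — this matches how the measurements are defined and
removes any dependence on calibration tags. One consequence: there is a
single axis convention everywhere, and no x/y swap is ever applied between
stages.

## Synthetic embryos

The generator is not a fixture factory but the package's model of the
data-generating process; every downstream guarantee is stated against it.

* **Geometry.** The cell and its nucleus are axis-aligned ellipsoids; the
  cytoplasm is cell minus nucleus. Defaults (70 px in-plane cell radius,
  8 slices axially) describe one P blastomere filling most of the frame.
* **Spots.** Each focus is a voxel-integrated 3D Gaussian (per-axis erf
  differences), so photons are conserved: integrated intensity is exactly
  `n_molecules × unit_intensity` up to edge truncation. Default PSF
  σ = 1 px in-plane and 1 slice axially, i.e. a ~150 nm-FWHM spot sampled
  at the high-magnification pixel pitch used for single-molecule work.
* **Clusters.** Molecule counts per focus follow truncated geometric
  distributions, with separate means inside granules (3.0) and in the
  dispersed cytoplasm (1.2), reflecting that granule-associated molecules
  coalesce into multi-copy clusters while cytoplasmic ones are mostly
  singles. The truncation cap (35) matches the largest observed cluster
  size. The molecule budget is split exactly by `p_granule`.
* **Focus separation.** Distinct foci are placed at least 4 px apart
  (≈ 4 σ) by default. This encodes the definition of a focus: molecules
  closer than the diffraction limit *are* one focus with summed intensity,
  so the generator never creates "two foci" that no optical method could
  distinguish. Crowded granules fall back to dispersed placement, and the
  truth flag follows the realized position.
* **Granules.** Axis-aligned ellipsoids, major axis along z (granules are
  tallest in height), minor radius 4–7 px — the scale of near-micron
  granule groupings at ~40–70 nm pixels. They are rendered as smoothed
  plateaus over a diffuse cytoplasmic marker pool (level 80, smooth
  heterogeneity sd 15, granule plateau +160): the fixation protocol
  disperses much of the granule protein, so the marker contrast is
  moderate. These levels are free parameters of the simulator, not
  measured values.
* **Noise.** Poisson shot noise on signal + background (level 100, plus an
  optional linear gradient) and additive Gaussian read noise (sd 5). With
  the default single-molecule intensity (4000 photons) the per-voxel peak
  SNR of a single is ≈ 12.
* **What is not modelled.** No Richards–Wolf PSF, spherical aberration,
  photobleaching, probe-hybridization chemistry, sub-granule condensate
  types, or autofluorescence texture. Passing tests therefore demonstrate
  correctness of the estimators under a faithful statistical model of
  spots, clusters and granules — not robustness to every optical artifact
  of real stacks.

## Lineage series

`generate_lineage_series` models the asymmetric P1 → P4 divisions as
molecule bookkeeping: the germline daughter keeps a binomial
`inherit_fraction` of granule-associated molecules and a `volume_ratio`
share of cytoplasmic ones, while its volume shrinks by `volume_ratio`.
With full localization and inheritance and halving volumes, concentration
doubles per division — 8× over three divisions — exactly in the truth
table, and measurably in the rendered stacks.

Two deliberate geometry choices keep the *measured* ratio unbiased:

* Cell volume is halved by scaling the x/y radii (by √volume_ratio) while
  the z geometry of cell and nucleus stays fixed. Real nuclei do not
  shrink 8-fold with the cell, and holding the axial profile constant
  means out-of-focus PSF spill into the nucleus mask — which the
  concentration formula subtracts — is identical at every stage and
  cancels in the P4/P1 ratio.
* The lineage simulator uses its own imaging defaults (300 nm pixels →
  σ_xy ≈ 0.21 px, 1 µm z-steps), emulating the lower-magnification
  objective used for whole-cell concentration measurements; granule
  association is carried as bookkeeping and molecules are rendered
  uniformly in the cytoplasm, because the single-slice integrated-density
  readout integrates over the cell area and spatial clumping only inflates
  its sampling variance without changing the partitioning model.

With 20,000 molecules and three P1 / three P4 replicates the measured
ratio lands within ~3% of 8 (residual bias is PSF spill at the shrinking
cell and nucleus boundaries).

## Spot detection and fitting

* **Background.** Per-slice rolling-ball subtraction: grey opening with a
  disk (default radius 50 px), computed on a 3×3-mean-smoothed copy so
  shot noise does not imprint the min-envelope, with shrink-and-zoom
  acceleration for large radii and the estimate clipped to never exceed
  the data.
* **Candidates.** 3D local maxima above the threshold, then non-maximum
  suppression (inclusive, Euclidean, default 1 px) ordered by intensity.
  The interactive per-session thresholding of manual workflows is
  replaced by an explicit config value plus a reproducible automatic
  default, median + k·MAD of the background-subtracted stack (k = 8).
* **Fitting.** Iterative Gaussian-mask centroid refinement with fixed σ
  from config (not refit per spot); the window spans ±3σ (+1) per axis,
  the window-rim median is the local background, and iteration stops at a
  0.01 px shift or 100 rounds. The intensity estimator `Σ(m·I)/Σ(m²)` with
  a voxel-integrated mask matches the rendering model exactly, giving
  noiseless accuracy of ~0.01 px and ~0.5% intensity.
* **Dense-field guard.** Fits converging within 1 px merge (brighter
  wins) — this also deduplicates noise-induced shoulder seeds on bright
  clusters. A seed left with no accepted spot within 2 px was captured by
  a brighter neighbour during free iteration; it is refit with a tighter
  ±2σ window and the centroid clamped to 1 px of the seed. Without this
  second pass, ~7% of dim foci beside ≥7×-brighter clusters vanish.
* **Edges.** Truncated windows are fitted, not discarded, and flagged via
  an inflated residual; non-convergence returns the seed position with an
  infinite residual.

## Calibration and molecule binning

The single-molecule intensity is the median integrated intensity of
somatic-lineage spots (≥ 50 by default), with MAD as the dispersion
diagnostic; MAD/median > 0.5 logs a poor-calibration warning. The median
tolerates ≥ 20% multi-molecule contamination with < 3% bias. Counts are
`max(1, floor(I/unit + 0.5))` — nearest integer, half-up ties, floor at
one molecule, no cap — and `n ≥ 4` flags a cluster. An equivalent view of
the same rule: a focus is assigned n when `I > (n − ½)·unit`.

## Granule segmentation

Pipeline: background subtraction → 3D Gaussian blur (σ = 1) → 256-bin
histogram → Kapur maximum-entropy threshold → per-slice distance-transform
watershed with watershed lines (splitting touching objects, as a 2D binary
watershed does) → 3D connected components (6-connectivity) → minimum
volume filter (4 voxels) → measurements. A full-3D watershed is available
behind `watershed_3d`.

Two deterministic guards replace the manual threshold adjustment and ROI
curation of interactive workflows:

* **Noise floor.** A two-class entropy split is meaningless on a
  granule-free image (it will happily split noise), so the automatic
  threshold must clear median + 8·MAD of the blurred stack; below that the
  image is declared granule-free.
* **Local mid-level refinement** (`refine_granule_boundaries`, on by
  default). On sparse bright foregrounds the entropy threshold provably
  sits at the top of the background class, so every object carries a
  contrast-dependent dilation shell of 0.5–2 voxels — enough to inflate
  small-granule volumes by tens of percent. Each component is therefore
  re-cut at the midpoint between its interior plateau (median over the
  eroded core, the voxels least contaminated by the edge ramp) and its
  local background (median of a surrounding shell). Refinement operates
  only within the component's 1-voxel dilation, so it cannot merge
  neighbours; it places the boundary at the half-edge of the blurred
  object, where rendered and measured extents coincide. With it, radii are
  recovered within 1 px and pooled granule volume within a few percent.

Measurements: minor radius = equivalent-circle radius of the largest-area
z-slice; major radius = max(z half-extent, half the longest principal
axis, minor radius); volume = voxel count. The membership cube has x/y
half-extents `minor + pad` (pad 2 px, room for error) and z half-extent
`major`.

## Colocalization

Cube membership is inclusive on all three axes; with several containing
cubes the nearest centroid wins (ties to the lower id). Percent of
molecules in granules is molecule-weighted. Cluster–cluster matching is
one-to-one nearest-Euclidean among candidates within *all* axis tolerances
(2 px / 2 px / 2 slices), ties broken by id; the same rule run as an
O(n²) enumeration is the test oracle. Reported alongside is the enrichment
above baseline: the in-granule percentage minus the percentage of
cytoplasm occupied by granules, which is what a uniformly distributed
(well-translated) transcript scores. Note that for a *uniform* transcript
the expected membership percentage is the cytoplasm fraction occupied by
the membership **cubes**, which exceeds the bare granule-volume fraction
by construction (the cube pads each granule).

## Concentration and enrichment

`[P] = I_cell/A_cell − I_nucleus/A_nucleus` on the raw (not
background-subtracted) mid-nucleus slice — the slice maximizing the
nucleus cross-section; the nuclear term is the in-cell background control,
so any uniform offset cancels exactly. Enrichment is `[P4]` over the mean
of ≥ 3 `[P1]` records; non-positive denominators are errors, negative
concentrations are returned but logged.

## Screen classification and statistics

Group I/II/III is a pure function of the per-transcript booleans: any
P-blastomere focus flag + PGC pattern → I, foci without pattern → II, no
foci → III (a PGC-like pattern without foci still classifies as III).
Report percentages round half-up to integers; full precision is kept in
the tables. Fisher's exact test sums hypergeometric probabilities ≤ that
of the observed table using exact `Fraction` arithmetic, so probability
ties are handled without floating-point tolerances; degenerate margins
return p = 1 by convention. The unpaired t-test is a thin scipy wrapper.

## Problem sizes and determinism

The shipped verification runs use 20,000-molecule lineage series (three
replicates per stage), 200-focus fitting fields, 500-molecule cluster
embryos, 100 random histograms / 2×2 tables, 50 random pairing scenes and
20 granule embryos — sizes at which every acceptance bound holds with
margin while a full run stays around a minute. All randomness flows from
a single integer seed through `numpy.random.SeedSequence`; identical seeds
reproduce identical images, tables and manifests bit for bit.

## Known limitations

* Foci closer than ~4 σ are genuinely unresolvable and are treated as one
  focus by both the generator and the detector; the package makes no
  attempt at multi-emitter deconvolution.
* The Kapur threshold's background-top behaviour is intrinsic; without the
  local refinement step, granule volumes are overestimated by 20–90%
  depending on contrast and size. The refinement assumes granules are
  plateau-like objects at least ~2 voxels across.
* Measured in-granule percentages are cube-based and therefore slightly
  generous relative to truth membership flags (see Colocalization above).
* The enrichment readout carries a small (~2–3%) negative bias from PSF
  spill across shrinking cell boundaries, visible in the idealized 8×
  measurement.
* Cell and nucleus masks are inputs (simulator-provided or hand-drawn);
  automatic cell segmentation is out of scope.
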