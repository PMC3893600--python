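# Methods

This note records the models, conventions and numerical choices behind
`calcimorph`, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

Volumes are (z, y, x) arrays; the slice index is axis 0 and x varies
fastest in files. Voxels are isotropic with edge length `voxel_size` in
mm; anisotropic input is rejected rather than resampled. Voxel `i` is the
cube centred at `(i + 0.5) · voxel_size` mm, and every mesh vertex,
centroid and Feret diameter is expressed in these world coordinates. All
output tables carry units in their column names (mm, mm², mm³, mm⁻¹).

Fixed protocol constants (`defaults.py`): 35 μm reference voxel size;
sub-resolution bound 2 voxels (0.000086 mm³ at 35 μm); mammographic
visibility threshold 0.0042 mm³ — the volume of a 0.2 mm-diameter sphere,
i.e. two 0.1 mm mammography pixels across; macrocalcification bound 1 mm
maximum Feret diameter; α = 0.05.

## Segmentation

`global_threshold` is plain Otsu with strict `>` comparison (a boundary
intensity exactly at the threshold is background); a constant volume
yields an empty mask with a warning. Otsu's bimodal assumption fails on
realistic cores, which carry *three* intensity populations (formalin,
soft tissue, calcification) — it then separates background from tissue
and floods the core. The default method is therefore
`local_adaptive_threshold`, a seeded local-mean hysteresis:

* a global **floor** — the top boundary of a 3-class multi-Otsu split,
  falling back to plain Otsu on bimodal data — isolates the calcified
  intensity range;
* **candidates** exceed the floor *and* `(1 − f)` × the local mean in a
  cubic window (radius 5 voxels, offset fraction `f` = 0.15 by default);
* **seeds** additionally exceed `(1 + f)` × the local mean (locally
  conspicuous voxels);
* the mask grows from seeds by 26-neighbour accretion through the
  candidate set to a fixpoint (≤ 50 iterations; non-convergence is an
  error). The result is a superset of the seeds and the operator is
  idempotent on a binary rendering of its own output.

The local term trims partial-volume skirts near bright objects, and the
multi-Otsu floor sits below dim calcifications that plain Otsu loses
under cupping-like intensity drift, so those are recovered. Window
radius, offset and iteration cap are config values, not measurements;
they were chosen once and are logged with every run.

Connectivity defaults to 26 (face + edge + corner), with 6 available;
labels are ordered by decreasing voxel count, ties broken by scan order,
so runs are deterministic. Exclusion rules: objects whose maximum Feret
diameter (largest pairwise distance between voxel centres of the object's
convex hull) exceeds 1 mm are macrocalcifications — removed and reported;
objects of ≤ 2 voxels are sub-resolution — kept in the object count
Obj.N but excluded from per-object morphometry, and both counts are
reported. This reconciles subject-level totals with per-class counts in
the reference tables (e.g. 414 malignant objects of which 318 are small
when the 56 sub-resolution objects are included).

## Morphometry

**Meshing.** Each object's bounding subgrid is padded by two background
voxels and meshed by marching cubes at iso-level 0.5, guaranteeing a
closed, consistently oriented surface regardless of position in the
volume. The binary indicator is first smoothed by a Gaussian of σ = 0.5
voxel: marching cubes on raw binary data overestimates surface area by
~8–9 % (staircase bias); the light smoothing brings the sphere-surface
error under 5 % while moving enclosed volume by ~0.1 %. Structures thin
enough that smoothing would erode them (> 30 % of object voxels fall
below the iso-level) are meshed from the raw binary grid instead.

**Obj.V** is the signed volume of the closed mesh (divergence theorem);
an inside-out mesh is sign-corrected with a warning, an open mesh is an
error. **Obj.S** is the summed triangle area of the same mesh — taking
surface and volume from one representation keeps Obj.S/Obj.V
self-consistent. Voxel-face surface area was rejected: it overestimates
by tens of percent.

**St.Th** is Hildebrand–Rüegsegger local thickness. With `EDT(c)` the
Euclidean distance from object voxel c to the nearest background voxel
centre (volume border padded as background), the maximal inscribed
sphere at c has radius `ρ_c = EDT(c) − 0.5` (the object boundary lies
halfway between foreground and background centres), and covers voxel p
when `|p − c| ≤ EDT(c)` (p's cube intersects the sphere). Then
`τ(p) = 2 · max{ρ_c : |p − c| ≤ EDT(c)}`, computed by painting spheres
in decreasing-radius order, and St.Th is the volume-weighted mean of τ
over object voxels. Consequences: a 1-voxel object has τ = 1 voxel, a
radius-r rod ≈ 2r, a t-voxel plate ≈ t, a d-voxel sphere within ~1 voxel
of d (a systematic ≈ −1 voxel bias at coarse resolution; exact lattice
ties can put the sphere error at exactly 1.0 voxel). The test suite holds
the implementation to *exact* agreement with an exhaustive
sphere-fitting oracle on random 12³ masks.

**SMI** = 6 · V · S′ / S², with S′ estimated by displacing every vertex
by ε along its outward vertex normal and recomputing the area:
S′ ≈ (S(ε) − S)/ε, ε = 10⁻³ × mean edge length (tying ε to edge length
makes the estimate scale-invariant). Closed forms give exactly 4 / 3 / 0
for the ideal sphere / infinite rod / infinite plate. Values are
reported unclamped; concave structures may legitimately go negative.
Note that *finite* archetypes do not reach the ideal limits: a finite
cylinder of length L and radius r has SMI = 3L(L + 2r)/(L + r)² < 3, and
a 1 : 6 : 6 box has SMI ≈ 1 — only strongly anisotropic plates approach 0.
Voxelized spheres at r ≥ 10 voxels measure ≈ 3.7.

Convergence behaviour on voxelized spheres (radii 5/10/20 voxels):
volume error decreases monotonically (9 % → 1.7 % → 0.6 %) and thickness
error is non-increasing, but surface error is bias-dominated rather than
monotone (the staircase bias and the smoothing correction partially
cancel, differently at each radius); it stays below 5 % at working
resolutions. Tests assert exactly that.

## Statistics

Parameters are first averaged per subject over measurable (> 2 voxel)
objects; zero measurable objects yield missing values, never zeros.
Mean ± SD uses the n − 1 denominator, which reproduces the reference
cohort's summary cells at printed precision. One published cell (benign
SMI, "3.02 ± 0.11") is internally inconsistent with its own per-subject
values, which imply 3.15 ± 0.32; the tests assert what the data imply
and flag the cell.

Group comparisons gate on a Lilliefors-corrected one-sample KS normality
test per group (table-based p; n ≥ 4 required, smaller groups fall back
to the non-parametric branch): both pass → pooled-variance two-sided
t-test, else Mann–Whitney U with mid-ranks and the tie-corrected
asymptotic two-sided p. The paired expert-vs-automated comparison
aggregates the six readings per subject (mean by default; per-reader and
per-session aggregations are available) and applies the Wilcoxon
signed-rank test, asymptotic normal p without continuity correction,
zero differences dropped. Bland–Altman limits are mean difference ±
2 sample SD. Three count-ratio estimators (through-origin slope Σxy/Σx²,
OLS slope, ratio of totals Σy/Σx) are computed with normal-theory 95 %
CIs and reported separately — on these skewed counts they range from
0.15 to 0.41 and do not estimate the same quantity, so no single "ratio"
is privileged. No multiple-testing correction is applied; each parameter
is tested independently at α = 0.05 and every report says so.

## Synthetic phantoms

The generator emulates a reconstructed biopsy core: a soft-tissue
cylinder (3 mm × 23 mm by default) in formalin background with
high-intensity calcifications, then isotropic Gaussian blur (a
point-spread stand-in; the true acquisition blur is not characterised)
and additive Gaussian intensity noise (reconstructed-domain phantom;
Poisson projection noise is out of scope). Default intensities 50 / 90 /
200 on an 8-bit scale are arbitrary but fixed; no acceptance check
depends on a particular contrast value.

Voxelization uses voxel-centre inclusion — simple and oracle-checkable;
partial volume comes from the blur stage. Shapes smaller than half a
voxel rasterize to the single voxel containing their centre so
sub-resolution calcifications remain countable. Morphology stand-ins:
"teacup" = spherical-cap shell, "popcorn" = union of 3–8 overlapping
spheres, "V-branch" = two capsules sharing an endpoint.

Cohorts mirror the reference contrast — benign cores: fewer (mean 36.6
per subject), larger (log-normal mean 0.0159 mm³) objects; malignant:
more (mean 69.0), smaller (0.0078 mm³) — with gamma-Poisson counts
(dispersion k = 3) and σ_log = 1.5, values taken from the reference
per-subject table. Placement is rejection sampling with bounding-sphere
separation; infeasible draws are periodically redrawn, so object sizes
are implicitly conditioned on feasibility within the remaining space,
and a genuinely full core raises after a bounded attempt budget. A
subject-level sampler (`sample_subject_summaries`) draws per-subject
parameter means directly from the reference group distributions for
statistical power studies where rendering volumes adds nothing.

What passing phantom tests show: the pipeline recovers known geometry,
counts and group contrasts under controlled blur/noise. What they do not
show: performance on real tissue texture, beam hardening, ring
artifacts, touching calcifications (no watershed splitting is
implemented), or any diagnostic claim.

## Problem sizes and determinism

Tests and examples run cohorts at 70–100 μm voxels and shorter cores so
the whole suite completes in a few minutes on one CPU; the analysis
itself is resolution-agnostic and the fixed thresholds are expressed in
mm. All randomness flows through explicit integer seeds; identical
config + seed reproduces every output table byte for byte, and each run
directory's manifest records config hash, seed and package version.

## Known limitations

* Mesh-based Obj.S carries the smoothing/staircase bias discussed above;
  whether the original commercial tool used mesh- or voxel-face surfaces
  is not documented, so absolute Obj.S values may differ between tools.
* St.Th has a ≈ −1 voxel discretization bias; at 35 μm this is small
  relative to the 0.19–0.26 mm thicknesses of interest.
* The local-adaptive threshold's window and offset are design defaults,
  not fitted to scanner data.
* Sub-voxel objects depend on the blur/noise realization to be detected
  at all; counts at the resolution limit are inherently unstable.
* The reader-count fixtures are printed summaries of the original study;
  per-subject raw images are not available, so image-level claims rest
  entirely on the synthetic phantoms.
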