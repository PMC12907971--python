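# Methods

This note documents the measurement model, the synthetic phantom, the
numerical choices, and the limitations of `calvapit`.

## Measurement model

A resorption pit is measured as the volume of its *morphological fill*:
the difference between a reconstructed "intact" plate and the observed
bone.  The pipeline is deterministic given the volume and its parameters.

**Grid conventions.** All grids are `(z, y, x)`, isotropic voxels of edge
`a` μm, voxel centers at `index · a`.  The outer calvarial surface faces
`z = 0`.  The only unit conversion in the package is
`volume = voxel count · a³`.  Anisotropic input is rejected, not resampled.

**Denoising (σ_d, default a/2 μm).**  The volume is Gaussian-smoothed
before thresholding.  i.i.d. voxel noise displaces the thresholded surface
by roughly `σ_noise / g` per voxel (edge gradient `g`); without smoothing
this roughness makes the closing step emit dozens of thin spurious "fill"
sheets wherever the reference surface rides on noise bumps.  Half a voxel
of smoothing attenuates the noise ~2.4× at negligible cost in resolution.
A blurred interface also shifts the apparent surface of a *curved* cavity
inward by ≈ σ²/r (mean-curvature flow of the half-intensity level set), so
σ_d should not be made large: at σ_d = 1 voxel the smallest default
phantom pits already lose ~10–15% of their volume.  Set
`smoothing_sigma_um=0` for noise-free data.

**Thresholding.**  Global, inclusive (`I ≥ t` is bone).  `t` is either
supplied (the operator's "all bone picked up, pits well defined" value) or
computed by Otsu's criterion (maximal between-class variance over a
256-bin histogram).  Absolute intensities are scanner- and
reconstruction-dependent, so thresholds are always per-volume.  The
largest 26-connected component is kept, discarding detached debris.

**ROI.**  A cylinder along z centered at the user-supplied bregma voxel,
diameter 7 mm by default, full depth so both plate surfaces are included.
Distances are measured between voxel centers, boundary inclusive.

**Close and fill.**  Three mechanisms reconstruct the intact plate from
the bone mask `B ∧ ROI`:

1. *Ball closing*, radius `r_c` (default 150 μm = 20 voxels at 7.5 μm),
   computed by thresholding exact Euclidean distance transforms — provably
   identical to dilation-then-erosion with the discrete ball
   `{o : |o| ≤ r_c/a}` at O(n) cost independent of radius.  The volume is
   padded with background by the ball radius so border behaviour is as if
   empty space extended outward.
2. *Cavity filling*: background regions not 6-connected to the outside are
   set to bone (internal voids).
3. *Lid filling*: per-column outer and inner surface maps
   `z_t(y,x) = min{z : bone}` and `z_b(y,x) = max{z : bone}` are
   regularized with a flat disc of radius `r_c` — grayscale opening for
   `z_t`, closing for `z_b` — and each column is filled between the lidded
   surfaces.

The lid fill is what makes wide pits measurable.  A rolling ball alone
cannot reproduce the intended "filled" reference: a ball with radius below
the pit's carving radius rolls into the cavity and fills nothing, and a
larger ball resting on the opening rim of radius `a_o` sags by
`r_c − √(r_c² − a_o²)`, losing 7–40% of a spherical-cap pit's volume for
any affordable radius (measured on the phantom).  A flat structuring
element, by contrast, preserves linear ramps exactly and follows a plate
of curvature radius `R_p` to within `r_c²/(2 R_p)` (≈ 0.3 voxel for the
phantom dome), so the lid sits at the level of the surrounding surface.
The choice of `r_c` then only needs to exceed the widest expected pit
*opening* radius (120 μm in the default phantom) and to stay well below
the separation between defects.  A per-slice 2D hole fill was considered
and rejected: it loses the tilted mouth layer of each pit and fills a
spurious lens under the curved inner surface.

**Subtraction and labeling.**  Pit fills are `F ∧ ¬B ∧ ROI`; 26-connected
components with volume ≥ `min_volume` (default 30 voxels ≈ 1.27 × 10⁴ μm³
at 7.5 μm — a noise floor well below any pit of interest) become
candidates, id'd 1..N by descending voxel count (ties by lexicographic
centroid).  Candidates touching the lateral ROI boundary are flagged and
kept.

**Surface classification and review.**  Each candidate is dilated by one
voxel and tested against the background connected to the `z=0` face
(outer) and to the `z=max` face (inner): outer only → resorption-pit
geometry; both → through-going channel; inner only / neither → inner
concavity / internal void.  The background used here is
`¬bone ∧ ¬(all candidate fills)` — removing the fills first is essential,
since an open vascular channel would otherwise connect the outer and inner
backgrounds into one component and make every candidate look
through-going.  The automatic review accepts exactly the outer class,
codifying the manual "resorption pit vs natural porosity" call; the
editable manifest allows a human override, supported by optional per-pit
orthogonal maximum-projection montages.  There is no operational
definition of natural porosity in the assay description; the outer-surface
rule is this package's codification, not an established criterion.

## Synthetic phantom

The phantom stands in for animal scans in all tests and acceptance runs.

| parameter | default | rationale |
|---|---|---|
| grid | 60 × 256 × 256 at 7.5 μm | 1.92 mm field, matches scan voxel size |
| plate thickness | 150 μm | juvenile mouse calvaria scale |
| dome sag | 40 μm across the field | mild curvature; real curvature untabulated |
| intensities | bone 200 / background 50 | arbitrary units |
| blur σ | 5 μm | partial-volume proxy (sub-voxel PSF) |
| noise sd | 15 | SNR ≈ 10 at the bone–background contrast |
| pits | 12 hemispherical caps, sphere radius 40–120 μm | cap volumes 0.13–3.6 × 10⁶ μm³ bracket the reported mean pit volumes (read as μm³ × 1000) |
| porosity | 6 through channels, radius 15 μm | vascular-channel scale |

Pits are carved as sphere–plate intersections from the outer surface
(depth `h` ≤ sphere radius `r`, never perforating); the analytic cap
volume `π h² (3r − h)/3` and the exact count of removed voxels are both
recorded as ground truth.  Channels are z-aligned cylinders through the
plate.  Defects whose bounding spheres intersect are rejected so per-pit
truths stay unambiguous.  Layout: a jittered 4 × 3 grid with ≥ ~200 μm of
intact surface between pit rims — fills can never extend beyond a pit's
own opening, so disjoint openings with a bone strip between them suffice
for unambiguous counting.  Blur is applied to the clean plate, then i.i.d.
Gaussian noise; everything is reproducible from the spec + seed.

What the phantom does *not* model: sutures, beam hardening and ring
artifacts, intensity inhomogeneity, correlated noise, irregular pit
shapes, TRAP-staining appearance.  Passing the recovery tests therefore
demonstrates the correctness of the geometry pipeline under idealized
image formation, not robustness to scanner physics; on real scans the
operator threshold and the review step absorb those effects.

Measured on the default phantom over 10 seeds (all-defaults analysis):
12/12 pits confirmed and 6/6 channels rejected at every seed, per-pit
volume within 8.3% of voxelized truth, summed volume within 4%, and zero
confirmed pits on a defect-free plate.  The residual underestimate is the
blur-induced inward surface shift described above.

## Statistics

* **Effect sizes** — fold change `μ₁/μ₂` and percent decrease
  `100(μ_ref − μ_t)/μ_ref`, reported at 1 decimal place in summaries.
* **Two-way ANOVA** (treatment × sex, with interaction) — balanced designs
  use the classical sums-of-squares decomposition (computed in-package and
  cross-checked against statsmodels); unbalanced designs use Type II sums
  of squares via statsmodels, which is well-defined without ordering
  assumptions and coincides with the classical decomposition when
  balanced.  Zero residual variance is an error, never a NaN.
* **Tukey HSD** — all-pairs comparisons with Tukey–Kramer standard errors
  and p-values from `scipy.stats.studentized_range`.
* **Sex contrasts** — within-treatment M−F cell-mean comparisons, adjusted
  by the studentized range over the full family of treatment × sex cell
  means (the assay's contrast machinery is unstated; this is a
  conservative, standard choice).
* **Sample size** — smallest per-group `n` whose exact noncentral-t power
  for a two-sided two-sample t-test reaches the target (default α = 0.05,
  power 0.8).  The assay's published sample-size table cannot be
  recomputed because the group standard deviations are never reported;
  tests instead verify self-consistency by Monte-Carlo power simulation
  (the returned n achieves ≥ 0.8, n−1 does not).

## Numerical choices and degenerate inputs

* Threshold semantics inclusive (`≥ t`); Otsu ties resolved by the
  histogram implementation, with tests asserting the achieved
  between-class variance rather than a tie order.
* Foreground connectivity 26, background/fill connectivity 6 (the standard
  complementary pair); largest-component ties go to the earliest raster
  first-voxel.
* Results CSVs are written with `%.17g` and parsed with round-trip float
  precision, so write→read is bit-exact and reruns are byte-identical.
* Degenerate inputs error loudly: constant volumes (Otsu), empty masks,
  sub-voxel closing radii, empty ANOVA cells, zero residual variance,
  perforating or overlapping phantom defects.

## Problem sizes

Test and acceptance runs use the 60 × 256 × 256 default phantom
(~3.9 × 10⁶ voxels, ~4 s per analysis), 10 seeds for recovery, 10⁴ null
replicates for the ANOVA type-I-error check, and ≥ 1.5 × 10⁵ Monte-Carlo
replicates per power evaluation — sizes at which every Monte-Carlo
tolerance in the suite is several standard errors wide.
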