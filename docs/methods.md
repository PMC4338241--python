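# Methods

## The phantom model

Each synthetic "patient" is a union of rigid analytic pieces in a
right-handed mm frame (x left→right, y posterior→anterior, z
inferior→superior, origin at the volume corner):

* **Cranial-base shelf** — two stacked plates with a spherical sella
  depression and five hemispherical relief bumps. The relief matters: a
  featureless plate admits in-plane sliding, which would make registration
  on the cranial base artificially ill-posed.
* **Foramen magnum rim** — a thick-walled annulus; its posterior outer wall
  carries the two foramen fiducial patches and the ~1.0 × 1.5 cm posterior
  rim reference region.
* **Zygomatic arches** — slender arc tubes (radius 30 mm, ~95° span) with a
  linear radius taper (4.0 → 2.5 mm), a ±1.5 mm vertical undulation of the
  tube axis (three cycles) and two bulges per side. An unadorned circular
  arc tube is a torus segment, and sliding along a torus is a rigid
  self-isometry: ICP restricted to such an arch would be ill-posed and a
  trimmed fit can silently slide. The taper, undulation and bulges give the
  arch the irregularity real arches have, making the single-arch technique
  well-posed (and honestly bad, rather than degenerate).
* **Maxilla** — two hemimaxilla boxes meeting at the midline, carrying
  incisor prongs and a cylindrical piriform notch; the notch rim provides
  the piriform measurement points.
* **Orbital-rim bars and a mastoid prong** carry the landmarks used by the
  three-point technique and the coarse (FH-plane-like) initial alignment.

**Treatment** (rapid maxillary expansion) is piecewise-rigid: each
hemimaxilla translates laterally by ±expansion/2 (default total 9.0 mm ≈
0.6 mm/day × 15 days) and each arch rotates outward by `zygoma_bend_deg`
(default 2.0°) about a vertical axis through its posterior root. Rigid
pieces give *exact* landmark ground truth; elastic deformation would not
change which structures are form-stable, only blur the truth. The cranial
base, foramen ring, orbital bars and mastoid never move — by construction,
not approximately. The 2.0° bend displaces mid-arch surface by ~1 mm,
chosen so that registration on the altered arch produces accuracy errors of
the order reported for single-arch superimposition (~1.5 mm at the fiducial
lever arms); it is a modelling choice, not a measured quantity.

**Rescan** (patient repositioning between acquisitions) samples a rigid
transform — rotation uniform in axis and in angle up to 5°, about the solid
centroid; translation direction uniform with magnitude up to 4 mm — and
applies it to the *analytic* solid before rasterisation. Re-rasterising
rather than resampling voxels keeps interpolation error out of the
registration error budget. Draws that would push the solid through the
2-voxel grid margin are rejected and redrawn.

## Rasterisation: the scanner model

Voxels are 0.8 mm isotropic by default. Intensities follow a **two-voxel
linear partial-volume ramp** of the exact signed distance to the solid
(background 0 HU, bone 1200 HU), which is what lets marching cubes place the
isosurface sub-voxel: on a 20 mm sphere the extracted area is within ~1.3%
of 4πr² and the maximal vertex error halves when the voxel size halves. A
strictly binary rasterisation (`partial_volume=False`) is retained for
contract tests; binary voxel data inflate marching-cubes surface area by
roughly 9% and are not a realistic CT edge model.

Two noise processes are added per scan:

* **white HU noise**, sd 25 HU (typical CT noise at diagnostic dose);
* a **smooth bias field** — a Gaussian random field with 60 mm correlation
  length scaled to sd 120 HU — standing in for scan-specific beam-hardening
  and calibration drift. Through the edge ramp it shifts reconstructed
  surfaces locally by ~0.16 mm (1 sd). Its correlation length is comparable
  to the reference-region extent, so a registration can absorb the field
  *inside* its own reference region but inherits the unabsorbed field at
  distant structures. This is the mechanism that separates the techniques:
  the gold standard pins both the cranial base and the foramen, while the
  cranial-base-only registration extrapolates ~60 mm to the foramen
  fiducials. The amplitude was calibrated so the gold-standard accuracy
  floor sits in the reported 0.04–0.17 mm range of such workflows.

## Operator model

Human variability enters as (a) isotropic Gaussian jitter (default sd
0.75 mm) on every picked landmark, re-projected onto the mesh surface, and
(b) a bounded perturbation (±20%) of the selected region extent. The jitter
sd was calibrated so the three-point technique's duplicate-control error
matches the level reported for human operators (median ≈ 0.5 mm); region
selection need not be identical between the two models, matching the
workflow being emulated.

## Registration engine

* **Coarse alignment** builds an orthonormal frame from the infraorbital
  line and the plane through the landmark triple on each model and maps one
  frame onto the other (exact for congruent noiseless landmarks).
* **Robust ICP** draws seeded area-weighted samples on the moving region
  (default 20 000 library-side, 3 000 in the pipeline — enough that
  sampling error is far below the scan-noise floor), finds *exact* closest
  points on the masked fixed surface (KD-tree-accelerated point-to-triangle
  queries, verified against exhaustive scans; ties break to the lowest face
  id), rejects pairs hitting the mask or mesh boundary, trims the worst 10%
  by distance, and solves the small-angle linearised point-to-plane least
  squares about the pair centroid, composing the increment by an exact
  rotation exponential. Step halving guarantees the trimmed RMS never
  increases.
* **Convergence.** The engine iterates to stationarity (|ΔRMS| < 1e-6 mm,
  or RMS < 1e-7 mm, or 100 iterations). The deviation tolerance
  (default 0.3 mm, matching "at least 0.3 mm" registration-precision
  settings of commercial engines) certifies the `converged` flag rather
  than stopping iteration: stopping at 0.3 mm would freeze duplicate-model
  registrations two orders of magnitude short of what the software being
  emulated achieves (D < 0.001 mm). Samples are drawn once per registration
  so the RMS history is comparable across iterations.
* **Trimming** is a fixed fraction (0.1) rather than adaptive; it is enough
  to absorb 5% gross outlier faces without moving the fit (verified to
  < 0.05 mm translation change).

## Measurement

Accuracy patches are geodesic 5 mm² face sets grown around the transformed
fiducial landmark on the registered post-treatment mesh; each patch is
compared with the reference mesh by ≥ 200 area-weighted samples (mean
Euclidean closest-point distance D; signed per-axis means Dx/Dy/Dz with
positive = result outside the reference surface). Samples with no
correspondence within 10 mm are dropped (the "grey zone" behaviour of
deviation colour maps); a patch with no correspondence at all is an error.
Landmark displacement maps the post-treatment point through the recovered
transform and subtracts the pre-treatment point.

## Statistics

The crossed design (technique fixed, operator random, session fixed,
patients as replicates) is analysed by distance-based permutational MANOVA:
responses floored at 1e-4 mm (duplicate controls are numerically zero) and
log10-transformed, Euclidean distances, sums of squares partitioned by
orthonormal Helmert-contrast bases (equivalent to Gower-matrix projection;
a Gower eigen-route supports the semimetric Bray–Curtis option), and
pseudo-F with expected-mean-square denominators: an effect without the
random factor is tested against its interaction with the random factor,
effects containing it against the residual. p-values use unrestricted
permutation of raw data (default 9999); a moment-matched log-Pearson-III
approximation of the permutation distribution supplies the Monte Carlo
p-value used when few unique permutations exist. All-equal responses yield
an explicitly undefined test, not p = 0. PERMDISP uses distances to group
spatial medians (Weiszfeld) with an ANOVA F and label permutation. Pairwise
technique contrasts are pooled-variance permutation t-tests,
Bonferroni-multiplied by the number of pairs and capped at 1. Bland–Altman
summaries report median / IQR / exact binomial 95% CI of the median of
paired differences against the gold standard; quartiles use the (n+1)p
interpolation rule, which makes small-sample summaries hand-checkable.

## Problem sizes

The default pipeline registers ~57 000-face meshes (under the 100 000
polygon budget) with 3 000 ICP samples. The test suite exercises the study
at these sizes where the claim depends on them (duplicate control,
transform recovery over 20 phantoms, an 8-patient ranking cohort) and at a
1.6 mm-voxel quarter-resolution phantom elsewhere; these sizes are the
package's own defaults for a desk-scale reproduction.

## What passing tests do and do not show

The phantom reproduces the *structure* of the evaluation: exactly
form-stable references, treatment-altered arches, partial-volume edges,
scan noise, smooth scan-level artifacts, operator pick variability, and the
full measurement chain. It does not model real anatomy's shape complexity,
bone-density heterogeneity, metal artifacts, genuine biological remodelling
of "stable" structures, or segmentation-threshold disagreement between
scans — all of which add error in clinical data. Passing tests therefore
validate the algorithms and the relative behaviour of the techniques
(ordering, duplicate-control exactness, transform recovery), not absolute
clinical error levels. Known limitations: the arch-region descriptor covers
only the mid-arch; piecewise-rigid treatment makes hemimaxilla motion
perfectly rigid; the bias-field model is stationary and Gaussian; and the
mixed-model denominator convention, while the classical one, is itself a
modelling choice for permutation tests.
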