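# Methods

`rtpseudo` implements and stress-tests a pragmatic route to MRI-based
brain radiotherapy planning: instead of synthesizing CT numbers from MR
intensities, a *prior diagnostic CT* (DCT) of the same patient is rigidly
registered into the planning geometry and its outer body is corrected to
match the planning scan. The package provides the full loop — synthetic
scan generation, pseudo-CT synthesis, planning-grade dose computation, and
dosimetric verification — so the method's error budget can be measured
end to end without patient data.

## The pseudo-CT model

The central assumption is anatomical: in a fully grown adult head, all
differences between two scan sessions are confined to the outer soft
tissue (weight change, immobilization equipment, scan coverage), while
skull and brain are rigid and stable. Under that assumption a rigid
6-DOF transform aligns the interior exactly, and only the outer-body
disagreement needs repair:

* **tissue excess** — voxels inside the aligned DCT body but outside the
  reference (planning CT or MR) body — is overwritten with air,
  −1000 HU;
* **tissue deficiency** — voxels inside the reference body but outside
  the DCT body — is overwritten with bulk soft tissue, 0 HU;
* **unscanned anatomy** — reference-body voxels the DCT never covered
  (thick-slice diagnostic scans often stop above the skull base) — is
  treated as deficiency, 0 HU, with no attempt to recover true density.

Everything inside both bodies is copied unchanged. The resulting volume
has the diagnostic scan's interior HU and the planning scan's outer
shape, which is the method's defining contract, and it carries no
out-of-scan sentinel so it is directly dose-calculable. Precedence when
rules overlap: deficiency rules dominate (a reference-body voxel that is
both unscanned and outside the DCT body gets 0 HU); sentinels outside
both bodies become air. These precedences are a declared design choice —
under the rigidity assumption the ambiguous cases cannot reach interior
anatomy.

Body contours are delineated by pixel density: largest connected
component above a threshold (default −400 HU for CT; configurable
intensity threshold for MR in MRI-only mode), hole-filled in 3D and
slice-wise so internal air (sinuses) stays inside the body. −400 HU
separates air from tissue at every noise level the phantom generates and
is insensitive to the exact value within roughly ±300 HU.

## Registration

Rigid registration is multi-resolution (shrink factors 4/2/1, smoothing
2/1/0 mm), geometric-center initialized, and seeded so results are
reproducible. Two modes:

* `bone-CTCT` — mean-squared HU difference restricted to fixed-image
  voxels above 300 HU. The skull is the shared rigid anchor, so matching
  bone is the right criterion for CT–CT pairs; 300 HU cleanly separates
  skull from soft tissue.
* `intermodal` — Mattes mutual information (50 bins) over the whole
  head, for CT↔MR pairs.

The optimizer is regular-step gradient descent (learning rate 1, minimum
step 1e−6, ≤500 iterations, physical-shift scaling, 25% regular sampling
with a fixed seed). On the noisy phantom, random transforms up to 15° /
20 mm are recovered within 1° / 1 mm (typically ≪0.1 mm in translation);
tightening the minimum step below 1e−6 no longer changes the result at
the grid resolutions used here.

When moving and fixed volumes are the same grid with identical voxels,
registration returns the exact identity: the bone-mask metric is already
zero and optimization could only wander. This makes the zero-perturbation
limit of the whole pipeline exactly reproducible (all deltas identically
zero), which is the cleanest possible self-test of the verification
protocol.

In the full workflow the planning MR is first rigidly *reoriented* into
the planning-CT frame (geometry transformed, no resampling), and the DCT
is then registered either directly to the planning CT in bone mode (the
default — the reoriented MR shares the PCT frame, so the transform is the
same) or to the MR with mutual information. In MRI-only mode the MR frame
is the reference, the fusion step is skipped, and the reference body is
contoured on the MR.

## The synthetic head

The phantom is a nested-ellipsoid adult head: scalp (40 HU, 6 mm), skull
(700 HU, 6 mm), brain (30 HU), spherical CSF ventricle (10 HU, 16 mm
radius), semi-axes 70/85/90 mm, on a 2 mm isotropic ground-truth grid
with Gaussian noise (σ = 10 HU, 15 MR units). The MR table inverts bone
contrast (skull dark, CSF bright) as on T1 images, so intermodal
registration faces a genuine contrast inversion. HU values are standard
textbook magnitudes; nothing downstream depends on their exact values
beyond air/tissue/bone ordering.

Three PTV spheres (16 mm radius, ≈17 cc, in the volume range of adult
brain lesions) probe the heterogeneity extremes: a deep ordinary site, a
site abutting the ventricle (lowest density), and a site abutting the
skull (highest density).

Acquisition simulation reproduces the features that make diagnostic
scans non-ideal for planning: gantry tilt about the left–right axis
(0–23.3°, the clinical lens-sparing range), thick slices (5 mm DCT vs 1.25 mm planning CT /
2.5 mm MR), and a limited inferior extent (default 30 mm cut) that
creates a genuinely unscanned region. Slice-axis box averaging emulates
the finite slice sensitivity profile before linear resampling. The
body change between sessions is a uniform morphological dilation/erosion
of the scalp surface (EDT-based, with a half-voxel surface offset so
sub-voxel changes behave sensibly); interior labels are never touched,
and an erosion deeper than the scalp raises an error rather than
silently violating the rigidity assumption.

What the phantom does *not* emulate: real soft-tissue texture, MR
geometric distortion and bias fields, contrast-agent enhancement,
posture-dependent deformation, or bone-density variation. Passing tests
therefore demonstrate the correctness and self-consistency of the
algorithmic chain under the stated assumptions, not clinical accuracy on
patients.

## Dose engine

A deliberately simple primary-photon model stands in for a commercial
convolution algorithm:

    D(p) = w · exp(−μ · d_eff(p)) · (SAD / r(p))² · f_lat(p)

with μ = 0.05 cm⁻¹ (6 MV primary magnitude), SAD = 1000 mm, and a
separable Gaussian-penumbra aperture (σ = 3 mm at the isocenter plane).
`d_eff` is the radiological (water-equivalent) depth: the line integral
of relative electron density from the patient surface. HU converts to
density through a piecewise-linear two-segment calibration
(−1000 → 0.0, 0 → 1.0, 1500 → 1.85, clamped). Scatter, electron
transport, and MLC modelling are out of scope: the engine's job is to be
deterministic, desk-scale, and *heterogeneity-sensitive* — replacing the
skull by water changes the dose 2 cm downstream by more than 1%, so any
density error the pseudo-CT introduces is visible in the verification
comparison.

Two depth implementations exist on purpose: a single-ray exact Siddon
integral (every voxel-boundary crossing contributes its exact segment)
used as the reference, and a vectorized fixed-step midpoint sampler
(1 mm steps from the volume-box entry, edge-extended interpolation to
match the Siddon box model) used for whole-volume dose. They agree to a
fraction of a voxel and the tests hold them against each other.

A plan is five square-field beams — four coplanar plus one couch-rotated
(non-coplanar) — with the isocenter at the PTV centroid and the field
covering the PTV extent plus an 8 mm margin. Any beam whose entry ray
crosses the unscanned region is rotated in gantry by the smallest
admissible 5° multiple, since HU in that region is assigned, not
measured. Beam weights start from equalized mean PTV contributions and
are multiplicatively reduced (≤50 iterations) until the maximum PTV dose
respects the 110% planning limit. The final global normalization uses
the descending order statistic at rank ⌈0.95 n⌉, which sets D95 = 100
exactly and makes V100% equal ⌈0.95 n⌉/n — within 0.1 percentage points
of 95.0 whenever the PTV holds ≥1000 dose-grid voxels (the default
2.5 mm dose grid and 17 cc PTV give n ≈ 1100). Dose is reported in
percent of prescription throughout; no absolute calibration is modelled.

Verification freezes the plan: the same beams, weights, and
normalization factor are re-applied to the reference CT resampled onto
the planning grid. Nothing is re-optimized or re-normalized, so every
difference between the two dose grids is attributable to the CT volumes.

## Evaluation

* **DVH** — cumulative, monotone non-increasing, 100% at level zero.
* **Plan metrics** — Min/Mean/Max PTV dose, V95%, V100%, and the
  conformity index CI = (volume receiving ≥100%) / (PTV volume), ideal
  1.0. (The inverse reading of CI would be ≤1; the ≥1-with-ideal-1
  convention is used because that is the form in which values like
  1.07 ± 0.04 are meaningful.)
* **Dose difference** — signed evaluated−reference map in percent points
  of prescription on the 10×10 cm coronal isocenter plane (configurable),
  with the pass rate at the 2% criterion.
* **Gamma** — global-normalization γ with 2%/1 mm criteria: exhaustive
  minimization over an interpolated sub-grid of the evaluated dose (step
  = distance criterion /10, search radius = 3× distance criterion, no
  pruning). The offset grid always contains the zero offset, so the γ
  pass rate can never fall below the dose-difference pass rate. An
  independent brute-force implementation (per-pixel loops, hand-rolled
  bilinear interpolation) is kept in the test suite and the engine must
  match it to 1e−6.

## Numerical choices and edge cases

* Out-of-scan voxels carry NaN, never a fake HU; every consumer either
  handles it (contouring treats it as air, correction eliminates it) or
  rejects it (density conversion, beam dose).
* Geometry is LPS millimeters, 0-based voxel-center indexing,
  `physical = origin + direction · (spacing ⊙ index)`; direction
  matrices must be proper rotations to 1e−6.
* Masks resample by nearest neighbour only, and stay strictly binary.
* Degenerate inputs raise typed errors: empty body, empty PTV, zero-length
  rays, no admissible beam angle, erosion through the scalp, registration
  without overlap or without bone voxels.
* Problem sizes: the default phantom uses a 2 mm truth grid, 2 mm
  in-plane scan resolution, and a 2.5 mm dose grid; the test suite runs
  a 2.5 mm compact variant of the same anatomy. These sizes keep every
  quantity stable to well within the tolerances asserted while remaining
  single-CPU friendly.

## Known limitations

* The dose model is primary-only; absolute dose levels and penumbra
  shapes are not clinically representative, only density-sensitivity is.
* Gamma analysis is 2D in-plane (the full-volume mode evaluates each
  plane with in-plane search, an upper bound on true 3D γ).
* The inter-scan body change is uniform; localized changes (surgical
  packing, asymmetric swelling) are representable only approximately by
  the correction scheme itself, not by the generator.
* CT truth and pseudo-CT share the same HU lookup table, so systematic
  scanner-calibration differences between diagnostic and planning CT
  scanners are not modelled.
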