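# Methods

## Coordinate conventions

All spatial quantities live in the magnet/patient frame with axes ordered
(AP, RL, SI), millimeters, isocenter at the origin: AP positive toward
posterior, RL positive toward left, SI positive toward superior (the bore
axis).  Voxel indices are 0-based; image geometry is a 4×4 voxel→mm
affine, which may permute axes (the simulator's coronal stacks store data
as (RL, SI, AP)).  NIfTI files written by the package carry this affine
directly (documented in the JSON sidecar); DICOM-like sidecars use the
LPS patient frame, converted at the boundary by the pure permutation
(AP, RL, SI) = (P, L, S).

## Gradient-coil model and nonlinearity tensor

Channel fields are expanded in real solid harmonics
`c·R^(1−n)·r^n P_n^m(cos θ){cos|sin}(mφ)` with unnormalized (Ferrers)
associated Legendre functions without the Condon–Shortley phase, polar
axis along SI, and reference radius R (default 250 mm).  In this basis
the n = 1 harmonics are exactly the Cartesian coordinates, so expressing
coefficients relative to each channel's linear term makes normalization
explicit: every channel has unit gradient at the isocenter and the tensor
**L**ᴹ(r) — the Jacobian of the three normalized fields, row *i* =
∇f_i — is the identity at the origin (enforced to 1e-9).

Harmonic polynomials and their gradients are generated symbolically
(sympy) once per model and evaluated as vectorized numpy closures; this
makes the tensor evaluation analytic rather than finite-difference (the
finite-difference oracle exists only in the tests).  Evaluating the
default model on the full 121³ 5-mm grid takes a few seconds; tests and
the validation suite use 10–20 mm grids, which for the low-degree fields
involved changes correctors by < 0.05% after trilinear resampling.

### The synthetic generic model

True vendor coefficients are proprietary and unpublished, so the default
generic model is a stand-in with the qualitative structure of a
horizontal-bore whole-body gradient set: per channel a dominant degree-3
term and a small degree-5 term (SI: −0.2 and +0.02; AP/RL: −0.08 and
+0.008 relative to the linear term).  The signs produce the classic bias
pattern — achieved gradient rolls off along the bore and piles up
transversally, hence C_av < 1 at superior offsets and > 1 in-plane — and
the amplitude was fixed a priori to give ≈ −21% direction-averaged
b-value bias at a 120 mm superior offset, i.e. a "substantial (> 10%)"
offset-position bias.  Any other model can be supplied as a plain-text
coefficient table.

## Scale-factor calibration

System-specific tensors are obtained by *value* scaling (not spatial
scaling): `L_ii = F_i (Lᴹ_ii − 1) + 1` on the diagonal and
`L_ij = F_i Lᴹ_ij` off the diagonal, where the off-diagonal scale is the
**row** channel's factor (the cross-term inherits the scale of the
channel that produces it; the choice between row and column is not
empirically constrained for an isotropic phantom).

`fit_scale_factors` is closed-form weighted least squares of
`y − 1 = F·(Lᴹ_ii − 1)` jointly over all profiles of a channel
(typically its SI and transverse cross-sections), with weights 1/sd² or
uniform when no sd is given.  A single scalar F per channel is fitted
even when the two cross-sections disagree; the disagreement then appears
in the reported uncertainty, which is the reduced-χ²-scaled standard
error divided by F.  Profiles whose generic-model signal never exceeds
1e-4 in |Lᴹ_ii − 1| are rejected as degenerate (no information about F).

Default synthetic calibration profiles run −150…150 mm in 25-mm steps
(13 points per cross-section), a realistic sampling for tube-phantom
channel characterization.  With 2% multiplicative Gaussian noise this
design predicts, from the WLS algebra alone, a median relative error of
≈ 3–5% for factors near (1, 1, 0.7) — consistent with the 3–7%
calibration uncertainty band the acceptance suite checks.

## Correctors

`C_k(r) = ‖(L u_k)(L u_k)ᵀ‖_F`, which for a rank-1 dyadic equals
|L(r)u_k|²; the identity is asserted against a brute-force Frobenius
evaluation in the tests.  Directions must arrive unit-normalized —
deviations beyond 1e-3 (DICOM rounding scale) are rejected rather than
silently renormalized.  `C_av` is the arithmetic mean over the schema;
for any orthonormal triad Σ_k |L u_k|² = ‖L‖²_F, so C_av is
schema-invariant (LAB vs the oblique triad agree to 1e-10), which is why
a single average corrector per system suffices for isotropic media.
Non-orthonormal schemas are computed with a warning and tagged "custom".
Resampling onto image geometry is trilinear (`scipy.ndimage`
`map_coordinates`, order 1); voxels outside the corrector FOV raise with
the offending extent.

## ADC pipeline

Repeated excitations are averaged arithmetically on magnitude images
(vendor-typical; Rician noise-floor bias is *not* corrected), then the
trace image is the geometric mean across the three directions —
algebraically identical to averaging log-intensities.  ADC is the
two-point log-trace difference between b = 0 and the highest shell
(intermediate shells are used only in the regression cross-check); voxels
with nonpositive intensities are masked, not raised.  Values outside
0.5–3.3 ×10⁻³ mm²/s are set to zero with the mask cleared; the clip is
idempotent and re-applied after correction.

`correct_intensities` implements the equivalent b-value route by
rescaling each direction's log-decay by 1/C_k (i.e. mapping the effective
b C_k back to nominal b).  For noiseless isotropic input this coincides
with `correct_adc` exactly (asserted to 1e-9); with noise the two routes
differ at the noise level because one averages decays before dividing by
C_av and the other divides per direction first.

Low-resolution acquisitions can be zero-fill interpolated in the
frequency domain (`zero_fill`), which preserves the original samples
exactly and shrinks the voxel spacing so physical coverage is unchanged.

## ROI statistics

Histograms use fixed 0.02-wide bins on 1–2.5 ×10⁻³ mm²/s.  The median is
taken on the raw in-ROI sample (independent of binning).  FWHM is the
distance between the outermost half-maximum crossings of the binned
counts with linear interpolation between bin centers, no smoothing by
default (an odd moving-average window is available); the outermost rule
makes the width span multi-modal, skewed bias-broadened histograms rather
than a single peak.  Degenerate (single-bin) histograms report one bin
width as a floor — consequently the protocol binning cannot report a
nonuniformity below ≈ 1% at ADC ≈ 2, and sub-percent uniformity claims
are evaluated with finer bins.

The exact Wilcoxon rank-sum test enumerates all C(n+m, n) group
assignments of the midranked pooled sample and doubles the smaller tail,
capped at 1; ties are therefore exact by construction.  Enumeration is
refused above 24 pooled observations unless the normal-approximation
fallback is requested.  Pearson R uses the t-transform p-value with n−2
degrees of freedom (scipy).  Cross-system medians use the standard
mean-of-central-values convention for even n.  The isocenter reference
ROI is a 30-mm cube (27 cm³, spanning 5 slices at 6-mm spacing) whose CI
is reported as 2·SD — for the noise-dominated Gaussian reference region
this is equivalent to the histogram FWHM description.

## Phantom simulator: what it emulates, and what it does not

The simulator states the validation world: a 17-cm sphere of uniform gel
(default true ADC 2.0 ×10⁻³ mm²/s at 20 °C, 2.5%/°C temperature
coefficient, bore temperatures 17–22 °C across the synthetic sites),
scanned coronally at the isocenter, at +120 mm superior, and at a
(−90, 0, +90) superior–anterior composite offset; b = 0/500/1000 s/mm²,
three-direction LAB or non-LAB schema, eight excitations, single-shot
protocol matrices, SNR 20 at b = 1000 by default (protocol floor "> 15").
GNL enters the forward model as b_eff = b·C_k(r) computed from the true
tensor; noise is Rician per excitation with σ set so the
excitation-averaged b = 1000 image hits the configured SNR; the in-plane
FOV stays fixed on the magnet (the phantom moves, the landmark does not).
Everything is deterministic under the configured seed, which is recorded
in every output sidecar.

Not modeled: EPI readout physics and geometric distortion (optional
apparent-position shift and a shim-like multiplicative perturbation can
inject small non-GNL bias), coil eddy currents, agar relaxometry, the
Rician noise floor inside the ADC fit.  A green round-trip test therefore
establishes that the correction chain inverts the stated forward model —
it does not certify performance against distortion-dominated real data,
where residual errors at the few-percent level are expected.

The six-system validation suite pairs the bundled per-system channel
scale factors with this simulator, clipping them to [0.45, 2.0]: the
published-style factors were fitted against a much weaker generic model,
and applied raw to the deliberately stronger synthetic model the extremes
would drive the achieved gradient through zero inside the FOV.

## Bundled multicenter summary table

`gnlcorr.datasets` ships the per-system summary statistics of a
six-scanner multicenter agar-phantom validation study (ROI medians, FWHM,
centers, volumes for two offset positions and the reference scan, plus
acquisition parameters).  `summarize_systems` recomputes every
study-level figure of merit from those cells alone — rank-sum p-values,
bias and nonuniformity medians, fold reductions, Pearson correlations.
Statistics recomputed from the rounded table cells can differ from
unrounded-data values in the last digit (e.g. a pre-correction
median-with-reference correlation of 0.73 vs a reported 0.72); the test
suite pins the recomputable values and asserts only the significance
conclusions where rounding prevents exact reproduction.

## Known limitations

* Single scalar F per channel cannot capture systems whose SI and
  transverse nonlinearity scale differently; the misfit is only reported,
  not modeled.
* The corrector assumes isotropic media; no b-matrix rotation for
  anisotropic (DTI) correction.
* No EPI distortion correction: correction factors are applied at
  apparent, not true, voxel locations.
* Exact rank-sum enumeration cost grows as C(n+m, n); beyond 24 pooled
  observations only the normal approximation is offered.
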