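# gnlcorr

Retrospective gradient-nonlinearity (GNL) bias correction for quantitative
diffusion-weighted MRI (DWI).

## The problem

The apparent diffusion coefficient (ADC) is a quantitative imaging
biomarker: tissue diffusivity estimated from the monoexponential decay of
the DWI signal with diffusion weighting *b*.  Real gradient coils are not
perfectly linear — away from the magnet isocenter the achieved gradient
deviates from the nominal one, so the achieved *b*-value (quadratic in
gradient amplitude) is spatially biased.  The resulting ADC errors are
deterministic and system-specific: they grow roughly quadratically with
distance from the isocenter, differ between scanner models, shift and
artificially broaden ADC histograms from large regions of interest, and
inflate cross-site variability in multicenter trials.

Because the bias is static for a given gradient system, it can be removed
retrospectively by a central analysis site that never sees the scanned
object: characterize each system once with a phantom, precompute a 3D
corrector map, and divide every subsequent ADC map by it.  `gnlcorr`
implements that workflow end to end, for physicists and trial
methodologists who need to harmonize ADC measurements across scanners.

## The model

* **Nonlinearity tensor.**  Each gradient channel *i* ∈ {AP, RL, SI}
  produces a field whose spatial profile is expanded in real solid
  harmonics `r^n P_n^m(cos θ) {cos, sin}(mφ)`; the 3×3 dimensionless
  tensor **L**(**r**) is the Jacobian of the three normalized channel
  fields, with **L**(0) = **I** at the isocenter.
* **System calibration.**  A generic coil model **L**ᴹ is value-rescaled
  per channel with factors *F_i* fitted by weighted least squares to 1D
  phantom profiles (measured directional ADC / 1.1×10⁻³ mm²/s ice-water
  reference):
  `L_ii = F_i (Lᴹ_ii − 1) + 1`, `L_ij = F_i Lᴹ_ij`.
* **Corrector maps.**  For a diffusion direction **u**_k the *b*-value
  bias is the Frobenius norm of the achieved-direction dyadic,
  `C_k(r) = ‖(L u_k)(L u_k)ᵀ‖_F = |L(r) u_k|²`; for an isotropic medium
  and an orthonormal three-direction schema the direction average
  `C_av = mean_k C_k` is schema-invariant.
* **Correction.**  `ADC = [ln S_trace(0) − ln S_trace(b_high)] / b_high`
  from geometric-mean (trace) DWI, clipped to the plausible 0.5–3.3
  ×10⁻³ mm²/s window, then `ADC_c(r) = ADC(r) / C_av(r)`.  An equivalent
  per-direction intensity/b-value route (`b → b·C_k`) is provided.
* **Figures of merit.**  ROI histogram median and FWHM (0.02-wide bins on
  1–2.5), nonuniformity = FWHM/median, percent bias against the isocenter
  reference scan, cross-system range-to-median ratios, exact Wilcoxon
  rank-sum tests and Pearson correlations.

Since vendor harmonic coefficients are proprietary, the package ships a
synthetic generic model with the horizontal-bore structure (gradient
roll-off along the bore, pile-up transversally) plus a spherical-phantom
simulator (17-cm agar sphere, three bore positions, Rician noise,
temperature-dependent diffusivity) so the whole chain is testable with
known ground truth.

## Worked example

```python
import gnlcorr as g
from gnlcorr.workflow import section_roi

model   = g.default_generic_model()
generic = g.evaluate_generic_tensor(model, g.GridSpec.centered(600.0, 10.0))

# system-specific tensor and direction-averaged corrector
F      = g.ChannelScaleFactors(1.2, 1.1, 0.7)
system = g.rescale_tensor(generic, F)
c_av   = g.schema_average_corrector(system, g.DirectionSchema.lab())

# synthetic phantom scanned 120 mm superior of the isocenter
cfg  = g.SimulationConfig(snr_b1000=20.0, seed=1)
scan = g.simulate_series(cfg, system)[2]
adc  = g.compute_adc(scan.series)
adc_c = g.correct_adc(adc, g.resample_to_image(c_av, scan.series.geometry))

roi = section_roi(scan)
pre, post = g.roi_histogram(adc, roi), g.roi_histogram(adc_c, roi)
```

Output (ADC in 10⁻³ mm²/s):

```
C_av at +120 mm SI: 0.791        # b-value under-weighted superiorly
C_av at +120 mm RL: 1.124        # and over-weighted transversally
pre : median 1.59, FWHM 0.67, nonuniformity 42.1%
post: median 1.99, FWHM 0.10, nonuniformity 4.8%
true ADC 2.00, percent bias pre -20.3%, post -0.5%
```

The uncorrected map at the superior position under-reads the true gel ADC
by 20% and the spatial bias gradient broadens the ROI histogram to a 42%
nonuniformity; division by the precomputed corrector restores the median
to within 0.5% of truth and collapses the width to the noise floor.

## Command line

```bash
gnlcorr simulate --out sim --seed 4           # three-position phantom series
gnlcorr compute-adc --dwi sim/position2 --out adc.nii.gz
gnlcorr correct --adc adc.nii.gz --corrector sim/position2_cav.nii.gz --out adc_c.nii.gz
gnlcorr roi-stats --adc adc_c.nii.gz --roi '{"AP":[-10,10],"RL":[-50,50],"SI":[60,180]}'
gnlcorr validate --out report --seed 1        # six-system suite + summary TSV
```

Also available: `fit-model` (scale factors from profile TSVs),
`make-corrector`, `export-model`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Recomputes the workflow's headline statistics from scratch: the
cross-system ROI statistics of the bundled six-system multicenter summary
table (exact rank-sum p-values, bias and nonuniformity medians, Pearson
correlations), and a fresh synthetic six-system validation run at the
given seed, printing both summaries and writing the results JSON.
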