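# Methods

## Spectral model

A heart Raman spectrum over 520–1750 cm⁻¹ is modelled as a linear
mixture of pure-component emission profiles on a broad fluorescence
background:

    I(x) = B(x)
         + m · [(1 − f) · q · oMb(x) + f · dMb(x)]
         + c · [r_c · cytC(x) + r_b · cytB(x)]
         + a · amideI(x) + ε(x)

where `f` is the deoxygenated myoglobin fraction, `r_c`/`r_b` the
reduced fractions of the c-type and b-type cytochrome pools, `m`/`c`/`a`
abundance scalars, and `q` the ν4 scattering-efficiency advantage of
oxy- over deoxymyoglobin.  Oxidized cytochromes are not modelled: at
532 nm their resonance scatter is negligible, which is precisely why
band intensity tracks redox state.  All bands are Lorentzians with a
14 cm⁻¹ FWHM (a typical heme resonance-Raman linewidth; 40 cm⁻¹ for the
broad amide-I envelope), at the assigned positions: reduced c-type at
604, 750, 1310, 1582 cm⁻¹; reduced b-type at 750, 1127, 1300, 1337,
1582 cm⁻¹; oMb at 1377, 1587, 1640 cm⁻¹; dMb at 1358, 1556, 1606 cm⁻¹;
amide-I at 1658 cm⁻¹.  In intact tissue the c-type methine band sits at
1310 cm⁻¹ (downshifted from its 1313 cm⁻¹ position in purified
cytochrome c by overlap with the b-type 1300 cm⁻¹ band); a
purified-protein band library with 1313 cm⁻¹ is provided separately.

The species-unique markers are 604 (reduced c-type), 1337 (reduced
b-type), 1377 (oMb ν4) and 1358 cm⁻¹ (dMb ν4).

## The deoxymyoglobin estimator

The ν4 band positions of oMb (1377 cm⁻¹) and dMb (1358 cm⁻¹) do not
overlap with strong cytochrome bands, but dMb scatters roughly half as
efficiently as oMb at 532 nm.  The fraction estimator corrects for this
with the calibration constant `q`:

    f = q·I_1358 / (q·I_1358 + I_1377),   q = I_ν4(oMb) / I_ν4(dMb)

at matched concentration.  By construction equal amounts of oMb and dMb
give f = 0.5, f is monotone in each intensity, and the two endpoint
identities (no dMb → 0, no oMb → 1) hold exactly.  `q` is estimated as
the mean over independent experiments of the ν4 amplitude ratio between
hearts with fully oxygenated Mb and hearts fully reduced with sodium
dithionite.  The default calibration uses *raw* fitted amplitudes and
therefore assumes matched acquisition gain between the two groups; a
sum-normalized variant (`calibrate_q(..., normalize=True)`) is
available, but note that full reduction adds cytochrome signal to the
normalizing total, so the normalized ratio is not an unbiased estimate
of the scattering-efficiency ratio.  The shipped default is
q = 1.55 ± 0.10 (n = 3); every estimator takes `q` explicitly — there
is no hidden constant.

## Baseline correction

Fluorescence backgrounds in tissue are several times the band heights.
The default estimator (`method="arpls"`) is a two-stage asymmetric
penalized least squares: a robust cubic polynomial captured with
logistic reweighting first, then arPLS — a Whittaker smoother
(second-difference penalty λ, default 1e7) whose weights follow a
logistic of the residual scaled by the noise level estimated from
negative residuals — on the remainder.  Two properties motivated the
hybrid over classic asymmetric least squares (which is also provided as
`method="als"`): the polynomial stage reproduces smooth low-order
backgrounds essentially exactly, and the arPLS weights centre the
baseline *in* the noise rather than under it, so the corrected spectrum
carries no noise-floor pedestal and a second application of the
estimator is close to a no-op.  Convergence is declared when either the
weight vector or the baseline stops moving (relative tolerance 1e-3);
exceeding `max_iter` raises an error carrying the iteration
diagnostics.

A residual zero-level can be estimated as the median corrected
intensity over band-free regions (`zero_level_offset`) and subtracted
before pixel-sum integration.  On real tissue spectra the 900–1300 cm⁻¹
stretch contains additional unassigned bands, so this band-free-region
assumption is weaker there than in the simulation.

## Band quantification

Two modes.  `height` is the classical operation — the maximum corrected
intensity within ±8 cm⁻¹ of the band center — appropriate for isolated
bands and kept as the `band_amplitude` default.  `fit` decomposes a
whole cluster of mutually overlapping library bands (grouped at a
40 cm⁻¹ gap: {604}, {750}, {1127}, {1300–1377}, {1556–1658}) into
fixed-center, fixed-width Lorentzians by bounded-variable least squares
with non-negative amplitudes, plus a free-signed local quadratic that
absorbs whatever locally smooth pedestal the global baseline left.
Isolated bands use a ±4-FWHM window (a lone Lorentzian over a narrow
window is nearly collinear with the local quadratic, which would
triple the amplitude noise); clusters use ±2 FWHM around their extreme
centers.  The ν4 pair is 19 cm⁻¹ apart at 14 cm⁻¹ FWHM — height mode
cross-talks ~12% between 1358 and 1377 cm⁻¹, which is why the pipeline
quantifies all bands in fit mode.  Nearly degenerate designs (bands
closer than the grid can distinguish; Gram condition number above 1e3)
are ridge-regularized, flagged, and warned about.

The pipeline normalizes amplitudes by the *model total intensity* — the
summed area of all fitted Lorentzians, Σ amp·(π/2)·FWHM/step — rather
than the raw pixel sum.  The pixel sum (`total_intensity`, also
provided and used by `normalized_intensity` by default) carries a
residual baseline deficit that is approximately constant across
conditions and therefore biases cross-condition ratios of normalized
intensities by 1–2%; the model total is immune to this while preserving
scale invariance.

## Synthetic data: what it emulates, and what it does not

The generator (`cardioraman.simulate`) produces seeded spectra on a
520–1750 cm⁻¹ grid at 1 cm⁻¹ steps with: the mixture model above; a
positive, monotonically decreasing cubic fluorescence baseline with
amplitude 3× the strongest band; and additive Gaussian noise with SD
2% of the strongest band.  Defaults place the cytochrome pools at ~7%
of the integrated spectrum (myoglobin dominates the resonance scatter
of intact tissue; the true tissue ratio is not well quantified and the
scalars are explicit parameters).  Within-profile amplitudes encode
that 750 cm⁻¹ is dominated by c-type and 1127 cm⁻¹ by b-type
cytochromes (cross-contributions 0.07 and 0.02 of the dominant pool's
band).

Scenario presets encode the study conditions:

| preset | f_dMb | r_c | r_b | rationale |
|---|---|---|---|---|
| control | 0.05 | 0.40 | 0.40 | ≥95% Mb oxygenation in arrested perfused heart |
| oxygenated | 0.00 | 0.40 | 0.40 | calibration reference |
| fccp_5min | 0.05 | 0.222 | 0.162 | uncoupling oxidizes the chain |
| fccp_10min | 0.05 | 0.243 | 0.142 | — |
| ischemia_15 | 0.25 | 0.60 | 0.40 | progressive O₂ depletion |
| ischemia_30 | 0.50 | 0.80 | 0.40 | half the Mb pool deoxygenated; c-type reduction doubled, b-type flat |
| reperfusion_5/30 | 0.05 | 0.40 | 0.40 | full recovery within 5 min |
| sdt | 1.00 | 1.00 | 1.00 | chemical full reduction |

The FCCP reduced fractions were solved (fixed-point iteration on the
total-intensity ratio) so that the noise-free sum-normalized 750 and
1127 cm⁻¹ intensities fall to 56.8%/42.4% of control at 5 min and
61.6%/37.4% at 10 min — the uncoupling effect sizes the package is
meant to resolve.  Replicate seeds derive deterministically from a
master seed, so a dataset is a pure function of (scenario, seed).

Not emulated: the unassigned 900–1300 cm⁻¹ bands of real tissue,
Poisson (shot) noise, cosmic-ray spikes, self-absorption and depth-of-
focus optics, beating-heart motion.  Passing recovery tests on this
generator therefore demonstrates correctness of the analysis chain
under the stated model, not robustness to every artifact of real
acquisitions.

## Statistics

Condition summaries are mean ± SE.  The omnibus comparison is
Kruskal–Wallis (scipy); pairwise comparisons use Dunn's rank-sum z test
with tie correction, Bonferroni-adjusted over the number of pairs.
Fully tied data yield p = 1 rather than an error.  No further
multiple-testing correction is applied beyond the post hoc adjustment.

## Numerical choices and degenerate inputs

* Spectra must have strictly increasing shifts in [100, 4000] cm⁻¹ and
  at least 2 samples; file readers sort descending files and reject
  duplicated shifts.
* Intervals are closed; no implicit unit conversion; resampling is
  linear interpolation with no extrapolation.
* Negative corrected intensities are retained in spectra but clipped to
  zero inside amplitude estimates; non-negative least squares clips
  absent bands to zero, which slightly inflates the mean of
  near-noise-level amplitudes (visible in percent-of-control values of
  the weakest bands).
* An undefined c/b ratio (zero fitted 1127 amplitude in a noisy
  spectrum) propagates as NaN through reports so group means can skip
  it instead of aborting the run.
* Zero-intensity spectra: baseline and corrected both zero; indices
  raise an undefined-ratio error rather than returning arbitrary
  numbers.

## Validation problem sizes

The test suite and the acceptance script size their simulations to run
comfortably on a single CPU: 10 calibration experiments of 3 + 3
hearts, a 5-point oxygenation grid at 10 seeds, and 15–25 master seeds
of the ischemia (5 timepoints × 3 hearts) and FCCP (3 × 3) scenarios —
a few hundred spectra per run, a few seconds each.

## Known limitations

* The height-mode operation conflates the 1582/1587 cm⁻¹ and ν4 band
  pairs; fit mode is the supported route for those regions.
* The raw-gain assumption of the default calibration is right for the
  simulator and for experiments acquired at fixed optics; across
  instruments the normalized variant (with its stated bias) may be the
  only option.
* f_dMb near the endpoints is compressed by amplitude clipping (an
  absent band cannot fit negative), so recovery error is smallest at
  the extremes and largest mid-range.
* The band library ships tissue positions; purified-protein work should
  load `purified_cytochrome_c_library()` or a custom CSV.
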