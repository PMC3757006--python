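# cardioraman

Resonance Raman quantification of mitochondrial cytochrome redox state
and myoglobin oxygenation in perfused heart tissue.

Under 532 nm excitation, the resonance Raman spectrum of heart muscle is
dominated by heme chromophores: the reduced (Fe²⁺) c- and b-type
cytochromes of the electron transport chain and cytosolic myoglobin
(Mb).  Because oxidized cytochromes scatter negligibly at this
wavelength, band intensities report the *redox state* of the chain, and
the position of the porphyrin ν4 band reports Mb *oxygenation*
(1377 cm⁻¹ for oxy-Mb, 1358 cm⁻¹ for deoxy-Mb).  This package turns raw
one-dimensional heart spectra into those physiological read-outs.  It
is aimed at cardiac physiologists and biophysicists running perfused
heart or cardiomyocyte Raman experiments, and at methodologists who
need a fully seeded synthetic testbed for such analyses.

## What it computes

Given a baseline-corrected spectrum with band amplitudes *I_ν*:

* **Sum-normalized band intensities** — *I_ν / I_sum*, with *I_sum* the
  total spectral intensity over 520–1750 cm⁻¹, making acquisitions with
  different optical gain comparable.
* **The c/b redox ratio** — *I₇₅₀ / I₁₁₂₇*.  The 750 cm⁻¹ band is
  dominated by reduced cytochromes c + c₁, the 1127 cm⁻¹ band by
  reduced b-type cytochromes, so the ratio localizes where electrons
  accumulate in the chain.
* **The deoxymyoglobin fraction** from the ν4 marker pair,

  *f*₍dMb₎ = *q*·*I*₁₃₅₈ / (*q*·*I*₁₃₅₈ + *I*₁₃₇₇),

  where *q* is the empirically calibrated ratio of ν4 scattering
  efficiency of oxy- to deoxy-Mb (1.55 ± 0.10 from fully oxygenated vs
  dithionite-reduced hearts), so equal oMb and dMb concentrations give
  *f* = 0.5.
* **Group statistics** — per-condition mean ± SE, Kruskal–Wallis
  omnibus and Dunn's post-hoc comparisons, percent-of-control series.

The processing chain is: read (two-column text or JCAMP-DX) → subtract
the fluorescence baseline (robust cubic + arPLS Whittaker smoothing) →
decompose band clusters into fixed-center Lorentzians by non-negative
least squares → indices → report.  A seeded synthetic-spectrum
generator (`cardioraman.simulate`) produces heart spectra with known
ground truth for the bundled experimental scenarios: control perfusion,
FCCP uncoupling, stop-flow ischemia/reperfusion, and sodium-dithionite
(SDT) full reduction.

## Worked example

Estimate Mb oxygenation and c-type cytochrome reduction for three
simulated hearts per condition:

```python
import numpy as np
from cardioraman import (
    preset_states, synth_heart_spectrum, subtract_baseline,
    compute_indices, DEFAULT_Q,
)

states = preset_states()
for label in ("control", "ischemia_30", "sdt"):
    f_vals, r_vals = [], []
    for rep in range(3):                      # n = 3 hearts
        spectrum, _ = synth_heart_spectrum(states[label], seed=100 + rep)
        corrected, _ = subtract_baseline(spectrum)
        idx = compute_indices(corrected, q=DEFAULT_Q)
        f_vals.append(idx.f_dmb)
        r_vals.append(idx.norm_750)
    print(f"{label:12s}  f_dMb = {np.mean(f_vals):.3f} ± {np.std(f_vals):.3f}"
          f"   I750/Isum = {np.mean(r_vals):.5f}")
```

prints

```
control       f_dMb = 0.070 ± 0.018   I750/Isum = 0.00056
ischemia_30   f_dMb = 0.508 ± 0.017   I750/Isum = 0.00119
sdt           f_dMb = 0.991 ± 0.011   I750/Isum = 0.00154
```

Control hearts are almost fully oxygenated (true *f*₍dMb₎ = 0.05); at
30 min of stop-flow ischemia half the myoglobin pool is deoxygenated
and the normalized 750 cm⁻¹ intensity has roughly doubled (c-type
cytochromes accumulate electrons upstream of cytochrome oxidase); SDT
reduces everything and deoxygenates Mb completely.

## Command line

```sh
cardioraman simulate --scenario ischemia --out data --seed 1
cardioraman analyze  --config config.yaml      # indices.csv + report.json
cardioraman calibrate --oxy o1.txt --oxy o2.txt --reduced r1.txt --reduced r2.txt
cardioraman bands                              # dump the 14-band heart library
```

A minimal `config.yaml`:

```yaml
manifest: data/manifest.csv
control_condition: control
q_constant: 1.55
output_dir: out
```

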