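"""Derived redox and oxygenation indices.

The physiologically meaningful read-outs of a heart Raman spectrum:

* sum-normalized band intensities I_band / I_sum, comparable across
  acquisitions;
* the c-type vs b-type reduced-cytochrome ratio I_750 / I_1127;
* the deoxymyoglobin fraction estimated from the ν4 marker pair,

      f_dMb = q · I_1358 / (q · I_1358 + I_1377),

  where q is the empirical ratio of ν4 scattering efficiency of
  oxygenated to deoxygenated myoglobin (1.55 ± 0.10 from perfused-heart
  calibration), so that equal oMb and dMb concentrations give
  f_dMb = 0.5;
* percent-of-control series for treatment time courses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .bands import Band, BandLibrary, default_library
from .errors import CalibrationError, UndefinedRatioError, ValidationError
from .quantify import AmplitudeMode, band_amplitude, cluster_amplitude, total_intensity
from .spectrum import RamanSpectrum

#: default whole-spectrum normalization window (cm⁻¹)
DEFAULT_SUM_RANGE = (520.0, 1750.0)


@dataclass(frozen=True)
class CalibrationConstant:
    """The ν4 oMb/dMb scattering-efficiency ratio q.

    ``q`` multiplies the dMb ν4 intensity to make it concentration-
    commensurate with the oMb ν4 intensity; ``se`` and ``n`` record the
    spread and count of the calibration experiments it came from.
    """

    q: float
    se: float = 0.0
    n: int = 1
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValidationError("q must be positive")
        if self.se < 0:
            raise ValidationError("se must be non-negative")
        if self.n < 1:
            raise ValidationError("n must be at least 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationConstant":
        with open(path) as fh:
            return cls(**json.load(fh))


#: the published perfused-heart value (mean ± SE over 3 experiments)
DEFAULT_Q = CalibrationConstant(q=1.55, se=0.10, n=3, provenance="published heart calibration")


@dataclass(frozen=True)
class RedoxIndices:
    """Per-spectrum derived quantities."""

    norm_604: float
    norm_750: float
    norm_1127: float
    norm_1337: float
    norm_1358: float
    norm_1377: float
    ratio_c_b: float
    f_dmb: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("norm_604", "norm_750", "norm_1127", "norm_1337",
                     "norm_1358", "norm_1377"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name}={value:g} outside [0, 1]")
        if self.ratio_c_b < 0:
            raise ValidationError("ratio_c_b must be non-negative")
        if not (0.0 <= self.f_dmb <= 1.0):
            raise ValidationError("f_dmb must lie in [0, 1]")


def normalized_intensity(
    spectrum: RamanSpectrum,
    band: Band,
    range_: tuple[float, float] = DEFAULT_SUM_RANGE,
    mode: AmplitudeMode = "height",
    library: BandLibrary | None = None,
) -> float:
    """I_band / I_sum for one band of a baseline-corrected spectrum.

    Invariant under global intensity scaling; lies in [0, 1].
    """
    i_sum = total_intensity(spectrum, range_)
    if i_sum <= 0:
        raise UndefinedRatioError("I_sum is not positive; cannot normalize")
    if mode == "fit" and library is not None:
        amp = cluster_amplitude(spectrum, library, band, mode)
    else:
        amp = band_amplitude(spectrum, band, mode)
    return amp / i_sum


def c_to_b_ratio(
    spectrum: RamanSpectrum,
    library: BandLibrary | None = None,
    mode: AmplitudeMode = "height",
) -> float:
    """I_750 / I_1127: relative reduction of c-type vs b-type cytochromes.

    The 750 cm⁻¹ band is dominated by reduced cytochromes c and c1, the
    1127 cm⁻¹ band by reduced b-type cytochromes, so their ratio tracks
    which segment of the electron transport chain holds the electrons.
    """
    if library is None:
        library = default_library()
    i750 = band_amplitude(spectrum, library[750.0], mode)
    i1127 = band_amplitude(spectrum, library[1127.0], mode)
    if i1127 == 0:
        raise UndefinedRatioError("zero 1127 cm⁻¹ amplitude; ratio undefined")
    return i750 / i1127


def dmb_fraction(i_1358: float, i_1377: float, q: CalibrationConstant | float) -> float:
    """Deoxymyoglobin fraction from the ν4 marker pair.

    f = q·I_1358 / (q·I_1358 + I_1377).  Monotone increasing in the dMb
    intensity and decreasing in the oMb intensity; equal true
    concentrations yield 0.5 by construction of q.
    """
    q_value = q.q if isinstance(q, CalibrationConstant) else float(q)
    if q_value <= 0:
        raise ValidationError("q must be positive")
    if i_1358 < 0 or i_1377 < 0:
        raise ValidationError("intensities must be non-negative")
    weighted = q_value * i_1358
    denom = weighted + i_1377
    if denom == 0:
        raise UndefinedRatioError("both ν4 intensities are zero; fraction undefined")
    return weighted / denom


def calibrate_q(
    oxy_spectra: Sequence[RamanSpectrum],
    reduced_spectra: Sequence[RamanSpectrum],
    library: BandLibrary | None = None,
    mode: AmplitudeMode = "fit",
    normalize: bool = False,
    sum_range: tuple[float, float] = DEFAULT_SUM_RANGE,
) -> CalibrationConstant:
    """Estimate q from fully oxygenated and fully reduced (SDT) hearts.

    q is the mean over experiments of I_1377(oxy) / I_1358(reduced),
    both measured from baseline-corrected spectra.  Groups of equal
    size are paired in order; otherwise every oxy spectrum is ratioed
    against the reduced-group mean.  With ``normalize=True`` each ν4
    intensity is first divided by its spectrum's I_sum; the default
    uses raw amplitudes and therefore assumes matched acquisition gain.
    """
    if len(oxy_spectra) < 1 or len(reduced_spectra) < 1:
        raise ValidationError("need at least one spectrum per group")
    if library is None:
        library = default_library()
    b1377 = library[1377.0]
    b1358 = library[1358.0]

    def nu4(spectrum: RamanSpectrum, band: Band, label: str) -> float:
        if mode == "fit":
            value = cluster_amplitude(spectrum, library, band, mode)
        else:
            value = band_amplitude(spectrum, band, mode)
        if normalize:
            value /= total_intensity(spectrum, sum_range)
        if value <= 0:
            raise CalibrationError(
                f"zero ν4 intensity at {band.center:g} cm⁻¹ in {label} spectrum"
            )
        return value

    oxy = [nu4(s, b1377, f"oxy[{i}]") for i, s in enumerate(oxy_spectra)]
    red = [nu4(s, b1358, f"reduced[{i}]") for i, s in enumerate(reduced_spectra)]
    if len(oxy) == len(red):
        ratios = np.array(oxy) / np.array(red)
    else:
        ratios = np.array(oxy) / float(np.mean(red))
    q = float(np.mean(ratios))
    se = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return CalibrationConstant(
        q=q, se=se, n=len(ratios),
        provenance=f"calibrated from {len(oxy)} oxy / {len(red)} reduced spectra",
    )


def model_total_intensity(amplitudes: dict, library: BandLibrary, step: float = 1.0) -> float:
    """Total band intensity reconstructed from fitted amplitudes.

    The integrated area of every fitted Lorentzian, expressed in
    pixel-sum units (divided by the grid step): Σ amp·(π/2)·fwhm/step.
    Unlike the raw pixel sum it carries no residual baseline pedestal,
    so normalized intensities built from it compare cleanly across
    conditions.
    """
    total = 0.0
    for band in library:
        amp = amplitudes.get(band.name, amplitudes.get(band.center, 0.0))
        total += amp * (np.pi / 2.0) * band.fwhm / step
    return total


def compute_indices(
    corrected: RamanSpectrum,
    library: BandLibrary | None = None,
    q: CalibrationConstant | float = DEFAULT_Q,
    mode: AmplitudeMode = "fit",
    sum_range: tuple[float, float] = DEFAULT_SUM_RANGE,
    meta: dict | None = None,
) -> RedoxIndices:
    """All derived indices for one baseline-corrected spectrum.

    In the default ``fit`` mode every band is quantified by cluster
    decomposition and normalized intensities use the model total
    intensity; in ``height`` mode peak heights are normalized by the
    pixel sum (:func:`total_intensity`) over ``sum_range``.
    """
    if library is None:
        library = default_library()
    amps = {
        b.center: cluster_amplitude(corrected, library, b, mode) for b in library
    }
    if mode == "fit":
        i_sum = model_total_intensity(amps, library)
    else:
        i_sum = total_intensity(corrected, sum_range)
    if i_sum <= 0:
        raise UndefinedRatioError("total intensity is not positive")
    # undefined ratio (zero 1127 fit in a noisy spectrum) propagates as NaN
    # so that group means can skip it rather than abort the whole run
    ratio_c_b = amps[750.0] / amps[1127.0] if amps[1127.0] > 0 else float("nan")
    try:
        f_dmb = dmb_fraction(amps[1358.0], amps[1377.0], q)
    except UndefinedRatioError:
        f_dmb = 0.0
    return RedoxIndices(
        norm_604=amps[604.0] / i_sum,
        norm_750=amps[750.0] / i_sum,
        norm_1127=amps[1127.0] / i_sum,
        norm_1337=amps[1337.0] / i_sum,
        norm_1358=amps[1358.0] / i_sum,
        norm_1377=amps[1377.0] / i_sum,
        ratio_c_b=ratio_c_b,
        f_dmb=f_dmb,
        meta=dict(meta or {}),
    )


def percent_of_control(values, control) -> np.ndarray:
    """Express values as percent of the control mean (control maps to 100)."""
    control_mean = float(np.mean(control))
    if control_mean == 0:
        raise UndefinedRatioError("control mean is zero; percent undefined")
    return 100.0 * np.asarray(values, dtype=float) / control_mean
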