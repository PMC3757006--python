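"""Seeded synthetic heart Raman spectra with known ground truth.

Emulates 532 nm resonance Raman spectra of perfused heart tissue as a
linear mixture of pure-component emission profiles — reduced c-type and
b-type cytochromes, oxy- and deoxymyoglobin, and the amide-I protein
band — on a broad fluorescence-like polynomial baseline with additive
Gaussian detector noise:

    I(x) = baseline(x)
         + mb_scale · [(1 − f_dMb) · q_true · oMb(x) + f_dMb · dMb(x)]
         + cyt_scale · [r_c · cytC(x) + r_b · cytB(x)]
         + amide_amp · amideI(x)
         + ε,   ε ~ N(0, noise_sd · peak)

Oxidized cytochromes scatter negligibly at 532 nm and are not
simulated; their redox state enters only through the reduced fractions
r_c and r_b.  The oMb profile carries the ν4 scattering-efficiency
advantage q_true over dMb, which is what the calibration stage is meant
to recover.  Scenario presets encode the study conditions: control
perfusion, FCCP uncoupling, stop-flow ischemia with reperfusion, and
dithionite (SDT) full reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .spectrum import RamanSpectrum, default_grid
from .quantify import lorentzian

__all__ = [
    "ComponentProfile", "PhysiologicalState", "Scenario", "SimulatedSpectrum",
    "component_profiles", "component_spectrum", "synth_heart_spectrum",
    "preset_states", "scenario_presets", "synth_scenario", "write_dataset",
    "scenario_from_dict",
]


@dataclass(frozen=True)
class ComponentProfile:
    """A pure-component emission profile: (center, relative amplitude, fwhm)."""

    species: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.peaks:
            amps = [a for _, a, _ in self.peaks]
            if min(amps) < 0:
                raise ValidationError("relative amplitudes must be non-negative")
            if abs(max(amps) - 1.0) > 1e-12:
                raise ValidationError("strongest relative amplitude must be 1")


def component_profiles() -> dict[str, ComponentProfile]:
    """Default pure-component profiles of the heart spectrum.

    Relative in-profile amplitudes encode that the 750 cm⁻¹ band is
    dominated by c-type and the 1127 cm⁻¹ band by b-type cytochromes
    (cross-contributions 0.07 and 0.02), and that the dMb ν4 band is
    intrinsically as strong within its profile as the oMb ν4 band — the
    overall oMb/dMb efficiency difference is applied as q_true at
    mixing time.
    """
    return {
        "oMb": ComponentProfile("oMb", (
            (1377.0, 0.55, 14.0), (1587.0, 1.0, 14.0), (1640.0, 0.7, 14.0),
        )),
        "dMb": ComponentProfile("dMb", (
            (1358.0, 0.55, 14.0), (1556.0, 1.0, 14.0), (1606.0, 0.7, 14.0),
        )),
        "cyt_c_red": ComponentProfile("cyt_c_red", (
            (604.0, 0.25, 14.0), (750.0, 1.0, 14.0), (1127.0, 0.02, 14.0),
            (1310.0, 0.5, 14.0), (1582.0, 0.8, 14.0),
        )),
        "cyt_b_red": ComponentProfile("cyt_b_red", (
            (750.0, 0.07, 14.0), (1127.0, 1.0, 14.0), (1300.0, 0.5, 14.0),
            (1337.0, 0.8, 14.0), (1582.0, 0.8, 14.0),
        )),
        "amide_I": ComponentProfile("amide_I", ((1658.0, 1.0, 40.0),)),
    }


@dataclass(frozen=True)
class PhysiologicalState:
    """Ground-truth composition of a simulated heart.

    f_dmb:
        Fraction of myoglobin deoxygenated, in [0, 1].
    r_c, r_b:
        Fractions of c-type / b-type cytochromes reduced, in [0, 1].
    mb_scale, cyt_scale:
        Abundance scalars of the myoglobin and cytochrome pools.  The
        defaults keep the cytochrome share of the integrated spectrum
        small (≈7 %), as expected when cytosolic myoglobin dominates
        the resonance scatter of intact tissue.
    q_true:
        ν4 scattering-efficiency ratio of oMb to dMb applied to the
        oMb profile (published calibration: 1.55).
    baseline_amp:
        Fluorescence baseline height at the low-shift edge, as a
        multiple of the strongest noise-free band.
    noise_sd:
        Gaussian noise SD as a fraction of the strongest band.
    amide_amp:
        Amide-I band amplitude relative to mb_scale units.
    """

    f_dmb: float
    r_c: float
    r_b: float
    mb_scale: float = 1.0
    cyt_scale: float = 0.25
    q_true: float = 1.55
    baseline_amp: float = 3.0
    noise_sd: float = 0.02
    amide_amp: float = 1.4

    def __post_init__(self) -> None:
        for name in ("f_dmb", "r_c", "r_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.mb_scale <= 0 or self.cyt_scale <= 0:
            raise ValidationError("abundance scales must be positive")
        if self.q_true <= 0:
            raise ValidationError("q_true must be positive")
        if self.baseline_amp < 0 or self.noise_sd < 0 or self.amide_amp < 0:
            raise ValidationError("baseline_amp, noise_sd, amide_amp must be ≥ 0")

    def component_weights(self) -> dict[str, float]:
        """Mixing coefficient applied to each unit-max component profile."""
        return {
            "oMb": self.mb_scale * (1.0 - self.f_dmb) * self.q_true,
            "dMb": self.mb_scale * self.f_dmb,
            "cyt_c_red": self.cyt_scale * self.r_c,
            "cyt_b_red": self.cyt_scale * self.r_b,
            "amide_I": self.amide_amp,
        }

    def true_band_amplitudes(self) -> dict[float, float]:
        """Noise-free total Lorentzian amplitude at every band center."""
        weights = self.component_weights()
        amps: dict[float, float] = {}
        for species, profile in component_profiles().items():
            for center, rel, _ in profile.peaks:
                amps[center] = amps.get(center, 0.0) + weights[species] * rel
        return amps


@dataclass(frozen=True)
class Scenario:
    """An ordered list of (timepoint label, state, n_replicates)."""

    name: str
    timepoints: tuple[tuple[str, PhysiologicalState, int], ...]

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValidationError("a scenario needs at least one timepoint")
        for label, _, n in self.timepoints:
            if n < 1:
                raise ValidationError(f"timepoint {label!r}: n_replicates must be ≥ 1")


@dataclass(frozen=True)
class SimulatedSpectrum:
    """One simulator output: the spectrum plus its ground truth."""

    spectrum: RamanSpectrum
    ground_truth: dict
    condition: str = ""
    replicate: int = 0
    seed: int = 0


def component_spectrum(profile: ComponentProfile, grid: np.ndarray) -> RamanSpectrum:
    """Noise-free spectrum of one pure component (max intensity 1)."""
    grid = np.asarray(grid, dtype=float)
    intensities = np.zeros_like(grid)
    for center, rel, fwhm in profile.peaks:
        intensities += rel * lorentzian(grid, center, fwhm)
    return RamanSpectrum(grid, intensities, {"species": profile.species})


def _band_signal(state: PhysiologicalState, grid: np.ndarray) -> np.ndarray:
    weights = state.component_weights()
    signal = np.zeros_like(grid, dtype=float)
    for species, profile in component_profiles().items():
        signal += weights[species] * component_spectrum(profile, grid).intensities
    return signal


def _fluorescence_baseline(grid: np.ndarray, amplitude: float) -> np.ndarray:
    # positive, monotone-decreasing cubic: broad fluorescence background
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    shape = 1.0 - 0.9 * t + 0.15 * t**2 + 0.05 * t**3
    return amplitude * shape


def synth_heart_spectrum(
    state: PhysiologicalState,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[RamanSpectrum, dict]:
    """Simulate one heart spectrum; returns (spectrum, ground truth).

    Identical (state, seed) pairs produce bit-identical spectra.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    signal = _band_signal(state, grid)
    peak = float(signal.max()) if signal.size else 0.0
    baseline = _fluorescence_baseline(grid, state.baseline_amp * peak)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, state.noise_sd * peak, size=grid.size) if state.noise_sd > 0 else 0.0
    spectrum = RamanSpectrum(
        grid,
        baseline + signal + noise,
        {"excitation_nm": 532, "simulated": True, "seed": seed},
    )
    truth = {
        "f_dmb": state.f_dmb,
        "r_c": state.r_c,
        "r_b": state.r_b,
        "q_true": state.q_true,
        "mb_scale": state.mb_scale,
        "cyt_scale": state.cyt_scale,
        "amide_amp": state.amide_amp,
        "baseline_amp": state.baseline_amp,
        "noise_sd": state.noise_sd,
        "seed": seed,
        "band_amplitudes": state.true_band_amplitudes(),
    }
    return spectrum, truth


# ---------------------------------------------------------------------------
# Scenario presets: the experimental conditions the simulator emulates.
#
# Control hearts keep ≥95 % of myoglobin oxygenated and c/b cytochrome
# pools ~40 % reduced.  The FCCP reduced fractions are solved (fixed
# point on the I_sum ratio) so that the sum-normalized 750 and 1127
# band intensities fall to 56.7 %/42.3 % of control at 5 min and
# 61.5 %/37.3 % at 10 min.  Stop-flow ischemia deoxygenates myoglobin
# (f_dMb 0.25 at 15 min, 0.5 at 30 min) and backs electrons up into the
# c-type pool (r_c doubles) while b-type reduction stays flat;
# reperfusion restores the control state.  SDT reduces everything.
# ---------------------------------------------------------------------------

def preset_states() -> dict[str, PhysiologicalState]:
    control = PhysiologicalState(f_dmb=0.05, r_c=0.4, r_b=0.4)
    return {
        "control": control,
        "oxygenated": replace(control, f_dmb=0.0),
        "fccp_5min": replace(control, r_c=0.2222, r_b=0.1616),
        "fccp_10min": replace(control, r_c=0.2433, r_b=0.1416),
        "ischemia_15": replace(control, f_dmb=0.25, r_c=0.6),
        "ischemia_30": replace(control, f_dmb=0.5, r_c=0.8),
        "reperfusion_5": control,
        "reperfusion_30": control,
        "sdt": replace(control, f_dmb=1.0, r_c=1.0, r_b=1.0),
    }


def scenario_presets(n_replicates: int = 3) -> dict[str, Scenario]:
    """The bundled experiment designs (default n = 3 hearts per point)."""
    s = preset_states()
    n = n_replicates

    def scen(name: str, labels: Iterable[str]) -> Scenario:
        return Scenario(name, tuple((lab, s[lab], n) for lab in labels))

    return {
        "control": scen("control", ["control"]),
        "fccp": scen("fccp", ["control", "fccp_5min", "fccp_10min"]),
        "ischemia": scen(
            "ischemia",
            ["control", "ischemia_15", "ischemia_30", "reperfusion_5", "reperfusion_30"],
        ),
        "sdt": scen("sdt", ["control", "sdt"]),
        "calibration": scen("calibration", ["oxygenated", "sdt"]),
    }


def _replicate_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def synth_scenario(
    scenario: Scenario,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> list[SimulatedSpectrum]:
    """Simulate every replicate of a scenario.

    Per-replicate seeds are derived deterministically from the master
    seed, so replicates differ in noise but a rerun with the same
    master seed reproduces the dataset exactly.
    """
    dataset: list[SimulatedSpectrum] = []
    index = 0
    for label, state, n in scenario.timepoints:
        for replicate in range(n):
            rep_seed = _replicate_seed(seed, index)
            spectrum, truth = synth_heart_spectrum(state, grid, seed=rep_seed)
            spectrum.meta["condition"] = label
            spectrum.meta["replicate"] = replicate
            dataset.append(
                SimulatedSpectrum(spectrum, truth, condition=label,
                                  replicate=replicate, seed=rep_seed)
            )
            index += 1
    return dataset


def write_dataset(dataset: list[SimulatedSpectrum], outdir) -> Path:
    """Write spectra + manifest.csv + ground_truth.csv; returns manifest path."""
    from .io import write_spectrum  # deferred: io does not depend on simulate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = ["filename,condition,replicate,seed"]
    truth_header = None
    truth_rows = []
    for item in dataset:
        fname = f"{item.condition}_rep{item.replicate}.txt"
        write_spectrum(item.spectrum, outdir / fname)
        manifest_rows.append(f"{fname},{item.condition},{item.replicate},{item.seed}")
        flat = {k: v for k, v in item.ground_truth.items() if k != "band_amplitudes"}
        for center, amp in sorted(item.ground_truth["band_amplitudes"].items()):
            flat[f"amp_{center:g}"] = amp
        if truth_header is None:
            truth_header = ["filename", *flat]
            truth_rows.append(",".join(truth_header))
        truth_rows.append(",".join([fname] + [f"{flat[k]:.10g}" for k in truth_header[1:]]))
    (outdir / "manifest.csv").write_text("\n".join(manifest_rows) + "\n")
    (outdir / "ground_truth.csv").write_text("\n".join(truth_rows) + "\n")
    return outdir / "manifest.csv"


def scenario_from_dict(config: Mapping) -> Scenario:
    """Build a scenario from a plain mapping (parsed YAML/TOML).

    Expected shape::

        name: my_experiment
        timepoints:
          - label: control
            n_replicates: 3
            state: {f_dmb: 0.05, r_c: 0.4, r_b: 0.4}

    State entries may also name a preset: ``state: ischemia_30``.
    """
    presets = preset_states()
    timepoints = []
    for tp in config["timepoints"]:
        raw_state = tp["state"]
        if isinstance(raw_state, str):
            state = presets[raw_state]
        else:
            state = PhysiologicalState(**raw_state)
        timepoints.append((str(tp["label"]), state, int(tp.get("n_replicates", 3))))
    return Scenario(str(config.get("name", "custom")), tuple(timepoints))
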