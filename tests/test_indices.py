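"""Redox and oxygenation indices: normalization, ratios, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioraman import (
    CalibrationConstant,
    RamanSpectrum,
    UndefinedRatioError,
    ValidationError,
    c_to_b_ratio,
    calibrate_q,
    compute_indices,
    dmb_fraction,
    lorentzian,
    normalized_intensity,
    percent_of_control,
    subtract_baseline,
)
from cardioraman.simulate import preset_states, synth_heart_spectrum


def band_mix(grid, **amps):
    y = np.zeros(grid.size)
    for center, amp in amps.items():
        y += amp * lorentzian(grid, float(center.lstrip("c")), 14.0)
    return RamanSpectrum(grid, y)


class TestNormalizedIntensity:
    def test_scale_invariance(self, grid, library):
        s = band_mix(grid, c750=30.0, c1127=20.0)
        band = library[750.0]
        base = normalized_intensity(s, band)
        assert normalized_intensity(s.scaled(10.0), band) == pytest.approx(base, rel=1e-9)

    def test_direct_arithmetic_oracle(self, library):
        # two-band toy spectrum: height / pixel-sum computed by hand
        shifts = 700.0 + np.arange(120.0)
        y = np.zeros(120)
        y[50] = 4.0  # lone spike at 750 cm-1
        y[10] = 1.0
        s = RamanSpectrum(shifts, y)
        value = normalized_intensity(s, library[750.0], range_=(700.0, 819.0))
        assert value == pytest.approx(4.0 / 5.0)

    def test_zero_amplitude_band_near_zero(self, grid, library):
        s = band_mix(grid, c1127=20.0)
        # only the far Lorentzian tail of the 1127 band reaches 604
        assert normalized_intensity(s, library[604.0]) < 1e-4

    def test_zero_spectrum_raises(self, grid, library):
        s = RamanSpectrum(grid, np.zeros(grid.size))
        with pytest.raises(UndefinedRatioError):
            normalized_intensity(s, library[750.0])


class TestCToBRatio:
    def test_equal_amplitudes_give_unity(self, grid):
        s = band_mix(grid, c750=25.0, c1127=25.0)
        assert c_to_b_ratio(s) == pytest.approx(1.0, rel=5e-3)

    def test_scale_invariance(self, grid):
        s = band_mix(grid, c750=30.0, c1127=20.0)
        assert c_to_b_ratio(s.scaled(7.0)) == pytest.approx(c_to_b_ratio(s), rel=1e-9)

    def test_doubling_c_band_doubles_ratio(self, grid):
        s1 = band_mix(grid, c750=20.0, c1127=25.0)
        s2 = band_mix(grid, c750=40.0, c1127=25.0)
        assert c_to_b_ratio(s2) == pytest.approx(2.0 * c_to_b_ratio(s1), rel=0.05)

    def test_zero_denominator_raises(self, grid):
        y = np.zeros(grid.size)
        y[np.searchsorted(grid, 750.0)] = 20.0  # spike: no tail at 1127
        with pytest.raises(UndefinedRatioError):
            c_to_b_ratio(RamanSpectrum(grid, y))


class TestDmbFraction:
    def test_endpoints(self):
        assert dmb_fraction(0.0, 5.0, 1.55) == 0.0
        assert dmb_fraction(3.0, 0.0, 1.55) == 1.0

    def test_equal_intensities_with_unit_q(self):
        assert dmb_fraction(2.0, 2.0, 1.0) == pytest.approx(0.5)

    def test_both_zero_raises(self):
        with pytest.raises(UndefinedRatioError):
            dmb_fraction(0.0, 0.0, 1.55)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValidationError):
            dmb_fraction(1.0, 1.0, -2.0)

    @settings(max_examples=50, deadline=None)
    @given(
        i1358=st.floats(min_value=1e-6, max_value=1e3),
        i1377=st.floats(min_value=1e-6, max_value=1e3),
        q=st.floats(min_value=0.1, max_value=10.0),
        bump=st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_monotone_and_complement_identity(self, i1358, i1377, q, bump):
        f = dmb_fraction(i1358, i1377, q)
        assert 0.0 <= f <= 1.0
        # monotone: more dMb signal, larger fraction; more oMb, smaller
        assert dmb_fraction(i1358 + bump, i1377, q) >= f
        assert dmb_fraction(i1358, i1377 + bump, q) <= f
        # complement with swapped roles and efficiency 1/q sums to one
        complement = dmb_fraction(i1377, i1358, 1.0 / q)
        assert f + complement == pytest.approx(1.0, abs=1e-9)


class TestCalibrationConstant:
    def test_validation(self):
        with pytest.raises(ValidationError):
            CalibrationConstant(q=-1.0)
        with pytest.raises(ValidationError):
            CalibrationConstant(q=1.0, se=-0.1)
        with pytest.raises(ValidationError):
            CalibrationConstant(q=1.0, n=0)

    def test_json_roundtrip(self, tmp_path):
        c = CalibrationConstant(q=1.55, se=0.1, n=3, provenance="test")
        path = tmp_path / "q.json"
        c.to_json(path)
        assert CalibrationConstant.from_json(path) == c


class TestCalibrateQ:
    def test_identical_groups_same_band_give_unity(self, grid, library):
        # same ν4 content quantified at 1377 in both roles ⇒ ratio of
        # equal amplitudes: build spectra with equal 1358 and 1377 amps
        s = band_mix(grid, c1358=10.0, c1377=10.0)
        result = calibrate_q([s, s], [s, s], library=library)
        assert result.q == pytest.approx(1.0, rel=1e-3)
        assert result.n == 2

    def test_single_pair_has_zero_se(self, grid, library):
        oxy = band_mix(grid, c1377=31.0)
        red = band_mix(grid, c1358=20.0)
        result = calibrate_q([oxy], [red], library=library)
        assert result.q == pytest.approx(31.0 / 20.0, rel=1e-3)
        assert result.se == 0.0
        assert result.n == 1

    def test_zero_nu4_raises_naming_spectrum(self, grid, library):
        oxy = band_mix(grid, c1377=31.0)
        blank = RamanSpectrum(grid, np.zeros(grid.size))
        with pytest.raises(Exception, match="reduced\\[0\\]"):
            calibrate_q([oxy], [blank], library=library)

    def test_recovers_generator_q_over_seeds(self, library):
        """3 oxy + 3 SDT hearts per experiment, q_true = 1.55, seeds 0-9."""
        states = preset_states()
        estimates = []
        for seed in range(10):
            oxy, red = [], []
            for rep in range(3):
                s, _ = synth_heart_spectrum(states["oxygenated"], seed=1000 + seed * 10 + rep)
                oxy.append(subtract_baseline(s)[0])
                s, _ = synth_heart_spectrum(states["sdt"], seed=5000 + seed * 10 + rep)
                red.append(subtract_baseline(s)[0])
            estimates.append(calibrate_q(oxy, red, library=library).q)
        assert np.mean(estimates) == pytest.approx(1.55, abs=0.10)


class TestPercentOfControl:
    def test_half_of_control_is_fifty(self):
        assert percent_of_control([2.0], [4.0])[0] == pytest.approx(50.0)

    def test_control_group_mean_is_exactly_100(self):
        control = np.array([3.0, 4.0, 5.0])
        assert np.mean(percent_of_control(control, control)) == pytest.approx(100.0)

    def test_zero_control_raises(self):
        with pytest.raises(UndefinedRatioError):
            percent_of_control([1.0], [0.0])


class TestComputeIndices:
    def test_scale_invariance_of_all_indices(self, library):
        states = preset_states()
        s, _ = synth_heart_spectrum(states["control"], seed=12)
        corr, _ = subtract_baseline(s)
        a = compute_indices(corr, library=library)
        b = compute_indices(corr.scaled(25.0), library=library)
        for name in ("norm_750", "norm_1127", "norm_1377", "ratio_c_b", "f_dmb"):
            assert getattr(b, name) == pytest.approx(getattr(a, name), rel=1e-6)

    def test_indices_lie_in_declared_ranges(self, library):
        states = preset_states()
        s, _ = synth_heart_spectrum(states["ischemia_30"], seed=3)
        corr, _ = subtract_baseline(s)
        idx = compute_indices(corr, library=library)
        assert 0.0 <= idx.f_dmb <= 1.0
        for name in ("norm_604", "norm_750", "norm_1127", "norm_1337",
                     "norm_1358", "norm_1377"):
            assert 0.0 <= getattr(idx, name) <= 1.0
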