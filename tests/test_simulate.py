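"""Synthetic heart-spectrum generator: profiles, mixing, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import argrelmax

from cardioraman import (
    ComponentProfile,
    PhysiologicalState,
    Scenario,
    ValidationError,
    component_profiles,
    component_spectrum,
    compute_indices,
    preset_states,
    scenario_from_dict,
    scenario_presets,
    subtract_baseline,
    synth_heart_spectrum,
    synth_scenario,
    write_dataset,
)
from cardioraman.quantify import cluster_amplitude


def local_maxima_positions(spectrum):
    idx = argrelmax(spectrum.intensities, order=3)[0]
    strong = idx[spectrum.intensities[idx] > 0.05 * spectrum.intensities.max()]
    return set(np.round(spectrum.shifts[strong]).astype(int))


class TestComponentProfiles:
    @pytest.mark.parametrize(
        "species,expected",
        [
            ("oMb", {1377, 1587, 1640}),
            ("dMb", {1358, 1556, 1606}),
            ("cyt_c_red", {604, 750, 1310, 1582}),
            ("cyt_b_red", {750, 1127, 1300, 1337, 1582}),
        ],
    )
    def test_local_maxima_at_assigned_positions(self, grid, species, expected):
        spectrum = component_spectrum(component_profiles()[species], grid)
        maxima = local_maxima_positions(spectrum)
        assert expected <= maxima

    def test_profiles_peak_at_unity(self, grid):
        for profile in component_profiles().values():
            s = component_spectrum(profile, grid)
            assert s.intensities.max() == pytest.approx(1.0, abs=0.05)

    def test_empty_profile_all_zero(self, grid):
        s = component_spectrum(ComponentProfile("metMb", ()), grid)
        assert np.all(s.intensities == 0.0)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValidationError):
            ComponentProfile("oMb", ((1377.0, 0.5, 14.0),))  # max amp != 1


class TestSynthHeartSpectrum:
    def test_degenerate_mixture_proportional_to_omb(self, grid):
        state = PhysiologicalState(
            f_dmb=0.0, r_c=1e-12, r_b=1e-12, cyt_scale=1e-12,
            baseline_amp=0.0, noise_sd=0.0, amide_amp=0.0,
        )
        spectrum, _ = synth_heart_spectrum(state, grid, seed=0)
        pure = component_spectrum(component_profiles()["oMb"], grid)
        expected = state.mb_scale * state.q_true * pure.intensities
        assert np.allclose(spectrum.intensities, expected, atol=1e-9)

    def test_sdt_shows_604_and_no_1377(self, library):
        """Full reduction: the c-type marker appears, the oMb ν4 vanishes."""
        spectrum, _ = synth_heart_spectrum(preset_states()["sdt"], seed=4)
        corrected, _ = subtract_baseline(spectrum)
        a604 = cluster_amplitude(corrected, library, library[604.0])
        a1377 = cluster_amplitude(corrected, library, library[1377.0])
        assert a604 > 0.03
        assert a1377 < 0.03

    def test_same_seed_bit_identical(self):
        state = preset_states()["control"]
        a, _ = synth_heart_spectrum(state, seed=99)
        b, _ = synth_heart_spectrum(state, seed=99)
        assert np.array_equal(a.intensities, b.intensities)
        c, _ = synth_heart_spectrum(state, seed=100)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_doubling_mb_scale_doubles_omb_band(self, grid):
        base = PhysiologicalState(f_dmb=0.2, r_c=0.4, r_b=0.4,
                                  baseline_amp=0.0, noise_sd=0.0, amide_amp=0.0)
        s1, t1 = synth_heart_spectrum(base, grid, seed=0)
        s2, t2 = synth_heart_spectrum(replace(base, mb_scale=2.0), grid, seed=0)
        assert t2["band_amplitudes"][1377.0] == pytest.approx(
            2.0 * t1["band_amplitudes"][1377.0]
        )
        i1377 = np.searchsorted(grid, 1377.0)
        assert s2.intensities[i1377] == pytest.approx(2.0 * s1.intensities[i1377], rel=0.02)

    def test_sdt_cytochrome_bands_exceed_control(self, library):
        """Reduction increases cytochrome scatter at 750 and 1127 cm⁻¹."""
        control, _ = synth_heart_spectrum(preset_states()["control"], seed=21)
        sdt, _ = synth_heart_spectrum(preset_states()["sdt"], seed=22)
        c_corr, _ = subtract_baseline(control)
        s_corr, _ = subtract_baseline(sdt)
        for center in (750.0, 1127.0):
            assert cluster_amplitude(s_corr, library, library[center]) > \
                cluster_amplitude(c_corr, library, library[center])

    def test_ground_truth_consistency_noise_free(self, library):
        """Noise-free pipeline recovers f_dMb within 0.01, amplitudes within 2%."""
        state = replace(preset_states()["ischemia_30"], noise_sd=0.0)
        spectrum, truth = synth_heart_spectrum(state, seed=0)
        corrected, _ = subtract_baseline(spectrum)
        idx = compute_indices(corrected, library=library, q=state.q_true)
        assert idx.f_dmb == pytest.approx(state.f_dmb, abs=0.01)
        for center in (604.0, 750.0, 1127.0, 1337.0, 1358.0, 1377.0):
            est = cluster_amplitude(corrected, library, library[center])
            assert est == pytest.approx(truth["band_amplitudes"][center], rel=0.02)

    @pytest.mark.parametrize(
        "kwargs", [{"f_dmb": 1.5}, {"r_c": -0.1}, {"mb_scale": 0.0}, {"noise_sd": -1.0}]
    )
    def test_invalid_state_rejected(self, kwargs):
        defaults = {"f_dmb": 0.1, "r_c": 0.4, "r_b": 0.4}
        defaults.update(kwargs)
        with pytest.raises(ValidationError):
            PhysiologicalState(**defaults)


class TestPresets:
    def test_required_states_present_with_anchored_values(self):
        states = preset_states()
        assert states["ischemia_30"].f_dmb == 0.5
        assert states["ischemia_30"].r_c == pytest.approx(2 * states["control"].r_c)
        assert states["ischemia_30"].r_b == states["control"].r_b
        assert states["control"].f_dmb == 0.05
        assert states["sdt"].f_dmb == 1.0 and states["sdt"].r_c == 1.0
        # uncoupling leaves myoglobin oxygenation untouched
        assert states["fccp_5min"].f_dmb == states["control"].f_dmb
        # reperfusion returns to the pre-ischemic state
        assert states["reperfusion_5"] == states["control"]
        assert states["reperfusion_30"] == states["control"]

    def test_scenarios_cover_presets_with_n3(self):
        scenarios = scenario_presets()
        assert {"control", "fccp", "ischemia", "sdt"} <= set(scenarios)
        ischemia = scenarios["ischemia"]
        assert len(ischemia.timepoints) == 5
        assert all(n == 3 for _, _, n in ischemia.timepoints)


class TestSynthScenario:
    def test_counting_and_distinct_noise(self):
        scenario = scenario_presets()["control"]
        data = synth_scenario(scenario, seed=0)
        assert len(data) == 3
        assert len({tuple(d.spectrum.intensities[:50]) for d in data}) == 3
        assert len({d.ground_truth["f_dmb"] for d in data}) == 1

    def test_full_ischemia_scenario_counts(self):
        data = synth_scenario(scenario_presets()["ischemia"], seed=0)
        assert len(data) == 15  # 5 timepoints x 3 replicates

    def test_same_master_seed_reproduces_dataset(self):
        scenario = scenario_presets()["fccp"]
        a = synth_scenario(scenario, seed=5)
        b = synth_scenario(scenario, seed=5)
        assert all(
            np.array_equal(x.spectrum.intensities, y.spectrum.intensities)
            for x, y in zip(a, b)
        )

    def test_write_dataset_layout(self, tmp_path):
        data = synth_scenario(scenario_presets()["control"], seed=1)
        manifest = write_dataset(data, tmp_path / "ds")
        assert manifest.name == "manifest.csv"
        lines = manifest.read_text().strip().splitlines()
        assert lines[0] == "filename,condition,replicate,seed"
        assert len(lines) == 4
        assert (tmp_path / "ds" / "ground_truth.csv").exists()
        assert (tmp_path / "ds" / "control_rep0.txt").exists()


def test_scenario_from_dict_with_presets_and_explicit_states():
    config = {
        "name": "custom",
        "timepoints": [
            {"label": "baseline", "state": "control", "n_replicates": 2},
            {"label": "hypoxic", "state": {"f_dmb": 0.7, "r_c": 0.9, "r_b": 0.5}},
        ],
    }
    scenario = scenario_from_dict(config)
    assert scenario.name == "custom"
    assert scenario.timepoints[0][1] == preset_states()["control"]
    assert scenario.timepoints[0][2] == 2
    assert scenario.timepoints[1][1].f_dmb == 0.7
    assert scenario.timepoints[1][2] == 3


def test_empty_scenario_rejected():
    with pytest.raises(ValidationError):
        Scenario("empty", ())
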