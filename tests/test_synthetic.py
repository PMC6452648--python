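"""Scenario presets, trajectory generation, and mass-balance invariants."""

import dataclasses

import numpy as np
import pytest

from syntropyr import mossbauer as mb
from syntropyr import stoich, synthetic

from conftest import perturbed_template


class TestPresets:
    def test_culture_endpoints(self):
        presets = synthetic.scenario_presets()
        assert presets["J5"].ch4_plateau_mmol_per_L == pytest.approx(0.7)
        assert presets["abiotic"].h2s_final_mmol_per_L == pytest.approx(3.7)
        assert presets["BES"].ch4_plateau_mmol_per_L == 0.0
        assert presets["penicillin"].ch4_plateau_mmol_per_L == pytest.approx(0.15)
        assert presets["penicillin_H2"].ch4_plateau_mmol_per_L > 10.0
        assert presets["penicillin_H2"].headspace_h2_fraction == pytest.approx(0.79)

    def test_inhibited_scenarios_form_no_pyrite(self):
        presets = synthetic.scenario_presets()
        for name in ("abiotic", "BES", "penicillin", "penicillin_H2"):
            assert presets[name].final_phase_comp.get("FeS2", 0.0) == 0.0

    def test_temperature_series_peaks_at_28(self):
        series = synthetic.scenario_presets()["temperature_series"].temperature_series
        by_temp = dict(series)
        assert by_temp[4.0] == 0.0 and by_temp[60.0] == 0.0
        assert by_temp[16.0] > 0.0 and by_temp[46.0] > 0.0
        assert max(by_temp, key=by_temp.get) == 28.0

    def test_phase_fractions_validated(self):
        with pytest.raises(ValueError):
            synthetic.ScenarioParams(name="bad", final_phase_comp={"FeS": 0.5})


class TestGenerate:
    def test_noiseless_j5_endpoints(self, j5_noiseless):
        ser = j5_noiseless
        assert ser.ch4_mmol_per_L[-1] == pytest.approx(0.7)
        comp = ser.final_composition()
        assert 0.53 <= comp["FeS2"] <= 0.63
        state = stoich.ConversionState(5.0, comp, ser.ch4_mmol_per_L[-1])
        assert 3.2 <= stoich.pyrite_methane_ratio(state) <= 4.5

    def test_exact_syntrophic_coupling(self, j5_noiseless):
        # delta FeS2 (mM) = 4 x delta CH4 at every time point
        fes2 = j5_noiseless.phases["FeS2"] * 5.0
        assert np.allclose(fes2, 4.0 * j5_noiseless.ch4_mmol_per_L, atol=1e-12)

    def test_zero_duration_gives_initial_state(self):
        params = dataclasses.replace(
            synthetic.scenario_presets()["J5"], duration_d=0.0, noise=0.0
        )
        ser = synthetic.generate(params)
        assert ser.time_d.tolist() == [0.0]
        assert ser.ch4_mmol_per_L[0] == 0.0
        assert ser.h2s_mmol_per_L[0] == pytest.approx(6.0)
        assert ser.final_composition()["FeS"] == pytest.approx(1.0)

    def test_seed_determinism(self):
        params = dataclasses.replace(synthetic.scenario_presets()["J5"], seed=5)
        a, b = synthetic.generate(params), synthetic.generate(params)
        c = synthetic.generate(dataclasses.replace(params, seed=6))
        assert np.array_equal(a.ch4_mmol_per_L, b.ch4_mmol_per_L)
        assert not np.array_equal(a.ch4_mmol_per_L, c.ch4_mmol_per_L)

    def test_iron_conservation(self):
        for name in ("J5", "abiotic", "penicillin"):
            params = dataclasses.replace(
                synthetic.scenario_presets()[name], noise=0.0
            )
            ser = synthetic.generate(params)
            total = sum(ser.phases.values())
            assert np.allclose(total, 1.0, atol=1e-12)
            # noisy mode: renormalization keeps iron exactly conserved
            noisy = synthetic.generate(dataclasses.replace(params, noise=0.05))
            assert np.allclose(sum(noisy.phases.values()), 1.0, atol=1e-9)

    def test_sulfur_conservation(self, j5_noiseless):
        ser = j5_noiseless
        consumed = 6.0 - ser.h2s_mmol_per_L
        assert np.allclose(
            consumed, ser.sulfide_to_pyrite_mM + ser.sulfide_to_fesx_mM, atol=1e-12
        )
        assert np.all(ser.sulfide_to_fesx_mM >= -1e-12)
        # biotic channel takes exactly 1 S from solution per FeS2 formed
        assert np.allclose(ser.sulfide_to_pyrite_mM, ser.phases["FeS2"] * 5.0)

    def test_series_monotone_and_nonnegative(self, j5_noiseless):
        ser = j5_noiseless
        assert np.all(np.diff(ser.time_d) > 0)
        for arr in (ser.ch4_mmol_per_L, ser.h2s_mmol_per_L, ser.cells_per_mL):
            assert np.all(arr >= 0)

    def test_cell_growth_reaches_final_density(self, j5_noiseless):
        assert j5_noiseless.cells_per_mL[0] == pytest.approx(2e5)
        assert j5_noiseless.cells_per_mL[-1] == pytest.approx(4e6)


class TestSpectrumBridge:
    def test_abiotic_composition_round_trip(self):
        comp = mb.PhaseComposition({"FeS": 0.64, "FeSx": 0.36})
        spec = synthetic.spectrum_for(comp)
        template = perturbed_template(mb.sites_for_composition(dict(comp)))
        fit = mb.fit_spectrum(spec, template)
        assert mb.phase_fractions(fit)["FeS"] == pytest.approx(0.64, abs=0.01)

    def test_pure_pyrite_is_a_doublet(self):
        spec = synthetic.spectrum_for({"FeS2": 1.0})
        depth = spec.baseline - spec.signal
        # two resolved minima of equal depth around the center shift
        peaks = spec.velocity[depth > 0.9 * depth.max()]
        assert peaks.min() < 0.4 < peaks.max()

    def test_unknown_phase_rejected(self):
        with pytest.raises(KeyError):
            synthetic.spectrum_for({"wustite": 1.0})

    def test_seeded_noise_reproducible(self):
        comp = {"FeS": 0.64, "FeSx": 0.36}
        a = synthetic.spectrum_for(comp, seed=3, noise_sd=0.01)
        b = synthetic.spectrum_for(comp, seed=3, noise_sd=0.01)
        assert np.array_equal(a.signal, b.signal)


def test_tsv_round_trip(tmp_path, j5_noiseless):
    path = tmp_path / "traj.tsv"
    j5_noiseless.write(path)
    df = synthetic.read_time_series(path)
    assert "ch4_mmol_per_L" in df.columns
    assert df["ch4_mmol_per_L"].iloc[-1] == pytest.approx(0.7)
    assert (tmp_path / "traj.tsv.meta.json").exists()


def test_end_to_end_ratio_recovery(j5_noiseless):
    """generate -> spectrum -> fit -> fractions -> ratio round trip."""
    comp = j5_noiseless.final_composition()
    spec = synthetic.spectrum_for(comp)
    template = perturbed_template(mb.sites_for_composition(dict(comp)), dv=0.03, db=1.03)
    fit = mb.fit_spectrum(spec, template)
    fitted = mb.phase_fractions(fit)
    state = stoich.ConversionState(5.0, fitted, j5_noiseless.ch4_mmol_per_L[-1])
    generating = stoich.pyrite_methane_ratio(
        stoich.ConversionState(5.0, comp, j5_noiseless.ch4_mmol_per_L[-1])
    )
    assert stoich.pyrite_methane_ratio(state) == pytest.approx(generating, abs=0.3)
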