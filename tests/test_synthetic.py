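"""Simulator components, phenotype gating, cohort reproducibility."""
import numpy as np
import pytest

from optoerg.errors import DomainError
from optoerg.photometry import Adaptation, StimulusSpec
from optoerg.preprocessing import Channel
from optoerg.synthetic import (
    CohortSpec,
    ComponentTemplate,
    GENOTYPES,
    ProtocolEntry,
    RD1_REACHR,
    WT,
    WT_REACHR,
    component_wave,
    default_protocol,
    default_template,
    simulate_cohort,
    simulate_sweepset,
    validate_protocol,
)

from conftest import time_grid

LIGHT_100 = StimulusSpec(100.0, background_luminance=30.0)
LIGHT_10 = StimulusSpec(10.0, background_luminance=30.0)


class TestComponentWave:
    def test_pulse_extremum_at_peak(self):
        tpl = ComponentTemplate("b", 50.0, 40.0, rise_sigma_ms=8.0, decay_sigma_ms=12.0)
        t = time_grid()
        wave = component_wave(tpl, t)
        assert wave[np.argmax(wave)] == pytest.approx(40.0, rel=1e-9)
        assert abs(t[np.argmax(wave)] - 50.0) <= 0.5

    def test_ao_first_sample_exceeds_noise_criterion(self):
        """The optogenetic deflection is already clearly off baseline 0.5 ms in."""
        template = default_template(WT_REACHR)
        ao = next(
            gc.template
            for gc in template.erg["light"]
            if gc.template.kind == "a_o"
        )
        value = component_wave(ao, np.array([0.5]))[0]
        assert abs(value) > 3 * 3.0  # 3 x default noise sd

    def test_ao_zero_before_stimulus(self):
        tpl = ComponentTemplate("a_o", 8.0, -30.0, rise_sigma_ms=3.0, decay_sigma_ms=2.5)
        assert np.all(component_wave(tpl, np.array([-5.0, -0.5])) == 0.0)

    def test_mains_matches_closed_form(self):
        tpl = ComponentTemplate("mains", 0.0, 2.0, frequency_hz=50.0)
        t = time_grid()
        expected = 2.0 * np.sin(2 * np.pi * 50.0 * t / 1000.0)
        assert np.allclose(component_wave(tpl, t), expected)

    def test_oscillatory_kind_silent_before_onset(self):
        tpl = ComponentTemplate(
            "op_burst", 25.0, 1.0, frequency_hz=110.0, decay_tau_ms=15.0
        )
        t = time_grid()
        wave = component_wave(tpl, t)
        assert np.all(wave[t < 25.0] == 0.0)

    def test_white_noise_kind_is_not_deterministic(self):
        tpl = ComponentTemplate("white_noise", 0.0, 3.0)
        with pytest.raises(DomainError):
            component_wave(tpl, time_grid())

    def test_oscillatory_frequency_must_be_in_op_band(self):
        with pytest.raises(DomainError):
            ComponentTemplate("op_burst", 25.0, 1.0, frequency_hz=50.0, decay_tau_ms=15.0)


class TestSuperposition:
    def test_noise_free_sweep_equals_component_sum(self, calibration):
        template = default_template(WT_REACHR)
        ss = simulate_sweepset(
            template, LIGHT_100, noise_sd_uv=0.0, mains_amplitude_uv=0.0, seed=0
        )
        t = time_grid()
        manual = np.zeros_like(t)
        for tpl in template.concrete_components(LIGHT_100, Channel.ERG, calibration):
            manual += component_wave(tpl, t)
        assert np.allclose(ss.sweeps[0], manual)
        assert np.allclose(ss.sweeps, ss.sweeps[0])  # all sweeps identical


class TestIntensityResponse:
    def test_component_amplitudes_nondecreasing_in_energy(self, calibration):
        energies = [5.0, 10.0, 30.0, 100.0, 900.0]
        for genotype in GENOTYPES:
            template = default_template(genotype)
            previous: dict[str, float] = {}
            for energy in energies:
                stim = StimulusSpec(energy, background_luminance=30.0)
                for tpl in template.concrete_components(stim, Channel.ERG, calibration):
                    size = abs(tpl.peak_amplitude_uv)
                    if tpl.kind in previous:
                        assert size >= previous[tpl.kind] - 1e-12
                    previous[tpl.kind] = size


class TestPhenotypeGating:
    def test_wild_type_has_no_early_trough(self):
        ss = simulate_sweepset(WT, LIGHT_100, noise_sd_uv=0.0, mains_amplitude_uv=0.0)
        t = time_grid()
        early = ss.sweeps[0][(t > 0.0) & (t < 12.0)]
        assert early.min() > -3 * 3.0  # never below 3 x default noise sd

    def test_degenerate_retina_silent_below_reachr_threshold(self):
        ss = simulate_sweepset(
            RD1_REACHR, LIGHT_10, noise_sd_uv=0.0, mains_amplitude_uv=0.0
        )
        assert np.abs(ss.sweeps).max() < 2.0

    def test_reachr_trace_troughs_at_published_time(self):
        ss = simulate_sweepset(
            WT_REACHR, LIGHT_100, noise_sd_uv=0.0, mains_amplitude_uv=0.0
        )
        t = time_grid()
        window = (t > 0.5) & (t <= 12.0)
        trough_time = t[window][np.argmin(ss.sweeps[0][window])]
        assert trough_time == pytest.approx(8.0, abs=0.5)

    def test_blue_flash_on_amber_background_dampens_b_harder(self, calibration):
        blue = StimulusSpec(
            5.0, background_luminance=3500.0,
            flash_color="blue", background_color="amber",
        )
        wtr = default_template(WT_REACHR)
        comps = {
            c.kind: c for c in wtr.concrete_components(blue, Channel.ERG, calibration)
        }
        assert comps["b"].peak_amplitude_uv == pytest.approx(107.86 * 0.538, rel=1e-9)
        assert "a_o" not in comps  # blue flash is below the ReaChR threshold

    def test_unknown_genotype_rejected(self):
        with pytest.raises(DomainError):
            simulate_sweepset("WT_ChR2", LIGHT_100)


class TestTrialStructure:
    def test_default_trial_counts_follow_protocol(self):
        dark = simulate_sweepset(
            WT, StimulusSpec(3.0, adaptation=Adaptation.DARK), seed=0
        )
        assert dark.n_trials == 3
        light = simulate_sweepset(WT, LIGHT_100, seed=0)
        assert light.n_trials == 20
        brief = simulate_sweepset(
            WT, StimulusSpec(150.0, background_luminance=30.0), seed=0
        )
        assert brief.n_trials == 5

    def test_trial_onsets_follow_intertrial_interval(self):
        ss = simulate_sweepset(WT, LIGHT_100, seed=0)
        onsets = np.asarray(ss.trial_onset_times_s)
        assert np.allclose(np.diff(onsets), 0.987)

    def test_dark_adapted_itis_warn_about_mains_period(self):
        entries = [
            ProtocolEntry(StimulusSpec(0.01, adaptation=Adaptation.DARK),
                          Channel.ERG, 3, 5.0)
        ]
        with pytest.warns(UserWarning, match="multiple of"):
            messages = validate_protocol(entries)
        assert len(messages) == 1

    def test_light_adapted_itis_pass_validation(self):
        entries = [e for e in default_protocol()
                   if e.stimulus.adaptation is Adaptation.LIGHT]
        assert validate_protocol(entries) == []


class TestCohort:
    def test_same_seed_is_bitwise_identical(self):
        spec = CohortSpec(
            n_per_group={WT: 2, WT_REACHR: 2, RD1_REACHR: 2},
            seed=7,
            protocol=(ProtocolEntry(LIGHT_100, Channel.ERG, 5, 0.987),),
        )
        rec1, truth1 = simulate_cohort(spec)
        rec2, truth2 = simulate_cohort(spec)
        assert truth1.equals(truth2)
        for a, b in zip(rec1, rec2):
            assert a.animal_id == b.animal_id
            assert np.array_equal(a.sweepset.sweeps, b.sweepset.sweeps)

    def test_zero_variability_makes_animals_identical_to_template(self):
        spec = CohortSpec(
            n_per_group={WT: 3},
            seed=3,
            noise_sd_uv=0.0,
            mains_amplitude_uv=0.0,
            between_animal_cv=0.0,
            time_jitter_sd_ms=0.0,
            protocol=(ProtocolEntry(LIGHT_100, Channel.ERG, 2, 0.987),),
        )
        recordings, _ = simulate_cohort(spec)
        reference = simulate_sweepset(
            WT, LIGHT_100, n_sweeps=2, iti_s=0.987,
            noise_sd_uv=0.0, mains_amplitude_uv=0.0,
        )
        for rec in recordings:
            assert np.allclose(rec.sweepset.sweeps, reference.sweeps)

    def test_truth_table_carries_all_components(self):
        spec = CohortSpec(
            n_per_group={WT_REACHR: 2}, seed=1,
            protocol=(ProtocolEntry(LIGHT_100, Channel.ERG, 2, 0.987),),
        )
        _, truth = simulate_cohort(spec)
        kinds = set(truth["component"])
        assert {"a", "b", "a_o", "op_burst", "N1", "N1_o"} <= kinds

    def test_group_counts_validated(self):
        with pytest.raises(DomainError):
            CohortSpec(n_per_group={WT: 0})
        with pytest.raises(DomainError):
            CohortSpec(n_per_group={"sparrow": 3})
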