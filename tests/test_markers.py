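"""Wave-marker placement: conventions, presence logic, extremum correctness."""
import numpy as np
import pytest

from optoerg.errors import DomainError
from optoerg.markers import (
    DEFAULT_WINDOWS,
    amplitude,
    detect_ao,
    implicit_time,
    place_erg_markers,
    place_vep_markers,
)
from optoerg.photometry import Adaptation, StimulusSpec
from optoerg.pipeline import noise_free_markerset
from optoerg.preprocessing import Channel
from optoerg.synthetic import (
    GENOTYPES,
    RD1_REACHR,
    WT,
    WT_REACHR,
    default_protocol,
    default_template,
)

from conftest import make_trace, time_grid

LIGHT_100 = StimulusSpec(100.0, background_luminance=30.0)
DARK_3 = StimulusSpec(3.0, adaptation=Adaptation.DARK)


def gaussian(t_ms, tp, amp, sr, sd):
    return np.where(
        t_ms < tp,
        amp * np.exp(-((t_ms - tp) ** 2) / (2 * sr**2)),
        amp * np.exp(-((t_ms - tp) ** 2) / (2 * sd**2)),
    )


class TestExtremumOracle:
    """The reported extremum must equal a brute-force scan of the window."""

    @pytest.mark.parametrize("seed", range(5))
    def test_erg_and_vep_windows_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0.0, 5.0, 1000)
        trace = make_trace(values)
        t = trace.time_ms()

        def brute(window, mode):
            mask = (t > window[0]) & (t <= window[1])
            seg = values[mask]
            idx = np.argmin(seg) if mode == "min" else np.argmax(seg)
            return t[mask][idx], seg[idx]

        erg = place_erg_markers(trace, LIGHT_100)
        base = np.mean(values[:40])
        for name, window, mode in [
            ("a_o", DEFAULT_WINDOWS.a_o, "min"),
            ("a", DEFAULT_WINDOWS.a, "min"),
            ("b", DEFAULT_WINDOWS.b, "max"),
        ]:
            marker = erg[name]
            if not marker.present:
                continue
            t_exp, v_exp = brute(window, mode)
            assert marker.implicit_time_ms == t_exp
            assert marker.amplitude_uv == pytest.approx(abs(v_exp - base), rel=1e-12)

        vep = place_vep_markers(trace)
        for name, window, mode in [
            ("N1_o", DEFAULT_WINDOWS.n1_o, "min"),
            ("P1", DEFAULT_WINDOWS.p1, "max"),
        ]:
            marker = vep[name]
            if marker.present:
                t_exp, _ = brute(window, mode)
                assert marker.implicit_time_ms == t_exp

    def test_plateau_resolves_to_earliest_sample(self):
        values = np.zeros(1000)
        t = time_grid()
        values[(t >= 15.0) & (t <= 25.0)] = -10.0  # flat trough across a window
        marker = place_erg_markers(make_trace(values), LIGHT_100)["a"]
        assert marker.present
        # earliest attainment inside (12, 30]
        assert marker.implicit_time_ms == 15.0


class TestDetectAo:
    def test_reachr_trace_yields_published_trough_time(self, config):
        ms = noise_free_markerset(WT_REACHR, LIGHT_100, Channel.ERG, config)
        assert ms["a_o"].present
        assert ms["a_o"].implicit_time_ms == pytest.approx(8.0, abs=0.5)

    @pytest.mark.parametrize("energy", [10.0, 30.0, 100.0, 900.0])
    def test_wild_type_never_shows_ao(self, energy, config):
        stim = StimulusSpec(energy, background_luminance=30.0)
        ms = noise_free_markerset(WT, stim, Channel.ERG, config)
        assert not ms["a_o"].present

    def test_flat_trace_with_noise_estimate_is_absent(self):
        marker = detect_ao(make_trace(np.zeros(1000)), noise_sd=1.0)
        assert not marker.present

    def test_window_exceeding_trace_rejected(self):
        with pytest.raises(DomainError):
            detect_ao(make_trace(np.zeros(30)), noise_sd=1.0)


class TestErgConventions:
    def test_dark_adapted_b_referenced_to_a_trough(self, config):
        ms = noise_free_markerset(WT, DARK_3, Channel.ERG, config)
        assert ms["a"].present and ms["b"].present and not ms["a_o"].present
        assert ms["b"].reference == "a_peak"
        # b from the a trough exceeds b from baseline
        assert ms["b"].amplitude_uv > 300.0

    def test_light_adapted_b_referenced_to_baseline(self, config):
        ms = noise_free_markerset(WT, LIGHT_100, Channel.ERG, config)
        assert ms["b"].reference == "baseline"

    def test_degenerate_retina_silent_below_threshold(self, config):
        stim = StimulusSpec(10.0, background_luminance=30.0)
        ms = noise_free_markerset(RD1_REACHR, stim, Channel.ERG, config)
        assert not any(m.present for m in ms.markers.values())

    def test_polarity_convention_on_negated_trace(self, config):
        t = time_grid()
        valid = gaussian(t, 17.4, -15.0, 2.5, 4.0) + gaussian(t, 51.62, 60.0, 8.0, 12.0)
        ms_valid = place_erg_markers(make_trace(valid), LIGHT_100)
        ms = place_erg_markers(make_trace(-valid), LIGHT_100)
        # flipping polarity leaves at most the inverted a-wave tail in the
        # b window: absent, or tiny next to the true b-wave
        if ms["b"].present:
            assert ms["b"].amplitude_uv < 0.2 * ms_valid["b"].amplitude_uv

    def test_a_flagged_low_confidence_under_ao(self, config):
        ms = noise_free_markerset(WT_REACHR, LIGHT_100, Channel.ERG, config)
        assert ms["a_o"].present
        assert ms["a"].present
        assert ms["a"].confidence.value == "low"

    def test_short_trace_rejected(self):
        with pytest.raises(DomainError):
            place_erg_markers(make_trace(np.zeros(100)), LIGHT_100)


class TestVepConventions:
    def test_reachr_vep_shows_both_deflections_at_published_times(self, config):
        ms = noise_free_markerset(WT_REACHR, LIGHT_100, Channel.VEP, config)
        assert ms["N1"].present and ms["N1_o"].present
        assert ms["N1"].implicit_time_ms == pytest.approx(55.25, abs=0.5)
        assert ms["N1_o"].implicit_time_ms == pytest.approx(27.12, abs=0.5)
        assert ms["N1"].reference == "P1_peak"

    def test_wild_type_vep_lacks_early_deflection(self, config):
        ms = noise_free_markerset(WT, LIGHT_100, Channel.VEP, config)
        assert ms["N1"].present
        assert not ms["N1_o"].present

    def test_flat_trace_yields_no_markers(self):
        ms = place_vep_markers(make_trace(np.zeros(1000)))
        assert not any(m.present for m in ms.markers.values())

    def test_n1_must_follow_p1(self):
        # positive peak at the very end of the P1 window, nothing after
        t = time_grid()
        values = gaussian(t, 50.0, 30.0, 3.0, 3.0)
        ms = place_vep_markers(make_trace(values))
        if ms["P1"].present:
            n1 = ms["N1"]
            assert (not n1.present) or n1.implicit_time_ms > ms["P1"].implicit_time_ms


class TestAmplitudeQueries:
    def test_light_adapted_b_amplitude_from_baseline(self):
        t = time_grid()
        values = gaussian(t, 50.0, 40.0, 5.0, 5.0)
        ms = place_erg_markers(make_trace(values), LIGHT_100)
        assert amplitude(ms, "b") == pytest.approx(40.0, rel=1e-3)
        assert implicit_time(ms, "b") == pytest.approx(50.0, abs=0.5)

    def test_dark_adapted_b_amplitude_spans_a_trough(self):
        t = time_grid()
        values = gaussian(t, 16.0, -30.0, 2.0, 2.0) + gaussian(t, 40.0, 50.0, 5.0, 5.0)
        ms = place_erg_markers(make_trace(values), DARK_3)
        assert amplitude(ms, "b") == pytest.approx(80.0, rel=1e-2)

    def test_absent_marker_returns_none(self):
        ms = place_erg_markers(make_trace(np.zeros(1000)), LIGHT_100)
        assert amplitude(ms, "a_o") is None
        assert implicit_time(ms, "a_o") is None


class TestScaleInvariance:
    def test_scaling_preserves_times_and_scales_amplitudes(self, config):
        ms1 = noise_free_markerset(WT, LIGHT_100, Channel.ERG, config)
        sweep = noise_free_markerset  # noqa: F841 (documentation of provenance)
        t = time_grid()
        template = default_template(WT)
        clean = template.clean_trace(LIGHT_100, t, Channel.ERG, config.calibration)
        c = 2.5
        ms_a = place_erg_markers(make_trace(clean), LIGHT_100)
        ms_b = place_erg_markers(make_trace(c * clean), LIGHT_100)
        for name in ("a", "b"):
            assert ms_a[name].present and ms_b[name].present
            assert ms_b[name].implicit_time_ms == ms_a[name].implicit_time_ms
            assert ms_b[name].amplitude_uv == pytest.approx(
                c * ms_a[name].amplitude_uv, rel=1e-9
            )


class TestTemplateRecovery:
    """Noise-free simulator traces across all genotypes and protocol stimuli.

    Every clear-confidence marker must match the generating template: ERG
    times within one sample and amplitudes within 1 %.  VEP amplitudes are
    asserted at 35 %: the 3–100 Hz cortical band-pass removes a calculable
    fraction of slow-pulse amplitude, so pre-filter template amplitudes are
    not recoverable to 1 % by construction (times still hold to one sample).
    Low-confidence markers (a-wave under an a_o) are contaminated by design
    and only checked for presence.
    """

    @pytest.mark.parametrize("genotype", GENOTYPES)
    def test_presence_and_values_match_generating_truth(self, genotype, config):
        template = default_template(genotype)
        for entry in default_protocol():
            stim, channel = entry.stimulus, entry.channel
            expected = template.expected_markers(stim, channel, config.calibration)
            ms = noise_free_markerset(genotype, stim, channel, config)
            for name, exp in expected.items():
                got = ms[name]
                context = f"{genotype} {stim.label} {channel.value} {name}"
                assert got.present == exp.present, context
                if not exp.present or got.confidence.value == "low":
                    continue
                assert got.implicit_time_ms == pytest.approx(
                    exp.implicit_time_ms, abs=0.5
                ), context
                amp_tol = 0.35 if channel is Channel.VEP else 0.01
                assert got.amplitude_uv == pytest.approx(
                    exp.amplitude_uv, rel=amp_tol
                ), context
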