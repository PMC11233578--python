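"""Intrinsic-feature extraction and L1-interneuron classification."""

import numpy as np
import pytest

from gabacircuit.ephys import (
    ClassifierConfig,
    Spike,
    classify_l1_interneuron,
    detect_aps,
    extract_features,
    first_ahp_latency,
    hump_amplitude,
    input_resistance,
    membrane_time_constant,
    sag_ratio,
)
from gabacircuit.simulate import PlantedCellParams, SweepSet, simulate_voltage_sweeps

FS = 20000.0


def _passive_sweeps(rin_mohm=100.0, tau_ms=20.0, v_rest=-65.0):
    """Ideal ohmic cell, no sag, no spikes: analytic construction."""
    t = np.arange(int(1.5 * FS)) / FS - 0.2
    currents = np.arange(-50.0, 50.1, 10.0)
    tau = tau_ms / 1000.0
    v = np.empty((currents.size, t.size))
    for j, i_pa in enumerate(currents):
        d = i_pa * rin_mohm * 1e-3 * (1 - np.exp(-np.clip(t, 0, None) / tau))
        d[t < 0] = 0.0
        off = t > 1.0
        d[off] = d[np.searchsorted(t, 1.0) - 1] * np.exp(-(t[off] - 1.0) / tau)
        v[j] = v_rest + d
    return SweepSet(t, v, currents, FS, 0.0, 1.0, PlantedCellParams())


class TestInputResistance:
    def test_ideal_ohmic_cell_exact(self):
        assert input_resistance(_passive_sweeps(100.0)) == pytest.approx(100.0, rel=1e-6)

    def test_zero_deflection_gives_zero(self):
        sw = _passive_sweeps(100.0)
        sw.voltage[:] = -65.0
        assert input_resistance(sw) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        sw = simulate_voltage_sweeps(
            PlantedCellParams(rin_mohm=150.0), noise_sd=0.3, seed=4
        )
        assert input_resistance(sw) == pytest.approx(150.0, rel=0.05)


class TestMembraneTimeConstant:
    @pytest.mark.parametrize("tau_ms,rel", [(20.0, 0.01), (5.0, 0.02)])
    def test_closed_form_exponential_recovered(self, tau_ms, rel):
        sw = _passive_sweeps(tau_ms=tau_ms)
        assert membrane_time_constant(sw) == pytest.approx(tau_ms, rel=rel)

    def test_constant_trace_flagged(self):
        sw = _passive_sweeps()
        sw.voltage[:] = -65.0
        with pytest.raises(ValueError):
            membrane_time_constant(sw)


class TestSagRatio:
    def test_arithmetic_on_fabricated_deflections(self):
        sw = _passive_sweeps(tau_ms=1.0)  # settles immediately
        j = 0  # −50 pA sweep
        i_on, i_off = int(0.2 * FS), int(1.2 * FS)
        sw.voltage[j, i_on:i_off] = -65.0 - 5.0
        sw.voltage[j, i_on: i_on + int(0.1 * FS)] = -65.0 - 10.0
        assert sag_ratio(sw) == pytest.approx(0.5, rel=1e-9)

    def test_no_sag_limit_is_one(self):
        sw = simulate_voltage_sweeps(PlantedCellParams(sag_depth_mv=0.0))
        assert sag_ratio(sw) == pytest.approx(1.0, abs=0.01)

    def test_ratio_strictly_decreases_with_planted_sag_depth(self):
        ratios = [
            sag_ratio(simulate_voltage_sweeps(PlantedCellParams(sag_depth_mv=d)))
            for d in (0.0, 2.0, 4.0, 6.0)
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestDetectAps:
    def test_subthreshold_sweep_has_no_spikes(self):
        sw = _passive_sweeps()
        assert detect_aps(sw.voltage[2], FS) == []

    def test_two_inserted_spikes_detected_in_order(self):
        sw = simulate_voltage_sweeps(PlantedCellParams(archetype="SBC-like"))
        from gabacircuit.simulate import _spike_waveform

        p = sw.params
        t = sw.time
        v = sw.voltage[5].copy()  # 0 pA sweep: flat baseline
        v += _spike_waveform(t, 0.1, p) + _spike_waveform(t, 0.3, p)
        spikes = detect_aps(v, FS, int(0.2 * FS))
        assert len(spikes) == 2
        assert spikes[0].peak_index < spikes[1].peak_index

    def test_planted_latency_recovered_to_one_sample(self, sbc_sweeps, ngf_sweeps):
        for sw in (sbc_sweeps, ngf_sweeps):
            i_on = int(0.2 * sw.sampling_rate)
            j = int(np.flatnonzero(sw.current_steps == sw.params.rheobase_pa)[0])
            spikes = detect_aps(sw.voltage[j], sw.sampling_rate, i_on)
            assert spikes, "no spike detected on the rheobase sweep"
            planted = sw.params.planted["spike_latency_s"]
            assert abs(spikes[0].peak_time - planted) <= 1.0 / sw.sampling_rate + 1e-12

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_aps(np.zeros(100), 5000.0)


class TestFirstAhpLatency:
    def test_search_bounded_by_second_spike(self):
        v = np.zeros(2000)
        spikes = [
            Spike(100, 0.005, 10.0, 110, 0.0055, 80.0),
            Spike(400, 0.02, 10.0, 410, 0.0205, 80.0),
        ]
        v[300] = -20.0  # true AHP minimum before second spike
        v[600] = -50.0  # deeper minimum, but beyond the bound
        lat = first_ahp_latency(v, spikes, FS, 1900)
        assert lat == pytest.approx((300 - 100) / FS)

    def test_no_spikes_is_error(self):
        with pytest.raises(ValueError):
            first_ahp_latency(np.zeros(100), [], FS, 99)

    def test_minimum_at_step_end_flagged(self):
        v = -np.arange(2000.0)  # monotonically decreasing: no local AHP
        spikes = [Spike(10, 0.0, 0.0, 20, 0.0005, 50.0)]
        with pytest.raises(ValueError):
            first_ahp_latency(v, spikes, FS, 2000)


class TestHumpAmplitude:
    def test_flat_depolarisation_gives_zero_ngf_hump(self):
        v = np.full(int(0.8 * FS), -60.0)
        ngf, sbc = hump_amplitude(v, FS, 0, [])
        assert ngf == pytest.approx(0.0)
        assert np.isnan(sbc)

    def test_planted_hump_recovered_by_both_rules(self, sbc_sweeps, ngf_sweeps):
        for sw, rule in ((ngf_sweeps, "hump_ngf_mv"), (sbc_sweeps, "hump_sbc_mv")):
            feats, _ = extract_features(sw)
            got = feats.hump_ngf_rule_mv if rule == "hump_ngf_mv" else feats.hump_sbc_rule_mv
            assert got == pytest.approx(sw.params.planted[rule], rel=0.02)


class TestClassifyL1Interneuron:
    def test_archetypes_map_to_expected_classes(self, sbc_sweeps, ngf_sweeps):
        _, call_sbc = extract_features(sbc_sweeps)
        _, call_ngf = extract_features(ngf_sweeps)
        assert call_sbc.cell_class == "pSBC"
        assert call_ngf.cell_class == "pNGF"

    def test_boundary_ties_to_pngf(self):
        cfg = ClassifierConfig(spike_latency_threshold_s=0.1)
        assert classify_l1_interneuron(0.1, 0.01, cfg).cell_class == "pNGF"
        assert classify_l1_interneuron(0.0999, 0.01, cfg).cell_class == "pSBC"

    def test_missing_feature_gives_other(self):
        assert classify_l1_interneuron(float("nan"), 0.01).cell_class == "other"


class TestDcOffsetInvariance:
    def test_features_invariant_except_threshold(self, sbc_sweeps):
        feats, _ = extract_features(sbc_sweeps)
        shifted = SweepSet(
            sbc_sweeps.time, sbc_sweeps.voltage + 7.0, sbc_sweeps.current_steps,
            sbc_sweeps.sampling_rate, sbc_sweeps.step_onset, sbc_sweeps.step_duration,
            sbc_sweeps.params,
        )
        f2, _ = extract_features(shifted)
        assert f2.input_resistance_mohm == pytest.approx(feats.input_resistance_mohm, rel=1e-9)
        assert f2.membrane_tau_ms == pytest.approx(feats.membrane_tau_ms, rel=1e-6)
        assert f2.sag_ratio == pytest.approx(feats.sag_ratio, rel=1e-9)
        assert f2.first_spike_latency_s == feats.first_spike_latency_s
        assert f2.ap_amplitude_mv == pytest.approx(feats.ap_amplitude_mv, rel=1e-9)
        assert f2.ap_threshold_mv == pytest.approx(feats.ap_threshold_mv + 7.0, abs=1e-9)
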