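"""FF-IPSC isolation, exclusion rules, charge, spike probability and
connectivity summaries."""

import numpy as np
import pandas as pd
import pytest

from gabacircuit.simulate import PscSim, _biexp, simulate_psc_recording
from gabacircuit.synaptic import (
    apply_exclusion_rules,
    connectivity_summary,
    inward_charge,
    isolate_ff_ipsc,
    spike_probability,
)

FS = 20000.0


class TestIsolateFfIpsc:
    def test_pure_scaling_leaves_zero_residual(self):
        tr = simulate_psc_recording(PscSim(ipsc_release_probability=0.0))
        res = isolate_ff_ipsc(
            tr.trials_minus50.mean(0), tr.trials_minus92.mean(0),
            tr.stim_time_s, tr.sampling_rate,
        )
        assert not res.ipsc_detected
        assert np.abs(res.isolated_trace).max() < 1e-9

    def test_planted_ipsc_recovered(self, psc_trials):
        res = isolate_ff_ipsc(
            psc_trials.trials_minus50.mean(0), psc_trials.trials_minus92.mean(0),
            psc_trials.stim_time_s, psc_trials.sampling_rate,
        )
        assert res.amplitude_pa == pytest.approx(50.0, rel=0.05)
        assert res.latency_ms == pytest.approx(3.0, abs=0.2)
        assert res.scale_factor == pytest.approx(50.0 / 92.0, rel=0.01)

    def test_noise_only_fails_gracefully(self, rng):
        noise = rng.normal(0, 1.0, (5, 1600))
        with pytest.raises(ValueError):
            isolate_ff_ipsc(noise.mean(0), noise.mean(0), 0.01, FS)

    def test_exact_identity_for_affine_scaled_kernels(self):
        # compound = k·EPSC + delayed IPSC → residual recovers the IPSC
        # to numerical precision (linear-algebra identity, no noise)
        t = np.arange(1600) / FS
        epsc = -120.0 * _biexp(t, 0.011, 0.5, 5.0)
        ipsc = 40.0 * _biexp(t, 0.015, 1.0, 12.0)
        compound = 0.6 * epsc + ipsc
        res = isolate_ff_ipsc(compound, epsc, 0.01, FS)
        assert np.abs(res.isolated_trace - ipsc).max() < 1e-6


class TestExclusionRules:
    def _isolate(self, tr):
        return isolate_ff_ipsc(
            tr.trials_minus50.mean(0), tr.trials_minus92.mean(0),
            tr.stim_time_s, tr.sampling_rate,
        )

    def test_full_incidence_excluded(self, psc_trials):
        res = apply_exclusion_rules(psc_trials, self._isolate(psc_trials))
        assert res.excluded and res.exclusion_reason == "outward_incidence_100"
        assert res.outward_incidence == 1.0

    def test_short_latency_excluded(self):
        tr = simulate_psc_recording(PscSim(ipsc_latency_ms=0.6, ipsc_release_probability=0.5))
        res = apply_exclusion_rules(tr, self._isolate(tr))
        assert res.excluded and res.exclusion_reason == "latency_below_1ms"

    def test_partial_incidence_normal_latency_kept(self):
        tr = simulate_psc_recording(PscSim(ipsc_release_probability=0.7, seed=3))
        res = apply_exclusion_rules(tr, self._isolate(tr))
        assert 0.0 < res.outward_incidence < 1.0
        assert not res.excluded and res.exclusion_reason == "none"
        # detection matches the planted per-trial ground truth
        assert res.outward_incidence == pytest.approx(tr.ipsc_present.mean())


class TestInwardCharge:
    def test_rectangle(self):
        trace = np.zeros(int(0.01 * FS))
        trace[40: 40 + int(0.002 * FS)] = -100.0
        q = inward_charge(trace, FS, (0.0, 0.01))
        assert q.inward_charge_pc == pytest.approx(0.2, rel=1e-6)

    def test_purely_outward_is_zero(self):
        assert inward_charge(np.full(200, 30.0), FS, (0.0, 0.01)).inward_charge_pc == 0.0

    def test_biexponential_matches_analytic_integral(self):
        t = np.arange(int(0.4 * FS)) / FS
        tr_ms, td_ms, amp = 0.5, 5.0, 80.0
        trace = -amp * _biexp(t, 0.0, tr_ms, td_ms)
        tr, td = tr_ms / 1000, td_ms / 1000
        t_pk = tr * td / (td - tr) * np.log(td / tr)
        peak = np.exp(-t_pk / td) - np.exp(-t_pk / tr)
        analytic = amp * (td - tr) / peak * 1.0  # pA·s == pC
        got = inward_charge(trace, FS, (0.0, 0.4)).inward_charge_pc
        assert got == pytest.approx(analytic, rel=0.01)

    def test_additive_over_disjoint_windows_and_outward_invariant(self, rng):
        trace = rng.normal(0, 20, 4000)
        a = inward_charge(trace, FS, (0.0, 0.1)).inward_charge_pc
        b = inward_charge(trace, FS, (0.1, 0.2)).inward_charge_pc
        whole = inward_charge(trace, FS, (0.0, 0.2)).inward_charge_pc
        assert a + b == pytest.approx(whole, rel=1e-9)
        plus_outward = trace + np.abs(rng.normal(0, 5, 4000)) * (trace > 0)
        assert inward_charge(plus_outward, FS, (0.0, 0.2)).inward_charge_pc == pytest.approx(
            whole, rel=1e-9
        )

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            inward_charge(np.zeros(100), FS, (0.0, 1.0))


class TestSpikeProbability:
    def test_percentages(self):
        df = spike_probability(
            {"before": np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool),
             "during": np.zeros(10, bool)}
        )
        assert df.set_index("condition").loc["before", "probability_pct"] == 30.0
        assert df.set_index("condition").loc["during", "probability_pct"] == 0.0

    def test_bernoulli_simulation_recovers_suppression(self, rng):
        n = 400
        df = spike_probability(
            {"before": rng.random(n) < 0.7, "during_opto": rng.random(n) < 0.45}
        )
        p = df.set_index("condition").probability_pct / 100.0
        assert p["before"] == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / n))
        assert p["during_opto"] == pytest.approx(0.45, abs=3 * np.sqrt(0.45 * 0.55 / n))

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            spike_probability({"before": np.array([], bool)})


class TestConnectivitySummary:
    def test_percentages_round_trip_counts(self, rng):
        tested = rng.integers(1, 100, 20)
        connected = rng.integers(0, tested + 1)
        df = connectivity_summary(
            pd.DataFrame(dict(cell_type=[f"c{i}" for i in range(20)],
                              connected=connected, tested=tested))
        )
        back = df.percentage * df.tested / 100.0
        np.testing.assert_allclose(back, df.connected, atol=0.005 * df.tested.max())

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            connectivity_summary(
                pd.DataFrame(dict(cell_type=["a"], connected=[5], tested=[0]))
            )
        with pytest.raises(ValueError):
            connectivity_summary(
                pd.DataFrame(dict(cell_type=["a"], connected=[5], tested=[4]))
            )
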