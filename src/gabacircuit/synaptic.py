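"""Feedforward-IPSC isolation and synaptic summary statistics.

Disynaptic (feedforward) inhibition recorded at an intermediate holding
potential (~−50 mV) rides on the monosynaptic EPSC.  The pure EPSC is
available at E_GABA (−92 mV), where GABA_A currents vanish.  The FF
IPSC is isolated by scaling the pure EPSC to the initial slope of the
compound PSC and subtracting:

    FF_IPSC(t) = compound(t) − (slope_compound / slope_pure) · pure(t)

which leaves the outward IPSC at the compound's own holding potential.
Recordings are excluded when apparent outward IPSCs occur on 100% of
−50 mV trials, or when the isolated IPSC-to-EPSC onset latency is below
1 ms — both signatures of antidromic (not feedforward) activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .simulate import PscTrialSet

__all__ = [
    "FfIpscResult",
    "ChargeResult",
    "detect_onset",
    "isolate_ff_ipsc",
    "apply_exclusion_rules",
    "inward_charge",
    "spike_probability",
    "connectivity_summary",
]

_FILTER_HZ = 3000.0


@dataclass
class FfIpscResult:
    isolated_trace: np.ndarray
    scale_factor: float
    epsc_onset_s: float
    ipsc_onset_s: float
    latency_ms: float
    amplitude_pa: float
    ipsc_detected: bool = True
    excluded: bool = False
    exclusion_reason: str = "none"  # outward_incidence_100 | latency_below_1ms | none
    outward_incidence: float | None = None


@dataclass(frozen=True)
class ChargeResult:
    inward_charge_pc: float
    window_s: tuple[float, float]
    holding_mv: float | None = None


def _lowpass(x: np.ndarray, fs: float, cutoff: float = _FILTER_HZ) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= nyq:
        return np.asarray(x, float)
    b, a = butter(4, cutoff / nyq)
    return filtfilt(b, a, np.asarray(x, float))


def detect_onset(
    trace: np.ndarray,
    stim_time_s: float,
    sampling_rate: float,
    sign: int,
    frac: float = 0.05,
    min_peak_pa: float = 5.0,
) -> float:
    """Onset (s) as the first crossing of ``frac`` × peak after the
    stimulus, on the 3-kHz-filtered trace.

    ``sign`` is −1 for inward (EPSC) and +1 for outward (IPSC) events.
    Raises when the post-stimulus peak is below ``min_peak_pa``.
    """
    x = sign * _lowpass(trace, sampling_rate)
    i_stim = int(round(stim_time_s * sampling_rate))
    seg = x[i_stim:]
    peak = seg.max()
    if peak < min_peak_pa:
        raise ValueError("onset undetectable: post-stimulus peak below the detection floor")
    above = np.flatnonzero(seg >= frac * peak)
    return (i_stim + above[0]) / sampling_rate


def _initial_slope(
    trace: np.ndarray, onset_s: float, sampling_rate: float, slope_window_ms: float
) -> float:
    i0 = int(round(onset_s * sampling_rate))
    i1 = i0 + int(round(slope_window_ms / 1000.0 * sampling_rate))
    seg = np.asarray(trace, float)[i0:i1]
    t = np.arange(seg.size) / sampling_rate
    return float(np.polyfit(t, seg, 1)[0])


def isolate_ff_ipsc(
    compound_avg: np.ndarray,
    pure_avg: np.ndarray,
    stim_time_s: float,
    sampling_rate: float,
    slope_window_ms: float = 0.5,
    onset_frac: float = 0.05,
) -> FfIpscResult:
    """Scaled-subtraction isolation of the feedforward IPSC from the
    averaged compound (−50 mV) and pure-EPSC (−92 mV) traces.

    An undetectable EPSC onset raises; an undetectable IPSC on the
    residual (no feedforward inhibition) returns the ~zero residual with
    ``ipsc_detected=False`` and NaN onset/latency.
    """
    compound_avg = np.asarray(compound_avg, float)
    pure_avg = np.asarray(pure_avg, float)
    e_on = detect_onset(pure_avg, stim_time_s, sampling_rate, sign=-1, frac=onset_frac)
    slope_p = _initial_slope(pure_avg, e_on, sampling_rate, slope_window_ms)
    c_on = detect_onset(compound_avg, stim_time_s, sampling_rate, sign=-1, frac=onset_frac)
    slope_c = _initial_slope(compound_avg, c_on, sampling_rate, slope_window_ms)
    if slope_p == 0:
        raise ValueError("zero initial slope on the pure EPSC")
    scale = slope_c / slope_p
    ff = compound_avg - scale * pure_avg
    try:
        i_on = detect_onset(ff, e_on, sampling_rate, sign=+1, frac=onset_frac)
    except ValueError:
        return FfIpscResult(
            isolated_trace=ff, scale_factor=float(scale), epsc_onset_s=float(e_on),
            ipsc_onset_s=float("nan"), latency_ms=float("nan"),
            amplitude_pa=float(_lowpass(ff, sampling_rate).max()), ipsc_detected=False,
        )
    amp = float(_lowpass(ff, sampling_rate)[int(round(i_on * sampling_rate)):].max())
    return FfIpscResult(
        isolated_trace=ff,
        scale_factor=float(scale),
        epsc_onset_s=float(e_on),
        ipsc_onset_s=float(i_on),
        latency_ms=float((i_on - e_on) * 1e3),
        amplitude_pa=amp,
    )


def apply_exclusion_rules(
    trials: PscTrialSet,
    result: FfIpscResult,
    detect_window_ms: float = 10.0,
    sd_factor: float = 3.0,
    abs_floor_pa: float = 5.0,
) -> FfIpscResult:
    """Flag recordings dominated by antidromic inhibition.

    Per-trial outward IPSCs are detected on the residual (trial −
    scale·pure-EPSC average) over a window starting 1 ms after the EPSC
    onset; the detection threshold is max(``sd_factor`` × pre-stimulus
    SD of the trial, ``abs_floor_pa``).  Excluded when the incidence is
    100%, or when the isolated latency is below 1 ms.
    """
    fs = trials.sampling_rate
    pure_avg = trials.trials_minus92.mean(axis=0)
    i_stim = int(round(trials.stim_time_s * fs))
    i0 = int(round(result.epsc_onset_s * fs)) + int(round(0.001 * fs))
    i1 = i0 + int(round(detect_window_ms / 1000.0 * fs))
    n_out = 0
    for trial in trials.trials_minus50:
        resid = trial - result.scale_factor * pure_avg
        base_sd = float(np.std(trial[:i_stim]))
        thr = max(sd_factor * base_sd, abs_floor_pa)
        if resid[i0:i1].max() > thr:
            n_out += 1
    incidence = n_out / trials.trials_minus50.shape[0]
    result.outward_incidence = incidence
    if incidence == 1.0:
        result.excluded = True
        result.exclusion_reason = "outward_incidence_100"
    elif result.latency_ms < 1.0:
        result.excluded = True
        result.exclusion_reason = "latency_below_1ms"
    else:
        result.excluded = False
        result.exclusion_reason = "none"
    return result


def inward_charge(
    trace_pa: np.ndarray,
    sampling_rate: float,
    window_s: tuple[float, float],
    holding_mv: float | None = None,
) -> ChargeResult:
    """Charge (pC) of the inward (negative) current component over a
    window of a baseline-subtracted trace; outward current contributes
    nothing.  1 pA·s = 1 pC."""
    trace_pa = np.asarray(trace_pa, float)
    i0 = int(round(window_s[0] * sampling_rate))
    i1 = int(round(window_s[1] * sampling_rate))
    if i0 < 0 or i1 > trace_pa.size or i1 <= i0:
        raise ValueError("charge window outside the trace")
    stop = i1 + 1 if i1 < trace_pa.size else i1  # close the interval so
    inward = np.minimum(trace_pa[i0:stop], 0.0)  # adjoining windows add exactly
    q = -np.trapezoid(inward, dx=1.0 / sampling_rate)
    return ChargeResult(float(q), window_s, holding_mv)


def spike_probability(outcomes_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    """Percentage of trials with a spike per condition (e.g. before /
    during / after optogenetic stimulation)."""
    rows = []
    for cond, outcomes in outcomes_by_condition.items():
        outcomes = np.asarray(outcomes, dtype=bool)
        if outcomes.size == 0:
            raise ValueError(f"condition {cond!r} has zero trials")
        rows.append(
            dict(condition=cond, n_trials=int(outcomes.size),
                 n_spikes=int(outcomes.sum()),
                 probability_pct=100.0 * outcomes.mean())
        )
    return pd.DataFrame(rows)


def connectivity_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Connectivity percentages per cell type from connected/tested
    counts, reported to two decimals (100 × connected / tested)."""
    req = {"cell_type", "connected", "tested"}
    if not req.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(req)}")
    out = counts.copy()
    if (out.tested <= 0).any():
        raise ValueError("tested counts must be positive")
    if (out.connected > out.tested).any() or (out.connected < 0).any():
        raise ValueError("connected counts must be in [0, tested]")
    out["percentage"] = np.round(100.0 * out.connected / out.tested, 2)
    return out
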