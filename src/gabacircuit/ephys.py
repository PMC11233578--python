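"""Intrinsic-electrophysiology features from current-clamp sweeps and
classification of L1 interneurons.

Feature definitions follow standard whole-cell conventions:

* input resistance — slope of the median steady-state voltage
  deflection (last 0.3 s of the 1-s step) against injected current over
  the non-spiking ±30 pA sweeps;
* membrane time constant — single-exponential fit to the first 0.1 s of
  the voltage relaxation at −50 pA;
* sag ratio — median steady-state deflection (last 0.3 s) divided by
  the minimum deflection in the first 0.3 s of the −50 pA step, both
  relative to the pre-step baseline (1 means no sag);
* AP threshold — membrane voltage at the first sample where dV/dt
  exceeds 50 V/s (computed by central differences after a 3-kHz
  zero-phase low-pass mirroring the acquisition filter);
* AP amplitude — peak minus threshold;
* first spike latency — time of the first AP *peak* relative to step
  onset;
* first AHP latency — time from the first AP threshold crossing to the
  post-spike voltage minimum (bounded by the next spike or step end);
* depolarising hump — two rules: for early-spiking cells (SBC-like),
  threshold of the first AP minus the potential 0.3 s into the step;
  for late-spiking cells (NGF-like), maximal potential in the first
  0.3 s minus the potential at 0.3 s.

L1 interneurons are classified as putative neurogliaform (pNGF,
long-latency) vs putative single-bouquet (pSBC, short-latency) cells
from first spike latency and first AHP latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt

from .simulate import SweepSet

logger = logging.getLogger(__name__)

__all__ = [
    "Spike",
    "EphysFeatureSet",
    "ClassifierConfig",
    "CellClassCall",
    "input_resistance",
    "membrane_time_constant",
    "sag_ratio",
    "detect_aps",
    "first_ahp_latency",
    "hump_amplitude",
    "classify_l1_interneuron",
    "extract_features",
]

DVDT_THRESHOLD_V_PER_S = 50.0
_ACQ_FILTER_HZ = 3000.0


@dataclass(frozen=True)
class Spike:
    threshold_index: int
    threshold_time: float  # s, relative to step onset
    threshold_voltage: float  # mV
    peak_index: int
    peak_time: float  # s, relative to step onset
    peak_voltage: float  # mV

    @property
    def amplitude(self) -> float:
        return self.peak_voltage - self.threshold_voltage


@dataclass
class EphysFeatureSet:
    input_resistance_mohm: float
    membrane_tau_ms: float
    sag_ratio: float
    first_spike_latency_s: float
    ap_threshold_mv: float
    ap_amplitude_mv: float
    hump_amplitude_mv: float
    hump_ngf_rule_mv: float
    hump_sbc_rule_mv: float
    first_ahp_latency_s: float
    dvdt_threshold: float = DVDT_THRESHOLD_V_PER_S


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision rule on (first spike latency, first AHP latency).

    Cells at or above either latency threshold are called pNGF
    (late-spiking); cells below both are pSBC.  A boundary case ties to
    pNGF.  When both thresholds are None a 2-class Gaussian mixture on
    the two (log-)latencies is fitted instead.
    """

    spike_latency_threshold_s: float | None = 0.1
    ahp_latency_threshold_s: float | None = None


@dataclass(frozen=True)
class CellClassCall:
    cell_class: str  # pNGF | pSBC | other
    first_spike_latency_s: float
    first_ahp_latency_s: float
    rule: str


def _lowpass(v: np.ndarray, fs: float, cutoff: float = _ACQ_FILTER_HZ) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= nyq:
        return np.asarray(v, float)
    b, a = butter(4, cutoff / nyq)
    return filtfilt(b, a, np.asarray(v, float))


def _step_slice(sweeps: SweepSet):
    fs = sweeps.sampling_rate
    i_on = int(round((sweeps.step_onset - sweeps.time[0]) * fs))
    i_off = i_on + int(round(sweeps.step_duration * fs))
    return i_on, i_off


def _baseline(v: np.ndarray, i_on: int) -> float:
    return float(np.median(v[:i_on])) if i_on > 0 else float(v[0])


def detect_aps(
    v: np.ndarray,
    sampling_rate: float,
    step_onset_index: int = 0,
    dvdt_threshold: float = DVDT_THRESHOLD_V_PER_S,
    peak_search_s: float = 0.005,
) -> list[Spike]:
    """Action potentials from one sweep by the dV/dt criterion.

    dV/dt (V/s) is computed by central differences on the 3-kHz
    low-passed trace; each contiguous region above threshold yields one
    spike whose threshold is the first sample of the region and whose
    peak is the voltage maximum within ``peak_search_s`` after it.
    """
    if sampling_rate < 10000:
        raise ValueError("sampling rate must be >= 10 kHz for AP detection")
    v = np.asarray(v, float)
    vf = _lowpass(v, sampling_rate)
    dvdt = np.gradient(vf) * sampling_rate / 1000.0  # mV/ms == V/s
    above = dvdt > dvdt_threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    spikes: list[Spike] = []
    n_peak = int(round(peak_search_s * sampling_rate))
    last_peak = -1
    for e in edges:
        if e <= last_peak:
            continue  # retriggering within the previous spike's rise
        seg = v[e : min(e + n_peak, v.size)]
        pk = e + int(np.argmax(seg))
        spikes.append(
            Spike(
                threshold_index=e,
                threshold_time=(e - step_onset_index) / sampling_rate,
                threshold_voltage=float(v[e]),
                peak_index=pk,
                peak_time=(pk - step_onset_index) / sampling_rate,
                peak_voltage=float(v[pk]),
            )
        )
        last_peak = pk
    return spikes


def input_resistance(sweeps: SweepSet, current_limit_pa: float = 30.0) -> float:
    """Slope (MΩ) of median steady-state deflection vs injected current.

    Uses non-spiking sweeps with |I| ≤ ``current_limit_pa``; the
    steady-state window is the last 0.3 s of the step.
    """
    i_on, i_off = _step_slice(sweeps)
    fs = sweeps.sampling_rate
    n_ss = int(round(0.3 * fs))
    cur, defl = [], []
    for j, i_pa in enumerate(sweeps.current_steps):
        if abs(i_pa) > current_limit_pa:
            continue
        v = sweeps.voltage[j]
        if detect_aps(v, fs, i_on):
            continue
        base = _baseline(v, i_on)
        cur.append(i_pa)
        defl.append(float(np.median(v[i_off - n_ss : i_off])) - base)
    if len(cur) < 2:
        raise ValueError("input resistance needs >= 2 non-spiking sweeps")
    slope = np.polyfit(cur, defl, 1)[0]  # mV/pA == GΩ
    return float(slope * 1e3)


def membrane_time_constant(sweeps: SweepSet, fit_range_s: float = 0.1) -> float:
    """Time constant (ms) of a single-exponential fit to the first
    ``fit_range_s`` of the voltage relaxation at −50 pA."""
    i_on, _ = _step_slice(sweeps)
    fs = sweeps.sampling_rate
    j = int(np.argmin(np.abs(sweeps.current_steps - (-50.0))))
    v = sweeps.voltage[j]
    base = _baseline(v, i_on)
    n_fit = int(round(fit_range_s * fs))
    t = np.arange(n_fit) / fs
    y = v[i_on : i_on + n_fit] - base
    if np.ptp(y) < 1e-9:
        raise ValueError("degenerate (constant) relaxation; cannot fit tau")

    def model(tt, dv, tau):
        return dv * (1.0 - np.exp(-tt / tau))

    try:
        popt, _ = curve_fit(model, t, y, p0=[y[-1], 0.02], maxfev=10000)
    except RuntimeError as err:  # pragma: no cover - non-convergence flag
        raise ValueError("membrane time-constant fit did not converge") from err
    return float(abs(popt[1]) * 1e3)


def sag_ratio(sweeps: SweepSet) -> float:
    """Steady-state ÷ peak deflection of the −50 pA sweep (both
    baseline-relative); the peak is the voltage minimum in the first
    0.3 s, the steady state the median over the last 0.3 s of the step."""
    i_on, i_off = _step_slice(sweeps)
    fs = sweeps.sampling_rate
    j = int(np.argmin(np.abs(sweeps.current_steps - (-50.0))))
    if sweeps.current_steps[j] >= 0:
        raise ValueError("sag ratio requires a hyperpolarising sweep")
    v = sweeps.voltage[j]
    base = _baseline(v, i_on)
    n_03 = int(round(0.3 * fs))
    steady = float(np.median(v[i_off - n_03 : i_off])) - base
    peak = float(v[i_on : i_on + n_03].min()) - base
    if peak == 0:
        raise ValueError("zero peak deflection")
    return steady / peak


def first_ahp_latency(
    v: np.ndarray, spikes: list[Spike], sampling_rate: float, step_end_index: int
) -> float:
    """Seconds from the first spike's threshold crossing to the
    afterhyperpolarisation minimum (bounded by the next spike's
    threshold, or the step end)."""
    if not spikes:
        raise ValueError("no spikes")
    s0 = spikes[0]
    stop = spikes[1].threshold_index if len(spikes) > 1 else step_end_index
    seg = np.asarray(v, float)[s0.peak_index : stop]
    if seg.size < 3:
        raise ValueError("truncated AHP: no post-spike segment before the bound")
    i_min = s0.peak_index + int(np.argmin(seg))
    if i_min >= stop - 1 and len(spikes) == 1:
        raise ValueError("truncated AHP: minimum at the step end")
    return (i_min - s0.threshold_index) / sampling_rate


def hump_amplitude(
    v: np.ndarray,
    sampling_rate: float,
    step_onset_index: int,
    spikes: list[Spike],
) -> tuple[float, float]:
    """Depolarising-hump amplitude by both class rules.

    Returns ``(ngf_rule, sbc_rule)``: maximal potential in the first
    0.3 s minus the potential at 0.3 s (NGF rule, spike-free window
    required), and first-AP threshold minus the potential at 0.3 s
    (SBC rule; NaN when there is no spike).
    """
    v = np.asarray(v, float)
    n_03 = int(round(0.3 * sampling_rate))
    i_03 = step_onset_index + n_03
    if i_03 >= v.size:
        raise ValueError("sweep shorter than 0.3 s after step onset")
    v_03 = float(v[i_03])
    early = v[step_onset_index : i_03]
    # NGF rule: exclude AP excursions from the early maximum
    early_spikes = [s for s in spikes if s.threshold_index < i_03]
    if early_spikes:
        mask = np.ones(early.size, dtype=bool)
        for s in early_spikes:
            a = max(0, s.threshold_index - step_onset_index)
            b = min(early.size, s.peak_index - step_onset_index + int(0.02 * sampling_rate))
            mask[a:b] = False
        ngf = float(early[mask].max() - v_03) if mask.any() else float("nan")
    else:
        ngf = float(early.max() - v_03)
    sbc = float(spikes[0].threshold_voltage - v_03) if spikes else float("nan")
    return ngf, sbc


def classify_l1_interneuron(
    first_spike_latency_s: float,
    first_ahp_latency_s: float,
    config: ClassifierConfig | None = None,
) -> CellClassCall:
    """pNGF vs pSBC call from the two latency features.

    With configured thresholds, a cell at or above either threshold is
    pNGF (delayed spiking), otherwise pSBC; missing features give
    'other'.
    """
    cfg = config or ClassifierConfig()
    if not np.isfinite(first_spike_latency_s) or not np.isfinite(first_ahp_latency_s):
        return CellClassCall("other", first_spike_latency_s, first_ahp_latency_s, "missing-feature")
    checks = []
    if cfg.spike_latency_threshold_s is not None:
        checks.append(first_spike_latency_s >= cfg.spike_latency_threshold_s)
    if cfg.ahp_latency_threshold_s is not None:
        checks.append(first_ahp_latency_s >= cfg.ahp_latency_threshold_s)
    if not checks:
        raise ValueError("no thresholds configured; fit the Gaussian fallback instead")
    cls = "pNGF" if any(checks) else "pSBC"
    return CellClassCall(cls, first_spike_latency_s, first_ahp_latency_s, "threshold")


def extract_features(
    sweeps: SweepSet, classifier: ClassifierConfig | None = None
) -> tuple[EphysFeatureSet, CellClassCall]:
    """Full intrinsic-feature set plus the class call for one cell.

    The near-threshold sweep is the lowest current step that elicits at
    least one spike.
    """
    i_on, i_off = _step_slice(sweeps)
    fs = sweeps.sampling_rate
    near, spikes = None, None
    for j in np.argsort(sweeps.current_steps):
        if sweeps.current_steps[j] <= 0:
            continue
        sp = detect_aps(sweeps.voltage[j], fs, i_on)
        sp = [s for s in sp if s.threshold_index >= i_on]
        if sp:
            near, spikes = j, sp
            break
    if near is None:
        raise ValueError("no suprathreshold sweep: cannot extract spike features")
    v = sweeps.voltage[near]
    ngf_rule, sbc_rule = hump_amplitude(v, fs, i_on, spikes)
    ahp = first_ahp_latency(v, spikes, fs, i_off)
    call = classify_l1_interneuron(spikes[0].peak_time, ahp, classifier)
    hump = ngf_rule if call.cell_class == "pNGF" else sbc_rule
    feats = EphysFeatureSet(
        input_resistance_mohm=input_resistance(sweeps),
        membrane_tau_ms=membrane_time_constant(sweeps),
        sag_ratio=sag_ratio(sweeps),
        first_spike_latency_s=spikes[0].peak_time,
        ap_threshold_mv=spikes[0].threshold_voltage,
        ap_amplitude_mv=spikes[0].amplitude,
        hump_amplitude_mv=hump,
        hump_ngf_rule_mv=ngf_rule,
        hump_sbc_rule_mv=sbc_rule,
        first_ahp_latency_s=ahp,
    )
    return feats, call
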