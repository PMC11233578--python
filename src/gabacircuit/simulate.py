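"""Forward models generating synthetic inputs with planted ground truth.

Three generators emulate the three recording modalities the analysis
pipeline consumes:

* :func:`simulate_session_set` — CNMF-style per-ROI fluorescence traces
  (with an overlapping background estimate) over three imaging sessions
  at 20 Hz, with stimulus-locked activated / inactivated / nonresponsive
  populations, an optogenetic gain applied in session 2, slow drift and
  Gaussian noise.  Activity is an event-rate model (baseline Poisson
  firing; a rate increase during the 1-s stimulus for activated neurons,
  a rate suppression for inactivated ones) convolved with a
  double-exponential indicator kernel (GCaMP6s-like: rise 0.2 s, decay
  1.6 s).
* :func:`simulate_voltage_sweeps` — current-clamp sweep sets at 20 kHz
  (1-s steps, −50 to +50 pA in 10 pA increments) from a passive-membrane
  model with a delayed sag component and stereotyped action-potential
  waveforms, for two L1-interneuron archetypes (early-spiking
  SBC-like, late-spiking NGF-like).  Planted feature values are computed
  from the closed-form waveform design, independently of the feature
  extractor.
* :func:`simulate_psc_recording` — voltage-clamp PSC trials at −50 mV
  (compound EPSC + probabilistic delayed outward IPSC) and at −92 mV
  (E_GABA; pure EPSC), from biexponential kernels.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

__all__ = [
    "SimConfig",
    "SessionSet",
    "simulate_session_set",
    "PlantedCellParams",
    "SweepSet",
    "simulate_voltage_sweeps",
    "PscSim",
    "PscTrialSet",
    "simulate_psc_recording",
]

# ---------------------------------------------------------------------------
# calcium imaging sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the imaging simulation.

    Defaults mirror the recording protocol the pipeline is built for:
    three 15-min sessions at 20 Hz with 24 one-second mechanical stimuli
    per session at random intervals, optogenetic gain applied in session
    2 only.  ``session_length`` is reducible (all analysis windows are
    in seconds, so shrinkage is transparent); reduce ``max_interval``
    accordingly.
    """

    n_neurons: int = 100
    frame_rate: float = 20.0
    session_length: float = 900.0
    n_sessions: int = 3
    n_stimuli_per_session: int = 24
    stimulus_duration: float = 1.0
    min_interval: float = 10.0
    max_interval: float = 50.0
    fraction_activated: float = 0.40
    fraction_inactivated: float = 0.25
    fraction_nonresponsive: float = 0.35
    evoked_amplitude: float = 0.2
    opto_gain_session2: float = 1.5
    indicator_rise_tau: float = 0.2
    indicator_decay_tau: float = 1.6
    noise_sd: float = 0.02
    drift_amplitude: float = 0.05
    drift_period: float = 300.0
    spontaneous_rate_hz: float = 2.0
    spontaneous_spike_amplitude: float = 0.05
    evoked_rate_hz: float = 20.0
    suppression: float = 1.0
    withdrawal_threshold: float | None = None
    background_offset: float = 0.3
    background_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.fraction_activated + self.fraction_inactivated + self.fraction_nonresponsive
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {fr}")
        if min(self.indicator_rise_tau, self.indicator_decay_tau) <= 0:
            raise ValueError("indicator taus must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be >= 0")
        if self.n_stimuli_per_session * (self.stimulus_duration + self.min_interval) > self.session_length:
            raise ValueError("stimulus schedule does not fit the session")


@dataclass
class SessionSet:
    """Per-ROI fluorescence + background across sessions, with the
    stimulus-event table and planted per-neuron ground truth."""

    fluorescence: list  # one [n_neurons, n_frames] array per session
    background: list
    events: pd.DataFrame  # session, onset_frame, duration_frames, withdrawal, opto
    ml_coordinate_um: np.ndarray
    ground_truth: pd.DataFrame  # neuron_id, cls, amplitude
    frame_rate: float
    config: SimConfig | None = None

    @property
    def n_sessions(self) -> int:
        return len(self.fluorescence)

    @property
    def n_neurons(self) -> int:
        return self.fluorescence[0].shape[0]

    def onsets_for_session(self, session: int) -> np.ndarray:
        sub = self.events[self.events.session == session]
        return sub.onset_frame.to_numpy(dtype=int)


def _indicator_kernel(rise_tau: float, decay_tau: float, frame_rate: float) -> np.ndarray:
    t = np.arange(0, 8 * decay_tau, 1.0 / frame_rate)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return k / k.max()


def _schedule_onsets(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    fs = cfg.frame_rate
    lead = 2.0
    tail = 5.5  # full post-onset analysis window must fit
    for _ in range(50):
        gaps = rng.uniform(cfg.min_interval, cfg.max_interval, cfg.n_stimuli_per_session)
        onsets_s = lead + np.cumsum(gaps) - gaps[0] + rng.uniform(0, cfg.min_interval)
        onsets_s += np.arange(cfg.n_stimuli_per_session) * cfg.stimulus_duration
        if onsets_s[-1] + cfg.stimulus_duration + tail <= cfg.session_length:
            return np.round(onsets_s * fs).astype(int)
    raise ValueError("infeasible stimulus schedule: reduce intervals or stimulus count")


def simulate_session_set(config: SimConfig) -> SessionSet:
    """Generate a full imaging dataset with planted responsive classes.

    With ``evoked_amplitude == 0`` every neuron is nonresponsive in the
    ground truth (the null case used for bootstrap calibration).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.frame_rate
    T = int(round(cfg.session_length * fs))
    n = cfg.n_neurons
    dur_frames = int(round(cfg.stimulus_duration * fs))

    if cfg.evoked_amplitude == 0:
        classes = np.array(["nonresponsive"] * n)
    else:
        n_act = int(round(n * cfg.fraction_activated))
        n_inact = int(round(n * cfg.fraction_inactivated))
        classes = np.array(
            ["activated"] * n_act
            + ["inactivated"] * n_inact
            + ["nonresponsive"] * (n - n_act - n_inact)
        )
        rng.shuffle(classes)

    kernel = _indicator_kernel(cfg.indicator_rise_tau, cfg.indicator_decay_tau, fs)
    # per-spike amplitude that makes the expected evoked transient peak
    # equal evoked_amplitude (rate box convolved with the kernel)
    box = np.full(dur_frames, cfg.evoked_rate_hz / fs)
    peak_conv = np.convolve(box, kernel).max() if dur_frames else 1.0
    f0_base = 100.0 * np.exp(rng.normal(0, 0.2, n))
    ml = rng.uniform(0, 600, n)

    fluo, bg, event_rows = [], [], []
    for s in range(cfg.n_sessions):
        gain = cfg.opto_gain_session2 if s == 1 else 1.0
        opto = int(s == 1)
        onsets = _schedule_onsets(cfg, rng)
        stim_mask = np.zeros(T, dtype=bool)
        for o in onsets:
            stim_mask[o : o + dur_frames] = True

        rate = np.full((n, T), cfg.spontaneous_rate_hz / fs)
        evoked_rate = np.zeros((n, T))
        act = classes == "activated"
        inact = classes == "inactivated"
        if cfg.evoked_amplitude > 0:
            evoked_rate[np.ix_(act, np.flatnonzero(stim_mask))] = cfg.evoked_rate_hz / fs
            rate[np.ix_(inact, np.flatnonzero(stim_mask))] *= 1.0 - cfg.suppression

        spont_spikes = rng.poisson(rate) * cfg.spontaneous_spike_amplitude
        q_ev = cfg.evoked_amplitude * gain / peak_conv if peak_conv > 0 else 0.0
        ev_spikes = rng.poisson(evoked_rate) * q_ev
        spikes = spont_spikes + ev_spikes
        calcium = fftconvolve(spikes, kernel[None, :], axes=1)[:, :T]

        phase = rng.uniform(0, 2 * np.pi, n)[:, None]
        tgrid = np.arange(T)[None, :] / fs
        drift = cfg.drift_amplitude * np.sin(2 * np.pi * tgrid / cfg.drift_period + phase)
        noise = rng.normal(0, cfg.noise_sd, (n, T))
        f = f0_base[:, None] * (1.0 + calcium + drift + noise)

        shared = gaussian_filter1d(rng.normal(0, 1.0, T), 2.0 * fs)
        shared = shared / max(shared.std(), 1e-12)
        b = f0_base[:, None] * (
            cfg.background_offset + cfg.background_amplitude * shared[None, :]
        )
        fluo.append(f)
        bg.append(b)

        # withdrawal: noisy thresholded summed activated-population response
        exp_pop = act.sum() * cfg.evoked_amplitude * gain * 0.5
        thr = cfg.withdrawal_threshold if cfg.withdrawal_threshold is not None else 0.5 * exp_pop
        for o in onsets:
            ev_cal = calcium[act, o : o + dur_frames].mean() * act.sum() if act.any() else 0.0
            w = ev_cal + rng.normal(0, 0.1 * max(exp_pop, 1e-3))
            event_rows.append(
                dict(session=s, onset_frame=int(o), duration_frames=dur_frames,
                     withdrawal=int(w > thr), opto=opto)
            )

    events = pd.DataFrame(event_rows)
    gt = pd.DataFrame(
        dict(neuron_id=np.arange(n), cls=classes,
             amplitude=np.where(classes == "nonresponsive", 0.0, cfg.evoked_amplitude))
    )
    return SessionSet(fluo, bg, events, ml, gt, fs, cfg)


# ---------------------------------------------------------------------------
# current-clamp sweeps
# ---------------------------------------------------------------------------


@dataclass
class PlantedCellParams:
    """Closed-form design parameters of one simulated cell, plus the
    derived planted feature values filled in by the generator."""

    archetype: str = "SBC-like"  # or "NGF-like"
    rin_mohm: float = 150.0
    tau_ms: float = 20.0
    sag_depth_mv: float = 3.0
    v_rest_mv: float = -65.0
    rheobase_pa: float = 40.0
    spike_latency_s: float | None = None  # archetype default when None
    ahp_latency_ms: float = 8.0
    ap_amplitude_mv: float = 80.0
    ahp_depth_mv: float = 5.0
    hump_mv: float = 6.0
    # derived planted values (filled by the generator)
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rin_mohm <= 0 or self.tau_ms <= 0:
            raise ValueError("Rin and tau must be positive")
        if self.sag_depth_mv < 0:
            raise ValueError("sag depth must be >= 0")
        if self.spike_latency_s is None:
            object.__setattr__(
                self, "spike_latency_s", 0.02 if self.archetype == "SBC-like" else 0.4
            )


@dataclass
class SweepSet:
    """One cell's current-clamp protocol: 1-s steps, −50..+50 pA."""

    time: np.ndarray
    voltage: np.ndarray  # [n_sweeps, n_samples] mV
    current_steps: np.ndarray  # pA
    sampling_rate: float
    step_onset: float  # s
    step_duration: float  # s
    params: PlantedCellParams


_SPIKE_RISE_MS = 1.2
_SAG_DELAY_S = 0.12
_SAG_TAU_S = 0.06
_HUMP_TAU_SBC_S = 0.02
_HUMP_TAU_NGF_S = 0.1


def _alpha(t: np.ndarray, tau: float) -> np.ndarray:
    """Alpha function normalised to peak 1 at t = tau; zero for t < 0."""
    u = np.where(t > 0, t / tau, 0.0)
    return np.where(t > 0, u * np.exp(1.0 - u), 0.0)


def _subthreshold_deflection(t: np.ndarray, i_pa: float, p: PlantedCellParams,
                             step_dur: float) -> np.ndarray:
    """Deflection (mV) from rest during the step, closed form.

    Passive charging I·Rin·(1 − e^(−t/τ)) plus, for hyperpolarising
    currents, a delayed sag component (Ih-like, activating after
    ~120 ms) scaled linearly with |I|/50 pA.
    """
    tau = p.tau_ms / 1000.0
    d = i_pa * p.rin_mohm * 1e-3 * (1.0 - np.exp(-np.clip(t, 0, None) / tau))
    d = np.where(t < 0, 0.0, d)
    off = t > step_dur
    d_end = i_pa * p.rin_mohm * 1e-3 * (1.0 - np.exp(-step_dur / tau))
    d[off] = d_end * np.exp(-(t[off] - step_dur) / tau)
    if i_pa < 0 and p.sag_depth_mv > 0:
        sag = p.sag_depth_mv * (abs(i_pa) / 50.0) * _alpha(t - _SAG_DELAY_S, _SAG_TAU_S)
        sag = np.where((t >= 0) & (t <= step_dur), sag, 0.0)
        d = d - sag
    return d


def _hump_component(t: np.ndarray, p: PlantedCellParams) -> np.ndarray:
    tau = _HUMP_TAU_SBC_S if p.archetype == "SBC-like" else _HUMP_TAU_NGF_S
    return p.hump_mv * _alpha(t, tau)


def _spike_waveform(t: np.ndarray, t_peak: float, p: PlantedCellParams) -> np.ndarray:
    """Stereotyped AP added to the base trajectory.

    Half-cosine rise (amplitude ``ap_amplitude_mv`` over 1.2 ms), then a
    cosine fall to the AHP minimum and a curvature-matched cosine
    recovery, so the minimum of the summed trace is sharp and symmetric.
    """
    A = p.ap_amplitude_mv
    D = p.ahp_depth_mv
    t_r = _SPIKE_RISE_MS / 1000.0
    # threshold crossing (dV/dt = 50 V/s) inside the rise, closed form
    u_star = (t_r / np.pi) * np.arcsin(min(1.0, 50.0 * 2 * t_r * 1e3 / (A * np.pi)))
    t_x = t_peak - t_r + u_star
    t_f = (p.ahp_latency_ms / 1000.0) - (t_peak - t_x)  # fall: peak -> AHP min
    if t_f <= 0:
        raise ValueError("AHP latency shorter than the spike rise")
    t_rec = t_f * np.sqrt(D / (A + D))  # matches curvature at the minimum
    s = np.zeros_like(t)
    u = t - (t_peak - t_r)
    m = (u >= 0) & (u < t_r)
    s[m] = A / 2.0 * (1.0 - np.cos(np.pi * u[m] / t_r))
    w = t - t_peak
    m = (w >= 0) & (w < t_f)
    s[m] = -D + (A + D) / 2.0 * (1.0 + np.cos(np.pi * w[m] / t_f))
    r = t - t_peak - t_f
    m = (r >= 0) & (r < t_rec)
    s[m] = -D / 2.0 * (1.0 + np.cos(np.pi * r[m] / t_rec))
    return s


def simulate_voltage_sweeps(
    params: PlantedCellParams,
    sampling_rate: float = 20000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pre: float = 0.2,
    step_duration: float = 1.0,
    post: float = 0.3,
) -> SweepSet:
    """Current-clamp sweep set for one archetype with planted features.

    Planted feature values (input resistance, time constant, sag ratio,
    spike latency, AHP latency, hump amplitudes, AP threshold/amplitude)
    are derived from the closed-form design — evaluated on a dense 1-MHz
    grid and mapped to the recording grid for latencies — before noise
    is added, and stored in ``params.planted``.
    """
    p = params
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    dt = 1.0 / fs
    currents = np.arange(-50.0, 50.1, 10.0)
    t = np.arange(int(round((pre + step_duration + post) * fs))) * dt - pre
    sweeps = np.empty((currents.size, t.size))

    spike_latency = float(p.spike_latency_s)
    for j, i_pa in enumerate(currents):
        v = p.v_rest_mv + _subthreshold_deflection(t, i_pa, p, step_duration)
        if i_pa >= p.rheobase_pa:
            v = v + _hump_component(t, p)
            lat = spike_latency if i_pa == p.rheobase_pa else max(
                0.01, spike_latency * p.rheobase_pa / i_pa
            )
            v = v + _spike_waveform(t, lat, p)
        if noise_sd > 0:
            v = v + rng.normal(0, noise_sd, v.size)
        sweeps[j] = v

    # --- planted ground truth from the continuous design -----------------
    tau = p.tau_ms / 1000.0
    dense = np.arange(0.0, step_duration, 1e-6)
    d50 = -50.0 * p.rin_mohm * 1e-3 * (1.0 - np.exp(-dense / tau))
    d50 = d50 - p.sag_depth_mv * _alpha(dense - _SAG_DELAY_S, _SAG_TAU_S)
    steady = np.median(d50[dense >= step_duration - 0.3])
    peak_neg = d50[dense < 0.3].min()
    sag_ratio = steady / peak_neg

    A, t_r = p.ap_amplitude_mv, _SPIKE_RISE_MS / 1000.0
    u_star = (t_r / np.pi) * np.arcsin(min(1.0, 50.0 * 2 * t_r * 1e3 / (A * np.pi)))
    t_x = spike_latency - t_r + u_star
    grid_x = np.ceil(t_x / dt - 1e-9) * dt  # first recording sample past crossing
    base_near = (
        p.v_rest_mv
        + _subthreshold_deflection(np.array([grid_x]), p.rheobase_pa, p, step_duration)[0]
        + _hump_component(np.array([grid_x]), p)[0]
    )
    thr_v = base_near + _spike_waveform(np.array([grid_x]), spike_latency, p)[0]
    # AHP minimum of the continuous summed waveform around the nominal time
    t_ahp_nom = t_x + p.ahp_latency_ms / 1000.0
    win = np.arange(t_ahp_nom - 0.004, t_ahp_nom + 0.004, 1e-7)
    v_win = (
        _subthreshold_deflection(win, p.rheobase_pa, p, step_duration)
        + _hump_component(win, p)
        + _spike_waveform(win, spike_latency, p)
    )
    t_ahp = win[np.argmin(v_win)]
    # hump amplitudes by both class rules
    fine = np.arange(0.0, 0.3 + 1e-6, 1e-5)
    base_fine = (
        _subthreshold_deflection(fine, p.rheobase_pa, p, step_duration)
        + _hump_component(fine, p)
    )
    hump_ngf = float(base_fine.max() - base_fine[-1])
    v_at_03 = p.v_rest_mv + base_fine[-1]
    hump_sbc = float(thr_v - v_at_03)

    base_peak = (
        p.v_rest_mv
        + _subthreshold_deflection(np.array([spike_latency]), p.rheobase_pa, p, step_duration)[0]
        + _hump_component(np.array([spike_latency]), p)[0]
    )
    p.planted = dict(
        rin_mohm=p.rin_mohm,
        tau_ms=p.tau_ms,
        sag_ratio=float(sag_ratio),
        spike_latency_s=float(np.round(spike_latency / dt) * dt),
        ap_threshold_mv=float(thr_v),
        ap_amplitude_mv=float(base_peak + A - thr_v),
        ahp_latency_s=float(np.round(t_ahp / dt) * dt - grid_x),
        hump_ngf_mv=hump_ngf,
        hump_sbc_mv=hump_sbc,
        threshold_time_s=float(grid_x),
    )
    return SweepSet(t, sweeps, currents, fs, 0.0, step_duration, p)


# ---------------------------------------------------------------------------
# voltage-clamp PSC trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PscSim:
    """Compound-PSC simulation: EPSC at both holding potentials plus a
    probabilistic delayed outward IPSC at −50 mV only (absent at −92 mV,
    the GABA_A reversal potential)."""

    epsc_amplitude_pa: float = 100.0  # peak, inward, at −92 mV
    epsc_rise_ms: float = 0.5
    epsc_decay_ms: float = 5.0
    ipsc_amplitude_pa: float = 50.0  # peak, outward, at −50 mV
    ipsc_rise_ms: float = 1.0
    ipsc_decay_ms: float = 12.0
    ipsc_latency_ms: float = 3.0
    ipsc_release_probability: float = 0.5
    n_trials: int = 20
    noise_sd: float = 0.0
    sampling_rate: float = 20000.0
    duration_s: float = 0.08
    stim_time_s: float = 0.01
    synaptic_delay_ms: float = 1.0
    holding_mv: tuple[float, float] = (-50.0, -92.0)
    e_exc_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ipsc_latency_ms <= 0:
            raise ValueError("IPSC latency must be positive")
        if not 0.0 <= self.ipsc_release_probability <= 1.0:
            raise ValueError("release probability must be in [0, 1]")


@dataclass
class PscTrialSet:
    trials_minus50: np.ndarray  # [n_trials, n_samples] pA
    trials_minus92: np.ndarray
    stim_time_s: float
    sampling_rate: float
    ipsc_present: np.ndarray  # bool per −50 mV trial (ground truth)
    config: PscSim

    @property
    def epsc_onset_true_s(self) -> float:
        return self.stim_time_s + self.config.synaptic_delay_ms / 1000.0

    @property
    def ipsc_onset_true_s(self) -> float:
        return self.epsc_onset_true_s + self.config.ipsc_latency_ms / 1000.0


def _biexp(t: np.ndarray, onset: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Biexponential kernel normalised to peak 1, zero before onset."""
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    u = t - onset
    k = np.where(u > 0, np.exp(-np.clip(u, 0, None) / td) - np.exp(-np.clip(u, 0, None) / tr), 0.0)
    t_pk = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_pk / td) - np.exp(-t_pk / tr)
    return k / peak


def simulate_psc_recording(psc: PscSim) -> PscTrialSet:
    """PSC trial set at both holding potentials.

    −92 mV trials contain the pure (inward) EPSC only; −50 mV trials
    contain the EPSC scaled by the excitatory driving-force ratio plus,
    with ``ipsc_release_probability`` per trial, an outward IPSC at the
    planted latency.
    """
    rng = np.random.default_rng(psc.seed)
    fs = psc.sampling_rate
    t = np.arange(int(round(psc.duration_s * fs))) / fs
    e_on = psc.stim_time_s + psc.synaptic_delay_ms / 1000.0
    i_on = e_on + psc.ipsc_latency_ms / 1000.0
    epsc = -psc.epsc_amplitude_pa * _biexp(t, e_on, psc.epsc_rise_ms, psc.epsc_decay_ms)
    ipsc = psc.ipsc_amplitude_pa * _biexp(t, i_on, psc.ipsc_rise_ms, psc.ipsc_decay_ms)
    v50, v92 = psc.holding_mv
    k_drive = (v50 - psc.e_exc_mv) / (v92 - psc.e_exc_mv)

    present = rng.random(psc.n_trials) < psc.ipsc_release_probability
    tr50 = np.tile(k_drive * epsc, (psc.n_trials, 1))
    tr50[present] += ipsc
    tr92 = np.tile(epsc, (psc.n_trials, 1))
    if psc.noise_sd > 0:
        tr50 = tr50 + rng.normal(0, psc.noise_sd, tr50.shape)
        tr92 = tr92 + rng.normal(0, psc.noise_sd, tr92.shape)
    return PscTrialSet(tr50, tr92, psc.stim_time_s, fs, present, psc)
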