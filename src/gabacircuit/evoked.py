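"""Stimulus-evoked response summaries.

Works on trial-mean ΔF/F0 traces: areas under the curve (AUC) over the
0–5 s, 0–1 s (during-stimulus) and 1–5 s (post-stimulus) windows,
window means, fold change of AUC between sessions, and assignment of
neurons to cortical layers from their medio-lateral coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .traces import AlignedResponse

__all__ = [
    "Layer",
    "LayerBoundaries",
    "FoldChange",
    "ResponseMetrics",
    "mean_evoked_response",
    "compute_auc",
    "mean_dff_window",
    "fold_change",
    "assign_layer",
    "metrics_table",
]


class Layer(str, Enum):
    L1 = "L1"
    L23 = "L2/3"
    L5 = "L5"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class LayerBoundaries:
    """Depth thresholds (µm) partitioning the imaged coordinate range.

    Half-open bins: [0, l1_l23) → L1, [l1_l23, l23_l5) → L2/3,
    [l23_l5, l5_max) → L5; anything outside [0, l5_max) is unassigned.
    A coordinate exactly on a boundary belongs to the deeper layer.
    """

    l1_l23: float = 100.0
    l23_l5: float = 300.0
    l5_max: float = 900.0

    def __post_init__(self) -> None:
        if not 0 < self.l1_l23 < self.l23_l5 < self.l5_max:
            raise ValueError("layer boundaries must be strictly increasing")


@dataclass(frozen=True)
class FoldChange:
    """AUC change of a target session relative to a reference session,
    (AUC_target − AUC_ref) / |AUC_ref|; undefined when the reference is 0."""

    value: float
    reference_session: int
    target_session: int
    defined: bool


@dataclass
class ResponseMetrics:
    neuron_id: int
    session_id: int
    mean_trace: np.ndarray
    auc_0_5: float
    auc_0_1: float
    auc_1_5: float
    mean_dff_0_1: float
    mean_dff_1_5: float


def mean_evoked_response(aligned: AlignedResponse) -> np.ndarray:
    """Framewise arithmetic mean of the aligned ΔF/F0 over trials."""
    if aligned.n_trials < 1:
        raise ValueError("mean evoked response requires at least one trial")
    return aligned.dff.mean(axis=0)


def _window_slice(time_axis: np.ndarray, window: tuple[float, float], frame_rate: float):
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    eps = 0.5 / frame_rate
    idx = np.flatnonzero((time_axis >= t0 - eps) & (time_axis < t1 - eps))
    if idx.size == 0:
        raise ValueError(f"window {window} outside the time axis")
    return idx


def compute_auc(
    mean_trace: np.ndarray,
    time_axis: np.ndarray,
    window: tuple[float, float],
    frame_rate: float,
) -> float:
    """Trapezoidal integral of the signed mean trace over a half-open window.

    The integral runs from the first frame at/after the window start up
    to (but excluding) the first frame at/after the window end, so AUCs
    over adjoining windows add exactly: to close each sub-interval the
    trapezoid uses the next frame's sample as right edge when available.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    idx = _window_slice(np.asarray(time_axis), window, frame_rate)
    stop = idx[-1] + 1
    if stop < mean_trace.size:
        seg = mean_trace[idx[0] : stop + 1]
    else:
        seg = mean_trace[idx[0] : stop]
    return float(np.trapezoid(seg, dx=1.0 / frame_rate))


def mean_dff_window(
    mean_trace: np.ndarray,
    time_axis: np.ndarray,
    window: tuple[float, float],
    frame_rate: float,
) -> float:
    """Mean ΔF/F0 over a half-open window of the trial-mean trace."""
    idx = _window_slice(np.asarray(time_axis), window, frame_rate)
    return float(np.asarray(mean_trace, dtype=float)[idx].mean())


def fold_change(auc_ref: float, auc_target: float, reference_session: int = 1,
                target_session: int = 2) -> FoldChange:
    """(target − ref) / |ref|; flagged undefined when the reference AUC is 0."""
    if auc_ref == 0:
        return FoldChange(np.nan, reference_session, target_session, defined=False)
    return FoldChange(
        (auc_target - auc_ref) / abs(auc_ref), reference_session, target_session, True
    )


def assign_layer(ml_coordinate_um: float, boundaries: LayerBoundaries | None = None) -> Layer:
    """Interval lookup of the cortical layer for one coordinate (µm)."""
    b = boundaries or LayerBoundaries()
    x = float(ml_coordinate_um)
    if x < 0 or x >= b.l5_max or not np.isfinite(x):
        return Layer.UNASSIGNED
    if x < b.l1_l23:
        return Layer.L1
    if x < b.l23_l5:
        return Layer.L23
    return Layer.L5


def response_metrics(aligned: AlignedResponse) -> ResponseMetrics:
    """All evoked-response summaries for one neuron/session."""
    mt = mean_evoked_response(aligned)
    ta, fr = aligned.time_axis, aligned.frame_rate
    return ResponseMetrics(
        neuron_id=aligned.neuron_id,
        session_id=aligned.session_id,
        mean_trace=mt,
        auc_0_5=compute_auc(mt, ta, (0.0, 5.0), fr),
        auc_0_1=compute_auc(mt, ta, (0.0, 1.0), fr),
        auc_1_5=compute_auc(mt, ta, (1.0, 5.0), fr),
        mean_dff_0_1=mean_dff_window(mt, ta, (0.0, 1.0), fr),
        mean_dff_1_5=mean_dff_window(mt, ta, (1.0, 5.0), fr),
    )


def metrics_table(
    metrics: list[ResponseMetrics],
    ml_coordinates: dict[int, float] | None = None,
    boundaries: LayerBoundaries | None = None,
) -> pd.DataFrame:
    """Results table with per-neuron AUCs, window means, layer and the
    session-2/3 fold changes relative to session 1.

    Neurons whose session-1 AUC is exactly 0 get undefined fold changes
    (flagged, excluded from group statistics downstream).
    """
    rows = []
    for m in metrics:
        layer = Layer.UNASSIGNED
        if ml_coordinates is not None and m.neuron_id in ml_coordinates:
            layer = assign_layer(ml_coordinates[m.neuron_id], boundaries)
        rows.append(
            dict(
                neuron_id=m.neuron_id,
                session=m.session_id,
                layer=layer.value,
                auc_0_5=m.auc_0_5,
                auc_0_1=m.auc_0_1,
                auc_1_5=m.auc_1_5,
                mean_0_1=m.mean_dff_0_1,
                mean_1_5=m.mean_dff_1_5,
            )
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    ref = df[df.session == df.session.min()].set_index("neuron_id")["auc_0_5"]
    for target in sorted(df.session.unique())[1:]:
        tgt = df[df.session == target].set_index("neuron_id")["auc_0_5"]
        fc, defined = {}, {}
        for nid in ref.index:
            if nid in tgt.index:
                r = fold_change(ref[nid], tgt[nid], int(df.session.min()), int(target))
                fc[nid], defined[nid] = r.value, r.defined
        df[f"fold_change_s{target}"] = df.neuron_id.map(fc)
        df[f"fold_change_s{target}_defined"] = df.neuron_id.map(defined)
    return df
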