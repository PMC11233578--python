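"""Ensemble discovery: PCA + k-means on binned evoked responses.

Each neuron's trial-mean ΔF/F0 from 1 s before to 2 s after stimulus
onset is binned (0.1 s bins) per session and the three sessions are
concatenated (90 features at the defaults).  Features are column-
centred, projected on the first four principal components, and
clustered by k-means (Euclidean distance, multiple seeded restarts);
the number of clusters is chosen by the mean silhouette index.  With
k = 2 the cluster whose session-1 response rises after onset is
labelled vF-activated, the other vF-inactivated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleParams",
    "build_feature_matrix",
    "pca_project",
    "kmeans_cluster",
    "optimal_k_silhouette",
    "label_ensembles",
    "ensemble_proportions",
    "EnsembleClustering",
    "EnsembleResults",
]


@dataclass(frozen=True)
class EnsembleParams:
    bin_width: float = 0.1
    window: tuple[float, float] = (-1.0, 2.0)
    n_components: int = 4
    min_variance_explained: float = 0.60
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    kmeans_n_init: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        span = self.window[1] - self.window[0]
        n_bins = span / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("window must divide into whole bins")
        if not 0.0 < self.min_variance_explained < 1.0:
            raise ValueError("min_variance_explained must be in (0, 1)")

    @property
    def n_bins(self) -> int:
        return int(round((self.window[1] - self.window[0]) / self.bin_width))


def build_feature_matrix(
    mean_traces: np.ndarray,
    time_axis: np.ndarray,
    frame_rate: float,
    params: EnsembleParams | None = None,
) -> np.ndarray:
    """Binned concatenated evoked responses, [neuron × (bins × sessions)].

    ``mean_traces`` is [n_sessions, n_neurons, n_frames] of trial-mean
    ΔF/F0; bins are per-bin means of the frames in each half-open 0.1-s
    bin, concatenated in session order.
    """
    params = params or EnsembleParams()
    mean_traces = np.asarray(mean_traces, float)
    if mean_traces.ndim != 3:
        raise ValueError("mean_traces must be [session, neuron, frame]")
    n_sessions, n_neurons, _ = mean_traces.shape
    t0, _ = params.window
    eps = 0.5 / frame_rate
    cols = []
    for s in range(n_sessions):
        for b in range(params.n_bins):
            lo = t0 + b * params.bin_width
            hi = lo + params.bin_width
            idx = np.flatnonzero((time_axis >= lo - eps) & (time_axis < hi - eps))
            if idx.size == 0:
                raise ValueError(f"bin [{lo}, {hi}) s has no frames on the time axis")
            cols.append(mean_traces[s][:, idx].mean(axis=1))
    return np.column_stack(cols)


def pca_project(
    features: np.ndarray, params: EnsembleParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Projection on the leading principal components of the centred
    feature matrix; returns (projection, variance_explained ratios)."""
    params = params or EnsembleParams()
    X = np.asarray(features, float)
    if X.shape[0] < params.n_components + 1:
        raise ValueError("need more neurons than components")
    n_comp = min(params.n_components, min(X.shape) - 1, np.linalg.matrix_rank(X - X.mean(0)))
    n_comp = max(n_comp, 1)
    pca = PCA(n_components=n_comp, random_state=params.seed)
    proj = pca.fit_transform(X - X.mean(axis=0))
    var = pca.explained_variance_ratio_
    if var.sum() < params.min_variance_explained:
        logger.warning(
            "first %d PCs explain only %.1f%% of variance (threshold %.0f%%)",
            n_comp, 100 * var.sum(), 100 * params.min_variance_explained,
        )
    return proj, var


def kmeans_cluster(
    projection: np.ndarray, k: int, params: EnsembleParams | None = None
) -> np.ndarray:
    """Best-inertia k-means labels (Euclidean, seeded restarts)."""
    params = params or EnsembleParams()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > projection.shape[0]:
        raise ValueError("k cannot exceed the number of neurons")
    km = KMeans(n_clusters=k, n_init=params.kmeans_n_init, random_state=params.seed)
    return km.fit_predict(projection)


def optimal_k_silhouette(
    projection: np.ndarray, params: EnsembleParams | None = None
) -> tuple[int, dict[int, float]]:
    """k maximising the mean silhouette index over the candidates
    (ties break to the smallest k)."""
    params = params or EnsembleParams()
    if len(params.k_candidates) < 2:
        raise ValueError("need at least two candidate k values")
    if np.allclose(projection, projection[0]):
        raise ValueError("all points identical; silhouette undefined")
    candidates = [k for k in sorted(set(params.k_candidates))
                  if 2 <= k <= projection.shape[0] - 1]
    if not candidates:
        raise ValueError("no candidate k fits the number of points")
    scores: dict[int, float] = {}
    for k in candidates:
        labels = kmeans_cluster(projection, k, params)
        if len(np.unique(labels)) < 2:
            scores[k] = float("-inf")
            continue
        scores[k] = float(silhouette_score(projection, labels, metric="euclidean"))
    best = max(sorted(scores), key=lambda k: scores[k])  # sorted → smallest k wins ties
    return best, scores


def label_ensembles(
    labels: np.ndarray,
    features: np.ndarray,
    params: EnsembleParams | None = None,
) -> dict[int, str]:
    """Map the two clusters to vF-activated / vF-inactivated.

    The cluster with the larger session-1 (post-onset minus pre-onset)
    mean binned response is vF-activated.  Exact ties break to cluster
    0 = activated with a warning.  Refused for k ≠ 2.
    """
    params = params or EnsembleParams()
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"ensemble labelling requires exactly 2 clusters, got {uniq.size}")
    n_bins = params.n_bins
    pre_bins = int(round(-params.window[0] / params.bin_width))
    s1 = np.asarray(features, float)[:, :n_bins]  # session-1 block
    contrast = s1[:, pre_bins:].mean(axis=1) - s1[:, :pre_bins].mean(axis=1)
    means = {int(c): float(contrast[labels == c].mean()) for c in uniq}
    c0, c1 = (int(u) for u in uniq)
    if means[c0] == means[c1]:
        logger.warning("cluster contrast tie; defaulting cluster %d to vF-activated", c0)
        return {c0: "vF-activated", c1: "vF-inactivated"}
    act = c0 if means[c0] > means[c1] else c1
    other = c1 if act == c0 else c0
    return {act: "vF-activated", other: "vF-inactivated"}


def ensemble_proportions(
    labels_by_group: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Contingency table of ensemble labels across groups, with Fisher's
    exact test (2×2) and the χ² test."""
    if len(labels_by_group) != 2:
        raise ValueError("exactly two groups are required")
    for g, lab in labels_by_group.items():
        if len(lab) == 0:
            raise ValueError(f"group {g!r} is empty")
    cats = sorted({c for lab in labels_by_group.values() for c in np.unique(lab)})
    table = pd.DataFrame(
        {g: [int(np.sum(np.asarray(lab) == c)) for c in cats]
         for g, lab in labels_by_group.items()},
        index=cats,
    ).T
    tests: dict[str, float] = {}
    arr = table.to_numpy()
    chi2 = chi2_contingency(arr)
    tests["chi2_p"] = float(chi2.pvalue)
    tests["chi2_stat"] = float(chi2.statistic)
    if arr.shape == (2, 2):
        odds, p = fisher_exact(arr)
        tests["fisher_p"] = float(p)
        tests["fisher_odds_ratio"] = float(odds)
    return table, tests


class EnsembleClustering:
    """Ensemble-discovery model over per-session trial-mean responses.

    Construct from the stacked mean traces ([session, neuron, frame]
    with a shared time axis) or directly from a prebuilt feature matrix
    via :meth:`from_features`; ``fit()`` returns an
    :class:`EnsembleResults`.
    """

    def __init__(
        self,
        mean_traces: np.ndarray,
        time_axis: np.ndarray,
        frame_rate: float,
        params: EnsembleParams | None = None,
    ) -> None:
        self.params = params or EnsembleParams()
        self.features = build_feature_matrix(mean_traces, time_axis, frame_rate, self.params)

    @classmethod
    def from_features(cls, features: np.ndarray, params: EnsembleParams | None = None):
        obj = cls.__new__(cls)
        obj.params = params or EnsembleParams()
        obj.features = np.asarray(features, float)
        return obj

    def fit(self) -> "EnsembleResults":
        proj, var = pca_project(self.features, self.params)
        chosen_k, scores = optimal_k_silhouette(proj, self.params)
        labels = kmeans_cluster(proj, chosen_k, self.params)
        ensemble_map: dict[int, str] | None = None
        if chosen_k == 2:
            ensemble_map = label_ensembles(labels, self.features, self.params)
        else:
            logger.warning("chosen k = %d != 2; clusters left unlabelled", chosen_k)
        return EnsembleResults(
            feature_matrix=self.features,
            pc_projection=proj,
            variance_explained=var,
            silhouette_by_k=scores,
            chosen_k=chosen_k,
            labels=labels,
            ensemble_map=ensemble_map,
            params=self.params,
        )


@dataclass
class EnsembleResults:
    feature_matrix: np.ndarray
    pc_projection: np.ndarray
    variance_explained: np.ndarray
    silhouette_by_k: dict[int, float]
    chosen_k: int
    labels: np.ndarray
    ensemble_map: dict[int, str] | None
    params: EnsembleParams = field(default_factory=EnsembleParams)

    def ensemble_labels(self) -> np.ndarray:
        """Per-neuron 'vF-activated'/'vF-inactivated' strings (k = 2)."""
        if self.ensemble_map is None:
            raise ValueError("clusters are unlabelled (chosen k != 2)")
        return np.array([self.ensemble_map[int(c)] for c in self.labels])

    def summary(self) -> str:
        lines = [
            "Ensemble discovery (PCA + k-means, silhouette-selected k)",
            "=" * 58,
            f"neurons: {self.feature_matrix.shape[0]}"
            f"   features: {self.feature_matrix.shape[1]}",
            f"variance explained by {self.pc_projection.shape[1]} PCs: "
            f"{100 * self.variance_explained.sum():.1f}%",
            "silhouette by k: "
            + ", ".join(f"{k}: {v:.3f}" for k, v in sorted(self.silhouette_by_k.items())),
            f"chosen k: {self.chosen_k}",
        ]
        if self.ensemble_map is not None:
            labs = self.ensemble_labels()
            n_act = int((labs == "vF-activated").sum())
            lines.append(
                f"vF-activated: {n_act} ({100 * n_act / labs.size:.1f}%)   "
                f"vF-inactivated: {labs.size - n_act}"
            )
        return "\n".join(lines)
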