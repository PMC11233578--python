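"""Statistical comparisons on pipeline outputs.

Thin orchestration over scipy's standard tests — the value added here
is correct pairing, comparison families and Bonferroni correction for
each experimental contrast, not the tests themselves.  Dunn's post-hoc
test after Friedman is implemented locally (rank-sum z statistic with
average-rank tie handling), as no pre-packaged implementation is part
of the dependency stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonSpec",
    "StatResult",
    "run_comparison",
    "dunn_posthoc_friedman",
    "responsive_proportion_trend",
    "build_report",
]

_TESTS = {
    "friedman_dunn",
    "wilcoxon_bonferroni",
    "mannwhitney_bonferroni",
    "fisher_exact",
    "chi2",
    "one_sample_t_vs_50",
}


@dataclass(frozen=True)
class ComparisonSpec:
    name: str
    test: str
    paired: bool = False
    alpha: float = 0.05
    correction_family_size: int = 1

    def __post_init__(self) -> None:
        if self.test not in _TESTS:
            raise ValueError(f"unknown test {self.test!r}; choose from {sorted(_TESTS)}")
        if self.correction_family_size < 1:
            raise ValueError("correction family size must be >= 1")


@dataclass
class StatResult:
    name: str
    test: str
    statistic: float
    raw_p: float
    corrected_p: float
    n: tuple
    significant: bool
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return dict(
            name=self.name, test=self.test, statistic=float(self.statistic),
            raw_p=float(self.raw_p), corrected_p=float(self.corrected_p),
            n=str(self.n), significant=bool(self.significant),
            degenerate=bool(self.degenerate),
        )


def _bonferroni(p: float, family: int) -> float:
    return float(min(1.0, p * family))


def dunn_posthoc_friedman(
    samples: Sequence[np.ndarray], pairs: Sequence[tuple[int, int]]
) -> list[tuple[tuple[int, int], float, float]]:
    """Dunn's z test on within-subject mean ranks after a Friedman test.

    Ranks are assigned per subject across conditions with average-rank
    tie handling; for conditions i, j the statistic is
    z = (R̄_i − R̄_j) / sqrt(k(k+1) / (6n)).  Returns
    [(pair, z, two-sided raw p), ...] — correction is the caller's job.
    """
    data = np.column_stack([np.asarray(s, float) for s in samples])
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(((i, j), float(z), float(p)))
    return out


def run_comparison(spec: ComparisonSpec, *groups) -> StatResult | list[StatResult]:
    """Dispatch one comparison to the appropriate standard test.

    ``groups`` are the samples (arrays) or, for the count-based tests, a
    contingency table.  Multi-stage tests (Friedman + Dunn, paired
    Wilcoxon families) return one StatResult per post-hoc pair.
    """
    if spec.test == "one_sample_t_vs_50":
        (x,) = groups
        x = np.asarray(x, float)
        if x.size < 2:
            raise ValueError("one-sample t needs n >= 2")
        t, p = sps.ttest_1samp(x, popmean=50.0)
        cp = _bonferroni(p, spec.correction_family_size)
        return StatResult(spec.name, spec.test, float(t), float(p), cp, (x.size,),
                          cp < spec.alpha, extra={"direction": "above" if t > 0 else "below"})

    if spec.test == "fisher_exact":
        (table,) = groups
        table = np.asarray(table)
        odds, p = sps.fisher_exact(table)
        cp = _bonferroni(p, spec.correction_family_size)
        return StatResult(spec.name, spec.test, float(odds), float(p), cp,
                          tuple(int(x) for x in table.sum(axis=1)), cp < spec.alpha)

    if spec.test == "chi2":
        (table,) = groups
        res = sps.chi2_contingency(np.asarray(table))
        cp = _bonferroni(res.pvalue, spec.correction_family_size)
        return StatResult(spec.name, spec.test, float(res.statistic), float(res.pvalue),
                          cp, tuple(int(x) for x in np.asarray(table).sum(axis=1)),
                          cp < spec.alpha)

    if spec.test == "mannwhitney_bonferroni":
        a, b = (np.asarray(g, float) for g in groups)
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        cp = _bonferroni(p, spec.correction_family_size)
        return StatResult(spec.name, spec.test, float(u), float(p), cp,
                          (a.size, b.size), cp < spec.alpha)

    if spec.test == "wilcoxon_bonferroni":
        a, b = (np.asarray(g, float) for g in groups)
        if a.size != b.size:
            raise ValueError("paired test requires equal-length matched samples")
        diffs = a - b
        if np.all(diffs == 0):
            return StatResult(spec.name, spec.test, float("nan"), 1.0, 1.0,
                              (a.size,), False, degenerate=True)
        w, p = sps.wilcoxon(a, b)
        cp = _bonferroni(p, spec.correction_family_size)
        return StatResult(spec.name, spec.test, float(w), float(p), cp,
                          (a.size,), cp < spec.alpha)

    if spec.test == "friedman_dunn":
        samples = [np.asarray(g, float) for g in groups]
        if len(samples) < 3:
            raise ValueError("Friedman test needs >= 3 conditions")
        stat, p = sps.friedmanchisquare(*samples)
        pairs = [(0, j) for j in range(1, len(samples))]
        family = spec.correction_family_size if spec.correction_family_size > 1 else len(pairs)
        results = [
            StatResult(spec.name, "friedman", float(stat), float(p),
                       float(p), (samples[0].size, len(samples)), p < spec.alpha)
        ]
        for (i, j), z, raw in dunn_posthoc_friedman(samples, pairs):
            cp = _bonferroni(raw, family)
            results.append(
                StatResult(f"{spec.name}:dunn_{i}v{j}", "dunn", z, raw, cp,
                           (samples[0].size,), cp < spec.alpha)
            )
        return results

    raise AssertionError("unreachable")


def responsive_proportion_trend(
    flags_by_session: dict[int, np.ndarray], alpha: float = 0.05
) -> list[StatResult]:
    """Session-wise trend of the responsive proportion.

    Overall χ² across all sessions, then session-1-referenced pairwise
    Fisher exact tests with Bonferroni correction (family = number of
    pairwise tests).
    """
    sessions = sorted(flags_by_session)
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    counts = []
    for s in sessions:
        f = np.asarray(flags_by_session[s], dtype=bool)
        if f.size == 0:
            raise ValueError(f"session {s} is empty")
        counts.append([int(f.sum()), int((~f).sum())])
    table = np.asarray(counts)
    chi = sps.chi2_contingency(table)
    out = [
        StatResult("responsive_trend", "chi2", float(chi.statistic), float(chi.pvalue),
                   float(chi.pvalue), tuple(table.sum(axis=1)), chi.pvalue < alpha)
    ]
    ref = sessions[0]
    pairs = sessions[1:]
    for s in pairs:
        sub = table[[sessions.index(ref), sessions.index(s)]]
        odds, p = sps.fisher_exact(sub)
        cp = _bonferroni(p, len(pairs))
        out.append(
            StatResult(f"responsive_s{ref}_vs_s{s}", "fisher_exact", float(odds),
                       float(p), cp, tuple(sub.sum(axis=1)), cp < alpha)
        )
    return out


def build_report(results: Sequence[StatResult]) -> tuple[pd.DataFrame, str]:
    """Aggregate StatResults into a table and a canonical JSON string.

    The JSON is key-sorted and fixed-format, so identical inputs give a
    byte-identical report.
    """
    rows = [r.as_row() for r in results]
    df = pd.DataFrame(
        rows, columns=["name", "test", "statistic", "raw_p", "corrected_p",
                       "n", "significant", "degenerate"],
    )
    payload = [
        {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
        for row in rows
    ]
    return df, json.dumps(payload, sort_keys=True, indent=2)
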