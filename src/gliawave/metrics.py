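"""Participation statistics and group comparisons.

The headline quantity is the *percent of ROIs responsive per wave*: a ROI
counts as responsive for a wave when it has a transient onset inside the
wave's coincidence window, ``[wave onset - pre_s, wave offset + post_s]``.
The default window extends 5 s past the wave offset (matching the glial
onset lag) and does not reach before the onset.  Each event is assigned to
at most one wave, the one with the nearest onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import (
    DffTraces,
    ItiDistribution,
    ParticipationSummary,
    TransientEvent,
    WaveEpoch,
    events_by_roi,
)

__all__ = [
    "responsive_per_wave",
    "responsive_any_wave",
    "participation_timecourse",
    "inter_transient_intervals",
    "evoked_response_average",
    "compare_groups",
    "event_match_score",
]


def _responsive_sets(
    events: Iterable[TransientEvent],
    waves: Sequence[WaveEpoch],
    pre_s: float,
    post_s: float,
) -> list[set[int]]:
    """Per-wave sets of responsive ROI ids (nearest-onset assignment)."""
    onsets = np.array([w.onset_s for w in waves])
    hit: list[set[int]] = [set() for _ in waves]
    for ev in events:
        w = int(np.argmin(np.abs(onsets - ev.onset_s)))
        if waves[w].onset_s - pre_s <= ev.onset_s <= waves[w].offset_s + post_s:
            hit[w].add(ev.roi_id)
    return hit


def responsive_per_wave(
    events: Iterable[TransientEvent],
    waves: Sequence[WaveEpoch],
    n_rois: int,
    pre_s: float = 0.0,
    post_s: float = 5.0,
    condition: str = "",
) -> ParticipationSummary:
    """Percent of ROIs with a coincident transient, per wave."""
    if n_rois <= 0:
        raise ValueError("need at least one ROI")
    if len(waves) == 0:
        raise ValueError("need at least one wave epoch")
    hit = _responsive_sets(events, waves, pre_s, post_s)
    pct = [100.0 * len(s) / n_rois for s in hit]
    return ParticipationSummary(per_wave_pct=pct, n_rois=n_rois, n_waves=len(waves), condition=condition)


def responsive_any_wave(
    events: Iterable[TransientEvent],
    waves: Sequence[WaveEpoch],
    n_rois: int,
    pre_s: float = 0.0,
    post_s: float = 5.0,
) -> float:
    """Percent of ROIs responsive during at least one wave."""
    if n_rois <= 0:
        raise ValueError("need at least one ROI")
    if len(waves) == 0:
        raise ValueError("need at least one wave epoch")
    hit = _responsive_sets(events, waves, pre_s, post_s)
    return 100.0 * len(set().union(*hit)) / n_rois


def participation_timecourse(
    events: Iterable[TransientEvent],
    n_rois: int,
    bin_s: float,
    duration_s: float,
    t0_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram over time of the percent of ROIs with an event onset per bin.

    Returns ``(bin_edges, pct)`` with ``len(pct) = len(bin_edges) - 1``.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    edges = np.arange(t0_s, t0_s + duration_s + bin_s, bin_s)
    pct = np.zeros(len(edges) - 1)
    per_bin: list[set[int]] = [set() for _ in pct]
    for ev in events:
        b = int((ev.onset_s - t0_s) // bin_s)
        if 0 <= b < len(per_bin):
            per_bin[b].add(ev.roi_id)
    for b, s in enumerate(per_bin):
        pct[b] = 100.0 * len(s) / n_rois
    return edges, pct


def inter_transient_intervals(events: Iterable[TransientEvent]) -> ItiDistribution:
    """Successive onset differences within each ROI, pooled across ROIs."""
    intervals: list[float] = []
    for roi_events in events_by_roi(events).values():
        onsets = [e.onset_s for e in roi_events]
        intervals.extend(np.diff(onsets))
    return ItiDistribution(intervals_s=np.asarray(intervals))


def evoked_response_average(
    traces: DffTraces, stim_windows: Sequence[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Average dF/F segments aligned to focal-application onsets.

    Segments (one per ROI per window) are aligned to the window start and
    truncated to the shortest window.  Returns ``(t_rel, mean, sd,
    per_roi_peak)`` where ``per_roi_peak`` is each ROI's peak of its
    application-averaged response -- the amplitude compared across drug
    conditions.
    """
    if traces.dff is None:
        raise ValueError("compute_dff must be applied first")
    t = traces.t_s
    dt = 1.0 / traces.frame_rate_hz
    n_samples = None
    starts = []
    for w0, w1 in stim_windows:
        # the window end is exclusive: [w0, w1) covers frames up to t[-1] + dt
        if w0 < t[0] - 0.5 * dt or w1 > t[-1] + dt + 1e-9:
            raise ValueError(f"stimulation window [{w0}, {w1}] exceeds the recording")
        i0 = int(np.searchsorted(t, w0 - 0.5 * dt))
        n = int(round((w1 - w0) / dt))
        n = min(n, len(t) - i0)
        starts.append(i0)
        n_samples = n if n_samples is None else min(n_samples, n)
    if n_samples is None or n_samples < 1:
        raise ValueError("no usable stimulation windows")

    segs = np.stack(
        [traces.dff[:, i0 : i0 + n_samples] for i0 in starts], axis=0
    )  # (n_windows, n_rois, n_samples)
    per_roi_mean = segs.mean(axis=0)
    mean = per_roi_mean.mean(axis=0)
    sd = segs.reshape(-1, n_samples).std(axis=0, ddof=0)
    per_roi_peak = per_roi_mean.max(axis=1)
    t_rel = np.arange(n_samples) * dt
    return t_rel, mean, sd, per_roi_peak


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc test after Kruskal-Wallis.

    Z statistics use pooled mean ranks with the usual tie correction;
    p-values are two-sided normal, Bonferroni-adjusted over all pairs.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[i : i + n].mean()
        i += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for a, b in combinations(names, 2):
        se = np.sqrt(var_factor * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {"group1": a, "group2": b, "statistic": z, "pvalue": min(1.0, p * m), "reject": p * m < 0.05}
        )
    return pd.DataFrame(rows)


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    values = np.concatenate([groups[g] for g in groups])
    labels = np.concatenate([[g] * len(groups[g]) for g in groups])
    res = pairwise_tukeyhsd(values, labels, alpha=0.05)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame.rename(columns={"p-adj": "pvalue"})


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None


def compare_groups(
    samples: dict[str, Sequence[float]], method: str = "parametric"
) -> GroupComparison:
    """Compare condition groups the way the field reports them.

    Two groups: two-sided independent t-test (parametric) or Mann-Whitney
    U.  More than two: one-way ANOVA with Tukey post-hoc, or
    Kruskal-Wallis with Dunn post-hoc (``method='nonparametric'``).
    This is plumbing over standard statistical routines; the significance
    level is 0.05 throughout.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs n >= 2")
    if method not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown method {method!r}")
    vals = list(groups.values())

    if len(groups) == 2:
        if method == "parametric":
            res = stats.ttest_ind(vals[0], vals[1])
            return GroupComparison("t-test", float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return GroupComparison("Mann-Whitney U", float(res.statistic), float(res.pvalue))

    if method == "parametric":
        res = stats.f_oneway(*vals)
        return GroupComparison(
            "one-way ANOVA", float(res.statistic), float(res.pvalue), _tukey_posthoc(groups)
        )
    res = stats.kruskal(*vals)
    return GroupComparison(
        "Kruskal-Wallis", float(res.statistic), float(res.pvalue), _dunn_posthoc(groups)
    )


def event_match_score(
    detected: Iterable[TransientEvent],
    truth_onsets: dict[int, list[float]],
    tol_s: float,
) -> tuple[float, float]:
    """(precision, recall) of detected events against ground-truth onsets.

    Greedy one-to-one matching per ROI: a detected event matches an unused
    true onset when their onsets differ by at most ``tol_s``.
    """
    det = events_by_roi(detected)
    tp = 0
    n_det = 0
    n_true = sum(len(v) for v in truth_onsets.values())
    for rid, evs in det.items():
        n_det += len(evs)
        remaining = sorted(truth_onsets.get(rid, []))
        for ev in evs:
            best = None
            for i, t0 in enumerate(remaining):
                d = abs(ev.onset_s - t0)
                if d <= tol_s and (best is None or d < abs(ev.onset_s - remaining[best])):
                    best = i
            if best is not None:
                remaining.pop(best)
                tp += 1
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_true if n_true else 1.0
    return precision, recall
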