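"""Retinal-wave epoch detection from voltage-clamp current traces.

Waves appear in a ganglion-cell recording as prolonged compound inward
(negative) EPSCs.  The detector smooths the trace with a short moving
average, takes the median as baseline and a MAD-based robust SD as the
noise scale, and declares an epoch wherever the current stays below
``baseline - c * robust_sd`` for at least ``min_dur_s``; nearby epochs
are merged.  Because both the baseline and the noise scale are estimated
from the trace itself, the detection is invariant under positive
rescaling of the current.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import EphysTrace, StimProtocol, WaveEpoch

__all__ = ["detect_wave_epochs", "focal_stim_epochs"]


def detect_wave_epochs(
    trace: EphysTrace,
    smooth_s: float = 0.2,
    threshold_sd: float = 4.0,
    min_dur_s: float = 1.0,
    merge_gap_s: float = 2.0,
) -> list[WaveEpoch]:
    """Find compound-EPSC epochs; returns disjoint, time-ordered epochs.

    Charge is the trapezoidal integral of (baseline - current) over the
    epoch, reported positive, in pC (pA x s).
    """
    t, i_pa = trace.time_s, trace.current_pA
    if len(t) < 2:
        return []
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("wave detection requires uniform sampling")
    dt = float(dts[0])

    width = max(1, int(round(smooth_s / dt)))
    sm = uniform_filter1d(i_pa, size=width, mode="nearest")
    baseline = float(np.median(sm))
    rsd = float(1.4826 * np.median(np.abs(sm - baseline)))
    thr = baseline - threshold_sd * rsd

    below = sm < thr
    if not below.any():
        return []
    edges = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(below))

    runs = list(zip(starts, ends))
    merged: list[list[int]] = []
    for s0, e0 in runs:
        if merged and (s0 - merged[-1][1]) * dt < merge_gap_s:
            merged[-1][1] = e0
        else:
            merged.append([s0, e0])

    epochs = []
    for s0, e0 in merged:
        if (e0 - s0) * dt < min_dur_s:
            continue
        # the threshold crossing lags the physiological onset by the rise to
        # threshold; backtrack to where the current was last within half a
        # robust SD of baseline (stopping short of baseline itself avoids
        # chasing correlated noise wander)
        back_lvl = baseline - 0.5 * rsd
        while s0 > 0 and sm[s0 - 1] < back_lvl:
            s0 -= 1
        seg = i_pa[s0:e0]
        charge = float(np.trapezoid(baseline - seg, dx=dt))
        epochs.append(
            WaveEpoch(
                onset_s=float(t[s0]),
                offset_s=float(t[e0 - 1]),
                peak_current_pA=float(seg.min()),
                charge_pC=charge,
            )
        )
    return epochs


def focal_stim_epochs(protocol: StimProtocol, window_s: float = 10.0) -> list[tuple[float, float]]:
    """Analysis windows ``[t, t + window_s]`` per focal application.

    Overlapping windows (applications closer than the window) raise a
    warning but are still returned.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    windows = [(float(t), float(t) + window_s) for t in protocol.application_times_s]
    for (a0, a1), (b0, _) in zip(windows, windows[1:]):
        if b0 < a1:
            warnings.warn(
                f"focal-stimulation windows overlap ({a0:.1f}-{a1:.1f} s vs {b0:.1f} s)",
                stacklevel=2,
            )
            break
    return windows
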