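"""Shared in-memory containers for movies, ROIs, traces, events and epochs.

All times are in seconds on a common axis whose origin is the first movie
frame.  Image coordinates are 0-based ``(row, col)`` with pixel centres on
integer coordinates; ROI ids are 1-based so they can double as values in a
label image (0 = background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from skimage.measure import regionprops

__all__ = [
    "MovieStack",
    "Roi",
    "RoiMap",
    "EphysTrace",
    "GroundTruth",
    "DffTraces",
    "TransientEvent",
    "WaveEpoch",
    "StimProtocol",
    "ParticipationSummary",
    "ItiDistribution",
    "roi_circularity",
]


def roi_circularity(mask: np.ndarray) -> float:
    """Isoperimetric circularity 4*pi*A/P**2 of a binary mask, clipped to 1.

    Perimeter is the weighted boundary estimate of ``skimage.measure
    .regionprops``; for very small rasterised shapes it underestimates the
    true perimeter, which can push the raw ratio above 1, hence the clip.
    """
    props = regionprops(mask.astype(np.uint8))
    if not props:
        raise ValueError("empty mask has no circularity")
    p = props[0]
    if p.area < 2 or p.perimeter == 0:
        raise ValueError("degenerate ROI (fewer than 2 pixels or zero perimeter)")
    return float(min(1.0, 4.0 * np.pi * p.area / p.perimeter**2))


@dataclass
class MovieStack:
    """A fluorescence movie: ``data`` is (frames, rows, cols)."""

    data: np.ndarray
    frame_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be (frames, rows, cols) with >= 1 frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, seconds."""
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class Roi:
    id: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    shape_class: str  # 'stalk' | 'lateral_process' | 'grid'
    circularity: float

    @property
    def area(self) -> int:
        return len(self.pixels)


@dataclass
class RoiMap:
    """A label image plus per-ROI records; labels and pixel sets agree."""

    labels: np.ndarray
    rois: list[Roi] = field(default_factory=list)

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, shape_classes: dict[int, str] | str | None = None
    ) -> "RoiMap":
        """Build from a label image, computing circularity per ROI.

        ``shape_classes`` may be a single class for all ROIs, a mapping
        id -> class, or None to classify by shape (see
        :func:`gliawave.segmentation.classify_roi_shape`).
        """
        from .segmentation import classify_roi_shape

        labels = np.asarray(labels)
        rois = []
        for rid in np.unique(labels):
            if rid == 0:
                continue
            mask = labels == rid
            pixels = np.argwhere(mask)
            circ = roi_circularity(mask)
            if isinstance(shape_classes, str):
                cls_name = shape_classes
            elif isinstance(shape_classes, dict):
                cls_name = shape_classes[int(rid)]
            else:
                cls_name = classify_roi_shape(mask)
            rois.append(Roi(int(rid), pixels, cls_name, circ))
        return cls(labels=labels, rois=rois)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def roi_ids(self) -> list[int]:
        return [r.id for r in self.rois]


@dataclass
class EphysTrace:
    """Whole-cell voltage-clamp current record (inward currents negative)."""

    time_s: np.ndarray
    current_pA: np.ndarray
    sample_rate_hz: float
    holding_mV: float = -60.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if len(self.time_s) != len(self.current_pA):
            raise ValueError("time and current must have equal length")


@dataclass
class GroundTruth:
    """Simulator bookkeeping: which wave recruited which ROI, and when."""

    wave_onsets_s: np.ndarray
    recruited: list[set[int]]
    event_onsets: dict[int, list[float]]
    n_rois: int

    @property
    def n_waves(self) -> int:
        return len(self.wave_onsets_s)

    @property
    def true_participation_per_wave(self) -> list[float]:
        if self.n_rois == 0:
            return [0.0 for _ in self.recruited]
        return [len(s) / self.n_rois for s in self.recruited]

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.event_onsets.values())

    def all_event_onsets(self) -> list[tuple[int, float]]:
        """(roi_id, onset_s) pairs, time-sorted."""
        out = [(rid, t) for rid, ts in self.event_onsets.items() for t in ts]
        return sorted(out, key=lambda x: x[1])


@dataclass
class DffTraces:
    """Per-ROI mean-intensity traces and their dF/F normalisation.

    ``raw_mean`` has shape (n_rois, n_frames).  ``dff`` and ``f0`` are None
    until :func:`gliawave.traces.compute_dff` is applied; afterwards
    ``dff = (raw_mean - f0[:, None]) / f0[:, None]``.
    """

    roi_ids: list[int]
    t_s: np.ndarray
    raw_mean: np.ndarray
    frame_rate_hz: float
    f0: np.ndarray | None = None
    dff: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def reconstruct_raw(self) -> np.ndarray:
        """F = F0 * (1 + dF/F); identity check for the normalisation."""
        if self.dff is None or self.f0 is None:
            raise ValueError("dF/F not computed yet")
        return self.f0[:, None] * (1.0 + self.dff)


@dataclass
class TransientEvent:
    """A detected fluorescence transient in one ROI."""

    roi_id: int
    onset_s: float
    peak_s: float
    offset_s: float
    peak_dff: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s <= self.offset_s):
            raise ValueError("event must satisfy onset <= peak <= offset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class WaveEpoch:
    """A retinal-wave epoch: interval of compound inward EPSC activity."""

    onset_s: float
    offset_s: float
    peak_current_pA: float
    charge_pC: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("epoch onset must precede offset")


@dataclass
class StimProtocol:
    """Focal agonist application protocol (times of pressure pulses)."""

    application_times_s: list[float]
    duration_s: float = 0.1
    agent: str = "ACSF"

    def __post_init__(self) -> None:
        t = np.asarray(self.application_times_s, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("application times must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("application duration must be positive")


@dataclass
class ParticipationSummary:
    """Percent of ROIs responsive per wave, plus summary moments."""

    per_wave_pct: list[float]
    n_rois: int
    n_waves: int
    condition: str = ""

    @property
    def mean_pct(self) -> float:
        return float(np.mean(self.per_wave_pct))

    @property
    def sd_pct(self) -> float:
        return float(np.std(self.per_wave_pct, ddof=1)) if len(self.per_wave_pct) > 1 else 0.0


@dataclass
class ItiDistribution:
    """Pooled inter-transient intervals and their empirical CDF."""

    intervals_s: np.ndarray

    @property
    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.sort(np.asarray(self.intervals_s, dtype=float))
        if len(x) == 0:
            return x, x
        return x, np.arange(1, len(x) + 1) / len(x)


def events_by_roi(events: Iterable[TransientEvent]) -> dict[int, list[TransientEvent]]:
    out: dict[int, list[TransientEvent]] = {}
    for ev in events:
        out.setdefault(ev.roi_id, []).append(ev)
    for lst in out.values():
        lst.sort(key=lambda e: e.onset_s)
    return out
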