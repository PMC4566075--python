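"""Synthetic two-photon experiment generator.

Produces, from a :class:`~gliawave.config.SimulationConfig` and a seed, the
four objects a real recording session would yield: the fluorescence movie,
the simultaneous whole-cell current trace, the true ROI layout, and the
ground-truth event bookkeeping used for recovery testing.

The generative model is deliberately simple and matches the assumptions of
the analysis pipeline:

* ROIs are bright structures (baseline ``baseline_f0``) on a dimmer
  neuropil background, either round disks (stalk cross-sections) or thin
  rotated bars (lateral processes), placed without overlap.
* Waves arrive with truncated-normal inter-wave intervals; each wave
  independently recruits each ROI with probability ``participation_p``;
  recruited ROIs fire one transient with onset lagged uniformly within
  ``glial_lag_s`` of the wave onset.
* A transient multiplies the ROI's baseline by ``1 + kernel(t)`` where the
  kernel rises linearly to ``peak_dff`` over ``rise_s`` then decays
  exponentially with time constant ``decay_s``.
* Each wave adds a compound inward EPSC envelope to the current trace.
* Pixel noise is additive Gaussian; optional drift is a global integer
  translation growing linearly with frame index.
"""

from __future__ import annotations

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import binary_dilation
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk as disk_footprint

from .config import SimulationConfig
from .core import EphysTrace, GroundTruth, MovieStack, Roi, RoiMap, roi_circularity

__all__ = [
    "make_layout",
    "simulate_waves",
    "render_movie",
    "simulate_ephys",
    "generate_experiment",
    "transient_kernel",
]

_PLACEMENT_GAP_PX = 6  # min free pixels between ROIs, keeps segmentation 1:1
_MAX_TRIES_PER_ROI = 2000


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float, peak: float) -> np.ndarray:
    """Linear-rise / exponential-decay fluorescence transient, peak at ``rise_s``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_s)
    out[rising] = peak * t[rising] / rise_s
    decaying = t >= rise_s
    out[decaying] = peak * np.exp(-(t[decaying] - rise_s) / decay_s)
    return out


def _stalk_mask(shape, center, radius) -> tuple[np.ndarray, np.ndarray]:
    return draw_disk(center, radius, shape=shape)


def _bar_mask(shape, center, length, width, angle) -> tuple[np.ndarray, np.ndarray]:
    """Rasterised rotated rectangle (length x width) centred on ``center``."""
    c, s = np.cos(angle), np.sin(angle)
    dl = np.array([c, s]) * length / 2.0
    dw = np.array([-s, c]) * width / 2.0
    corners = np.array([center + dl + dw, center + dl - dw, center - dl - dw, center - dl + dw])
    return draw_polygon(corners[:, 0], corners[:, 1], shape=shape)


def make_layout(config: SimulationConfig, rng: Generator | int | None = None) -> RoiMap:
    """Place ``n_stalks`` disks and ``n_lateral`` elongated bars without overlap.

    Raises ``RuntimeError`` if the field is too crowded to place all ROIs
    within a bounded number of retries.
    """
    rng = rng if isinstance(rng, Generator) else default_rng(rng)
    rows, cols = config.field_size
    labels = np.zeros((rows, cols), dtype=np.int32)
    blocked = np.zeros((rows, cols), dtype=bool)  # occupied + safety gap
    footprint = disk_footprint(_PLACEMENT_GAP_PX)
    classes: dict[int, str] = {}

    specs = [("stalk", i) for i in range(config.n_stalks)] + [
        ("lateral_process", i) for i in range(config.n_lateral)
    ]
    margin = 14
    if rows <= 2 * margin or cols <= 2 * margin:
        if specs:
            raise RuntimeError("field too small to place ROIs")
        return RoiMap(labels=labels, rois=[])

    next_id = 1
    for shape_class, _ in specs:
        for attempt in range(_MAX_TRIES_PER_ROI):
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            if shape_class == "stalk":
                radius = int(rng.integers(3, 6))
                rr, cc = _stalk_mask((rows, cols), (r, c), radius)
            else:
                length = float(rng.uniform(14, 22))
                width = float(rng.uniform(3.0, 4.0))
                angle = float(rng.uniform(0, np.pi))
                rr, cc = _bar_mask((rows, cols), np.array([r, c]), length, width, angle)
            if len(rr) < 6:
                continue
            if blocked[rr, cc].any():
                continue
            labels[rr, cc] = next_id
            mask = np.zeros((rows, cols), dtype=bool)
            mask[rr, cc] = True
            blocked |= binary_dilation(mask, structure=footprint)
            classes[next_id] = shape_class
            next_id += 1
            break
        else:
            raise RuntimeError(
                f"could not place ROI {next_id} after {_MAX_TRIES_PER_ROI} tries: "
                "field too crowded"
            )

    rois = []
    for rid, cls_name in classes.items():
        mask = labels == rid
        rois.append(Roi(rid, np.argwhere(mask), cls_name, roi_circularity(mask)))
    return RoiMap(labels=labels, rois=rois)


def _draw_interval(config: SimulationConfig, rng: Generator) -> float:
    """Truncated-normal inter-wave interval (rejection sampling)."""
    while True:
        x = rng.normal(config.wave_interval_mean_s, config.wave_interval_sd_s)
        if x >= config.wave_interval_min_s:
            return float(x)


def simulate_waves(
    config: SimulationConfig, rng: Generator | int | None = None, n_rois: int | None = None
) -> GroundTruth:
    """Draw wave onsets, per-wave recruited ROI sets and lagged event onsets.

    Waves are placed so that the glial lag window plus the transient rise
    fits inside the recording (a transient whose peak falls past the end
    of the record would be unobservable, a boundary artifact rather than a
    property of the conditions being emulated).  An empty wave list is
    valid when the recording is shorter than the first drawn interval.
    """
    rng = rng if isinstance(rng, Generator) else default_rng(rng)
    if n_rois is None:
        n_rois = config.n_rois
    duration = config.duration_s
    onsets: list[float] = []
    t = _draw_interval(config, rng)
    while t + config.glial_lag_s + config.rise_s <= duration:
        onsets.append(t)
        t += _draw_interval(config, rng)

    recruited: list[set[int]] = []
    event_onsets: dict[int, list[float]] = {rid: [] for rid in range(1, n_rois + 1)}
    for onset in onsets:
        hit = np.flatnonzero(rng.random(n_rois) < config.participation_p) + 1
        recruited.append(set(int(i) for i in hit))
        for rid in hit:
            event_onsets[int(rid)].append(onset + float(rng.uniform(0, config.glial_lag_s)))
    return GroundTruth(
        wave_onsets_s=np.asarray(onsets),
        recruited=recruited,
        event_onsets={k: sorted(v) for k, v in event_onsets.items()},
        n_rois=n_rois,
    )


def render_movie(
    layout: RoiMap,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Generator | int | None = None,
) -> MovieStack:
    """Render the fluorescence movie implied by layout + ground truth.

    Pixels inside ROI *i* read ``baseline_f0 * (1 + sum_k kernel(t - t_ik))``,
    background pixels read ``background_f0``; Gaussian noise and integer
    drift are applied last and the stack is quantised to uint16 (photon
    counts are integers; it also makes TIFF round-trips exact).
    """
    rng = rng if isinstance(rng, Generator) else default_rng(rng)
    rows, cols = config.field_size
    if layout.labels.shape != (rows, cols):
        raise ValueError("layout field size does not match config")
    times = np.arange(config.n_frames) / config.frame_rate_hz

    base = np.full((rows, cols), config.background_f0, dtype=np.float32)
    base[layout.labels > 0] = config.baseline_f0
    movie = np.repeat(base[None, :, :], config.n_frames, axis=0)

    flat = movie.reshape(config.n_frames, -1)
    for roi in layout.rois:
        onsets = truth.event_onsets.get(roi.id, [])
        if not onsets:
            continue
        amp = np.zeros(config.n_frames)
        for t0 in onsets:
            amp += transient_kernel(times - t0, config.rise_s, config.decay_s, config.peak_dff)
        idx = roi.pixels[:, 0] * cols + roi.pixels[:, 1]
        flat[:, idx] = (config.baseline_f0 * (1.0 + amp))[:, None].astype(np.float32)

    if config.noise_sd > 0:
        movie += rng.normal(0.0, config.noise_sd, size=movie.shape).astype(np.float32)

    if config.drift_px_per_frame != 0:
        for i in range(config.n_frames):
            dy = int(round(config.drift_px_per_frame * i))
            if dy:
                movie[i] = np.roll(movie[i], dy, axis=0)

    movie = np.clip(np.round(movie), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return MovieStack(data=movie, frame_rate_hz=config.frame_rate_hz)


def simulate_ephys(
    truth: GroundTruth, config: SimulationConfig, rng: Generator | int | None = None
) -> EphysTrace:
    """Simulate the voltage-clamp current trace: baseline noise plus one
    compound inward EPSC envelope per wave, starting at the wave onset."""
    rng = rng if isinstance(rng, Generator) else default_rng(rng)
    n = int(round(config.duration_s * config.ephys_rate_hz))
    t = np.arange(n) / config.ephys_rate_hz
    current = rng.normal(0.0, config.ephys_noise_sd_pA, size=n)
    for onset in truth.wave_onsets_s:
        current += transient_kernel(
            t - onset, config.epsc_rise_s, config.epsc_decay_s, config.epsc_peak_pA
        )
    return EphysTrace(time_s=t, current_pA=current, sample_rate_hz=config.ephys_rate_hz)


def generate_experiment(
    config: SimulationConfig,
) -> tuple[MovieStack, EphysTrace, RoiMap, GroundTruth]:
    """Compose a full seeded experiment; deterministic given ``config.seed``."""
    ss = SeedSequence(config.seed)
    r_layout, r_waves, r_movie, r_ephys = (default_rng(s) for s in ss.spawn(4))
    layout = make_layout(config, r_layout)
    truth = simulate_waves(config, r_waves, n_rois=layout.n_rois)
    movie = render_movie(layout, truth, config, r_movie)
    ephys = simulate_ephys(truth, config, r_ephys)
    return movie, ephys, layout, truth
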