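"""Simulation and analysis configuration.

:class:`SimulationConfig` bundles every knob of the synthetic experiment
generator.  The defaults describe a standard recording session of the
developing mouse retina: a 256 x 256 two-photon field of view in the inner
plexiform layer scanned at 0.74 Hz, ~40 Mueller-cell compartments
(round stalk cross-sections plus elongated lateral processes), retinal
waves arriving roughly every 40 s, and a slow calcium sensor whose
transients last 3-5 s.

The packaged *condition table* (``data/conditions.yaml``) maps condition
labels (age and bath pharmacology, e.g. ``P11_TBOA``) to config overrides.
Pharmacology is represented purely as a change in the per-ROI per-wave
recruitment probability; no receptor kinetics are modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = ["SimulationConfig", "SENSOR_KINETICS", "load_conditions", "condition_config"]

# Default transient kinetics (rise_s, decay_tau_s) per sensor. The calcium
# numbers give a full-width-at-10%-of-peak of ~4.6 s (0.9*rise + tau*ln 10),
# inside the 3-5 s range typical of GCaMP3 transients in these cells; the
# glutamate sensor (iGluSnFR) is markedly faster, ~1.8 s full width.
SENSOR_KINETICS: dict[str, tuple[float, float]] = {
    "calcium": (3.6, 0.6),
    "glutamate": (0.5, 0.6),
}


@dataclass
class SimulationConfig:
    """All parameters of one synthetic imaging + ephys experiment.

    Attributes
    ----------
    n_frames, frame_rate_hz, field_size
        Movie geometry. Standard acquisitions are 256 x 256 pixels at
        0.74 or 1.7 Hz.
    n_stalks, n_lateral
        Number of round (stalk) and elongated (lateral-process) ROIs to
        place in the field.
    wave_interval_mean_s, wave_interval_sd_s, wave_interval_min_s
        Truncated-normal inter-wave interval, seconds.  Wave frequency at
        these ages is not well constrained; the default (40 +- 15 s,
        floor 15 s) yields well-separated epochs, ~5 per standard
        150-frame movie at 0.74 Hz.
    participation_p
        Probability that a given ROI is recruited by a given wave; this is
        the quantity the downstream pipeline estimates.
    sensor
        'calcium' (slow GCaMP-like kinetics) or 'glutamate' (fast
        iGluSnFR-like kinetics).
    transient_rise_s, transient_decay_s
        Override the sensor's default kernel kinetics (None = use
        ``SENSOR_KINETICS[sensor]``).
    peak_dff
        Peak dF/F of a single transient (dimensionless).
    baseline_f0, background_f0
        Baseline fluorescence inside labelled structures and in the
        surrounding neuropil (arbitrary units).  Labelled cells are
        brighter than background, which is what makes silent ROIs visible
        to morphological segmentation.
    noise_sd
        Additive Gaussian noise per pixel per frame, same units as
        fluorescence.  With the defaults the single-pixel transient SNR
        (peak_dff * baseline_f0 / noise_sd) is ~6.
    drift_px_per_frame
        Slow focal-plane drift along the row axis, pixels per frame;
        rounded to integer displacement per frame.
    glial_lag_s
        Glial event onsets lag the wave onset by Uniform(0, glial_lag_s).
    ephys_rate_hz
        Sample rate of the simulated whole-cell current trace.  1 kHz by
        default: wave epochs are seconds long, so this comfortably
        oversamples every feature the detector uses (acquisition hardware
        rates are far higher but add nothing at this timescale).
    epsc_peak_pA, epsc_rise_s, epsc_decay_s, ephys_noise_sd_pA
        Compound-EPSC envelope added per wave (inward = negative) and
        baseline current noise.
    seed
        Master seed; all randomness derives from it.
    """

    n_frames: int = 150
    frame_rate_hz: float = 0.74
    field_size: tuple[int, int] = (256, 256)
    n_stalks: int = 20
    n_lateral: int = 20
    wave_interval_mean_s: float = 40.0
    wave_interval_sd_s: float = 15.0
    wave_interval_min_s: float = 15.0
    participation_p: float = 0.5
    sensor: str = "calcium"
    transient_rise_s: float | None = None
    transient_decay_s: float | None = None
    peak_dff: float = 0.5
    baseline_f0: float = 100.0
    background_f0: float = 20.0
    noise_sd: float = 8.0
    drift_px_per_frame: float = 0.0
    glial_lag_s: float = 3.0
    ephys_rate_hz: float = 1000.0
    epsc_peak_pA: float = -100.0
    epsc_rise_s: float = 0.3
    epsc_decay_s: float = 1.5
    ephys_noise_sd_pA: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation_p <= 1.0:
            raise ValueError("participation_p must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.sensor not in SENSOR_KINETICS:
            raise ValueError(f"unknown sensor {self.sensor!r}")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if self.ephys_rate_hz <= 0:
            raise ValueError("ephys_rate_hz must be positive")
        self.field_size = tuple(self.field_size)  # type: ignore[assignment]

    @property
    def rise_s(self) -> float:
        if self.transient_rise_s is not None:
            return self.transient_rise_s
        return SENSOR_KINETICS[self.sensor][0]

    @property
    def decay_s(self) -> float:
        if self.transient_decay_s is not None:
            return self.transient_decay_s
        return SENSOR_KINETICS[self.sensor][1]

    @property
    def n_rois(self) -> int:
        return self.n_stalks + self.n_lateral

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)


def load_conditions() -> dict[str, dict]:
    """Load the packaged condition table (label -> config overrides)."""
    text = resources.files("gliawave").joinpath("data/conditions.yaml").read_text()
    return yaml.safe_load(text)


def condition_config(name: str, **extra) -> SimulationConfig:
    """Build a :class:`SimulationConfig` for a packaged condition label.

    ``extra`` keyword overrides are applied after the table entry (e.g.
    ``seed=3``).
    """
    table = load_conditions()
    if name not in table:
        raise KeyError(f"unknown condition {name!r}; known: {sorted(table)}")
    overrides = dict(table[name])
    overrides.update(extra)
    if "field_size" in overrides:
        overrides["field_size"] = tuple(overrides["field_size"])
    return SimulationConfig(**overrides)
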