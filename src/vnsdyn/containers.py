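"""Shared data containers for the biomarker-dynamics pipeline.

The pipeline moves through four representations:

``Waveform``
    Uniformly sampled raw signal (ECG or transmissive PPG).
``BeatSeries``
    Beat-by-beat biomarker values at the (nonuniform) beat times —
    instantaneous heart rate in bpm or per-beat PPG amplitude in
    arbitrary units.
``UniformSeries``
    A uniformly resampled series, by convention at 1 Hz and normalized
    to the day's resting value (unitless fraction of rest).
``AdministrationDataset``
    One 300-second input/output pair around a single stimulus
    administration: the normalized biomarker output together with the
    trapezoidal stimulus-amplitude input on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Waveform",
    "BeatSeries",
    "UniformSeries",
    "AdministrationDataset",
]


@dataclass
class Waveform:
    """Uniformly sampled raw signal.

    Parameters
    ----------
    samples : ndarray
        Signal samples; must be finite.
    fs : float
        Sampling rate in Hz (> 0).
    channel : str
        ``"ecg"`` or ``"ppg"``.
    """

    samples: np.ndarray
    fs: float
    channel: str = "ecg"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel not in ("ecg", "ppg"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class BeatSeries:
    """Beat-by-beat biomarker values at strictly increasing anchor times."""

    times_s: np.ndarray
    values: np.ndarray
    kind: str = "hr"  # "hr" (bpm) or "ppg_amp" (AU)

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("beat times must be strictly increasing")
        if self.kind not in ("hr", "ppg_amp"):
            raise ValueError(f"unknown beat-series kind {self.kind!r}")
        if self.kind == "hr" and len(self.values) and np.any(self.values <= 0):
            raise ValueError("heart-rate values must be positive")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class UniformSeries:
    """Uniformly sampled series (1 Hz by default, normalized units)."""

    values: np.ndarray
    start_time_s: float = 0.0
    fs: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.values)) / self.fs

    def __len__(self) -> int:
        return len(self.values)

    def copy_with(self, **kw) -> "UniformSeries":
        return replace(self, **kw)


@dataclass
class AdministrationDataset:
    """One administration window: stimulus input u and biomarker output y.

    The nominal window spans 60 s before stimulation onset, the 120 s
    stimulation period, and 120 s afterwards (300 samples at 1 Hz, onset
    at sample index 60).  Recordings that end early yield shorter windows
    flagged ``truncated``.
    """

    output: UniformSeries
    input: UniformSeries
    onset_index: int = 60
    subject: str = ""
    day: int = 0
    administration: int = 0
    biomarker: str = "hr"
    group: str = "active"
    truncated: bool = False
    stimulus_amplitude_au: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.output) != len(self.input):
            raise ValueError("input and output must share the sample grid")
        if self.onset_index > 0 and np.any(
            np.abs(self.input.values[: self.onset_index]) > 0
        ):
            raise ValueError("stimulus input must be zero before onset")

    @property
    def u(self) -> np.ndarray:
        return self.input.values

    @property
    def y(self) -> np.ndarray:
        return self.output.values

    @property
    def n_samples(self) -> int:
        return len(self.output)

    def label(self) -> str:
        return f"{self.subject}/adm{self.administration}/{self.biomarker}"
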