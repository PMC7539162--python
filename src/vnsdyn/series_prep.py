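"""Preparation of beat-by-beat biomarker series for modeling.

The preparation chain: a causal 5-point moving average
attenuates high-frequency beat-to-beat artifacts, the nonuniform beat
series is resampled onto a uniform 1 Hz grid, normalized to the day's
resting value (subtract then divide), and finally parsed into one
300-second window per stimulus administration (60 s pre, 120 s
stimulation, 120 s post).  The matching stimulus input is a unit boxcar
of 120 s width passed through the same 5-point causal moving average,
giving a trapezoid that replicates the ramp-up and stabilization of the
device amplitude.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AdministrationDataset, BeatSeries, UniformSeries

__all__ = [
    "causal_moving_average",
    "resample_uniform",
    "normalize_to_rest",
    "parse_administrations",
    "build_input_waveform",
    "prepare_day",
    "prepare_from_files",
]

NOMINAL_PRE_S = 60
NOMINAL_STIM_S = 120
NOMINAL_POST_S = 120
NOMINAL_WINDOW_S = NOMINAL_PRE_S + NOMINAL_STIM_S + NOMINAL_POST_S  # 300


def causal_moving_average(series: BeatSeries, n_points: int = 5) -> BeatSeries:
    """Causal rectangular moving average over the last ``n_points`` beats.

    The window shrinks at the head of the series (the first output is
    the first input, the second the mean of the first two, ...), so no
    fabricated zeros bias the early rest samples.  Anchor times are
    unchanged.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if len(series) == 0:
        raise ValueError("cannot average an empty series")
    v = series.values
    csum = np.concatenate([[0.0], np.cumsum(v)])
    k = np.arange(1, len(v) + 1)
    lo = np.maximum(0, k - n_points)
    out = (csum[k] - csum[lo]) / (k - lo)
    return BeatSeries(series.times_s.copy(), out, series.kind)


def resample_uniform(series: BeatSeries, fs: float = 1.0) -> UniformSeries:
    """Linearly interpolate a beat series onto the uniform integer grid.

    The grid spans the beat times (no extrapolation): it starts at the
    first grid point at or after the first beat and ends at the last
    grid point at or before the last beat.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 beats to resample")
    t = series.times_s
    t0 = np.ceil(t[0] * fs) / fs
    t1 = np.floor(t[-1] * fs) / fs
    n = int(round((t1 - t0) * fs)) + 1
    if n < 1:
        raise ValueError("resampling grid is empty")
    grid = t0 + np.arange(n) / fs
    vals = np.interp(grid, t, series.values)
    return UniformSeries(values=vals, start_time_s=t0, fs=fs)


def normalize_to_rest(series: UniformSeries, rest_value: float) -> UniformSeries:
    """Normalize to rest: value -> (value - rest) / rest (unitless)."""
    if rest_value <= 0:
        raise ValueError("rest value must be positive")
    return series.copy_with(values=(series.values - rest_value) / rest_value)


def denormalize_from_rest(series: UniformSeries, rest_value: float) -> UniformSeries:
    if rest_value <= 0:
        raise ValueError("rest value must be positive")
    return series.copy_with(values=series.values * rest_value + rest_value)


def rest_value(series: UniformSeries, rest_start_s: float = 0.0,
               rest_duration_s: float = 120.0) -> float:
    """Mean of the designated per-day rest segment."""
    t = series.times_s
    mask = (t >= rest_start_s) & (t < rest_start_s + rest_duration_s)
    if not np.any(mask):
        raise ValueError("rest segment lies outside the series span")
    return float(series.values[mask].mean())


def build_input_waveform(length_s: int, onset_index: int, width_s: int = 120,
                         smooth_points: int = 5, amplitude: float = 1.0,
                         start_time_s: float = 0.0) -> UniformSeries:
    """Trapezoidal stimulus input on the 1 Hz grid.

    A boxcar of ``width_s`` seconds and the given amplitude starting at
    ``onset_index`` is passed through a causal ``smooth_points``-point
    moving average, producing a 5-sample ramp (0.2, 0.4, 0.6, 0.8, 1.0
    for unit amplitude), a plateau, and a symmetric ramp-down.  Samples
    before the onset are exactly zero.
    """
    if onset_index + width_s > length_s:
        raise ValueError("stimulus window exceeds the series length")
    box = np.zeros(length_s + smooth_points)
    box[onset_index:onset_index + width_s] = amplitude
    kern = np.ones(smooth_points) / smooth_points
    smoothed = np.convolve(box, kern)[:length_s]
    # the causal MA cannot act before the onset; enforce exact zeros
    smoothed[:onset_index] = 0.0
    return UniformSeries(values=smoothed, start_time_s=start_time_s, fs=1.0)


def parse_administrations(series: UniformSeries, onsets_s, pre_s: int = NOMINAL_PRE_S,
                          stim_s: int = NOMINAL_STIM_S, post_s: int = NOMINAL_POST_S,
                          smooth_points: int = 5, **meta) -> list[AdministrationDataset]:
    """Cut one input/output window per administration onset.

    Each window is ``[onset - pre_s, onset + stim_s + post_s)`` at 1 Hz
    (300 samples nominally).  A series ending early yields a shortened
    window flagged ``truncated``; an onset with less than ``pre_s`` of
    history is an error.
    """
    if series.fs != 1.0:
        raise ValueError("administration parsing expects a 1 Hz series")
    out = []
    total = pre_s + stim_s + post_s
    t0 = series.start_time_s
    n = len(series)
    for adm_idx, onset in enumerate(onsets_s):
        start = int(round(onset - pre_s - t0))
        if start < 0:
            raise ValueError(
                f"onset at {onset} s has less than {pre_s} s of history")
        stop = start + total
        truncated = False
        if stop > n:
            stop = n
            truncated = True
        if stop - start < pre_s + stim_s:
            raise ValueError(
                f"onset at {onset} s: window shorter than pre + stimulation")
        length = stop - start
        y = UniformSeries(series.values[start:stop],
                          start_time_s=t0 + start, fs=1.0)
        u = build_input_waveform(length, pre_s, width_s=stim_s,
                                 smooth_points=smooth_points,
                                 start_time_s=t0 + start)
        out.append(AdministrationDataset(
            output=y, input=u, onset_index=pre_s, administration=adm_idx,
            truncated=truncated, **meta))
    return out


# ---------------------------------------------------------------------------
# higher-level drivers


def prepare_day(hr_beats: BeatSeries, ppg_beats: BeatSeries, onsets_s,
                rest_start_s: float = 0.0, rest_duration_s: float = 120.0,
                n_ma: int = 5, **meta) -> list[AdministrationDataset]:
    """Full preparation chain for one recording day (both biomarkers).

    Moving average -> 1 Hz resampling -> rest normalization -> parsing,
    applied to the heart-rate and PPG-amplitude beat series.
    """
    datasets = []
    for beats, biomarker in ((hr_beats, "hr"), (ppg_beats, "ppg_amp")):
        smoothed = causal_moving_average(beats, n_ma)
        uni = resample_uniform(smoothed, fs=1.0)
        rest = rest_value(uni, rest_start_s, rest_duration_s)
        norm = normalize_to_rest(uni, rest)
        datasets.extend(
            parse_administrations(norm, onsets_s, biomarker=biomarker, **meta))
    return datasets


def write_datasets(datasets, out_dir) -> None:
    """Write per-administration CSVs (t_s, u, y) with JSON sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for d in datasets:
        stem = f"dataset_{d.subject}_d{d.day}_a{d.administration}_{d.biomarker}"
        pd.DataFrame({"t_s": d.output.times_s, "u": d.u, "y": d.y}).to_csv(
            out_dir / f"{stem}.csv", index=False)
        sidecar = {
            "subject": d.subject, "day": d.day,
            "administration": d.administration, "biomarker": d.biomarker,
            "group": d.group, "onset_index": d.onset_index,
            "truncated": bool(d.truncated),
            "stimulus_amplitude_au": d.stimulus_amplitude_au,
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))


def read_datasets(in_dir) -> list[AdministrationDataset]:
    """Read back datasets written by :func:`write_datasets`."""
    in_dir = Path(in_dir)
    out = []
    for csv_path in sorted(in_dir.glob("dataset_*.csv")):
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        df = pd.read_csv(csv_path)
        t0 = float(df["t_s"].iloc[0])
        out.append(AdministrationDataset(
            output=UniformSeries(df["y"].to_numpy(), start_time_s=t0),
            input=UniformSeries(df["u"].to_numpy(), start_time_s=t0),
            onset_index=int(meta["onset_index"]), subject=meta["subject"],
            day=int(meta["day"]), administration=int(meta["administration"]),
            biomarker=meta["biomarker"], group=meta["group"],
            truncated=bool(meta["truncated"]),
            stimulus_amplitude_au=float(meta.get("stimulus_amplitude_au", 1.0)),
        ))
    return out


def prepare_from_files(beats_dir, schedule_csv, out_dir=None,
                       rest_duration_s: float = 120.0) -> list[AdministrationDataset]:
    """Prepare datasets from an on-disk cohort (beats + schedule).

    Expects the cohort layout written by the synthetic-cohort module:
    ``<subject>/day<d>/beats.csv`` with columns time_s, hr_bpm,
    ppg_amp_au, and a ``schedule.csv`` with columns subject, day,
    onset_s, group, amplitude_au.
    """
    beats_dir = Path(beats_dir)
    sched = pd.read_csv(schedule_csv)
    datasets = []
    for (subject, day), rows in sched.groupby(["subject", "day"], sort=True):
        beats = pd.read_csv(beats_dir / str(subject) / f"day{day}" / "beats.csv")
        hr = BeatSeries(beats["time_s"].to_numpy(),
                        beats["hr_bpm"].to_numpy(), "hr")
        ppg = BeatSeries(beats["time_s"].to_numpy(),
                         beats["ppg_amp_au"].to_numpy(), "ppg_amp")
        day_sets = prepare_day(
            hr, ppg, rows["onset_s"].tolist(),
            rest_duration_s=rest_duration_s,
            subject=str(subject), day=int(day), group=rows["group"].iloc[0])
        # administration indices continue across days
        datasets.extend(day_sets)
    # renumber administrations chronologically per subject/biomarker
    for subject in {d.subject for d in datasets}:
        for biomarker in ("hr", "ppg_amp"):
            subs = [d for d in datasets
                    if d.subject == subject and d.biomarker == biomarker]
            subs.sort(key=lambda d: (d.day, d.output.start_time_s))
            for i, d in enumerate(subs):
                d.administration = i
    if out_dir is not None:
        write_datasets(datasets, out_dir)
    return datasets
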