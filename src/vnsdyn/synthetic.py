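"""Synthetic cohort generation with known ground-truth dynamics.

Every stage of the analysis can be verified against this module: it
produces per-subject linear time-invariant response systems with dead
time (active subjects: heart rate responds downward, PPG amplitude
upward; sham subjects: zero-gain null responders), simulates normalized
biomarker series at 1 Hz with innovations noise, derives beat-by-beat
series whose sampling nonuniformity is driven by the heart rate itself,
and optionally renders template-based raw ECG/PPG waveforms for the
feature-extraction stage.

The default cohort replicates the usual trial structure for this kind
of protocol: 24 subjects, 12 per group, four administrations each (two
on day 1, one on each of days 2 and 3), i.e. 96 administrations and 192
input/output datasets across the two biomarkers.  Per-subject response
gains, time constants and noise levels are not observable quantities in
such trials; the defaults here are realistic stand-ins chosen once
(flagged in the config) with the established response directions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .containers import AdministrationDataset, BeatSeries, UniformSeries, Waveform
from .series_prep import build_input_waveform, parse_administrations
from .statespace import StateSpaceParams, shift_input

__all__ = [
    "GroundTruthSystem",
    "SubjectSpec",
    "SyntheticRecording",
    "CohortConfig",
    "Cohort",
    "make_ground_truth",
    "simulate_biomarker_series",
    "generate_beat_sequence",
    "synthesize_waveforms",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class GroundTruthSystem:
    """Known LTI responder: the generating analogue of the fitted model."""

    order: int
    state_matrix: np.ndarray
    input_vector: np.ndarray
    output_vector: np.ndarray
    innovation_gain: np.ndarray
    dead_time_s: int
    noise_sd: float

    def __post_init__(self):
        self.state_matrix = np.atleast_2d(np.asarray(self.state_matrix, float))
        self.input_vector = np.asarray(self.input_vector, float).reshape(-1, 1)
        self.output_vector = np.asarray(self.output_vector, float).reshape(1, -1)
        self.innovation_gain = np.asarray(self.innovation_gain, float).reshape(-1, 1)
        if not (0 <= self.dead_time_s <= 35):
            raise ValueError("dead time must lie in [0, 35] s")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if np.max(np.abs(np.linalg.eigvals(self.state_matrix))) >= 1.0:
            raise ValueError("ground-truth state matrix must be Schur-stable")

    def as_params(self) -> StateSpaceParams:
        return StateSpaceParams(self.state_matrix, self.input_vector,
                                self.output_vector, self.innovation_gain,
                                dead_time=self.dead_time_s)

    def dc_gain(self) -> float:
        return self.as_params().dc_gain()

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("state_matrix", "input_vector", "output_vector",
                  "innovation_gain"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class SubjectSpec:
    """Cohort-structure description of one synthetic subject."""

    subject_id: str
    group: str  # "active" | "sham"
    rest_hr_bpm: float
    rest_ppg_amp_au: float
    per_day_rest_scale: tuple  # one multiplicative factor per day
    administration_onsets_s: tuple  # ((day, onset_s), ...) - 4 entries
    stimulus_amplitude_au: tuple  # device amplitude per administration

    def __post_init__(self):
        if len(self.administration_onsets_s) != 4:
            raise ValueError("exactly 4 administrations per subject")
        days = [d for d, _ in self.administration_onsets_s]
        if days.count(1) != 2:
            raise ValueError("day 1 must carry 2 administrations")
        if self.rest_hr_bpm <= 0 or self.rest_ppg_amp_au <= 0:
            raise ValueError("rest values must be positive")


@dataclass
class SyntheticRecording:
    """One subject-day of generated data (beats, optional raw waveforms)."""

    subject_id: str
    day: int
    beat_times_s: np.ndarray
    hr_beats: BeatSeries
    ppg_amp_beats: BeatSeries
    normalized_1hz: dict  # biomarker -> UniformSeries (ground-truth path)
    raw_ecg: Waveform | None = None
    raw_ppg: Waveform | None = None


# ---------------------------------------------------------------------------
# ground-truth systems


def make_ground_truth(order: int, dead_time_s: int, dc_gain: float,
                      dominant_time_constant_s: float, noise_sd: float = 0.0,
                      seed: int = 0, innovation_scale: float = 0.1,
                      ) -> GroundTruthSystem:
    """Build a Schur-stable responder with prescribed slow dynamics.

    The dominant pole is exp(-1 / dominant_time_constant_s) at 1 Hz;
    additional poles (order > 1) are faster by successive factors of 3.
    The input vector is scaled so the unit-step steady-state output
    equals ``dc_gain`` exactly (zero gain gives an all-zero input vector:
    a null responder).  The innovation gain distributes a modest
    fraction of the innovation into the state so that noisy outputs show
    serial correlation.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if dominant_time_constant_s <= 0:
        raise ValueError("time constant must be positive")
    rng = np.random.default_rng(seed)
    taus = dominant_time_constant_s / (3.0 ** np.arange(order))
    # mild seeded variation of the non-dominant time constants
    if order > 1:
        taus[1:] *= 1.0 + 0.2 * rng.uniform(-1, 1, size=order - 1)
    poles = np.exp(-1.0 / taus)
    A = np.diag(poles)
    C = np.ones((1, order))
    # equal per-mode DC contributions summing to dc_gain
    B = ((1.0 - poles) * dc_gain / order).reshape(-1, 1)
    K = (innovation_scale * (1.0 - poles)).reshape(-1, 1)
    return GroundTruthSystem(order, A, B, C, K, int(dead_time_s),
                             float(noise_sd))


def simulate_biomarker_series(system: GroundTruthSystem, input_series,
                              duration_s: int | None = None,
                              seed: int = 0) -> UniformSeries:
    """Simulate the normalized biomarker output at 1 Hz with innovations.

    y = (noise-free state-space response to the dead-time-shifted input)
    + innovations e ~ N(0, noise_sd^2) propagated through the innovation
    gain K.  Deterministic for a fixed seed.
    """
    if isinstance(input_series, UniformSeries):
        u = input_series.values
        start = input_series.start_time_s
    else:
        u = np.asarray(input_series, dtype=float)
        start = 0.0
    if duration_s is None:
        duration_s = len(u)
    if duration_s < len(u):
        raise ValueError("duration must cover the input length")
    u = np.concatenate([u, np.zeros(duration_s - len(u))])
    A, B, C, K = (system.state_matrix, system.input_vector,
                  system.output_vector, system.innovation_gain)
    den = np.poly(A)
    num_u = _signal.ss2tf(A, B, C, np.zeros((1, 1)))[0].ravel()
    y = _signal.lfilter(num_u, den, shift_input(u, system.dead_time_s))
    if system.noise_sd > 0:
        rng = np.random.default_rng(seed)
        e = rng.normal(0.0, system.noise_sd, size=duration_s)
        num_k = _signal.ss2tf(A, K, C, np.zeros((1, 1)))[0].ravel()
        y = y + e + _signal.lfilter(num_k, den, e)
    return UniformSeries(values=y, start_time_s=start, fs=1.0)


# ---------------------------------------------------------------------------
# beats and waveforms


def generate_beat_sequence(hr_series: UniformSeries | np.ndarray, seed: int = 0,
                           jitter_sd_s: float = 0.0) -> np.ndarray:
    """Generate beat times whose intervals follow the heart-rate series.

    Each interval equals 60 / HR evaluated (by linear interpolation) at
    the previous beat time, plus optional Gaussian jitter.  Beat times
    are strictly increasing and span the series duration.
    """
    if isinstance(hr_series, UniformSeries):
        hr = hr_series.values
        t0 = hr_series.start_time_s
        fs = hr_series.fs
    else:
        hr = np.asarray(hr_series, dtype=float)
        t0, fs = 0.0, 1.0
    if np.any(hr < 30) or np.any(hr > 220):
        raise ValueError("heart rate outside the physiological range "
                         "[30, 220] bpm")
    grid = t0 + np.arange(len(hr)) / fs
    duration = grid[-1]
    rng = np.random.default_rng(seed)
    times = [t0]
    t = t0
    while True:
        interval = 60.0 / np.interp(t, grid, hr)
        if jitter_sd_s > 0:
            interval = max(60.0 / 220.0, interval + rng.normal(0, jitter_sd_s))
        t = t + interval
        if t > duration + 1e-9:
            break
        times.append(t)
    return np.array(times)


_ECG_SIGMA_S = 0.012   # Gaussian QRS width
_ECG_HALF_WIDTH_S = 0.05


def synthesize_waveforms(beat_times_s, ppg_amplitudes, fs: float = 2000.0,
                         seed: int = 0, noise_sd: float = 0.0,
                         duration_s: float | None = None,
                         ) -> tuple[Waveform, Waveform]:
    """Render template-based raw ECG and PPG waveforms.

    ECG: unit-amplitude Gaussian QRS complexes centered at the beat
    times.  PPG: one asymmetric (fast-rise, slow-fall) pulse per beat,
    scaled so the within-beat max - min equals the requested amplitude.
    Optional band-limited additive noise on both channels.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    ppg_amplitudes = np.asarray(ppg_amplitudes, dtype=float)
    if fs < 100:
        raise ValueError("waveform synthesis needs fs >= 100 Hz")
    if len(beat_times_s) < 2:
        raise ValueError("need at least 2 beats")
    if np.any(np.diff(beat_times_s) < 2 * _ECG_HALF_WIDTH_S):
        raise ValueError("beat interval shorter than the QRS template width")
    if duration_s is None:
        duration_s = beat_times_s[-1] + 1.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    ecg = np.zeros(n)
    half = int(round(_ECG_HALF_WIDTH_S * fs))
    tmpl_t = np.arange(-half, half + 1) / fs
    qrs = np.exp(-0.5 * (tmpl_t / _ECG_SIGMA_S) ** 2)
    qrs -= 0.12 * np.exp(-0.5 * ((tmpl_t - 0.03) / 0.015) ** 2)
    qrs -= 0.10 * np.exp(-0.5 * ((tmpl_t + 0.03) / 0.015) ** 2)
    for bt in beat_times_s:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        s0 = max(0, -lo)
        s1 = len(tmpl_t) - max(0, hi - n)
        ecg[max(0, lo):min(n, hi)] += qrs[s0:s1]

    ppg = np.zeros(n)
    n_amp = len(ppg_amplitudes)
    # asymmetric (fast-rise, slow-fall) smooth pulse; the phase warp puts
    # the systolic peak at ~35% of the beat while keeping the harmonic
    # content inside the downstream 0.4-8 Hz PPG passband
    warp = 0.65
    for b in range(len(beat_times_s) - 1):
        lo = int(np.ceil(beat_times_s[b] * fs))
        hi = min(n, int(np.ceil(beat_times_s[b + 1] * fs)))
        if hi <= lo:
            continue
        phase = (t[lo:hi] - beat_times_s[b]) / (beat_times_s[b + 1]
                                                - beat_times_s[b])
        pulse = np.sin(np.pi * phase ** warp) ** 2
        amp = ppg_amplitudes[min(b, n_amp - 1)]
        ppg[lo:hi] = amp * pulse / (pulse.max() - pulse.min())

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        kern = _signal.windows.gaussian(int(0.02 * fs) | 1, 0.004 * fs)
        kern /= kern.sum()
        for w in (ecg, ppg):
            raw = rng.normal(0.0, 1.0, size=n)
            band = _signal.fftconvolve(raw, kern, mode="same")
            w += noise_sd * band / band.std()

    return (Waveform(ecg, fs, "ecg"), Waveform(ppg, fs, "ppg"))


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortConfig:
    """Generator settings.

    Response gains, time constants, dead times and noise levels are
    plausible stand-ins (real trials do not expose per-subject ground
    truth); directions follow the established physiology: active heart
    rate responds downward, active PPG amplitude upward, sham responses
    are null.
    """

    hr_gain: float = -0.04            # fraction of rest (active group)
    ppg_gain: float = 0.5             # fraction of rest (active group)
    gain_jitter: float = 0.25         # relative inter-subject spread
    time_constant_range_s: tuple = (10.0, 30.0)
    dead_time_range_s: tuple = (10, 25)   # inclusive, drawn uniformly
    order_choices: tuple = (1, 2)
    hr_noise_sd: float = 0.01         # normalized units
    ppg_noise_sd: float = 0.05
    rest_hr_range_bpm: tuple = (60.0, 80.0)
    rest_ppg_range_au: tuple = (0.8, 2.0)
    day_scale_sd: float = 0.02
    beat_jitter_sd_s: float = 0.0     # off by default: analytic fixtures exact
    day1_onsets_s: tuple = (180.0, 540.0)
    late_day_onset_s: float = 180.0
    rest_duration_s: float = 120.0
    tail_s: float = 20.0
    include_waveforms: bool = False
    waveform_fs: float = 2000.0
    waveform_noise_sd: float = 0.02


@dataclass
class Cohort:
    subjects: list
    truths: dict          # subject_id -> {"hr": GroundTruthSystem, "ppg_amp": ...}
    recordings: dict      # (subject_id, day) -> SyntheticRecording
    datasets: list        # ground-truth-path AdministrationDatasets
    config: CohortConfig
    seed: int

    @property
    def n_administrations(self) -> int:
        return sum(len(s.administration_onsets_s) for s in self.subjects)

    def subject_datasets(self, subject_id: str, biomarker: str):
        return [d for d in self.datasets
                if d.subject == subject_id and d.biomarker == biomarker]


def _day_onsets(cfg: CohortConfig):
    return {1: list(cfg.day1_onsets_s), 2: [cfg.late_day_onset_s],
            3: [cfg.late_day_onset_s]}


def _day_duration(onsets, cfg: CohortConfig) -> int:
    return int(max(onsets) + 240 + cfg.tail_s)


def generate_cohort(n_subjects: int = 24, n_active: int = 12, seed: int = 0,
                    config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort.

    The first ``n_active`` subjects form the active group (nonzero-gain
    responders: heart rate down, PPG amplitude up); the remainder are
    sham null responders.  Each subject receives 4 administrations (2 on
    day 1, 1 on each of days 2 and 3); one input/output dataset is
    enumerated per subject x administration x biomarker.
    """
    if n_active > n_subjects:
        raise ValueError("n_active cannot exceed n_subjects")
    cfg = config or CohortConfig()
    onsets_by_day = _day_onsets(cfg)
    for day, onsets in onsets_by_day.items():
        onsets = sorted(onsets)
        for a, b in zip(onsets, onsets[1:]):
            if b - a < 300:
                raise ValueError(
                    f"administration windows overlap on day {day}")
    rng = np.random.default_rng(seed)

    subjects, truths, recordings, datasets = [], {}, {}, []
    for s_idx in range(n_subjects):
        group = "active" if s_idx < n_active else "sham"
        sid = f"S{s_idx + 1:02d}"
        rest_hr = rng.uniform(*cfg.rest_hr_range_bpm)
        rest_ppg = rng.uniform(*cfg.rest_ppg_range_au)
        day_scales = tuple(1.0 + rng.normal(0, cfg.day_scale_sd, 3))
        adm_onsets = tuple((day, onset) for day in (1, 2, 3)
                           for onset in onsets_by_day[day])
        if group == "active":
            amps = tuple(np.clip(rng.normal(3.0, 0.8, 4), 0.5, 5.0))
        else:
            amps = tuple(np.clip(rng.normal(4.4, 1.2, 4), 0.5, 5.0))
        spec = SubjectSpec(sid, group, rest_hr, rest_ppg, day_scales,
                           adm_onsets, amps)
        subjects.append(spec)

        subj_truth = {}
        for biomarker, gain, noise_sd in (
                ("hr", cfg.hr_gain, cfg.hr_noise_sd),
                ("ppg_amp", cfg.ppg_gain, cfg.ppg_noise_sd)):
            if group == "active":
                g = gain * (1.0 + cfg.gain_jitter * rng.uniform(-1, 1))
            else:
                g = 0.0
            order = int(rng.choice(cfg.order_choices))
            tau = int(rng.integers(cfg.dead_time_range_s[0],
                                   cfg.dead_time_range_s[1] + 1))
            tc = rng.uniform(*cfg.time_constant_range_s)
            subj_truth[biomarker] = make_ground_truth(
                order, tau, g, tc, noise_sd,
                seed=int(rng.integers(2 ** 31)))
        truths[sid] = subj_truth

        adm_counter = {"hr": 0, "ppg_amp": 0}
        for day in (1, 2, 3):
            onsets = onsets_by_day[day]
            dur = _day_duration(onsets, cfg)
            u = np.zeros(dur)
            for onset in onsets:
                u += build_input_waveform(dur, int(onset)).values
            norm = {}
            for biomarker in ("hr", "ppg_amp"):
                series = simulate_biomarker_series(
                    subj_truth[biomarker], u, dur,
                    seed=int(rng.integers(2 ** 31)))
                norm[biomarker] = series
                day_sets = parse_administrations(
                    series, onsets, subject=sid, day=day, group=group,
                    biomarker=biomarker)
                for d in day_sets:
                    d.administration = adm_counter[biomarker]
                    d.stimulus_amplitude_au = amps[adm_counter[biomarker]]
                    adm_counter[biomarker] += 1
                datasets.extend(day_sets)

            # absolute-unit series and beats for the extraction path
            scale = day_scales[day - 1]
            hr_abs = np.clip(rest_hr * scale * (1.0 + norm["hr"].values),
                             35.0, 210.0)
            amp_abs = np.clip(
                rest_ppg * scale * (1.0 + norm["ppg_amp"].values),
                0.05 * rest_ppg, None)
            beat_times = generate_beat_sequence(
                UniformSeries(hr_abs), seed=int(rng.integers(2 ** 31)),
                jitter_sd_s=cfg.beat_jitter_sd_s)
            rr = np.diff(beat_times)
            hr_beats = BeatSeries(beat_times[1:], 60.0 / rr, "hr")
            t_grid = np.arange(dur)
            amp_at_beats = np.interp(beat_times[:-1], t_grid, amp_abs)
            ppg_beats = BeatSeries(beat_times[:-1], amp_at_beats, "ppg_amp")

            raw_ecg = raw_ppg = None
            if cfg.include_waveforms:
                raw_ecg, raw_ppg = synthesize_waveforms(
                    beat_times, amp_at_beats, fs=cfg.waveform_fs,
                    seed=int(rng.integers(2 ** 31)),
                    noise_sd=cfg.waveform_noise_sd, duration_s=dur)
            recordings[(sid, day)] = SyntheticRecording(
                sid, day, beat_times, hr_beats, ppg_beats, norm,
                raw_ecg, raw_ppg)

    return Cohort(subjects, truths, recordings, datasets, cfg, seed)


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: Cohort, out_dir, include_raw: bool = False) -> None:
    """Write the cohort as delimited text plus a ground-truth JSON.

    Layout: ``<subject>/day<d>/beats.csv`` (time_s, hr_bpm, ppg_amp_au),
    optional ``raw.csv`` (time_s, ecg, ppg), a cohort-level
    ``schedule.csv`` (subject, day, onset_s, group, amplitude_au) and
    ``truth.json`` with the generating systems for recovery scoring.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in cohort.subjects:
        for adm, (day, onset) in enumerate(spec.administration_onsets_s):
            rows.append({
                "subject": spec.subject_id, "day": day, "onset_s": onset,
                "group": spec.group,
                "amplitude_au": spec.stimulus_amplitude_au[adm],
            })
    pd.DataFrame(rows).to_csv(out / "schedule.csv", index=False)

    for (sid, day), rec in cohort.recordings.items():
        ddir = out / sid / f"day{day}"
        ddir.mkdir(parents=True, exist_ok=True)
        # beats.csv merges HR (anchored at the later beat) and PPG
        # amplitude (anchored at beat start) on the beat index
        n = len(rec.hr_beats)
        pd.DataFrame({
            "time_s": rec.hr_beats.times_s,
            "hr_bpm": rec.hr_beats.values,
            "ppg_amp_au": rec.ppg_amp_beats.values[:n],
        }).to_csv(ddir / "beats.csv", index=False)
        if include_raw and rec.raw_ecg is not None:
            pd.DataFrame({
                "time_s": rec.raw_ecg.times_s,
                "ecg": rec.raw_ecg.samples,
                "ppg": rec.raw_ppg.samples,
            }).to_csv(ddir / "raw.csv", index=False)

    truth = {
        sid: {bm: sys.to_dict() for bm, sys in systems.items()}
        for sid, systems in cohort.truths.items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
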