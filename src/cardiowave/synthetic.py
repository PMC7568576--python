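"""Synthetic SCG/GCG cohort generator.

Produces labeled six-axis inertial recordings (three seismocardiogram
accelerometer axes, three gyrocardiogram gyroscope axes) with the
statistical structure the downstream pipeline assumes:

* a quasi-periodic beat train of Gaussian-windowed sinusoids repeated at
  the subject's heart rate, with all oscillation centers below 25 Hz;
* a class-dependent "murmur" component — band-limited noise gated by the
  beat envelope — whose band sits below 10 Hz for the aortic-stenosis
  (AS) family and whose gain is zero for non-AS subjects;
* subject-level random effects (heart rate, per-channel gain, murmur
  gain) so that subject-wise validation is strictly harder than
  segment-wise validation;
* broadband white sensor noise; and
* sporadic high-amplitude motion-artifact bursts (Poisson placed) that
  the RMS-median segmentation stage must reject.

The beat model is deliberately non-physiological: it is a sum of
windowed tones, not a template of cardiac mechanics.  It reproduces the
spectral and amplitude structure the pipeline's filtering, segmentation
and time-frequency stages rely on, nothing more.  Signal units are
arbitrary (no sensor amplitude scale is modeled).

The module also provides direct feature-table and scalogram-image
fixtures with planted ground truth, used to exercise the feature
selection and classification layers in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import InvalidArgumentError, InvalidLabelError

#: Canonical channel order: accelerometer (SCG) then gyroscope (GCG) axes.
CHANNELS: tuple[str, ...] = ("SCG_X", "SCG_Y", "SCG_Z", "GCG_X", "GCG_Y", "GCG_Z")

#: Recognised class labels.  AS = aortic stenosis; the suffixed labels are
#: AS with a co-existing valvular disease (mitral insufficiency, mitral
#: stenosis, tricuspid regurgitation).
CLASS_LABELS: tuple[str, ...] = ("AS", "NON_AS", "AS_MI", "AS_MS", "AS_TR")
AS_FAMILY: tuple[str, ...] = ("AS", "AS_MI", "AS_MS", "AS_TR")

# Murmur band shared by the AS family (below 10 Hz, where the
# discriminative energy of stenotic vibration concentrates).
_PRIMARY_BAND = (3.0, 9.0)
# Distinct secondary bands make the four AS sub-classes separable.
_SECONDARY_BANDS = {"AS_MI": (10.0, 14.0), "AS_MS": (14.0, 18.0), "AS_TR": (18.0, 23.0)}

# Relative channel gains; the dorso-ventral accelerometer axis (SCG_Z)
# and the head-to-toe gyroscope axis (GCG_Y) carry the strongest cardiac
# vibration, mirroring which axes dominate in practice.
_CHANNEL_GAIN = np.array([0.8, 0.8, 1.3, 0.9, 1.5, 0.9])

_DEFAULT_FS_HZ = 256.0


@dataclasses.dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters; ``seed`` fixes the realization."""

    subject_id: str
    class_label: str
    heart_rate_bpm: float
    beat_amplitude: tuple[float, ...]          # one gain per channel
    base_freqs_hz: tuple[float, ...]           # beat oscillation centers, < 25 Hz
    class_effect_band_hz: tuple[float, float]  # murmur band
    class_effect_gain: float                   # 0 for NON_AS
    secondary_band_hz: tuple[float, float] | None
    secondary_gain: float
    murmur_floor: float            # 0 = fully beat-gated murmur, 1 = continuous
    noise_sd: float
    artifact_rate_per_min: float
    seed: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidLabelError(f"unknown class label {self.class_label!r}")
        if len(self.beat_amplitude) != len(CHANNELS):
            raise InvalidArgumentError("beat_amplitude must have one entry per channel")
        if any(a < 0 for a in self.beat_amplitude):
            raise InvalidArgumentError("beat amplitudes must be non-negative")
        if not 40.0 <= self.heart_rate_bpm <= 120.0:
            raise InvalidArgumentError("heart rate outside 40-120 bpm")
        freqs = list(self.base_freqs_hz) + list(self.class_effect_band_hz)
        if self.secondary_band_hz is not None:
            freqs += list(self.secondary_band_hz)
        if any(not 0.0 < f <= 25.0 for f in freqs):
            raise InvalidArgumentError("all frequencies must lie in (0, 25] Hz")
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be positive")
        if self.class_effect_gain < 0 or self.secondary_gain < 0:
            raise InvalidArgumentError("effect gains must be non-negative")
        if self.artifact_rate_per_min < 0:
            raise InvalidArgumentError("artifact rate must be non-negative")
        if not 0.0 <= self.murmur_floor <= 1.0:
            raise InvalidArgumentError("murmur_floor must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class RecordingSession:
    """One subject's six-channel recording.

    ``samples`` is a (6, N) array in canonical channel order with
    N = round(fs_hz * duration_s).  ``artifact_intervals`` records the
    (start_s, end_s) span of every injected motion burst — ground truth
    for segmentation tests, not something a real sensor would provide.
    """

    subject_id: str
    fs_hz: float
    duration_s: float
    channels: tuple[str, ...]
    samples: np.ndarray
    class_label: str
    artifact_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.channels != CHANNELS:
            raise InvalidArgumentError("channels must be the canonical six, in order")
        n_expected = int(round(self.fs_hz * self.duration_s))
        if self.samples.shape != (len(CHANNELS), n_expected):
            raise InvalidArgumentError(
                f"samples shape {self.samples.shape} != (6, {n_expected})"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, channel: str) -> int:
        from .exceptions import InvalidChannelError

        if channel not in CHANNELS:
            raise InvalidChannelError(f"unknown channel {channel!r}")
        return CHANNELS.index(channel)


def _subject_seed(seed: int, index: int) -> int:
    """A stable 31-bit child seed for subject ``index`` of cohort ``seed``."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_subject(
    class_label: str,
    seed: int,
    *,
    subject_id: str | None = None,
    effect_scale: float = 1.0,
    noise_scale: float = 1.0,
    artifact_rate_per_min: float | None = None,
    murmur_continuity: float = 0.7,
) -> SubjectProfile:
    """Draw one subject's generative parameters.

    Deterministic in ``(class_label, seed)``.  ``effect_scale`` and
    ``noise_scale`` rescale the class-effect gain and sensor-noise level
    relative to the defaults (useful for difficulty sweeps); the class
    contract — zero effect gain for NON_AS, positive for the AS family,
    murmur band inside (0, 10] Hz — is unaffected.
    """
    if class_label not in CLASS_LABELS:
        raise InvalidLabelError(f"unknown class label {class_label!r}")
    if seed < 0:
        raise InvalidArgumentError("seed must be non-negative")
    rng = np.random.default_rng([int(seed), CLASS_LABELS.index(class_label)])

    heart_rate = rng.uniform(50.0, 95.0)
    beat_amplitude = tuple(_CHANNEL_GAIN * rng.uniform(0.7, 1.3, size=len(CHANNELS)))
    base_freqs = (rng.uniform(7.0, 10.0), rng.uniform(12.0, 16.0), rng.uniform(18.0, 23.0))

    if class_label in AS_FAMILY:
        gain = 0.25 * rng.uniform(0.75, 1.25) * effect_scale
    else:
        gain = 0.0
    secondary = _SECONDARY_BANDS.get(class_label)
    sec_gain = 0.20 * rng.uniform(0.75, 1.25) * effect_scale if secondary else 0.0

    noise_sd = rng.uniform(0.30, 0.40) * noise_scale
    rate = rng.uniform(1.0, 3.0) if artifact_rate_per_min is None else float(artifact_rate_per_min)

    return SubjectProfile(
        subject_id=subject_id or f"{class_label}_{seed:06d}",
        class_label=class_label,
        heart_rate_bpm=heart_rate,
        beat_amplitude=beat_amplitude,
        base_freqs_hz=base_freqs,
        class_effect_band_hz=_PRIMARY_BAND,
        class_effect_gain=gain,
        secondary_band_hz=secondary,
        secondary_gain=sec_gain,
        murmur_floor=float(murmur_continuity),
        noise_sd=noise_sd,
        artifact_rate_per_min=rate,
        seed=int(seed),
    )


def _beat_envelope(t: np.ndarray, beat_times: np.ndarray, sigma_s: float) -> np.ndarray:
    """Sum of unit Gaussian windows centered on each beat time."""
    env = np.zeros_like(t)
    half = 4.0 * sigma_s
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    for tk in beat_times:
        lo = max(0, int((tk - half) * fs))
        hi = min(len(t), int((tk + half) * fs) + 1)
        if lo < hi:
            env[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tk) / sigma_s) ** 2)
    return env


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS white noise band-passed to ``band``."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(
    profile: SubjectProfile,
    duration_s: float = 300.0,
    fs_hz: float = _DEFAULT_FS_HZ,
) -> RecordingSession:
    """Synthesize the six-channel recording realized by ``profile``.

    Each channel is ``beat_amplitude[ch] * (beat train + murmur
    components) + white noise``; motion-artifact bursts (>= 10x the beat
    amplitude, 0.5-2 s long) are added at Poisson-distributed times and
    hit all channels simultaneously, as torso motion does.
    """
    if duration_s < 20.0:
        raise InvalidArgumentError("duration must be at least 20 s")
    if fs_hz < 64.0:
        raise InvalidArgumentError("sampling rate must be at least 64 Hz")

    rng = np.random.default_rng([profile.seed, 1])
    n = int(round(fs_hz * duration_s))
    t = np.arange(n) / fs_hz

    interval = 60.0 / profile.heart_rate_bpm
    n_beats = int(duration_s / interval) + 2
    beat_times = (rng.uniform(0.0, interval)
                  + np.arange(n_beats) * interval
                  + rng.normal(0.0, 0.01 * interval, size=n_beats))
    beat_times = beat_times[(beat_times > 0.2) & (beat_times < duration_s - 0.2)]

    # Shared cardiac waveform: continuous tones at the subject's base
    # frequencies (dominant energy at base_freqs_hz[0]), amplitude-
    # modulated by the beat envelope with a 0.6 floor.  The floor models
    # the continuous chest-wall micro-vibration present between beats;
    # it also keeps the clean-signal RMS envelope stable (max well
    # below 1.5x its median), which is what lets the artifact-rejection
    # threshold work on real-shaped data.
    tone_weights = (1.0, 0.45, 0.2)
    carrier = np.zeros(n)
    for f, w in zip(profile.base_freqs_hz, tone_weights):
        carrier += w * np.sin(2 * np.pi * f * t + rng.uniform(0.0, 2 * np.pi))
    beat_env = np.minimum(_beat_envelope(t, beat_times, sigma_s=0.12), 1.0)
    cardiac = (0.8 + 0.2 * beat_env) * carrier

    # Murmur: band-limited noise gated by a slightly delayed, wider beat
    # envelope (systolic ejection burst).
    murmur = np.zeros(n)
    env = None
    if profile.class_effect_gain > 0 or (
            profile.secondary_band_hz is not None and profile.secondary_gain > 0):
        env = np.minimum(_beat_envelope(t, beat_times + 0.10, sigma_s=0.09), 1.0)
        env = profile.murmur_floor + (1.0 - profile.murmur_floor) * env
    if profile.class_effect_gain > 0:
        murmur += profile.class_effect_gain * env * _band_noise(rng, n, fs_hz, profile.class_effect_band_hz)
    if profile.secondary_band_hz is not None and profile.secondary_gain > 0:
        murmur += profile.secondary_gain * env * _band_noise(rng, n, fs_hz, profile.secondary_band_hz)

    amp = np.asarray(profile.beat_amplitude)
    samples = np.empty((len(CHANNELS), n))
    for c in range(len(CHANNELS)):
        # small per-channel timing skew models sensor-axis projection
        shift = int(rng.integers(0, max(1, int(0.02 * fs_hz))))
        chan_wave = np.roll(cardiac + murmur, shift)
        samples[c] = amp[c] * chan_wave + rng.standard_normal(n) * profile.noise_sd

    # Motion artifacts: Poisson count over the recording.  Onsets and
    # durations snap to the 0.5-s RMS grid so that every envelope cell
    # an artifact touches contains a full-amplitude chunk of it — the
    # rejection oracle (overlapped window => RMS > 1.5x median) then
    # holds exactly by construction, with no marginal edge overlaps.
    intervals: list[tuple[float, float]] = []
    cell = 0.5
    n_cells = int(duration_s / cell)
    n_artifacts = rng.poisson(profile.artifact_rate_per_min * duration_s / 60.0)
    for _ in range(n_artifacts):
        dur_cells = int(rng.integers(1, 5))               # 0.5-2.0 s
        start_cell = int(rng.integers(0, max(n_cells - dur_cells, 1)))
        start, dur = start_cell * cell, dur_cells * cell
        lo, hi = int(start * fs_hz), int((start + dur) * fs_hz)
        for c in range(len(CHANNELS)):
            burst = 12.0 * amp[c] * rng.standard_normal(hi - lo)
            samples[c, lo:hi] += burst
        intervals.append((start, start + dur))

    return RecordingSession(
        subject_id=profile.subject_id,
        fs_hz=float(fs_hz),
        duration_s=float(duration_s),
        channels=CHANNELS,
        samples=samples,
        class_label=profile.class_label,
        artifact_intervals=tuple(sorted(intervals)),
    )


def generate_cohort(
    n_per_class: Mapping[str, int],
    duration_s: float = 300.0,
    fs_hz: float = _DEFAULT_FS_HZ,
    seed: int = 0,
    **profile_kwargs,
) -> list[RecordingSession]:
    """Generate one recording per requested subject, deterministically.

    ``n_per_class`` maps class labels to subject counts (>= 0, at least
    one positive).  Extra keyword arguments are forwarded to
    :func:`generate_subject` for every subject.
    """
    if not n_per_class or sum(n_per_class.values()) == 0:
        raise InvalidArgumentError("request at least one subject")
    for label, count in n_per_class.items():
        if label not in CLASS_LABELS:
            raise InvalidLabelError(f"unknown class label {label!r}")
        if count < 0:
            raise InvalidArgumentError("subject counts must be non-negative")

    sessions: list[RecordingSession] = []
    idx = 0
    for label in CLASS_LABELS:            # canonical order => deterministic ids
        for k in range(n_per_class.get(label, 0)):
            profile = generate_subject(
                label,
                _subject_seed(seed, idx),
                subject_id=f"{label}_{k:02d}",
                **profile_kwargs,
            )
            sessions.append(generate_recording(profile, duration_s, fs_hz))
            idx += 1
    return sessions


# ---------------------------------------------------------------------------
# Plain-text writers


def session_to_frame(session: RecordingSession) -> pd.DataFrame:
    """Per-session CSV layout: time_s plus the six channels, lower-cased."""
    data = {"time_s": np.arange(session.n_samples) / session.fs_hz}
    for i, ch in enumerate(session.channels):
        data[ch.lower()] = session.samples[i]
    return pd.DataFrame(data)


def write_cohort_csv(sessions: Sequence[RecordingSession], out_dir) -> pd.DataFrame:
    """Write one CSV per session plus a cohort metadata CSV; returns metadata."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in sessions:
        session_to_frame(s).to_csv(out / f"{s.subject_id}.csv", index=False)
        meta.append({"subject_id": s.subject_id, "class_label": s.class_label, "fs_hz": s.fs_hz})
    frame = pd.DataFrame(meta)
    frame.to_csv(out / "cohort.csv", index=False)
    return frame


def save_cohort_npz(sessions: Sequence[RecordingSession], path) -> None:
    """Lossless NPZ bundle for a cohort."""
    arrays = {}
    meta = []
    for s in sessions:
        arrays[f"samples_{s.subject_id}"] = s.samples
        arrays[f"artifacts_{s.subject_id}"] = np.asarray(s.artifact_intervals, dtype=float).reshape(-1, 2)
        meta.append((s.subject_id, s.class_label, s.fs_hz, s.duration_s))
    arrays["meta"] = np.asarray(meta, dtype=object)
    np.savez(path, **arrays, allow_pickle=True)


def load_cohort_npz(path) -> list[RecordingSession]:
    with np.load(path, allow_pickle=True) as data:
        sessions = []
        for subject_id, class_label, fs_hz, duration_s in data["meta"]:
            artifacts = data[f"artifacts_{subject_id}"]
            sessions.append(RecordingSession(
                subject_id=str(subject_id),
                fs_hz=float(fs_hz),
                duration_s=float(duration_s),
                channels=CHANNELS,
                samples=data[f"samples_{subject_id}"],
                class_label=str(class_label),
                artifact_intervals=tuple(map(tuple, artifacts.tolist())),
            ))
    return sessions


# ---------------------------------------------------------------------------
# Direct fixtures for the selection / classification layers


def planted_feature_table(
    n_segments: int = 200,
    n_features: int = 200,
    n_informative: int = 10,
    effect_size: float = 2.0,
    seed: int = 0,
    segments_per_subject: int = 1,
):
    """Feature table with a known informative subset.

    Features are unit-variance Gaussian noise; the first
    ``n_informative`` columns are shifted by ``effect_size`` standard
    deviations in the positive (AS) class.  Returns ``(table,
    planted_names)`` where the table's labels alternate AS / NON_AS.
    """
    from .feature_select import FeatureTable

    rng = np.random.default_rng(seed)
    y = np.arange(n_segments) % 2            # 1 = AS, 0 = NON_AS
    X = rng.standard_normal((n_segments, n_features))
    X[y == 1, :n_informative] += effect_size
    names = [f"F{j:04d}" for j in range(n_features)]
    labels = ["AS" if v else "NON_AS" for v in y]
    subjects = [f"S{i // segments_per_subject:04d}" for i in range(n_segments)]
    table = FeatureTable(matrix=X, feature_names=names, subject_ids=subjects, labels=labels)
    return table, names[:n_informative]


def subject_effect_table(
    n_subjects_per_class: int = 10,
    segments_per_subject: int = 8,
    n_features: int = 60,
    n_informative: int = 8,
    effect_size: float = 1.5,
    subject_sd: float = 1.0,
    seed: int = 0,
):
    """Two-class feature table with subject-level random intercepts.

    Every subject draws a Gaussian offset (sd ``subject_sd``) added to
    all of their segments' informative features, so segment-wise splits
    leak subject identity while subject-wise splits do not — the
    structure that makes leave-one-subject-out the harder scheme.
    """
    from .feature_select import FeatureTable

    rng = np.random.default_rng(seed)
    rows, labels, subjects = [], [], []
    for label, cls in (("AS", 1), ("NON_AS", 0)):
        for s in range(n_subjects_per_class):
            offset = rng.normal(0.0, subject_sd, size=n_informative)
            for _ in range(segments_per_subject):
                x = rng.standard_normal(n_features)
                x[:n_informative] += cls * effect_size + offset
                rows.append(x)
                labels.append(label)
                subjects.append(f"{label}_{s:02d}")
    names = [f"F{j:04d}" for j in range(n_features)]
    return FeatureTable(
        matrix=np.asarray(rows), feature_names=names,
        subject_ids=subjects, labels=labels,
    )


def generate_scalogram_images(
    n_per_class: int = 80,
    shape: tuple[int, int] = (60, 80),
    band_rows: tuple[tuple[int, int], tuple[int, int]] | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
):
    """Separable synthetic scalogram images for CNN smoke training.

    Each class activates a disjoint frequency-row band with beat-like
    Gaussian bursts along the time axis, on top of white noise; images
    are min-max normalized to [0, 1].  Returns ``(images, labels)`` with
    images of shape (N, H, W, 1) and binary labels.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if band_rows is None:       # disjoint bands scaled to the image height
        band_rows = ((int(0.13 * h), int(0.30 * h)),
                     (int(0.60 * h), int(0.77 * h)))
    images = np.empty((2 * n_per_class, h, w, 1), dtype=np.float64)
    labels = np.empty(2 * n_per_class, dtype=np.int64)
    cols = np.arange(w)
    order = rng.permutation(2 * n_per_class)
    for i, k in enumerate(order):
        cls = 0 if i < n_per_class else 1
        lo, hi = band_rows[cls]
        img = rng.standard_normal((h, w)) * noise_sd
        n_bursts = rng.integers(6, 10)
        centers = rng.uniform(0, w, size=n_bursts)
        width = rng.uniform(2.0, 4.0)
        burst = np.exp(-0.5 * ((cols[None, :] - centers[:, None]) / width) ** 2).sum(axis=0)
        rows = np.zeros(h)
        rows[lo:hi] = np.hanning(hi - lo)
        img += 1.5 * rows[:, None] * burst[None, :]
        img -= img.min()
        peak = img.max()
        if peak > 0:
            img /= peak
        images[k, :, :, 0] = img
        labels[k] = cls
    return images, labels
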