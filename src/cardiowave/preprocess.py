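"""Band-pass filtering and RMS-median segmentation.

Raw inertial channels are band-passed to 0.8-25 Hz (4th-order
Butterworth, applied forward-backward for zero phase), then tiled into
non-overlapping 10-s candidate windows starting at t = 0.  A window is
kept only if every 0.5-s RMS-envelope value inside it stays at or below
1.5x the median envelope of the whole recording — a single motion burst
disqualifies the window.  The envelope uses non-overlapping 0.5-s
windows (window = step), so its length is deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidArgumentError, InvalidChannelError, NyquistViolationError
from .synthetic import CHANNELS, RecordingSession

DEFAULT_BAND_HZ = (0.8, 25.0)
DEFAULT_SEGMENT_S = 10.0
DEFAULT_RMS_STEP_S = 0.5
DEFAULT_THRESHOLD = 1.5
_FILTER_ORDER = 4


@dataclasses.dataclass(frozen=True)
class Segment:
    """A fixed-length low-noise excerpt of one filtered channel."""

    subject_id: str
    channel: str
    start_s: float
    fs_hz: float
    samples: np.ndarray
    class_label: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InvalidChannelError(f"unknown channel {self.channel!r}")
        if self.start_s < 0:
            raise InvalidArgumentError("start_s must be non-negative")


@dataclasses.dataclass(frozen=True)
class RmsEnvelope:
    values: np.ndarray          # one value per non-overlapping window, all >= 0
    step_s: float
    window_s: float


def design_bandpass(fs_hz: float, band_hz: tuple[float, float] = DEFAULT_BAND_HZ) -> np.ndarray:
    """Second-order sections of the 0.8-25 Hz Butterworth band-pass."""
    low, high = band_hz
    if fs_hz <= 2.0 * high:
        raise NyquistViolationError(
            f"fs={fs_hz} Hz cannot represent a {high} Hz pass-band edge"
        )
    return sps.butter(_FILTER_ORDER, (low, high), btype="bandpass", fs=fs_hz, output="sos")


def bandpass(
    samples: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> np.ndarray:
    """Zero-phase band-pass; same length as the input."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("expected a 1-D sample vector")
    sos = design_bandpass(fs_hz, band_hz)
    # forward-backward padding needs a few filter lengths of signal
    if x.size < 3 * (2 * _FILTER_ORDER + 1):
        raise InvalidArgumentError("input too short for zero-phase filtering")
    return sps.sosfiltfilt(sos, x)


def rms_envelope(samples: np.ndarray, fs_hz: float, step_s: float = DEFAULT_RMS_STEP_S) -> RmsEnvelope:
    """RMS over consecutive non-overlapping windows; trailing partial dropped."""
    x = np.asarray(samples, dtype=float)
    if step_s <= 0:
        raise InvalidArgumentError("step_s must be positive")
    win = int(round(step_s * fs_hz))
    if x.size < win or win == 0:
        raise InvalidArgumentError("input shorter than one RMS window")
    n_win = x.size // win
    blocks = x[: n_win * win].reshape(n_win, win)
    values = np.sqrt(np.mean(blocks**2, axis=1))
    return RmsEnvelope(values=values, step_s=step_s, window_s=step_s)


def accept_mask(
    envelope: RmsEnvelope,
    segment_s: float = DEFAULT_SEGMENT_S,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Boolean acceptance per candidate window from an envelope.

    Candidate k covers envelope indices [k*m, (k+1)*m) with
    m = segment_s / step_s; it is accepted iff the maximum envelope
    value inside stays <= threshold x the recording-level median.
    """
    m = int(round(segment_s / envelope.step_s))
    n_cand = envelope.values.size // m
    if n_cand == 0:
        return np.zeros(0, dtype=bool)
    cutoff = threshold * float(np.median(envelope.values))
    peaks = envelope.values[: n_cand * m].reshape(n_cand, m).max(axis=1)
    return peaks <= cutoff


def segment_recording(
    session: RecordingSession,
    channel: str,
    *,
    segment_s: float = DEFAULT_SEGMENT_S,
    threshold: float = DEFAULT_THRESHOLD,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    step_s: float = DEFAULT_RMS_STEP_S,
) -> list[Segment]:
    """Filter one channel and return its accepted 10-s segments in time order.

    Recordings shorter than one segment yield an empty list.  The RMS
    median is computed per channel over the full filtered recording.
    """
    idx = session.channel_index(channel)
    if session.duration_s < segment_s:
        return []
    filtered = bandpass(session.samples[idx], session.fs_hz, band_hz)
    env = rms_envelope(filtered, session.fs_hz, step_s)
    mask = accept_mask(env, segment_s, threshold)
    seg_len = int(round(segment_s * session.fs_hz))
    segments = []
    for k in np.flatnonzero(mask):
        start = k * seg_len
        segments.append(Segment(
            subject_id=session.subject_id,
            channel=channel,
            start_s=k * segment_s,
            fs_hz=session.fs_hz,
            samples=filtered[start: start + seg_len],
            class_label=session.class_label,
        ))
    return segments


def accepted_windows(
    session: RecordingSession,
    channels: tuple[str, ...] = CHANNELS,
    **kwargs,
) -> np.ndarray:
    """Indices of candidate windows accepted on *every* requested channel.

    Used when features from several channels are concatenated per
    window: the window must be low-noise on all of them.
    """
    masks = []
    for ch in channels:
        idx = session.channel_index(ch)
        filtered = bandpass(session.samples[idx], session.fs_hz,
                            kwargs.get("band_hz", DEFAULT_BAND_HZ))
        env = rms_envelope(filtered, session.fs_hz, kwargs.get("step_s", DEFAULT_RMS_STEP_S))
        masks.append(accept_mask(env, kwargs.get("segment_s", DEFAULT_SEGMENT_S),
                                 kwargs.get("threshold", DEFAULT_THRESHOLD)))
    if not masks:
        return np.zeros(0, dtype=int)
    joint = np.logical_and.reduce(masks)
    return np.flatnonzero(joint)


def segment_cohort(sessions, channels: tuple[str, ...] = CHANNELS, **kwargs):
    """Segment every session on the joint acceptance mask.

    Returns a list of ``(session, window_index, {channel: Segment})``
    tuples, one entry per accepted window, aligned across channels.
    """
    out = []
    for session in sessions:
        seg_s = kwargs.get("segment_s", DEFAULT_SEGMENT_S)
        seg_len = int(round(seg_s * session.fs_hz))
        filtered = {
            ch: bandpass(session.samples[session.channel_index(ch)], session.fs_hz,
                         kwargs.get("band_hz", DEFAULT_BAND_HZ))
            for ch in channels
        }
        for k in accepted_windows(session, channels, **kwargs):
            per_channel = {
                ch: Segment(
                    subject_id=session.subject_id, channel=ch,
                    start_s=k * seg_s, fs_hz=session.fs_hz,
                    samples=filtered[ch][k * seg_len:(k + 1) * seg_len],
                    class_label=session.class_label,
                )
                for ch in channels
            }
            out.append((session, int(k), per_channel))
    return out
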