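"""Morse-wavelet CWT, per-frequency statistics, and scalogram images.

The continuous wavelet transform uses the generalized Morse wavelet
family, evaluated directly in the frequency domain:

    psi_hat(w) ∝ w^beta * exp(-w^gamma),   w > 0  (analytic)

with the symmetry parameter gamma = 3 and time-bandwidth product
gamma*beta = 60 (beta = 20), the common default for this wavelet.  The
peak (center) angular frequency is w_p = (beta/gamma)^(1/gamma); a
scale is assigned to each grid frequency f so that the wavelet peaks at
2*pi*f.  The wavelet is normalized so a unit-amplitude real sinusoid at
a grid frequency produces ridge magnitude ~= 1 (L1-type normalization).

Frequencies are log2-spaced over 0.79-25.39 Hz with a configurable
number of voices per octave.  Statistics (MEAN, MED, MAX, STD, IQR) are
taken along time for every frequency row; feature names encode channel,
statistic and frequency so downstream distribution summaries can be
reconstructed from names alone.

Boundary handling: segments are zero-padded to the FFT length; no
cone-of-influence masking is applied.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import fft as sfft

from ._parula import PARULA_128
from .exceptions import (
    InvalidArgumentError,
    MalformedFeatureNameError,
    NyquistViolationError,
)
from .preprocess import Segment
from .synthetic import CHANNELS

logger = logging.getLogger(__name__)

F_MIN_HZ = 0.79
F_MAX_HZ = 25.39
MORSE_GAMMA = 3.0
MORSE_BETA = 20.0
STATS = ("MEAN", "MED", "MAX", "STD", "IQR")

#: Default image sizes: (H, W) grayscale for the custom CNN, square RGB
#: for the transfer-learning path.
GRAY_SHAPE = (600, 800)
RGB_SHAPE = (224, 224)


@dataclasses.dataclass(frozen=True)
class CwtGrid:
    """Log2-spaced analysis frequencies and Morse parameters."""

    f_min_hz: float
    f_max_hz: float
    voices_per_octave: int
    gamma: float
    beta: float
    frequencies_hz: np.ndarray      # descending

    @property
    def time_bandwidth(self) -> float:
        return self.gamma * self.beta

    @property
    def n_frequencies(self) -> int:
        return self.frequencies_hz.size


@dataclasses.dataclass(frozen=True)
class Scalogram:
    """|CWT| magnitude on a fixed grid; rows follow grid order (descending f)."""

    magnitude: np.ndarray           # (F, T), all >= 0
    grid: CwtGrid
    times_s: np.ndarray
    source: tuple[str, str]         # (subject_id, channel)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    names: list[str]
    values: np.ndarray


def build_grid(
    fs_hz: float,
    voices_per_octave: int = 16,
    f_min_hz: float = F_MIN_HZ,
    f_max_hz: float = F_MAX_HZ,
    gamma: float = MORSE_GAMMA,
    beta: float = MORSE_BETA,
) -> CwtGrid:
    """Frequency grid with ``voices_per_octave`` points per octave.

    The grid holds floor(v * log2(f_max/f_min)) + 1 frequencies, clipped
    to [f_min, f_max], returned in descending order.
    """
    if not 0 < f_min_hz < f_max_hz:
        raise InvalidArgumentError("need 0 < f_min < f_max")
    if f_max_hz >= fs_hz / 2.0:
        raise NyquistViolationError(f"f_max={f_max_hz} Hz >= Nyquist ({fs_hz / 2} Hz)")
    if voices_per_octave < 1:
        raise InvalidArgumentError("voices_per_octave must be >= 1")
    n = int(np.floor(voices_per_octave * np.log2(f_max_hz / f_min_hz))) + 1
    freqs = f_min_hz * 2.0 ** (np.arange(n) / voices_per_octave)
    freqs = np.clip(freqs, f_min_hz, f_max_hz)
    return CwtGrid(
        f_min_hz=f_min_hz, f_max_hz=f_max_hz,
        voices_per_octave=int(voices_per_octave),
        gamma=float(gamma), beta=float(beta),
        frequencies_hz=freqs[::-1].copy(),
    )


_FILTER_CACHE: dict[tuple, np.ndarray] = {}


def _morse_filters(grid: CwtGrid, n_fft: int, fs_hz: float) -> np.ndarray:
    """(F, n_fft) frequency-domain Morse filters, peak value 2.

    Cached per (grid, FFT length, fs): the bank depends only on these,
    and rebuilding it per segment dominates extraction time otherwise.
    """
    key = (grid.f_min_hz, grid.f_max_hz, grid.voices_per_octave,
           grid.gamma, grid.beta, n_fft, fs_hz)
    cached = _FILTER_CACHE.get(key)
    if cached is not None:
        return cached
    gamma, beta = grid.gamma, grid.beta
    w_peak = (beta / gamma) ** (1.0 / gamma)
    omega = 2.0 * np.pi * sfft.fftfreq(n_fft, d=1.0 / fs_hz)   # rad/s
    filters = np.zeros((grid.n_frequencies, n_fft))
    pos = omega > 0
    for i, f in enumerate(grid.frequencies_hz):
        scale = w_peak / (2.0 * np.pi * f)
        a = scale * omega[pos]
        # log-domain evaluation; peak exactly 2 at a == w_peak
        expo = beta * np.log(a) - a**gamma - (beta * np.log(w_peak) - w_peak**gamma)
        filters[i, pos] = 2.0 * np.exp(np.clip(expo, -745.0, 0.0))
    if len(_FILTER_CACHE) > 8:        # keep a handful of (fs, length) combos
        _FILTER_CACHE.clear()
    _FILTER_CACHE[key] = filters
    return filters


def cwt_morse(segment: Segment | np.ndarray, grid: CwtGrid, fs_hz: float | None = None) -> Scalogram:
    """Morse CWT magnitude of one segment on the grid's frequencies."""
    if isinstance(segment, Segment):
        x = segment.samples
        fs = segment.fs_hz
        source = (segment.subject_id, segment.channel)
    else:
        if fs_hz is None:
            raise InvalidArgumentError("fs_hz required for raw sample vectors")
        x = np.asarray(segment, dtype=float)
        fs = float(fs_hz)
        source = ("", "")
    if x.ndim != 1 or x.size == 0:
        raise InvalidArgumentError("segment samples must be a non-empty vector")
    if grid.f_max_hz >= fs / 2.0:
        raise InvalidArgumentError("grid exceeds the segment's Nyquist frequency")

    n = x.size
    n_fft = sfft.next_fast_len(2 * n)          # zero-padding at the boundary
    spectrum = sfft.fft(x, n_fft)
    coeffs = sfft.ifft(spectrum[None, :] * _morse_filters(grid, n_fft, fs), axis=1)
    magnitude = np.abs(coeffs[:, :n])
    return Scalogram(
        magnitude=magnitude, grid=grid,
        times_s=np.arange(n) / fs, source=source,
    )


def feature_name(channel: str, stat: str, freq_hz: float) -> str:
    return f"{channel}_{stat}_{freq_hz:.2f}"


def parse_feature_name(name: str) -> tuple[str, str, float]:
    """Recover (channel, statistic, frequency) from a feature name."""
    parts = name.rsplit("_", 2)
    if len(parts) != 3:
        raise MalformedFeatureNameError(f"cannot parse feature name {name!r}")
    channel, stat, freq_str = parts
    if channel not in CHANNELS or stat not in STATS:
        raise MalformedFeatureNameError(f"cannot parse feature name {name!r}")
    try:
        freq = float(freq_str)
    except ValueError as exc:
        raise MalformedFeatureNameError(f"cannot parse feature name {name!r}") from exc
    return channel, stat, freq


def extract_features(scalogram: Scalogram, channel: str | None = None) -> FeatureVector:
    """The five per-frequency statistics along time, ordered (stat, desc f).

    MED uses the linear-interpolation (type-7) quantile, STD the
    population estimator (divide by N), IQR = Q3 - Q1 with type-7
    quantiles — fixed so expected values are exactly reproducible.
    """
    mag = scalogram.magnitude
    if mag.size == 0:
        raise InvalidArgumentError("empty scalogram")
    ch = channel or scalogram.source[1]
    if not ch:
        raise InvalidArgumentError("channel unknown; pass channel= explicitly")
    q1, med, q3 = np.percentile(mag, [25.0, 50.0, 75.0], axis=1)
    stat_values = {
        "MEAN": mag.mean(axis=1),
        "MED": med,
        "MAX": mag.max(axis=1),
        "STD": mag.std(axis=1),            # population (ddof=0)
        "IQR": q3 - q1,
    }
    names, values = [], []
    for stat in STATS:
        for j, f in enumerate(scalogram.grid.frequencies_hz):
            names.append(feature_name(ch, stat, f))
            values.append(stat_values[stat][j])
    return FeatureVector(names=names, values=np.asarray(values))


def render_image(
    scalogram: Scalogram,
    mode: str = "GRAY_1CH",
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Min-max normalized scalogram as an image tensor.

    ``GRAY_1CH`` returns (H, W, 1) floats in [0, 1] (default 600x800),
    bilinearly resized; ``PARULA_RGB`` returns (H, W, 3) floats via the
    128-level parula-style lookup (default 224x224).  A constant
    scalogram cannot be normalized; it renders as zeros with a warning.
    """
    from PIL import Image

    if mode not in ("GRAY_1CH", "PARULA_RGB"):
        raise InvalidArgumentError(f"unknown render mode {mode!r}")
    h, w = out_shape or (GRAY_SHAPE if mode == "GRAY_1CH" else RGB_SHAPE)
    if h <= 0 or w <= 0:
        raise InvalidArgumentError("output shape must be positive")

    mag = scalogram.magnitude
    lo, hi = float(mag.min()), float(mag.max())
    if hi <= lo:
        warnings.warn("constant scalogram: normalization degenerate, rendering zeros")
        norm = np.zeros_like(mag)
    else:
        norm = (mag - lo) / (hi - lo)

    img = Image.fromarray((norm * 255.0).astype(np.float32), mode="F")
    resized = np.asarray(img.resize((w, h), resample=Image.BILINEAR), dtype=np.float64) / 255.0
    resized = np.clip(resized, 0.0, 1.0)
    if mode == "GRAY_1CH":
        return resized[:, :, None]
    idx = np.round(resized * (PARULA_128.shape[0] - 1)).astype(int)
    return PARULA_128[idx]


def segment_features(per_channel_segments: dict[str, Segment], grid: CwtGrid) -> FeatureVector:
    """Concatenate per-channel feature vectors for one accepted window."""
    names: list[str] = []
    values: list[np.ndarray] = []
    for ch in CHANNELS:
        if ch not in per_channel_segments:
            continue
        fv = extract_features(cwt_morse(per_channel_segments[ch], grid), channel=ch)
        names.extend(fv.names)
        values.append(fv.values)
    if not values:
        raise InvalidArgumentError("no channels provided")
    return FeatureVector(names=names, values=np.concatenate(values))
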