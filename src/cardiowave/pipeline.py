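"""End-to-end helpers tying the stages together.

These are the compositions the command-line interface and scripted
analyses use: raw sessions -> joint-window segmentation -> Morse-CWT
statistical features (one row per accepted 10-s window, channels
concatenated) or -> scalogram image stacks for the CNN.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .exceptions import InvalidArgumentError
from .feature_select import FeatureTable
from .preprocess import segment_cohort
from .synthetic import CHANNELS, RecordingSession
from .timefreq import build_grid, cwt_morse, render_image, segment_features


def build_feature_table(
    sessions: Sequence[RecordingSession],
    channels: tuple[str, ...] = CHANNELS,
    voices_per_octave: int = 16,
    **segment_kwargs,
) -> FeatureTable:
    """Feature table over all accepted windows of a cohort.

    A window contributes one row only if it passes the RMS acceptance
    test on every requested channel; its row concatenates the five
    per-frequency statistics of each channel's scalogram.
    """
    if not sessions:
        raise InvalidArgumentError("empty cohort")
    grids = {}
    rows, names, subjects, labels = [], None, [], []
    for session, _k, per_channel in segment_cohort(sessions, channels, **segment_kwargs):
        fs = session.fs_hz
        if fs not in grids:
            grids[fs] = build_grid(fs, voices_per_octave)
        fv = segment_features(per_channel, grids[fs])
        if names is None:
            names = fv.names
        rows.append(fv.values)
        subjects.append(session.subject_id)
        labels.append(session.class_label)
    if not rows:
        raise InvalidArgumentError("no accepted windows in the cohort")
    return FeatureTable(
        matrix=np.vstack(rows), feature_names=names,
        subject_ids=subjects, labels=labels,
    )


def build_image_set(
    sessions: Sequence[RecordingSession],
    channel: str = "SCG_Z",
    out_shape: tuple[int, int] = (60, 80),
    mode: str = "GRAY_1CH",
    voices_per_octave: int = 16,
    positive_labels: tuple[str, ...] = ("AS", "AS_MI", "AS_MS", "AS_TR"),
    **segment_kwargs,
):
    """Scalogram images of one channel's accepted windows.

    Returns ``(images, labels, subject_ids)``; labels are 1 for the AS
    family and 0 otherwise.
    """
    grids = {}
    images, labels, subjects = [], [], []
    for session, _k, per_channel in segment_cohort(sessions, (channel,), **segment_kwargs):
        fs = session.fs_hz
        if fs not in grids:
            grids[fs] = build_grid(fs, voices_per_octave)
        scalogram = cwt_morse(per_channel[channel], grids[fs])
        images.append(render_image(scalogram, mode=mode, out_shape=out_shape))
        labels.append(1 if session.class_label in positive_labels else 0)
        subjects.append(session.subject_id)
    if not images:
        raise InvalidArgumentError("no accepted windows in the cohort")
    return np.stack(images), np.asarray(labels), subjects
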