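"""Parula-style colormap lookup table.

MATLAB's parula colormap data is proprietary, so this module builds a
close approximation by piecewise-linear interpolation through a small
set of published anchor colors spanning the same dark-blue -> teal ->
green -> yellow ramp.  The table is materialized at 128 levels, the
resolution used when scalograms are rendered to RGB.
"""

from __future__ import annotations

import numpy as np

# (position in [0, 1], R, G, B) anchors of the parula ramp.
_ANCHORS = np.array([
    [0.000, 0.2081, 0.1663, 0.5292],
    [0.125, 0.0704, 0.3345, 0.7487],
    [0.250, 0.0165, 0.4416, 0.8786],
    [0.375, 0.0329, 0.5430, 0.8260],
    [0.500, 0.0231, 0.6418, 0.7924],
    [0.625, 0.2258, 0.7178, 0.6293],
    [0.750, 0.6473, 0.7456, 0.4188],
    [0.875, 0.9184, 0.7411, 0.2323],
    [1.000, 0.9763, 0.9831, 0.0538],
])

N_LEVELS = 128


def parula_table(n_levels: int = N_LEVELS) -> np.ndarray:
    """(n_levels, 3) RGB table in [0, 1], dark blue at index 0."""
    pos = np.linspace(0.0, 1.0, n_levels)
    return np.column_stack([
        np.interp(pos, _ANCHORS[:, 0], _ANCHORS[:, 1 + c]) for c in range(3)
    ])


PARULA_128 = parula_table(N_LEVELS)
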