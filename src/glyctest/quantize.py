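"""Audiometric quantization: rounding to 5 dB steps, clamping to range.

Clinical audiometers report thresholds in 5 dB steps on a bounded dial;
all simulated measurements pass through these helpers so that outputs are
bit-reproducible.  Rounding is half-away-from-zero, which is symmetric and
therefore cannot inject a sign bias into simulated threshold changes.
"""

from __future__ import annotations

import numpy as np

AUDIOMETER_MIN_DB = -10.0
AUDIOMETER_MAX_DB = 120.0
DEFAULT_STEP_DB = 5.0

__all__ = [
    "round_to_step",
    "clamp_to_audiometer",
    "is_multiple_of_step",
    "AUDIOMETER_MIN_DB",
    "AUDIOMETER_MAX_DB",
    "DEFAULT_STEP_DB",
]


def round_to_step(x, step: float = DEFAULT_STEP_DB):
    """Round to the nearest multiple of ``step``, halves away from zero."""
    if not step > 0:
        raise ValueError(f"step must be > 0, got {step}")
    x = np.asarray(x, dtype=float)
    out = step * np.sign(x) * np.floor(np.abs(x) / step + 0.5)
    out = out + 0.0  # fold -0.0 into +0.0
    return float(out) if out.ndim == 0 else out


def clamp_to_audiometer(x, lo: float = AUDIOMETER_MIN_DB, hi: float = AUDIOMETER_MAX_DB):
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    return float(x) if x.ndim == 0 else x


def is_multiple_of_step(x, step: float = DEFAULT_STEP_DB):
    x = np.asarray(x, dtype=float)
    out = np.isclose(np.mod(x, step), 0.0) | np.isclose(np.mod(x, step), step)
    return bool(out) if out.ndim == 0 else out
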