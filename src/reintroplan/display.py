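"""Display-side number formatting.

All user-facing numbers are TRUNCATED (floored toward zero), never rounded:
an eigenvalue of 0.90494 prints as 0.904, a proportion of 6.72% prints as
6%.  Internal arithmetic is always carried at full precision; truncation is
applied only when a value is formatted for display, and machine-readable
outputs carry full-precision values alongside any ``*_display`` fields.
"""

from __future__ import annotations

import math

import numpy as np


def truncate(x, decimals: int = 0):
    """Truncate toward zero at ``decimals`` decimal places.

    Works on scalars and arrays; returns a float (or float array), e.g.
    ``truncate(0.90494, 3) == 0.904`` and ``truncate(6.72) == 6.0``.
    """
    factor = 10.0 ** decimals
    a = np.asarray(x, dtype=float)
    out = np.trunc(a * factor) / factor
    if np.isscalar(x) or a.ndim == 0:
        return float(out)
    return out


def truncate_int(x) -> int:
    """Truncate a scalar toward zero to an integer."""
    return int(math.trunc(float(x)))


def format_sig(x: float, sig: int = 12) -> str:
    """Format a float with ``sig`` significant digits (machine outputs)."""
    return f"{float(x):.{sig}g}"


def format_truncated(x: float, decimals: int = 0) -> str:
    """Format a truncated display value with a fixed number of decimals."""
    if decimals <= 0:
        return str(truncate_int(x))
    return f"{truncate(x, decimals):.{decimals}f}"
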