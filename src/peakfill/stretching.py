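"""Stretching: interpolate the bucket-resolution baseline back to full length.

Because the buckets were represented by *minimum* values, the estimated
baseline is anchored at the bucket centre points and interpolated between
them — linearly (fast, robust) or with a shape-preserving piecewise cubic
(smoother, no overshoot past adjacent knots).  Channels before the first
centre or after the last take the terminal knot value.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .binning import BinScheme

__all__ = ["stretch", "baseline_interpolant"]

_METHODS = ("linear", "spline")


def baseline_interpolant(
    suppressed, scheme: BinScheme, method: str = "linear"
) -> Callable[[np.ndarray], np.ndarray]:
    """Callable baseline over channel indices, knotted at bucket centres.

    ``method="linear"`` is piecewise linear; ``"spline"`` is a monotone
    shape-preserving cubic (PCHIP) through the same knots.  Both extend the
    terminal knot values as constants outside the centre range.
    """
    sup = np.asarray(suppressed, dtype=float)
    if sup.ndim != 1 or sup.size != scheme.n_bins:
        raise ValueError(
            f"expected one suppressed value per bin "
            f"({scheme.n_bins}), got {sup.size}"
        )
    if method not in _METHODS:
        raise ValueError(
            f"unknown interpolation method {method!r}; choose from {_METHODS}"
        )
    centres = scheme.centres
    if sup.size == 1 or method == "linear":
        return lambda x: np.interp(np.asarray(x, dtype=float), centres, sup)
    pchip = PchipInterpolator(centres, sup, extrapolate=False)

    def _eval(x):
        x = np.clip(np.asarray(x, dtype=float), centres[0], centres[-1])
        return pchip(x)

    return _eval


def stretch(
    suppressed,
    scheme: BinScheme,
    n_channels: int | None = None,
    method: str = "linear",
) -> np.ndarray:
    """Full-resolution baseline from one suppressed value per bucket."""
    if n_channels is None:
        n_channels = scheme.n_channels
    if n_channels != scheme.n_channels:
        raise ValueError(
            f"n_channels ({n_channels}) does not match the bin scheme "
            f"({scheme.n_channels})"
        )
    f = baseline_interpolant(suppressed, scheme, method)
    return f(np.arange(n_channels, dtype=float))
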