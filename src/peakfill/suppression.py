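"""Iterative moving-window suppression of the subsampled spectrum.

A window slides across the bucket-resolution vector and each visited value
is replaced by the minimum of itself and the window mean.  Four details
matter, and each is deliberate:

* ``min(current, window mean)`` — not the median — pulls the vector down
  onto the perceived baseline without undershooting it, provided the window
  width suits the bucket count.
* the vector is updated *in place* as the window moves, which converges
  faster but is directional, so every iteration sweeps left-to-right and
  then right-to-left to avoid bias around peaks.
* the half-width shrinks logarithmically from its initial value down to
  ±1 bucket over the iterations: wide early windows work fast, narrow late
  ones avoid dragging the estimate too low.
* near the vector ends the window shrinks symmetrically about the cursor,
  so steep baselines at the spectrum edges are not underestimated.

The inner loops use plain sequential float accumulation on purpose: the
vectors are bucket-resolution (hundreds of points), and the evaluation
order is then fully specified, so an independent loop oracle can check the
implementation for exact, bitwise agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["WindowSchedule", "window_schedule", "suppress_sweep", "suppress"]


@dataclass(frozen=True)
class WindowSchedule:
    """Half-widths used in successive suppression iterations.

    Non-increasing; the first element is at most the initial half-width and
    the last equals 1 whenever there is more than one iteration.
    """

    halfwidths: Tuple[int, ...]

    def __post_init__(self):
        hw = self.halfwidths
        if not hw:
            raise ValueError("window schedule must not be empty")
        if any(h < 1 for h in hw):
            raise ValueError("window half-widths must be >= 1")
        if any(b > a for a, b in zip(hw, hw[1:])):
            raise ValueError("window half-widths must be non-increasing")
        if len(hw) >= 2 and hw[-1] != 1:
            raise ValueError("window schedule must end at half-width 1")

    def __len__(self) -> int:
        return len(self.halfwidths)

    def __iter__(self):
        return iter(self.halfwidths)


def window_schedule(hwi: int, it: int) -> WindowSchedule:
    """Logarithmically shrinking half-width schedule.

    ``halfwidths[k] = ceil(10**d_k)`` with ``d_k`` stepping linearly from
    ``log10(hwi)`` down to 0 across ``it`` iterations, so the window ends at
    ±1 bucket.  A single iteration keeps the initial half-width.

    Parameters
    ----------
    hwi : int
        Initial half-width, in subsampled (bucket) points; ``>= 1``.
        A starting point for new data is half the width of the widest peak.
    it : int
        Number of suppression iterations (right+left passes); ``>= 1``.
    """
    if int(hwi) != hwi or hwi < 1:
        raise ValueError("hwi must be a positive integer")
    if int(it) != it or it < 1:
        raise ValueError("it must be a positive integer")
    hwi, it = int(hwi), int(it)
    if it == 1:
        return WindowSchedule((hwi,))
    d = np.linspace(np.log10(hwi), 0.0, it)
    hw = np.ceil(10.0 ** d).astype(int)
    # ceil(10**log10(hwi)) can land one above hwi through roundoff; guard
    # the schedule's invariants without touching the formula.
    hw = np.minimum(hw, hwi)
    hw = np.minimum.accumulate(hw)
    return WindowSchedule(tuple(int(h) for h in hw))


def suppress_sweep(v, halfwidth: int, direction: str = "ltr") -> np.ndarray:
    """One directional pass of min(current, window-mean) replacement.

    Visiting positions left-to-right (``"ltr"``) or right-to-left
    (``"rtl"``), replaces ``v[j]`` with ``min(v[j], mean(v[j-a .. j+a]))``
    where ``a = min(halfwidth, j, n-1-j)`` (the symmetric end-shrinkage).
    The mean at each step sees values already updated earlier in the same
    sweep.

    Returns the updated vector; the input is not modified.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("suppress_sweep expects a non-empty 1-D vector")
    if int(halfwidth) != halfwidth or halfwidth < 1:
        raise ValueError("halfwidth must be a positive integer")
    if direction not in ("ltr", "rtl"):
        raise ValueError(f"unknown sweep direction: {direction!r}")
    halfwidth = int(halfwidth)
    w = [float(x) for x in v]
    n = len(w)
    order = range(n) if direction == "ltr" else range(n - 1, -1, -1)
    for j in order:
        a = min(halfwidth, j, n - 1 - j)
        s = 0.0
        for k in range(j - a, j + a + 1):
            s += w[k]
        m = s / (2 * a + 1)
        if m < w[j]:
            w[j] = m
    return np.array(w)


def suppress(v, schedule: WindowSchedule) -> np.ndarray:
    """Full iterative suppression: for each scheduled half-width, sweep
    left-to-right and then right-to-left.

    The result is pointwise less than or equal to the input, and every
    intermediate sweep is itself pointwise non-increasing.
    """
    v = np.asarray(v, dtype=float)
    out = v.copy()
    for hw in schedule:
        out = suppress_sweep(out, hw, "ltr")
        out = suppress_sweep(out, hw, "rtl")
    return out
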