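"""Intentionally naive, loop-based reference implementations.

These mirror the stage definitions one index at a time using plain Python
lists and sequential accumulation, independent of the production code
paths.  Because both sides fix the same floating-point evaluation order,
agreement can be asserted bitwise.
"""

from __future__ import annotations


def naive_subsample_min(y, edges):
    """Minimum per (start, end) inclusive interval, by explicit scan."""
    out = []
    for start, end in edges:
        m = float(y[start])
        for k in range(start + 1, end + 1):
            val = float(y[k])
            if val < m:
                m = val
        out.append(m)
    return out


def naive_suppress(v, halfwidths):
    """Iterative min(current, window-mean) suppression, lists only.

    For each half-width: visit positions left-to-right and then
    right-to-left, replacing each value by the window mean when the mean is
    smaller; the window shrinks symmetrically near the ends and the working
    vector is updated in place.
    """
    w = [float(x) for x in v]
    n = len(w)
    for hw in halfwidths:
        for order in (range(n), range(n - 1, -1, -1)):
            for j in order:
                a = min(hw, j, n - 1 - j)
                s = 0.0
                for k in range(j - a, j + a + 1):
                    s += w[k]
                m = s / (2 * a + 1)
                if m < w[j]:
                    w[j] = m
    return w
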