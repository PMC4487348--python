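"""Subsampling bins: partition the channel axis into buckets.

The baseline is not estimated on the full-resolution spectrum but on a
coarse grid of buckets; the minimum intensity in each bucket stands in for
the spectrum there.  Buckets are contiguous, non-overlapping channel-index
intervals that jointly cover every channel.  They may be equal-width (a
count) or fully custom (explicit start/end intervals), which is how sharp
local baseline structure such as the dips in LIBS spectra is accommodated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np

__all__ = ["BinScheme", "make_bins", "subsample_min"]

Edges = Sequence[Tuple[int, int]]


@dataclass(frozen=True)
class BinScheme:
    """Resolved bucket boundaries on the channel-index axis.

    Attributes
    ----------
    edges : tuple of (start, end)
        0-based, inclusive channel-index intervals; disjoint, ordered, and
        jointly covering ``0 .. n_channels - 1``.
    n_channels : int
        Number of channels the scheme covers.
    """

    edges: Tuple[Tuple[int, int], ...]
    n_channels: int

    def __post_init__(self):
        if not self.edges:
            raise ValueError("bins: a scheme needs at least one interval")
        prev_end = -1
        for start, end in self.edges:
            if start != prev_end + 1:
                raise ValueError(
                    f"bins: intervals must tile the channels without gaps or "
                    f"overlaps (interval starting at {start} follows one "
                    f"ending at {prev_end})"
                )
            if end < start:
                raise ValueError(f"bins: empty interval ({start}, {end})")
            prev_end = end
        if prev_end != self.n_channels - 1:
            raise ValueError(
                f"bins: intervals cover channels 0..{prev_end} but the "
                f"spectrum has {self.n_channels} channels"
            )

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def centres(self) -> np.ndarray:
        """Bin centres as (possibly half-integral) channel indices."""
        return np.array([(s + e) / 2.0 for s, e in self.edges])

    def centres_on_axis(self, axis: np.ndarray) -> np.ndarray:
        """Map the index-space centres to axis units (m/z, nm, ...)."""
        axis = np.asarray(axis, dtype=float)
        if axis.size != self.n_channels:
            raise ValueError("axis length does not match the bin scheme")
        return np.interp(self.centres, np.arange(self.n_channels), axis)


def make_bins(n_channels: int, bins: Union[int, Edges]) -> BinScheme:
    """Build a :class:`BinScheme` from a count or explicit intervals.

    For a count ``b`` the channels are split into ``b`` contiguous
    near-equal intervals; when the division leaves a remainder of ``r``
    channels, the trailing ``r`` intervals are one channel wider.  Explicit
    intervals are 0-based inclusive ``(start, end)`` pairs and must tile the
    channel range exactly.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    if isinstance(bins, (int, np.integer)):
        b = int(bins)
        if b < 2:
            raise ValueError("bins: a bin count must be at least 2")
        if b > n_channels:
            raise ValueError(
                f"bins: {b} bins requested for only {n_channels} channels"
            )
        base, rem = divmod(n_channels, b)
        widths = [base] * (b - rem) + [base + 1] * rem
        edges = []
        start = 0
        for w in widths:
            edges.append((start, start + w - 1))
            start += w
        return BinScheme(tuple(edges), n_channels)
    edges = tuple((int(s), int(e)) for s, e in bins)
    return BinScheme(edges, n_channels)


def subsample_min(y, scheme: BinScheme) -> np.ndarray:
    """Minimum intensity per bucket — the bucket's local representative.

    Parameters
    ----------
    y : array_like, shape (n_channels,)
        One spectrum (typically already smoothed).
    scheme : BinScheme
        Bucket layout; must cover exactly ``len(y)`` channels.

    Returns
    -------
    ndarray, shape (n_bins,)
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != scheme.n_channels:
        raise ValueError(
            f"spectrum length ({y.size}) does not match the bin scheme "
            f"({scheme.n_channels} channels)"
        )
    out = np.empty(scheme.n_bins)
    for j, (s, e) in enumerate(scheme.edges):
        out[j] = y[s : e + 1].min()
    return out
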