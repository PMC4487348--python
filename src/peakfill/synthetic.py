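"""Synthetic spectra with known ground-truth baselines.

The generator exists so the whole pipeline can be exercised and *scored*
without external data: every generated spectrum carries its true baseline
and a peak-free channel mask, so the recovery error of an estimate is
directly computable.  Two presets emulate the qualitative shapes the
method targets: a MALDI-TOF-like spectrum (smoothly decaying baseline
under a cluster of Gaussian peaks) and a LIBS-like emission spectrum
(locally structured baseline with two dips and a steep ridge, plus many
narrow lines).

No attempt is made to simulate instrument physics (detector saturation,
isotope envelopes, chemical noise).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.special import expit

from .binning import Edges
from .spectra import SpectraSet, write_spectra

__all__ = [
    "SyntheticSpec",
    "generate",
    "maldi_like_preset",
    "libs_like_preset",
    "libs_like_bin_edges",
    "variable_bin_edges",
    "write_synthetic",
]

_BASELINE_KINDS = ("linear", "polynomial", "exponential-decay", "sigmoid-dip")

# Gaussian mass beyond 4 sigma is negligible, so channels farther than
# 4 sigma from every peak centre count as peak-free for scoring.
PEAK_FREE_SIGMAS = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic spectrum.

    Attributes
    ----------
    n_channels : int
        Spectrum length.
    baseline_kind : str
        One of ``linear`` (intercept, slope), ``polynomial`` (coefficients,
        highest power first), ``exponential-decay`` (amplitude, decay
        constant, offset) — all evaluated on the normalised position
        t = i/(n-1) — or ``sigmoid-dip`` (a dict with ``base`` level plus
        flat-bottomed ``dips`` and flat-topped ``ridges`` given as
        (centre channel, magnitude, half-width in channels)).
    peaks : sequence of (centre, height, sigma)
        Gaussian peaks in channel units.
    noise_sigma : float
        Standard deviation of the additive Gaussian noise.
    seed : int
        Seed for the noise generator; identical seeds give identical output.
    axis_range : (float, float)
        Axis values of the first and last channel (m/z, nm, ...).
    """

    n_channels: int
    baseline_kind: str
    baseline_params: object
    peaks: Tuple[Tuple[float, float, float], ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0
    axis_range: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be at least 2")
        if self.baseline_kind not in _BASELINE_KINDS:
            raise ValueError(
                f"unknown baseline_kind {self.baseline_kind!r}; "
                f"choose from {_BASELINE_KINDS}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for c, h, s in self.peaks:
            if not 0 <= c < self.n_channels:
                raise ValueError(f"peak centre {c} outside [0, {self.n_channels})")
            if h < 0:
                raise ValueError("peak heights must be non-negative")
            if s <= 0:
                raise ValueError("peak sigmas must be positive")
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))

    @property
    def axis(self) -> np.ndarray:
        lo, hi = self.axis_range
        if lo >= hi:
            return np.arange(self.n_channels, dtype=float)
        return np.linspace(lo, hi, self.n_channels)


def _flat_top_bump(i: np.ndarray, centre: float, halfwidth: float) -> np.ndarray:
    # Product of two logistics: ~1 on [centre-hw, centre+hw], smooth shoulders.
    s = halfwidth / 4.0
    rise = expit((i - (centre - halfwidth)) / s)
    fall = expit(-(i - (centre + halfwidth)) / s)
    return rise * fall


def true_baseline(spec: SyntheticSpec) -> np.ndarray:
    """Evaluate the ground-truth baseline of a recipe."""
    i = np.arange(spec.n_channels, dtype=float)
    t = i / (spec.n_channels - 1)
    kind, p = spec.baseline_kind, spec.baseline_params
    if kind == "linear":
        b0, b1 = p
        return b0 + b1 * t
    if kind == "polynomial":
        return np.polyval(np.asarray(p, dtype=float), t)
    if kind == "exponential-decay":
        amplitude, tau, offset = p
        return amplitude * np.exp(-t / tau) + offset
    base = float(p["base"]) * np.ones_like(i)
    for centre, depth, hw in p.get("dips", ()):
        base -= depth * _flat_top_bump(i, centre, hw)
    for centre, height, hw in p.get("ridges", ()):
        base += height * _flat_top_bump(i, centre, hw)
    return base


def generate(spec: SyntheticSpec):
    """Simulate a spectrum: baseline + Gaussian peaks + Gaussian noise.

    Returns
    -------
    spectra : SpectraSet
        A one-row set on the recipe's axis.
    truth : ndarray, (n_channels,)
        The noise- and peak-free baseline.
    peak_free : boolean ndarray, (n_channels,)
        True for channels farther than 4 sigma from every peak centre.
    """
    truth = true_baseline(spec)
    i = np.arange(spec.n_channels, dtype=float)
    signal = truth.copy()
    peak_free = np.ones(spec.n_channels, dtype=bool)
    for centre, height, sigma in spec.peaks:
        signal += height * np.exp(-0.5 * ((i - centre) / sigma) ** 2)
        peak_free &= np.abs(i - centre) > PEAK_FREE_SIGMAS * sigma
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, spec.n_channels)
    return SpectraSet(spec.axis, signal), truth, peak_free


def maldi_like_preset(seed: int = 2015) -> SyntheticSpec:
    """MALDI-TOF-like recipe: 4000 channels, decaying baseline, peak cluster.

    The baseline decays exponentially from ~65 down to ~8 counts across the
    m/z range; 20 Gaussian peaks (heights 10–120, widths 3–15 channels) are
    drawn reproducibly from *seed*, and noise has unit standard deviation.
    """
    rng = np.random.default_rng(seed)
    centres = np.sort(rng.uniform(200, 3800, 20))
    heights = rng.uniform(10, 120, 20)
    sigmas = rng.uniform(3, 15, 20)
    return SyntheticSpec(
        n_channels=4000,
        baseline_kind="exponential-decay",
        baseline_params=(60.0, 0.35, 5.0),
        peaks=tuple(zip(centres, heights, sigmas)),
        noise_sigma=1.0,
        seed=seed,
        axis_range=(1000.0, 15000.0),
    )


# LIBS preset geometry, in channel units on the 300-600 nm axis of 2000
# channels: dips near 360 nm and 530 nm, a steep ridge near 400 nm.
_LIBS_DIPS = ((400.0, 25.0, 40.0), (1533.0, 25.0, 40.0))
_LIBS_RIDGE = (667.0, 35.0, 25.0)


def libs_like_preset(seed: int = 2016) -> SyntheticSpec:
    """LIBS-like recipe: baseline with two localized dips and a steep ridge.

    2000 channels spanning 300–600 nm; the baseline sits at ~40 counts with
    flat-bottomed dips around 360 nm and 530 nm and a steep ridge around
    400 nm.  30 narrow emission lines (heights 30–300, widths 2–5 channels)
    are drawn reproducibly from *seed*; noise sigma is 0.8.
    """
    rng = np.random.default_rng(seed)
    centres = np.sort(rng.uniform(50, 1950, 30))
    heights = rng.uniform(30, 300, 30)
    sigmas = rng.uniform(2, 5, 30)
    return SyntheticSpec(
        n_channels=2000,
        baseline_kind="sigmoid-dip",
        baseline_params={
            "base": 40.0,
            "dips": list(_LIBS_DIPS),
            "ridges": [_LIBS_RIDGE],
        },
        peaks=tuple(zip(centres, heights, sigmas)),
        noise_sigma=0.8,
        seed=seed,
        axis_range=(300.0, 600.0),
    )


def variable_bin_edges(
    regions: Sequence[Tuple[int, int, int]], n_channels: int
) -> Edges:
    """Tile contiguous channel regions with buckets of per-region width.

    *regions* is an ordered list of ``(start, end, approx_width)`` with
    0-based inclusive bounds that must jointly cover ``0..n_channels-1``;
    each region is split into near-equal buckets of roughly the requested
    width (trailing buckets absorb the remainder).
    """
    edges: list[Tuple[int, int]] = []
    for start, end, width in regions:
        length = end - start + 1
        if length < 1 or width < 1:
            raise ValueError("regions must be non-empty with positive widths")
        k = max(1, round(length / width))
        base, rem = divmod(length, k)
        pos = start
        for j in range(k):
            w = base + (1 if j >= k - rem else 0)
            edges.append((pos, pos + w - 1))
            pos += w
    if edges[0][0] != 0 or edges[-1][1] != n_channels - 1:
        raise ValueError("regions do not cover the channel range")
    return tuple(edges)


def libs_like_bin_edges(n_channels: int = 2000) -> Edges:
    """Hand-tuned variable buckets for the LIBS-like preset.

    Narrow buckets inside the two baseline dips, medium buckets across the
    steep ridge, wide buckets where the baseline is flat — the bucket
    layout that lets one baseline model follow sharp local structure
    without rising into the peaks elsewhere.
    """
    (d1c, _, d1w), (d2c, _, d2w) = _LIBS_DIPS
    rc, _, rw = _LIBS_RIDGE
    d1a, d1b = int(d1c - 2 * d1w), int(d1c + 2 * d1w)
    d2a, d2b = int(d2c - 2 * d2w), int(d2c + 2 * d2w)
    ra, rb = int(rc - 4 * rw), int(rc + 4 * rw)
    regions = [
        (0, d1a - 1, 20),
        (d1a, d1b, 8),          # dip near 360 nm
        (d1b + 1, ra - 1, 40),
        (ra, rb, 5),            # steep ridge near 400 nm
        (rb + 1, d2a - 1, 20),
        (d2a, d2b, 8),          # dip near 530 nm
        (d2b + 1, n_channels - 1, 20),
    ]
    return variable_bin_edges(regions, n_channels)


def write_synthetic(
    spec: SyntheticSpec,
    spectrum_path,
    truth_path,
    meta_path,
    delimiter: str = "\t",
) -> None:
    """Generate a recipe and write spectrum, truth sidecar, and metadata.

    The spectrum and truth files use the same delimited format the
    estimator reads; the metadata file is the JSON-serialised recipe.
    """
    spectra, truth, _ = generate(spec)
    write_spectra(spectrum_path, spectra, delimiter=delimiter)
    write_spectra(
        truth_path, SpectraSet(spec.axis, truth), delimiter=delimiter
    )
    with open(meta_path, "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, default=list)
        fh.write("\n")
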