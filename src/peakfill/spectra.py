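"""Spectrum container and delimited-text I/O.

A :class:`SpectraSet` is the package's I/O currency: a shared, strictly
increasing axis (m/z, wavelength in nm, or plain channel index) plus a matrix
of intensities with one row per spectrum and one column per channel.

Files are plain delimited text (tab or comma), optionally with a first header
row holding the axis values and one spectrum per subsequent row.  Values are
written with enough digits that a read/write round trip is lossless.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np

__all__ = ["SpectraSet", "read_spectra", "write_spectra"]


class SpectraSet:
    """One or more 1-D spectra sampled on a common axis.

    Parameters
    ----------
    axis : array_like, shape (n_channels,)
        Strictly increasing channel positions (m/z, nm, or index).
    intensities : array_like, shape (n_spectra, n_channels) or (n_channels,)
        Intensity values; a 1-D array is treated as a single spectrum.

    Raises
    ------
    ValueError
        If the axis is not strictly increasing, shapes disagree, or any
        value is missing / non-finite.
    """

    def __init__(self, axis, intensities):
        axis = np.asarray(axis, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim == 1:
            intensities = intensities[np.newaxis, :]
        if axis.ndim != 1:
            raise ValueError("axis must be one-dimensional")
        if intensities.ndim != 2:
            raise ValueError("intensities must be a matrix (spectra x channels)")
        if intensities.shape[1] != axis.size:
            raise ValueError(
                f"axis length ({axis.size}) does not match the number of "
                f"channels ({intensities.shape[1]})"
            )
        if not np.all(np.isfinite(axis)):
            raise ValueError("axis contains non-finite values")
        if not np.all(np.isfinite(intensities)):
            raise ValueError("intensities contain missing or non-finite values")
        if axis.size > 1 and not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be strictly increasing")
        self.axis = axis
        self.intensities = intensities

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SpectraSet(n_spectra={self.n_spectra}, "
            f"n_channels={self.n_channels}, "
            f"axis=[{self.axis[0]:g}..{self.axis[-1]:g}])"
        )

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.axis.copy(), self.intensities.copy())


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def read_spectra(
    path: Union[str, os.PathLike],
    delimiter: str | None = None,
    axis_row: bool = True,
) -> SpectraSet:
    """Read spectra from a delimited text file.

    Parameters
    ----------
    path : path-like
        File with one row per spectrum; if *axis_row* the first row holds
        the axis values.
    delimiter : str, optional
        Field delimiter; sniffed from the first line (tab, comma, then
        whitespace) when not given.
    axis_row : bool
        Whether the first row is the axis header.  If ``False`` the axis is
        the 0-based channel index.
    """
    with open(path, "r") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"empty input file: {path}")
    if delimiter is None:
        delimiter = _sniff_delimiter(first)
    data = np.loadtxt(
        path, delimiter=None if delimiter == " " else delimiter, ndmin=2
    )
    if axis_row:
        if data.shape[0] < 2:
            raise ValueError(
                "input declares an axis header row but contains no spectra"
            )
        axis, intensities = data[0], data[1:]
    else:
        axis = np.arange(data.shape[1], dtype=float)
        intensities = data
    return SpectraSet(axis, intensities)


def write_spectra(
    path: Union[str, os.PathLike],
    spectra: SpectraSet,
    delimiter: str = "\t",
    axis_row: bool = True,
) -> None:
    """Write spectra as delimited text, losslessly round-trippable.

    Uses the ``%.17g`` format so every IEEE double survives a read/write
    cycle bit-for-bit (well beyond 15 significant digits).
    """
    rows = spectra.intensities
    if axis_row:
        rows = np.vstack([spectra.axis, rows])
    np.savetxt(path, rows, fmt="%.17g", delimiter=delimiter)
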