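"""Optional plotting helpers (requires matplotlib)."""

from __future__ import annotations


def plot_baseline(result, index: int = 0, ax=None):
    """Overlay spectrum, smoothed spectrum, and estimated baseline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = result.spectra.axis
    ax.plot(x, result.spectra.intensities[index], lw=0.5, label="spectrum")
    ax.plot(x, result.smoothed[index], lw=0.8, label="smoothed")
    ax.plot(x, result.baseline[index], lw=1.5, label="baseline")
    centres = result.bin_scheme.centres_on_axis(x)
    ax.plot(centres, result.suppressed[index], ".", ms=3, label="suppressed bins")
    ax.legend()
    ax.set_xlabel("axis")
    ax.set_ylabel("intensity")
    return ax


def plot_corrected(result, index: int = 0, ax=None):
    """Baseline-corrected spectrum with the zero line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    corrected = result.subtract()
    ax.plot(corrected.axis, corrected.intensities[index], lw=0.5)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("axis")
    ax.set_ylabel("corrected intensity")
    return ax
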