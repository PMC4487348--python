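"""Whittaker smoothing with a second-derivative penalty.

The smoother returns the unique minimiser of

    S(z) = ||y - z||^2 + lam * ||D2 z||^2

where ``D2`` is the discrete second-difference operator and
``lam = 10**lambda_log10``.  Setting the stage before baseline estimation,
it damps spurious noise spikes and — via the size of ``lam`` — lets the
user centre the eventual baseline inside the noise band rather than at its
bottom.  Severe shrinkage of real peaks is harmless here because only the
space *between* peaks informs the baseline.

The stationarity condition is the sparse pentadiagonal system
``(I + lam * D2' D2) z = y``, solved to double precision.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = ["whittaker_smooth"]


def whittaker_smooth(y, lambda_log10: float) -> np.ndarray:
    """Smooth a vector by penalised least squares.

    Parameters
    ----------
    y : array_like, shape (n,)
        Signal to smooth; must be finite with ``n >= 3``.
    lambda_log10 : float
        log10 of the penalty weight; the effective penalty is
        ``10**lambda_log10``.  ``-inf`` gives a zero penalty and returns
        ``y`` unchanged.

    Returns
    -------
    ndarray, shape (n,)
        The penalised least-squares fit ``z``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("whittaker_smooth expects a 1-D signal")
    if y.size < 3:
        raise ValueError("whittaker_smooth needs at least 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("whittaker_smooth: input contains non-finite values")
    lam = float(10.0 ** lambda_log10)
    if lam == 0.0:
        return y.copy()
    n = y.size
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = (sparse.identity(n, format="csc") + lam * (d2.T @ d2)).tocsc()
    lu = splu(a)
    z = lu.solve(y)
    # iterative refinement with the residual accumulated in extended
    # precision: the system's condition number grows like 16*lam, so large
    # penalties lose digits that a double-precision residual cannot recover
    kernel = np.array([1.0, -2.0, 1.0], dtype=np.longdouble)
    y_ld = y.astype(np.longdouble)
    for _ in range(2):
        z_ld = z.astype(np.longdouble)
        pen = np.convolve(np.diff(z_ld, 2), kernel, mode="full")
        r = y_ld - z_ld - np.longdouble(lam) * pen
        z = z + lu.solve(r.astype(float))
    return z
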