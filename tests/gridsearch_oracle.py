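"""Independent brute-force oracle for the period search.

Solves the constant+sinusoid normal equations explicitly on a dense period
grid — a different code path (3×3 Gram solve, vectorized over periods) from
the package's SVD least squares plus golden-section refinement.
"""

import numpy as np


def dense_grid_period(
    t: np.ndarray,
    y: np.ndarray,
    lo: float = 16.0,
    hi: float = 40.0,
    step: float = 0.001,
) -> tuple[float, float]:
    """Return (argmin period, min SSE) over a dense period grid."""
    periods = np.arange(lo, hi + step / 2, step)
    omega = 2.0 * np.pi / periods[:, None]
    S = np.sin(omega * t)
    C = np.cos(omega * t)
    n = float(t.size)
    A = np.empty((periods.size, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = S.sum(axis=1)
    A[:, 0, 2] = A[:, 2, 0] = C.sum(axis=1)
    A[:, 1, 1] = (S * S).sum(axis=1)
    A[:, 2, 2] = (C * C).sum(axis=1)
    A[:, 1, 2] = A[:, 2, 1] = (S * C).sum(axis=1)
    b = np.empty((periods.size, 3))
    b[:, 0] = y.sum()
    b[:, 1] = S @ y
    b[:, 2] = C @ y
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    sse = float(y @ y) - np.einsum("pi,pi->p", beta, b)
    i = int(np.argmin(sse))
    return float(periods[i]), float(sse[i])
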