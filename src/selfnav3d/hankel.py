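"""Multi-shot multi-coil block-Hankel matrices and low-rank truncation.

The annihilation relations between shots sharing one magnitude image, and
between coils with band-limited sensitivities, make the concatenated
block-Hankel matrix

    H(x) = [ Hshot(x_1)  Hshot(x_2)  ...  Hshot(x_Nshot) ],
    Hshot(x_u) = [ H1(x_u,1)  ...  H1(x_u,Ncoil) ]

rank-deficient.  ``H1`` collects all sliding ``wH x wH`` windows of one 2D
k-space channel as rows; columns are ordered shot-major, coil-minor, window
offsets row-major.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as la
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "build_hankel",
    "adjoint_hankel",
    "hankel_weights",
    "hankel_shape",
    "svd_hard_threshold",
    "randomized_svd",
]


def hankel_shape(nchan: int, n1: int, n2: int, wh: int) -> tuple[int, int]:
    """Shape of the block-Hankel matrix of ``nchan`` channels on an n1 x n2 grid."""
    return ((n1 - wh + 1) * (n2 - wh + 1), nchan * wh * wh)


def build_hankel(x: np.ndarray, wh: int) -> np.ndarray:
    """Block-Hankel matrix of multi-channel 2D k-space.

    Parameters
    ----------
    x : ndarray
        Channel-stacked k-space of shape (..., n1, n2); leading axes (for the
        phase-estimation problem: shot, coil) are flattened into column
        blocks in order.
    wh : int
        Sliding-window (kernel) size.
    """
    n1, n2 = x.shape[-2:]
    if wh > min(n1, n2):
        raise ValueError(f"window {wh} exceeds grid {n1}x{n2}")
    nchan = int(np.prod(x.shape[:-2], dtype=int))
    xc = x.reshape(nchan, n1, n2)
    r1, r2 = n1 - wh + 1, n2 - wh + 1
    out = np.empty((r1, r2, nchan, wh, wh), dtype=x.dtype)
    for dy in range(wh):
        for dx in range(wh):
            out[:, :, :, dy, dx] = xc[:, dy : dy + r1, dx : dx + r2].transpose(1, 2, 0)
    return out.reshape(r1 * r2, nchan * wh * wh)


def adjoint_hankel(m: np.ndarray, shape: tuple[int, ...], wh: int) -> np.ndarray:
    """Exact adjoint of :func:`build_hankel` (overlap-add of window entries)."""
    n1, n2 = shape[-2:]
    nchan = int(np.prod(shape[:-2], dtype=int))
    r1, r2 = n1 - wh + 1, n2 - wh + 1
    mr = m.reshape(r1, r2, nchan, wh, wh)
    out = np.zeros((nchan, n1, n2), dtype=m.dtype)
    for dy in range(wh):
        for dx in range(wh):
            out[:, dy : dy + r1, dx : dx + r2] += mr[:, :, :, dy, dx].transpose(2, 0, 1)
    return out.reshape(shape)


def hankel_weights(n1: int, n2: int, wh: int) -> np.ndarray:
    """Window-multiplicity map: ``adjoint(build(x)) == weights * x`` per channel."""
    ones = np.ones((1, n1, n2))
    return adjoint_hankel(build_hankel(ones, wh), (1, n1, n2), wh)[0].real


def randomized_svd(
    a: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    oversample: int = 10,
    n_power: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded randomized range-finder SVD (top-``rank`` factors)."""
    m, n = a.shape
    p = min(min(m, n), rank + oversample)
    omega = rng.standard_normal((n, p))
    if np.iscomplexobj(a):
        omega = omega + 1j * rng.standard_normal((n, p))
    omega = omega.astype(a.dtype)
    q, _ = la.qr(a @ omega, mode="economic")
    for _ in range(n_power):
        q2, _ = la.qr(a.conj().T @ q, mode="economic")
        q, _ = la.qr(a @ q2, mode="economic")
    b = q.conj().T @ a
    ub, s, vh = la.svd(b, full_matrices=False)
    k = min(rank, s.size)
    return (q @ ub)[:, :k], s[:k], vh[:k]


def svd_hard_threshold(
    m: np.ndarray,
    n_keep: int,
    method: str = "exact",
    rng: np.random.Generator | None = None,
    oversample: int = 10,
    n_power: int = 1,
) -> np.ndarray:
    """Best rank-``n_keep`` approximation by singular-value hard thresholding.

    ``method="exact"`` uses a full LAPACK SVD; ``method="randomized"`` uses a
    seeded randomized SVD (pass ``rng``), appropriate inside iterative
    solvers where the matrix is large and its spectrum decays quickly.
    If ``n_keep`` is at least the smaller matrix dimension the input is
    returned unchanged.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep >= min(m.shape):
        return m.copy()
    if method == "exact":
        u, s, vh = la.svd(m, full_matrices=False)
        u, s, vh = u[:, :n_keep], s[:n_keep], vh[:n_keep]
    elif method == "randomized":
        if rng is None:
            raise ValueError("randomized truncation requires an rng")
        u, s, vh = randomized_svd(m, n_keep, rng, oversample=oversample, n_power=n_power)
    else:
        raise ValueError(f"unknown method {method!r}")
    return (u * s) @ vh
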