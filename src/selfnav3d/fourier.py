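"""Centered, orthonormal Fourier transforms.

Every transform in the package uses the same convention: the DC sample of an
N-point axis sits at index ``N // 2`` and the transform is unitary
(``norm="ortho"``).  This makes energy bookkeeping exact and k-space mask
indices unambiguous.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fftc", "ifftc", "fft2c", "ifft2c", "fftnc", "ifftnc", "center_index"]


def center_index(n: int) -> int:
    """Grid index of the DC sample on an ``n``-point centered axis."""
    return n // 2


def fftc(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def ifftc(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def fftnc(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifftnc(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )
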