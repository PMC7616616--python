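"""SPIRiT self-consistency kernels, coil sensitivity estimation, coil compression.

SPIRiT models every k-space sample as a fixed linear combination of its
multi-coil neighborhood: ``x = G x`` where ``G`` applies one small
(default 5x5) kernel per coil pair.  Kernels are calibrated on fully sampled
calibration data by Tikhonov-regularized least squares, GRAPPA-style, with
the own-coil center weight forced to zero.

Sensitivity maps are estimated with a compact single-map eigenvector method:
the calibration-matrix row space is projected into the image domain and the
leading per-voxel eigenvector of the projection operator gives the map
(soft-weighting and secondary maps are not modeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .fourier import fft2c, ifft2c

__all__ = [
    "SpiritKernel",
    "SensitivityMaps",
    "CalibrationError",
    "calibrate_kernel",
    "apply_kernel",
    "apply_kernel_adjoint",
    "kernel_image_transfer",
    "estimate_sensitivities",
    "fit_coil_compression",
    "compress_coils",
]


class CalibrationError(RuntimeError):
    """Kernel calibration failed (e.g. singular normal equations)."""


@dataclass(frozen=True)
class SpiritKernel:
    """Per-coil-pair k-space interpolation weights.

    ``weights[t, c, dy, dx]`` is the contribution of coil ``c`` at offset
    ``(dy - h, dx - h)`` to coil ``t`` at the center, ``h = size // 2``.
    The own-coil center weight is exactly zero.
    """

    weights: np.ndarray  # (ncoil_out, ncoil_in, size, size)

    @property
    def ncoil(self) -> int:
        return self.weights.shape[0]

    @property
    def size(self) -> int:
        return self.weights.shape[-1]


@dataclass(frozen=True)
class SensitivityMaps:
    """Complex coil maps (ncoil, nx, ny), voxelwise sum-of-squares 1 in support."""

    maps: np.ndarray

    def support(self) -> np.ndarray:
        return (np.abs(self.maps) ** 2).sum(axis=0) > 0.5


def _calibration_matrix(calib: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Rows = vectorized size x size multi-coil patches; targets = patch centers."""
    ncoil = calib.shape[0]
    sw = sliding_window_view(calib, (size, size), axis=(1, 2))  # (nc, wy, wx, size, size)
    a = sw.transpose(1, 2, 0, 3, 4).reshape(-1, ncoil * size * size)
    h = size // 2
    b = calib[:, h : calib.shape[1] - h, h : calib.shape[2] - h]
    b = b.reshape(ncoil, -1).T  # (nrows, ncoil)
    return a, b


def calibrate_kernel(
    calib: np.ndarray, kernel_size: int = 5, tikhonov: float = 1e-4
) -> SpiritKernel:
    """Fit the SPIRiT kernel on fully sampled 2D multi-coil calibration k-space.

    Each k-space point is regressed on its ``kernel_size`` square multi-coil
    neighborhood excluding its own center, with Tikhonov regularization
    ``tikhonov * trace(A^H A) / ncols``.
    """
    ncoil = calib.shape[0]
    if min(calib.shape[1:]) < kernel_size:
        raise CalibrationError("calibration region smaller than the kernel")
    nrows = (calib.shape[1] - kernel_size + 1) * (calib.shape[2] - kernel_size + 1)
    if nrows < ncoil * kernel_size**2:
        raise CalibrationError(
            "calibration region too small to determine the kernel "
            f"({nrows} fit equations for {ncoil * kernel_size**2} weights)"
        )
    a, b = _calibration_matrix(calib, kernel_size)
    aha = a.conj().T @ a
    ahb = a.conj().T @ b
    ncols = aha.shape[0]
    lam = tikhonov * np.real(np.trace(aha)) / ncols
    h = kernel_size // 2
    weights = np.zeros((ncoil, ncoil, kernel_size, kernel_size), dtype=complex)
    for t in range(ncoil):
        center_col = t * kernel_size * kernel_size + h * kernel_size + h
        keep = np.delete(np.arange(ncols), center_col)
        lhs = aha[np.ix_(keep, keep)]
        if lam == 0 and np.linalg.matrix_rank(lhs) < lhs.shape[0]:
            raise CalibrationError(
                "singular calibration normal equations; use tikhonov > 0"
            )
        rhs = ahb[keep, t]
        w = la.solve(lhs + lam * np.eye(len(keep)), rhs, assume_a="pos")
        full = np.zeros(ncols, dtype=complex)
        full[keep] = w
        weights[t] = full.reshape(ncoil, kernel_size, kernel_size)
    return SpiritKernel(weights=weights)


def apply_kernel(g: SpiritKernel, x: np.ndarray) -> np.ndarray:
    """Apply ``G`` to multi-coil 2D k-space ``x`` (ncoil, ny, nx).

    Correlation with the calibrated neighborhood weights, zero-padded
    borders.  Linear, with the exact adjoint in :func:`apply_kernel_adjoint`.
    """
    if x.shape[0] != g.ncoil:
        raise ValueError("coil count mismatch")
    out = np.zeros_like(x, dtype=complex)
    for t in range(g.ncoil):
        for c in range(g.ncoil):
            # target(k) = sum_d w[d] x(k + d)  -> correlation
            out[t] += ndimage.correlate(
                x[c].real, g.weights[t, c].real, mode="constant"
            ) - ndimage.correlate(x[c].imag, g.weights[t, c].imag, mode="constant") + 1j * (
                ndimage.correlate(x[c].real, g.weights[t, c].imag, mode="constant")
                + ndimage.correlate(x[c].imag, g.weights[t, c].real, mode="constant")
            )
    return out


def apply_kernel_adjoint(g: SpiritKernel, y: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`apply_kernel`."""
    flipped = np.conj(g.weights[:, :, ::-1, ::-1]).transpose(1, 0, 2, 3)
    return apply_kernel(SpiritKernel(weights=flipped), y)


def kernel_image_transfer(g: SpiritKernel, nx: int, ny: int) -> np.ndarray:
    """Image-domain transfer matrices ``T`` of the circular realization of G.

    Returns ``T`` of shape (nx, ny, ncoil_out, ncoil_in) such that for
    ``x = fft2c(img)`` per coil, ``G x == fft2c(einsum('xyab,b...->a...'))``
    up to circular boundary wrap.  Used by iterative solvers where applying
    G every iteration in k-space would be wasteful.
    """
    nc, size = g.ncoil, g.size
    h = size // 2
    pad = np.zeros((nc, nc, nx, ny), dtype=complex)
    cx, cy = nx // 2, ny // 2
    # correlation with w == convolution with w flipped; place flipped kernel
    pad[:, :, cx - h : cx + h + 1, cy - h : cy + h + 1] = g.weights[:, :, ::-1, ::-1]
    t = ifft2c(pad) * np.sqrt(nx * ny)
    return t.transpose(2, 3, 0, 1)


def estimate_sensitivities(
    calib_kz0: np.ndarray,
    crop_threshold: float = 0.8,
    kernel_size: int = 6,
    acs: int = 24,
    sv_threshold: float = 1e-3,
) -> SensitivityMaps:
    """Eigenvector coil sensitivity estimation from central calibration k-space.

    The central ``acs`` square of the fully sampled kz=0 calibration data is
    assembled into a block-Hankel calibration matrix; its dominant right
    singular vectors (relative singular value >= ``sv_threshold``) are mapped
    to image space, and the leading eigenvector of the resulting per-voxel
    projection operator gives the sensitivity.  Voxels whose leading
    eigenvalue falls below ``crop_threshold`` (relative to the ideal value 1)
    are zeroed.  Maps are phase-referenced to coil 1 and sum-of-squares
    normalized inside the support.
    """
    ncoil, nx, ny = calib_kz0.shape
    acs = min(acs, nx, ny)
    cx, cy = nx // 2, ny // 2
    lo_x, lo_y = cx - acs // 2, cy - acs // 2
    region = calib_kz0[:, lo_x : lo_x + acs, lo_y : lo_y + acs]
    a, _ = _calibration_matrix(region, kernel_size)
    _, s, vh = la.svd(a, full_matrices=False)
    keep = s >= sv_threshold * s[0]
    v = vh[keep].conj()  # (nkern, ncoil*size*size)
    nkern = v.shape[0]
    kernels = v.reshape(nkern, ncoil, kernel_size, kernel_size)
    # embed kernels at the spectrum center and move to image space
    pad = np.zeros((nkern, ncoil, nx, ny), dtype=complex)
    h = kernel_size // 2
    pad[:, :, cx - h : cx + h + kernel_size % 2, cy - h : cy + h + kernel_size % 2] = kernels[
        :, :, ::-1, ::-1
    ]
    imgs = ifft2c(pad) * np.sqrt(nx * ny) / kernel_size
    # per-voxel ncoil x ncoil projection operator and its leading eigenvector
    gg = np.einsum("kaxy,kbxy->xyab", imgs.conj(), imgs)
    evals, evecs = np.linalg.eigh(gg)
    lead_val = evals[:, :, -1]
    lead_vec = evecs[:, :, :, -1]  # (nx, ny, ncoil)
    maps = lead_vec.transpose(2, 0, 1)
    mask = lead_val > crop_threshold
    maps = maps * mask[None]
    # phase-reference to coil 1, unit sum-of-squares where supported
    ref = np.exp(-1j * np.angle(maps[0]))
    maps = maps * ref[None]
    norm = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps = np.where(norm[None] > 0, maps / np.where(norm[None] == 0, 1, norm[None]), 0)
    return SensitivityMaps(maps=maps)


def fit_coil_compression(calib: np.ndarray, target: int) -> np.ndarray:
    """SVD coil-compression matrix (target, ncoil) with orthonormal rows."""
    ncoil = calib.shape[0]
    if not 1 <= target <= ncoil:
        raise ValueError(f"target coil count must be in [1, {ncoil}]")
    x = calib.reshape(ncoil, -1)
    u, _, _ = la.svd(x, full_matrices=False)
    return u[:, :target].conj().T


def compress_coils(
    kspace: np.ndarray, target: int = 8, calib: np.ndarray | None = None, coil_axis: int = 0
) -> np.ndarray:
    """Compress the coil dimension of ``kspace`` to ``target`` virtual coils.

    The compression is fitted on ``calib`` (or on the data itself) and applied
    as a unitary-row rotation, so it can be used consistently on calibration
    and imaging data.
    """
    c = fit_coil_compression(calib if calib is not None else kspace, target)
    moved = np.moveaxis(kspace, coil_axis, 0)
    out = np.tensordot(c, moved, axes=(1, 0))
    return np.moveaxis(out, 0, coil_axis)
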