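"""Phase-corrected multi-shot SPIRiT reconstruction of the 3D slab.

Solves

    argmin_X  sum_j || M_j F phi_dj F^-1 X - y_j ||^2 + lam4 ||(G_slab - I) X||^2

by fixed-budget conjugate gradient on the normal equations.  The shot phases
``phi_dj`` are unit-magnitude 2D maps broadcast along z, so after a Fourier
transform along kx the problem decouples exactly into independent ky-kz
planes; ``G_slab`` is a per-x SPIRiT kernel trained on calibration data in the
same hybrid (x, ky, kz) space.  The slab image is the voxelwise
root-sum-of-squares of the coil images of the solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import fftc, fftnc, ifftc, ifftnc
from .simulate import KSpaceData
from .slr import conjugate_gradient
from .spirit import SpiritKernel, calibrate_kernel, kernel_image_transfer

__all__ = [
    "CorrectedKspace",
    "calibrate_slab_kernels",
    "slab_transfer",
    "forward_operator",
    "adjoint_operator",
    "reconstruct_slab",
    "sos_combine",
    "nrmse",
    "phase_mae",
    "combine_overlapping_slabs",
]

_AXES3 = (-3, -2, -1)


@dataclass
class CorrectedKspace:
    """Phase-error-corrected multi-coil 3D k-space (ncoil, nx, ny, nkz)."""

    data: np.ndarray


def calibrate_slab_kernels(
    calib_hybrid: np.ndarray, kernel_size: int = 5, tikhonov: float = 1e-4
) -> list[SpiritKernel]:
    """Train one ky-kz SPIRiT kernel per x position of hybrid-space calibration.

    ``calib_hybrid``: (ncoil, x, ky, kz) — calibration k-space after an
    inverse FFT along kx.
    """
    return [
        calibrate_kernel(calib_hybrid[:, ix], kernel_size=kernel_size, tikhonov=tikhonov)
        for ix in range(calib_hybrid.shape[1])
    ]


def slab_transfer(kernels: list[SpiritKernel], ny: int, nkz: int) -> np.ndarray:
    """Stacked per-x image-domain normal matrices of (G_slab - I).

    Returns (nx, ny, nkz, ncoil, ncoil) such that the SPIRiT normal term is a
    per-voxel coil mixing in (x, y, z) image space.
    """
    mats = []
    eye = np.eye(kernels[0].ncoil)
    for g in kernels:
        t = kernel_image_transfer(g, ny, nkz) - eye[None, None]
        mats.append(np.einsum("yzba,yzbc->yzac", t.conj(), t))
    return np.stack(mats)


def _check_phases(phases: np.ndarray) -> None:
    if not np.allclose(np.abs(phases), 1.0, atol=1e-6):
        raise ValueError("shot phase maps must have unit magnitude")


def forward_operator(x: np.ndarray, phases: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Per-shot sampled k-space from corrected k-space ``x``.

    ``x``: (ncoil, nx, ny, nkz); ``phases``: unit-magnitude (nshot, nx, ny)
    broadcast along coil and z; ``masks``: (nshot, ny, nkz).
    """
    _check_phases(phases)
    img = ifftnc(x, axes=_AXES3)
    out = np.empty((phases.shape[0],) + x.shape, dtype=complex)
    for j in range(phases.shape[0]):
        shot_img = img * phases[j][None, :, :, None]
        out[j] = fftnc(shot_img, axes=_AXES3) * masks[j][None, None]
    return out


def adjoint_operator(y: np.ndarray, phases: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`forward_operator`."""
    _check_phases(phases)
    acc = np.zeros(y.shape[1:], dtype=complex)
    for j in range(phases.shape[0]):
        img = ifftnc(y[j] * masks[j][None, None], axes=_AXES3)
        acc += img * np.conj(phases[j])[None, :, :, None]
    return fftnc(acc, axes=_AXES3)


def reconstruct_slab(
    kspace: KSpaceData,
    phases: np.ndarray,
    slab_normal: np.ndarray | None,
    lam4: float = 1e-4,
    cg_iters: int = 30,
) -> CorrectedKspace:
    """Phase-corrected multi-shot reconstruction by CG on the normal equations.

    The data are Fourier-transformed along kx and each (ky, kz) plane is
    solved independently with its own fixed-budget CG — the decoupling along
    x is exact because the phases vary only in (x, y).  ``slab_normal`` is
    the per-voxel (G_slab - I)^H (G_slab - I) stack from
    :func:`slab_transfer` (``None`` disables the SPIRiT term).
    """
    _check_phases(phases)
    nshot = phases.shape[0]
    ncoil, nx, ny, nkz = kspace.data.shape[1:]
    masks = kspace.masks.astype(float)[:, None, :, :]  # (nshot, 1, ny, nkz)
    y_hyb = ifftc(kspace.data, axis=2)  # (nshot, ncoil, x, ky, kz)
    axes2 = (-2, -1)

    out = np.empty((ncoil, nx, ny, nkz), dtype=complex)
    for ix in range(nx):
        ph = phases[:, ix, :]  # (nshot, ny)
        yx = y_hyb[:, :, ix]  # (nshot, ncoil, ny, nkz)

        def fwd(v: np.ndarray) -> np.ndarray:
            img = np.fft.fftshift(
                np.fft.ifft2(np.fft.ifftshift(v, axes=axes2), axes=axes2, norm="ortho"),
                axes=axes2,
            )
            shot = img[None] * ph[:, None, :, None]
            k = np.fft.fftshift(
                np.fft.fft2(np.fft.ifftshift(shot, axes=axes2), axes=axes2, norm="ortho"),
                axes=axes2,
            )
            return k * masks

        def adj(d: np.ndarray) -> np.ndarray:
            img = np.fft.fftshift(
                np.fft.ifft2(np.fft.ifftshift(d * masks, axes=axes2), axes=axes2, norm="ortho"),
                axes=axes2,
            )
            acc = (img * np.conj(ph)[:, None, :, None]).sum(axis=0)
            return np.fft.fftshift(
                np.fft.fft2(np.fft.ifftshift(acc, axes=axes2), axes=axes2, norm="ortho"),
                axes=axes2,
            )

        if slab_normal is not None and lam4 > 0:
            npix = slab_normal[ix]  # (ny, nkz, ncoil, ncoil)

            def operator(v: np.ndarray) -> np.ndarray:
                img = np.fft.fftshift(
                    np.fft.ifft2(np.fft.ifftshift(v, axes=axes2), axes=axes2, norm="ortho"),
                    axes=axes2,
                )
                mixed = np.einsum("yzab,byz->ayz", npix, img)
                sp = np.fft.fftshift(
                    np.fft.fft2(np.fft.ifftshift(mixed, axes=axes2), axes=axes2, norm="ortho"),
                    axes=axes2,
                )
                return adj(fwd(v)) + lam4 * sp

        else:

            def operator(v: np.ndarray) -> np.ndarray:
                return adj(fwd(v))

        out[:, ix] = conjugate_gradient(operator, adj(yx), iters=cg_iters)
    return CorrectedKspace(data=fftc(out, axis=1))


def sos_combine(x: CorrectedKspace | np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination of the inverse-FFT slab image."""
    data = x.data if isinstance(x, CorrectedKspace) else x
    img = ifftnc(data, axes=_AXES3)
    return np.sqrt((np.abs(img) ** 2).sum(axis=0))


def nrmse(recon: np.ndarray, reference: np.ndarray) -> float:
    """L2 error of magnitude volumes normalized by the reference norm."""
    ref = np.linalg.norm(reference)
    if ref == 0:
        raise ValueError("reference has zero norm")
    return float(np.linalg.norm(np.asarray(recon) - np.asarray(reference)) / ref)


def phase_mae(est: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Circular mean absolute phase error over shots inside a spatial mask.

    ``est``/``truth`` are complex unit-phase (or will be normalized) maps of
    shape (nshot, nx, ny).  Each shot's global phase offset is removed before
    averaging, matching how shot phases are only defined relative to the
    reference shot.
    """
    if est.shape != truth.shape:
        raise ValueError("shape mismatch")
    e = np.exp(1j * np.angle(est))
    t = np.exp(1j * np.angle(truth))
    errs = []
    for j in range(e.shape[0]):
        d = e[j, mask] * np.conj(t[j, mask])
        offset = np.angle(d.sum())
        errs.append(np.abs(np.angle(d * np.exp(-1j * offset))))
    return float(np.concatenate(errs).mean())


def combine_overlapping_slabs(slabs: list[np.ndarray], overlap: int) -> np.ndarray:
    """Concatenate slab magnitude volumes along z, averaging overlapped slices."""
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if not slabs:
        raise ValueError("no slabs")
    out = slabs[0].astype(float)
    for nxt in slabs[1:]:
        if overlap > 0:
            shared = 0.5 * (out[..., -overlap:] + nxt[..., :overlap])
            out = np.concatenate([out[..., :-overlap], shared, nxt[..., overlap:]], axis=-1)
        else:
            out = np.concatenate([out, nxt], axis=-1)
    return out
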