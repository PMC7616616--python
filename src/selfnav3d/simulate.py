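"""Synthetic multi-coil, multi-shot k-space data for 3D multi-slab diffusion MRI.

Implements the acquisition forward model: for shot ``j`` and coil ``v``

    y_jv = M_j F ( S_v * exp(i psi_j) * rho ) + n_jv

where ``rho`` is the motion-phase-free complex slab image, ``S_v`` a smooth
coil sensitivity with limited k-space support, ``psi_j`` a smooth 2D
shot-dependent motion phase (broadcast along z — the thin-slab
approximation), ``M_j`` the shot's (ky, kz) line mask with fully sampled kx
readouts, and ``n`` i.i.d. complex Gaussian noise.  All transforms are
centered and orthonormal.

Every generator is deterministic for a given seed, so downstream stages are
testable without any acquired data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import fft2c, fftnc, ifft2c, ifftnc
from .sampling import SamplingConfig, ShotPattern

__all__ = [
    "SlabPhantom",
    "CoilSensitivities",
    "ShotPhaseSet",
    "NoiseSpec",
    "KSpaceData",
    "make_phantom",
    "make_sensitivities",
    "make_shot_phases",
    "encode",
    "encode_forward",
    "encode_adjoint",
    "make_calibration",
    "calibration_kz0",
    "calibration_per_x",
]


@dataclass(frozen=True)
class SlabPhantom:
    """Complex slab image volume ``rho`` of shape (nx, ny, nz)."""

    image: np.ndarray

    @property
    def projection(self) -> np.ndarray:
        """Unit-scaled z-sum: the image whose spectrum is the central kz plane."""
        return self.image.sum(axis=-1) / np.sqrt(self.image.shape[-1])


@dataclass(frozen=True)
class CoilSensitivities:
    """Complex coil maps with limited centered k-space support.

    ``maps`` is (ncoil, nx, ny) for thin-slab 2D maps (spectrum exactly zero
    outside the central ``s x s`` block) or (ncoil, nx, ny, nz) for 3D maps
    with an additional small kz support.
    """

    maps: np.ndarray
    support: int  # in-plane k-space support size s (odd)

    @property
    def ncoil(self) -> int:
        return self.maps.shape[0]

    @property
    def is3d(self) -> bool:
        return self.maps.ndim == 4

    def maps3d(self, nz: int) -> np.ndarray:
        """(ncoil, nx, ny, nz) maps; 2D maps broadcast along the slab."""
        if self.is3d:
            if self.maps.shape[-1] != nz:
                raise ValueError("slab thickness mismatch")
            return self.maps
        return np.broadcast_to(self.maps[:, :, :, None], self.maps.shape + (nz,))

    def sos(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


@dataclass(frozen=True)
class ShotPhaseSet:
    """Real 2D motion-phase maps psi_j (nshot, nx, ny), radians.

    Shot 1 (the kz0 traversal shot) is the phase reference, ``psi_1 == 0``.
    """

    psi: np.ndarray

    @property
    def phasors(self) -> np.ndarray:
        return np.exp(1j * self.psi)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive complex Gaussian noise: std ``sigma`` per real/imag channel."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class KSpaceData:
    """Acquired multi-shot multi-coil k-space with its sampling masks.

    ``data`` has shape (nshot, ncoil, nx, ny, nkz), zero at unacquired
    positions; ``masks`` has shape (nshot, ny, nkz) (kx is fully sampled).
    """

    data: np.ndarray
    masks: np.ndarray

    @property
    def nshot(self) -> int:
        return self.data.shape[0]

    @property
    def ncoil(self) -> int:
        return self.data.shape[1]


def make_phantom(nx: int, ny: int, nz: int, seed: int = 0) -> SlabPhantom:
    """Deterministic complex slab phantom.

    Overlapping ellipsoids with piecewise-constant magnitude in [0, 1], a
    smooth low-order background phase, and a tapered slab profile along z.
    All support lies strictly inside the central 90% box.
    """
    if nx < 16 or ny < 16:
        raise ValueError("in-plane dims must be >= 16")
    if nz < 4:
        raise ValueError("nz must be >= 4")
    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx, endpoint=False),
        np.linspace(-1, 1, ny, endpoint=False),
        np.linspace(-1, 1, nz, endpoint=False),
        indexing="ij",
    )
    mag = np.zeros((nx, ny, nz))
    # outer "head" ellipsoid, then interior structures overriding the level
    mag[(x / 0.72) ** 2 + (y / 0.80) ** 2 + (z / 0.88) ** 2 < 1] = 0.8
    for _ in range(6):
        c = rng.uniform(-0.35, 0.35, size=3)
        ax = rng.uniform(0.08, 0.3, size=3)
        level = rng.uniform(0.2, 1.0)
        inside = ((x - c[0]) / ax[0]) ** 2 + ((y - c[1]) / ax[1]) ** 2 + (
            (z - c[2]) / ax[2]
        ) ** 2 < 1
        mag[inside] = level
    # slab excitation profile: flat center, smooth taper at slab edges
    profile = np.clip(1.25 * np.cos(0.5 * np.pi * z**1.0) ** 0.5, 0, 1)
    mag *= profile
    coef = rng.uniform(-1, 1, size=6)
    phase = 0.9 * (
        coef[0] * x + coef[1] * y + coef[2] * z + coef[3] * x * y + coef[4] * x * x + coef[5] * y * z
    )
    return SlabPhantom(mag * np.exp(1j * phase))


def make_sensitivities(
    ncoil: int,
    nx: int,
    ny: int,
    s: int = 5,
    seed: int = 0,
    nz: int | None = None,
    sz: int = 3,
) -> CoilSensitivities:
    """Smooth coil maps synthesized directly on a limited k-space support.

    With ``nz=None`` (thin-slab 2D maps) each coil's centered spectrum is
    exactly zero outside the central ``s x s`` block, so the coil rank bound
    of the multi-coil block-Hankel matrix holds by construction.  With ``nz``
    given, 3D maps are synthesized on an ``s x s x sz`` support — the gentle
    through-slab variation a real receive array exhibits, which gives the
    slab SPIRiT kernel its resolving power along kz.  Maps are globally
    scaled so the mean voxelwise sum-of-squares is 1.
    """
    if s % 2 == 0:
        raise ValueError("k-space support size s must be odd")
    if s > min(nx, ny) / 4:
        raise ValueError("support size too large for the grid")
    rng = np.random.default_rng(seed)
    h = s // 2
    t = np.hanning(s + 2)[1:-1]
    taper = np.outer(t, t)
    coeff = (rng.standard_normal((ncoil, s, s)) + 1j * rng.standard_normal((ncoil, s, s))) * taper
    coeff *= 0.6
    # dominant DC term per coil: maps are variations around a flat profile
    coeff[:, h, h] = 2.0 * np.exp(1j * rng.uniform(-np.pi, np.pi, ncoil))
    if nz is None:
        k = np.zeros((ncoil, nx, ny), dtype=complex)
        k[:, nx // 2 - h : nx // 2 + h + 1, ny // 2 - h : ny // 2 + h + 1] = coeff
        maps = ifft2c(k)
    else:
        if sz % 2 == 0 or sz > nz:
            raise ValueError("sz must be odd and at most nz")
        hz = sz // 2
        cz = nz // 2
        kz_taper = np.hanning(sz + 2)[1:-1]
        coeff_z = (
            rng.standard_normal((ncoil, s, s, sz)) + 1j * rng.standard_normal((ncoil, s, s, sz))
        ) * (taper[:, :, None] * kz_taper[None, None, :])
        coeff_z *= 0.25
        coeff_z[:, :, :, hz] = coeff  # DC kz plane carries the 2D profile
        k = np.zeros((ncoil, nx, ny, nz), dtype=complex)
        k[
            :,
            nx // 2 - h : nx // 2 + h + 1,
            ny // 2 - h : ny // 2 + h + 1,
            cz - hz : cz + hz + 1,
        ] = coeff_z
        maps = ifftnc(k, axes=(-3, -2, -1))
    sos2 = (np.abs(maps) ** 2).sum(axis=0)
    maps /= np.sqrt(sos2.mean())
    return CoilSensitivities(maps=maps, support=s)


def make_shot_phases(
    nshot: int, nx: int, ny: int, amplitude: float = 2.0, seed: int = 0
) -> ShotPhaseSet:
    """Smooth band-limited 2D motion phases, one map per shot.

    Each map (except shot 1, the zero reference) is a random superposition of
    plane waves with at most 2 cycles across the FOV — a ramp-like tilt plus
    gentle sinusoidal structure — scaled so the peak |psi| is at most
    ``amplitude`` radians.  Band-limitation is exact: the spectrum lives on
    the central 5x5 block.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(nx) / nx, np.arange(ny) / ny, indexing="ij")
    freqs = [(fx, fy) for fx in range(-2, 3) for fy in range(-2, 3)]
    psi = np.zeros((nshot, nx, ny))
    for j in range(1, nshot):
        field = np.zeros((nx, ny))
        for fx, fy in freqs:
            if fx == 0 and fy == 0:
                continue
            weight = 1.0 / (1.0 + fx * fx + fy * fy)
            c = rng.standard_normal() + 1j * rng.standard_normal()
            field += weight * np.real(c * np.exp(2j * np.pi * (fx * gx + fy * gy)))
        peak = np.abs(field).max()
        if peak > 0 and amplitude > 0:
            field *= amplitude * rng.uniform(0.7, 1.0) / peak
        else:
            field[:] = 0.0
        psi[j] = field
    return ShotPhaseSet(psi)


def _shot_volume(
    phantom: SlabPhantom, sens: CoilSensitivities, phasor_2d: np.ndarray
) -> np.ndarray:
    """(ncoil, nx, ny, nz) coil-weighted, phase-modulated image volume."""
    maps = sens.maps3d(phantom.image.shape[-1])
    return maps * phasor_2d[None, :, :, None] * phantom.image[None]


def encode_forward(
    image: np.ndarray,
    sens: CoilSensitivities,
    phases: ShotPhaseSet,
    masks: np.ndarray,
) -> np.ndarray:
    """Noiseless forward model applied to an arbitrary volume ``image``."""
    nshot = phases.psi.shape[0]
    out = np.empty((nshot, sens.ncoil) + image.shape, dtype=complex)
    for j in range(nshot):
        vol = _shot_volume(SlabPhantom(image), sens, np.exp(1j * phases.psi[j]))
        out[j] = fftnc(vol, axes=(-3, -2, -1)) * masks[j][None, None, :, :]
    return out


def encode_adjoint(
    y: np.ndarray,
    sens: CoilSensitivities,
    phases: ShotPhaseSet,
    masks: np.ndarray,
) -> np.ndarray:
    """Exact adjoint of :func:`encode_forward` (maps data back to a volume)."""
    nshot = y.shape[0]
    out = np.zeros(y.shape[2:], dtype=complex)
    maps = sens.maps3d(y.shape[-1])
    for j in range(nshot):
        vol = ifftnc(y[j] * masks[j][None, None, :, :], axes=(-3, -2, -1))
        weighted = np.conj(maps * np.exp(1j * phases.psi[j])[None, :, :, None])
        out += (weighted * vol).sum(axis=0)
    return out


def encode(
    phantom: SlabPhantom,
    sens: CoilSensitivities,
    phases: ShotPhaseSet,
    patterns: list[ShotPattern],
    config: SamplingConfig,
    noise: NoiseSpec = NoiseSpec(),
) -> KSpaceData:
    """Simulate the multi-shot multi-coil acquisition of a slab."""
    nx, ny, nz = phantom.image.shape
    if sens.maps.shape[1:3] != (nx, ny):
        raise ValueError("sensitivity maps do not match the phantom grid")
    if phases.psi.shape[0] != len(patterns):
        raise ValueError("number of phase maps does not match number of shots")
    if config.ny != ny or config.nkz != nz:
        raise ValueError("sampling configuration does not match the phantom grid")
    masks = np.stack([p.mask(config) for p in patterns]).astype(bool)
    data = encode_forward(phantom.image, sens, phases, masks)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        n = noise.sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data += n * masks[:, None, None, :, :]
    return KSpaceData(data=data, masks=masks)


def make_calibration(phantom: SlabPhantom, sens: CoilSensitivities) -> np.ndarray:
    """Fully sampled multi-coil calibration k-space (ncoil, nx, ny, nkz).

    Emulates a motion-phase-free gradient-echo coil calibration scan:
    ``S_v * rho`` including the object's static background phase (a property
    of the field, shared by every acquisition of the same object) but no
    shot-dependent motion phase.  Identical for any shot-phase realization.
    """
    vol = sens.maps3d(phantom.image.shape[-1]) * phantom.image[None]
    return fftnc(vol, axes=(-3, -2, -1))


def calibration_kz0(calib: np.ndarray) -> np.ndarray:
    """Central-kz-plane calibration: fully sampled (ncoil, kx, ky) k-space."""
    return calib[:, :, :, calib.shape[-1] // 2]


def calibration_per_x(calib: np.ndarray) -> np.ndarray:
    """Hybrid-space calibration (ncoil, x, ky, kz) for per-x kernel training."""
    from .fourier import ifftc

    return ifftc(calib, axis=1)
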