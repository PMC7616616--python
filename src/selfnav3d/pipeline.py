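"""End-to-end benchmark pipeline: simulate, design, calibrate, estimate, reconstruct.

The benchmark emulates the retrospective evaluation protocol: a known slab,
known coil maps and known shot phases are encoded with the optimized
extended-CAIPI sampling; the shot phases are then re-estimated from the
self-navigation points alone and used in the phase-corrected multi-shot
reconstruction.  Reported metrics compare phase maps against the simulated
truth and magnitude reconstructions against the fully sampled reference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from time import perf_counter

import numpy as np

from .fourier import ifftnc
from .hankel import hankel_shape
from .metrics_support import support_mask
from .recon import (
    calibrate_slab_kernels,
    nrmse,
    phase_mae,
    reconstruct_slab,
    slab_transfer,
    sos_combine,
)
from .sampling import (
    SamplingConfig,
    SamplingMaskSet,
    gap_metric,
    greedy_optimize,
    nav_distance,
    overlap_metric,
)
from .simulate import (
    KSpaceData,
    NoiseSpec,
    encode,
    make_calibration,
    make_phantom,
    make_sensitivities,
    make_shot_phases,
    calibration_kz0,
    calibration_per_x,
)
from .slr import (
    AdmmParams,
    admm_solve,
    extract_phase,
    extract_selfnav,
    magnitude_reference,
)
from .spirit import calibrate_kernel, estimate_sensitivities, SensitivityMaps

__all__ = ["RunConfig", "BenchmarkReport", "SimulatedSlab", "simulate_slab", "run_benchmark"]


@dataclass
class RunConfig:
    """All geometry, simulation and solver settings of one benchmark run."""

    # geometry (desk-scale defaults)
    nx: int = 64
    ny: int = 64
    nkz: int = 12
    ncoil: int = 8
    nshot: int = 12
    ry: int = 3
    pf: float = 1.0
    # sampling
    dmax: float = 15.0
    # simulation
    phase_amplitude: float = 2.0
    noise_sigma: float = 0.0
    sens_support: int = 5
    seed: int = 0
    # reconstruction
    admm: AdmmParams = field(default_factory=lambda: AdmmParams(n_keep=196))
    lam4: float = 1.0
    recon_cg_iters: int = 100
    filter_window: int = 32
    sensitivities: str = "estimated"  # or "truth"
    # optional stages; ablation arms share one reduced, equal ADMM budget
    run_ablations: bool = False
    run_shot_drop: bool = False
    ablation_admm_iters: int = 15

    def sampling_config(self) -> SamplingConfig:
        return SamplingConfig(
            ny=self.ny, nkz=self.nkz, nshot=self.nshot, ry=self.ry, pf=self.pf, dmax=self.dmax
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["admm"]["dtype"] = np.dtype(self.admm.dtype).name
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        admm = dict(d.pop("admm", {}))
        if "dtype" in admm:
            admm["dtype"] = np.dtype(admm["dtype"]).type
        return cls(admm=AdmmParams(**admm), **d)


@dataclass
class SimulatedSlab:
    """Ground truth plus acquired data for one synthetic slab."""

    config: RunConfig
    sampling: SamplingConfig
    patterns: list
    phantom: object
    sens: object
    phases: object
    kspace: KSpaceData
    calib: np.ndarray

    @property
    def reference_sos(self) -> np.ndarray:
        """Fully sampled coil-weighted magnitude reference."""
        vol = self.sens.maps3d(self.phantom.image.shape[-1]) * self.phantom.image[None]
        return np.sqrt((np.abs(vol) ** 2).sum(axis=0))

    def support(self) -> np.ndarray:
        """In-plane support mask of the slab (projection magnitude)."""
        return support_mask(np.abs(self.phantom.projection))


@dataclass
class BenchmarkReport:
    """Per-method metrics and traces from one benchmark run."""

    config: dict
    sampling_metrics: dict
    phase_metrics: dict
    recon_metrics: dict
    traces: dict
    runtime_s: dict

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_slab(config: RunConfig, patterns: list | None = None) -> SimulatedSlab:
    """Generate ground truth, design the sampling, and encode the k-space."""
    sampling = config.sampling_config()
    if patterns is None:
        patterns = greedy_optimize(sampling)
    phantom = make_phantom(config.nx, config.ny, config.nkz, seed=config.seed)
    sens = make_sensitivities(
        config.ncoil,
        config.nx,
        config.ny,
        s=config.sens_support,
        seed=config.seed + 1,
        nz=config.nkz,
    )
    phases = make_shot_phases(
        config.nshot, config.nx, config.ny, amplitude=config.phase_amplitude, seed=config.seed + 2
    )
    kspace = encode(
        phantom,
        sens,
        phases,
        patterns,
        sampling,
        NoiseSpec(sigma=config.noise_sigma, seed=config.seed + 3),
    )
    calib = make_calibration(phantom, sens)
    return SimulatedSlab(
        config=config,
        sampling=sampling,
        patterns=patterns,
        phantom=phantom,
        sens=sens,
        phases=phases,
        kspace=kspace,
        calib=calib,
    )


def _relative_phases(phi: np.ndarray, ref: int = 0) -> np.ndarray:
    """Phase maps relative to a reference shot (removes shared spatial phase)."""
    return phi * np.conj(phi[ref])[None]


def estimate_shot_phases(
    sim: SimulatedSlab,
    variant: str = "full",
    drop_shot: int | None = None,
    admm: AdmmParams | None = None,
    callback=None,
):
    """Run the SLR phase estimation on a simulated slab.

    Returns ``(phases_unit, result, kept)`` where ``phases_unit`` are the raw
    (unfiltered) unit-magnitude maps for the kept shots and ``kept`` the kept
    shot indices.  Dropping the kz0 traversal shot disables the magnitude
    reference.
    """
    config = sim.config
    y, ky_masks = extract_selfnav(sim.kspace, sim.sampling)
    kept = [j for j in range(config.nshot) if j != drop_shot]
    y = y[kept]
    ky = ky_masks[kept]

    gkz0 = calibrate_kernel(calibration_kz0(sim.calib), kernel_size=5)
    if config.sensitivities == "truth":
        eff = (sim.sens.maps3d(config.nkz) * sim.phantom.image[None]).sum(axis=-1)
        norm = np.sqrt((np.abs(eff) ** 2).sum(axis=0))
        sens = SensitivityMaps(maps=eff / np.maximum(norm, 1e-12)[None])
    else:
        sens = estimate_sensitivities(calibration_kz0(sim.calib))

    has_traversal = 0 in kept
    m_prime = None
    if has_traversal:
        tr = kept.index(0)
        m_prime = magnitude_reference(y[tr], ky[tr], gkz0)

    result = admm_solve(
        y,
        ky,
        gkz0,
        m_prime,
        sens,
        params=admm if admm is not None else sim.config.admm,
        variant=variant,
        traversal_index=kept.index(0) if has_traversal else None,
        callback=callback,
    )
    phi = extract_phase(result.xhat, sens)
    return phi, result, kept


def _phase_error(sim: SimulatedSlab, phi: np.ndarray, kept: list[int]) -> float:
    """Circular MAE of estimated vs true phases, relative to the first kept shot."""
    support = sim.support()
    rel_est = _relative_phases(phi, ref=0)
    truth = np.exp(1j * sim.phases.psi[kept])
    rel_truth = _relative_phases(truth, ref=0)
    return phase_mae(rel_est[1:], rel_truth[1:], support)


def run_benchmark(config: RunConfig) -> BenchmarkReport:
    """Full benchmark: simulate, estimate phases, reconstruct, evaluate."""
    times: dict[str, float] = {}
    t0 = perf_counter()
    sim = simulate_slab(config)
    times["simulate"] = perf_counter() - t0

    masks = SamplingMaskSet.from_patterns(sim.patterns, sim.sampling)
    nshot = config.nshot
    sampling_metrics = {
        "overlap_per_step": [overlap_metric(masks, i) for i in range(1, nshot + 1)],
        "gap_per_step": [gap_metric(masks, i) for i in range(1, nshot + 1)],
        "nav_distance_per_shot": [nav_distance(p, sim.sampling) for p in sim.patterns],
        "hankel_shape": list(
            hankel_shape(nshot * config.ncoil, config.nx, config.ny, config.admm.wh)
        ),
    }

    t0 = perf_counter()
    phi_full, result_full, kept = estimate_shot_phases(sim, variant="full")
    times["slr_full"] = perf_counter() - t0

    support = sim.support()
    phase_metrics = {"full": _phase_error(sim, phi_full, kept)}
    traces = {"full": result_full.log}

    t0 = perf_counter()
    calib_hybrid = calibration_per_x(sim.calib)
    kernels = calibrate_slab_kernels(calib_hybrid)
    slab_normal = slab_transfer(kernels, config.ny, config.nkz)
    times["calibrate_slab"] = perf_counter() - t0

    reference = sim.reference_sos

    def run_recon(phases_unit: np.ndarray) -> float:
        rec = reconstruct_slab(
            sim.kspace, phases_unit, slab_normal, lam4=config.lam4, cg_iters=config.recon_cg_iters
        )
        return nrmse(sos_combine(rec), reference)

    t0 = perf_counter()
    ones = np.ones((nshot, config.nx, config.ny), dtype=complex)
    truth_phases = np.exp(1j * sim.phases.psi)
    filt = config.filter_window
    from .slr import hamming_filter

    phi_slr_filtered = np.exp(1j * np.angle(hamming_filter(_relative_phases(phi_full), filt)))
    recon_metrics = {
        "no_correction": run_recon(ones),
        "true_phase": run_recon(truth_phases),
        "slr_phase": run_recon(phi_slr_filtered),
    }
    times["recon"] = perf_counter() - t0

    ablation_admm = replace(config.admm, admm_iters=config.ablation_admm_iters)

    if config.run_ablations:
        t0 = perf_counter()
        for variant in ("shots", "coils"):
            phi_v, result_v, kept_v = estimate_shot_phases(sim, variant=variant, admm=ablation_admm)
            phase_metrics[variant] = _phase_error(sim, phi_v, kept_v)
            traces[variant] = result_v.log
        times["ablations"] = perf_counter() - t0

    if config.run_shot_drop:
        t0 = perf_counter()
        for label, drop in (("drop_last", nshot - 1), ("drop_kz0", 0)):
            phi_d, _result_d, kept_d = estimate_shot_phases(sim, drop_shot=drop, admm=ablation_admm)
            phase_metrics[label] = _phase_error(sim, phi_d, kept_d)
            phi_d_filt = np.exp(
                1j * np.angle(hamming_filter(_relative_phases(phi_d), filt))
            )
            sub = KSpaceData(data=sim.kspace.data[kept_d], masks=sim.kspace.masks[kept_d])
            rec = reconstruct_slab(
                sub, phi_d_filt, slab_normal, lam4=config.lam4, cg_iters=config.recon_cg_iters
            )
            recon_metrics[label] = nrmse(sos_combine(rec), reference)
        times["shot_drop"] = perf_counter() - t0

    return BenchmarkReport(
        config=config.to_dict(),
        sampling_metrics=sampling_metrics,
        phase_metrics=phase_metrics,
        recon_metrics=recon_metrics,
        traces=traces,
        runtime_s=times,
    )
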