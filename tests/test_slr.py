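"""Self-navigation extraction, magnitude reference, phase extraction, ADMM pieces."""

import numpy as np
import pytest

from selfnav3d.fourier import fft2c, ifft2c
from selfnav3d.pipeline import (
    RunConfig,
    _phase_error,
    _relative_phases,
    estimate_shot_phases,
    simulate_slab,
)
from selfnav3d.recon import phase_mae
from selfnav3d.simulate import calibration_kz0
from selfnav3d.slr import (
    AdmmDivergenceError,
    AdmmParams,
    annihilation_warm_start,
    conjugate_gradient,
    extract_phase,
    extract_selfnav,
    hamming_filter,
    magnitude_reference,
)
from selfnav3d.spirit import SensitivityMaps, calibrate_kernel, estimate_sensitivities


@pytest.fixture(scope="module")
def kz0_setup():
    sim = simulate_slab(RunConfig())  # default 8-coil desk-scale geometry
    y, ky = extract_selfnav(sim.kspace, sim.sampling)
    gkz0 = calibrate_kernel(calibration_kz0(sim.calib))
    sens = estimate_sensitivities(calibration_kz0(sim.calib))
    return sim, y, ky, gkz0, sens


def truth_kz0(sim):
    """Ground-truth per-shot kz=0 multi-coil k-space from the forward model."""
    nz = sim.phantom.image.shape[-1]
    proj = (sim.sens.maps3d(nz) * sim.phantom.image[None]).sum(axis=-1) / np.sqrt(nz)
    return np.stack([fft2c(proj * np.exp(1j * psi)[None]) for psi in sim.phases.psi])


class TestExtractSelfnav:
    def test_traversal_shot_keeps_every_ry_th_line(self, kz0_setup):
        sim, y, ky, *_ = kz0_setup
        assert ky[0].sum() == len(range(0, 64, 3))

    def test_line_bookkeeping_matches_combined_mask(self, kz0_setup):
        sim, y, ky, *_ = kz0_setup
        cz = sim.sampling.kz_center
        assert ky.sum() == sim.kspace.masks[:, :, cz].sum()

    def test_missing_selfnav_raises_with_shot_number(self, kz0_setup):
        sim = kz0_setup[0]
        broken = type(sim.kspace)(
            data=sim.kspace.data.copy(), masks=sim.kspace.masks.copy()
        )
        broken.masks[3, :, sim.sampling.kz_center] = False
        with pytest.raises(ValueError, match="shot 4"):
            extract_selfnav(broken, sim.sampling)


class TestMagnitudeReference:
    def test_fully_sampled_equals_sos(self, kz0_setup):
        sim, y, ky, gkz0, _ = kz0_setup
        xt = truth_kz0(sim)
        full_mask = np.ones(64, dtype=bool)
        m = magnitude_reference(xt[0], full_mask, gkz0)
        expected = np.sqrt((np.abs(ifft2c(xt[0])) ** 2).sum(axis=0))
        assert np.abs(m - expected).max() < 1e-8

    def test_undersampled_recovery(self, kz0_setup):
        sim, y, ky, gkz0, _ = kz0_setup
        m = magnitude_reference(y[0], ky[0], gkz0)
        truth = np.sqrt((np.abs(ifft2c(truth_kz0(sim)[0])) ** 2).sum(axis=0))
        assert np.linalg.norm(m - truth) / np.linalg.norm(truth) < 0.05
        assert np.all(m >= 0)


class TestExtractPhase:
    def test_unit_magnitude_everywhere(self, kz0_setup):
        sim, y, ky, gkz0, sens = kz0_setup
        phi = extract_phase(truth_kz0(sim), sens)
        assert np.abs(np.abs(phi) - 1).max() < 1e-12

    def test_ground_truth_recovery(self, kz0_setup):
        sim, *_ , sens = kz0_setup
        phi = extract_phase(truth_kz0(sim), sens)
        rel = _relative_phases(phi)
        truth = _relative_phases(np.exp(1j * sim.phases.psi))
        assert phase_mae(rel[1:], truth[1:], sim.support()) < 0.02

    def test_identical_shots_identical_phases(self, kz0_setup):
        sim, *_, sens = kz0_setup
        xt = truth_kz0(sim)
        pair = np.stack([xt[2], xt[2]])
        phi = extract_phase(pair, sens)
        assert np.array_equal(phi[0], phi[1])


class TestHammingFilter:
    def test_dc_image_preserved_up_to_gain(self):
        img = np.full((64, 64), 2.0 + 1j)
        out = hamming_filter(img, 32)
        ratio = out / img
        assert np.abs(ratio - ratio[0, 0]).max() < 1e-10

    def test_nyquist_checkerboard_removed(self):
        ix = np.arange(64)
        img = ((-1.0) ** (ix[:, None] + ix[None, :])).astype(complex)
        out = hamming_filter(img, 32)
        assert np.abs(out).max() < 1e-10

    def test_double_filter_equals_squared_window(self, rng):
        img = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        twice = hamming_filter(hamming_filter(img, 32), 32)
        w1 = np.hamming(32)
        wk = np.zeros((64, 64))
        wk[16:48, 16:48] = np.outer(w1, w1) ** 2
        direct = ifft2c(fft2c(img) * wk)
        assert np.abs(twice - direct).max() < 1e-10

    def test_window_validation(self):
        with pytest.raises(ValueError):
            hamming_filter(np.zeros((16, 16), dtype=complex), 32)


class TestConjugateGradient:
    def test_solves_hermitian_system(self, rng):
        a = rng.standard_normal((40, 40)) + 1j * rng.standard_normal((40, 40))
        aha = a.conj().T @ a + 0.5 * np.eye(40)
        xt = rng.standard_normal(40) + 1j * rng.standard_normal(40)
        x = conjugate_gradient(lambda v: aha @ v, aha @ xt, iters=200)
        assert np.linalg.norm(x - xt) / np.linalg.norm(xt) < 1e-8

    def test_divergence_guard_triggers(self):
        # CG on symmetric indefinite systems loses monotonicity; the guard
        # must catch a run whose residual explodes
        rng = np.random.default_rng(0)
        tripped = False
        for _ in range(10):
            a = rng.standard_normal((6, 6))
            a = a + a.T
            rhs = rng.standard_normal(6)
            try:
                conjugate_gradient(lambda v: a @ v, rhs, iters=60)
            except AdmmDivergenceError:
                tripped = True
                break
        assert tripped


class TestWarmStart:
    def test_annihilation_warm_start_close_to_truth(self, kz0_setup):
        sim, y, ky, gkz0, sens = kz0_setup
        x0 = annihilation_warm_start(y, ky, gkz0)
        phi = extract_phase(x0, sens)
        rel = _relative_phases(phi)
        truth = _relative_phases(np.exp(1j * sim.phases.psi))
        assert phase_mae(rel[1:], truth[1:], sim.support()) < 0.1


@pytest.fixture(scope="module")
def instrumented_admm_run():
    """10-iteration ADMM at 4 coils with a per-iteration phase-error trace."""
    from selfnav3d.recon import phase_mae as _mae

    cfg = RunConfig(ncoil=4)
    cfg.admm.admm_iters = 10
    sim = simulate_slab(cfg)
    sens = estimate_sensitivities(calibration_kz0(sim.calib))
    supp = sim.support()
    truth = _relative_phases(np.exp(1j * sim.phases.psi))

    def cb(it, x):
        phi = extract_phase(np.asarray(x, complex), sens)
        rel = _relative_phases(phi)
        return {"mae": _mae(rel[1:], truth[1:], supp)}

    phi, result, kept = estimate_shot_phases(sim, callback=cb)
    trace = [e["mae"] for e in result.log]
    return sim, _phase_error(sim, phi, kept), trace


class TestAdmm:
    def test_phase_error_trace_is_non_increasing(self, instrumented_admm_run):
        # allow small transient violations (relative 1%, at most 5% of steps)
        _, _, trace = instrumented_admm_run
        violations = sum(1 for a, b in zip(trace, trace[1:]) if b > 1.01 * a)
        assert violations <= max(1, round(0.05 * len(trace)))

    def test_zero_motion_data_yields_flat_phases(self):
        cfg = RunConfig(phase_amplitude=0.0)
        cfg.admm.admm_iters = 5
        sim = simulate_slab(cfg)
        phi, result, kept = estimate_shot_phases(sim)
        assert _phase_error(sim, phi, kept) < 0.05

    def test_magnitude_constraint_does_not_hurt_early_convergence(self, instrumented_admm_run):
        _, err_with, _ = instrumented_admm_run
        cfg2 = RunConfig(ncoil=4)
        cfg2.admm.admm_iters = 10
        cfg2.admm.lam3 = 0.0
        sim2 = simulate_slab(cfg2)
        phi_without, *_ = estimate_shot_phases(sim2)
        err_without = _phase_error(sim2, phi_without, list(range(12)))
        assert err_with <= err_without * 1.05

    def test_log_records_fidelity_and_residual(self):
        cfg = RunConfig(ncoil=4)
        cfg.admm.admm_iters = 2
        sim = simulate_slab(cfg)
        _, result, _ = estimate_shot_phases(sim)
        assert len(result.log) == 2
        assert {"iter", "fidelity", "primal_residual"} <= set(result.log[0])

    def test_invalid_variant_rejected(self, kz0_setup):
        sim, y, ky, gkz0, sens = kz0_setup
        from selfnav3d.slr import admm_solve

        with pytest.raises(ValueError):
            admm_solve(y, ky, gkz0, None, sens, variant="bogus")
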