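# Methods

`selfnav3d` implements a self-navigated acquisition/reconstruction framework
for 3D multi-slab diffusion MRI: an extended-CAIPI multi-shot sampling design
whose every shot crosses the central kz plane, a SPIRiT-regularized
structured low-rank (SLR) ADMM that estimates one 2D motion-phase map per
shot from those central-plane samples, and a phase-corrected multi-shot
SPIRiT reconstruction of the slab. This note records the model, the
numerical choices, and what the synthetic benchmark does and does not show.

## Signal model

For shot j and coil v the acquired k-space is

    y_jv = M_j F ( S_v · e^{i ψ_j} · ρ ) + n_jv ,

with ρ the motion-phase-free complex slab image, S_v smooth coil
sensitivities with limited k-space support, ψ_j a smooth, real, purely 2D
motion phase (the thin-slab approximation: non-diffusive motion during
diffusion encoding imprints an in-plane phase that is constant across the
thin slab), M_j the shot's Cartesian (ky, kz) line mask with fully sampled kx
readouts, and n complex white Gaussian noise. All Fourier transforms are
centered (DC at index N//2) and orthonormal, so energy bookkeeping is exact
and mask indices unambiguous.

Because ψ_j is 2D, the central (DC) kz plane of shot j's 3D spectrum is the
2D spectrum of `e^{i ψ_j} · Σ_z S_v ρ` — all shots share one underlying
complex profile per coil and differ only by their smooth phase. This is the
identifiability the whole method rests on.

## Sampling design

Each shot follows a triangular kz waveform of width `w = floor(Nkz/2)+1`
(minimal width crossing the central plane; period `2w−2` acquired lines),
parameterized by a CAIPI ky shift `s_ky ∈ [0, Ry−1]`, a band position
`s_kz ∈ [0, Nkz−w]` and a periodic shift `s_p ∈ [0, 2w−3]`. Shot 1 traverses
the central plane without kz blips and anchors the magnitude of the shared
navigator image. Shots 2…Nshot are chosen by exhaustive greedy search
(216 candidates per step for Nkz=12, Ry=3) minimizing overlap plus k-space
gaps subject to a self-navigation constraint `d ≤ dmax`, where

- overlap counts multiply-acquired points *with multiplicity*
  (Σ max(count−1, 0)); the reported metric `overlap_metric` is the plain
  count of cells acquired more than once;
- gaps are fully-contained empty 3×3 windows of the combined mask
  (`valid`-mode convolution, so grid borders are not spuriously counted);
- d is the Euclidean grid-index distance of the shot's nearest
  central-plane sample to the ky-kz center.

Design choices worth recording: the self-navigation distance acts as a
*feasibility constraint only*. Folding d additively into the greedy cost
makes the final shots trade residual k-space gaps against a few index units
of navigation distance and produces patterns with ~10 empty 3×3 windows and
double the overlap; as a constraint the optimizer yields patterns with zero
gaps and ≤2.7 % overlap on both the 180×12 and 204×12 grids, all shots
within dmax=15 — the pattern quality the method is designed around. Ties
break lexicographically on (s_ky, s_kz, s_p), making the search fully
deterministic.

## Phase estimation (SPIRiT-SLR ADMM)

The central-plane samples of all shots are jointly completed by solving

    argmin_x ||M x − y||² + λ1 ||(G − I) x||² + λ2 ||H(x)||_*
           (+ λ3 ||x − F m' Φ||²)

where `x` is the (Nshot × Ncoil × Nx × Ny) stack of fully sampled kz=0
planes, G the 5×5 SPIRiT kernel calibrated on central-plane calibration data
(Tikhonov weight 1e−4·trace-normalized; own-coil center weight fixed to 0),
H the shot+coil block-Hankel matrix with window wH=10, m' the magnitude of
the SPIRiT-CG-reconstructed traversal shot, and Φ the phase of the previous
iterate's coil-combined images re-expanded through the sensitivities. ADMM
splits off Z = H(x): the x-update is 30 CG iterations on the normal
equations (the Hankel-coupling normal term is a diagonal window-count
weighting; the SPIRiT normal term is a precomputed per-pixel coil-mixing
matrix in image space — the circular realization of the k-space
convolution), the Z-update is singular-value hard thresholding at rank N,
and the scaled dual accumulates the truncation residual. 50 outer
iterations; λ1=1, λ2=1e−4, β=10. λ3 (never published) defaults to 0.01 —
weak, so the magnitude anchor guides rather than dominates.

Numerical choices:

- **Truncation rank.** The benchmark uses N = (wH+s−1)² = 196, the coil
  rank bound for sensitivities with k-space support s=5, rather than
  N = wH² = 100. On the synthetic conditions (2-rad multi-sinusoid phases,
  exact-support coils) the true solution's Hankel matrix has numerical rank
  just under 196, and hard thresholding below the true rank provably
  discards signal: started at the exact solution the ADMM drifts to a
  ~0.15 rad phase-error plateau with N=100 and is stable (0.02 rad) at
  N=196. `AdmmParams(n_keep=None)` still selects wH².
- **Initialization.** Zero-filled initialization (and every β/λ3 setting
  tried with it) leaves the iteration stuck near a spurious low-rank
  solution in which every shot equals the traversal shot: the per-shot data
  (a handful of sampled lines) enters the x-update against a Hankel
  coupling weighted ~β/2·wH², and the measured escape rate is ~0.002 rad
  per iteration. The solver therefore starts from the annihilation relation
  used constructively: the traversal shot's plane is fully recovered by
  SPIRiT-CG (100 CG iterations; converged), and each remaining shot's plane
  is that plane convolved with one small (9×9) k-space kernel fitted by
  Tikhonov least squares to the shot's own sampled lines — the same
  shared-magnitude annihilation structure the nuclear-norm term enforces,
  solved in closed form for a warm start. The ADMM then refines and
  maintains this solution.
- **SVD of the Hankel matrix.** Exact SVDs of the 3025×9600 matrix are
  wasteful inside the loop; the Z-update uses a seeded randomized SVD whose
  sketch recycles the previous iteration's right-singular subspace plus a
  few fresh random directions (one power iteration on the first call). The
  public `svd_hard_threshold` defaults to the exact LAPACK path and the
  randomized path is validated against it in the tests.
- Inner arithmetic is complex64; results are returned as complex128.

Phase maps are extracted per shot as the voxelwise-normalized
conjugate-sensitivity combination of the inverse-FFT images, reported
relative to the traversal shot (removing the estimation-intrinsic shared
spatial phase). Sensitivities come from a compact single-map eigenvector
estimator (calibration-matrix row space projected to image space; leading
per-voxel eigenvector, eigenvalue-cropped, phase-referenced to coil 1).

Two ablation structures mirror the method's design rationale: a
coil-combined shots-only variant (the original 2D SLR formulation with a
SENSE forward model through the sensitivities, Hankel over shots) and a
per-shot coils-only variant (independent coil-block truncations, no
cross-shot sharing; zero-filled init since no cross-shot information is
allowed). In the benchmark the ablation and shot-drop arms run with a
reduced, equal ADMM budget (25 iterations); their conclusions are decided by
~25× differences in phase error and are insensitive to the budget.

## Phase-corrected reconstruction

The slab is reconstructed by CG on the normal equations of

    argmin_X Σ_j ||M_j F φ_j F^{-1} X − y_j||² + λ4 ||(G_slab − I) X||² ,

with φ_j the unit-magnitude (optionally 32×32-Hamming-filtered) phase maps
broadcast along z. Because φ varies only in (x, y) the problem decouples
exactly along x after a kx FFT; each ky-kz plane is solved independently
with its own fixed 100-iteration CG, using a per-x 5×5 SPIRiT kernel trained
on hybrid-space calibration data. λ4 defaults to 1: with noiseless
consistent data the minimizer is λ4-invariant, while small λ4 leaves the
unsampled-mode cluster of the normal operator at eigenvalues ~λ4 and a
fixed-budget CG visibly unconverged (λ4=1e−4 with 30 iterations stalls at
44 % NRMSE on data whose true solution it fits to 5e−8). The published
λ4=1e−4 / 30-iteration setting remains available as parameters. The slab
image is the root-sum-of-squares of the coil images.

## Synthetic data

The generator emulates the study conditions at desk scale: 64×64×12 grid,
8 coils, 12 shots, Ry=3, dmax=15, phase amplitude 2 rad, noiseless by
default (σ configurable).

- **Phantom:** overlapping ellipsoids with piecewise-constant magnitude in
  [0, 1], a low-order smooth background phase, and a tapered slab profile;
  support strictly inside the grid.
- **Coils:** synthesized directly on a limited k-space support. 2D maps
  (exact s×s support, default s=5) are used where the rank bound is the
  point of the test; the benchmark uses 3D maps with an additional small
  (3-point) kz support — the gentle through-slab variation of a real
  receive array, without which the per-x slab kernels have no resolving
  power along kz and the reconstruction is ill-determined at the sparsely
  covered outer kz planes.
- **Motion phases:** random superpositions of plane waves with at most
  2 cycles across the FOV (ramp-like tilt plus gentle sinusoids), peak
  |ψ| ≤ amplitude, exactly band-limited by construction; shot 1 is the zero
  reference. A true linear ramp is not band-limited and is represented by
  the ±1-cycle components.
- **Calibration:** a fully sampled motion-phase-free scan of S_v·ρ, keeping
  the object's static background phase (a property of the field shared by
  every acquisition of the same object); only the shot-dependent motion
  phase is absent.

What the benchmark does **not** emulate: T2*/off-resonance decay along the
EPI train, slab-profile saturation, coil noise covariance, bulk rigid
motion, partial-Fourier completion (PF only restricts masks), and
eddy-current effects. Passing tests therefore demonstrate the correctness
and internal consistency of the sampling/estimation/reconstruction chain
under the stated model, not robustness to those confounds.

## Evaluation

- NRMSE of magnitude volumes against the fully sampled coil-weighted
  reference.
- Circular phase MAE inside the object support (magnitude > 10 % of peak),
  with each shot's global phase offset removed; estimated and true maps are
  compared relative to the traversal shot.
- The benchmark reports the correction ordering (no correction ≫ SLR ≈ true
  phases), the shot-drop ordering (losing the traversal shot is much worse
  than losing the last CAIPI shot), and the SLR-structure ablations
  (shots-only and shot+coil both ≪ coils-only).

## Known limitations

- The fixed-rank hard threshold requires the rank to cover the true
  solution (see above); with wider phase spectra than the generator's, N
  must grow accordingly.
- The annihilation warm start assumes a usable traversal shot; without one
  (shot-drop experiments) the solver falls back to zero-filled
  initialization and, consistent with the method's design rationale, fails
  to produce accurate phases.
- Desk-scale grids make each shot's central-plane line count (1–4 lines)
  smaller in absolute terms than at acquisition scale (5–10), so absolute
  phase errors are not comparable to in-vivo values; only orderings and
  model checks are meaningful.
- The CLI is a thin wrapper; headless batch use is expected to go through
  `selfnav3d.pipeline.RunConfig` / `run_benchmark`.
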