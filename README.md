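# selfnav3d

Self-navigated 3D multi-slab diffusion MRI: extended-CAIPI sampling design
and structured low-rank (SLR) shot-phase estimation with phase-corrected
multi-shot SPIRiT reconstruction — fully testable on synthetic multi-coil
k-space data.

## The problem

3D multi-slab acquisitions give diffusion MRI its best SNR efficiency, but
every slab is built from many EPI shots, and non-diffusive motion (cardiac
pulsation, respiration) imprints a different smooth 2D phase ψ_j on each
shot. Uncorrected, these shot-to-shot phase errors destroy the multi-shot
combination. The conventional fix — acquiring a 2D navigator echo after
every imaging echo — costs 25–50 % scan time and extra SAR.

This package implements a navigator-free alternative. Each shot's kz
trajectory is a periodic triangular ("extended CAIPI") waveform of width
`w = floor(Nkz/2)+1` that crosses the central kz plane every period; those
crossings are *self-navigation points*. The multi-shot pattern is optimized
by exhaustive greedy search over per-shot parameters (ky shift, kz shift,
periodic shift) to minimize overlap and k-space gaps while keeping every
shot's self-navigation points within a distance `dmax` of the k-space
center. One non-blipped shot traverses the whole central plane and anchors
the shared magnitude. A SPIRiT-regularized SLR reconstruction then jointly
completes the central plane of every shot from the self-navigation points,

    argmin_x ||M x − y||² + λ1 ||(G − I) x||² + λ2 ||H(x)||_* ,

solved by ADMM with singular-value hard thresholding of the shot+coil
block-Hankel matrix H(x) and an optional magnitude-consistency anchor
`λ3 ||x − F m' Φ||²`. Unit-magnitude phase maps φ_j extracted from the
result enter the final phase-corrected multi-shot reconstruction

    argmin_X Σ_j ||M_j F φ_j F^{-1} X − y_j||² + λ4 ||(G_slab − I) X||² .

See `docs/methods.md` for the model, the numerical choices and their
rationale, and what the synthetic benchmark does and does not demonstrate.

## Worked example

```python
import numpy as np
from selfnav3d.sampling import SamplingConfig, SamplingMaskSet, greedy_optimize, \
    gap_metric, overlap_metric, nav_distance
from selfnav3d.pipeline import RunConfig, run_benchmark

# 1.22 mm protocol geometry: 180 ky lines, 12 kz planes, 12 shots, Ry=3
config = SamplingConfig(ny=180, nkz=12, nshot=12, ry=3, dmax=15.0)
patterns = greedy_optimize(config)
masks = SamplingMaskSet.from_patterns(patterns, config)
print("gaps:", gap_metric(masks, 12),
      "overlap cells:", overlap_metric(masks, 12),
      "max nav distance:", max(nav_distance(p, config) for p in patterns))

# desk-scale synthetic benchmark: 64x64x12, 8 coils, 2-rad motion phases
report = run_benchmark(RunConfig())
print({k: round(v, 3) for k, v in report.phase_metrics.items()})
print({k: round(v, 3) for k, v in report.recon_metrics.items()})
```

prints

```
gaps: 0 overlap cells: 0 max nav distance: 14.0
{'full': 0.022}
{'no_correction': 0.454, 'true_phase': 0.028, 'slr_phase': 0.039}
```

The optimized 180×12 pattern covers k-space with no empty 3×3 window, no
double-acquired cell, and a self-navigation point within 14 grid units of
the center for every shot. On the synthetic slab, reconstructing without
phase correction leaves 45 % NRMSE; with the SLR-estimated phase maps
(recovered to 0.022 rad mean absolute error from the self-navigation points
alone) the error drops to 3.9 %, close to the 2.8 % achieved with the
ground-truth phases.

A thin CLI mirrors the library:

```bash
selfnav3d design --ny 180 --nkz 12 --nshot 12 --ry 3 --dmax 15 --out pattern.h5
selfnav3d plot-pattern --pattern pattern.h5 --out pattern.png
selfnav3d simulate --out data.h5
selfnav3d estimate-phase --data data.h5 --out phase.h5
selfnav3d reconstruct --data data.h5 --phase phase.h5 --out recon.nii.gz
selfnav3d benchmark --report report.json --ablations --shot-drop
```

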