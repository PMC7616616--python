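"""HDF5 / NIfTI / YAML containers for patterns, k-space data and results.

HDF5 is used for k-space-domain artifacts (no community raw format is
assumed), NIfTI for image volumes.  Every container embeds the package
version and the generating configuration as attributes so reported metrics
remain recomputable from stored artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .pipeline import RunConfig
from .sampling import SamplingConfig, SamplingMaskSet, ShotParams, ShotPattern
from .simulate import KSpaceData

__all__ = [
    "SchemaError",
    "write_pattern_file",
    "read_pattern_file",
    "write_simulation_file",
    "read_simulation_file",
    "write_phase_file",
    "read_phase_file",
    "write_nifti",
    "write_report",
    "load_config",
    "save_config",
]


class SchemaError(IOError):
    """A container file is missing a required dataset."""


def _require(f: h5py.File, names: list[str]) -> None:
    missing = [n for n in names if n not in f]
    if missing:
        raise SchemaError(f"{f.filename}: missing dataset(s) {missing}")


def _stamp(f: h5py.File) -> None:
    f.attrs["selfnav3d_version"] = __version__


def write_pattern_file(
    path: str | Path, patterns: list[ShotPattern], config: SamplingConfig
) -> None:
    masks = SamplingMaskSet.from_patterns(patterns, config)
    params = np.array([[p.params.s_ky, p.params.s_kz, p.params.s_p] for p in patterns])
    with h5py.File(path, "w") as f:
        f["params"] = params.astype(np.int64)
        f["masks"] = masks.masks.astype(np.uint8)
        f["combined"] = masks.combined.astype(np.uint16)
        f["is_kz0_traversal"] = np.array([p.is_kz0_traversal for p in patterns], dtype=np.uint8)
        for k, v in (("ny", config.ny), ("nkz", config.nkz), ("nshot", config.nshot),
                     ("ry", config.ry), ("pf", config.pf), ("dmax", config.dmax)):
            f.attrs[k] = v
        _stamp(f)


def read_pattern_file(path: str | Path) -> tuple[list[ShotPattern], SamplingConfig]:
    with h5py.File(path, "r") as f:
        _require(f, ["params", "masks", "combined"])
        config = SamplingConfig(
            ny=int(f.attrs["ny"]), nkz=int(f.attrs["nkz"]), nshot=int(f.attrs["nshot"]),
            ry=int(f.attrs["ry"]), pf=float(f.attrs["pf"]), dmax=float(f.attrs["dmax"]),
        )
        params = f["params"][()]
        masks = f["masks"][()]
        traversal = f["is_kz0_traversal"][()].astype(bool)
    patterns = []
    for row, m, trav in zip(params, masks, traversal):
        ky, kz = np.nonzero(m)
        order = np.argsort(ky)
        patterns.append(
            ShotPattern(
                params=ShotParams(*[int(v) for v in row]),
                lines=np.stack([ky[order], kz[order]], axis=1),
                is_kz0_traversal=bool(trav),
            )
        )
    return patterns, config


def export_pattern_csv(path: str | Path, patterns: list[ShotPattern]) -> None:
    with open(path, "w") as fh:
        fh.write("shot,ky,kz\n")
        for j, p in enumerate(patterns, start=1):
            for ky, kz in p.lines:
                fh.write(f"{j},{ky},{kz}\n")


def write_simulation_file(path: str | Path, sim) -> None:
    """Persist a :class:`~selfnav3d.pipeline.SimulatedSlab` to HDF5."""
    with h5py.File(path, "w") as f:
        f["kspace"] = sim.kspace.data
        f["mask"] = sim.kspace.masks.astype(np.uint8)
        f["calib"] = sim.calib
        f["sens_truth"] = sim.sens.maps
        f["phase_truth"] = sim.phases.psi
        f["phantom"] = sim.phantom.image
        f.attrs["config"] = json.dumps(sim.config.to_dict())
        _stamp(f)


def read_simulation_file(path: str | Path):
    from .pipeline import SimulatedSlab
    from .simulate import CoilSensitivities, ShotPhaseSet, SlabPhantom

    with h5py.File(path, "r") as f:
        _require(f, ["kspace", "mask", "calib", "sens_truth", "phase_truth", "phantom"])
        config = RunConfig.from_dict(json.loads(f.attrs["config"]))
        kspace = KSpaceData(data=f["kspace"][()], masks=f["mask"][()].astype(bool))
        calib = f["calib"][()]
        sens = CoilSensitivities(maps=f["sens_truth"][()], support=config.sens_support)
        phases = ShotPhaseSet(psi=f["phase_truth"][()])
        phantom = SlabPhantom(image=f["phantom"][()])
    sampling = config.sampling_config()
    from .sampling import greedy_optimize
    from .pipeline import SimulatedSlab

    return SimulatedSlab(
        config=config, sampling=sampling, patterns=greedy_optimize(sampling),
        phantom=phantom, sens=sens, phases=phases, kspace=kspace, calib=calib,
    )


def write_phase_file(
    path: str | Path, phase: np.ndarray, phase_filtered: np.ndarray | None = None,
    kz0_images: np.ndarray | None = None, log: list[dict] | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f["phase"] = phase
        if phase_filtered is not None:
            f["phase_filtered"] = phase_filtered
        if kz0_images is not None:
            f["kz0_images"] = kz0_images
        if log is not None:
            f["log"] = json.dumps(log)
        _stamp(f)


def read_phase_file(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        _require(f, ["phase"])
        out = {"phase": f["phase"][()]}
        for k in ("phase_filtered", "kz0_images"):
            if k in f:
                out[k] = f[k][()]
        if "log" in f:
            out["log"] = json.loads(f["log"][()])
    return out


def write_nifti(path: str | Path, volume: np.ndarray, voxel_size: tuple = (1.0, 1.0, 1.0)) -> None:
    """RAS-coded NIfTI export of a real image volume."""
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def save_config(path: str | Path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
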