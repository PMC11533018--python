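"""NIfTI-1 and JSON-sidecar I/O for phantom, echo-series and map volumes."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .forward import EchoSeries
from .geometry import AcquisitionGeometry
from .phantom import PhantomTruth


def _affine(geometry: AcquisitionGeometry) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = geometry.voxel_size_mm
    return affine


def save_volume(path: Path, data: np.ndarray, geometry: AcquisitionGeometry) -> None:
    data = np.asarray(data)
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(geometry))
    img.header.set_zooms(geometry.voxel_size_mm + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_echo_series(series: EchoSeries, out_dir: Path, seed: int | None = None) -> None:
    """Write 4-D magnitude and phase NIfTIs plus a JSON acquisition sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = series.geometry
    save_volume(out_dir / "magnitude.nii", series.magnitude, geom)
    save_volume(out_dir / "phase.nii", series.phase, geom)
    sidecar = {
        "echo_times_ms": list(geom.echo_times_ms),
        "b0_strength_t": geom.b0_strength_t,
        "b0_direction": list(geom.b0_direction),
        "voxel_size_mm": list(geom.voxel_size_mm),
        "gyromagnetic_ratio_mhz_per_t": geom.gyromagnetic_ratio_mhz_per_t,
        "seed": seed,
    }
    (out_dir / "mgre.json").write_text(json.dumps(sidecar, indent=2))


def load_echo_series(in_dir: Path) -> EchoSeries:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "mgre.json").read_text())
    magnitude = load_volume(in_dir / "magnitude.nii")
    phase = load_volume(in_dir / "phase.nii")
    geometry = AcquisitionGeometry(
        grid_shape=magnitude.shape[:3],
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
        b0_strength_t=sidecar["b0_strength_t"],
        b0_direction=tuple(sidecar["b0_direction"]),
        gyromagnetic_ratio_mhz_per_t=sidecar["gyromagnetic_ratio_mhz_per_t"],
        echo_times_ms=tuple(sidecar["echo_times_ms"]),
    )
    return EchoSeries(magnitude=magnitude, phase=phase, geometry=geometry)


def save_phantom_truth(truth: PhantomTruth, out_dir: Path,
                       geometry: AcquisitionGeometry) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(out_dir / "chi_ppb.nii", truth.chi, geometry)
    save_volume(out_dir / "r2star_s.nii", truth.r2star, geometry)
    save_volume(out_dir / "m0.nii", truth.m0, geometry)
    save_volume(out_dir / "labels.nii", truth.labels.astype(np.int16), geometry)
    save_volume(out_dir / "brain_mask.nii", truth.brain_mask.astype(np.uint8),
                geometry)
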