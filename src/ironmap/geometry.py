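"""Acquisition geometry for multi-echo gradient-echo (MGRE) simulation and recon.

The default echo train reproduces a 7 T MGRE protocol with ten echoes,
TE1 = 1.68 ms and echo spacing 3.05 ms, at 0.8 mm isotropic resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.576

DEFAULT_TE1_MS = 1.68
DEFAULT_DELTA_TE_MS = 3.05
DEFAULT_N_ECHOES = 10


def default_echo_times_ms() -> tuple[float, ...]:
    """Echo times (ms) of the default ten-echo train: 1.68 + k*3.05, k=0..9."""
    return tuple(DEFAULT_TE1_MS + k * DEFAULT_DELTA_TE_MS for k in range(DEFAULT_N_ECHOES))


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Grid, field strength and echo timing of an MGRE acquisition.

    Parameters
    ----------
    grid_shape : tuple of int
        Matrix size in voxels, one entry per spatial axis.
    voxel_size_mm : tuple of float
        Voxel edge length per axis, millimetres.
    b0_strength_t : float
        Main field strength in tesla.
    b0_direction : tuple of float
        Unit vector of B0 in the image frame (normalised on construction).
    gyromagnetic_ratio_mhz_per_t : float
        Reduced gyromagnetic ratio of the proton, MHz/T.
    echo_times_ms : tuple of float
        Strictly increasing echo times in milliseconds.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)
    b0_strength_t: float = 7.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gyromagnetic_ratio_mhz_per_t: float = GYROMAGNETIC_RATIO_MHZ_PER_T
    echo_times_ms: tuple[float, ...] = field(default_factory=default_echo_times_ms)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive numbers")
        if self.b0_strength_t <= 0:
            raise ValueError("b0_strength_t must be positive")
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 1 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        direction = np.asarray(self.b0_direction, dtype=float)
        norm = float(np.linalg.norm(direction))
        if norm == 0:
            raise ValueError("b0_direction must be a nonzero vector")
        object.__setattr__(self, "b0_direction", tuple(direction / norm))
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "echo_times_ms", tuple(float(t) for t in te))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def echo_times_s(self) -> np.ndarray:
        """Echo times in seconds, as an array."""
        return np.asarray(self.echo_times_ms, dtype=float) / 1e3

    @property
    def larmor_frequency_hz(self) -> float:
        """Proton Larmor frequency at B0, in Hz."""
        return self.gyromagnetic_ratio_mhz_per_t * 1e6 * self.b0_strength_t

    @property
    def hz_per_ppb(self) -> float:
        """Field shift in Hz corresponding to 1 ppb of susceptibility (≈0.298 at 7 T)."""
        return self.larmor_frequency_hz * 1e-9
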