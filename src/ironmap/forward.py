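"""Forward MGRE signal model: dipole field from susceptibility, echo simulation.

A susceptibility distribution shifts the local Larmor frequency by the
convolution of chi with the unit dipole response; in k-space this is the
multiplication by D(k) = 1/3 - (k.b)^2/|k|^2.  The complex MGRE signal per
voxel then decays mono-exponentially with R2* while its phase accrues
linearly with the local frequency offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fftfreq, fftn, ifftn

from .geometry import AcquisitionGeometry
from .phantom import PhantomTruth


@dataclass
class KSpaceKernel:
    """Dipole kernel sampled on the FFT grid; zero at the DC component."""

    values: np.ndarray
    dc_convention: float = 0.0


@dataclass
class FieldMap:
    """Frequency offset map in Hz with a validity mask and optional residual."""

    frequency: np.ndarray       # Hz
    mask: np.ndarray            # bool
    residual: np.ndarray | None = None   # rad, weighted RMS fit residual


@dataclass
class EchoSeries:
    """Multi-echo magnitude/phase volumes (space x echo) with their geometry."""

    magnitude: np.ndarray       # >= 0, shape grid + (n_echoes,)
    phase: np.ndarray           # rad, wrapped to (-pi, pi]
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.shape[-1] != self.geometry.n_echoes:
            raise ValueError("echo count does not match geometry.echo_times")

    @property
    def complex_signal(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


def _dipole_values(shape, voxel_size_mm, b0_direction) -> np.ndarray:
    ks = [
        fftfreq(n, d=h) for n, h in zip(shape, voxel_size_mm)
    ]
    kx = ks[0][:, None, None]
    ky = ks[1][None, :, None]
    kz = ks[2][None, None, :]
    b = np.asarray(b0_direction, dtype=float)
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[k2 == 0] = 0.0
    return d


def dipole_kernel(geometry: AcquisitionGeometry) -> KSpaceKernel:
    """Unit dipole response D(k) = 1/3 - (k.b)^2/|k|^2 on the FFT grid.

    The DC component is set to 0, i.e. a uniform susceptibility produces no
    frequency shift (the mean field offset is unobservable).
    """
    values = _dipole_values(
        geometry.grid_shape, geometry.voxel_size_mm, geometry.b0_direction
    )
    return KSpaceKernel(values=values, dc_convention=0.0)


def forward_field(
    truth: PhantomTruth | np.ndarray,
    geometry: AcquisitionGeometry,
    pad_factor: int = 2,
) -> FieldMap:
    """Frequency map (Hz) induced by a susceptibility volume in ppb.

    FFT convolution with the dipole kernel; the grid is zero-padded by
    ``pad_factor`` to suppress circular wrap-around (``pad_factor=1`` keeps
    the purely circular convolution).  Linear in chi.
    """
    if isinstance(truth, PhantomTruth):
        chi = truth.chi
        mask = truth.brain_mask
    else:
        chi = np.asarray(truth, dtype=float)
        mask = np.ones(chi.shape, dtype=bool)
    if chi.shape != tuple(geometry.grid_shape):
        raise ValueError(
            f"chi shape {chi.shape} does not match geometry {geometry.grid_shape}"
        )
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    shape = tuple(int(n * pad_factor) for n in chi.shape)
    d = _dipole_values(shape, geometry.voxel_size_mm, geometry.b0_direction)
    chi_pad = np.zeros(shape)
    chi_pad[: chi.shape[0], : chi.shape[1], : chi.shape[2]] = chi
    field_ppb = np.real(ifftn(fftn(chi_pad) * d))
    field_ppb = field_ppb[: chi.shape[0], : chi.shape[1], : chi.shape[2]]
    return FieldMap(frequency=field_ppb * geometry.hz_per_ppb, mask=mask)


def simulate_mgre(
    truth: PhantomTruth,
    field: FieldMap,
    geometry: AcquisitionGeometry,
    snr: float = np.inf,
    seed: int = 0,
) -> EchoSeries:
    """Simulate the complex MGRE signal and split into magnitude and phase.

    Per voxel and echo n the noiseless signal is
    ``m0 * exp(-r2star * TE_n) * exp(i * 2*pi * frequency * TE_n)`` with TE in
    seconds.  Independent Gaussian noise of equal variance is added to the
    real and imaginary channels; ``snr`` is the mean first-echo brain-tissue
    magnitude divided by the per-channel noise standard deviation
    (``snr=inf`` for a noiseless acquisition).  Deterministic per seed.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    te = geometry.echo_times_s
    m0 = truth.m0[..., None]
    r2s = truth.r2star[..., None]
    freq = field.frequency[..., None]
    signal = m0 * np.exp(-r2s * te) * np.exp(2j * np.pi * freq * te)
    if np.isfinite(snr):
        first_echo = np.abs(signal[..., 0])
        ref = float(first_echo[truth.brain_mask].mean())
        sigma = ref / snr
        rng = np.random.default_rng(seed)
        signal = signal + sigma * (
            rng.standard_normal(signal.shape)
            + 1j * rng.standard_normal(signal.shape)
        )
    return EchoSeries(
        magnitude=np.abs(signal), phase=np.angle(signal), geometry=geometry
    )
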