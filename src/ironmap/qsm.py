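"""Quantitative susceptibility mapping from a multi-echo gradient-echo series.

Stages: Laplacian phase unwrapping, magnitude-weighted field fitting with a
residual-based reliability mask, variable-radius spherical-mean-value
(V-SHARP) background-field removal, thresholded k-space division (TKD)
dipole inversion, and referencing to the brain mean.  Susceptibility is
reported in ppb throughout (1 ppb corresponds to about 0.298 Hz at 7 T).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from numpy.fft import fftn, ifftn
from scipy.fft import dctn, idctn

from .forward import EchoSeries, FieldMap, _dipole_values
from .geometry import AcquisitionGeometry


def _default_smv_radii() -> tuple[float, ...]:
    # smallest kernel kept >= ~2.5 voxels at 0.8 mm; a 1 mm sphere is too few
    # voxels to act as a spherical mean and leaves the background in place
    return tuple(float(r) for r in range(12, 1, -1))


@dataclass(frozen=True)
class ReconConfig:
    """Tunable parameters of the QSM reconstruction chain."""

    unwrap_method: str = "laplacian"
    smv_radii_mm: tuple[float, ...] = dc_field(default_factory=_default_smv_radii)
    smv_tsvd_threshold: float = 0.01
    tkd_threshold: float = 0.05          # delta, dimensionless
    residual_threshold_rad: float = 0.3
    reference: str = "brain_mean"        # or "none"

    def __post_init__(self) -> None:
        if not 0 < self.tkd_threshold < 1:
            raise ValueError("tkd_threshold must be in (0, 1)")
        radii = tuple(float(r) for r in self.smv_radii_mm)
        if any(r <= 0 for r in radii) or any(np.diff(radii) >= 0):
            raise ValueError("smv_radii_mm must be positive and descending")
        object.__setattr__(self, "smv_radii_mm", radii)


@dataclass
class SusceptibilityMap:
    """Susceptibility map in ppb with its validity mask."""

    chi: np.ndarray
    mask: np.ndarray
    reference: str = "none"


def _dct_laplace_eigenvalues(shape, voxel_size_mm) -> np.ndarray:
    lam = np.zeros(shape)
    for axis, (n, h) in enumerate(zip(shape, voxel_size_mm)):
        k = np.arange(n)
        lam_axis = (2.0 - 2.0 * np.cos(np.pi * k / n)) / h**2
        sl = [None] * len(shape)
        sl[axis] = slice(None)
        lam = lam + lam_axis[tuple(sl)]
    return lam


def unwrap_phase(
    series: EchoSeries,
    mask: np.ndarray,
    method: str = "laplacian",
    n_refine: int = 3,
) -> np.ndarray:
    """Spatially unwrap each echo's phase; returns a 4-D array in rad.

    Laplacian method: the true-phase Laplacian is computed from the wrapped
    phase via cos*L(sin) - sin*L(cos) with a DCT spectral Laplacian (Neumann
    boundaries) and inverted by a Poisson solve.  The estimate is refined by
    re-unwrapping the wrapped residual (``n_refine`` fixed-point passes, which
    shrinks the smooth boundary-induced drift of the first solve), then
    snapped to a value congruent with the wrapped input — exact up to a 2*pi
    constant wherever the refined estimate is within pi of the truth.
    """
    if method != "laplacian":
        raise ValueError(f"unknown unwrap method: {method}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    geom = series.geometry
    shape = series.phase.shape[:-1]
    lam = _dct_laplace_eigenvalues(shape, geom.voxel_size_mm)
    inv_lam = np.zeros_like(lam)
    nonzero = lam > 0
    inv_lam[nonzero] = 1.0 / lam[nonzero]

    def lap(g):
        return idctn(-lam * dctn(g, norm="ortho"), norm="ortho")

    def solve(wrapped):
        s, c = np.sin(wrapped), np.cos(wrapped)
        rhs = c * lap(s) - s * lap(c)
        return idctn(-inv_lam * dctn(rhs, norm="ortho"), norm="ortho")

    out = np.empty_like(series.phase)
    for e in range(series.phase.shape[-1]):
        psi = series.phase[..., e]
        est = solve(psi)
        for _ in range(n_refine):
            resid = np.angle(np.exp(1j * (psi - est)))
            est = est + solve(resid)
        # align the estimate's global offset so est - psi sits at a whole
        # multiple of 2*pi (the Poisson solve is zero-mean, which can land the
        # offset exactly between two congruence classes)
        offset = np.angle(np.mean(np.exp(1j * (psi - est))[mask]))
        est = est + offset
        out[..., e] = psi + 2.0 * np.pi * np.round((est - psi) / (2.0 * np.pi))
    return out


def fit_field(unwrapped: np.ndarray, series: EchoSeries) -> FieldMap:
    """Magnitude-weighted linear fit of phase vs echo time, per voxel.

    Weights are the squared magnitudes; the slope over 2*pi is stored as
    frequency in Hz and the weighted RMS phase residual (rad) is kept for
    reliability filtering.  The phase intercept is discarded.
    """
    geom = series.geometry
    te = geom.echo_times_s
    if te.size < 2:
        raise ValueError("need at least 2 echoes to fit a field map")
    w = series.magnitude.astype(float) ** 2
    y = unwrapped
    sw = w.sum(axis=-1)
    swt = (w * te).sum(axis=-1)
    swtt = (w * te**2).sum(axis=-1)
    swy = (w * y).sum(axis=-1)
    swty = (w * te * y).sum(axis=-1)
    denom = sw * swtt - swt**2
    ok = denom > 0
    slope = np.zeros_like(sw)
    intercept = np.zeros_like(sw)
    slope[ok] = (sw[ok] * swty[ok] - swt[ok] * swy[ok]) / denom[ok]
    intercept[ok] = (swy[ok] - slope[ok] * swt[ok]) / sw[ok]
    resid = y - (slope[..., None] * te + intercept[..., None])
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt((w * resid**2).sum(axis=-1) / np.where(sw > 0, sw, np.nan))
    rms = np.nan_to_num(rms, nan=np.inf)
    rms[~ok] = np.inf
    return FieldMap(frequency=slope / (2.0 * np.pi), mask=ok, residual=rms)


def reliability_mask(
    field: FieldMap,
    config: ReconConfig,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels whose weighted phase-fit residual stays below the threshold.

    Returned as the intersection with ``mask`` (or the field's own mask);
    rejected voxels are simply dropped downstream, never interpolated.
    """
    if field.residual is None:
        raise ValueError("field map carries no fit residual")
    base = field.mask if mask is None else (np.asarray(mask, bool) & field.mask)
    return base & (field.residual <= config.residual_threshold_rad)


def _sphere_kernel_fft(shape, voxel_size_mm, radius_mm):
    """FFT of a normalized sphere of given radius centered at the origin."""
    dist2 = np.zeros(shape)
    for axis, (n, h) in enumerate(zip(shape, voxel_size_mm)):
        x = np.arange(n, dtype=float)
        x = np.minimum(x, n - x) * h
        sl = [None] * len(shape)
        sl[axis] = slice(None)
        dist2 = dist2 + x[tuple(sl)] ** 2
    kernel = (dist2 <= radius_mm**2).astype(float)
    kernel /= kernel.sum()
    return fftn(kernel)


def remove_background(
    field: FieldMap,
    mask: np.ndarray,
    config: ReconConfig,
    geometry: AcquisitionGeometry,
) -> FieldMap:
    """Variable-radius SMV (V-SHARP) background-field removal.

    Each voxel is high-pass filtered with the largest sphere still fully
    inside the mask; the combined filtered field is then deconvolved by the
    largest-radius SMV operator with truncated inversion
    (|1 - S(k)| < ``smv_tsvd_threshold`` suppressed).  The output is defined
    on the mask eroded by the smallest radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    shape = mask.shape
    f = np.where(mask, field.frequency, 0.0)
    fk = fftn(f)
    mk = fftn(mask.astype(float))

    local = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    for radius in config.smv_radii_mm:
        sk = _sphere_kernel_fft(shape, geometry.voxel_size_mm, radius)
        # voxels whose whole sphere support lies inside the mask
        coverage = np.real(ifftn(mk * sk))
        eroded = mask & (coverage >= 1.0 - 1e-6)
        new = eroded & ~assigned
        if not new.any():
            continue
        # SHARP at this radius: masked high-pass, deconvolved by 1 - S(k)
        high_pass = np.where(eroded, f - np.real(ifftn(fk * sk)), 0.0)
        op = 1.0 - sk
        inv = np.zeros_like(op)
        keep = np.abs(op) >= config.smv_tsvd_threshold
        inv[keep] = 1.0 / op[keep]
        sharp = np.real(ifftn(fftn(high_pass) * inv))
        local[new] = sharp[new]
        assigned |= eroded
    if not assigned.any():
        raise ValueError("mask is smaller than the smallest SMV kernel")
    local[~assigned] = 0.0
    return FieldMap(frequency=local, mask=assigned, residual=field.residual)


def invert_dipole(
    local: FieldMap,
    geometry: AcquisitionGeometry,
    config: ReconConfig,
) -> SusceptibilityMap:
    """Thresholded k-space division of the local field (Hz) into chi (ppb).

    chi(k) = F(k)/D(k) where |D(k)| >= delta, else F(k)/(delta*sign(D(k)));
    the sign at D = 0 is taken positive.
    """
    delta = config.tkd_threshold
    if not 0 < delta < 1:
        raise ValueError("tkd threshold must be in (0, 1)")
    d = _dipole_values(
        local.frequency.shape, geometry.voxel_size_mm, geometry.b0_direction
    )
    sign = np.where(d >= 0, 1.0, -1.0)
    d_clamped = np.where(np.abs(d) >= delta, d, delta * sign)
    fk = fftn(np.where(local.mask, local.frequency, 0.0))
    chi_hz = np.real(ifftn(fk / d_clamped))
    chi_ppb = chi_hz / geometry.hz_per_ppb
    chi_ppb[~local.mask] = 0.0
    return SusceptibilityMap(chi=chi_ppb, mask=local.mask, reference="none")


def reference_qsm(
    chi_map: SusceptibilityMap,
    mask: np.ndarray | None = None,
    reference: str = "brain_mean",
) -> SusceptibilityMap:
    """Re-express chi relative to the mean over the mask (idempotent)."""
    if reference == "none":
        return chi_map
    if reference != "brain_mean":
        raise ValueError(f"unknown reference: {reference}")
    mask = chi_map.mask if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("reference mask is empty")
    chi = chi_map.chi.copy()
    chi[chi_map.mask] -= chi[mask].mean()
    return SusceptibilityMap(chi=chi, mask=chi_map.mask, reference="brain_mean")


def reconstruct_qsm(
    series: EchoSeries,
    mask: np.ndarray,
    config: ReconConfig | None = None,
) -> tuple[SusceptibilityMap, FieldMap, np.ndarray]:
    """Full chain: unwrap, fit, filter, background removal, TKD, reference.

    Returns the susceptibility map, the local field map and the reliability
    mask actually used.
    """
    config = config or ReconConfig()
    geom = series.geometry
    unwrapped = unwrap_phase(series, mask, method=config.unwrap_method)
    field = fit_field(unwrapped, series)
    reliable = reliability_mask(field, config, mask)
    local = remove_background(field, mask, config, geom)
    local.mask &= reliable
    chi_map = invert_dipole(local, geom, config)
    chi_map = reference_qsm(chi_map, reference=config.reference)
    return chi_map, local, reliable
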