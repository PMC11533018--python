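"""Digital brain phantom with known susceptibility and R2* in deep gray matter.

The phantom is a brain-shaped ellipsoid containing seven bilateral ellipsoidal
deep-gray-matter (DGM) structures (accumbens, amygdala, caudate, globus
pallidus, hippocampus, putamen, thalamus) placed mirror-symmetrically about
the mid-sagittal plane.  Default susceptibilities are the female linear age
models evaluated at age 65 (putamen and caudate strongly positive, thalamus
and limbic structures negative); R2* is tied to susceptibility by an affine
map so both iron proxies vary together, as they do in tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry

DGM_STRUCTURES = (
    "accumbens",
    "amygdala",
    "caudate",
    "globus_pallidus",
    "hippocampus",
    "putamen",
    "thalamus",
)

# label code = 2*index+1 for left, 2*index+2 for right (0 = background)
LABEL_CODES = {
    name: (2 * i + 1, 2 * i + 2) for i, name in enumerate(DGM_STRUCTURES)
}


def label_code(roi_name: str, hemisphere: str) -> int:
    left, right = LABEL_CODES[roi_name]
    if hemisphere == "L":
        return left
    if hemisphere == "R":
        return right
    raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")


@dataclass(frozen=True)
class StructureSpec:
    """One bilateral DGM structure: ellipsoid placement plus tissue values.

    ``center_mm`` is the right-hemisphere center relative to the grid center
    (axis 0 = left-right); the left copy is mirrored about the mid-sagittal
    plane.  ``chi_ppb`` is susceptibility relative to background tissue.
    """

    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    chi_ppb: float
    r2star_s: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"{self.name}: semi-axes must be positive")
        if self.r2star_s < 0:
            raise ValueError(f"{self.name}: r2star must be >= 0")


def r2star_from_chi(chi_ppb: float, base: float = 30.0, slope: float = 0.5,
                    floor: float = 5.0) -> float:
    """Affine susceptibility-to-R2* map used by the default phantom (s^-1)."""
    return max(floor, base + slope * chi_ppb)


def _table1_chi_at_65() -> dict[str, float]:
    # female linear age models evaluated at age 65 (intercept + slope*65, ppb)
    from .cohort import load_table1_models

    chi = {}
    for m in load_table1_models():
        if m.sex == "F" and m.metric == "qsm":
            chi[m.roi_name] = m.intercept + m.slope * 65.0
    return chi


def default_structure_specs() -> list[StructureSpec]:
    """The seven bilateral DGM ellipsoids of the default phantom."""
    placement = {
        # name: (center_mm right hemisphere, semi_axes_mm)
        "caudate": ((10.0, 10.0, 8.0), (3.5, 7.0, 5.0)),
        "putamen": ((18.0, 2.0, 0.0), (5.0, 8.0, 6.0)),
        "globus_pallidus": ((9.0, 0.0, -2.0), (3.0, 4.5, 4.0)),
        "thalamus": ((8.0, -12.0, 2.0), (5.0, 7.0, 5.5)),
        "hippocampus": ((18.0, -13.0, -6.0), (4.0, 7.5, 4.5)),
        "amygdala": ((16.0, 2.0, -12.0), (4.5, 5.0, 4.0)),
        "accumbens": ((7.0, 9.0, -6.0), (3.0, 3.5, 3.0)),
    }
    chi = _table1_chi_at_65()
    return [
        StructureSpec(
            name=name,
            center_mm=placement[name][0],
            semi_axes_mm=placement[name][1],
            chi_ppb=chi[name],
            r2star_s=r2star_from_chi(chi[name]),
        )
        for name in DGM_STRUCTURES
    ]


@dataclass
class PhantomTruth:
    """Ground-truth volumes of the digital phantom."""

    chi: np.ndarray          # ppb
    r2star: np.ndarray       # s^-1
    m0: np.ndarray           # arbitrary units
    labels: np.ndarray       # int, 0 = background
    brain_mask: np.ndarray   # bool
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.r2star < 0):
            raise ValueError("r2star must be non-negative everywhere")
        if np.any((self.labels != 0) & ~self.brain_mask):
            raise ValueError("labels must be zero outside the brain mask")

    def roi_mask(self, roi_name: str, hemisphere: str | None = None) -> np.ndarray:
        left, right = LABEL_CODES[roi_name]
        if hemisphere == "L":
            return self.labels == left
        if hemisphere == "R":
            return self.labels == right
        return (self.labels == left) | (self.labels == right)


def _grid_coords_mm(geometry: AcquisitionGeometry) -> list[np.ndarray]:
    coords = []
    for n, h in zip(geometry.grid_shape, geometry.voxel_size_mm):
        coords.append((np.arange(n) - (n - 1) / 2.0) * h)
    return coords


def _ellipsoid_mask(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    q = (
        ((x[:, None, None] - center[0]) / semi_axes[0]) ** 2
        + ((y[None, :, None] - center[1]) / semi_axes[1]) ** 2
        + ((z[None, None, :] - center[2]) / semi_axes[2]) ** 2
    )
    return q <= 1.0


def make_phantom(
    geometry: AcquisitionGeometry,
    structures: list[StructureSpec] | None = None,
    seed: int = 0,
    brain_semi_axes_mm: tuple[float, float, float] = (33.0, 36.0, 33.0),
    background_chi_ppb: float = 0.0,
    background_r2star_s: float = 30.0,
    background_m0: float = 100.0,
    m0_texture_sd: float = 0.03,
) -> PhantomTruth:
    """Build the bilateral ellipsoid phantom on the acquisition grid.

    Structures are placed mirror-symmetrically about the mid-sagittal plane
    (axis 0).  Overlapping structures or structures poking outside the brain
    ellipsoid raise a ``ValueError`` naming the offender.  Deterministic for a
    fixed ``seed`` (the seed only drives a mild smooth M0 texture).
    """
    if structures is None:
        structures = default_structure_specs()
    coords = _grid_coords_mm(geometry)
    brain_mask = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), brain_semi_axes_mm)

    labels = np.zeros(geometry.grid_shape, dtype=np.int16)
    chi = np.full(geometry.grid_shape, 0.0)
    chi[brain_mask] = background_chi_ppb
    r2star = np.zeros(geometry.grid_shape)
    r2star[brain_mask] = background_r2star_s
    owner = {}  # code -> (name, hemisphere)

    for spec in structures:
        for hemi in ("R", "L"):
            cx, cy, cz = spec.center_mm
            center = (cx if hemi == "R" else -cx, cy, cz)
            mask = _ellipsoid_mask(coords, center, spec.semi_axes_mm)
            if np.any(mask & ~brain_mask):
                raise ValueError(
                    f"structure {spec.name} ({hemi}) extends outside the brain"
                )
            clash = mask & (labels != 0)
            if np.any(clash):
                other_code = int(labels[clash][0])
                other = owner[other_code]
                raise ValueError(
                    f"structures overlap: {spec.name} ({hemi}) and "
                    f"{other[0]} ({other[1]})"
                )
            code = label_code(spec.name, hemi)
            labels[mask] = code
            owner[code] = (spec.name, hemi)
            chi[mask] = spec.chi_ppb
            r2star[mask] = spec.r2star_s

    rng = np.random.default_rng(seed)
    m0 = np.zeros(geometry.grid_shape)
    if m0_texture_sd > 0:
        texture = ndimage.gaussian_filter(
            rng.standard_normal(geometry.grid_shape), sigma=3.0
        )
        texture = texture / max(texture.std(), 1e-12) * m0_texture_sd
    else:
        texture = np.zeros(geometry.grid_shape)
    m0[brain_mask] = background_m0 * (1.0 + texture[brain_mask])
    np.clip(m0, 0.0, None, out=m0)

    return PhantomTruth(
        chi=chi, r2star=r2star, m0=m0, labels=labels,
        brain_mask=brain_mask, seed=seed,
    )
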