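"""Synthetic diffusion-weighted phantom with known ground truth.

The phantom emulates the periventricular geometry the ALPS protocol reads at
the level of the deep medullary veins: a central CSF-filled ventricle flanked
on each side by a projection-fiber band (principal diffusion axis
inferior-superior, z) and, lateral to it, an association-fiber band
(principal axis anterior-posterior, y). Deep medullary veins run left-right
(x), perpendicular to both tracts, so x-diffusivity in the two bands carries
the perivascular-flow signal the ALPS index measures.

Signals follow the single-tensor model S = S0 * exp(-b g^T D g); magnitude
noise is Rician. Every voxel's assigned tensor, the per-hemisphere analytic
ALPS index, and suggested ROI centers are recorded as ground truth so the
full imaging pipeline can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionScheme, make_scheme, write_bvals_bvecs

__all__ = [
    "REGION_LABELS",
    "PhantomSpec",
    "DWIVolume",
    "PhantomTruth",
    "LesionMasks",
    "default_tissue_tensors",
    "tensor_signal",
    "build_alps_phantom",
    "add_rician_noise",
    "simulate_lesion_masks",
]

# integer codes for the region map
REGION_LABELS = {
    "background": 0,
    "ventricle_CSF": 1,
    "projection_fiber_L": 2,
    "projection_fiber_R": 3,
    "association_fiber_L": 4,
    "association_fiber_R": 5,
    "hematoma": 6,
    "edema": 7,
}
_LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}


def _diag(dx: float, dy: float, dz: float) -> np.ndarray:
    return np.diag([dx, dy, dz]).astype(float)


def default_tissue_tensors() -> dict[str, np.ndarray]:
    """Default tissue tensors (mm^2/s), phantom parameters rather than claims.

    Fiber diagonals are chosen so the analytic ALPS index of a healthy
    hemisphere, (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc), equals
    (1.15 + 1.04) / (0.8 + 0.7) = 1.46 — the center of the healthy-control
    range this index takes in adults.
    """
    return {
        "background": _diag(0.7e-3, 0.7e-3, 0.7e-3),
        "ventricle_CSF": _diag(3.0e-3, 3.0e-3, 3.0e-3),
        "projection_fiber_L": _diag(1.15e-3, 0.8e-3, 1.7e-3),
        "projection_fiber_R": _diag(1.15e-3, 0.8e-3, 1.7e-3),
        "association_fiber_L": _diag(1.04e-3, 1.7e-3, 0.7e-3),
        "association_fiber_R": _diag(1.04e-3, 1.7e-3, 0.7e-3),
        "hematoma": _diag(0.4e-3, 0.4e-3, 0.4e-3),
        "edema": _diag(1.2e-3, 1.2e-3, 1.2e-3),
    }


@dataclass
class PhantomSpec:
    """Parameters of the synthetic DWI phantom.

    Attributes
    ----------
    shape : voxel grid (nx, ny, nz).
    voxel_size_mm : in-plane and through-plane voxel dimensions.
    s0 : unweighted signal amplitude (arbitrary units).
    tensors : label name -> 3x3 symmetric positive-definite tensor (mm^2/s).
    noise_sigma : Rician noise level in the units of ``s0``.
    scheme : acquisition; defaults to 30 directions at b=1000 plus one b=0.
    region_map : optional precomputed label volume; when None the default
        periventricular geometry is built.
    lesion_center_vox / hematoma_radii_mm / lesion_radii_mm : optional nested
        hematoma / total-lesion ellipsoids painted into the region map.
    seed : seed for the noise generator.
    """

    shape: tuple[int, int, int] = (96, 96, 40)
    voxel_size_mm: tuple[float, float, float] = (1.7, 1.7, 2.0)
    s0: float = 1000.0
    tensors: dict[str, np.ndarray] = field(default_factory=default_tissue_tensors)
    noise_sigma: float = 0.0
    scheme: Optional[AcquisitionScheme] = None
    region_map: Optional[np.ndarray] = None
    lesion_center_vox: Optional[tuple[float, float, float]] = None
    hematoma_center_vox: Optional[tuple[float, float, float]] = None
    hematoma_radii_mm: Optional[tuple[float, float, float]] = None
    lesion_radii_mm: Optional[tuple[float, float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme is None:
            self.scheme = make_scheme(30, 1000.0, 1)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name, D in self.tensors.items():
            if name not in REGION_LABELS:
                raise ValueError(f"unknown region label {name!r}")
            D = np.asarray(D, dtype=float)
            if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
                raise ValueError(f"tensor for {name!r} must be symmetric 3x3")
            if np.any(np.linalg.eigvalsh(D) <= 0):
                raise ValueError(f"tensor for {name!r} must be positive definite")
            self.tensors[name] = D

    @property
    def affine(self) -> np.ndarray:
        """Axis-aligned RAS affine with the world origin at the volume center."""
        aff = np.eye(4)
        vox = np.asarray(self.voxel_size_mm, dtype=float)
        aff[:3, :3] = np.diag(vox)
        aff[:3, 3] = -vox * (np.asarray(self.shape) - 1) / 2.0
        return aff


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal stack with its affine and scheme."""

    data: np.ndarray  # (x, y, z, volume)
    affine: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must equal the scheme "
                f"volume count ({self.scheme.n_volumes})"
            )
        if np.any(self.data < 0):
            raise ValueError("signals must be non-negative")

    def save(self, out_dir, stem: str = "dwi") -> dict[str, Path]:
        """Write NIfTI-1 (.nii.gz) plus FSL bval/bvec; returns written paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "dwi": out_dir / f"{stem}.nii.gz",
            "bval": out_dir / f"{stem}.bval",
            "bvec": out_dir / f"{stem}.bvec",
        }
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), paths["dwi"])
        write_bvals_bvecs(self.scheme, paths["bval"], paths["bvec"])
        return paths


@dataclass
class LesionMasks:
    """Binary hematoma and total-lesion masks on (possibly distinct) grids."""

    hematoma: np.ndarray
    total_lesion: np.ndarray
    hematoma_affine: np.ndarray
    total_lesion_affine: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hematoma", "total_lesion"):
            m = np.asarray(getattr(self, name))
            if not np.isin(m, [0, 1]).all():
                raise ValueError(f"{name} mask must be binary")
            setattr(self, name, m.astype(bool))
        if self.hematoma.shape == self.total_lesion.shape:
            if np.any(self.hematoma & ~self.total_lesion):
                raise ValueError("hematoma mask must be contained in the total lesion mask")


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom (test oracle)."""

    region_map: np.ndarray
    tensors: dict[str, np.ndarray]
    roi_centers: dict[tuple[str, str], tuple[int, int, int]]  # (hemisphere, fiber) -> ijk
    dmv_slice: int
    analytic_alps: dict[str, float]  # hemisphere -> index
    lesion_masks: Optional[LesionMasks] = None

    def tensor_field(self) -> np.ndarray:
        """Per-voxel (nx, ny, nz, 3, 3) ground-truth tensor array."""
        out = np.zeros(self.region_map.shape + (3, 3))
        for name, code in REGION_LABELS.items():
            sel = self.region_map == code
            if np.any(sel):
                out[sel] = self.tensors[name]
        return out


def tensor_signal(D: np.ndarray, scheme: AcquisitionScheme, s0: float) -> np.ndarray:
    """Single-tensor DWI signal S_i = s0 * exp(-b_i g_i^T D g_i).

    b=0 entries equal ``s0`` exactly.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("D must be a symmetric 3x3 tensor")
    if np.any(np.linalg.eigvalsh(D) < -1e-12):
        raise ValueError("D must be positive semidefinite")
    g = scheme.bvectors
    adc = np.einsum("ij,jk,ik->i", g, D, g)
    return float(s0) * np.exp(-scheme.bvalues * adc)


def _build_region_map(spec: PhantomSpec) -> np.ndarray:
    """Default periventricular geometry, symmetric about the midline."""
    nx, ny, nz = spec.shape
    region = np.zeros(spec.shape, dtype=np.int16)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    # widths in voxels, scaled to the grid
    vent_hw = max(2, nx // 16)        # ventricle half-width (x)
    band_w = max(2, nx // 16)         # fiber band width (x)
    y_hw = max(3, ny // 6)            # anterior-posterior half-extent
    z0, z1 = nz // 4, nz - nz // 4    # central slab of slices

    dx = ii - cx
    in_y = np.abs(jj - cy) <= y_hw
    vent = (np.abs(dx) <= vent_hw) & in_y
    proj = (np.abs(dx) > vent_hw) & (np.abs(dx) <= vent_hw + band_w) & in_y
    assoc = (
        (np.abs(dx) > vent_hw + band_w)
        & (np.abs(dx) <= vent_hw + 2 * band_w)
        & in_y
    )
    left = dx < 0  # RAS: +x is right

    sl = np.s_[:, :, z0:z1]
    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[vent] = REGION_LABELS["ventricle_CSF"]
    plane[proj & left] = REGION_LABELS["projection_fiber_L"]
    plane[proj & ~left] = REGION_LABELS["projection_fiber_R"]
    plane[assoc & left] = REGION_LABELS["association_fiber_L"]
    plane[assoc & ~left] = REGION_LABELS["association_fiber_R"]
    region[sl] = plane[:, :, None]
    return region


def _ellipsoid_mask(shape, voxel_size, center_vox, radii_mm) -> np.ndarray:
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii <= 0):
        return np.zeros(shape, dtype=bool)
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(
        (((c - c0) * v) / r) ** 2
        for c, c0, v, r in zip(coords, center_vox, voxel_size, radii)
    )
    return d2 <= 1.0


def simulate_lesion_masks(spec: PhantomSpec) -> LesionMasks:
    """Voxelize the spec's nested hematoma / total-lesion ellipsoids.

    The hematoma ellipsoid must be geometrically contained in the total
    lesion ellipsoid (axis-aligned nesting check); the region between them
    is the perihematomal edema.
    """
    if spec.lesion_center_vox is None or spec.lesion_radii_mm is None:
        raise ValueError("spec defines no lesion (lesion_center_vox / lesion_radii_mm)")
    hema_r = np.asarray(spec.hematoma_radii_mm if spec.hematoma_radii_mm else (0, 0, 0), float)
    total_r = np.asarray(spec.lesion_radii_mm, dtype=float)
    hema_c = np.asarray(
        spec.hematoma_center_vox if spec.hematoma_center_vox is not None
        else spec.lesion_center_vox, dtype=float,
    )
    total_c = np.asarray(spec.lesion_center_vox, dtype=float)
    offset_mm = np.abs(hema_c - total_c) * np.asarray(spec.voxel_size_mm)
    if np.any(hema_r > 0) and np.any(offset_mm + hema_r > total_r):
        raise ValueError("hematoma ellipsoid is not contained in the total lesion ellipsoid")
    hema = _ellipsoid_mask(spec.shape, spec.voxel_size_mm, hema_c, hema_r)
    total = _ellipsoid_mask(spec.shape, spec.voxel_size_mm, spec.lesion_center_vox, total_r)
    return LesionMasks(
        hematoma=hema,
        total_lesion=total,
        hematoma_affine=spec.affine,
        total_lesion_affine=spec.affine,
    )


def _analytic_alps(tensors: dict[str, np.ndarray], hemisphere: str) -> float:
    suffix = "L" if hemisphere == "left" else "R"
    proj = tensors[f"projection_fiber_{suffix}"]
    assoc = tensors[f"association_fiber_{suffix}"]
    return float((proj[0, 0] + assoc[0, 0]) / (proj[1, 1] + assoc[2, 2]))


def build_alps_phantom(spec: PhantomSpec) -> tuple[DWIVolume, PhantomTruth]:
    """Generate the DWI phantom and its ground truth.

    Noiseless signals equal ``tensor_signal`` of each voxel's assigned
    tensor; Rician noise is added when ``spec.noise_sigma > 0``. ROI centers
    are the per-hemisphere fiber-band centroids on the deep-medullary-vein
    slice (the central slice of the phantom).
    """
    region = spec.region_map.copy() if spec.region_map is not None else _build_region_map(spec)
    if region.shape != tuple(spec.shape):
        raise ValueError("region_map shape must match spec.shape")
    lesions = None
    if spec.lesion_center_vox is not None and spec.lesion_radii_mm is not None:
        lesions = simulate_lesion_masks(spec)
        edema = lesions.total_lesion & ~lesions.hematoma
        region[edema] = REGION_LABELS["edema"]
        region[lesions.hematoma] = REGION_LABELS["hematoma"]

    labels_present = np.unique(region)
    unknown = set(labels_present.tolist()) - set(_LABEL_NAMES)
    if unknown:
        raise ValueError(f"region map contains unknown labels: {sorted(unknown)}")

    data = np.empty(tuple(spec.shape) + (spec.scheme.n_volumes,))
    for code in labels_present:
        name = _LABEL_NAMES[int(code)]
        if name not in spec.tensors:
            raise ValueError(f"no tensor assigned for region {name!r}")
        data[region == code] = tensor_signal(spec.tensors[name], spec.scheme, spec.s0)

    dwi = DWIVolume(data=data, affine=spec.affine, scheme=spec.scheme)
    if spec.noise_sigma > 0:
        dwi = add_rician_noise(dwi, spec.noise_sigma, spec.seed)

    # ground-truth ROI centers: the most interior voxel of each fiber band on
    # the deep-medullary-vein slice, so a small disc stays inside the band
    from scipy import ndimage

    dmv_slice = spec.shape[2] // 2
    roi_centers: dict[tuple[str, str], tuple[int, int, int]] = {}
    for hemi, suffix in (("left", "L"), ("right", "R")):
        for fiber in ("projection", "association"):
            code = REGION_LABELS[f"{fiber}_fiber_{suffix}"]
            plane = region[:, :, dmv_slice] == code
            if np.any(plane):
                depth = ndimage.distance_transform_edt(
                    plane, sampling=spec.voxel_size_mm[:2]
                )
                i, j = np.unravel_index(int(np.argmax(depth)), plane.shape)
                roi_centers[(hemi, fiber)] = (int(i), int(j), dmv_slice)

    truth = PhantomTruth(
        region_map=region,
        tensors=dict(spec.tensors),
        roi_centers=roi_centers,
        dmv_slice=dmv_slice,
        analytic_alps={h: _analytic_alps(spec.tensors, h) for h in ("left", "right")},
        lesion_masks=lesions,
    )
    return dwi, truth


def add_rician_noise(dwi: DWIVolume, sigma: float, seed: int = 0) -> DWIVolume:
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return dwi
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=dwi.data.shape)
    n2 = rng.normal(0.0, sigma, size=dwi.data.shape)
    noisy = np.sqrt((dwi.data + n1) ** 2 + n2**2)
    return DWIVolume(data=noisy, affine=dwi.affine, scheme=dwi.scheme)
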