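"""DTI-ALPS: diffusivity ratio along the perivascular space.

At the level of the lateral-ventricle body the deep medullary veins run
left-right (x), perpendicular both to the projection fibers (principal axis
z) and to the association fibers (principal axis y). Water movement along
the perivascular spaces of those veins raises x-diffusivity in both tracts,
so the index

    ALPS = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)

compares diffusivity along the perivascular axis against each tract's
non-dominant, non-perivascular axes. An index near 1 means no preferential
perivascular diffusion; healthy adults typically measure ~1.3-1.7.

ROIs are 5 mm diameter discs drawn on a single axial slice of the
color-coded FA map (membership = voxel center within the disc, native grid,
no partial-volume weighting). Measurement is attempted bilaterally; the
hematoma side maps indices to ipsilateral/contralateral, while subtentorial
or absent lesions use only the mean of the two sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ROISpec",
    "ROIMeans",
    "ALPSResult",
    "extract_roi_means",
    "roi_voxel_indices",
    "compute_alps",
    "lateralize",
    "alps_from_maps",
    "suggest_roi_centers",
    "read_roi_file",
    "write_roi_file",
]

FIBER_CLASSES = ("projection", "association")
HEMISPHERES = ("left", "right")
LESION_SIDES = ("left", "right", "subtentorial", "none")


@dataclass(frozen=True)
class ROISpec:
    """A circular ROI on one axial slice.

    ``center_vox`` is a 0-based (i, j, k) voxel index; the disc of
    ``diameter_mm`` lives in the axial (i, j) plane of slice k.
    """

    hemisphere: str
    fiber_class: str
    center_vox: tuple[int, int, int]
    diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.fiber_class not in FIBER_CLASSES:
            raise ValueError(f"fiber_class must be one of {FIBER_CLASSES}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


@dataclass
class ROIMeans:
    """Mean Dxx/Dyy/Dzz over the projection and association ROIs of one
    hemisphere (mm^2/s), with the contributing voxel counts."""

    dx_proj: float
    dy_proj: float
    dz_proj: float
    dx_assoc: float
    dy_assoc: float
    dz_assoc: float
    n_voxels_proj: int
    n_voxels_assoc: int


@dataclass
class ALPSResult:
    """Per-hemisphere and lateralized ALPS indices.

    ``ipsilateral``/``contralateral`` are None for subtentorial lesions or
    when no lesion side applies; ``average`` is always the mean of the two
    hemispheric indices.
    """

    left: float
    right: float
    lesion_side: str
    ipsilateral: Optional[float] = None
    contralateral: Optional[float] = None
    average: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def roi_voxel_indices(shape, voxel_size_mm, roi: ROISpec) -> np.ndarray:
    """(n, 3) voxel indices whose in-plane centers fall within the ROI disc."""
    ci, cj, k = roi.center_vox
    nx, ny, nz = shape[:3]
    if not (0 <= ci < nx and 0 <= cj < ny and 0 <= k < nz):
        raise ValueError(
            f"ROI {roi.hemisphere}/{roi.fiber_class} center {roi.center_vox} "
            f"is outside the volume {tuple(shape[:3])}"
        )
    r = roi.diameter_mm / 2.0
    vx, vy = float(voxel_size_mm[0]), float(voxel_size_mm[1])
    di = int(np.floor(r / vx)) + 1
    dj = int(np.floor(r / vy)) + 1
    ii, jj = np.meshgrid(
        np.arange(max(0, ci - di), min(nx, ci + di + 1)),
        np.arange(max(0, cj - dj), min(ny, cj + dj + 1)),
        indexing="ij",
    )
    inside = ((ii - ci) * vx) ** 2 + ((jj - cj) * vy) ** 2 <= r**2
    out = np.column_stack([ii[inside], jj[inside], np.full(int(inside.sum()), k)])
    if out.shape[0] == 0:
        raise ValueError(f"ROI {roi.hemisphere}/{roi.fiber_class} contains no voxel centers")
    return out


def extract_roi_means(
    dxx: np.ndarray,
    dyy: np.ndarray,
    dzz: np.ndarray,
    roi: ROISpec,
    voxel_size_mm,
    mask: Optional[np.ndarray] = None,
) -> tuple[float, float, float, int]:
    """Mean of each axis-diffusivity map over the ROI disc.

    Returns (Dxx_mean, Dyy_mean, Dzz_mean, n_voxels). Voxels outside
    ``mask`` (when given) are excluded; an ROI with no usable voxels is an
    error naming the ROI.
    """
    idx = roi_voxel_indices(dxx.shape, voxel_size_mm, roi)
    sel = tuple(idx.T)
    if mask is not None:
        keep = mask[sel]
        if not np.any(keep):
            raise ValueError(
                f"ROI {roi.hemisphere}/{roi.fiber_class} at {roi.center_vox} "
                "has no voxels inside the fit mask"
            )
        sel = tuple(idx[keep].T)
    return (
        float(dxx[sel].mean()),
        float(dyy[sel].mean()),
        float(dzz[sel].mean()),
        int(sel[0].shape[0]),
    )


def compute_alps(means: ROIMeans) -> float:
    """The ALPS ratio (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)."""
    denom = means.dy_proj + means.dz_assoc
    if denom <= 0:
        raise ValueError("ALPS denominator (Dyy_proj + Dzz_assoc) must be positive")
    return float((means.dx_proj + means.dx_assoc) / denom)


def lateralize(
    left: Optional[float], right: Optional[float], lesion_side: str
) -> ALPSResult:
    """Map hemispheric indices onto ipsilateral/contralateral by lesion side.

    Unilateral supratentorial lesions define ipsilateral = lesion hemisphere;
    subtentorial lesions and lesion-free subjects carry only the average.
    """
    if lesion_side not in LESION_SIDES:
        raise ValueError(f"lesion_side must be one of {LESION_SIDES}")
    if left is None or right is None:
        raise ValueError("both hemispheric indices are required")
    avg = (left + right) / 2.0
    if lesion_side == "left":
        return ALPSResult(left, right, lesion_side, ipsilateral=left,
                          contralateral=right, average=avg)
    if lesion_side == "right":
        return ALPSResult(left, right, lesion_side, ipsilateral=right,
                          contralateral=left, average=avg)
    return ALPSResult(left, right, lesion_side, average=avg)


def alps_from_maps(
    dxx: np.ndarray,
    dyy: np.ndarray,
    dzz: np.ndarray,
    rois: list[ROISpec],
    voxel_size_mm,
    lesion_side: str = "none",
    mask: Optional[np.ndarray] = None,
) -> tuple[ALPSResult, dict[str, ROIMeans]]:
    """Full ROI-to-index computation for both hemispheres.

    ``rois`` must contain one projection and one association ROI per
    hemisphere. Returns the lateralized result and the per-hemisphere
    :class:`ROIMeans`.
    """
    by_key = {(r.hemisphere, r.fiber_class): r for r in rois}
    indices: dict[str, float] = {}
    means_out: dict[str, ROIMeans] = {}
    for hemi in HEMISPHERES:
        for fiber in FIBER_CLASSES:
            if (hemi, fiber) not in by_key:
                raise ValueError(f"missing {fiber} ROI for the {hemi} hemisphere")
        px, py, pz, npx = extract_roi_means(dxx, dyy, dzz, by_key[(hemi, "projection")],
                                            voxel_size_mm, mask)
        ax, ay, az, nax = extract_roi_means(dxx, dyy, dzz, by_key[(hemi, "association")],
                                            voxel_size_mm, mask)
        means = ROIMeans(px, py, pz, ax, ay, az, npx, nax)
        means_out[hemi] = means
        indices[hemi] = compute_alps(means)
    return lateralize(indices["left"], indices["right"], lesion_side), means_out


def suggest_roi_centers(
    features, voxel_size_mm, slice_index: Optional[int] = None, band_halfwidth_mm: float = 30.0
) -> list[ROISpec]:
    """Advisory ROI placement from the color-FA map.

    Searches an in-plane band around the volume center on one axial slice
    for the voxel with the strongest z-dominant (projection) and y-dominant
    (association) color-FA per hemisphere. The output is a starting point to
    be reviewed, mirroring manual placement practice.
    """
    color = features.color
    nx, ny, nz = color.shape[:3]
    k = nz // 2 if slice_index is None else slice_index
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    band = (np.abs((ii - cx) * voxel_size_mm[0]) <= band_halfwidth_mm) & (
        np.abs((jj - cy) * voxel_size_mm[1]) <= band_halfwidth_mm
    )
    out = []
    for hemi, hemi_sel in (("left", ii < cx), ("right", ii > cx)):
        region = band & hemi_sel
        for fiber, axis in (("projection", 2), ("association", 1)):
            others = [a for a in (0, 1, 2) if a != axis]
            score = color[:, :, k, axis] - np.maximum(
                color[:, :, k, others[0]], color[:, :, k, others[1]]
            )
            score = np.where(region, score, -np.inf)
            i, j = np.unravel_index(int(np.argmax(score)), score.shape)
            out.append(ROISpec(hemisphere=hemi, fiber_class=fiber, center_vox=(int(i), int(j), k)))
    return out


def write_roi_file(rois: list[ROISpec], path) -> None:
    payload = [
        {
            "hemisphere": r.hemisphere,
            "fiber_class": r.fiber_class,
            "center_voxel": list(r.center_vox),
            "diameter_mm": r.diameter_mm,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_roi_file(path) -> list[ROISpec]:
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        out.append(
            ROISpec(
                hemisphere=item["hemisphere"],
                fiber_class=item["fiber_class"],
                center_vox=tuple(int(v) for v in item["center_voxel"]),
                diameter_mm=float(item.get("diameter_mm", 5.0)),
            )
        )
    return out
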