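"""Lesion volumetry: hematoma and edema volumes, relative edema ratio.

Hematoma masks come from susceptibility-weighted images and total-lesion
masks from T2-weighted images, so the two may live on different grids;
volumes are computed on each mask's native grid and combined as scalars.
Edema is total lesion minus hematoma; the relative edema ratio is
edema / hemorrhage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeReport",
    "mask_volume",
    "edema_volume",
    "relative_edema_ratio",
    "volume_report",
    "load_mask",
    "voxel_volume_mm3",
]

logger = logging.getLogger(__name__)


@dataclass
class VolumeReport:
    """Scalar volumetry summary per subject."""

    hemorrhage_ml: float
    edema_ml: float
    relative_edema_ratio: float

    def to_dict(self) -> dict:
        return asdict(self)


def voxel_volume_mm3(affine: np.ndarray, pixdim=None) -> float:
    """Voxel volume from the affine's column norms.

    A header pixdim disagreeing with the affine by more than 1e-3 is logged;
    the affine wins.
    """
    norms = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    if pixdim is not None:
        pixdim = np.asarray(pixdim, dtype=float)[:3]
        if np.any(np.abs(pixdim - norms) > 1e-3):
            logger.warning("header pixdim %s disagrees with affine voxel size %s", pixdim, norms)
    return float(np.prod(norms))


def mask_volume(mask: np.ndarray, voxel_vol_mm3: float) -> float:
    """Volume in mL: nonzero-voxel count x voxel volume (mm^3) / 1000.

    The mask must be binary (values 0/1 after any nonzero -> 1 relabeling is
    the caller's job; mixed values are rejected to catch probability maps).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, [0, 1]).all():
        raise ValueError("mask must be binary (0/1)")
    return float(np.count_nonzero(mask)) * float(voxel_vol_mm3) / 1000.0


def edema_volume(total_lesion_ml: float, hematoma_ml: float) -> float:
    """Edema = total lesion - hematoma, floored at 0.

    Cross-modality grids can disagree slightly; a negative difference is
    floored with a warning rather than raised.
    """
    if total_lesion_ml < 0 or hematoma_ml < 0:
        raise ValueError("volumes must be non-negative")
    diff = total_lesion_ml - hematoma_ml
    if diff < 0:
        logger.warning(
            "hematoma volume (%.3f mL) exceeds total lesion volume (%.3f mL); "
            "edema floored at 0", hematoma_ml, total_lesion_ml,
        )
        return 0.0
    return diff


def relative_edema_ratio(edema_ml: float, hemorrhage_ml: float) -> float:
    """Quotient of edema volume to hemorrhage volume."""
    if hemorrhage_ml <= 0:
        raise ValueError("relative edema ratio undefined: hemorrhage volume is zero")
    return edema_ml / hemorrhage_ml


def volume_report(
    hematoma_mask: np.ndarray,
    hematoma_affine: np.ndarray,
    total_lesion_mask: np.ndarray,
    total_lesion_affine: np.ndarray,
) -> VolumeReport:
    """Full per-subject volumetry from two native-grid masks."""
    hem_ml = mask_volume(hematoma_mask, voxel_volume_mm3(hematoma_affine))
    total_ml = mask_volume(total_lesion_mask, voxel_volume_mm3(total_lesion_affine))
    edema_ml = edema_volume(total_ml, hem_ml)
    ratio = relative_edema_ratio(edema_ml, hem_ml) if hem_ml > 0 else float("nan")
    return VolumeReport(hemorrhage_ml=hem_ml, edema_ml=edema_ml, relative_edema_ratio=ratio)


def load_mask(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Load a binary NIfTI mask; returns (mask, affine, voxel volume mm^3).

    Any nonzero value is relabeled to 1.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    mask = (data != 0).astype(np.uint8)
    vol = voxel_volume_mm3(img.affine, img.header.get_zooms()[:3])
    return mask, img.affine, vol
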