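"""Voxelwise diffusion-tensor estimation and derived maps.

The estimator is log-linear least squares: for each voxel the model

    ln S_i = ln S0 - b_i g_i^T D g_i

is linear in the seven parameters (six unique tensor components and ln S0)
and is solved in one shot for all masked voxels via the pseudoinverse of the
shared design matrix. A weighted variant (weights S_i^2, the standard
first-order variance correction for log-transformed Rician data) is
available by flag.

Derived maps: axis diffusivities Dxx/Dyy/Dzz (the diagonal of the tensor in
image axes, which the ALPS index reads), eigenvalues/eigenvectors,
fractional anisotropy, and direction-encoded color FA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionScheme, read_bvals_bvecs
from .phantom import DWIVolume

__all__ = [
    "TensorField",
    "TensorFeatures",
    "design_matrix",
    "fit_tensor_loglinear",
    "eigendecompose",
    "fractional_anisotropy",
    "color_fa",
    "axis_diffusivities",
    "load_dwi",
    "save_maps",
]

logger = logging.getLogger(__name__)

# storage order of the six unique tensor components
COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor.

    Attributes
    ----------
    components : (..., 6) array in the order Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
        (mm^2/s).
    s0 : per-voxel estimated unweighted signal.
    mask : voxels with a valid fit.
    affine : voxel -> world (RAS mm) transform.
    n_clamped : count of signals floored before the log transform.
    """

    components: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    n_clamped: int = 0

    def as_matrices(self) -> np.ndarray:
        """(..., 3, 3) symmetric tensor array."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3))
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out


@dataclass
class TensorFeatures:
    """Eigen-system and scalar maps derived from a :class:`TensorField`."""

    evals: np.ndarray          # (..., 3) sorted descending, mm^2/s
    evecs: np.ndarray          # (..., 3, 3) columns = eigenvectors, v1 first
    fa: np.ndarray             # (...,) in [0, 1]
    color: np.ndarray          # (..., 3) FA-weighted |v1|, in [0, 1]
    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    mask: np.ndarray
    affine: np.ndarray


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_volumes, 7) log-linear design: columns for the six tensor
    components (order of :data:`COMPONENTS`) and ln S0."""
    b = scheme.bvalues
    g = scheme.bvectors
    X = np.empty((scheme.n_volumes, 7))
    X[:, 0] = -b * g[:, 0] ** 2
    X[:, 1] = -b * g[:, 1] ** 2
    X[:, 2] = -b * g[:, 2] ** 2
    X[:, 3] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 4] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 5] = -2 * b * g[:, 1] * g[:, 2]
    X[:, 6] = 1.0
    return X


def fit_tensor_loglinear(
    dwi: DWIVolume,
    mask: Optional[np.ndarray] = None,
    weighted: bool = False,
    signal_floor_frac: float = 1e-6,
) -> TensorField:
    """Fit the tensor in every masked voxel by (weighted) log-linear LS.

    Parameters
    ----------
    dwi : the 4-D signal stack.
    mask : boolean volume restricting the fit; all voxels by default.
        Voxels whose signals are all zero are dropped from the mask.
    weighted : if True, weight each log-signal by the squared signal (WLS);
        otherwise ordinary least squares.
    signal_floor_frac : signals <= 0 are clamped to this fraction of the
        voxel's maximum signal before the log; clamped counts are logged.
    """
    scheme = dwi.scheme
    if scheme.n_weighted < 6:
        raise ValueError("scheme must have at least 6 weighted directions")
    if scheme.n_b0 < 1:
        raise ValueError("scheme must have at least one b=0 volume")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design matrix: directions do not span the tensor space")

    shape = dwi.data.shape[:3]
    mask = np.ones(shape, dtype=bool) if mask is None else mask.astype(bool)
    signals = dwi.data[mask]  # (n_vox, n_volumes)
    dead = ~np.any(signals > 0, axis=1)
    if np.any(dead):
        logger.warning("%d all-zero voxels excluded from the fit mask", int(dead.sum()))
        idx = np.argwhere(mask)
        mask = mask.copy()
        mask[tuple(idx[dead].T)] = False
        signals = signals[~dead]

    floor = signal_floor_frac * signals.max(axis=1, keepdims=True)
    clamped = signals <= 0
    n_clamped = int(clamped.sum())
    if n_clamped:
        logger.warning("%d non-positive signals clamped before log transform", n_clamped)
    logS = np.log(np.where(clamped, floor, signals))

    if weighted:
        # per-voxel weights; batched SVD solve avoids the ill-conditioned
        # normal equations (columns of X span ~6 orders of magnitude)
        sw = signals / signals.max(axis=1, keepdims=True)  # sqrt-weights, scale-free
        A = X[None, :, :] * sw[:, :, None]                 # (n_vox, n_vol, 7)
        beta = np.einsum("nij,nj->ni", np.linalg.pinv(A), sw * logS)
    else:
        beta = (np.linalg.pinv(X) @ logS.T).T            # (n_vox, 7)

    comp = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    comp[mask] = beta[:, :6]
    s0[mask] = np.exp(beta[:, 6])
    return TensorField(components=comp, s0=s0, mask=mask, affine=dwi.affine, n_clamped=n_clamped)


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean||| / ||lambda||, clipped to [0, 1].

    All-zero eigenvalue triplets return 0. Negative eigenvalues (noise) are
    clamped to 0 first, the standard convention for scalar maps.
    """
    ev = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    norm2 = np.sum(ev**2, axis=-1)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sum((ev - mean) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def _fix_eigvec_signs(evecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero component positive."""
    v = evecs.copy()
    # v has shape (..., 3, 3) with columns = eigenvectors
    for col in range(3):
        vec = v[..., :, col]
        # sign of the first component with |.| > tiny, scanning x, y, z
        sign = np.ones(vec.shape[:-1])
        decided = np.zeros(vec.shape[:-1], dtype=bool)
        for comp in range(3):
            c = vec[..., comp]
            pick = (~decided) & (np.abs(c) > 1e-12)
            sign = np.where(pick, np.sign(c), sign)
            decided |= pick
        v[..., :, col] = vec * sign[..., None]
    return v


def eigendecompose(tensor_field: TensorField) -> TensorFeatures:
    """Eigenvalues (descending), sign-fixed eigenvectors, FA, color FA and
    the axis-diffusivity maps of a fitted tensor field."""
    D = tensor_field.as_matrices()
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    evecs = _fix_eigvec_signs(evecs)
    fa = fractional_anisotropy(evals)
    v1 = evecs[..., :, 0]
    color = np.clip(fa[..., None] * np.abs(v1), 0.0, 1.0)
    out = TensorFeatures(
        evals=evals,
        evecs=evecs,
        fa=fa,
        color=color,
        dxx=tensor_field.components[..., 0],
        dyy=tensor_field.components[..., 1],
        dzz=tensor_field.components[..., 2],
        mask=tensor_field.mask,
        affine=tensor_field.affine,
    )
    return out


def color_fa(features: TensorFeatures) -> np.ndarray:
    """Direction-encoded color map, (r, g, b) = FA * |v1| componentwise."""
    return features.color


def axis_diffusivities(tensor_field: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The Dxx, Dyy, Dzz maps: tensor diagonal entries in canonical RAS
    image axes (x = left-right, y = anterior-posterior, z = inferior-superior)."""
    c = tensor_field.components
    return c[..., 0], c[..., 1], c[..., 2]


def load_dwi(dwi_path, bval_path, bvec_path) -> DWIVolume:
    """Load a NIfTI DWI stack, reoriented to closest-canonical (RAS)."""
    img = nib.as_closest_canonical(nib.load(str(dwi_path)))
    scheme = read_bvals_bvecs(bval_path, bvec_path)
    data = np.asarray(img.dataobj, dtype=float)
    return DWIVolume(data=np.clip(data, 0, None), affine=img.affine, scheme=scheme)


def save_maps(features: TensorFeatures, out_dir) -> dict[str, Path]:
    """Write Dxx/Dyy/Dzz/FA (3-D) and color FA (4-D, last dim 3) as NIfTI-1."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "Dxx": features.dxx,
        "Dyy": features.dyy,
        "Dzz": features.dzz,
        "FA": features.fa,
        "colorFA": features.color,
    }
    paths = {}
    for name, arr in arrays.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), features.affine), p)
        paths[name] = p
    return paths
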