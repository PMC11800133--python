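"""Diffusion acquisition schemes: b-values, gradient directions, FSL bval/bvec IO.

The default protocol mirrors a clinical single-shell DTI acquisition:
30 diffusion directions at b = 1000 s/mm^2 plus one unweighted (b=0) volume.
Directions are generated deterministically with a spherical Fibonacci point
set, which is near-uniform on the sphere for any count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "make_scheme",
    "fibonacci_directions",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-value and unit gradient direction per volume.

    Attributes
    ----------
    bvalues : (n_volumes,) float array, s/mm^2
    bvectors : (n_volumes, 3) float array; unit norm where b > 0, zero
        vectors allowed only where b == 0.
    """

    bvalues: np.ndarray
    bvectors: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        bvecs = np.asarray(self.bvectors, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvalues ({bvals.shape[0]}) and bvectors ({bvecs.shape[0]}) "
                "must have one entry per volume"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise ValueError("all nonzero-b directions must have unit norm (tol 1e-6)")
        if not np.any(~weighted):
            raise ValueError("scheme must contain at least one b=0 volume")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "bvectors", bvecs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.shape[0])

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def n_weighted(self) -> int:
        return self.n_volumes - self.n_b0

    @property
    def weighted_mask(self) -> np.ndarray:
        return self.bvalues > 0


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (spherical Fibonacci lattice).

    Points cover the upper hemisphere: diffusion directions are antipodally
    equivalent, and a hemispheric set avoids the rank-degenerate
    near-antipodal pairs a full-sphere lattice produces at small n.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    z = (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = _GOLDEN_ANGLE * i
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def make_scheme(n_directions: int = 30, b: float = 1000.0, n_b0: int = 1) -> AcquisitionScheme:
    """Build a single-shell scheme with ``n_b0`` leading b=0 volumes.

    Parameters
    ----------
    n_directions : number of diffusion-weighted directions (>= 6; six
        independent tensor components require six directions for
        identifiability).
    b : shell b-value in s/mm^2.
    n_b0 : number of unweighted volumes (>= 1, needed to anchor S0).
    """
    if n_directions < 6:
        raise ValueError(
            f"n_directions={n_directions}: tensor not identifiable with fewer "
            "than 6 diffusion directions"
        )
    if b <= 0:
        raise ValueError("b must be positive")
    if n_b0 < 1:
        raise ValueError("at least one b=0 volume is required")
    dirs = fibonacci_directions(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(bvalues=bvals, bvectors=bvecs)


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient tables (columns = volumes)."""
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvectors.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    """Read FSL-dialect bval/bvec text files into a scheme."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise ValueError(f"{bvec_path}: expected a 2-D gradient table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"{bvec_path}: expected 3 rows or 3 columns")
    return AcquisitionScheme(bvalues=bvals, bvectors=bvecs)
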