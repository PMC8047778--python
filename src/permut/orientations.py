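"""Rigid-body orientation extraction as unit quaternions.

Each molecule's orientation in a frame is the proper rotation that
optimally superimposes a fixed site template onto the molecule's observed
sites (both centered on their centroid). The rotation is obtained with
Horn's quaternion eigenvector method: the quaternion maximizing the
superposition overlap is the leading eigenvector of a 4x4 matrix built
from the template/site covariance. This is robust to site numbering and to
the small residual flexibility of constrained water models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_io import Trajectory

logger = logging.getLogger(__name__)

FLEX_RMSD_WARN = 0.02  # nm; beyond this the molecule is not rigid enough


@dataclass
class OrientationTrack:
    """Per-frame, per-molecule unit quaternions (w, x, y, z).

    A deterministic hemisphere (w >= 0, ties broken by the first nonzero
    component) is chosen for reproducibility; all downstream metrics handle
    the double cover, so the choice carries no information.
    """

    quaternions: np.ndarray  # (n_frames, N, 4)

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        norms = np.linalg.norm(self.quaternions, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be unit norm")

    @property
    def n_frames(self) -> int:
        return self.quaternions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.quaternions.shape[1]


def _canonical_sign(q: np.ndarray) -> np.ndarray:
    """Flip quaternions so w >= 0; tie -> first nonzero component positive."""
    q = np.array(q, dtype=float)
    flat = q.reshape(-1, 4)
    first = (np.abs(flat) > 1e-12).argmax(axis=1)
    lead = flat[np.arange(len(flat)), first]
    sign = np.where(lead < 0, -1.0, 1.0)
    flat *= sign[:, None]
    return flat.reshape(q.shape)


def _horn_quaternion(template: np.ndarray, sites: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation (as quaternion rotating template -> sites)
    and its superposition RMSD, for centered coordinates."""
    M = template.T @ sites  # 3x3 covariance
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, -1]  # leading eigenvector, (w, x, y, z)
    ssd = max(np.sum(sites**2) + np.sum(template**2) - 2.0 * vals[-1], 0.0)
    rmsd = np.sqrt(ssd / len(sites))
    return q, rmsd


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def extract_orientation(sites: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Orientation quaternion of one molecule from its site positions.

    ``template`` is the reference site geometry (same shape); the returned
    quaternion rotates the centered template onto the centered sites with
    minimal RMSD. Collinear/degenerate site sets are rejected, as is any
    fit requiring a reflection or exceeding the rigidity tolerance.
    """
    sites = np.asarray(sites, dtype=float)
    template = np.asarray(template, dtype=float)
    if sites.shape != template.shape or sites.shape[0] < 3:
        raise ValueError("need >= 3 matching sites")
    tc = template - template.mean(axis=0)
    sc = sites - sites.mean(axis=0)
    if np.linalg.matrix_rank(tc, tol=1e-9) < 2 or np.linalg.matrix_rank(sc, tol=1e-9) < 2:
        raise ValueError("collinear sites: orientation is underdetermined")
    q, rmsd = _horn_quaternion(tc, sc)
    if rmsd > FLEX_RMSD_WARN:
        # a large residual means the sites are not a rotated copy of the
        # template (flexible molecule or a reflection-requiring match)
        raise ValueError(
            f"superposition RMSD {rmsd:.4f} nm exceeds rigidity tolerance "
            f"{FLEX_RMSD_WARN} nm"
        )
    if rmsd > 1e-6:
        logger.debug("non-zero superposition RMSD %.2e nm", rmsd)
    return _canonical_sign(q)


def orient_trajectory(traj: Trajectory, template: np.ndarray | None = None) -> OrientationTrack:
    """Extract per-frame orientations for every molecule.

    The template defaults to the first molecule's centered sites in the
    first frame. Apply this to an already permutation-reduced trajectory to
    keep orientations consistent with relabeled positions.
    """
    if traj.site_positions is None:
        raise ValueError("trajectory has no site positions")
    if template is None:
        t0 = traj.site_positions[0, 0]
        template = t0 - t0.mean(axis=0)
    template = np.asarray(template, dtype=float)
    tc = template - template.mean(axis=0)
    if np.linalg.matrix_rank(tc, tol=1e-9) < 2:
        raise ValueError("collinear template: orientation is underdetermined")

    sites = traj.site_positions  # (n_f, N, S, 3)
    sc = sites - sites.mean(axis=2, keepdims=True)
    M = np.einsum("si,fnsj->fnij", tc, sc)  # batched covariance
    Sxx, Sxy, Sxz = M[..., 0, 0], M[..., 0, 1], M[..., 0, 2]
    Syx, Syy, Syz = M[..., 1, 0], M[..., 1, 1], M[..., 1, 2]
    Szx, Szy, Szz = M[..., 2, 0], M[..., 2, 1], M[..., 2, 2]
    K = np.empty(M.shape[:2] + (4, 4))
    K[..., 0, 0] = Sxx + Syy + Szz
    K[..., 0, 1] = K[..., 1, 0] = Syz - Szy
    K[..., 0, 2] = K[..., 2, 0] = Szx - Sxz
    K[..., 0, 3] = K[..., 3, 0] = Sxy - Syx
    K[..., 1, 1] = Sxx - Syy - Szz
    K[..., 1, 2] = K[..., 2, 1] = Sxy + Syx
    K[..., 1, 3] = K[..., 3, 1] = Szx + Sxz
    K[..., 2, 2] = -Sxx + Syy - Szz
    K[..., 2, 3] = K[..., 3, 2] = Syz + Szy
    K[..., 3, 3] = -Sxx - Syy + Szz
    vals, vecs = np.linalg.eigh(K)
    quats = vecs[..., -1]
    ssd = np.maximum(
        np.sum(sc**2, axis=(2, 3)) + np.sum(tc**2) - 2.0 * vals[..., -1], 0.0
    )
    rmsd = np.sqrt(ssd / sites.shape[2])
    if np.any(rmsd > FLEX_RMSD_WARN):
        raise ValueError(
            f"max superposition RMSD {rmsd.max():.4f} nm exceeds rigidity "
            f"tolerance {FLEX_RMSD_WARN} nm"
        )
    return OrientationTrack(_canonical_sign(quats))
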