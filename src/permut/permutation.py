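"""Permutation reduction: relabel identical molecules against a reference.

Solvent molecules are indistinguishable, so the sampled configuration space
is N!-fold redundant. Relabeling the molecules in every frame with the
permutation that minimizes the summed squared (minimum-image) distance to a
fixed reference configuration maps the trajectory into a single
permutation subspace, shrinking the volume to sample by the Gibbs factor N!
without changing any physical observable. Each molecule then stays
localized near its reference site, which makes per-molecule marginal
entropies well-defined and kNN-estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model_io import Frame, Trajectory


@dataclass
class ReferenceConfiguration:
    """Fixed reference positions {r_i} the assignment is made against."""

    positions: np.ndarray  # (N, 3) nm
    kind: str = "lattice"  # "lattice" | "frame"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("reference positions must be (N, 3)")

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]


@dataclass
class PermutedTrajectory(Trajectory):
    """A trajectory after per-frame optimal relabeling.

    ``permutations[f, i]`` is the original index of the molecule that carries
    label ``i`` in frame ``f``. ``unwrapped`` holds positions shifted to the
    periodic image nearest each molecule's reference site, and
    ``mean_positions`` their time average; both avoid box-wrap artifacts in
    cutoff selection and voxel maps.
    """

    permutations: Optional[np.ndarray] = None  # (n_frames, N) int
    objectives: Optional[np.ndarray] = None  # (n_frames,) nm^2
    reference: Optional[ReferenceConfiguration] = None
    unwrapped: Optional[np.ndarray] = None  # (n_frames, N, 3)
    mean_positions: Optional[np.ndarray] = None  # (N, 3)


def make_reference(
    box,
    n_molecules: int,
    kind: str = "lattice",
    traj: Optional[Trajectory] = None,
    frame_index: int = 0,
    factorization: Optional[Tuple[int, int, int]] = None,
) -> ReferenceConfiguration:
    """Build a reference configuration.

    ``kind="lattice"`` places a simple-cubic grid of sites centered in the
    box (spacing ``box_edge / n`` per axis); ``n_molecules`` must be a
    perfect cube unless an explicit ``(nx, ny, nz)`` factorization is given.
    ``kind="frame"`` copies a trajectory frame.
    """
    box = np.asarray(box, dtype=float)
    if kind == "frame":
        if traj is None:
            raise ValueError("kind='frame' requires a trajectory")
        return ReferenceConfiguration(traj.positions[frame_index].copy(), kind="frame")
    if kind != "lattice":
        raise ValueError(f"unknown reference kind {kind!r}")
    if factorization is None:
        n_side = round(n_molecules ** (1.0 / 3.0))
        if n_side**3 != n_molecules:
            raise ValueError(
                f"{n_molecules} molecules is not a perfect cube; "
                "supply an explicit factorization=(nx, ny, nz)"
            )
        factorization = (n_side, n_side, n_side)
    nx, ny, nz = factorization
    if nx * ny * nz != n_molecules:
        raise ValueError("factorization does not match molecule count")
    axes = [
        (np.arange(n) + 0.5) * (box[d] / n) for d, n in enumerate((nx, ny, nz))
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return ReferenceConfiguration(grid, kind="lattice")


def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement a - b under an orthorhombic box."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return d - box * np.round(d / box)


def min_image_sq_dist(a, b, box) -> np.ndarray:
    """Squared minimum-image distance; broadcasts over leading axes."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = min_image_displacement(a, b, box)
    return np.sum(d * d, axis=-1)


def _cost_matrix(positions: np.ndarray, reference: np.ndarray, box: np.ndarray) -> np.ndarray:
    # C[i, j] = squared min-image distance from molecule j to reference site i
    d = positions[None, :, :] - reference[:, None, :]
    d -= box * np.round(d / box)
    return np.einsum("ijk,ijk->ij", d, d)


def permute_frame(
    frame: Frame,
    reference: ReferenceConfiguration,
    sparse_cutoff: Optional[float] = None,
) -> Tuple[Frame, np.ndarray]:
    """Optimally relabel one frame against the reference.

    Returns the relabeled frame and the permutation ``pi`` such that
    ``new_positions[i] = old_positions[pi[i]]`` minimizes
    ``sum_i |x_pi(i) - r_i|^2`` (minimum image). ``sparse_cutoff`` forbids
    assignments beyond that distance (nm); if that renders the problem
    infeasible the dense problem is solved instead.
    """
    if reference.n_molecules != frame.positions.shape[0]:
        raise ValueError("reference and frame molecule counts differ")
    if not np.all(np.isfinite(frame.positions)):
        raise ValueError("non-finite coordinates")
    C = _cost_matrix(frame.positions, reference.positions, frame.box)
    if sparse_cutoff is not None:
        masked = np.where(C <= sparse_cutoff**2, C, np.inf)
        try:
            rows, cols = linear_sum_assignment(masked)
        except ValueError:  # infeasible under the cutoff -> dense fallback
            rows, cols = linear_sum_assignment(C)
    else:
        rows, cols = linear_sum_assignment(C)
    pi = np.empty(len(cols), dtype=np.intp)
    pi[rows] = cols
    new = Frame(frame.positions[pi].copy(), frame.time, frame.box.copy())
    return new, pi


def permute_trajectory(
    traj: Trajectory,
    reference: ReferenceConfiguration,
    sparse_cutoff: Optional[float] = None,
) -> PermutedTrajectory:
    """Apply per-frame optimal relabeling to a whole trajectory.

    Site positions (if present) are relabeled consistently. Unwrapped
    coordinates and time-averaged mean positions are computed relative to
    each molecule's reference site.
    """
    if reference.n_molecules != traj.n_molecules:
        raise ValueError("reference and trajectory molecule counts differ")
    n_f, N = traj.n_frames, traj.n_molecules
    positions = np.empty_like(traj.positions)
    perms = np.empty((n_f, N), dtype=np.intp)
    objectives = np.empty(n_f)
    sites = None if traj.site_positions is None else np.empty_like(traj.site_positions)
    for f in range(n_f):
        C = _cost_matrix(traj.positions[f], reference.positions, traj.box[f])
        if sparse_cutoff is not None:
            masked = np.where(C <= sparse_cutoff**2, C, np.inf)
            try:
                rows, cols = linear_sum_assignment(masked)
            except ValueError:
                rows, cols = linear_sum_assignment(C)
        else:
            rows, cols = linear_sum_assignment(C)
        pi = np.empty(N, dtype=np.intp)
        pi[rows] = cols
        perms[f] = pi
        positions[f] = traj.positions[f, pi]
        objectives[f] = C[np.arange(N), pi].sum()
        if sites is not None:
            sites[f] = traj.site_positions[f, pi]

    disp = positions - reference.positions[None, :, :]
    disp -= traj.box[:, None, :] * np.round(disp / traj.box[:, None, :])
    unwrapped = reference.positions[None, :, :] + disp
    if sites is not None:
        # shift each molecule's sites by the same image shift as its center
        shift = unwrapped - positions
        sites = sites + shift[:, :, None, :]

    return PermutedTrajectory(
        positions=positions,
        box=traj.box.copy(),
        times=traj.times.copy(),
        molecule_ids=traj.molecule_ids.copy(),
        site_positions=sites,
        metadata=dict(traj.metadata),
        permutations=perms,
        objectives=objectives,
        reference=reference,
        unwrapped=unwrapped,
        mean_positions=unwrapped.mean(axis=0),
    )
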