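"""Hydration-shell selection, per-molecule decomposition, voxel maps.

Permutation reduction localizes every solvent molecule near a reference
site, so per-molecule entropy contributions have a spatial meaning: the
pair and triple MI terms are split equally among the molecules involved,
and accumulating the per-molecule values on a 3-D grid weighted by where
each molecule actually spends its frames yields a spatially resolved
entropy map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .constants import nats_to_molar
from .model_io import EntropyReport
from .permutation import PermutedTrajectory


def select_shell(
    ptraj: PermutedTrajectory,
    solute_sites: np.ndarray,
    n_shell: int,
    method: str = "mean_position",
) -> np.ndarray:
    """Indices of the ``n_shell`` solvent molecules closest to the solute.

    Distance is the minimum over solute sites of the minimum-image distance
    from the molecule's time-averaged position (``method="mean_position"``,
    default) or the time average of the per-frame minimum distances
    (``method="frame_average"``). Ties are broken by molecule index.
    """
    solute = np.atleast_2d(np.asarray(solute_sites, dtype=float))
    if solute.size == 0:
        raise ValueError("solute has no sites")
    if n_shell > ptraj.n_molecules:
        raise ValueError("n_shell exceeds molecule count")
    box = ptraj.box[0]
    if method == "mean_position":
        d = ptraj.mean_positions[:, None, :] - solute[None, :, :]
        d -= box * np.round(d / box)
        dist = np.sqrt(np.einsum("msk,msk->ms", d, d)).min(axis=1)
    elif method == "frame_average":
        coords = ptraj.unwrapped if ptraj.unwrapped is not None else ptraj.positions
        d = coords[:, :, None, :] - solute[None, None, :, :]
        d -= box * np.round(d / box)
        dist = np.sqrt(np.einsum("fmsk,fmsk->fms", d, d)).min(axis=2).mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.lexsort((np.arange(ptraj.n_molecules), dist))
    return np.sort(order[:n_shell])


def per_molecule_decomposition(report: EntropyReport) -> Dict[str, np.ndarray]:
    """Split the assembled total into per-molecule shares, J mol^-1 K^-1.

    Each pair MI is debited half to each molecule, each triple MI credited
    a third to each, each translation-rotation term split between its
    translational and rotational molecule (all of it to the molecule for
    self terms). The shares sum exactly to the assembled total.
    """
    N = report.n_molecules
    I2_share = np.zeros(N)
    for (i, j), v in report.I2.items():
        I2_share[i] += v / 2.0
        I2_share[j] += v / 2.0
    I3_share = np.zeros(N)
    for (i, j, k), v in report.I3.items():
        I3_share[i] += v / 3.0
        I3_share[j] += v / 3.0
        I3_share[k] += v / 3.0
    Itr_share = np.zeros(N)
    for (j, k), v in report.I_tr.items():
        if j == k:
            Itr_share[j] += v
        else:
            Itr_share[j] += v / 2.0
            Itr_share[k] += v / 2.0
    total = (
        report.kinetic_per_molecule
        + nats_to_molar(report.S1_trans)
        - nats_to_molar(I2_share)
        + nats_to_molar(I3_share)
        - nats_to_molar(Itr_share)
    )
    if report.S1_rot is not None:
        total = total + nats_to_molar(report.S1_rot)
    return {
        "S1": nats_to_molar(report.S1_trans) + report.kinetic_per_molecule,
        "I2_share": -nats_to_molar(I2_share),
        "I3_share": nats_to_molar(I3_share),
        "I_tr_share": -nats_to_molar(Itr_share),
        "total": total,
    }


@dataclass
class VoxelMap:
    """Occupancy-weighted local entropy on a regular 3-D grid.

    ``values`` holds J mol^-1 K^-1 per molecule and is NaN where no
    molecule was ever observed (``occupancy == 0``); undefined is distinct
    from zero.
    """

    values: np.ndarray  # (nx, ny, nz)
    occupancy: np.ndarray  # (nx, ny, nz) frame counts
    origin: np.ndarray  # (3,) nm
    spacing: np.ndarray  # (3,) nm

    @property
    def defined(self) -> np.ndarray:
        return self.occupancy > 0


def build_voxel_map(
    ptraj: PermutedTrajectory,
    per_molecule_values: np.ndarray,
    grid_n: int = 128,
    reference_bulk: Optional[float] = None,
) -> VoxelMap:
    """Accumulate per-molecule entropies onto a voxel grid.

    Each frame, each molecule deposits its per-molecule value into the
    voxel containing its (wrapped) position; the voxel value is the
    occupancy-weighted mean. ``reference_bulk`` is subtracted if given, so
    the map reports entropy differences to bulk.
    """
    values = np.asarray(per_molecule_values, dtype=float)
    if values.shape != (ptraj.n_molecules,):
        raise ValueError("need one value per molecule")
    box = ptraj.box[0]
    spacing = box / grid_n
    pos = np.mod(ptraj.positions.reshape(-1, 3), box)
    idx = np.minimum((pos / spacing).astype(np.intp), grid_n - 1)
    flat = (idx[:, 0] * grid_n + idx[:, 1]) * grid_n + idx[:, 2]
    weights = np.broadcast_to(values, (ptraj.n_frames, ptraj.n_molecules)).ravel()
    occ = np.bincount(flat, minlength=grid_n**3).astype(float)
    acc = np.bincount(flat, weights=weights, minlength=grid_n**3)
    with np.errstate(invalid="ignore", divide="ignore"):
        vox = acc / occ
    vox = vox.reshape(grid_n, grid_n, grid_n)
    occ = occ.reshape(grid_n, grid_n, grid_n)
    if reference_bulk is not None:
        vox = np.where(occ > 0, vox - reference_bulk, vox)
    vox[occ == 0] = np.nan
    return VoxelMap(values=vox, occupancy=occ, origin=np.zeros(3), spacing=spacing)


def bulk_reference_value(
    ptraj: PermutedTrajectory,
    per_molecule_values: np.ndarray,
    solute_sites: np.ndarray,
    min_distance: float = 1.2,
) -> float:
    """Mean per-molecule value over molecules farther than ``min_distance``
    (nm) from every solute site -- the bulk baseline for difference maps."""
    solute = np.atleast_2d(np.asarray(solute_sites, dtype=float))
    box = ptraj.box[0]
    d = ptraj.mean_positions[:, None, :] - solute[None, :, :]
    d -= box * np.round(d / box)
    dist = np.sqrt(np.einsum("msk,msk->ms", d, d)).min(axis=1)
    mask = dist > min_distance
    if not np.any(mask):
        raise ValueError("no bulk molecules beyond the distance threshold")
    return float(np.mean(np.asarray(per_molecule_values)[mask]))


def write_dx(map_: VoxelMap, path: str, field: str = "values") -> None:
    """Write a voxel map as an OpenDX scalar field (.dx).

    Undefined voxels are written as 0 with their undefined status carried
    by the companion occupancy map.
    """
    data = getattr(map_, field)
    nx, ny, nz = data.shape
    out = np.nan_to_num(data, nan=0.0)
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin %.6f %.6f %.6f\n" % tuple(map_.origin))
        fh.write("delta %.6f 0.0 0.0\n" % map_.spacing[0])
        fh.write("delta 0.0 %.6f 0.0\n" % map_.spacing[1])
        fh.write("delta 0.0 0.0 %.6f\n" % map_.spacing[2])
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {out.size} data follows\n"
        )
        vals = out.ravel()
        for start in range(0, len(vals), 3):
            fh.write(" ".join("%.8g" % v for v in vals[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
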