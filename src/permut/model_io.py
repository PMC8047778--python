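"""Core data types and trajectory / report input-output.

The in-memory trajectory container keeps per-frame molecule positions as a
dense ``(n_frames, n_molecules, 3)`` array in nm, with an orthorhombic box
per frame. Optional per-molecule atomic sites (``(n_frames, n_molecules,
n_sites, 3)``) carry the rigid-body geometry from which orientations are
extracted. Standard MD formats are read through MDAnalysis; a plain
whitespace-separated text format is provided for fixtures and CLI output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .constants import GAS_CONSTANT_R, nats_to_molar


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """A single configuration: molecule positions (nm), time (ps), box (nm)."""

    positions: np.ndarray  # (N, 3)
    time: float
    box: np.ndarray  # (3,) orthorhombic edge lengths

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")


@dataclass
class Trajectory:
    """Ordered frames of identical solvent molecules.

    Attributes
    ----------
    positions : (n_frames, N, 3) array, nm
        One point per molecule per frame (center of geometry for
        multi-site species).
    box : (n_frames, 3) array, nm
        Orthorhombic edge lengths per frame.
    times : (n_frames,) array, ps
    molecule_ids : (N,) integer array of stable labels
    site_positions : optional (n_frames, N, S, 3) array, nm
        Atomic sites per molecule, used for orientation extraction.
    metadata : free-form dict (generator parameters, closed-form entropies...)
    """

    positions: np.ndarray
    box: np.ndarray
    times: np.ndarray
    molecule_ids: np.ndarray
    site_positions: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, N, 3)")
        if self.n_frames < 1:
            raise ValueError("trajectory needs at least one frame")
        self.box = np.atleast_2d(np.asarray(self.box, dtype=float))
        if self.box.shape == (1, 3) and self.n_frames > 1:
            self.box = np.repeat(self.box, self.n_frames, axis=0)
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must be (n_frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        self.times = np.asarray(self.times, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids)
        if self.molecule_ids.shape != (self.n_molecules,):
            raise ValueError("molecule_ids length mismatch")
        if self.site_positions is not None:
            self.site_positions = np.asarray(self.site_positions, dtype=float)
            if self.site_positions.shape[:2] != (self.n_frames, self.n_molecules):
                raise ValueError("site_positions shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    @property
    def n_sites(self) -> int:
        return 0 if self.site_positions is None else self.site_positions.shape[2]

    def frames(self) -> Iterator[Frame]:
        for f in range(self.n_frames):
            yield Frame(self.positions[f], float(self.times[f]), self.box[f])


@dataclass
class ThermoParams:
    """Thermodynamic parameters of the solvent species.

    ``length_unit`` is the arbitrary reference length (nm) that renders the
    configurational probability density dimensionless; the kinetic and
    configurational entropies each depend on it, their sum does not.
    """

    temperature: float  # K
    molecular_mass: float  # u
    length_unit: float = 1.0  # nm

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.molecular_mass <= 0 or self.length_unit <= 0:
            raise ValueError("temperature, mass and length unit must be positive")


@dataclass
class EntropyValue:
    """A molar entropy with uncertainty; ``basis`` keeps the raw nats value."""

    value: float  # J mol^-1 K^-1
    stderr: float = 0.0
    basis: float = float("nan")  # nats per molecule

    @classmethod
    def from_nats(cls, nats: float, stderr_nats: float = 0.0) -> "EntropyValue":
        return cls(value=nats_to_molar(nats), stderr=nats_to_molar(stderr_nats), basis=nats)


# ---------------------------------------------------------------------------
# MD-format reading (MDAnalysis)
# ---------------------------------------------------------------------------


def read_trajectory(
    structure_path: str,
    coords_path: Optional[str] = None,
    solvent_selection: str = "resname SOL or resname WAT or water",
) -> Trajectory:
    """Read solvent molecules from standard MD files into a :class:`Trajectory`.

    Parameters
    ----------
    structure_path : GRO/PDB (or any MDAnalysis topology) file
    coords_path : XTC/TRR/DCD/PDB coordinate file; omit to use the
        structure's own frames
    solvent_selection : MDAnalysis selection string; must match one or more
        chemically identical molecules (same residue composition)

    The per-molecule position is the center of geometry of its sites.
    Coordinates are converted from Angstrom to nm, times are in ps. Only
    orthorhombic boxes are supported.
    """
    import MDAnalysis as mda

    if not os.path.exists(structure_path):
        raise FileNotFoundError(structure_path)
    if coords_path is not None and not os.path.exists(coords_path):
        raise FileNotFoundError(coords_path)
    u = mda.Universe(structure_path) if coords_path is None else mda.Universe(
        structure_path, coords_path
    )
    group = u.select_atoms(solvent_selection)
    if len(group) == 0:
        raise ValueError(f"selection {solvent_selection!r} matches no atoms")
    residues = group.residues
    names = [tuple(res.atoms.names) for res in residues]
    if len(set(names)) != 1:
        raise ValueError(
            "selection spans chemically distinct molecules; permutation "
            "reduction requires identical solvent molecules"
        )
    n_mol = len(residues)
    n_sites = len(names[0])

    pos_frames, site_frames, boxes, times = [], [], [], []
    for ts in u.trajectory:
        if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
            raise ValueError("frame without box information")
        alpha, beta, gamma = ts.dimensions[3:6]
        if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
            raise ValueError("only orthorhombic boxes are supported")
        sites = group.positions.reshape(n_mol, n_sites, 3) * 0.1  # A -> nm
        site_frames.append(sites.copy())
        pos_frames.append(sites.mean(axis=1))
        boxes.append(ts.dimensions[:3] * 0.1)
        times.append(ts.time)

    return Trajectory(
        positions=np.array(pos_frames),
        box=np.array(boxes),
        times=np.array(times),
        molecule_ids=np.array(residues.resids),
        site_positions=np.array(site_frames) if n_sites > 1 else None,
    )


# ---------------------------------------------------------------------------
# Plain-text trajectory format (fixtures, CLI round trips)
# ---------------------------------------------------------------------------

_TEXT_MAGIC = "# permut-trajectory 1"


def write_trajectory_text(traj: Trajectory, path: str) -> None:
    """Write the whitespace-separated text format (lossless to ~12 digits)."""
    S = traj.n_sites
    with open(path, "w") as fh:
        fh.write(f"{_TEXT_MAGIC}\n")
        fh.write(f"{traj.n_frames} {traj.n_molecules} {S}\n")
        fh.write(" ".join(str(int(i)) for i in traj.molecule_ids) + "\n")
        for f in range(traj.n_frames):
            b = traj.box[f]
            fh.write(f"frame {traj.times[f]:.6f} {b[0]:.12g} {b[1]:.12g} {b[2]:.12g}\n")
            for m in range(traj.n_molecules):
                parts = ["%.12g" % v for v in traj.positions[f, m]]
                if S:
                    parts += ["%.12g" % v for v in traj.site_positions[f, m].ravel()]
                fh.write(" ".join(parts) + "\n")


def read_trajectory_text(path: str) -> Trajectory:
    with open(path) as fh:
        if fh.readline().strip() != _TEXT_MAGIC:
            raise ValueError(f"{path}: not a permut text trajectory")
        n_frames, n_mol, n_sites = (int(x) for x in fh.readline().split())
        ids = np.array([int(x) for x in fh.readline().split()])
        positions = np.empty((n_frames, n_mol, 3))
        sites = np.empty((n_frames, n_mol, n_sites, 3)) if n_sites else None
        box = np.empty((n_frames, 3))
        times = np.empty(n_frames)
        for f in range(n_frames):
            tok = fh.readline().split()
            if not tok or tok[0] != "frame":
                raise ValueError(f"{path}: malformed frame header at frame {f}")
            times[f] = float(tok[1])
            box[f] = [float(t) for t in tok[2:5]]
            for m in range(n_mol):
                vals = [float(t) for t in fh.readline().split()]
                positions[f, m] = vals[:3]
                if n_sites:
                    sites[f, m] = np.reshape(vals[3 : 3 + 3 * n_sites], (n_sites, 3))
    return Trajectory(positions=positions, box=box, times=times, molecule_ids=ids,
                      site_positions=sites)


# ---------------------------------------------------------------------------
# Entropy report
# ---------------------------------------------------------------------------


@dataclass
class EntropyReport:
    """Assembled per-molecule entropy terms.

    All raw estimator terms are in nats per molecule; ``kinetic`` and the
    derived totals are molar (J mol^-1 K^-1). MI maps are keyed by sorted
    molecule-index tuples; ``I_tr`` by (translational molecule, rotational
    molecule) pairs which may be self-pairs.
    """

    molecule_ids: np.ndarray
    S1_trans: np.ndarray  # (N,) nats
    I2: dict  # {(i, j): nats}
    I3: dict  # {(i, j, k): nats}
    S1_rot: Optional[np.ndarray] = None  # (N,) nats
    I_tr: dict = field(default_factory=dict)  # {(j, k): nats}
    kinetic_per_molecule: float = 0.0  # J mol^-1 K^-1
    n_f: int = 0
    params: dict = field(default_factory=dict)
    # filled by mie.assemble_total
    total: Optional[EntropyValue] = None
    components: dict = field(default_factory=dict)

    @property
    def n_molecules(self) -> int:
        return len(self.S1_trans)


_REPORT_COLUMNS = [
    "molecule_id", "S1_trans", "I2_share", "I3_share", "S1_rot", "I_tr_share", "total",
]


def write_report(report: EntropyReport, path: str) -> None:
    """Write the per-molecule entropy table as TSV plus a YAML sidecar.

    Columns are molar (J mol^-1 K^-1). MI shares follow the equal-split
    convention (half of each pair term, a third of each triple term). The
    sidecar ``<path>.yaml`` echoes the run parameters.
    """
    import pandas as pd
    import yaml

    from .spatial import per_molecule_decomposition

    dec = per_molecule_decomposition(report)
    df = pd.DataFrame(
        {
            "molecule_id": report.molecule_ids,
            "S1_trans": nats_to_molar(report.S1_trans) + report.kinetic_per_molecule,
            "I2_share": dec["I2_share"],
            "I3_share": dec["I3_share"],
            "S1_rot": (nats_to_molar(report.S1_rot) if report.S1_rot is not None
                       else np.full(report.n_molecules, np.nan)),
            "I_tr_share": dec["I_tr_share"],
            "total": dec["total"],
        }
    )
    with open(path, "w") as fh:
        for key, val in sorted(report.params.items()):
            fh.write(f"# {key}: {val}\n")
        fh.write(f"# n_f: {report.n_f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    sidecar = dict(report.params)
    sidecar["n_f"] = int(report.n_f)
    sidecar["n_molecules"] = int(report.n_molecules)
    if report.total is not None:
        sidecar["total_J_per_molK"] = float(report.total.value)
        sidecar["total_stderr"] = float(report.total.stderr)
    with open(path + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_report(path: str):
    """Read back a TSV report written by :func:`write_report` as a DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
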