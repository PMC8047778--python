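"""Seeded synthetic trajectory generators.

All pipeline inputs used in tests and validation runs are generated here:

* ``ideal_gas`` -- i.i.d. uniform positions per frame. Noninteracting
  particles have no dynamics to model: independent draws from the uniform
  equilibrium distribution are statistically identical to frames of a
  simulation, and the analytic Sackur-Tetrode entropy is the oracle.
* ``correlated_gaussian`` -- frames drawn from a specified joint Gaussian
  around lattice sites; the closed-form entropy
  1/2 ln((2 pi e)^(3p) det Sigma) is attached as metadata.
* ``lj_argon`` -- equilibrium configurations of a Lennard-Jones fluid at
  liquid-water number density sampled by Metropolis Monte Carlo (standard
  argon parameters sigma = 0.3405 nm, epsilon/k_B = 119.8 K, 1.2 nm
  cutoff). MC sampling targets the same Boltzmann distribution as NVT
  dynamics without requiring an MD engine.
* ``rigid_rotor`` -- three-site rigid molecules with ideal-gas positions
  and either Haar-uniform orientations or orientations tied to the
  position octant (a controllable translation-rotation coupling).

Identical spec + seed reproduce bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .model_io import Trajectory
from .orientations import quat_to_matrix

LJ_SIGMA_NM = 0.3405
LJ_EPS_OVER_KB = 119.8  # K


@dataclass
class FixtureSpec:
    """Parameters of a synthetic trajectory."""

    kind: str
    n_molecules: int
    box: Tuple[float, float, float]
    n_frames: int
    seed: int = 0
    temperature: float = 300.0
    options: dict = field(default_factory=dict)


def _box_array(spec: FixtureSpec) -> np.ndarray:
    box = np.asarray(spec.box, dtype=float)
    if box.shape == ():
        box = np.full(3, float(box))
    return box


def ideal_gas(spec: FixtureSpec) -> Trajectory:
    """Uniform i.i.d. positions in the box, every frame independent."""
    box = _box_array(spec)
    rng = np.random.default_rng(spec.seed)
    pos = rng.random((spec.n_frames, spec.n_molecules, 3)) * box
    return Trajectory(
        positions=pos,
        box=box[None, :],
        times=np.arange(spec.n_frames, dtype=float),
        molecule_ids=np.arange(spec.n_molecules),
        metadata={"kind": "ideal_gas", "seed": spec.seed},
    )


def correlated_gaussian(
    spec: FixtureSpec, covariance: np.ndarray, means: Optional[np.ndarray] = None
) -> Trajectory:
    """Joint Gaussian frames for p molecules with a given 3p x 3p covariance.

    Molecule means default to a lattice (or the box center for p = 1). The
    closed-form differential entropy of the sampled density is stored in
    ``metadata["entropy_nats"]``.
    """
    box = _box_array(spec)
    p = spec.n_molecules
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (3 * p, 3 * p):
        raise ValueError("covariance must be (3p, 3p)")
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    np.linalg.cholesky(cov)  # raises if not PD
    if means is None:
        from .permutation import make_reference

        try:
            means = make_reference(box, p, kind="lattice").positions
        except ValueError:
            means = np.tile(box / 2.0, (p, 1))
    rng = np.random.default_rng(spec.seed)
    flat = rng.multivariate_normal(
        np.asarray(means, dtype=float).reshape(3 * p), cov, size=spec.n_frames,
        method="cholesky",
    )
    entropy = 0.5 * (3 * p * math.log(2.0 * math.pi * math.e) + logdet)
    return Trajectory(
        positions=flat.reshape(spec.n_frames, p, 3),
        box=box[None, :],
        times=np.arange(spec.n_frames, dtype=float),
        molecule_ids=np.arange(p),
        metadata={"kind": "gaussian", "entropy_nats": entropy, "seed": spec.seed},
    )


@njit(cache=False)
def _lj_mc_chain(
    pos, box, beta_eps, sigma, cutoff, step, n_equil_sweeps, n_frames, sweeps_per_frame, raw
):  # pragma: no cover - numba
    """Metropolis chain on N LJ particles; returns frames and acceptance."""
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    frames = np.empty((n_frames, n, 3))
    accepted = 0
    attempted = 0
    total_sweeps = n_equil_sweeps + n_frames * sweeps_per_frame
    ptr = 0
    frame_idx = 0
    for sweep in range(total_sweeps):
        for move in range(n):
            i = int(raw[ptr] * n)
            if i >= n:
                i = n - 1
            dx = (raw[ptr + 1] - 0.5) * 2.0 * step
            dy = (raw[ptr + 2] - 0.5) * 2.0 * step
            dz = (raw[ptr + 3] - 0.5) * 2.0 * step
            acc_r = raw[ptr + 4]
            ptr += 5
            old0, old1, old2 = pos[i, 0], pos[i, 1], pos[i, 2]
            new0 = (old0 + dx) % box[0]
            new1 = (old1 + dy) % box[1]
            new2 = (old2 + dz) % box[2]
            dE = 0.0
            for j in range(n):
                if j == i:
                    continue
                # old energy
                ddx = old0 - pos[j, 0]
                ddx -= box[0] * round(ddx / box[0])
                ddy = old1 - pos[j, 1]
                ddy -= box[1] * round(ddy / box[1])
                ddz = old2 - pos[j, 2]
                ddz -= box[2] * round(ddz / box[2])
                r2 = ddx * ddx + ddy * ddy + ddz * ddz
                if r2 < cut2:
                    s2 = sigma * sigma / r2
                    s6 = s2 * s2 * s2
                    dE -= 4.0 * (s6 * s6 - s6)
                ddx = new0 - pos[j, 0]
                ddx -= box[0] * round(ddx / box[0])
                ddy = new1 - pos[j, 1]
                ddy -= box[1] * round(ddy / box[1])
                ddz = new2 - pos[j, 2]
                ddz -= box[2] * round(ddz / box[2])
                r2 = ddx * ddx + ddy * ddy + ddz * ddz
                if r2 < cut2:
                    s2 = sigma * sigma / r2
                    s6 = s2 * s2 * s2
                    dE += 4.0 * (s6 * s6 - s6)
            attempted += 1
            if dE <= 0.0 or acc_r < math.exp(-beta_eps * dE):
                pos[i, 0] = new0
                pos[i, 1] = new1
                pos[i, 2] = new2
                accepted += 1
        if sweep >= n_equil_sweeps and (sweep - n_equil_sweeps + 1) % sweeps_per_frame == 0:
            if frame_idx < n_frames:
                frames[frame_idx] = pos
                frame_idx += 1
    return frames, accepted, attempted


def _lj_total_energy(pos: np.ndarray, box: np.ndarray, sigma: float, cutoff: float) -> float:
    """Total LJ energy in units of epsilon (minimum image, cut)."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    iu = np.triu_indices(len(pos), k=1)
    r2 = r2[iu]
    r2 = r2[r2 < cutoff**2]
    s6 = (sigma**2 / r2) ** 3
    return float(np.sum(4.0 * (s6**2 - s6)))


def lj_argon(spec: FixtureSpec) -> Trajectory:
    """Metropolis Monte Carlo sampling of a Lennard-Jones argon fluid.

    Options (``spec.options``): ``sigma`` (nm), ``eps_over_kb`` (K),
    ``cutoff`` (nm, default 1.2), ``step`` (nm, max displacement per move,
    default 0.035), ``n_equil_sweeps`` (default 500), ``sweeps_per_frame``
    (default 10), ``epsilon_scale`` (lambda-style interaction scaling;
    0 reproduces the ideal gas). The mean acceptance rate and the
    second-half mean energy are recorded in the metadata.
    """
    box = _box_array(spec)
    opts = spec.options
    sigma = float(opts.get("sigma", LJ_SIGMA_NM))
    eps_over_kb = float(opts.get("eps_over_kb", LJ_EPS_OVER_KB))
    cutoff = float(opts.get("cutoff", 1.2))
    step = float(opts.get("step", 0.035))
    n_equil = int(opts.get("n_equil_sweeps", 500))
    spf = int(opts.get("sweeps_per_frame", 10))
    eps_scale = float(opts.get("epsilon_scale", 1.0))
    if np.any(box < 2.0 * cutoff):
        raise ValueError(
            f"box edges {box} must be at least twice the cutoff {cutoff} nm"
        )
    beta_eps = eps_scale * eps_over_kb / spec.temperature  # epsilon / (kB T)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    # start from a lattice to avoid overlaps
    from .permutation import make_reference

    try:
        pos = make_reference(box, n, kind="lattice").positions.copy()
    except ValueError:
        pos = rng.random((n, 3)) * box
    total_sweeps = n_equil + spec.n_frames * spf
    raw = rng.random(total_sweeps * n * 5)
    frames, accepted, attempted = _lj_mc_chain(
        pos, box, beta_eps, sigma, cutoff, step, n_equil, spec.n_frames, spf, raw
    )
    energies = np.array(
        [_lj_total_energy(frames[f], box, sigma, cutoff)
         for f in range(0, spec.n_frames, max(1, spec.n_frames // 50))]
    )
    return Trajectory(
        positions=frames,
        box=box[None, :],
        times=np.arange(spec.n_frames, dtype=float) * spf,
        molecule_ids=np.arange(n),
        metadata={
            "kind": "lj_argon",
            "seed": spec.seed,
            "acceptance_rate": accepted / max(attempted, 1),
            "mean_energy_eps": float(energies.mean()) if len(energies) else 0.0,
            "energy_series_eps": energies,
            "sigma": sigma,
            "eps_over_kb": eps_over_kb,
            "cutoff": cutoff,
            "epsilon_scale": eps_scale,
        },
    )


_ROTOR_TEMPLATE = np.array(
    [[0.08, 0.0, 0.0], [-0.04, 0.065, 0.0], [-0.04, -0.065, 0.02]]
)
_ROTOR_TEMPLATE = _ROTOR_TEMPLATE - _ROTOR_TEMPLATE.mean(axis=0)

# one representative rotation per octant, well separated on SO(3)
_OCTANT_QUATS = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [0.5, 0.5, 0.5, 0.5],
        [0.5, -0.5, 0.5, -0.5],
        [0.5, 0.5, -0.5, -0.5],
        [0.5, -0.5, -0.5, 0.5],
    ]
)


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def _haar_quaternions(rng: np.random.Generator, shape) -> np.ndarray:
    q = rng.standard_normal(shape + (4,))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def _small_rotations(rng: np.random.Generator, shape, angle_std: float) -> np.ndarray:
    axis = rng.standard_normal(shape + (3,))
    axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
    ang = rng.standard_normal(shape) * angle_std
    q = np.empty(shape + (4,))
    q[..., 0] = np.cos(ang / 2.0)
    q[..., 1:] = axis * np.sin(ang / 2.0)[..., None]
    return q


def rigid_rotor(spec: FixtureSpec, coupling: str = "none") -> Trajectory:
    """Three-site rigid molecules with controllable position-orientation
    coupling.

    ``coupling="none"``: Haar-uniform orientations independent of position
    (I_trans-rot = 0 in the population). ``coupling="octant"``: each
    molecule's orientation is a fixed octant-dependent rotation composed
    with a small random wobble (``options["wobble_std"]`` rad, default
    0.8), so position and orientation share ln 8 nats of dependence in the
    tight-wobble limit.
    """
    if coupling not in ("none", "octant"):
        raise ValueError(f"unknown coupling {coupling!r}")
    box = _box_array(spec)
    rng = np.random.default_rng(spec.seed)
    n_f, N = spec.n_frames, spec.n_molecules
    pos = rng.random((n_f, N, 3)) * box
    if coupling == "none":
        quats = _haar_quaternions(rng, (n_f, N))
    else:
        octant = (
            (pos[..., 0] > box[0] / 2).astype(int)
            + 2 * (pos[..., 1] > box[1] / 2).astype(int)
            + 4 * (pos[..., 2] > box[2] / 2).astype(int)
        )
        base = _OCTANT_QUATS[octant]
        wobble = _small_rotations(
            rng, (n_f, N), float(spec.options.get("wobble_std", 0.8))
        )
        quats = _quat_multiply(base, wobble)
        quats /= np.linalg.norm(quats, axis=-1, keepdims=True)

    # rotate the template by each quaternion and translate to the position
    w, x, y, z = quats[..., 0], quats[..., 1], quats[..., 2], quats[..., 3]
    R = np.empty(quats.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    sites = np.einsum("fnij,sj->fnsi", R, _ROTOR_TEMPLATE) + pos[:, :, None, :]

    return Trajectory(
        positions=pos,
        box=box[None, :],
        times=np.arange(n_f, dtype=float),
        molecule_ids=np.arange(N),
        site_positions=sites,
        metadata={
            "kind": "rigid_rotor",
            "coupling": coupling,
            "seed": spec.seed,
            "quaternions": quats,
            "template": _ROTOR_TEMPLATE.copy(),
        },
    )
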