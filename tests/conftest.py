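import numpy as np
import pytest

from permut.model_io import Trajectory
from permut.permutation import PermutedTrajectory, make_reference, permute_trajectory
from permut.synthetic import FixtureSpec, correlated_gaussian, ideal_gas


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_permuted(traj: Trajectory) -> PermutedTrajectory:
    """Wrap a localized trajectory as already-reduced (identity labels)."""
    return PermutedTrajectory(
        positions=traj.positions,
        box=traj.box,
        times=traj.times,
        molecule_ids=traj.molecule_ids,
        site_positions=traj.site_positions,
        metadata=traj.metadata,
        permutations=None,
        objectives=np.zeros(traj.n_frames),
        reference=None,
        unwrapped=traj.positions,
        mean_positions=traj.positions.mean(axis=0),
    )


def gaussian_ptraj(cov, n_frames=10000, seed=0, box=(50.0, 50.0, 50.0)):
    """A PermutedTrajectory of Gaussian molecules with known joint entropy.

    The box is large so the localized clouds never wrap.
    """
    p = cov.shape[0] // 3
    spec = FixtureSpec(kind="gaussian", n_molecules=p, box=box, n_frames=n_frames,
                       seed=seed)
    traj = correlated_gaussian(spec, cov)
    return as_permuted(traj), traj.metadata["entropy_nats"]


@pytest.fixture(scope="session")
def reduced_ideal_gas_small():
    """64 ideal-gas molecules at liquid-water density, permutation-reduced."""
    edge = (64 / 27.0) ** (1.0 / 3.0)
    spec = FixtureSpec(kind="ideal_gas", n_molecules=64, box=(edge,) * 3,
                       n_frames=3000, seed=11)
    traj = ideal_gas(spec)
    ref = make_reference(traj.box[0], 64, kind="lattice")
    return permute_trajectory(traj, ref)
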