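import math

import numpy as np
import pytest

from permut.constants import GAS_CONSTANT_R
from permut.geometry import CompositeMetricParams
from permut.knn import EstimatorParams
from permut.mie import (
    CutoffPolicy,
    assemble_total,
    compute_report,
    kinetic_entropy_trans,
    mutual_information_2,
    mutual_information_3,
    sackur_tetrode,
    select_pairs_triples,
    trans_rot_mi,
)
from permut.model_io import EntropyReport, ThermoParams
from permut.orientations import orient_trajectory
from permut.permutation import make_reference, permute_trajectory
from permut.synthetic import FixtureSpec, rigid_rotor

from conftest import as_permuted, gaussian_ptraj

ARGON = ThermoParams(temperature=300.0, molecular_mass=39.948)


def pair_cov(rho, sigma2=0.01):
    cov = np.eye(6) * sigma2
    for a in range(3):
        cov[a, a + 3] = cov[a + 3, a] = rho * sigma2
    return cov


class TestCutoffs:
    def test_triple_cutoff_cannot_exceed_pair_cutoff(self):
        with pytest.raises(ValueError, match="triple_cutoff"):
            CutoffPolicy(pair_cutoff=0.4, triple_cutoff=0.5)

    def test_pair_selection_by_mean_distance(self, rng):
        from permut.model_io import Trajectory

        pos = np.zeros((10, 3, 3))
        pos[:, 0] = [1.0, 1.0, 1.0]
        pos[:, 1] = [1.5, 1.0, 1.0]  # 0.5 nm from molecule 0
        pos[:, 2] = [3.5, 3.0, 3.0]  # > 1 nm from everything (box 8)
        traj = Trajectory(pos, np.tile([8.0] * 3, (10, 1)), np.arange(10.0),
                          np.arange(3))
        pt = as_permuted(traj)
        pairs, triples = select_pairs_triples(pt, CutoffPolicy(1.0, 0.45))
        assert pairs == [(0, 1)]
        assert triples == []

    def test_triple_requires_all_three_legs(self):
        from permut.model_io import Trajectory

        # pairwise distances 0.3 / 0.3 / 0.5: the long leg exceeds 0.45
        pos = np.zeros((5, 3, 3))
        pos[:, 0] = [1.0, 1.0, 1.0]
        pos[:, 1] = [1.5, 1.0, 1.0]
        pos[:, 2] = [1.25, 1.0 + math.sqrt(0.3**2 - 0.25**2), 1.0]
        traj = Trajectory(pos, np.tile([8.0] * 3, (5, 1)), np.arange(5.0), np.arange(3))
        pt = as_permuted(traj)
        pairs, triples = select_pairs_triples(pt, CutoffPolicy(1.0, 0.45))
        assert len(pairs) == 3 and triples == []
        # equilateral 0.3 nm triangle -> all legs below the cutoff
        pos2 = pos.copy()
        pos2[:, 1] = [1.3, 1.0, 1.0]
        pos2[:, 2] = [1.15, 1.0 + math.sqrt(0.3**2 - 0.15**2), 1.0]
        pt2 = as_permuted(Trajectory(pos2, np.tile([8.0] * 3, (5, 1)),
                                     np.arange(5.0), np.arange(3)))
        _, triples2 = select_pairs_triples(pt2, CutoffPolicy(1.0, 0.45))
        assert triples2 == [(0, 1, 2)]


class TestPairwiseMI:
    def test_independent_molecules_near_zero(self):
        pt, _ = gaussian_ptraj(np.eye(6) * 0.01, n_frames=10000, seed=31)
        mi = mutual_information_2(pt, 0, 1)
        assert mi == pytest.approx(0.0, abs=0.02)

    def test_gaussian_cross_covariance_closed_form(self):
        rho = 0.6
        pt, _ = gaussian_ptraj(pair_cov(rho), n_frames=30000, seed=32)
        exact = -1.5 * math.log(1 - rho**2)
        mi = mutual_information_2(pt, 0, 1)
        assert mi == pytest.approx(exact, rel=0.05)

    def test_negative_estimates_not_clipped(self):
        # with few samples, independent molecules give noisy, sometimes
        # negative MI; the estimate is returned untouched
        vals = []
        for seed in range(8):
            pt, _ = gaussian_ptraj(np.eye(6) * 0.01, n_frames=600, seed=40 + seed)
            vals.append(mutual_information_2(pt, 0, 1))
        assert min(vals) < 0  # at least one noisy negative survives


class TestTriplewiseMI:
    def test_independent_triple_near_zero(self):
        pt, _ = gaussian_ptraj(np.eye(9) * 0.01, n_frames=10000, seed=33)
        i3 = mutual_information_3(pt, 0, 1, 2)
        assert i3 == pytest.approx(0.0, abs=0.03)

    def test_third_order_assembly_matches_gaussian_closed_form(self):
        # coupled triple: the full third-order expansion must reproduce the
        # 9-D joint entropy
        rho = 0.5
        cov = np.eye(9) * 0.01
        for a in range(3):
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                cov[3 * i + a, 3 * j + a] = cov[3 * j + a, 3 * i + a] = rho * 0.01
        pt, joint_exact = gaussian_ptraj(cov, n_frames=30000, seed=34)
        cache = {}
        params = EstimatorParams()
        from permut.knn import marginal_entropy

        S = {m: marginal_entropy(pt, (m,), params) for m in range(3)}
        I2 = {p: mutual_information_2(pt, *p, params, cache)
              for p in [(0, 1), (0, 2), (1, 2)]}
        I3 = mutual_information_3(pt, 0, 1, 2, params, cache)
        assembled = sum(S.values()) - sum(I2.values()) + I3
        assert assembled == pytest.approx(joint_exact, rel=0.05)

    def test_duplicated_coordinates_degenerate_triple(self):
        # three near-copies of one molecule: assembly collapses towards the
        # single-molecule entropy
        rho = 0.995
        cov = np.eye(9) * 0.01
        for a in range(3):
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                cov[3 * i + a, 3 * j + a] = cov[3 * j + a, 3 * i + a] = rho * 0.01
        pt, joint_exact = gaussian_ptraj(cov, n_frames=20000, seed=35)
        from permut.knn import marginal_entropy

        params = EstimatorParams()
        cache = {}
        S = {m: marginal_entropy(pt, (m,), params) for m in range(3)}
        I2 = {p: mutual_information_2(pt, *p, params, cache)
              for p in [(0, 1), (0, 2), (1, 2)]}
        I3 = mutual_information_3(pt, 0, 1, 2, params, cache)
        assembled = sum(S.values()) - sum(I2.values()) + I3
        # exact joint is close to S_0 plus two tiny conditional residuals
        assert abs(assembled - joint_exact) < 0.25 * abs(joint_exact)


# 27 molecules at water number density: xi = 10 nm^-1 matches the
# position-localization and orientation scales, as in the target regime
@pytest.fixture(scope="module")
def rotor_pair():
    out = {}
    for coupling in ("none", "octant"):
        traj = rigid_rotor(
            FixtureSpec("rigid_rotor", 27, (1.0,) * 3, 6000, seed=51),
            coupling=coupling,
        )
        ref = make_reference(traj.box[0], 27, kind="lattice")
        pt = permute_trajectory(traj, ref)
        track = orient_trajectory(pt, template=traj.metadata["template"])
        out[coupling] = (pt, track)
    return out


class TestTransRotMI:

    def test_independent_streams_near_zero(self, rotor_pair):
        pt, track = rotor_pair["none"]
        itr = trans_rot_mi(pt, track, pairs=[(0, 0), (13, 13)])
        for v in itr.values():
            assert v == pytest.approx(0.0, abs=0.08)

    def test_octant_coupling_positive_and_monotone(self, rotor_pair):
        pt, track = rotor_pair["octant"]
        itr = trans_rot_mi(pt, track, pairs=[(m, m) for m in range(27)])
        mean_coupled = np.mean(list(itr.values()))
        pt0, track0 = rotor_pair["none"]
        itr0 = trans_rot_mi(pt0, track0, pairs=[(m, m) for m in range(27)])
        assert mean_coupled > 0.1
        assert mean_coupled > np.mean(list(itr0.values())) + 0.1
        # tighter wobble -> stronger position-orientation coupling
        traj_loose = rigid_rotor(
            FixtureSpec("rigid_rotor", 27, (1.0,) * 3, 6000, seed=52,
                        options={"wobble_std": 1.2}),
            coupling="octant",
        )
        ref = make_reference(traj_loose.box[0], 27, kind="lattice")
        ptl = permute_trajectory(traj_loose, ref)
        trackl = orient_trajectory(ptl, template=traj_loose.metadata["template"])
        itrl = trans_rot_mi(ptl, trackl, pairs=[(m, m) for m in range(27)])
        assert mean_coupled > np.mean(list(itrl.values()))

    def test_cross_terms_of_uncoupled_molecules_small(self, rotor_pair):
        pt, track = rotor_pair["none"]
        itr = trans_rot_mi(pt, track, pairs=[(0, 1), (2, 5)])
        for v in itr.values():
            assert v == pytest.approx(0.0, abs=0.08)

    def test_mismatched_track_rejected(self, rotor_pair):
        pt, track = rotor_pair["none"]
        from permut.orientations import OrientationTrack

        short = OrientationTrack(track.quaternions[:10])
        with pytest.raises(ValueError, match="frame counts"):
            trans_rot_mi(pt, short, pairs=[(0, 0)])


class TestKineticTerms:
    def test_argon_kinetic_entropy(self):
        assert kinetic_entropy_trans(ARGON) == pytest.approx(115.70, abs=0.01)

    def test_length_unit_invariance_of_total(self):
        # doubling l shifts the kinetic part by -3 R ln 2 and the
        # configurational part (measured in units of l) by +3 R ln 2
        a = kinetic_entropy_trans(ARGON)
        b = kinetic_entropy_trans(
            ThermoParams(300.0, 39.948, length_unit=2.0)
        )
        assert b - a == pytest.approx(3 * GAS_CONSTANT_R * math.log(2), rel=1e-12)

    def test_temperature_scaling(self):
        hot = ThermoParams(1200.0, 39.948)
        diff = kinetic_entropy_trans(hot) - kinetic_entropy_trans(ARGON)
        assert diff == pytest.approx(1.5 * GAS_CONSTANT_R * math.log(4), rel=1e-12)

    def test_sackur_tetrode_argon_reference(self):
        assert sackur_tetrode(ARGON, 27.0) == pytest.approx(96.6, abs=0.05)

    def test_density_halving_adds_r_ln2(self):
        d = sackur_tetrode(ARGON, 13.5) - sackur_tetrode(ARGON, 27.0)
        assert d == pytest.approx(GAS_CONSTANT_R * math.log(2), rel=1e-12)

    def test_stirling_consistency_with_kinetic_split(self):
        rho = 27.0
        conf_uniform = GAS_CONSTANT_R * (math.log(1.0 / rho) + 1.0)
        assert kinetic_entropy_trans(ARGON) + conf_uniform == pytest.approx(
            sackur_tetrode(ARGON, rho), rel=1e-12
        )


class TestAssembly:
    def test_zero_mi_total_is_first_order(self):
        rep = EntropyReport(
            molecule_ids=np.arange(3),
            S1_trans=np.array([-2.0, -2.1, -1.9]),
            I2={}, I3={},
            kinetic_per_molecule=115.7,
            n_f=100,
        )
        assemble_total(rep)
        expected = 115.7 + GAS_CONSTANT_R * (-2.0 - 2.1 - 1.9) / 3
        assert rep.total.value == pytest.approx(expected, rel=1e-12)

    def test_shares_sum_to_total(self):
        from permut.spatial import per_molecule_decomposition

        rep = EntropyReport(
            molecule_ids=np.arange(4),
            S1_trans=np.array([-2.0, -2.1, -1.9, -2.05]),
            I2={(0, 1): 0.05, (1, 2): 0.03},
            I3={(0, 1, 2): 0.01},
            I_tr={(0, 0): 0.02, (0, 1): 0.004},
            kinetic_per_molecule=115.7,
            n_f=100,
        )
        assemble_total(rep)
        dec = per_molecule_decomposition(rep)
        assert np.sum(dec["total"]) / 4 == pytest.approx(rep.total.value, rel=1e-12)

    def test_gaussian_three_molecule_pipeline(self):
        rho = 0.4
        cov = np.eye(9) * 0.01
        for a in range(3):
            for i, j in [(0, 1), (1, 2)]:
                cov[3 * i + a, 3 * j + a] = cov[3 * j + a, 3 * i + a] = rho * 0.01
        pt, joint_exact = gaussian_ptraj(cov, n_frames=30000, seed=36)
        rep = compute_report(
            pt, ARGON, policy=CutoffPolicy(pair_cutoff=60.0, triple_cutoff=60.0),
            order=3,
        )
        conf_nats = rep.total.basis * 3
        assert conf_nats == pytest.approx(joint_exact, rel=0.05)

    def test_subsampling_stability(self, reduced_ideal_gas_small):
        # halving the frame count moves the total by a few standard errors
        # at most
        from permut.mie import stride_frames

        policy = CutoffPolicy(pair_cutoff=0.5, triple_cutoff=0.4)
        full = compute_report(
            reduced_ideal_gas_small, ARGON, policy=policy,
            params=EstimatorParams(seed=5), order=2,
        )
        half = compute_report(
            stride_frames(reduced_ideal_gas_small, 2), ARGON, policy=policy,
            params=EstimatorParams(seed=5), order=2,
        )
        se = math.hypot(full.total.stderr, half.total.stderr)
        assert abs(full.total.value - half.total.value) < 3 * se

    def test_order_validation(self):
        pt, _ = gaussian_ptraj(np.eye(3) * 0.01, n_frames=200, seed=37)
        with pytest.raises(ValueError, match="order"):
            compute_report(pt, ARGON, order=4)
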