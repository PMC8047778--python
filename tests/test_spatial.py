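import numpy as np
import pytest

from permut.constants import GAS_CONSTANT_R
from permut.model_io import EntropyReport, Trajectory
from permut.spatial import (
    build_voxel_map,
    bulk_reference_value,
    per_molecule_decomposition,
    select_shell,
    write_dx,
)

from conftest import as_permuted


def static_ptraj(positions, box=8.0, n_frames=4):
    pos = np.tile(np.asarray(positions, dtype=float), (n_frames, 1, 1))
    n = pos.shape[1]
    traj = Trajectory(pos, np.tile([box] * 3, (n_frames, 1)),
                      np.arange(float(n_frames)), np.arange(n))
    return as_permuted(traj)


class TestShellSelection:
    def test_all_molecules_when_shell_is_everything(self):
        pt = static_ptraj([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        sel = select_shell(pt, [[0.0, 0.0, 0.0]], 3)
        np.testing.assert_array_equal(sel, [0, 1, 2])

    def test_ranking_matches_analytic_distances(self, reduced_ideal_gas_small):
        pt = reduced_ideal_gas_small
        solute = pt.box[0] / 2.0
        n_shell = 10
        sel = select_shell(pt, [solute], n_shell)
        d = pt.mean_positions - solute
        d -= pt.box[0] * np.round(d / pt.box[0])
        dist = np.linalg.norm(d, axis=1)
        expected = np.sort(np.argsort(dist, kind="stable")[:n_shell])
        np.testing.assert_array_equal(sel, expected)

    def test_shell_size_100_of_1728(self):
        rng = np.random.default_rng(0)
        pos = rng.random((1, 1728, 3)) * 4.0
        traj = Trajectory(pos, np.array([[4.0] * 3]), np.zeros(1), np.arange(1728))
        sel = select_shell(as_permuted(traj), [[2.0, 2.0, 2.0]], 100)
        assert len(sel) == 100

    def test_empty_solute_rejected(self):
        pt = static_ptraj([[1, 1, 1]])
        with pytest.raises(ValueError, match="solute"):
            select_shell(pt, np.zeros((0, 3)), 1)

    def test_frame_average_method_agrees_for_static_molecules(self):
        pt = static_ptraj([[1, 1, 1], [5, 5, 5], [2, 2, 2]])
        a = select_shell(pt, [[0.0, 0.0, 0.0]], 2, method="mean_position")
        b = select_shell(pt, [[0.0, 0.0, 0.0]], 2, method="frame_average")
        np.testing.assert_array_equal(a, b)


class TestDecomposition:
    def test_single_pair_split_equally(self):
        rep = EntropyReport(
            molecule_ids=np.arange(2),
            S1_trans=np.array([-1.0, -1.0]),
            I2={(0, 1): 0.1}, I3={},
            kinetic_per_molecule=0.0, n_f=10,
        )
        dec = per_molecule_decomposition(rep)
        np.testing.assert_allclose(
            dec["I2_share"], [-0.05 * GAS_CONSTANT_R] * 2
        )

    def test_no_mi_terms_reduces_to_s1(self):
        rep = EntropyReport(
            molecule_ids=np.arange(3),
            S1_trans=np.array([-1.0, -2.0, -0.5]),
            I2={}, I3={}, kinetic_per_molecule=10.0, n_f=10,
        )
        dec = per_molecule_decomposition(rep)
        np.testing.assert_allclose(dec["total"], dec["S1"])

    def test_conservation_to_1e10_relative(self):
        rng = np.random.default_rng(3)
        n = 20
        I2 = {(i, j): rng.normal(0, 0.01) for i in range(n) for j in range(i + 1, n)
              if rng.random() < 0.3}
        I3 = {(i, j, k): rng.normal(0, 0.003)
              for i in range(n) for j in range(i + 1, n) for k in range(j + 1, n)
              if rng.random() < 0.02}
        rep = EntropyReport(
            molecule_ids=np.arange(n),
            S1_trans=rng.normal(-2, 0.1, n),
            I2=I2, I3=I3,
            I_tr={(i, i): rng.normal(0, 0.01) for i in range(n)},
            kinetic_per_molecule=115.7, n_f=10,
        )
        from permut.mie import assemble_total

        assemble_total(rep)
        dec = per_molecule_decomposition(rep)
        assert np.sum(dec["total"]) == pytest.approx(
            rep.total.value * n, rel=1e-10
        )


class TestVoxelMap:
    def test_single_molecule_single_voxel(self):
        pt = static_ptraj([[1.0, 1.0, 1.0]], box=8.0, n_frames=6)
        vm = build_voxel_map(pt, np.array([42.0]), grid_n=4)
        assert vm.values[0, 0, 0] == pytest.approx(42.0)
        assert vm.occupancy[0, 0, 0] == 6
        assert np.isnan(vm.values[1, 1, 1])
        assert vm.defined.sum() == 1

    def test_weighted_mean_of_two_molecules(self):
        # molecule 0 occupies the voxel all 4 frames, molecule 1 moves away
        # after the first frame
        pos = np.zeros((4, 2, 3))
        pos[:, 0] = [0.5, 0.5, 0.5]
        pos[:, 1] = [6.5, 6.5, 6.5]
        pos[0, 1] = [0.6, 0.5, 0.5]  # same voxel as molecule 0 in frame 0
        traj = Trajectory(pos, np.tile([8.0] * 3, (4, 1)), np.arange(4.0),
                          np.arange(2))
        vm = build_voxel_map(as_permuted(traj), np.array([10.0, 50.0]), grid_n=4)
        assert vm.values[0, 0, 0] == pytest.approx((4 * 10.0 + 1 * 50.0) / 5)

    def test_occupancy_counts_all_frames(self, reduced_ideal_gas_small):
        pt = reduced_ideal_gas_small
        vm = build_voxel_map(pt, np.zeros(pt.n_molecules), grid_n=8)
        assert vm.occupancy.sum() == pt.n_frames * pt.n_molecules

    def test_invariant_under_molecule_relabeling(self):
        rng = np.random.default_rng(5)
        pos = rng.random((10, 6, 3)) * 8.0
        vals = rng.normal(0, 1, 6)
        traj = Trajectory(pos, np.tile([8.0] * 3, (10, 1)), np.arange(10.0),
                          np.arange(6))
        vm1 = build_voxel_map(as_permuted(traj), vals, grid_n=4)
        perm = rng.permutation(6)
        traj2 = Trajectory(pos[:, perm], np.tile([8.0] * 3, (10, 1)),
                           np.arange(10.0), np.arange(6))
        vm2 = build_voxel_map(as_permuted(traj2), vals[perm], grid_n=4)
        np.testing.assert_allclose(vm1.occupancy, vm2.occupancy)
        np.testing.assert_allclose(vm1.values, vm2.values, equal_nan=True)

    def test_coarsening_equals_weighted_pooling(self):
        rng = np.random.default_rng(6)
        pos = rng.random((50, 8, 3)) * 8.0
        vals = rng.normal(0, 1, 8)
        traj = Trajectory(pos, np.tile([8.0] * 3, (50, 1)), np.arange(50.0),
                          np.arange(8))
        pt = as_permuted(traj)
        fine = build_voxel_map(pt, vals, grid_n=8)
        coarse = build_voxel_map(pt, vals, grid_n=4)
        acc = np.nan_to_num(fine.values) * fine.occupancy
        pooled_occ = fine.occupancy.reshape(4, 2, 4, 2, 4, 2).sum(axis=(1, 3, 5))
        pooled_acc = acc.reshape(4, 2, 4, 2, 4, 2).sum(axis=(1, 3, 5))
        with np.errstate(invalid="ignore"):
            pooled = pooled_acc / pooled_occ
        np.testing.assert_allclose(coarse.values, pooled, equal_nan=True)

    def test_bulk_reference_and_difference_map(self):
        pt = static_ptraj([[0.5, 0.5, 0.5], [4.0, 4.0, 4.0]], box=8.0)
        vals = np.array([30.0, 70.0])
        bulk = bulk_reference_value(pt, vals, [[0.5, 0.5, 0.5]], min_distance=1.2)
        assert bulk == 70.0
        vm = build_voxel_map(pt, vals, grid_n=4, reference_bulk=bulk)
        assert vm.values[0, 0, 0] == pytest.approx(-40.0)

    def test_dx_round_trip_values(self, tmp_path):
        pt = static_ptraj([[0.5, 0.5, 0.5]], box=2.0)
        vm = build_voxel_map(pt, np.array([7.5]), grid_n=2)
        path = str(tmp_path / "map.dx")
        write_dx(vm, path)
        text = open(path).read()
        assert "gridpositions counts 2 2 2" in text
        data = []
        in_data = False
        for line in text.splitlines():
            if line.startswith("object 3"):
                in_data = True
                continue
            if in_data:
                if line.startswith("attribute"):
                    break
                data.extend(float(v) for v in line.split())
        arr = np.array(data).reshape(2, 2, 2)
        assert arr[0, 0, 0] == pytest.approx(7.5)
        assert arr.sum() == pytest.approx(7.5)  # undefined voxels written as 0
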