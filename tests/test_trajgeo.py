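"""Signed bending/tilting dihedrals and trajectory-ensemble statistics."""

import numpy as np
import pytest

from bmcshell import synthetic
from bmcshell.geometry import DegenerateGeometryError, signed_dihedral
from bmcshell.lattice import HexamerPair
from bmcshell.synthetic import ToyLatticeSpec, make_lattice, make_trajectory
from bmcshell.trajgeo import (
    angle_series,
    average_structure,
    bending_angle,
    bending_frame,
    com_deviation,
    plane_representation,
    rmsd_series,
    tilting_angle,
    tilting_frame,
)


def bent_pair(lattice, lmap, theta, mode="bend"):
    pair = HexamerPair(lattice.hexamers[0], lattice.hexamers[1])
    frame = bending_frame(pair, lmap) if mode == "bend" else tilting_frame(pair, lmap)
    rot, trans = frame.rotation_for(theta)
    moved = lattice.hexamers[1].transformed(rot, trans)
    return HexamerPair(lattice.hexamers[0], moved), moved


def test_flat_layer_reads_zero(arr_a_pair, lmap):
    assert abs(bending_angle(arr_a_pair, lmap)) < 1e-3
    assert abs(tilting_angle(arr_a_pair, lmap)) < 1e-3


@pytest.mark.parametrize("theta", [-40.0, -25.0, -10.0, 10.0, 25.0, 40.0])
def test_bending_recovers_imposed_hinge_rotation(arr_a_lattice, lmap, theta):
    pair, _ = bent_pair(arr_a_lattice, lmap, theta)
    assert abs(bending_angle(pair, lmap) - theta) < 0.5


def test_negative_bending_points_to_convex_face(arr_a_lattice, lmap):
    """Negative sign = displacement toward the convex (−z) side."""
    pair, moved = bent_pair(arr_a_lattice, lmap, -25.0)
    assert bending_angle(pair, lmap) < -24.5
    assert moved.com[2] < -5.0  # hexamer B swung below the layer plane
    pair_up, moved_up = bent_pair(arr_a_lattice, lmap, 10.0)
    assert bending_angle(pair_up, lmap) > 9.5
    assert moved_up.com[2] > 2.0


def test_tilting_recovers_imposed_rotation(arr_a_lattice, lmap):
    pair, _ = bent_pair(arr_a_lattice, lmap, 15.0, mode="tilt")
    assert abs(tilting_angle(pair, lmap) - 15.0) < 0.1
    # bending is unaffected by a pure tilt (wing parallel to the tilt hinge)
    assert abs(bending_angle(pair, lmap)) < 1e-3


def test_pure_bend_has_bounded_tilt_crosstalk(arr_a_lattice, lmap):
    for theta in (-25.0, 15.0, 40.0):
        pair, _ = bent_pair(arr_a_lattice, lmap, theta)
        assert abs(tilting_angle(pair, lmap)) < 0.12 * abs(theta)


def test_angles_invariant_under_rigid_motion(arr_a_lattice, lmap):
    from conftest import random_rigid_transform

    pair, _ = bent_pair(arr_a_lattice, lmap, -17.0)
    b0, t0 = bending_angle(pair, lmap), tilting_angle(pair, lmap)
    rng = np.random.default_rng(21)
    for _ in range(5):
        rot, trans = random_rigid_transform(rng)
        moved = HexamerPair(
            pair.hexamer_a.transformed(rot, trans),
            pair.hexamer_b.transformed(rot, trans),
        )
        assert abs(bending_angle(moved, lmap) - b0) < 1e-3
        assert abs(tilting_angle(moved, lmap) - t0) < 1e-3


def test_bending_symmetric_under_hexamer_swap(arr_a_lattice, lmap):
    pair, moved = bent_pair(arr_a_lattice, lmap, -25.0)
    swapped = HexamerPair(moved, arr_a_lattice.hexamers[0])
    assert np.isclose(bending_angle(pair, lmap), bending_angle(swapped, lmap),
                      atol=1e-3)
    assert np.isclose(tilting_angle(pair, lmap), tilting_angle(swapped, lmap),
                      atol=1e-3)


def test_degenerate_quadruple_raises():
    with pytest.raises(DegenerateGeometryError):
        signed_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


def test_noisy_angle_recovery_within_one_degree():
    spec = ToyLatticeSpec(bend=-25.0, noise_sigma=0.3, n_snapshots=100,
                          schedule="constant", seed=42)
    traj, truth = make_trajectory(spec)
    series = angle_series(traj, truth.landmark_map)
    imposed = series.table[series.table["interface"].isin(["0-1", "0-2"])]
    assert abs(imposed["bending"].mean() + 25.0) < 1.0


def test_angle_series_linear_schedule_mean():
    spec = ToyLatticeSpec(bend=-25.0, n_snapshots=21, schedule="linear", seed=0)
    traj, truth = make_trajectory(spec)
    series = angle_series(traj, truth.landmark_map)
    imposed = series.table[series.table["interface"].isin(["0-1", "0-2"])]
    assert np.isclose(imposed["bending"].mean(), -12.5, atol=1e-3)
    assert np.isclose(series.pooled_stats()["bending_mean"], -12.5, atol=1.0)
    assert series.table[series.table["snapshot"] == 0]["crystal_start"].all()
    assert not series.table[series.table["snapshot"] > 0]["crystal_start"].any()


def test_angle_series_plateau_schedule_mean_near_plateau():
    spec = ToyLatticeSpec(bend=-25.0, n_snapshots=80, schedule="plateau:0.05",
                          seed=0)
    traj, truth = make_trajectory(spec)
    series = angle_series(traj, truth.landmark_map)
    assert abs(series.pooled_stats()["bending_mean"] + 25.0) < 1.0


def test_constant_angle_series_has_noise_floor_sd():
    spec = ToyLatticeSpec(bend=-25.0, noise_sigma=0.2, n_snapshots=30,
                          schedule="constant", seed=5)
    traj, truth = make_trajectory(spec)
    stats = angle_series(traj, truth.landmark_map).pooled_stats()
    # dispersion from coordinate noise only (~2.3° at σ = 0.2 Å levers)
    assert stats["bending_sd"] < 3.0


def test_average_of_identical_snapshots_is_the_snapshot():
    spec = ToyLatticeSpec(bend=-25.0, n_snapshots=4, schedule="constant", seed=0)
    traj, _ = make_trajectory(spec)
    avg = average_structure(traj)
    assert np.abs(avg.coord - traj.snapshot(0).coord).max() < 1e-4


def test_average_of_symmetric_bends_reads_mid_pose(lmap):
    """±θ snapshots average to a configuration measuring the mid angle."""
    lat = make_lattice(ToyLatticeSpec(spacing=68.5), n_hex=3)
    import biotite.structure as struc

    from bmcshell.trajgeo import TrajectoryEnsemble

    snaps = []
    for theta in (10.0, -10.0):
        spec = ToyLatticeSpec(bend=theta, n_snapshots=2, schedule="constant",
                              seed=0)
        traj, _ = make_trajectory(spec)
        snaps.append(traj.snapshot(0))
    ens = TrajectoryEnsemble(
        stack=struc.stack(snaps),
        chain_groups=tuple(h.chain_ids for h in lat.hexamers),
    )
    avg = average_structure(ens)
    from bmcshell.trajgeo import hexamer_from_chains

    pair = HexamerPair(
        hexamer_from_chains(avg, ens.chain_groups[0]),
        hexamer_from_chains(avg, ens.chain_groups[1]),
    )
    assert abs(bending_angle(pair, lmap)) < 0.1


def test_average_of_noise_converges_to_truth():
    spec = ToyLatticeSpec(noise_sigma=0.5, n_snapshots=60, seed=8)
    traj, truth = make_trajectory(spec)
    clean, _ = make_trajectory(ToyLatticeSpec(n_snapshots=2, seed=8))
    avg = average_structure(traj, fit_selection=None)
    # per-atom deviation of the mean ~ sigma/sqrt(n); allow 5 sigma_mean
    dev = np.linalg.norm(avg.coord - clean.snapshot(0).coord, axis=1)
    assert np.median(dev) < 5 * 0.5 / np.sqrt(60)


def test_rmsd_series_zero_at_reference_snapshot():
    spec = ToyLatticeSpec(bend=-25.0, n_snapshots=5, schedule="linear", seed=0)
    traj, _ = make_trajectory(spec)
    series = rmsd_series(traj, traj.snapshot(2))
    assert series[2] < 1e-4
    assert series[0] > series[2] and series[4] > series[2]


def test_rmsd_series_noise_scaling():
    """Backbone RMSD against the clean reference ≈ σ√3 for isotropic noise."""
    sigma = 0.4
    spec = ToyLatticeSpec(noise_sigma=sigma, n_snapshots=20, seed=3)
    traj, _ = make_trajectory(spec)
    clean, _ = make_trajectory(ToyLatticeSpec(n_snapshots=2, seed=3))
    series = rmsd_series(traj, clean.snapshot(0))
    assert np.isclose(series.mean(), sigma * np.sqrt(3), rtol=0.1)


def test_rmsd_series_u_shape_for_monotone_bend():
    spec = ToyLatticeSpec(bend=-25.0, n_snapshots=15, schedule="linear", seed=0)
    traj, _ = make_trajectory(spec)
    avg = average_structure(traj)
    series = rmsd_series(traj, avg)
    mid = len(series) // 2
    assert series[mid] < series[0] and series[mid] < series[-1]


def test_com_deviation_zero_for_identical_models(trihex):
    per_pair, mean = com_deviation(trihex.atoms, trihex)
    assert abs(mean) < 1e-4
    assert all(abs(v) < 1e-4 for v in per_pair.values())


def test_com_deviation_uniform_contraction(trihex):
    """A 1 % isotropic contraction shortens every 68.5 Å pair by 0.685 Å."""
    coms = np.array([h.com for h in trihex.hexamers])
    centroid = coms.mean(axis=0)
    shrunk = trihex.atoms.copy()
    shrunk.coord = centroid + 0.99 * (shrunk.coord - centroid)
    per_pair, mean = com_deviation(shrunk, trihex)
    assert np.isclose(mean, -0.685, atol=1e-3)
    assert all(np.isclose(v, -0.685, atol=1e-3) for v in per_pair.values())


def test_com_deviation_single_displaced_hexamer(trihex):
    groups = [h.chain_ids for h in trihex.hexamers]
    moved = trihex.atoms.copy()
    axis = trihex.hexamers[1].com - trihex.hexamers[0].com
    axis = axis / np.linalg.norm(axis)
    sel = np.isin(moved.chain_id, list(groups[1]))
    moved.coord[sel] += (2.0 * axis).astype(np.float32)
    per_pair, _ = com_deviation(moved, trihex)
    assert np.isclose(per_pair[frozenset((0, 1))], 2.0, atol=1e-3)


def test_plane_representation_flat(trihex, lmap):
    planes = plane_representation(trihex, lmap)
    normals = planes[["nx", "ny", "nz"]].to_numpy()
    # all hexamer planes parallel (orientation sign is arbitrary)
    for n in normals[:3]:
        cosang = abs(np.dot(n, normals[0]))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 0.1
    # the COM plane contains all three COMs
    point = planes.iloc[3][["px", "py", "pz"]].to_numpy(dtype=float)
    normal = planes.iloc[3][["nx", "ny", "nz"]].to_numpy(dtype=float)
    for h in trihex.hexamers:
        assert abs(np.dot(h.com - point, normal)) < 1e-3


def test_plane_angle_matches_bending(arr_a_lattice, lmap):
    """Inter-plane angle equals the imposed bend within 2 degrees."""
    theta = -25.0
    _, moved = bent_pair(arr_a_lattice, lmap, theta)
    lat3 = make_lattice(ToyLatticeSpec(spacing=68.5), n_hex=3)
    hexes = [lat3.hexamers[0], moved, lat3.hexamers[2]]
    import biotite.structure as struc

    model = struc.concatenate([h.atoms for h in hexes])
    # hexamer 1 of lat3 shares chain ids with `moved` (both GHIJKL)
    planes = plane_representation(model, lmap,
                                  chain_groups=[h.chain_ids for h in hexes])
    n0 = planes.iloc[0][["nx", "ny", "nz"]].to_numpy(dtype=float)
    n1 = planes.iloc[1][["nx", "ny", "nz"]].to_numpy(dtype=float)
    ang = np.degrees(np.arccos(np.clip(abs(np.dot(n0, n1)), -1, 1)))
    assert abs(ang - abs(theta)) < 2.0
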