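"""Per-residue interface analytics: masks, profiles, scoring and ranking."""

import numpy as np
import pandas as pd
import pytest
import biotite.structure as struc

from bmcshell import synthetic
from bmcshell.interface import (
    energy_interval,
    interface_enrichment,
    interface_mask,
    mask_to_frame,
    naive_residue_score,
    rank_key_residues,
    read_energy_table,
    sidechain_rmsd_profile,
)
from bmcshell.synthetic import ToyLatticeSpec, make_trajectory
from bmcshell.trajgeo import average_structure


# ---------------------------------------------------------------- masks


def test_mask_isolated_hexamer_all_false(toy_hexamer):
    far = toy_hexamer.transformed(np.eye(3), np.array([500.0, 0, 0]))
    far_atoms = far.atoms.copy()
    far_atoms.chain_id = np.array([c.lower() for c in far_atoms.chain_id])
    both = struc.concatenate([toy_hexamer.atoms, far_atoms])
    mask = interface_mask(both, chain_groups=[tuple("ABCDEF"), tuple("abcdef")])
    assert not any(mask.values())


def test_mask_zero_cutoff_all_false(trihex):
    mask = interface_mask(trihex, contact_cutoff=0.0)
    assert not any(mask.values())


def test_mask_flags_constructed_rim_residues(trihex):
    mask = mask_to_frame(interface_mask(trihex))
    counts = mask.sum(axis=1)
    # the key lysine touches each of the three interfaces in 2 chains
    assert counts.loc[26] == 6
    # deep scaffold residues never touch another hexamer
    assert counts.loc[5] == 0
    assert counts.loc[40] == 0


# ----------------------------------------------------- side-chain profiles


@pytest.fixture(scope="module")
def small_traj():
    spec = ToyLatticeSpec(noise_sigma=0.15, n_snapshots=8, seed=13)
    return make_trajectory(spec)


def test_frozen_sidechains_profile_is_zero():
    spec = ToyLatticeSpec(bend=-25.0, n_snapshots=4, schedule="constant", seed=0)
    traj, _ = make_trajectory(spec)
    avg = average_structure(traj)
    prof = sidechain_rmsd_profile(traj, avg, exclude_first=1)
    assert float(prof.max().max()) < 1e-3


def test_profile_exclude_first_bounds(small_traj):
    traj, _ = small_traj
    avg = average_structure(traj)
    with pytest.raises(ValueError, match="exclude_first"):
        sidechain_rmsd_profile(traj, avg, exclude_first=traj.n_snapshots)


def test_profile_degenerates_to_last_snapshot(small_traj):
    """exclude_first = n−1 leaves the direct RMSD of the final snapshot."""
    traj, _ = small_traj
    avg = average_structure(traj)
    prof = sidechain_rmsd_profile(traj, avg, exclude_first=traj.n_snapshots - 1)
    # independent check for one residue/monomer
    from bmcshell.geometry import kabsch

    arr = avg
    snap = traj.snapshot(traj.n_snapshots - 1)
    bb = np.flatnonzero((arr.res_id == 26) & (arr.chain_id == "A")
                        & np.isin(arr.atom_name, ("N", "CA", "C", "O")))
    sc = np.flatnonzero((arr.res_id == 26) & (arr.chain_id == "A")
                        & ~np.isin(arr.atom_name, ("N", "CA", "C", "O")))
    rot, trans, _ = kabsch(snap.coord[bb], avg.coord[bb])
    moved = snap.coord[sc] @ rot.T + trans
    direct = np.sqrt(np.mean(np.sum((moved - avg.coord[sc]) ** 2, axis=1)))
    assert np.isclose(prof.loc[26, "A"], direct, atol=1e-6)


def test_jittered_residue_reads_higher(small_traj):
    traj, truth = small_traj
    noisy = synthetic.jitter_sidechains(traj, residue=40, chains=["A", "B"],
                                        sigma=1.5, seed=1)
    avg = average_structure(noisy)
    prof = sidechain_rmsd_profile(noisy, avg, exclude_first=2)
    jittered = prof.loc[40, ["A", "B"]].mean()
    quiet = prof.loc[40].drop(["A", "B"]).mean()
    assert jittered > 3 * quiet


# ------------------------------------------------------- matrix statistics


def test_energy_interval_constant_matrix_zero():
    prof = pd.DataFrame(np.full((5, 18), 2.5),
                        index=range(1, 6), columns=[f"m{i}" for i in range(18)])
    assert (energy_interval(prof) == 0).all()


def test_energy_interval_matches_brute_force():
    rng = np.random.default_rng(7)
    prof = pd.DataFrame(rng.normal(size=(40, 18)), index=range(1, 41),
                        columns=[f"m{i}" for i in range(18)])
    interval = energy_interval(prof)
    for res in prof.index:
        row = prof.loc[res].to_numpy()
        assert interval.loc[res] == row.max() - row.min()
    assert list(interval.values) == sorted(interval.values, reverse=True)


def test_energy_interval_missing_entries_error():
    prof = pd.DataFrame(np.ones((3, 4)), index=[1, 2, 3])
    prof.iloc[1, 2] = np.nan
    with pytest.raises(ValueError, match="2"):
        energy_interval(prof)


def test_enrichment_constructions():
    cols = [f"m{i}" for i in range(6)]
    mask = {(1, c): (c in cols[:2]) for c in cols}
    mask.update({(2, c): (c in cols[:2]) for c in cols})
    mask.update({(3, c): True for c in cols})  # all-interface residue
    flat = pd.DataFrame(np.ones((3, 6)), index=[1, 2, 3], columns=cols)
    flat.loc[2, cols[:2]] = -4.0  # −5 relative to the exposed copies
    delta, excluded = interface_enrichment(flat, mask)
    assert np.isclose(delta.loc[1], 0.0)
    assert np.isclose(delta.loc[2], -5.0)
    assert excluded == [3]


def test_mask_independent_matrix_has_zero_enrichment(trihex):
    mask = interface_mask(trihex)
    residues = sorted({r for r, _ in mask})
    monomers = sorted({c for _, c in mask})
    prof = pd.DataFrame(3.0, index=residues, columns=monomers)
    delta, _ = interface_enrichment(prof, mask)
    assert np.allclose(delta.values, 0.0)


# ------------------------------------------------------- the naive scorer


def _two_atom_groups(d):
    """A LYS NZ and a GLU OE1 pair at distance d, in two one-chain groups."""
    arr = struc.AtomArray(2)
    arr.coord = np.array([[0.0, 0, 0], [d, 0, 0]])
    arr.chain_id = np.array(["A", "B"])
    arr.res_id = np.array([26, 83])
    arr.res_name = np.array(["LYS", "GLU"])
    arr.atom_name = np.array(["NZ", "OE1"])
    arr.element = np.array(["N", "O"])
    arr.hetero = np.zeros(2, dtype=bool)
    return arr


def test_naive_score_isolated_hexamers_is_zero(toy_hexamer):
    far = toy_hexamer.transformed(np.eye(3), np.array([200.0, 0, 0]))
    far_atoms = far.atoms.copy()
    far_atoms.chain_id = np.array([c.lower() for c in far_atoms.chain_id])
    both = struc.concatenate([toy_hexamer.atoms, far_atoms])
    total = naive_residue_score(both, [tuple("ABCDEF"), tuple("abcdef")])
    assert float(np.abs(total.to_numpy()).max()) == 0.0


def test_naive_score_salt_bridge_hand_computed():
    d = 3.0
    arr = _two_atom_groups(d)
    total = naive_residue_score(arr, [("A",), ("B",)])
    from bmcshell.interface import COULOMB_KJ_A, VDW_RADII, _DIELECTRIC_SLOPE, _LJ_EPS

    e_c = COULOMB_KJ_A * (1.0) * (-0.5) / (_DIELECTRIC_SLOPE * d * d)
    rmin = VDW_RADII["N"] + VDW_RADII["O"]
    x6 = (rmin / d) ** 6
    e_s = _LJ_EPS * (x6 * x6 - 2 * x6)
    expected = e_c + e_s
    assert np.isclose(total.loc[26, "A"], expected, atol=1e-9)
    assert np.isclose(total.loc[83, "B"], expected, atol=1e-9)
    assert expected < -5.0  # strongly stabilizing


def test_naive_score_coulomb_scales_quadratically(trihex):
    _, c1 = naive_residue_score(trihex, return_components=True)
    _, c2 = naive_residue_score(trihex, charge_scale=2.0, return_components=True)
    assert np.allclose(c2["coulomb"].to_numpy(), 4 * c1["coulomb"].to_numpy())
    assert np.allclose(c2["steric"].to_numpy(), c1["steric"].to_numpy())


def test_naive_score_monomer_permutation_invariance(trihex):
    total = naive_residue_score(trihex)
    # scores are keyed by (residue, monomer); relabeling monomers permutes
    # columns without changing values
    arr = trihex.atoms.copy()
    swap = {"A": "B", "B": "A"}
    arr.chain_id = np.array([swap.get(c, c) for c in arr.chain_id])
    groups = [tuple(swap.get(c, c) for c in h.chain_ids) for h in trihex.hexamers]
    total2 = naive_residue_score(arr, groups)
    assert np.allclose(total2["A"].to_numpy(), total["B"].to_numpy())
    assert np.allclose(total2["B"].to_numpy(), total["A"].to_numpy())


def test_energy_table_round_trip(tmp_path):
    rows = [{"residue": r, "monomer": m, "value": r * 0.1 - (m == "A")}
            for r in (1, 2) for m in ("A", "B")]
    path = tmp_path / "energy.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    table = read_energy_table(path)
    assert table.shape == (2, 2)
    assert np.isclose(table.loc[1, "A"], -0.9)


# --------------------------------------------------------------- ranking


def planted_clamp_fixture(seed, clamp=26):
    """Trajectory + energy matrix where `clamp` is the sole clamping residue."""
    spec = ToyLatticeSpec(noise_sigma=0.12, n_snapshots=6, seed=seed)
    traj, truth = make_trajectory(spec)
    mask = interface_mask(traj.snapshot(0), truth.chain_groups)
    mframe = mask_to_frame(mask)
    off_chains = [c for c in mframe.columns if not mframe.loc[clamp, c]]
    noisy = synthetic.jitter_sidechains(traj, clamp, off_chains, sigma=1.0,
                                        seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    residues = sorted(mframe.index)
    energy = pd.DataFrame(
        rng.uniform(-0.05, 0.05, (len(residues), len(mframe.columns))),
        index=residues, columns=mframe.columns,
    )
    for c in mframe.columns:
        if mframe.loc[clamp, c]:
            energy.loc[clamp, c] = -8.0 + rng.uniform(-0.2, 0.2)
    return noisy, energy, mask


def test_planted_clamp_is_top_ranked_on_all_criteria():
    traj, energy, mask = planted_clamp_fixture(seed=100)
    avg = average_structure(traj)
    prof = sidechain_rmsd_profile(traj, avg, exclude_first=2)
    ranking = rank_key_residues(prof, energy, mask)
    top = ranking.iloc[0]
    assert top["residue"] == 26
    assert top["frozen_at_interface"]
    assert top["criteria_met"] == 3


def test_no_signal_flag():
    cols = [f"m{i}" for i in range(6)]
    mask = {(r, c): c in cols[:2] for r in (1, 2) for c in cols}
    zeros = pd.DataFrame(0.0, index=[1, 2], columns=cols)
    ranking = rank_key_residues(zeros, zeros, mask)
    assert ranking.attrs["no_signal"]
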