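"""Per-residue interface analytics: who clamps the hexamers together?

The key interactors of the tiled layer (K26, R79 and friends in PduA
numbering) were originally pinpointed by combining three per-residue signals
over the 18 monomers of a tri-hexamer: (i) side-chain RMSD against the MD
average — a clamping residue is conformationally frozen, but only at the
interface; (ii) the spread (max − min) of its per-monomer interaction
energy; (iii) stabilization at interfacial positions relative to exposed
ones.  This module computes those profiles from trajectories and from
per-residue energy tables (any external engine, read as plain TSV), plus a
documented, deterministic in-package residue scorer for tests and ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import kabsch
from .lattice import TriHexamerModel
from .trajgeo import TrajectoryEnsemble

_BACKBONE = ("N", "CA", "C", "O")


# --------------------------------------------------------------------------
# Interface masks
# --------------------------------------------------------------------------


def interface_mask(model, chain_groups=None, contact_cutoff=5.0) -> dict:
    """Flag per (residue, monomer): any heavy atom within cutoff of another hexamer.

    ``model`` is a TriHexamerModel or a bare AtomArray with explicit hexamer
    ``chain_groups``.  A cutoff of 0 flags nothing.
    """
    if isinstance(model, TriHexamerModel):
        arr = model.atoms
        chain_groups = tuple(h.chain_ids for h in model.hexamers)
    else:
        arr = model
        if not chain_groups:
            raise ValueError("chain_groups required for a bare atom model")
    chain_to_hex = {c: i for i, g in enumerate(chain_groups) for c in g}
    heavy = arr[arr.element != "H"]
    hex_idx = np.array([chain_to_hex[c] for c in heavy.chain_id])
    mask = {}
    for (r, c) in {(int(r), str(c)) for r, c in zip(arr.res_id, arr.chain_id)}:
        mask[(r, c)] = False
    if contact_cutoff <= 0:
        return mask
    trees = {
        h: cKDTree(heavy.coord[hex_idx == h]) for h in set(hex_idx)
    }
    for h in sorted(set(hex_idx)):
        sel = hex_idx == h
        coords = heavy.coord[sel]
        near = np.zeros(len(coords), dtype=bool)
        for other, tree in trees.items():
            if other == h:
                continue
            d, _ = tree.query(coords, k=1, distance_upper_bound=contact_cutoff)
            near |= np.isfinite(d)
        for k in np.flatnonzero(near):
            mask[(int(heavy.res_id[sel][k]), str(heavy.chain_id[sel][k]))] = True
    return mask


def mask_to_frame(mask: dict) -> pd.DataFrame:
    """Residue × monomer boolean DataFrame from an interface mask."""
    ser = pd.Series(mask)
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["residue", "monomer"])
    return ser.unstack("monomer").fillna(False).astype(bool)


# --------------------------------------------------------------------------
# Side-chain RMSD profiles
# --------------------------------------------------------------------------


def _residue_groups(arr):
    """{(res_id, chain): (backbone idx, side-chain idx)}; Ala→Cβ, Gly→Cα fallback."""
    groups = {}
    order = np.arange(arr.array_length())
    for key in {(int(r), str(c)) for r, c in zip(arr.res_id, arr.chain_id)}:
        r, c = key
        sel = order[(arr.res_id == r) & (arr.chain_id == c)]
        names = arr.atom_name[sel]
        bb = sel[np.isin(names, _BACKBONE)]
        sc = sel[~np.isin(names, _BACKBONE) & (arr.element[sel] != "H")]
        if len(sc) == 0:  # glycine: fall back to Cα
            sc = sel[names == "CA"]
        if len(bb) >= 3:
            groups[key] = (bb, sc)
    return groups


def sidechain_rmsd_profile(traj: TrajectoryEnsemble, avg, exclude_first: int = 8
                           ) -> pd.DataFrame:
    """Mean side-chain RMSD per residue per monomer against an average model.

    Each residue is locally superposed on its own backbone before the RMSD
    over side-chain atoms, so the profile reads conformational freezing, not
    rigid-body drift.  The first ``exclude_first`` snapshots are dropped
    (equilibration); ``exclude_first >= n_snapshots`` is an error.
    Returns a residue × monomer DataFrame.
    """
    n = traj.n_snapshots
    if exclude_first >= n:
        raise ValueError(f"exclude_first={exclude_first} >= {n} snapshots")
    if avg.array_length() != traj.snapshot(0).array_length():
        raise ValueError("average model topology does not match the trajectory")
    groups = _residue_groups(avg)
    sums = {key: 0.0 for key in groups}
    count = n - exclude_first
    coords_stack = traj.stack.coord[exclude_first:]
    avg_coord = avg.coord
    for key, (bb, sc) in groups.items():
        ref_bb = avg_coord[bb]
        ref_sc = avg_coord[sc]
        acc = 0.0
        for snap_coord in coords_stack:
            rot, trans, _ = kabsch(snap_coord[bb], ref_bb)
            moved = snap_coord[sc] @ rot.T + trans
            acc += float(np.sqrt(np.mean(np.sum((moved - ref_sc) ** 2, axis=1))))
        sums[key] = acc / count
    ser = pd.Series(sums)
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["residue", "monomer"])
    return ser.unstack("monomer")


# --------------------------------------------------------------------------
# Energy-profile statistics
# --------------------------------------------------------------------------


def read_energy_table(path) -> pd.DataFrame:
    """Residue × monomer energy matrix from a (residue, monomer, value) TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue", "monomer", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"energy table needs columns {sorted(required)}")
    return df.pivot(index="residue", columns="monomer", values="value")


def energy_interval(profile: pd.DataFrame) -> pd.Series:
    """Per-residue spread (max − min) across monomer copies, ranked descending."""
    if profile.isna().any().any():
        missing = sorted(profile.index[profile.isna().any(axis=1)])
        raise ValueError(f"profile has missing entries for residues {missing}")
    interval = profile.max(axis=1) - profile.min(axis=1)
    return interval.sort_values(ascending=False)


def interface_enrichment(profile: pd.DataFrame, mask: dict):
    """Per-residue Δ = mean(interface copies) − mean(exposed copies).

    Negative Δ marks residues more stabilized (energies) or more ordered
    (RMSD) at the interface.  Residues with an empty class are excluded and
    reported: returns ``(delta Series, excluded residue list)``.
    """
    mframe = mask_to_frame(mask).reindex(index=profile.index,
                                         columns=profile.columns)
    mframe = mframe.fillna(False).astype(bool)
    deltas = {}
    excluded = []
    for res in profile.index:
        vals = profile.loc[res]
        flags = mframe.loc[res]
        if flags.all() or (~flags).all():
            excluded.append(res)
            continue
        deltas[res] = float(vals[flags].mean() - vals[~flags].mean())
    return pd.Series(deltas).sort_values(), excluded


def rank_key_residues(rmsd_profile: pd.DataFrame | None,
                      energy_profile: pd.DataFrame | None,
                      mask: dict) -> pd.DataFrame:
    """Ranked key-interactor candidates with per-criterion evidence.

    Criteria: (a) interface copies conformationally frozen — interface-copy
    mean side-chain RMSD below the 25th percentile of off-interface copies;
    (b) large per-monomer energy interval; (c) negative interface enrichment
    of the energy.  The combined ordering is lexicographic (criteria met,
    then energy interval, then enrichment); each criterion's value is
    retained so the combination is auditable.  A ``no_signal`` attribute set
    on the frame flags the degenerate all-flat case.
    """
    mframe = mask_to_frame(mask)
    residues = set()
    if rmsd_profile is not None:
        residues |= set(rmsd_profile.index)
    if energy_profile is not None:
        residues |= set(energy_profile.index)
    rows = []
    for res in sorted(residues):
        row = {"residue": res, "frozen_at_interface": False,
               "energy_interval": 0.0, "enrichment": 0.0}
        if rmsd_profile is not None and res in rmsd_profile.index:
            flags = mframe.reindex(index=[res],
                                   columns=rmsd_profile.columns).fillna(False).astype(bool).loc[res]
            vals = rmsd_profile.loc[res]
            if flags.any() and (~flags).any():
                q25 = float(np.percentile(vals[~flags], 25))
                row["frozen_at_interface"] = bool(vals[flags].mean() < q25)
                row["interface_rmsd"] = float(vals[flags].mean())
                row["offsite_rmsd"] = float(vals[~flags].mean())
        if energy_profile is not None and res in energy_profile.index:
            vals = energy_profile.loc[res]
            row["energy_interval"] = float(vals.max() - vals.min())
            flags = mframe.reindex(index=[res],
                                   columns=energy_profile.columns).fillna(False).astype(bool).loc[res]
            if flags.any() and (~flags).any():
                row["enrichment"] = float(vals[flags].mean() - vals[~flags].mean())
        row["criteria_met"] = int(row["frozen_at_interface"]) + int(
            row["energy_interval"] > 1e-9
        ) + int(row["enrichment"] < -1e-9)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        by=["criteria_met", "energy_interval", "enrichment"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    df.attrs["no_signal"] = bool(
        df.empty
        or (
            df["criteria_met"].max() == 0
            and df["energy_interval"].max() <= 1e-9
        )
    )
    return df


# --------------------------------------------------------------------------
# In-package residue scorer (tests and ranking only — not physical energies)
# --------------------------------------------------------------------------

#: Formal charges on side-chain atoms (elementary charges).
FORMAL_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
}
HIS_CHARGES = {("HIS", "ND1"): 0.5, ("HIS", "NE2"): 0.5}

#: van-der-Waals radii (Å) for the steric term.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

COULOMB_KJ_A = 1389.35  # e²/Å -> kJ/mol
_DIELECTRIC_SLOPE = 4.0  # distance-dependent dielectric ε(r) = 4 r
_LJ_EPS = 0.2  # kJ/mol well depth of the steric term


def naive_residue_score(model, chain_groups=None, cutoff=12.0,
                        charge_scale=1.0, protonate_his=False,
                        return_components=False):
    """Deterministic per-residue inter-hexamer score matrix (kJ/mol-like).

    Sum over inter-hexamer atom pairs of a screened Coulomb term
    (``1389.35 q_i q_j / (4 r²)``, embedded integer/half formal charges) and
    a Lennard-Jones-like steric term with embedded vdW radii.  Intended for
    tests and ranking only; real per-residue energies from an external
    engine enter through :func:`read_energy_table`.
    """
    if isinstance(model, TriHexamerModel):
        arr = model.atoms
        chain_groups = tuple(h.chain_ids for h in model.hexamers)
    else:
        arr = model
        if not chain_groups:
            raise ValueError("chain_groups required for a bare atom model")
    heavy = arr[arr.element != "H"]
    chain_to_hex = {c: i for i, g in enumerate(chain_groups) for c in g}
    hex_idx = np.array([chain_to_hex[c] for c in heavy.chain_id])
    charges = dict(FORMAL_CHARGES)
    if protonate_his:
        charges.update(HIS_CHARGES)
    q = np.array([
        charges.get((rn, an), 0.0) * charge_scale
        for rn, an in zip(heavy.res_name, heavy.atom_name)
    ])
    radii = np.array([VDW_RADII.get(e, 1.7) for e in heavy.element])
    tree = cKDTree(heavy.coord)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        cross = hex_idx[pairs[:, 0]] != hex_idx[pairs[:, 1]]
        pairs = pairs[cross]
    keys = [(int(r), str(c)) for r, c in zip(heavy.res_id, heavy.chain_id)]
    coulomb = {}
    steric = {}
    for i, j in pairs:
        r = float(np.linalg.norm(heavy.coord[i] - heavy.coord[j]))
        if r < 0.5:
            r = 0.5
        e_c = COULOMB_KJ_A * q[i] * q[j] / (_DIELECTRIC_SLOPE * r * r)
        rmin = radii[i] + radii[j]
        x6 = (rmin / r) ** 6
        e_s = _LJ_EPS * (x6 * x6 - 2.0 * x6)
        for k in (i, j):
            coulomb[keys[k]] = coulomb.get(keys[k], 0.0) + e_c
            steric[keys[k]] = steric.get(keys[k], 0.0) + e_s

    def to_frame(d):
        ser = pd.Series(d, dtype=float)
        ser.index = pd.MultiIndex.from_tuples(ser.index, names=["residue", "monomer"])
        frame = ser.unstack("monomer")
        all_keys = pd.MultiIndex.from_tuples(sorted(set(keys)),
                                             names=["residue", "monomer"])
        full = pd.Series(0.0, index=all_keys)
        full.update(ser)
        return full.unstack("monomer").fillna(0.0)

    cou = to_frame(coulomb)
    ste = to_frame(steric)
    total = cou.add(ste, fill_value=0.0)
    if return_components:
        return total, {"coulomb": cou, "steric": ste}
    return total


def lowest_rmsd_snapshot(traj: TrajectoryEnsemble, avg) -> int:
    """Index of the snapshot closest to the average structure (backbone RMSD)."""
    from .trajgeo import rmsd_series

    series = rmsd_series(traj, avg)
    return int(np.argmin(series))
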