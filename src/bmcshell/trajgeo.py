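"""Signed inter-hexamer bending/tilting geometry over snapshot ensembles.

Bending is the signed dihedral over the Cα quadruple
``I38(A) – S27(A) – S27(B) – I38(B)`` taken from one interfacial monomer of
hexamer A and the symmetric monomer of hexamer B; tilting uses the midpoints
of the M24 and I18 Cα pairs of the two interfacial monomers of each hexamer
(PduA numbering; any homolog via the landmark map).  A flat layer reads 0°;
the hinge lies along the interface (S27–S27 for bending, the M24-midpoint
axis for tilting).  Negative angles are displacements toward the convex face
of the hexamer, the orientation adopted by closed shells; the convex side is
anchored by the concave-face residues declared in the landmark map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .geometry import (
    DegenerateGeometryError,
    fit_plane,
    signed_dihedral,
    wrap_angle,
)
from .lattice import (
    BACKBONE_NAMES,
    HexamerModel,
    HexamerPair,
    TriHexamerModel,
    backbone_com,
)
from .structures import LandmarkMap, ca_position


@dataclass
class TrajectoryEnsemble:
    """Ordered constant-topology snapshots of a (tri-)hexamer system."""

    stack: struc.AtomArrayStack
    frame_interval_ps: float = 250.0
    chain_groups: tuple = ()
    provenance: str = ""

    def __post_init__(self):
        if self.stack.stack_depth() < 2:
            raise ValueError("a trajectory needs at least 2 snapshots")

    @property
    def n_snapshots(self) -> int:
        return self.stack.stack_depth()

    def snapshot(self, i: int) -> struc.AtomArray:
        return self.stack[i]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_snapshots) * self.frame_interval_ps


def trajectory_from_file(path, frame_interval_ps=250.0, chain_groups=()):
    """Read a multi-MODEL PDB trajectory (constant topology enforced)."""
    from .structures import read_structure

    crystal = read_structure(path, fmt="pdb")
    n0 = crystal.models[0].array_length()
    for i, m in enumerate(crystal.models):
        if m.array_length() != n0 or not np.array_equal(
            m.atom_name, crystal.models[0].atom_name
        ):
            raise ValueError(f"model {i + 1} topology differs from model 1")
    return TrajectoryEnsemble(
        stack=struc.stack(crystal.models),
        frame_interval_ps=frame_interval_ps,
        chain_groups=tuple(chain_groups),
        provenance=str(path),
    )


def hexamer_from_chains(snapshot: struc.AtomArray, chain_ids,
                        core_range=(1, 90)) -> HexamerModel:
    sel = np.isin(snapshot.chain_id, list(chain_ids))
    return HexamerModel(
        atoms=snapshot[sel], chain_ids=tuple(chain_ids), core_range=core_range
    )


def concave_direction(hexamer: HexamerModel, lmap: LandmarkMap) -> np.ndarray:
    """Unit vector from the hexamer COM toward its concave face."""
    atoms = hexamer.atoms
    if lmap.concave_face_residues:
        sel = np.isin(atoms.res_id, list(lmap.concave_face_residues)) & (
            atoms.atom_name == "CA"
        )
        if sel.any():
            d = atoms.coord[sel].mean(axis=0) - backbone_com(atoms, lmap.core_range)
            return d / np.linalg.norm(d)
    # fall back to the +z-most plane normal of the chain COMs (unanchored)
    coms = np.array([hexamer.chain_com(c) for c in hexamer.chain_ids])
    _, n = fit_plane(coms)
    return n if n[2] >= 0 else -n


def _interfacial_chains(hexamer: HexamerModel, other: HexamerModel, n=2):
    """The n chains of ``hexamer`` nearest (by chain COM) to the other hexamer."""
    other_com = other.com
    dists = [
        (float(np.linalg.norm(hexamer.chain_com(c) - other_com)), c)
        for c in hexamer.chain_ids
    ]
    dists.sort()
    return tuple(c for _, c in dists[:n])


def _bending_chain_pair(pair: HexamerPair, lmap: LandmarkMap):
    """Facing monomer pair: the chains whose key-lysine Cα are mutually closest.

    The inter-lysine pair defines the facing monomers of an interface; it is
    also far better separated from the runner-up pairing than any S27-based
    choice, so the selection is robust to coordinate noise.
    """
    lys = lmap.lys_edge
    best = None
    for ca in _interfacial_chains(pair.hexamer_a, pair.hexamer_b):
        pa = ca_position(pair.hexamer_a.atoms, ca, lys)
        for cb in _interfacial_chains(pair.hexamer_b, pair.hexamer_a):
            pb = ca_position(pair.hexamer_b.atoms, cb, lys)
            d = np.linalg.norm(pa - pb)
            if best is None or d < best[0]:
                best = (d, ca, cb)
    return best[1], best[2]


@dataclass
class HingeFrame:
    """A dihedral hinge: axis line, orientation sense, and the 4 points."""

    axis: np.ndarray
    point: np.ndarray
    sense: float
    quadruple: np.ndarray = field(default=None, repr=False)

    def rotation_for(self, angle_deg: float):
        """(R, t) rotating the far hexamer so the measured angle reads ``angle_deg``.

        A right-handed rotation about the p2→p3 axis *decreases* the raw
        dihedral, hence the −sense factor.
        """
        from .geometry import rotation_about_axis

        return rotation_about_axis(self.axis, -self.sense * angle_deg, self.point)


def _frame_from_quadruple(p1, p2, p3, p4, concave) -> HingeFrame:
    axis = p3 - p2
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError("hinge axis has zero length")
    u = axis / norm
    w = np.cross(u, p4 - p3)
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise DegenerateGeometryError("terminal point lies on the hinge axis")
    # moving p4 along +w (right-hand about the p2->p3 axis) *decreases* the
    # raw dihedral; positive measured angle must mean motion toward the
    # concave face, so the sense flips when +w points concave-ward
    sense = -1.0 if float(np.dot(w, concave)) >= 0 else 1.0
    return HingeFrame(axis=u, point=p2.copy(), sense=sense,
                      quadruple=np.array([p1, p2, p3, p4]))


def bending_frame(pair: HexamerPair, lmap: LandmarkMap) -> HingeFrame:
    s27, i38 = lmap.bend_pair
    ca, cb = _bending_chain_pair(pair, lmap)
    p1 = ca_position(pair.hexamer_a.atoms, ca, i38)
    p2 = ca_position(pair.hexamer_a.atoms, ca, s27)
    p3 = ca_position(pair.hexamer_b.atoms, cb, s27)
    p4 = ca_position(pair.hexamer_b.atoms, cb, i38)
    return _frame_from_quadruple(p1, p2, p3, p4,
                                 concave_direction(pair.hexamer_a, lmap))


def tilting_frame(pair: HexamerPair, lmap: LandmarkMap) -> HingeFrame:
    m24, i18 = lmap.tilt_pair

    def mids(hexamer, other):
        chains = _interfacial_chains(hexamer, other)
        pm = np.mean([ca_position(hexamer.atoms, c, m24) for c in chains], axis=0)
        pi = np.mean([ca_position(hexamer.atoms, c, i18) for c in chains], axis=0)
        return pm, pi

    ma, ia = mids(pair.hexamer_a, pair.hexamer_b)
    mb, ib = mids(pair.hexamer_b, pair.hexamer_a)
    return _frame_from_quadruple(ia, ma, mb, ib,
                                 concave_direction(pair.hexamer_a, lmap))


def _signed_deviation(frame: HingeFrame) -> float:
    p1, p2, p3, p4 = frame.quadruple
    raw = signed_dihedral(p1, p2, p3, p4)
    # a flat layer puts the two wings trans (raw = 180); the bending/tilting
    # angle is the deviation from that reference
    return frame.sense * wrap_angle(raw - 180.0)


def bending_angle(pair: HexamerPair, lmap: LandmarkMap) -> float:
    """Signed bending angle (degrees) of a hexamer pair.

    Negative = displacement toward the convex face.  Raises
    :class:`DegenerateGeometryError` for colinear landmark quadruples.
    """
    return _signed_deviation(bending_frame(pair, lmap))


def tilting_angle(pair: HexamerPair, lmap: LandmarkMap) -> float:
    """Signed tilting angle (degrees) of a hexamer pair; sign as bending."""
    return _signed_deviation(tilting_frame(pair, lmap))


# --------------------------------------------------------------------------
# Ensemble statistics
# --------------------------------------------------------------------------


def _backbone_mask(arr, chain_ids=None):
    mask = np.isin(arr.atom_name, BACKBONE_NAMES)
    if chain_ids:
        mask &= np.isin(arr.chain_id, list(chain_ids))
    return mask


def average_structure(traj: TrajectoryEnsemble, fit_selection=None) -> struc.AtomArray:
    """Coordinate-wise mean after superposing every snapshot on the first.

    ``fit_selection`` is a chain-id collection (default: the first hexamer's
    chains when the trajectory carries chain groups, otherwise all chains);
    superposition uses its backbone atoms, following the convention of
    fitting on one hexamer so the other hexamers' drift remains visible.
    """
    ref = traj.snapshot(0)
    if fit_selection is None:
        fit_selection = traj.chain_groups[0] if traj.chain_groups else None
    mask = _backbone_mask(ref, fit_selection)
    if not mask.any():
        raise ValueError("empty fit selection")
    fitted, _ = struc.superimpose(ref, traj.stack, atom_mask=mask)
    avg = ref.copy()
    avg.coord = fitted.coord.mean(axis=0)
    return avg


def rmsd_series(traj: TrajectoryEnsemble, reference: struc.AtomArray,
                fit_selection=None) -> np.ndarray:
    """Backbone RMSD of each snapshot against a reference, after superposition."""
    if reference.array_length() != traj.snapshot(0).array_length():
        raise ValueError("reference topology does not match the trajectory")
    bb = _backbone_mask(reference, fit_selection)
    if not bb.any():
        raise ValueError("empty fit selection")
    fitted, _ = struc.superimpose(reference, traj.stack, atom_mask=bb)
    return np.asarray(
        struc.rmsd(reference[bb], fitted[..., bb]), dtype=float
    )


def com_deviation(avg: struc.AtomArray, crystal: TriHexamerModel,
                  chain_groups=None, core_range=(1, 90)):
    """Per-pair change of hexamer COM separation, MD average vs crystal.

    Negative values mean the layer contracted.  Returns ``(per_pair, mean)``
    where ``per_pair`` maps frozensets of hexamer indices to Δ separation Å.
    """
    if chain_groups is None:
        chain_groups = tuple(h.chain_ids for h in crystal.hexamers)
    if len(chain_groups) != 3:
        raise ValueError("expected three hexamer chain groups")
    avg_coms = [
        backbone_com(avg[np.isin(avg.chain_id, list(g))], core_range)
        for g in chain_groups
    ]
    cry_coms = [h.com for h in crystal.hexamers]
    per_pair = {}
    for i in range(3):
        for j in range(i + 1, 3):
            d_avg = np.linalg.norm(avg_coms[i] - avg_coms[j])
            d_cry = np.linalg.norm(cry_coms[i] - cry_coms[j])
            per_pair[frozenset((i, j))] = float(d_avg - d_cry)
    return per_pair, float(np.mean(list(per_pair.values())))


@dataclass
class AngleSeries:
    """Per-snapshot, per-interface signed angle table with run statistics."""

    table: pd.DataFrame
    frame_interval_ps: float = 250.0

    def interface_stats(self) -> pd.DataFrame:
        ok = self.table[self.table["valid"]]
        return ok.groupby("interface")[["bending", "tilting"]].agg(["mean", "std"])

    def pooled_stats(self) -> dict:
        ok = self.table[self.table["valid"]]
        return {
            "bending_mean": float(ok["bending"].mean()),
            "bending_sd": float(ok["bending"].std(ddof=1)),
            "tilting_mean": float(ok["tilting"].mean()),
            "tilting_sd": float(ok["tilting"].std(ddof=1)),
        }

    def summary(self) -> str:
        stats = self.pooled_stats()
        lines = [
            "Angle series over "
            f"{self.table['snapshot'].nunique()} snapshots × "
            f"{self.table['interface'].nunique()} interfaces "
            f"({self.frame_interval_ps:g} ps spacing)",
            f"  pooled bending  {stats['bending_mean']:8.2f} ± {stats['bending_sd']:.2f} deg",
            f"  pooled tilting  {stats['tilting_mean']:8.2f} ± {stats['tilting_sd']:.2f} deg",
            f"  flagged outliers: {int(self.table['outlier'].sum())}",
        ]
        return "\n".join(lines)


def angle_series(traj: TrajectoryEnsemble, lmap: LandmarkMap,
                 chain_groups=None) -> AngleSeries:
    """Bending/tilting for all three interfaces of every snapshot.

    Snapshot 0 is flagged as the crystal/start reading.  Rows whose landmark
    quadruple is degenerate are marked invalid rather than aborting the run;
    values more than 3 SD from their interface's run mean are flagged as
    outliers (flagged only — never corrected).
    """
    groups = chain_groups or traj.chain_groups
    if not groups or len(groups) != 3:
        raise ValueError("angle_series needs three hexamer chain groups")
    rows = []
    for i in range(traj.n_snapshots):
        snap = traj.snapshot(i)
        hexes = [hexamer_from_chains(snap, g, lmap.core_range) for g in groups]
        for (a, b), name in (((0, 1), "0-1"), ((0, 2), "0-2"), ((1, 2), "1-2")):
            pair = HexamerPair(hexes[a], hexes[b])
            try:
                bend = bending_angle(pair, lmap)
                tilt = tilting_angle(pair, lmap)
                valid = True
            except (DegenerateGeometryError, KeyError):
                bend = tilt = np.nan
                valid = False
            rows.append(
                {
                    "snapshot": i,
                    "time_ps": i * traj.frame_interval_ps,
                    "interface": name,
                    "bending": bend,
                    "tilting": tilt,
                    "valid": valid,
                    "crystal_start": i == 0,
                }
            )
    df = pd.DataFrame(rows)
    df["outlier"] = False
    for name, sub in df[df["valid"]].groupby("interface"):
        for col in ("bending", "tilting"):
            mu, sd = sub[col].mean(), sub[col].std(ddof=1)
            if sd and np.isfinite(sd) and sd > 0:
                flag = (sub[col] - mu).abs() > 3 * sd
                df.loc[sub.index[flag], "outlier"] = True
    return AngleSeries(table=df, frame_interval_ps=traj.frame_interval_ps)


# --------------------------------------------------------------------------
# Plane representations
# --------------------------------------------------------------------------


def plane_representation(model, lmap: LandmarkMap, chain_groups=None,
                         contact_cutoff=5.0) -> pd.DataFrame:
    """Hexamer planes through the interface-probe Cα triples, plus the COM plane.

    Each hexamer is represented by the exact plane through the plane-probe Cα
    of the three monomers closest to the neighboring hexamers; a final row
    holds the plane through the three hexamer COMs.  Columns: label, point
    (px,py,pz), unit normal (nx,ny,nz).
    """
    if isinstance(model, TriHexamerModel):
        hexamers = model.hexamers
    else:
        if not chain_groups:
            raise ValueError("chain_groups required for a bare atom model")
        hexamers = [hexamer_from_chains(model, g, lmap.core_range) for g in chain_groups]
    rows = []
    coms = [h.com for h in hexamers]
    for i, h in enumerate(hexamers):
        # rank chains by proximity to the other hexamers; take the 3 closest
        scored = []
        for c in h.chain_ids:
            ccom = h.chain_com(c)
            d = min(
                np.linalg.norm(ccom - coms[j]) for j in range(len(hexamers)) if j != i
            )
            scored.append((float(d), c))
        scored.sort()
        probes = np.array([
            ca_position(h.atoms, c, lmap.plane_probe) for _, c in scored[:3]
        ])
        v1, v2 = probes[1] - probes[0], probes[2] - probes[0]
        n = np.cross(v1, v2)
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            raise DegenerateGeometryError(f"plane probes of hexamer {i} are colinear")
        n /= nn
        point = probes.mean(axis=0)
        rows.append({"label": f"hexamer-{i}", "px": point[0], "py": point[1],
                     "pz": point[2], "nx": n[0], "ny": n[1], "nz": n[2]})
    point, n = fit_plane(np.array(coms))
    rows.append({"label": "com-plane", "px": point[0], "py": point[1],
                 "pz": point[2], "nx": n[0], "ny": n[1], "nz": n[2]})
    return pd.DataFrame(rows)
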