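"""Synthetic fixtures: toy C6 hexamers, tiled layers, bent trajectories, umbrella samples.

Every generator emits machine-readable ground truth next to its coordinates,
so downstream recovery tests never need external structures.  The toy hexamer
is a *pseudo-protein*: six C6-related chains of backbone+Cβ residues on a
disk, with the landmark residues of the PduA numbering placed at documented
positions engineered so that

* the inter-lysine distance across a head-on interface is exactly
  ``spacing - 2 * LYS_RADIUS``;
* a flat layer reads bending = tilting = 0;
* a rotation imposed about the bending (tilting) hinge axis is recovered
  exactly by the corresponding dihedral operator;
* bending reads exactly 0 under a pure imposed tilt (the S27–I38 wing is
  parallel to the tilt hinge), while tilting under a pure bend has a small,
  bounded cross-talk (< 10 % of the imposed angle) — the two dihedrals are
  not orthogonal observables, here or on real coordinates.

The convex face of the toy hexamer is the −z side; residues 91–93 mark the
concave (+z) face and anchor the sign convention (negative bending = toward
the convex side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .geometry import apply_transform, rotation_about_axis
from .lattice import HexamerModel, HexamerPair, TriHexamerModel, find_pairs
from .structures import CrystalStructure, LandmarkMap

# --------------------------------------------------------------------------
# Documented construction constants (chain-0 frame; the chain wedge spans
# polar angles [0°, 60°], its "clockwise" boundary ray is the +x axis).
# --------------------------------------------------------------------------

#: Nominal rim radius of the toy hexamer (Å); `make_toy_hexamer(radius=...)`
#: rescales the whole construction by radius / HEX_RADIUS.
HEX_RADIUS = 33.0

#: K26 Cα radius on the boundary ray; head-on d_lys = spacing − 2·LYS_RADIUS.
LYS_RADIUS = 30.25

# S27 y is large enough that its C2 self-image (meeting at lateral offset
# 2·y) stays clear of the supported Arr-B offset range (≤ 15.5 Å)
_S27 = np.array([33.3, 9.0, 0.0])
_I38 = np.array([23.0, 9.0, 0.0])  # same y as S27: bend wing ∥ tilt hinge
_K26 = np.array([LYS_RADIUS, 0.0, 0.0])
# Midpoints of the two interfacial copies across a head-on interface; equal
# x keeps the tilt hinge exactly along the COM axis, the I18 y-offset keeps
# the flat tilt quadruple non-degenerate, and x = 24 keeps both probes well
# inside the rim (no interface contacts of their own).
_M24_MID = np.array([24.0, 0.0])
_I18_MID = np.array([24.0, 8.0])


def _mid_inverse(target_xy):
    """Chain-0 position whose ch0/ch5 C6 pair has the given midpoint."""
    ang = np.radians(-60.0)
    rz = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    q = 0.5 * (np.eye(2) + rz)
    xy = np.linalg.solve(q, np.asarray(target_xy, dtype=float))
    return np.array([xy[0], xy[1], 0.0])


_M24 = _mid_inverse(_M24_MID)
_I18 = _mid_inverse(_I18_MID)

# Backbone offsets relative to Cα (rotated with the chain).  For residues
# beyond TANGENTIAL_RADIUS the offset frame is turned 90° in-plane so the
# backbone extends tangentially, not radially — otherwise facing rims would
# interpenetrate across a 68–71 Å interface.
_BB = {"N": (-1.20, 0.45, 0.25), "C": (1.20, 0.45, -0.25), "O": (1.85, 1.45, -0.35)}
_CB = (0.05, -0.75, 1.30)
TANGENTIAL_RADIUS = 29.0

# Landmark residues: id -> (residue name, Cα position, extra side-chain atoms)
_LANDMARKS = {
    18: ("ILE", _I18, {"CG1": (0.6, -0.9, 1.9), "CD1": (1.1, -1.0, 2.9)}),
    24: ("MET", _M24, {"CG": (0.5, -0.9, 2.0), "SD": (0.9, -1.0, 3.2)}),
    26: ("LYS", _K26, {"CG": (0.90, 0.30, 0.35), "CD": (1.40, -0.20, 1.05),
                       "CE": (1.85, 0.45, 0.35), "NZ": (2.15, 0.50, 0.95)}),
    27: ("SER", _S27, {"CB": (-0.7, 0.3, 1.3), "OG": (-0.5, 0.5, 1.6)}),
    28: ("ARG", np.array([28.0, 5.6, 0.8]),
         {"NE": (3.2, 1.2, 0.25), "CZ": (4.0, 1.6, 0.3),
          "NH1": (5.0, 1.9, 0.4), "NH2": (4.7, 2.5, -0.3)}),
    38: ("ILE", _I38, {"CG1": (0.6, -0.9, 1.9), "CD1": (1.1, -1.0, 2.9)}),
    49: ("ASP", np.array([28.0, 3.0, -0.8]),
         {"CG": (3.4, 1.0, -0.25), "OD1": (5.0, 1.5, -0.4), "OD2": (4.7, 2.1, -0.1)}),
    53: ("ALA", 28.0 * np.array([np.cos(np.radians(28)), np.sin(np.radians(28)), 0.0]), {}),
    54: ("VAL", 28.0 * np.array([np.cos(np.radians(32)), np.sin(np.radians(32)), 0.0]),
         {"CG1": (0.5, -1.0, 2.1), "CG2": (-0.6, -1.1, 2.0)}),
    79: ("ARG", np.array([30.9, -2.6, 0.4]),
         {"NE": (1.0, 0.7, -0.2), "CZ": (1.3, 0.8, -0.15),
          "NH1": (1.6, 0.6, -0.1), "NH2": (1.55, 1.4, -0.7)}),
    83: ("GLU", np.array([31.0, 2.6, 0.0]),
         {"CG": (0.9, -0.3, 0.2), "CD": (1.2, -0.45, 0.25),
          "OE1": (1.5, -0.6, 0.3), "OE2": (1.45, 0.15, -0.3)}),
}

# R28's NH1 lands at (33.0, 7.5, 1.2) and D49's OD1 at (33.0, 4.5, -1.2):
# their C2-image partners meet (y offsets summing to 12 Å) only across
# Arr-B-like sheared interfaces, while R79's guanidinium meets E83's
# carboxylate (y offsets summing to 0) only across head-on Arr-A interfaces.

# Rim contact bands: the low band (residues 60–67, near the 0° boundary) and
# the high band (68–75, near the 60° boundary) are staggered radially and in z
# so facing rims contact (< 5 Å) without vdW overlap at 68–71 Å spacings.
_RIM_RADII_LOW = (31.9, 32.4)
_RIM_RADII_HIGH = (30.2, 30.8)

#: Side-chain positions of these residues are engineered in absolute chain
#: coordinates (interface contacts by construction); never reoriented.
_KEEP_RADIAL = frozenset({26, 27, 28, 49, 79, 83})
_CONCAVE_MARKERS = (91, 92, 93)
_GLY_RES = 94
N_RESIDUES = 95

_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def toy_landmark_map() -> LandmarkMap:
    """Landmark map matching the toy hexamer (PduA-style numbering)."""
    return LandmarkMap(concave_face_residues=_CONCAVE_MARKERS)


def _template_chain(rng) -> list:
    """(res_id, res_name, atom_name, element, position) records for chain 0."""
    records = []

    def add_residue(res_id, name, ca, extras):
        ca = np.asarray(ca, dtype=float)
        tangential = np.linalg.norm(ca[:2]) > TANGENTIAL_RADIUS or res_id in (28, 49)

        def orient(off):
            off = np.asarray(off, dtype=float)
            if tangential:
                return np.array([-off[1], off[0], off[2]])
            return off

        records.append((res_id, name, "N", "N", ca + orient(_BB["N"])))
        records.append((res_id, name, "CA", "C", ca))
        records.append((res_id, name, "C", "C", ca + orient(_BB["C"])))
        records.append((res_id, name, "O", "O", ca + orient(_BB["O"])))
        if name != "GLY" and "CB" not in extras:
            records.append((res_id, name, "CB", "C", ca + orient(_CB)))
        for aname, off in extras.items():
            off = np.asarray(off, dtype=float)
            if res_id not in _KEEP_RADIAL:
                off = orient(off)
            records.append((res_id, name, aname, _ELEMENT.get(aname[0], "C"), ca + off))

    scaffold_ids = [i for i in range(1, 60) if i not in _LANDMARKS]
    for j, res_id in enumerate(scaffold_ids):
        t = j / (len(scaffold_ids) - 1)
        ang = np.radians(8.0 + 44.0 * t)
        rad = 12.0 + 13.0 * t
        z = 2.5 * np.sin(6.0 * np.pi * t) + rng.uniform(-0.1, 0.1)
        add_residue(res_id, "ALA", (rad * np.cos(ang), rad * np.sin(ang), z), {})
    for res_id, (name, ca, extras) in sorted(_LANDMARKS.items()):
        add_residue(res_id, name, ca, extras)
    # rim contact bands flanking both wedge boundaries
    for j in range(8):  # residues 60..67 near the 0° boundary
        ang = np.radians(3.0 + 0.72 * j)
        rad = _RIM_RADII_LOW[j % 2]
        z = 1.0 if j % 2 else -1.0
        add_residue(60 + j, "ALA", (rad * np.cos(ang), rad * np.sin(ang), z), {})
    for j in range(8):  # residues 68..75 near the 60° boundary
        ang = np.radians(60.0 - (3.0 + 0.72 * j))
        rad = _RIM_RADII_HIGH[j % 2]
        z = 2.2 if j % 2 else -2.2
        add_residue(68 + j, "ALA", (rad * np.cos(ang), rad * np.sin(ang), z), {})
    for j, res_id in enumerate(range(76, 91)):
        ang = np.radians(8.0 + 3.0 * j)
        z = -2.5 + 0.3 * j + rng.uniform(-0.1, 0.1)
        add_residue(res_id, "ALA", (26.0 * np.cos(ang), 26.0 * np.sin(ang), z), {})
    for j, res_id in enumerate(_CONCAVE_MARKERS):  # concave (+z) face markers
        ang = np.radians(15.0 + 15.0 * j)
        add_residue(res_id, "ALA", (15.0 * np.cos(ang), 15.0 * np.sin(ang), 4.0), {})
    add_residue(_GLY_RES, "GLY", (10.0 * np.cos(np.radians(20)), 10.0 * np.sin(np.radians(20)), -1.0), {})
    add_residue(95, "ALA", (10.0 * np.cos(np.radians(40)), 10.0 * np.sin(np.radians(40)), -1.0), {})
    return records


def make_toy_hexamer(radius: float = HEX_RADIUS, seed: int = 0,
                     chain_ids="ABCDEF") -> HexamerModel:
    """Deterministic C6-symmetric pseudo-protein hexamer.

    The same seed yields a bit-identical model; ``radius`` rescales the whole
    construction uniformly (default = the documented geometry).  The backbone
    COM over core residues 1–90 sits exactly at the origin and the convex
    face is −z.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    scale = radius / HEX_RADIUS
    rng = np.random.default_rng(seed)
    records = _template_chain(rng)
    n_per_chain = len(records)
    n_atoms = 6 * n_per_chain
    arr = struc.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    chain_id = np.empty(n_atoms, dtype="U4")
    res_id = np.empty(n_atoms, dtype=int)
    res_name = np.empty(n_atoms, dtype="U5")
    atom_name = np.empty(n_atoms, dtype="U6")
    element = np.empty(n_atoms, dtype="U2")
    template = np.array([r[4] for r in records]) * scale
    for k in range(6):
        ang = np.radians(60.0 * k)
        rz = np.array([
            [np.cos(ang), -np.sin(ang), 0.0],
            [np.sin(ang), np.cos(ang), 0.0],
            [0.0, 0.0, 1.0],
        ])
        sl = slice(k * n_per_chain, (k + 1) * n_per_chain)
        coords[sl] = template @ rz.T
        chain_id[sl] = chain_ids[k]
        res_id[sl] = [r[0] for r in records]
        res_name[sl] = [r[1] for r in records]
        atom_name[sl] = [r[2] for r in records]
        element[sl] = [r[3] for r in records]
    arr.coord = coords
    arr.chain_id = chain_id
    arr.res_id = res_id
    arr.res_name = res_name
    arr.atom_name = atom_name
    arr.element = element
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n_atoms))
    # center the core-backbone COM at the origin exactly
    core = (np.isin(arr.atom_name, ("N", "CA", "C", "O"))
            & (arr.res_id >= 1) & (arr.res_id <= 90))
    arr.coord = arr.coord - arr.coord[core].mean(axis=0)
    return HexamerModel(
        atoms=arr,
        chain_ids=tuple(chain_ids),
        normal=np.array([0.0, 0.0, -1.0]),  # convex face
        provenance={"generator": "make_toy_hexamer", "seed": seed, "radius": radius},
    )


@dataclass
class ToyLatticeSpec:
    """Construction parameters for synthetic layers and trajectories."""

    spacing: float = 68.5          # COM–COM distance, Å
    lateral_offset: float = 0.0    # in-plane offset from head-on, Å
    bend: float = 0.0              # target bending amplitude, degrees (signed)
    tilt: float = 0.0              # target tilting amplitude, degrees (signed)
    noise_sigma: float = 0.0       # isotropic Gaussian coordinate noise, Å
    n_snapshots: int = 1
    schedule: str = "constant"     # constant | linear | plateau:<fraction>
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if abs(self.lateral_offset) >= self.spacing / 2:
            raise ValueError("offset >= spacing/2 is non-physical (overlapping hexamers)")

    def schedule_fraction(self, i: int) -> float:
        n = self.n_snapshots
        if self.schedule == "constant" or n == 1:
            return 1.0
        if self.schedule == "linear":
            return i / (n - 1)
        if self.schedule.startswith("plateau"):
            frac = float(self.schedule.split(":")[1]) if ":" in self.schedule else 0.1
            t0 = max(1, int(round(frac * (n - 1))))
            return min(i / t0, 1.0)
        raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class LatticeTruth:
    """Generator-side ground truth accompanying a synthetic layer."""

    hexamers: list
    centers: np.ndarray
    spacing: float
    lateral_offset: float
    d_lys: float
    min_contact: float
    landmark_map: LandmarkMap
    crystal: CrystalStructure = None
    assembly: struc.AtomArray = None


_CHAIN_SETS = ["ABCDEF", "GHIJKL", "MNOPQR", "STUVWX", "YZabcd", "efghij", "klmnop"]


def _lattice_vectors(spacing, offset):
    a1 = np.array([np.sqrt(spacing**2 - offset**2), offset, 0.0])
    ang = np.radians(60.0)
    rz = np.array([
        [np.cos(ang), -np.sin(ang), 0.0],
        [np.sin(ang), np.cos(ang), 0.0],
        [0.0, 0.0, 1.0],
    ])
    return a1, rz @ a1


def _lattice_points(spacing, offset, n_hex):
    a1, a2 = _lattice_vectors(spacing, offset)
    pts = []
    for n1 in range(-3, 4):
        for n2 in range(-3, 4):
            pts.append(n1 * a1 + n2 * a2)
    pts.sort(key=lambda p: (round(np.linalg.norm(p), 6), np.arctan2(p[1], p[0])))
    return pts[:n_hex]


def make_lattice(spec: ToyLatticeSpec, n_hex: int = 2) -> LatticeTruth:
    """Planar hexagonal layer of toy hexamers with known metrics.

    Every hexamer is the same *translated* copy; the requested lateral
    offset is realized by shearing the lattice vector away from the head-on
    direction, so all interfaces are equivalent (related by the C6 symmetry)
    and each shows the same offset.  The returned truth carries the true
    inter-lysine distance, the minimal heavy-atom contact distance of the
    first interface, and a P1 crystal (γ = 60°) that regenerates the layer
    through symmetry expansion (in the cell's own frame, which is rotated
    in-plane by asin(offset/spacing) relative to the assembly).
    """
    if n_hex < 2:
        raise ValueError("a lattice needs at least 2 hexamers")
    if len(_CHAIN_SETS) < n_hex:
        raise ValueError(f"at most {len(_CHAIN_SETS)} hexamers supported")
    base = make_toy_hexamer(seed=spec.seed)
    points = _lattice_points(spec.spacing, spec.lateral_offset, n_hex)
    hexamers = []
    for idx, (pt, cids) in enumerate(zip(points, _CHAIN_SETS)):
        h = base.transformed(np.eye(3), pt)
        atoms = h.atoms.copy()
        mapping = dict(zip("ABCDEF", cids))
        atoms.chain_id = np.array([mapping[c] for c in atoms.chain_id])
        hexamers.append(
            HexamerModel(
                atoms=atoms,
                chain_ids=tuple(cids),
                normal=h.normal,
                provenance={"generator": "make_lattice", "index": idx},
            )
        )
    assembly = struc.concatenate([h.atoms for h in hexamers])
    # ground-truth metrics on the first interface (hexamers 0 and 1)
    a, b = hexamers[0], hexamers[1]
    k_a = a.atoms.coord[(a.atoms.res_id == 26) & (a.atoms.atom_name == "CA")]
    k_b = b.atoms.coord[(b.atoms.res_id == 26) & (b.atoms.atom_name == "CA")]
    d_lys = float(np.min(np.linalg.norm(k_a[:, None] - k_b[None, :], axis=2)))
    ha = a.atoms.coord[a.atoms.element != "H"]
    hb = b.atoms.coord[b.atoms.element != "H"]
    from scipy.spatial import cKDTree

    min_contact = float(cKDTree(hb).query(ha, k=1)[0].min())
    cell = (spec.spacing, spec.spacing, 120.0, 90.0, 90.0, 60.0)
    # express the reference hexamer in the cell frame (a-vector along +x)
    delta = np.degrees(np.arcsin(spec.lateral_offset / spec.spacing))
    rz_cell, _ = rotation_about_axis([0, 0, 1], -delta)
    cell_model = hexamers[0].atoms.copy()
    cell_model.coord = cell_model.coord @ rz_cell.T
    crystal = CrystalStructure(
        models=[cell_model],
        cell=cell,
        operators=[(np.eye(3), np.zeros(3))],
        space_group="P 1",
        source="synthetic lattice",
    )
    return LatticeTruth(
        hexamers=hexamers,
        centers=np.array(points),
        spacing=spec.spacing,
        lateral_offset=spec.lateral_offset,
        d_lys=d_lys,
        min_contact=min_contact,
        landmark_map=toy_landmark_map(),
        crystal=crystal,
        assembly=assembly,
    )


def make_pair(spec: ToyLatticeSpec) -> HexamerPair:
    """Convenience: a single contacting hexamer pair from a lattice spec."""
    truth = make_lattice(spec, n_hex=2)
    pairs = find_pairs(truth.hexamers, contact_cutoff=truth.min_contact + 1.0)
    if not pairs:
        raise RuntimeError("generator produced no contacting pair")
    return pairs[0]


# --------------------------------------------------------------------------
# Trajectories with imposed hinge rotations
# --------------------------------------------------------------------------


@dataclass
class TrajectoryTruth:
    """Imposed-angle table and construction record for a synthetic trajectory."""

    table: "object"                # pandas DataFrame
    spec: ToyLatticeSpec
    crystal: TriHexamerModel
    landmark_map: LandmarkMap
    chain_groups: tuple


def _hinge_frames(trihex, lmap):
    """Bending and tilting hinge frames for the (0,1) and (0,2) interfaces."""
    from .trajgeo import bending_frame, tilting_frame

    frames = []
    for j in (1, 2):
        pair = HexamerPair(trihex.hexamers[0], trihex.hexamers[j])
        frames.append(
            {
                "moving": j,
                "bend": bending_frame(pair, lmap),
                "tilt": tilting_frame(pair, lmap),
            }
        )
    return frames


def make_trajectory(spec: ToyLatticeSpec):
    """Tri-hexamer snapshot ensemble with scheduled hinge rotations + noise.

    Hexamer 0 stays fixed; hexamers 1 and 2 rotate about the bending (then
    tilting) hinge axes of their interface with hexamer 0, by the scheduled
    fraction of ``spec.bend`` / ``spec.tilt``.  Negative angles move toward
    the convex (−z) face, matching the measurement convention.  Returns
    ``(TrajectoryEnsemble, TrajectoryTruth)``; the truth table marks the two
    imposed interfaces (``imposed=True``) — the third interface's values are
    geometrically induced.
    """
    import pandas as pd

    from .trajgeo import TrajectoryEnsemble, bending_angle, tilting_angle

    if spec.n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    lmap = toy_landmark_map()
    lat = make_lattice(spec_flat(spec), n_hex=3)
    trihex = TriHexamerModel(
        hexamers=lat.hexamers,
        pairs=[
            HexamerPair(lat.hexamers[0], lat.hexamers[1]),
            HexamerPair(lat.hexamers[0], lat.hexamers[2]),
            HexamerPair(lat.hexamers[1], lat.hexamers[2]),
        ],
    )
    frames = _hinge_frames(trihex, lmap)
    rng = np.random.default_rng(spec.seed)
    snapshots = []
    rows = []
    chain_groups = tuple(h.chain_ids for h in trihex.hexamers)
    for i in range(spec.n_snapshots):
        f = spec.schedule_fraction(i)
        theta_b = spec.bend * f
        theta_t = spec.tilt * f
        hexes = [trihex.hexamers[0].atoms.copy()]
        clean_hexes = [trihex.hexamers[0]]
        for fr in frames:
            h = trihex.hexamers[fr["moving"]]
            if theta_b != 0.0:
                rot, trans = fr["bend"].rotation_for(theta_b)
                h = h.transformed(rot, trans)
            if theta_t != 0.0:
                rot, trans = fr["tilt"].rotation_for(theta_t)
                h = h.transformed(rot, trans)
            clean_hexes.append(h)
            hexes.append(h.atoms)
        snap = struc.concatenate(hexes)
        if spec.noise_sigma > 0:
            snap.coord = snap.coord + rng.normal(0.0, spec.noise_sigma, snap.coord.shape)
        snapshots.append(snap)
        # ground truth: imposed values for (0,1) and (0,2); induced for (1,2)
        for j, name in ((1, "0-1"), (2, "0-2")):
            rows.append({"snapshot": i, "interface": name, "bending_true": theta_b,
                         "tilting_true": theta_t, "imposed": True})
        pair12 = HexamerPair(clean_hexes[1], clean_hexes[2])
        try:
            b12 = bending_angle(pair12, lmap)
            t12 = tilting_angle(pair12, lmap)
        except ValueError:
            b12 = t12 = np.nan
        rows.append({"snapshot": i, "interface": "1-2", "bending_true": b12,
                     "tilting_true": t12, "imposed": False})
    traj = TrajectoryEnsemble(
        stack=struc.stack(snapshots),
        frame_interval_ps=250.0,
        chain_groups=chain_groups,
        provenance=f"synthetic trajectory seed={spec.seed}",
    )
    truth = TrajectoryTruth(
        table=pd.DataFrame(rows),
        spec=spec,
        crystal=trihex,
        landmark_map=lmap,
        chain_groups=chain_groups,
    )
    return traj, truth


def spec_flat(spec: ToyLatticeSpec) -> ToyLatticeSpec:
    """Copy of a spec with angles/noise removed (the crystal-like layer)."""
    return ToyLatticeSpec(
        spacing=spec.spacing,
        lateral_offset=spec.lateral_offset,
        seed=spec.seed,
    )


def jitter_sidechains(traj, residue, chains, sigma, seed=0):
    """Copy of a trajectory with extra side-chain noise on selected copies.

    Adds isotropic Gaussian noise (σ in Å) to the side-chain atoms (beyond
    Cβ excluded set: N/CA/C/O/CB untouched) of ``residue`` in the given
    chains, in every snapshot.  Used to plant a "clamp" signal: a residue
    left *un*-jittered at the interface while jittered elsewhere shows the
    frozen-at-interface RMSD signature.
    """
    import biotite.structure as struc

    from .trajgeo import TrajectoryEnsemble

    rng = np.random.default_rng(seed)
    stack = traj.stack.copy()
    arr0 = stack[0]
    sel = (
        (arr0.res_id == int(residue))
        & np.isin(arr0.chain_id, list(chains))
        & ~np.isin(arr0.atom_name, ("N", "CA", "C", "O"))
    )
    idx = np.flatnonzero(sel)
    coord = stack.coord.copy()
    coord[:, idx, :] += rng.normal(0.0, sigma, (stack.stack_depth(), len(idx), 3))
    stack.coord = coord
    return TrajectoryEnsemble(
        stack=stack,
        frame_interval_ps=traj.frame_interval_ps,
        chain_groups=traj.chain_groups,
        provenance=traj.provenance + f" + jitter(res={residue}, sigma={sigma})",
    )


# --------------------------------------------------------------------------
# Umbrella-window samples from known 1-D potentials
# --------------------------------------------------------------------------


def harmonic_potential(kappa: float, center: float = 0.0):
    """U(ξ) = κ/2 (ξ−c)², κ in kJ/mol/Å²."""

    def u(xi):
        return 0.5 * kappa * (np.asarray(xi) - center) ** 2

    u.description = f"harmonic(kappa={kappa}, center={center})"
    return u


def double_well_potential(barrier: float, half_separation: float, center: float = 0.0):
    """Symmetric quartic double well: minima at c ± a, barrier height at c."""
    a = half_separation

    def u(xi):
        x = np.asarray(xi) - center
        return barrier * ((x**2 - a**2) ** 2) / a**4

    u.description = f"double_well(barrier={barrier}, a={a}, center={center})"
    return u


def morse_potential(depth: float, width: float, x0: float):
    """Morse-like well of given depth (kJ/mol): D (1 − e^{−(ξ−x0)/w})²."""

    def u(xi):
        e = 1.0 - np.exp(-(np.asarray(xi) - x0) / width)
        return depth * e**2

    u.description = f"morse(depth={depth}, width={width}, x0={x0})"
    return u


KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K


def make_umbrella_samples(potential, centers, k_spring=1000.0, n_per_window=500,
                          temperature=298.0, seed=0, step=None, burn_in=200,
                          thin=10):
    """Metropolis samples from exp(−(U + bias)/k_BT) for each umbrella window.

    ``k_spring`` is in kJ/mol/nm² (the conventional umbrella-sampling unit)
    and is converted internally to kJ/mol/Å².  Returns a list of
    :class:`~bmcshell.pmf.UmbrellaWindow`, one per center, deterministically
    seeded per window.  The default step (~2 bias widths) and thinning leave
    recorded samples essentially uncorrelated, emulating the decorrelated
    sampling interval of production umbrella runs — and keeping the i.i.d.
    bootstrap calibrated.
    """
    from .pmf import UmbrellaWindow

    k_a = k_spring / 100.0  # kJ/mol/nm² -> kJ/mol/Å²
    kbt = KB_KJ_PER_MOL_K * temperature
    if step is None:
        step = 2.0 * np.sqrt(kbt / k_a)
    windows = []
    rng = np.random.default_rng(seed)
    for center in centers:
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))

        def energy(x, c=center):
            return float(potential(x)) + 0.5 * k_a * (x - c) ** 2

        x = float(center)
        e = energy(x)
        samples = np.empty(n_per_window)
        accepted = 0
        proposed = 0
        total_steps = burn_in + n_per_window * thin
        draws = sub.normal(0.0, step, total_steps)
        unif = sub.random(total_steps)
        kept = 0
        for t in range(total_steps):
            xn = x + draws[t]
            en = energy(xn)
            proposed += 1
            if en <= e or unif[t] < np.exp(-(en - e) / kbt):
                x, e = xn, en
                accepted += 1
            if t >= burn_in and (t - burn_in) % thin == 0:
                samples[kept] = x
                kept += 1
        if accepted / proposed < 0.01:
            raise RuntimeError(
                f"window at {center}: Metropolis acceptance "
                f"{accepted / proposed:.2%} < 1%; adjust the step size"
            )
        windows.append(
            UmbrellaWindow(
                center=float(center),
                k_spring=float(k_spring),
                samples=samples[:kept].copy(),
                sample_interval="synthetic Metropolis",
            )
        )
    return windows
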