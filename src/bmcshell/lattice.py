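"""Crystal-layer reconstruction: symmetry expansion, hexamer units and pairs.

The analysis unit is the *tri-hexamer*: three mutually contacting shell
hexamers extracted from a 2D-tiled crystal layer by applying the deposited
translation and symmetry operations.  This module expands a crystal into a
layer of placed hexamer copies, groups chains into C6 hexamer units, computes
backbone centers of mass (core residues, default 1–90), detects contacting
pairs and assembles the closed triangle of hexamers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

from .geometry import apply_transform, fit_plane, kabsch
from .structures import CrystalStructure, LandmarkMap, WATER_NAMES

#: Heavy-atom contact cutoff (Å) defining "interacting hexamers"; the source
#: analysis implies but never states one, so it is a parameter everywhere.
DEFAULT_CONTACT_CUTOFF = 5.0

#: Hexamer COMs within this distance (Å) of the best-fit reference plane count
#: as members of one layer (separates stacked sheets in piled crystals).
LAYER_HALF_THICKNESS = 6.0

BACKBONE_NAMES = ("N", "CA", "C", "O")

# Chain-id pool used when relabeling symmetry copies
_CHAIN_POOL = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


class PackingError(ValueError):
    """The crystal does not tile as a closed 2D hexamer layer."""


def protein_only(model: struc.AtomArray) -> struc.AtomArray:
    """Drop waters and other crystallographic ligands (hetero records)."""
    keep = ~model.hetero & ~np.isin(model.res_name, list(WATER_NAMES))
    return model[keep]


def backbone_com(model: struc.AtomArray, core_range=(1, 90)) -> np.ndarray:
    """Unweighted mean of N/Cα/C/O positions of core residues."""
    lo, hi = core_range
    sel = (
        np.isin(model.atom_name, BACKBONE_NAMES)
        & (model.res_id >= lo)
        & (model.res_id <= hi)
    )
    if not sel.any():
        raise ValueError(f"no backbone atoms in residue range {core_range}")
    return model.coord[sel].mean(axis=0)


@dataclass
class HexamerModel:
    """Six C6-related chains plus derived frame information."""

    atoms: struc.AtomArray
    chain_ids: tuple
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    provenance: dict = field(default_factory=dict)
    core_range: tuple = (1, 90)

    def __post_init__(self):
        if len(self.chain_ids) != 6:
            raise ValueError("a hexamer has exactly 6 chains")
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-6:
            self.normal = np.asarray(self.normal, dtype=float) / n

    @property
    def com(self) -> np.ndarray:
        return hexamer_com(self)

    def chain(self, chain_id) -> struc.AtomArray:
        return self.atoms[self.atoms.chain_id == str(chain_id)]

    def chain_com(self, chain_id) -> np.ndarray:
        return backbone_com(self.chain(chain_id), self.core_range)

    def transformed(self, rot, trans) -> "HexamerModel":
        atoms = self.atoms.copy()
        atoms.coord = apply_transform(atoms.coord, rot, trans)
        normal = np.asarray(rot) @ self.normal
        return HexamerModel(
            atoms=atoms,
            chain_ids=self.chain_ids,
            normal=normal,
            provenance=dict(self.provenance),
            core_range=self.core_range,
        )


@dataclass
class HexamerPair:
    """Two contacting hexamers and their interfacial monomers."""

    hexamer_a: HexamerModel
    hexamer_b: HexamerModel
    interfacial_a: tuple = ()
    interfacial_b: tuple = ()
    min_distance: float = np.nan

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.hexamer_a.com - self.hexamer_b.com))


@dataclass
class TriHexamerModel:
    """A closed triangle of three contacting hexamers (18 chains)."""

    hexamers: list
    pairs: list
    plane_point: np.ndarray = None
    plane_normal: np.ndarray = None

    def __post_init__(self):
        if len(self.hexamers) != 3 or len(self.pairs) != 3:
            raise ValueError("tri-hexamer needs 3 hexamers and 3 pairs")
        if self.plane_point is None:
            coms = np.array([h.com for h in self.hexamers])
            self.plane_point, self.plane_normal = fit_plane(coms)

    @property
    def atoms(self) -> struc.AtomArray:
        return struc.concatenate([h.atoms for h in self.hexamers])

    @property
    def chain_ids(self):
        return tuple(c for h in self.hexamers for c in h.chain_ids)


def hexamer_com(hexamer, core_range=None, backbone_only=True) -> np.ndarray:
    """Center of mass of a hexamer from backbone atoms of core residues.

    ``backbone_only=False`` averages all heavy atoms instead (not used by the
    standard analysis, provided for diagnostics).
    """
    if isinstance(hexamer, HexamerModel):
        atoms = hexamer.atoms
        core_range = core_range or hexamer.core_range
    else:
        atoms = hexamer
        core_range = core_range or (1, 90)
    if backbone_only:
        return backbone_com(atoms, core_range)
    lo, hi = core_range
    sel = (atoms.res_id >= lo) & (atoms.res_id <= hi) & (atoms.element != "H")
    if not sel.any():
        raise ValueError(f"no atoms in residue range {core_range}")
    return atoms.coord[sel].mean(axis=0)


def _cartesian_operators(crystal: CrystalStructure):
    m = crystal.frac_to_cart()
    minv = np.linalg.inv(m)
    return [(m @ r @ minv, m @ t) for r, t in crystal.operators], m


def expand_layer(crystal: CrystalStructure, radius: float, model=0):
    """All symmetry/translation images whose COM lies within ``radius``.

    Returns a list of ``(AtomArray, op_index, (n1, n2, n3))`` placements, the
    reference (identity, zero translation) first.  Waters and hetero ligands
    are removed before expansion.  Raises :class:`PackingError` when the
    structure carries no operators (pre-expanded assemblies should be passed
    to :func:`detect_hexamers` directly).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if crystal.missing_cell or crystal.cell is None:
        raise PackingError(
            "structure has no cell/symmetry operators; supply a pre-expanded assembly"
        )
    base = protein_only(crystal.models[model])
    if base.array_length() == 0:
        raise ValueError("model contains no protein atoms")
    cart_ops, m = _cartesian_operators(crystal)
    ref_com = base.coord.mean(axis=0)
    # enough integer translations to cover the radius in every direction
    min_len = min(np.linalg.norm(m[:, i]) for i in range(3))
    nmax = int(np.ceil(radius / min_len)) + 1
    shifts = [
        n1 * m[:, 0] + n2 * m[:, 1] + n3 * m[:, 2]
        for n1 in range(-nmax, nmax + 1)
        for n2 in range(-nmax, nmax + 1)
        for n3 in range(-nmax, nmax + 1)
    ]
    cells = [
        (n1, n2, n3)
        for n1 in range(-nmax, nmax + 1)
        for n2 in range(-nmax, nmax + 1)
        for n3 in range(-nmax, nmax + 1)
    ]
    placements = []
    seen = []
    for iop, (rot, trans) in enumerate(cart_ops):
        moved_base = apply_transform(base.coord, rot, trans)
        for cell_idx, shift in zip(cells, shifts):
            com = moved_base.mean(axis=0) + shift
            if np.linalg.norm(com - ref_com) > radius:
                continue
            if any(np.linalg.norm(com - s) < 0.1 for s in seen):
                continue  # duplicate placement (e.g. identity vs equivalent op)
            seen.append(com)
            arr = base.copy()
            arr.coord = moved_base + shift
            placements.append((arr, iop, cell_idx))
    # reference placement first
    placements.sort(
        key=lambda p: (p[1] != 0 or p[2] != (0, 0, 0), np.linalg.norm(p[0].coord.mean(axis=0) - ref_com))
    )
    return placements


def merge_placements(placements) -> struc.AtomArray:
    """Concatenate placements into one assembly with unique chain ids.

    Single-letter ids are used while they last (PDB-writable); larger
    assemblies continue with two-character ids, which only in-memory
    analysis accepts.
    """
    arrays = []
    used = 0
    for arr, _iop, _cell in placements:
        arr = arr.copy()
        old = list(dict.fromkeys(arr.chain_id))  # preserve order
        mapping = {}
        for c in old:
            if used < len(_CHAIN_POOL):
                mapping[c] = _CHAIN_POOL[used]
            else:
                k = used - len(_CHAIN_POOL)
                mapping[c] = _CHAIN_POOL[k // 10] + str(k % 10)
            used += 1
        arr.chain_id = np.array([mapping[c] for c in arr.chain_id])
        arrays.append(arr)
    return struc.concatenate(arrays)


def _rotation_angle_axis(rot):
    tr = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(tr))
    w, v = np.linalg.eig(rot)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return angle, axis / np.linalg.norm(axis)


def _chain_arrays(assembly):
    out = {}
    for cid in np.unique(assembly.chain_id):
        arr = assembly[assembly.chain_id == cid]
        ca = arr[arr.atom_name == "CA"]
        if ca.array_length() >= 3:
            out[str(cid)] = arr
    return out


def detect_hexamers(assembly, lmap: LandmarkMap | None = None, core_range=(1, 90),
                    rmsd_tol=1.5):
    """Group chains of an assembly into C6 hexamer units.

    Chains belong to one hexamer when pairwise superposition is a pure
    rotation by a multiple of 60° about a *common* axis (the C6 axis); the
    axis position is estimated per chain pair and clustered.  Returns
    ``(hexamers, ungrouped_chain_ids)``.
    """
    chains = _chain_arrays(protein_only(assembly) if assembly.hetero.any() else assembly)
    ids = sorted(chains)
    if len(ids) < 6:
        return [], ids
    coms = {c: chains[c].coord.mean(axis=0) for c in ids}
    # candidate C6-axis points voted per chain
    votes = {c: [] for c in ids}
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            if np.linalg.norm(coms[ci] - coms[cj]) > 55.0:
                continue
            ai, aj = chains[ci], chains[cj]
            common = np.intersect1d(
                ai.res_id[ai.atom_name == "CA"], aj.res_id[aj.atom_name == "CA"]
            )
            if len(common) < 3:
                continue
            pi = np.array([ai.coord[(ai.atom_name == "CA") & (ai.res_id == r)][0] for r in common])
            pj = np.array([aj.coord[(aj.atom_name == "CA") & (aj.res_id == r)][0] for r in common])
            try:
                rot, trans, rmsd = kabsch(pi, pj)
            except ValueError:
                continue
            if rmsd > rmsd_tol:
                continue
            angle, axis = _rotation_angle_axis(rot)
            if not any(abs(angle - k) < 8.0 for k in (60.0, 120.0, 180.0)):
                continue
            # require negligible screw translation along the axis
            if abs(np.dot(axis, trans)) > 2.0:
                continue
            # axis line point: least-squares solution of (I - R) p = t
            p0, *_ = np.linalg.lstsq(np.eye(3) - rot, trans, rcond=None)
            mid = 0.5 * (coms[ci] + coms[cj])
            center = p0 + axis * np.dot(axis, mid - p0)
            votes[ci].append(center)
            votes[cj].append(center)
    # per-chain center = modal vote cluster
    centers = {}
    for c in ids:
        if not votes[c]:
            continue
        pts = np.array(votes[c])
        best = None
        for k in range(len(pts)):
            close = pts[np.linalg.norm(pts - pts[k], axis=1) < 5.0]
            if best is None or len(close) > len(best):
                best = close
        if len(best) >= 2:
            centers[c] = best.mean(axis=0)
    # group chains sharing a center
    groups = []
    for c in sorted(centers):
        for g in groups:
            if np.linalg.norm(centers[c] - g["center"]) < 5.0:
                g["chains"].append(c)
                g["center"] = np.mean([centers[x] for x in g["chains"]], axis=0)
                break
        else:
            groups.append({"center": centers[c].copy(), "chains": [c]})
    hexamers, grouped = [], set()
    for g in groups:
        if len(g["chains"]) != 6:
            continue
        members = tuple(sorted(g["chains"]))
        atoms = struc.concatenate([chains[c] for c in members])
        hexamers.append(_finalize_hexamer(atoms, members, lmap, core_range))
        grouped.update(members)
    ungrouped = [c for c in ids if c not in grouped]
    return hexamers, ungrouped


def _finalize_hexamer(atoms, chain_ids, lmap, core_range):
    coms = np.array([
        atoms.coord[(atoms.chain_id == c)].mean(axis=0) for c in chain_ids
    ])
    _, normal = fit_plane(coms)
    normal = _orient_normal(atoms, normal, lmap, core_range)
    return HexamerModel(
        atoms=atoms, chain_ids=tuple(chain_ids), normal=normal, core_range=core_range
    )


def _orient_normal(atoms, normal, lmap, core_range):
    """Point the hexamer normal toward the convex face.

    The convention comes from the landmark config: residues declared to lie on
    the concave face push the normal the other way.  Without a declaration the
    +z-most orientation is kept (deterministic, but not anchored to a face).
    """
    if lmap is not None and lmap.concave_face_residues:
        sel = np.isin(atoms.res_id, list(lmap.concave_face_residues)) & (
            atoms.atom_name == "CA"
        )
        if sel.any():
            com = backbone_com(atoms, core_range)
            concave_dir = atoms.coord[sel].mean(axis=0) - com
            if np.dot(normal, concave_dir) > 0:
                normal = -normal
            return normal
    return normal if normal[2] >= 0 else -normal


def find_pairs(hexamers, contact_cutoff=DEFAULT_CONTACT_CUTOFF, max_separation=80.0):
    """Contacting hexamer pairs by minimal heavy-atom distance."""
    if len(hexamers) < 2:
        return []
    pairs = []
    trees = []
    heavy = []
    for h in hexamers:
        arr = h.atoms[h.atoms.element != "H"]
        heavy.append(arr)
        trees.append(cKDTree(arr.coord))
    for i in range(len(hexamers)):
        for j in range(i + 1, len(hexamers)):
            sep = np.linalg.norm(hexamers[i].com - hexamers[j].com)
            if sep > max_separation:
                continue
            d_ab, _ = trees[j].query(heavy[i].coord, k=1,
                                     distance_upper_bound=contact_cutoff)
            mask_a = np.isfinite(d_ab)
            if not mask_a.any():
                continue
            d_ba, _ = trees[i].query(heavy[j].coord, k=1,
                                     distance_upper_bound=contact_cutoff)
            mask_b = np.isfinite(d_ba)
            ia = tuple(sorted(set(heavy[i].chain_id[mask_a])))
            ib = tuple(sorted(set(heavy[j].chain_id[mask_b])))
            pairs.append(
                HexamerPair(
                    hexamer_a=hexamers[i],
                    hexamer_b=hexamers[j],
                    interfacial_a=ia,
                    interfacial_b=ib,
                    min_distance=float(d_ab[mask_a].min()),
                )
            )
    return pairs


def _reference_layer(placements):
    """Keep placements in the sheet containing the reference placement.

    Piled 2D crystals stack layers along one direction; the sheet is the
    best-fit plane through the placement COMs nearest the reference (the
    layer of the first deposited chain).
    """
    if len(placements) < 4:
        return placements
    coms = np.array([p[0].coord.mean(axis=0) for p in placements])
    ref = coms[0]
    # the sheet normal is the thinnest direction of the disc-like reference
    # content (robust against stacked layers being closer than in-plane
    # neighbors, as in piled crystals)
    ref_coords = placements[0][0].coord
    _, _, vt = np.linalg.svd(ref_coords - ref_coords.mean(axis=0), full_matrices=False)
    normal = vt[2]
    keep = [
        p for p, c in zip(placements, coms)
        if abs(np.dot(c - ref, normal)) <= LAYER_HALF_THICKNESS
    ]
    return keep if len(keep) >= 3 else placements


def _layer_filter(hexamers, reference_idx=0):
    coms = np.array([h.com for h in hexamers])
    ref = coms[reference_idx]
    near = coms[np.linalg.norm(coms - ref, axis=1) < 90.0]
    if len(near) < 3:
        return hexamers
    point, normal = fit_plane(near)
    keep = [
        h for h, c in zip(hexamers, coms)
        if abs(np.dot(c - point, normal)) <= LAYER_HALF_THICKNESS
    ]
    return keep


def build_trihexamer(crystal_or_hexamers, radius=100.0,
                     contact_cutoff=DEFAULT_CONTACT_CUTOFF,
                     lmap: LandmarkMap | None = None) -> TriHexamerModel:
    """Extract the closed triangle of three interacting hexamers.

    Accepts either a :class:`CrystalStructure` (expanded first; the layer
    containing the first deposited chain is used) or a pre-built hexamer
    list.  1D-stripe packings — contacts only along one lattice direction,
    no closed triangle — raise :class:`PackingError`, mirroring the crystal
    forms excluded from the tiled-layer taxonomy.
    """
    if isinstance(crystal_or_hexamers, CrystalStructure):
        placements = expand_layer(crystal_or_hexamers, radius)
        placements = _reference_layer(placements)
        assembly = merge_placements(placements)
        hexamers, _ = detect_hexamers(assembly, lmap=lmap)
    else:
        hexamers = list(crystal_or_hexamers)
    if len(hexamers) < 3:
        raise PackingError(
            f"only {len(hexamers)} hexamer(s) found within radius; no 2D layer"
        )
    hexamers = _layer_filter(hexamers)
    pairs = find_pairs(hexamers, contact_cutoff=contact_cutoff)
    adj = {}
    for p in pairs:
        i = hexamers.index(p.hexamer_a)
        j = hexamers.index(p.hexamer_b)
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    # closed triangle nearest the reference hexamer (index 0)
    best = None
    for i in sorted(adj):
        for j in sorted(adj[i]):
            if j <= i:
                continue
            for k in sorted(adj[i] & adj[j]):
                if k <= j:
                    continue
                tri = (i, j, k)
                score = min(tri)
                if best is None or score < best[0]:
                    best = (score, tri)
    if best is None:
        kind = "1D stripe" if pairs else "isolated hexamers"
        raise PackingError(
            f"no closed tri-hexamer triangle: packing looks like {kind!r}"
        )
    _, (i, j, k) = best
    tri_hex = [hexamers[i], hexamers[j], hexamers[k]]
    tri_pairs = [
        p for p in pairs
        if {hexamers.index(p.hexamer_a), hexamers.index(p.hexamer_b)} <= {i, j, k}
    ]
    coms = np.array([h.com for h in tri_hex])
    point, normal = fit_plane(coms)
    if max(abs(np.dot(c - point, normal)) for c in coms) > 3.0:
        raise PackingError("candidate hexamer triangle is not coplanar within 3 Å")
    return TriHexamerModel(
        hexamers=tri_hex, pairs=tri_pairs, plane_point=point, plane_normal=normal
    )
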