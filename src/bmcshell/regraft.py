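"""Superposition, Arr-A regrafting onto a template tri-hexamer, alanine edits.

Hexamers of planar-behaving homologs can be repositioned into the
ready-to-curve Arr-A geometry by superposing each one individually onto the
corresponding hexamer of a template tri-hexamer (PduA/3NGK in the source
protocol).  The graft preserves each donor's internal geometry exactly; the
steric consequences are *reported* (clash list at a van-der-Waals overlap
cutoff), matching the manual side-chain remediation step of the protocol —
rotamer rebuilding is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree

from .geometry import apply_transform, kabsch
from .lattice import HexamerModel, HexamerPair, TriHexamerModel

#: Heavy-atom distance (Å) below which two residues of different hexamers are
#: reported as clashing (≈ van-der-Waals overlap); the source protocol
#: alleviated clashes manually without stating a threshold.
CLASH_CUTOFF = 2.6

#: Donor hexamers superposing worse than this (Å backbone RMSD) are rejected.
MAX_GRAFT_RMSD = 3.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is improper (det < 0)")

    def apply(self, coords):
        return apply_transform(coords, self.rotation, self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls):
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class ClashReport:
    """Inter-hexamer residue pairs closer than the cutoff."""

    contacts: list = field(default_factory=list)  # (res_a, res_b, min distance Å)
    cutoff: float = CLASH_CUTOFF

    def __post_init__(self):
        bad = [c for c in self.contacts if c[2] >= self.cutoff]
        if bad:
            raise ValueError("clash report contains distances above its cutoff")

    @property
    def n_clashes(self) -> int:
        return len(self.contacts)

    def residues(self):
        out = set()
        for ra, rb, _ in self.contacts:
            out.add(ra)
            out.add(rb)
        return sorted(out)


def _selection_coords(model, selection):
    """(labels, coords) for a (chain, res, atom) selection; CA-of-core default."""
    arr = model.atoms if isinstance(model, HexamerModel) else model
    if selection is None:
        mask = (arr.atom_name == "CA") & (arr.res_id >= 1) & (arr.res_id <= 90)
    else:
        mask = selection(arr) if callable(selection) else selection
    labels = list(zip(arr.chain_id[mask], arr.res_id[mask], arr.atom_name[mask]))
    return labels, arr.coord[mask]


def superpose(mobile, target, selection=None):
    """Optimal least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    ``selection`` may be None (Cα of residues 1–90), a boolean mask function,
    or precomputed masks; the selection must map 1:1 by (chain, residue, atom)
    between the two models.  Returns ``(RigidTransform, rmsd)`` with the RMSD
    evaluated on the selection.
    """
    la, ca = _selection_coords(mobile, selection)
    lb, cb = _selection_coords(target, selection)
    if la != lb:
        common = [i for i, lab in enumerate(la) if lab in set(lb)]
        index_b = {lab: i for i, lab in enumerate(lb)}
        if len(common) < 3:
            raise ValueError("selection does not map 1:1 (fewer than 3 shared atoms)")
        ca = ca[common]
        cb = cb[[index_b[la[i]] for i in common]]
    rot, trans, rmsd = kabsch(ca, cb)
    return RigidTransform(rotation=rot, translation=trans), rmsd


def _stacked_ca(hexamer, chain_order, core_range=(1, 90)):
    arr = hexamer.atoms
    lo, hi = core_range
    coords = []
    for c in chain_order:
        mask = (
            (arr.chain_id == c)
            & (arr.atom_name == "CA")
            & (arr.res_id >= lo)
            & (arr.res_id <= hi)
        )
        sub = arr[mask]
        order = np.argsort(sub.res_id, kind="stable")
        coords.append(sub.coord[order])
    return coords


def _superpose_hexamer(donor: HexamerModel, template: HexamerModel,
                       core_range=(1, 90)):
    """Best C6 chain correspondence + Kabsch transform donor -> template."""
    t_coords = _stacked_ca(template, template.chain_ids, core_range)
    d_coords = _stacked_ca(donor, donor.chain_ids, core_range)
    n_min = min(min(len(c) for c in t_coords), min(len(c) for c in d_coords))
    t_all = np.concatenate([c[:n_min] for c in t_coords])
    best = None
    for shift in range(6):
        rolled = [d_coords[(i + shift) % 6][:n_min] for i in range(6)]
        d_all = np.concatenate(rolled)
        if d_all.shape != t_all.shape:
            continue
        rot, trans, rmsd = kabsch(d_all, t_all)
        if best is None or rmsd < best[2]:
            best = (rot, trans, rmsd, shift)
    if best is None:
        raise ValueError("no chain correspondence between donor and template")
    rot, trans, rmsd, shift = best
    return RigidTransform(rotation=rot, translation=trans), rmsd, shift


def clash_report(hexamers, cutoff=CLASH_CUTOFF) -> ClashReport:
    """Residue-level inter-hexamer contacts below the clash cutoff."""
    contacts = {}
    heavy = []
    for hi, h in enumerate(hexamers):
        arr = h.atoms[h.atoms.element != "H"]
        heavy.append((hi, arr, cKDTree(arr.coord)))
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            _, ai, _ = heavy[i]
            _, aj, tj = heavy[j]
            dists, idx = tj.query(ai.coord, k=1, distance_upper_bound=cutoff)
            for k in np.flatnonzero(np.isfinite(dists)):
                ra = (i, str(ai.chain_id[k]), int(ai.res_id[k]))
                rb = (j, str(aj.chain_id[idx[k]]), int(aj.res_id[idx[k]]))
                key = (ra, rb)
                d = float(dists[k])
                if key not in contacts or d < contacts[key]:
                    contacts[key] = d
    return ClashReport(
        contacts=[(ra, rb, d) for (ra, rb), d in sorted(contacts.items())],
        cutoff=cutoff,
    )


def regraft_arrA(hexamers, template: TriHexamerModel, core_range=(1, 90),
                 clash_cutoff=CLASH_CUTOFF):
    """Superpose three donor hexamers onto the hexamers of an Arr-A template.

    Each donor is superposed individually (Cα of ``core_range``, best cyclic
    C6 chain correspondence) onto one template hexamer, preserving its
    internal geometry exactly.  Returns ``(TriHexamerModel, ClashReport)``.
    Donors with superposition RMSD above 3 Å are rejected as too dissimilar.
    """
    if len(hexamers) != 3:
        raise ValueError("regrafting needs exactly 3 donor hexamers")
    placed = []
    for donor, tmpl_hex in zip(hexamers, template.hexamers):
        transform, rmsd, _ = _superpose_hexamer(donor, tmpl_hex, core_range)
        if rmsd > MAX_GRAFT_RMSD:
            raise ValueError(
                f"donor hexamer superposes at {rmsd:.2f} Å RMSD (> {MAX_GRAFT_RMSD}); "
                "too dissimilar to the template"
            )
        moved = donor.transformed(transform.rotation, transform.translation)
        moved.provenance["graft_rmsd"] = rmsd
        placed.append(moved)
    pairs = [
        HexamerPair(placed[0], placed[1]),
        HexamerPair(placed[0], placed[2]),
        HexamerPair(placed[1], placed[2]),
    ]
    model = TriHexamerModel(hexamers=placed, pairs=pairs)
    return model, clash_report(placed, cutoff=clash_cutoff)


# --------------------------------------------------------------------------
# Alanine-scan edits
# --------------------------------------------------------------------------

_BACKBONE_AND_CB = ("N", "CA", "C", "O", "CB")


def mutate_alanine(model, res_id, copies="interface", chain_groups=None,
                   contact_cutoff=5.0):
    """Truncate a residue's side chain to Cβ (rename to ALA) in selected copies.

    ``copies``: "interface" edits the monomers where the residue lies at an
    inter-hexamer interface (6 or 9 copies in a tri-hexamer depending on
    whether the residue sits near the interface center or edge), "all" edits
    every copy, or an explicit list of chain ids.  Backbone and Cβ positions
    are untouched.  Returns ``(edited model, n_edited)``.  Glycine targets
    (no Cβ) are an error, as is an absent residue.
    """
    if isinstance(model, TriHexamerModel):
        arr = model.atoms
        groups = tuple(h.chain_ids for h in model.hexamers)
    else:
        arr = model
        groups = chain_groups
    res_mask = arr.res_id == int(res_id)
    if not res_mask.any():
        raise ValueError(f"residue {res_id} absent from the model")
    names = set(arr.res_name[res_mask])
    if "GLY" in names:
        raise ValueError(f"residue {res_id} is glycine (no Cβ); cannot truncate")
    if isinstance(copies, str) and copies == "all":
        target_chains = sorted(set(arr.chain_id[res_mask]))
    elif isinstance(copies, str) and copies.startswith("interface"):
        if not groups:
            raise ValueError("interface selection needs hexamer chain groups")
        from .interface import interface_mask

        mask = interface_mask(arr, groups, contact_cutoff=contact_cutoff)
        target_chains = sorted(
            c for (r, c), flag in mask.items() if r == int(res_id) and flag
        )
    else:
        target_chains = sorted(str(c) for c in copies)
    edit = (
        res_mask
        & np.isin(arr.chain_id, target_chains)
        & ~np.isin(arr.atom_name, _BACKBONE_AND_CB)
    )
    already_ala = set(
        arr.chain_id[res_mask & (arr.res_name == "ALA")]
    )
    edited_chains = [
        c for c in target_chains
        if c not in already_ala and (edit & (arr.chain_id == c)).any()
    ]
    out = arr[~edit].copy()
    rename = (out.res_id == int(res_id)) & np.isin(out.chain_id, edited_chains)
    out.res_name = np.where(rename, "ALA", out.res_name)
    if isinstance(model, TriHexamerModel):
        new_hexes = []
        for h in model.hexamers:
            sel = np.isin(out.chain_id, list(h.chain_ids))
            new_hexes.append(
                HexamerModel(atoms=out[sel], chain_ids=h.chain_ids,
                             normal=h.normal, provenance=dict(h.provenance),
                             core_range=h.core_range)
            )
        pairs = [
            HexamerPair(new_hexes[0], new_hexes[1]),
            HexamerPair(new_hexes[0], new_hexes[2]),
            HexamerPair(new_hexes[1], new_hexes[2]),
        ]
        return TriHexamerModel(hexamers=new_hexes, pairs=pairs), len(edited_chains)
    return out, len(edited_chains)
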