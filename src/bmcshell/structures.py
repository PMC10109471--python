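"""Coordinate I/O, unit cells, symmetry operators and landmark residues.

Atoms are carried as :class:`biotite.structure.AtomArray` /
:class:`~biotite.structure.AtomArrayStack` objects throughout the package;
this module wraps them together with the crystallographic metadata
(unit cell, space group, symmetry operators) needed to rebuild 2D hexamer
layers, and defines the *landmark map* — the explicit role -> residue-number
table that makes every geometric operator portable between BMC-H homologs
(PduA numbering by default, user-supplied renumbering for homologs; transfer
is never done by sequence alignment).
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure


class FormatError(ValueError):
    """The file could not be parsed in the requested coordinate format."""


class LandmarkResolutionError(KeyError):
    """A landmark role could not be resolved to a Cα atom in a chain."""


# Standard water residue names; flagged (via the ``hetero`` annotation) but retained
# on reading — removal happens in the lattice layer.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass
class CrystalStructure:
    """Atom models plus the crystallographic frame they were deposited in.

    Attributes
    ----------
    models : list of AtomArray
        One entry per MODEL record (a single entry for plain files); constant
        topology across entries is *not* required here (it is for trajectories).
    cell : tuple or None
        ``(a, b, c, alpha, beta, gamma)`` in Å / degrees, or None when the
        file carried no CRYST1 record.
    operators : list of (ndarray(3,3), ndarray(3))
        Symmetry operators in fractional coordinates; always contains the
        identity first.
    space_group : str
        Hermann–Mauguin name, empty when unknown.
    missing_cell : bool
        True when no usable cell was found (operators then hold only the
        identity and lattice expansion is impossible).
    """

    models: list
    cell: tuple | None = None
    operators: list = field(default_factory=list)
    space_group: str = ""
    missing_cell: bool = False
    source: str = ""

    def __post_init__(self):
        if len(self.models) < 1:
            raise ValueError("CrystalStructure requires at least one model")
        if not self.operators:
            self.operators = [(np.eye(3), np.zeros(3))]
        if self.cell is not None and any(x <= 0 for x in self.cell[:3]):
            raise ValueError("cell lengths must be positive")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def frac_to_cart(self) -> np.ndarray:
        """Orthogonalization matrix (columns = cell vectors in Å)."""
        if self.cell is None:
            raise ValueError("structure has no unit cell")
        a, b, c, alpha, beta, gamma = self.cell
        al, be, ga = np.radians([alpha, beta, gamma])
        v = np.sqrt(
            1
            - np.cos(al) ** 2
            - np.cos(be) ** 2
            - np.cos(ga) ** 2
            + 2 * np.cos(al) * np.cos(be) * np.cos(ga)
        )
        return np.array(
            [
                [a, b * np.cos(ga), c * np.cos(be)],
                [0, b * np.sin(ga), c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)],
                [0, 0, c * v / np.sin(ga)],
            ]
        )


@dataclass(frozen=True)
class LandmarkMap:
    """Role -> residue-number table (PduA numbering in the shipped default).

    ``bend_pair`` (S27, I38) and ``tilt_pair`` (M24, I18) drive the signed
    dihedral operators; ``lys_edge`` (K26) defines the inter-lysine distance of
    the arrangement taxonomy; ``arg_insert``/``pocket_acid`` (R79, D/E83) the
    arginine-insertion flag; ``saltbridge_pair`` the R28–D49 contact (CcmK
    numbering).  ``concave_face_residues`` declare residues lying on the
    concave face and anchor the sign convention (negative bending = toward the
    convex face); when None the +z side of the layer plane is used and flagged.
    """

    lys_edge: int = 26
    bend_pair: tuple = (27, 38)
    tilt_pair: tuple = (24, 18)
    plane_probe: int = 54  # V54 Cα per the dihedral/plane analysis; A53 also common
    arg_insert: int = 79
    pocket_acid: int = 83
    saltbridge_pair: tuple = (28, 49)
    core_range: tuple = (1, 90)
    concave_face_residues: tuple | None = None

    def __post_init__(self):
        lo, hi = self.core_range
        if hi < lo:
            raise ValueError("core_range is empty")

    def roles(self) -> dict:
        """Flat role -> residue-number mapping (pair roles expanded)."""
        return {
            "lys_edge": self.lys_edge,
            "bend_a": self.bend_pair[0],
            "bend_b": self.bend_pair[1],
            "tilt_a": self.tilt_pair[0],
            "tilt_b": self.tilt_pair[1],
            "plane_probe": self.plane_probe,
            "arg_insert": self.arg_insert,
            "pocket_acid": self.pocket_acid,
            "saltbridge_a": self.saltbridge_pair[0],
            "saltbridge_b": self.saltbridge_pair[1],
        }

    def renumbered(self, mapping: dict) -> "LandmarkMap":
        """Transfer to a homolog with an explicit old -> new residue mapping."""

        def m(x):
            return mapping.get(x, x)

        return replace(
            self,
            lys_edge=m(self.lys_edge),
            bend_pair=(m(self.bend_pair[0]), m(self.bend_pair[1])),
            tilt_pair=(m(self.tilt_pair[0]), m(self.tilt_pair[1])),
            plane_probe=m(self.plane_probe),
            arg_insert=m(self.arg_insert),
            pocket_acid=m(self.pocket_acid),
            saltbridge_pair=(m(self.saltbridge_pair[0]), m(self.saltbridge_pair[1])),
        )


#: Shipped default: PduA (3NGK) author numbering.
PDUA_LANDMARKS = LandmarkMap()


def load_landmark_map(path, section=None) -> LandmarkMap:
    """Read a landmark map from a plain key/value config file.

    One section per protein; keys are role names, values residue numbers
    (comma-separated for pair roles), e.g. ``bend_pair = 27, 38``.
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    if section is None:
        section = cp.sections()[0]
    sec = cp[section]

    def ints(key, default):
        if key not in sec:
            return default
        vals = tuple(int(x) for x in sec[key].replace(",", " ").split())
        return vals if len(vals) > 1 else vals[0]

    concave = ints("concave_face_residues", None)
    if isinstance(concave, int):
        concave = (concave,)
    return LandmarkMap(
        lys_edge=ints("lys_edge", 26),
        bend_pair=ints("bend_pair", (27, 38)),
        tilt_pair=ints("tilt_pair", (24, 18)),
        plane_probe=ints("plane_probe", 54),
        arg_insert=ints("arg_insert", 79),
        pocket_acid=ints("pocket_acid", 83),
        saltbridge_pair=ints("saltbridge_pair", (28, 49)),
        core_range=ints("core_range", (1, 90)),
        concave_face_residues=concave,
    )


def _parse_cryst1(lines):
    for line in lines:
        if line.startswith("CRYST1"):
            try:
                cell = tuple(
                    float(line[i:j])
                    for i, j in ((6, 15), (15, 24), (24, 33), (33, 40), (40, 47), (47, 54))
                )
            except ValueError:
                return None, ""
            sg = line[55:66].strip()
            # Dummy cells written by non-crystallographic tools
            if cell[:3] == (1.0, 1.0, 1.0) and sg in ("P 1", ""):
                return None, ""
            return cell, sg
    return None, ""


def _parse_smtry(lines):
    """REMARK 290 SMTRY records -> list of (rotation, translation) in *Cartesian* Å.

    Deposited SMTRY matrices act on orthogonal coordinates; they are converted
    to fractional form by the caller, which knows the cell.
    """
    rows = {}
    for line in lines:
        if line.startswith("REMARK 290") and "SMTRY" in line:
            parts = line.split()
            # REMARK 290 SMTRYn  opno  r1 r2 r3 t
            try:
                axis = int(parts[2][-1])
                opno = int(parts[3])
                vals = [float(x) for x in parts[4:8]]
            except (IndexError, ValueError):
                continue
            rows.setdefault(opno, {})[axis] = vals
    ops = []
    for opno in sorted(rows):
        if set(rows[opno]) != {1, 2, 3}:
            continue
        mat = np.array([rows[opno][k][:3] for k in (1, 2, 3)])
        vec = np.array([rows[opno][k][3] for k in (1, 2, 3)])
        ops.append((mat, vec))
    return ops


def _ops_from_space_group(name):
    sg = gemmi.find_spacegroup_by_name(name)
    if sg is None:
        return []
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    return ops


def _ensure_identity_first(ops):
    ident = [
        i
        for i, (r, t) in enumerate(ops)
        if np.allclose(r, np.eye(3), atol=1e-9) and np.allclose(t, 0, atol=1e-9)
    ]
    if ident:
        first = ops.pop(ident[0])
        ops.insert(0, first)
    else:
        ops.insert(0, (np.eye(3), np.zeros(3)))
    return ops


def read_structure(path, fmt=None) -> CrystalStructure:
    """Read a PDB or mmCIF file into a :class:`CrystalStructure`.

    Alternate locations are reduced to the highest-occupancy conformer.
    Waters and other heteroatoms are retained (flagged through the ``hetero``
    annotation); they are stripped only where the analysis requires it.
    Symmetry operators come from REMARK 290 SMTRY records when present
    (authoritative for the deposited setting), otherwise from the space-group
    name in CRYST1; a file without a usable cell loads with the identity
    operator only and ``missing_cell=True``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt == "pdb":
        try:
            pdb = PDBFile.read(str(path))
            n = pdb.get_model_count()
            models = [
                pdb.get_structure(model=i, altloc="occupancy", extra_fields=["occupancy"])
                for i in range(1, n + 1)
            ]
        except Exception as exc:  # noqa: BLE001 - normalized into FormatError
            raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
        cell, sg_name = _parse_cryst1(pdb.lines)
        cart_ops = _parse_smtry(pdb.lines)
    elif fmt == "mmcif":
        try:
            cif = CIFFile.read(str(path))
            block = cif.block
            stack = _cif_get_structure(cif, model=None, altloc="occupancy",
                                       extra_fields=["occupancy"])
            models = [stack[i] for i in range(stack.stack_depth())]
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot parse {path} as mmCIF: {exc}") from exc
        cell, sg_name, cart_ops = None, "", []
        if "cell" in block:
            c = block["cell"]
            try:
                cell = tuple(
                    float(c[k].as_item())
                    for k in ("length_a", "length_b", "length_c",
                              "angle_alpha", "angle_beta", "angle_gamma")
                )
            except KeyError:
                cell = None
        if "symmetry" in block:
            try:
                sg_name = block["symmetry"]["space_group_name_H-M"].as_item()
            except KeyError:
                sg_name = ""
    else:
        raise FormatError(f"unknown format {fmt!r}")

    missing_cell = cell is None
    operators = []
    if not missing_cell:
        if cart_ops:
            # SMTRY matrices are Cartesian; convert to fractional form
            m = CrystalStructure(models=[models[0]], cell=cell).frac_to_cart()
            minv = np.linalg.inv(m)
            operators = [(minv @ r @ m, minv @ t) for r, t in cart_ops]
        elif sg_name:
            operators = _ops_from_space_group(sg_name)
    if missing_cell:
        warnings.warn(
            f"{path.name}: no usable CRYST1 cell; symmetry expansion disabled",
            stacklevel=2,
        )
    operators = _ensure_identity_first(operators)
    return CrystalStructure(
        models=models,
        cell=cell,
        operators=operators,
        space_group=sg_name,
        missing_cell=missing_cell,
        source=str(path),
    )


def write_model(model, path, multi_model=False, cell=None, space_group="P 1"):
    """Write atom model(s) as PDB text.

    ``model`` may be an AtomArray, an AtomArrayStack, or a list of AtomArrays
    with identical topology; MODEL/ENDMDL framing is used when ``multi_model``
    or when several models are given.  Coordinates survive a round trip
    through :func:`read_structure` to 1e-3 Å (the PDB field precision).
    """
    if isinstance(model, struc.AtomArrayStack):
        stack = model
    elif isinstance(model, (list, tuple)):
        if len(model) == 0:
            raise ValueError("empty model list")
        stack = struc.stack(model) if (multi_model or len(model) > 1) else None
        if stack is None:
            stack = model[0]
    else:
        stack = model
    arr0 = stack[0] if isinstance(stack, struc.AtomArrayStack) else stack
    if arr0.array_length() == 0:
        raise ValueError("empty model")
    too_long = sorted({c for c in np.unique(arr0.chain_id) if len(str(c)) > 1})
    if too_long:
        raise ValueError(f"chain ids not representable in PDB: {too_long}")
    pdb = PDBFile()
    pdb.set_structure(stack)
    if cell is not None:
        a, b, c, al, be, ga = cell
        cryst = (
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
            f"{space_group:<11s}{1:4d}"
        )
        pdb.lines.insert(0, cryst)
    pdb.write(str(path))


def chain_atoms(model: struc.AtomArray, chain_id: str) -> struc.AtomArray:
    return model[model.chain_id == str(chain_id)]


def ca_position(model: struc.AtomArray, chain_id: str, res_id: int) -> np.ndarray:
    sel = (
        (model.chain_id == str(chain_id))
        & (model.res_id == int(res_id))
        & (model.atom_name == "CA")
    )
    coords = model.coord[sel]
    if len(coords) == 0:
        raise LandmarkResolutionError(
            f"no Cα for residue {res_id} in chain {chain_id}"
        )
    return coords[0].astype(float)


def resolve_landmarks(structure, lmap: LandmarkMap, chain_id: str, model=0) -> dict:
    """Cα position per landmark role for one chain.

    ``structure`` may be a :class:`CrystalStructure` or a bare AtomArray.
    Raises :class:`LandmarkResolutionError` naming the offending role and
    chain when a mapped residue (or its Cα) is absent.
    """
    arr = structure.models[model] if isinstance(structure, CrystalStructure) else structure
    if str(chain_id) not in np.unique(arr.chain_id):
        raise LandmarkResolutionError(f"chain {chain_id} not present")
    out = {}
    for role, res_id in lmap.roles().items():
        try:
            out[role] = ca_position(arr, chain_id, res_id)
        except LandmarkResolutionError as exc:
            raise LandmarkResolutionError(
                f"landmark role {role!r} (residue {res_id}) unresolvable in "
                f"chain {chain_id}: {exc.args[0]}"
            ) from exc
    return out
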