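"""Structure containers, PDB I/O, geometric primitives, and the toy-complex generator.

The module holds everything the docking and PRE machinery needs to know about
a protein: atoms with coordinates and per-atom parameters (van der Waals
radius, partial charge, pair-potential type), rigid-body poses of a ligand
relative to a fixed receptor, interface detection, least-squares superposition,
and the interface RMSD (IRMSD) metric used throughout to measure how far a
docked pose is from the native binding mode.

Conventions
-----------
* Coordinates are in Angstrom, frames are right-handed.
* A :class:`Pose` acts on ligand coordinates expressed in the receptor frame
  as ``x -> R @ x + t``.
* Residue identifiers are ``(chain, residue_number, insertion_code)`` tuples
  using author numbering from the PDB file.
* Heavy atoms only enter docking energies and overlap checks; hydrogens, when
  present, are kept for PRE distance calculations.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Structure",
    "Pose",
    "ParamagneticLabel",
    "NativeComplex",
    "read_structure",
    "write_structure",
    "default_parameter_table",
    "read_parameter_table",
    "assign_parameters",
    "interface_residues",
    "superpose",
    "compute_irmsd",
    "irmsd_between",
    "attach_label",
    "make_toy_complex",
]

ResidueId = tuple[str, int, str]

#: fallback van der Waals radii (Angstrom) for atoms missing from a parameter table
DEFAULT_ELEMENT_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "MN": 1.40,
    "FE": 1.40,
    "ZN": 1.39,
}
_FALLBACK_RADIUS = 1.70


@dataclass
class Structure:
    """An ordered collection of atoms with coordinates and parameters.

    Arrays are parallel over atoms and kept in file order. ``radius``,
    ``charge`` and ``pair_type`` are populated by :func:`assign_parameters`
    (or by the synthetic generator); until then radii are zero.
    """

    chain: np.ndarray          # str, (n,)
    resid: np.ndarray          # int, author numbering, (n,)
    icode: np.ndarray          # str insertion codes, '' when absent, (n,)
    resname: np.ndarray        # str, (n,)
    atname: np.ndarray         # str, (n,)
    element: np.ndarray        # str, upper case, (n,)
    xyz: np.ndarray            # float, (n, 3)
    radius: np.ndarray = None  # float, (n,)
    charge: np.ndarray = None  # float, (n,)
    pair_type: np.ndarray = None  # int >= 0, (n,)
    occupancy: np.ndarray = None
    bfactor: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.xyz)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom positions must be finite")
        if self.radius is None:
            self.radius = np.zeros(n)
        if self.charge is None:
            self.charge = np.zeros(n)
        if self.pair_type is None:
            self.pair_type = np.zeros(n, dtype=int)
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        if self.bfactor is None:
            self.bfactor = np.zeros(n)
        for name in ("chain", "resid", "icode", "resname", "atname", "element"):
            setattr(self, name, np.asarray(getattr(self, name)))
        keys = list(zip(self.chain, self.resid, self.icode, self.atname))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom name) triples")

    def __len__(self) -> int:
        return len(self.xyz)

    def copy(self) -> "Structure":
        return Structure(**{k: np.array(getattr(self, k)) for k in (
            "chain", "resid", "icode", "resname", "atname", "element",
            "xyz", "radius", "charge", "pair_type", "occupancy", "bfactor")})

    # -- masks and lookups -------------------------------------------------
    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def residue_ids(self) -> list[ResidueId]:
        """Unique residue ids in order of first appearance."""
        seen: dict[ResidueId, None] = {}
        for c, r, i in zip(self.chain, self.resid, self.icode):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def residue_key_array(self) -> list[ResidueId]:
        return [(str(c), int(r), str(i))
                for c, r, i in zip(self.chain, self.resid, self.icode)]

    def atom_index(self, residue: ResidueId, atname: str) -> int | None:
        mask = ((self.chain == residue[0]) & (self.resid == residue[1])
                & (self.icode == residue[2]) & (self.atname == atname))
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None

    def ca_coords(self, residues: Iterable[ResidueId]) -> np.ndarray:
        """C-alpha coordinates for the given residues, in the given order."""
        out = []
        for rid in residues:
            i = self.atom_index(rid, "CA")
            if i is not None:
                out.append(self.xyz[i])
        return np.array(out).reshape(-1, 3)

    def center(self, heavy_only: bool = True) -> np.ndarray:
        mask = self.heavy_mask if heavy_only else slice(None)
        return self.xyz[mask].mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        new = self.copy()
        new.xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return new


@dataclass
class Pose:
    """Rigid-body placement of the ligand: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    energy: float | None = None
    irmsd: float | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("pose rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("pose rotation is not proper (det != 1)")
        self.rotation, self.translation = R, t

    @classmethod
    def identity(cls, energy: float | None = None) -> "Pose":
        return cls(np.eye(3), np.zeros(3), energy=energy)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation


@dataclass
class ParamagneticLabel:
    """A paramagnetic spin label with one metal position per rotamer.

    Positions are expressed in the ligand frame and move rigidly with the
    ligand under any pose. EDTA-Mn2+ labels conjugated at engineered surface
    cysteines typically populate a few discrete rotamers, each putting the
    metal ion at a different point; by default the rotamers carry equal weight.
    """

    residue: ResidueId
    positions: np.ndarray      # (K, 3)
    weights: np.ndarray = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.positions) < 1:
            raise ValueError("label needs at least one rotamer position")
        if self.weights is None:
            self.weights = np.full(len(self.positions), 1.0 / len(self.positions))
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("rotamer weights must sum to 1")

    @property
    def n_rotamers(self) -> int:
        return len(self.positions)

    def posed_positions(self, pose: Pose) -> np.ndarray:
        return pose.apply(self.positions)


@dataclass
class NativeComplex:
    """A receptor/ligand pair in the bound frame with interface annotations."""

    receptor: Structure
    ligand: Structure
    receptor_interface: list[ResidueId]
    ligand_interface: list[ResidueId]
    receptor_interface_center: np.ndarray
    ligand_interface_center: np.ndarray
    receptor_center: np.ndarray
    interface_cutoff: float = 10.0

    @classmethod
    def from_structures(cls, receptor: Structure, ligand: Structure,
                        cutoff: float = 10.0) -> "NativeComplex":
        rec_if, lig_if = interface_residues(receptor, ligand, cutoff=cutoff)
        if not rec_if or not lig_if:
            raise ValueError("no interface residues within cutoff; not a complex")
        rec_center = receptor.center()
        rc = _interface_center(receptor, rec_if)
        lc = _interface_center(ligand, lig_if)
        return cls(receptor, ligand, rec_if, lig_if, rc, lc, rec_center, cutoff)

    def ligand_interface_ca(self) -> np.ndarray:
        ca = self.ligand.ca_coords(self.ligand_interface)
        if len(ca) == 0:
            raise ValueError("no C-alpha atoms in the ligand interface")
        return ca


def _interface_center(structure: Structure, residues: Sequence[ResidueId]) -> np.ndarray:
    keys = structure.residue_key_array()
    rset = set(residues)
    mask = np.array([k in rset for k in keys])
    return structure.xyz[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, chain: str | None = None,
                   include_hetero: bool = False) -> Structure:
    """Read a PDB (or mmCIF) file into a :class:`Structure`.

    Waters and heteroatoms are excluded by default; alternate locations are
    resolved to the highest-occupancy conformer (ties broken by the
    alphabetically first altloc label).

    Parameters
    ----------
    path : file path
    chain : optional chain id; when given only that chain is kept and a
        missing chain raises ``KeyError`` listing the chains present.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise IOError(f"no models in {path}")
    model = st[0]
    available = [ch.name for ch in model]
    if chain is not None and chain not in available:
        raise KeyError(f"chain {chain!r} not found; available chains: {available}")

    rows: dict[tuple, tuple[float, str, dict]] = {}
    order: list[tuple] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.name == "HOH":
                continue
            if not include_hetero and res.het_flag == "H":
                continue
            for atom in res:
                key = (ch.name, res.seqid.num, res.seqid.icode.strip(), atom.name)
                rec = dict(
                    chain=ch.name, resid=res.seqid.num,
                    icode=res.seqid.icode.strip(), resname=res.name,
                    atname=atom.name, element=atom.element.name.upper(),
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=atom.occ, bfactor=atom.b_iso,
                )
                alt = atom.altloc or ""
                if key not in rows:
                    rows[key] = (atom.occ, alt, rec)
                    order.append(key)
                else:
                    occ0, alt0, _ = rows[key]
                    # highest occupancy wins; ties -> alphabetically first altloc
                    if atom.occ > occ0 or (atom.occ == occ0 and alt < alt0):
                        rows[key] = (atom.occ, alt, rec)
    if not order:
        raise IOError(f"no atoms read from {path}")
    recs = [rows[k][2] for k in order]
    return Structure(
        chain=np.array([r["chain"] for r in recs]),
        resid=np.array([r["resid"] for r in recs], dtype=int),
        icode=np.array([r["icode"] for r in recs]),
        resname=np.array([r["resname"] for r in recs]),
        atname=np.array([r["atname"] for r in recs]),
        element=np.array([r["element"] for r in recs]),
        xyz=np.array([r["xyz"] for r in recs], dtype=float),
        occupancy=np.array([r["occupancy"] for r in recs], dtype=float),
        bfactor=np.array([r["bfactor"] for r in recs], dtype=float),
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` to a PDB file (occupancy/B-factor preserved)."""
    st = gemmi.Structure()
    st.name = "encounterdock"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    last_res_key = None
    cur_res = None
    for i in range(len(structure)):
        cname = str(structure.chain[i])
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        res_key = (cname, int(structure.resid[i]), str(structure.icode[i]))
        if res_key != last_res_key:
            cur_res = gemmi.Residue()
            cur_res.name = str(structure.resname[i])
            cur_res.seqid = gemmi.SeqId(int(structure.resid[i]),
                                        str(structure.icode[i]) or " ")
            chains[cname].add_residue(cur_res)
            # gemmi copies the residue on add; keep a handle to the stored one
            cur_res = chains[cname][len(chains[cname]) - 1]
            last_res_key = res_key
        atom = gemmi.Atom()
        atom.name = str(structure.atname[i])
        atom.element = gemmi.Element(str(structure.element[i]))
        atom.pos = gemmi.Position(*structure.xyz[i])
        atom.occ = float(structure.occupancy[i])
        atom.b_iso = float(structure.bfactor[i])
        cur_res.add_atom(atom)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_pose_ensemble(receptor: Structure, ligand: Structure,
                        poses: Sequence[Pose], path: str | Path,
                        include_receptor: bool = False) -> None:
    """Write posed ligand copies as a multi-MODEL PDB ensemble."""
    lines: list[str] = []
    for m, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        if include_receptor:
            serial = _pdb_atom_lines(receptor, lines, serial)
        posed = ligand.transformed(pose.rotation, pose.translation)
        _pdb_atom_lines(posed, lines, serial)
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom_lines(structure: Structure, lines: list[str], serial: int) -> int:
    for i in range(len(structure)):
        name = str(structure.atname[i])
        pad = name if len(name) >= 4 else f" {name:<3s}"
        x, y, z = structure.xyz[i]
        lines.append(
            f"ATOM  {serial:5d} {pad:<4s}{structure.resname[i]:>4s} "
            f"{structure.chain[i]:1s}{structure.resid[i]:4d}{structure.icode[i]:1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{structure.occupancy[i]:6.2f}"
            f"{structure.bfactor[i]:6.2f}          {structure.element[i]:>2s}"
        )
        serial += 1
    return serial


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def default_parameter_table() -> pd.DataFrame:
    """A minimal element-based parameter table (wildcard residue/atom rows).

    Charges default to zero; pair types split atoms into a polar class (0)
    and an apolar/carbon class (1) so the pairwise contact potential has a
    non-trivial type alphabet.
    """
    rows = [
        ("*", "*", "C", 1.70, 0.0, 1),
        ("*", "*", "N", 1.55, 0.0, 0),
        ("*", "*", "O", 1.52, 0.0, 0),
        ("*", "*", "S", 1.80, 0.0, 1),
        ("*", "*", "H", 1.10, 0.0, 0),
        ("*", "*", "P", 1.80, 0.0, 0),
    ]
    return pd.DataFrame(rows, columns=["residue_name", "atom_name", "element",
                                       "radius", "charge", "pair_type"])


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"residue_name", "atom_name", "element", "radius", "charge", "pair_type"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return table


def assign_parameters(structure: Structure, table: pd.DataFrame) -> Structure:
    """Assign radius, charge and pair type to every atom from a lookup table.

    Matching order: exact ``(residue_name, atom_name)`` row, then a wildcard
    row matching the element. Atoms matched by neither get an element-default
    radius, zero charge and pair type 0, and are counted in a single warning.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty parameter table")
    by_res_atom = {}
    by_element = {}
    for _, row in table.iterrows():
        entry = (float(row["radius"]), float(row["charge"]), int(row["pair_type"]))
        if row["residue_name"] != "*" and row["atom_name"] != "*":
            by_res_atom[(row["residue_name"], row["atom_name"])] = entry
        else:
            by_element.setdefault(str(row["element"]).upper(), entry)

    new = structure.copy()
    n_fallback = 0
    for i in range(len(structure)):
        key = (str(structure.resname[i]), str(structure.atname[i]))
        elem = str(structure.element[i]).upper()
        if key in by_res_atom:
            r, q, t = by_res_atom[key]
        elif elem in by_element:
            r, q, t = by_element[elem]
        else:
            r = DEFAULT_ELEMENT_RADII.get(elem, _FALLBACK_RADIUS)
            q, t = 0.0, 0
            n_fallback += 1
        new.radius[i], new.charge[i], new.pair_type[i] = r, q, t
    if n_fallback:
        warnings.warn(f"{n_fallback} atoms not found in parameter table; "
                      "element-default radius, zero charge assigned",
                      stacklevel=2)
    return new


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def interface_residues(receptor: Structure, ligand: Structure,
                       cutoff: float = 10.0, heavy_only: bool = True
                       ) -> tuple[list[ResidueId], list[ResidueId]]:
    """Residues of each partner with any atom within ``cutoff`` of the other.

    Heavy atoms define contacts by default. Returns residue-id lists in order
    of first appearance in each structure.
    """
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("empty structure")
    rmask = receptor.heavy_mask if heavy_only else np.ones(len(receptor), bool)
    lmask = ligand.heavy_mask if heavy_only else np.ones(len(ligand), bool)
    rxyz, lxyz = receptor.xyz[rmask], ligand.xyz[lmask]
    tree = cKDTree(lxyz)
    rhits = tree.query_ball_point(rxyz, cutoff)
    rkeys = [k for k, m in zip(receptor.residue_key_array(), rmask) if m]
    lkeys = [k for k, m in zip(ligand.residue_key_array(), lmask) if m]
    rec_set: dict[ResidueId, None] = {}
    lig_set: dict[ResidueId, None] = {}
    for key, hits in zip(rkeys, rhits):
        if hits:
            rec_set.setdefault(key, None)
            for j in hits:
                lig_set.setdefault(lkeys[j], None)
    # preserve ligand file order
    lig_order = [k for k in ligand.residue_ids() if k in lig_set]
    rec_order = [k for k in receptor.residue_ids() if k in rec_set]
    return rec_order, lig_order


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of point sets.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile onto reference.
    Only proper rotations are returned. Degenerate (collinear or tiny) sets
    raise ``ValueError``.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if len(mob) != len(ref):
        raise ValueError("point counts differ")
    if len(mob) < 3:
        raise ValueError("need at least 3 points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    H = (mob - cm).T @ (ref - cr)
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], 1e-30)
    if S[1] / scale < 1e-8:
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((mob @ R.T + t - ref) ** 2, axis=1))))
    return R, t, rmsd


def irmsd_between(receptor_coords: np.ndarray, ligand_if_ca: np.ndarray,
                  native: NativeComplex) -> float:
    """IRMSD of an arbitrarily placed complex against the native one.

    The given receptor coordinates are superposed onto the native receptor;
    the same transform is applied to the ligand interface C-alpha coordinates
    before computing their RMSD to the native ligand interface C-alphas.
    """
    native_ca = native.ligand_interface_ca()
    R, t, _ = superpose(receptor_coords, native.receptor.xyz)
    moved = np.asarray(ligand_if_ca) @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - native_ca) ** 2, axis=1))))


def compute_irmsd(pose: Pose, native: NativeComplex) -> float:
    """Interface RMSD of a pose: C-alpha RMSD of the ligand's native-interface
    residues after superposing the receptor onto the native receptor.

    Poses keep the receptor fixed in the native frame, so the receptor
    superposition is the identity and the IRMSD reduces to the RMSD between
    posed and native ligand interface C-alpha positions.
    """
    ca = native.ligand_interface_ca()
    posed = pose.apply(ca)
    return float(np.sqrt(np.mean(np.sum((posed - ca) ** 2, axis=1))))


def attach_label(structure: Structure, residue: ResidueId | str,
                 metal_positions: np.ndarray,
                 weights: np.ndarray | None = None) -> ParamagneticLabel:
    """Attach a paramagnetic label at an existing residue of the structure."""
    rid = _parse_residue_id(residue)
    if rid not in set(structure.residue_ids()):
        raise KeyError(f"residue {rid} not present in structure")
    return ParamagneticLabel(rid, np.asarray(metal_positions, float), weights)


def _parse_residue_id(residue: ResidueId | str) -> ResidueId:
    if isinstance(residue, str):
        chain, _, num = residue.partition(":")
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        return (chain, int(num), icode)
    rid = tuple(residue)
    if len(rid) == 2:
        rid = (*rid, "")
    return (str(rid[0]), int(rid[1]), str(rid[2]))


# ---------------------------------------------------------------------------
# Synthetic toy complex
# ---------------------------------------------------------------------------

def _spiral_blob(n_res: int, radius: float, center: np.ndarray,
                 rng: np.random.Generator, jitter: float = 0.15) -> np.ndarray:
    """C-alpha positions of a pseudo-protein: a spherical spiral blob."""
    k = np.arange(n_res)
    # z spread over the sphere, golden-angle azimuth -> quasi-even cover
    z = -1.0 + 2.0 * (k + 0.5) / n_res
    az = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = radius * np.column_stack([rho * np.cos(az), rho * np.sin(az), z])
    pts += jitter * rng.standard_normal(pts.shape)
    return pts + center


def _backbone_from_ca(ca: np.ndarray, blob_center: np.ndarray):
    """Place N and C atoms around each C-alpha of a pseudo-chain.

    The N of residue i sits 1.45 A from CA_i, tilted off the CA(i-1)-CA(i)
    segment so that C(i-1), N(i), CA(i) are never collinear and the amide
    proton construction is well defined.
    """
    n_res = len(ca)
    Ns, Cs = np.empty((n_res, 3)), np.empty((n_res, 3))
    for i in range(n_res):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[0] - ca[1]
        next_dir = ca[i + 1] - ca[i] if i < n_res - 1 else ca[i] - ca[i - 1]
        u = prev_dir / np.linalg.norm(prev_dir)
        radial = ca[i] - blob_center
        perp = np.cross(u, radial)
        nperp = np.linalg.norm(perp)
        if nperp < 1e-6:
            perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
            nperp = np.linalg.norm(perp)
        perp /= nperp
        # 25-degree tilt away from the chain direction
        tilt = np.cos(np.deg2rad(25.0)) * u + np.sin(np.deg2rad(25.0)) * perp
        Ns[i] = ca[i] - 1.45 * tilt
        v = next_dir / np.linalg.norm(next_dir)
        Cs[i] = ca[i] + 1.52 * v
    return Ns, Cs


def _build_chain(ca: np.ndarray, chain_id: str, blob_center: np.ndarray,
                 charges_ca: np.ndarray, pair_types_ca: np.ndarray,
                 resid_start: int = 1) -> Structure:
    Ns, Cs = _backbone_from_ca(ca, blob_center)
    n_res = len(ca)
    chain, resid, icode, resname, atname, element = [], [], [], [], [], []
    xyz, radius, charge, ptype = [], [], [], []
    for i in range(n_res):
        for name, pos, elem, r in (("N", Ns[i], "N", 1.55),
                                   ("CA", ca[i], "C", 1.70),
                                   ("C", Cs[i], "C", 1.70)):
            chain.append(chain_id)
            resid.append(resid_start + i)
            icode.append("")
            resname.append("ALA")
            atname.append(name)
            element.append(elem)
            xyz.append(pos)
            radius.append(r)
            charge.append(charges_ca[i] if name == "CA" else 0.0)
            ptype.append(int(pair_types_ca[i]) if name == "CA" else 0)
    return Structure(
        chain=np.array(chain), resid=np.array(resid, int), icode=np.array(icode),
        resname=np.array(resname), atname=np.array(atname),
        element=np.array(element), xyz=np.array(xyz),
        radius=np.array(radius), charge=np.array(charge),
        pair_type=np.array(ptype, int),
    )


def make_toy_complex(seed: int = 0, n_receptor_residues: int = 24,
                     n_ligand_residues: int = 12, receptor_radius: float = 5.0,
                     ligand_radius: float = 3.5, gap: float = 3.4,
                     patch_charge: float = 1.0) -> NativeComplex:
    """Generate a deterministic synthetic two-chain complex with a planted
    charge-complementary interface.

    Two pseudo-globular chains of N/CA/C pseudo-residues face each other along
    the lab z axis, their surfaces separated by ``gap`` (about one van der
    Waals contact). Receptor residues on the top cap carry positive charge and
    ligand residues on the bottom cap negative charge, so the generated
    placement is a planted electrostatic energy minimum that end-to-end docking
    tests can recover. Apolar pair type 1 is assigned to the same patch atoms.

    The generated (identity) placement is the native pose: ``compute_irmsd`` of
    the identity pose is exactly zero.
    """
    rng = np.random.default_rng(seed)
    rec_center = np.zeros(3)
    lig_center = np.array([0.0, 0.0, receptor_radius + ligand_radius + gap])
    rec_ca = _spiral_blob(n_receptor_residues, receptor_radius, rec_center, rng)
    lig_ca = _spiral_blob(n_ligand_residues, ligand_radius, lig_center, rng)

    rec_patch = rec_ca[:, 2] > receptor_radius - 2.5
    lig_patch = lig_ca[:, 2] < lig_center[2] - (ligand_radius - 2.5)
    rec_q = np.where(rec_patch, patch_charge, 0.0)
    lig_q = np.where(lig_patch, -patch_charge, 0.0)
    rec_t = np.where(rec_patch, 1, 0)
    lig_t = np.where(lig_patch, 1, 0)

    receptor = _build_chain(rec_ca, "A", rec_center, rec_q, rec_t)
    ligand = _build_chain(lig_ca, "B", lig_center, lig_q, lig_t)
    return NativeComplex.from_structures(receptor, ligand, cutoff=10.0)
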