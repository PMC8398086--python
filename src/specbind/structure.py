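"""Protein structures, trajectories, and the geometric metrics on them.

Coordinates are orthogonal angstroms, no crystal symmetry and no periodic
imaging.  PDB parsing and writing are delegated to biotite; everything
else — Kabsch superposition RMSD, signed dihedrals, geometric hydrogen-bond
detection — is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

BACKBONE = ("N", "CA", "C")


class StructureError(ValueError):
    pass


class AtomMismatchError(StructureError):
    pass


class UndefinedDihedralError(StructureError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str
    coord: np.ndarray  # (3,) angstrom

    def __post_init__(self):
        c = np.asarray(self.coord, dtype=float)
        object.__setattr__(self, "coord", c)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.name}: coordinates must be finite 3-vectors")


@dataclass(frozen=True)
class Structure:
    """An ordered list of atoms with names, residues, chains and angstrom coordinates."""

    atoms: tuple[Atom, ...]
    hetero: tuple[bool, ...] = ()  # per-atom HETATM flag; empty means all False

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        het = self.hetero if self.hetero else (False,) * len(self.atoms)
        object.__setattr__(self, "hetero", tuple(het))
        if len(self.hetero) != len(self.atoms):
            raise StructureError("hetero flags must match atom count")

    def __len__(self):
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        new_atoms = tuple(
            Atom(a.name, a.element, a.residue_name, a.residue_index, a.chain, c)
            for a, c in zip(self.atoms, coords)
        )
        return Structure(new_atoms, self.hetero)

    def select(self, names=None, chains=None, protein_only=False) -> "Structure":
        keep, het = [], []
        for a, h in zip(self.atoms, self.hetero):
            if names is not None and a.name not in names:
                continue
            if chains is not None and a.chain not in chains:
                continue
            if protein_only and h:
                continue
            keep.append(a)
            het.append(h)
        return Structure(tuple(keep), tuple(het))

    def residues(self) -> list[tuple[tuple[str, int], dict[str, Atom]]]:
        """Group atoms by (chain, residue_index) preserving order; name -> atom."""
        order: list[tuple[str, int]] = []
        table: dict[tuple[str, int], dict[str, Atom]] = {}
        for a in self.atoms:
            key = (a.chain, a.residue_index)
            if key not in table:
                table[key] = {}
                order.append(key)
            table[key].setdefault(a.name, a)
        return [(k, table[k]) for k in order]


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames sharing one atom roster; times in ps, strictly increasing."""

    frames: tuple[Structure, ...]
    times: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(self.frames) != len(self.times):
            raise StructureError("one time per frame required")
        if not all(a < b for a, b in zip(self.times, self.times[1:])):
            raise StructureError("frame times must be strictly increasing")
        roster = [(a.name, a.residue_index, a.chain) for a in self.frames[0].atoms]
        for f in self.frames[1:]:
            if [(a.name, a.residue_index, a.chain) for a in f.atoms] != roster:
                raise StructureError("all frames must share one atom roster")

    def __len__(self):
        return len(self.frames)


@dataclass(frozen=True)
class HBond:
    """A donor-H...acceptor contact satisfying the geometric criteria."""

    donor: Atom
    acceptor: Atom
    hydrogen: Atom | None
    d_DA: float  # angstrom
    angle_DHA: float | None  # deg; None in heavy-atom-only mode


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _from_atom_array(arr: bts.AtomArray) -> Structure:
    atoms = tuple(
        Atom(
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            residue_name=str(arr.res_name[i]),
            residue_index=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]) or "A",
            coord=arr.coord[i],
        )
        for i in range(arr.array_length())
    )
    hetero = tuple(bool(h) for h in arr.hetero)
    return Structure(atoms, hetero)


def _to_atom_array(structure: Structure) -> bts.AtomArray:
    n = len(structure)
    arr = bts.AtomArray(n)
    for i, (a, h) in enumerate(zip(structure.atoms, structure.hetero)):
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.res_name[i] = a.residue_name
        arr.res_id[i] = a.residue_index
        arr.chain_id[i] = a.chain
        arr.hetero[i] = h
        arr.coord[i] = a.coord
    return arr


def read_pdb(path) -> Structure | Trajectory:
    """Read a PDB file; MODEL/ENDMDL blocks become a Trajectory.

    First altloc is kept; HETATM records are retained and flagged.
    Multi-model files get synthetic frame times 0, 1, 2, ... ps unless
    re-timed by the caller.
    """
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        if n_models == 1:
            arr = pdb.get_structure(model=1, altloc="first")
            return _from_atom_array(arr)
        frames = [
            _from_atom_array(pdb.get_structure(model=m, altloc="first"))
            for m in range(1, n_models + 1)
        ]
    except StructureError:
        raise
    except Exception as exc:
        raise StructureError(f"{path}: malformed PDB record ({exc})") from exc
    return Trajectory(tuple(frames), tuple(float(i) for i in range(n_models)))


def write_pdb(obj: Structure | Trajectory, path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL blocks) as PDB."""
    pdb = PDBFile()
    if isinstance(obj, Structure):
        pdb.set_structure(_to_atom_array(obj))
    else:
        stack = bts.stack([_to_atom_array(f) for f in obj.frames])
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Superposition RMSD
# ---------------------------------------------------------------------------


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q (proper, det=+1)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _matched_backbone(ref: Structure, mobile: Structure, selection) -> tuple[np.ndarray, np.ndarray]:
    key = lambda a: (a.chain, a.residue_index, a.name)
    ref_map = {key(a): a for a in ref.atoms if a.name in selection}
    mob_map = {key(a): a for a in mobile.atoms if a.name in selection}
    common = [k for k in ref_map if k in mob_map]
    unmatched = set(ref_map) ^ set(mob_map)
    if unmatched:
        listing = ", ".join(f"{c}/{r}/{n}" for c, r, n in sorted(unmatched)[:10])
        raise AtomMismatchError(f"unmatched atoms between structures: {listing}")
    if len(common) < 3:
        raise StructureError("need at least 3 matched atoms for superposition")
    P = np.array([mob_map[k].coord for k in common])
    Q = np.array([ref_map[k].coord for k in common])
    return P, Q


def backbone_rmsd(ref: Structure, mobile: Structure, selection=BACKBONE) -> float:
    """Minimum RMSD over rigid motions, computed by Kabsch superposition.

    Atoms are matched by (chain, residue_index, name) over ``selection``;
    a mismatch is an error listing the offending atoms.
    """
    P, Q = _matched_backbone(ref, mobile, selection)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff**2).sum() / len(P)))


def rmsd_series(traj: Trajectory, selection=BACKBONE) -> list[tuple[float, float]]:
    """Backbone RMSD of every frame against frame 0; first value is 0."""
    ref = traj.frames[0]
    return [(t, backbone_rmsd(ref, f, selection)) for t, f in zip(traj.times, traj.frames)]


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, right-hand convention, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedDihedralError("three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m @ n2
    ang = -np.degrees(np.arctan2(y, x))  # IUPAC sign: clockwise positive viewed p2->p3
    return 180.0 if ang == -180.0 else float(ang)


def backbone_dihedrals(structure: Structure) -> list[dict]:
    """Per-residue phi/psi/omega where defined (None at chain termini)."""
    residues = structure.residues()
    out = []
    for i, (key, atoms) in enumerate(residues):
        entry = {"key": key, "res_name": next(iter(atoms.values())).residue_name,
                 "phi": None, "psi": None, "omega": None}
        prev_atoms = residues[i - 1][1] if i > 0 else None
        next_atoms = residues[i + 1][1] if i + 1 < len(residues) else None
        have = lambda d, *names: d is not None and all(n in d for n in names)
        if have(prev_atoms, "C") and have(atoms, "N", "CA", "C"):
            entry["phi"] = dihedral(
                prev_atoms["C"].coord, atoms["N"].coord, atoms["CA"].coord, atoms["C"].coord
            )
        if have(atoms, "N", "CA", "C") and have(next_atoms, "N"):
            entry["psi"] = dihedral(
                atoms["N"].coord, atoms["CA"].coord, atoms["C"].coord, next_atoms["N"].coord
            )
        if have(atoms, "CA", "C") and have(next_atoms, "N", "CA"):
            entry["omega"] = dihedral(
                atoms["CA"].coord, atoms["C"].coord, next_atoms["N"].coord, next_atoms["CA"].coord
            )
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

#: Acceptor atom names: carbonyl/carboxyl/hydroxyl O and ring/amide N with
#: lone-pair capacity.
ACCEPTOR_NAMES = {
    "O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
    "ND1", "NE2", "OD", "OE",
}


def _angle_deg(a, b, c) -> float:
    v1 = a - b
    v2 = c - b
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    structure: Structure, d_cut: float = 3.5, angle_cut: float = 120.0
) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    Donors are N/O heavy atoms with a covalently attached hydrogen (within
    1.25 A in the same residue); acceptors are O/N atoms from the name table.
    A bond requires d(D,A) <= ``d_cut`` and, when the hydrogen is present,
    angle(D-H...A) >= ``angle_cut``.  Structures without any hydrogens fall
    back to a heavy-atom distance-only criterion (``angle_DHA`` is None).
    """
    atoms = structure.atoms
    has_h = any(a.element == "H" for a in atoms)

    # attach hydrogens to their heavy donor
    donors: list[tuple[Atom, Atom | None]] = []
    if has_h:
        by_res: dict[tuple[str, int], list[Atom]] = {}
        for a in atoms:
            by_res.setdefault((a.chain, a.residue_index), []).append(a)
        for a in atoms:
            if a.element not in ("N", "O"):
                continue
            for h in by_res.get((a.chain, a.residue_index), ()):
                if h.element == "H" and np.linalg.norm(h.coord - a.coord) <= 1.25:
                    donors.append((a, h))
    else:
        donors = [(a, None) for a in atoms if a.element in ("N", "O")]

    acceptors = [
        a for a in atoms
        if (a.element == "O") or (a.element == "N" and a.name in ACCEPTOR_NAMES)
    ]

    bonds: list[HBond] = []
    for d, h in donors:
        for acc in acceptors:
            if (acc.chain, acc.residue_index) == (d.chain, d.residue_index):
                continue
            dist = float(np.linalg.norm(d.coord - acc.coord))
            if dist > d_cut:
                continue
            if h is not None:
                ang = _angle_deg(d.coord, h.coord, acc.coord)
                if ang < angle_cut:
                    continue
                bonds.append(HBond(d, acc, h, dist, ang))
            else:
                bonds.append(HBond(d, acc, None, dist, None))
    return bonds


def hbond_series(
    traj: Trajectory,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
    donor_chains=None,
    acceptor_chains=None,
) -> list[tuple[float, int]]:
    """Per-frame hydrogen-bond counts, optionally restricted between chain groups.

    When ``donor_chains``/``acceptor_chains`` are given, only bonds whose
    donor and acceptor fall in the respective chain sets (in either
    direction, e.g. ligand-protein) are counted.
    """
    out = []
    for t, frame in zip(traj.times, traj.frames):
        bonds = detect_hbonds(frame, d_cut, angle_cut)
        if donor_chains is not None or acceptor_chains is not None:
            dc = set(donor_chains or [])
            ac = set(acceptor_chains or [])
            bonds = [
                b for b in bonds
                if (b.donor.chain in dc and b.acceptor.chain in ac)
                or (b.donor.chain in ac and b.acceptor.chain in dc)
            ]
        out.append((t, len(bonds)))
    return out
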