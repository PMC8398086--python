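"""Secondary-structure assignment and Ramachandran region accounting.

The assigner is a simplified Kabsch–Sander scheme: backbone hydrogen bonds
are scored with the electrostatic dipole model

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332   [kcal/mol]

and accepted when E < -0.5 kcal/mol.  Helices are runs of i -> i+4 bonds,
sheets are bridge-paired residues, turns are i -> i+3 bonds outside
helices, and everything else is coil — the four classes a typical MD
analysis tool reports (3-10 and pi helices are folded into H).

The Ramachandran map is an owned, versioned coarse rectangle grid over the
(phi, psi) torus with four levels (core / additional / generous /
disallowed) and a widened, symmetric map for glycine.  It is deliberately
coarse: the goal is self-consistent accounting, not replication of any
particular validation server's contour set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .structure import Structure, backbone_dihedrals

logger = logging.getLogger(__name__)

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_COUPLING = 0.084 * 332.0  # q1*q2*f of the Kabsch-Sander dipole model


@dataclass(frozen=True)
class SSFractions:
    """Percentages of helix / sheet / turn / coil; always sums to 100."""

    helix: float
    sheet: float
    turn: float
    coil: float

    def __post_init__(self):
        total = self.helix + self.sheet + self.turn + self.coil
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"fractions must sum to 100, got {total}")


@dataclass(frozen=True)
class RamaSummary:
    """Four-level Ramachandran accounting plus the per-residue classes."""

    core: float
    additional: float
    generous: float
    disallowed: float
    per_residue: tuple[str, ...]
    n_skipped: int = 0

    def __post_init__(self):
        total = self.core + self.additional + self.generous + self.disallowed
        if self.per_residue and abs(total - 100.0) > 1e-6:
            raise ValueError(f"fractions must sum to 100, got {total}")


# ---------------------------------------------------------------------------
# Backbone hydrogen bonds (Kabsch-Sander energy)
# ---------------------------------------------------------------------------


def _place_amide_h(n, ca, c_prev):
    """Geometric amide H: 1.01 A from N, opposite the bisector of its bonds."""
    u = (n - c_prev) / np.linalg.norm(n - c_prev)
    v = (n - ca) / np.linalg.norm(n - ca)
    d = u + v
    return n + 1.01 * d / np.linalg.norm(d)


def backbone_hbond_matrix(structure: Structure) -> tuple[np.ndarray, list]:
    """Boolean matrix hb[i, j]: amide N-H of residue i donates to C=O of j.

    Amide hydrogens are reconstructed geometrically when the file carries
    none (flagged by a log message).  Residues missing N/CA/C/O never bond.
    """
    residues = structure.residues()
    n = len(residues)
    coords = []
    reconstructed = False
    for i, (key, atoms) in enumerate(residues):
        entry = {}
        for name in ("N", "CA", "C", "O"):
            if name in atoms:
                entry[name] = atoms[name].coord
        h = atoms.get("H") or atoms.get("HN")
        if h is not None:
            entry["H"] = h.coord
        elif i > 0 and "N" in entry and "CA" in entry:
            prev = residues[i - 1][1]
            if "C" in prev:
                entry["H"] = _place_amide_h(entry["N"], entry["CA"], prev["C"].coord)
                reconstructed = True
        coords.append(entry)
    if reconstructed:
        logger.info("amide hydrogens reconstructed geometrically for H-bond scoring")

    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):  # donor
        di = coords[i]
        if "N" not in di or "H" not in di:
            continue
        for j in range(n):  # acceptor
            if abs(i - j) < 2:
                continue
            dj = coords[j]
            if "C" not in dj or "O" not in dj:
                continue
            r_on = np.linalg.norm(dj["O"] - di["N"])
            if r_on > 5.2:  # dipole energy can't reach the cutoff beyond this
                continue
            r_ch = np.linalg.norm(dj["C"] - di["H"])
            r_oh = np.linalg.norm(dj["O"] - di["H"])
            r_cn = np.linalg.norm(dj["C"] - di["N"])
            e = _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < HB_ENERGY_CUTOFF:
                hb[i, j] = True
    return hb, residues


def assign_secondary_structure(structure: Structure) -> tuple[list[str], SSFractions]:
    """Per-residue labels in {H, E, T, C} plus the class percentages.

    Chains shorter than 5 residues cannot form the i -> i+4 pattern and are
    assigned all-coil with a warning.
    """
    hb, residues = backbone_hbond_matrix(structure)
    n = len(residues)
    if n < 5:
        warnings.warn("chain shorter than 5 residues: all residues assigned coil")
        labels = ["C"] * n
        return labels, _fractions(labels)

    labels = ["C"] * n

    # helix: two consecutive i+4 -> i bonds mark residues i+1..i+4
    turn4 = [i for i in range(n - 4) if hb[i + 4, i]]
    helix = np.zeros(n, dtype=bool)
    t4set = set(turn4)
    for i in turn4:
        if i + 1 in t4set:
            helix[i + 1 : i + 5] = True

    # bridges (sheet): parallel / antiparallel ladder patterns
    sheet = np.zeros(n, dtype=bool)
    def bond(a, b):  # C=O of a accepts from N-H of b
        return 0 <= a < n and 0 <= b < n and hb[b, a]
    for i in range(n):
        for j in range(i + 3, n):
            parallel = (bond(i - 1, j) and bond(j, i + 1)) or (bond(j - 1, i) and bond(i, j + 1))
            antiparallel = (bond(i, j) and bond(j, i)) or (
                bond(i - 1, j + 1) and bond(j - 1, i + 1)
            )
            if parallel or antiparallel:
                sheet[i] = sheet[j] = True

    # turns: i+3 -> i bond, residues between, unless already helix/sheet
    turn = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        if hb[i + 3, i]:
            turn[i + 1 : i + 3] = True

    for i in range(n):
        if helix[i]:
            labels[i] = "H"
        elif sheet[i]:
            labels[i] = "E"
        elif turn[i]:
            labels[i] = "T"
    return labels, _fractions(labels)


def _fractions(labels: list[str]) -> SSFractions:
    n = max(len(labels), 1)
    counts = {k: labels.count(k) for k in "HETC"}
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    # close the sum exactly on the coil share
    pct["C"] = 100.0 - pct["H"] - pct["E"] - pct["T"]
    return SSFractions(helix=pct["H"], sheet=pct["E"], turn=pct["T"], coil=pct["C"])


# ---------------------------------------------------------------------------
# Ramachandran regions
# ---------------------------------------------------------------------------


def load_region_map() -> dict:
    """Load the shipped four-level rectangle map (see data/rama_map.json)."""
    text = resources.files("specbind").joinpath("data/rama_map.json").read_text()
    return json.loads(text)


def _in_boxes(phi: float, psi: float, boxes) -> bool:
    for pmin, pmax, smin, smax in boxes:
        if pmin <= phi <= pmax and smin <= psi <= smax:
            return True
    return False


def classify_rama(phi: float, psi: float, res_name: str, region_map: dict) -> str:
    key = "GLY" if res_name.upper() == "GLY" else "default"
    levels = region_map[key]
    for level in ("core", "additional", "generous"):
        if _in_boxes(phi, psi, levels[level]):
            return level
    return "disallowed"


def ramachandran_summary(structure: Structure, region_map: dict | None = None) -> RamaSummary:
    """Classify every interior residue's (phi, psi) into the four levels.

    Terminal residues (phi or psi undefined) and residues with missing
    backbone atoms are skipped and tallied, not errors.
    """
    if region_map is None:
        region_map = load_region_map()
    dihedrals = backbone_dihedrals(structure)
    if len(dihedrals) < 3:
        raise ValueError("ramachandran_summary needs >= 3 residues")
    classes: list[str] = []
    skipped = 0
    for entry in dihedrals:
        if entry["phi"] is None or entry["psi"] is None:
            skipped += 1
            continue
        classes.append(classify_rama(entry["phi"], entry["psi"], entry["res_name"], region_map))
    if not classes:
        return RamaSummary(0.0, 0.0, 0.0, 0.0, (), n_skipped=skipped)
    n = len(classes)
    pct = {k: 100.0 * classes.count(k) / n for k in ("core", "additional", "generous", "disallowed")}
    pct["disallowed"] = 100.0 - pct["core"] - pct["additional"] - pct["generous"]
    return RamaSummary(
        core=pct["core"],
        additional=pct["additional"],
        generous=pct["generous"],
        disallowed=pct["disallowed"],
        per_residue=tuple(classes),
        n_skipped=skipped,
    )
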