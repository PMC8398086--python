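"""Synthetic data with known ground truth for every pipeline stage.

No raw spectra or trajectories ship with the package, so each analysis
stage is exercised on data generated from the closed-form laws it is meant
to invert: quenched Gaussian emission peaks for the Stern–Volmer and
double-log fits, exact van't Hoff binding-constant series for the
thermodynamics stage, and ideal poly-alanine chains, rigid motions and
minimal donor/acceptor arrangements for the structural metrics.  Every
generator is a pure function of its parameters and an explicit seed.

Default study conditions mirror a casein–curcumin titration: quencher
concentrations {0, 2, 4, 6, 8, 10} x 1e-6 mol/L, emission grid 300–450 nm
at 1 nm, peak centers 337 nm (pH 7.4) and 334 nm (pH 2.0), binding and
quenching constants of order 1e4 L/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import EmissionSpectrum, TitrationSeries
from .structure import Atom, Structure

R_GAS = 8.314  # J/(mol K)

#: Default quencher concentration grid, mol/L.
DEFAULT_CONCS = tuple(c * 1e-6 for c in (0, 2, 4, 6, 8, 10))
#: Default emission wavelength grid, nm.
DEFAULT_GRID = (300.0, 450.0, 1.0)

DEFAULT_PEAK_CENTER = {7.4: 337.0, 2.0: 334.0}


@dataclass(frozen=True)
class QuenchTruth:
    """Ground truth for one synthetic titration.

    Exactly one of ``Ksv`` (Stern–Volmer mode, F = F0/(1 + Ksv [Q])) or
    ``(Kb, n)`` (double-log mode, F = F0/(1 + Kb [Q]^n)) must be set.  The
    two coincide at n = 1.
    """

    F0_peak: float = 1000.0  # a.u.
    Ksv: float | None = None  # L/mol
    Kb: float | None = None  # L/mol
    n: float | None = None
    lambda_center: float = 337.0  # nm
    sigma: float = 25.0  # nm Gaussian width
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def __post_init__(self):
        sv_mode = self.Ksv is not None
        kb_mode = self.Kb is not None and self.n is not None
        if sv_mode == kb_mode:
            raise ValueError("set exactly one of Ksv or (Kb, n)")
        if self.F0_peak <= 0 or self.sigma <= 0 or self.noise_sd < 0:
            raise ValueError("F0_peak, sigma must be > 0 and noise_sd >= 0")

    def quench_factor(self, conc: float) -> float:
        """F/F0 at quencher concentration ``conc`` under the active law."""
        if self.Ksv is not None:
            return 1.0 / (1.0 + self.Ksv * conc)
        return 1.0 / (1.0 + self.Kb * conc**self.n)


@dataclass(frozen=True)
class ThermoTruth:
    """Ground-truth enthalpy/entropy for a van't Hoff series."""

    dH: float  # kJ/mol
    dS: float  # J/(mol K)
    temperatures: tuple[float, ...] = (298.0, 305.0, 312.0)

    def __post_init__(self):
        if len(set(self.temperatures)) < 2:
            raise ValueError("need >= 2 distinct temperatures")


def generate_emission_titration(
    truth: QuenchTruth,
    concs=DEFAULT_CONCS,
    T: float = 298.0,
    pH: float = 7.4,
    grid=DEFAULT_GRID,
    blank_level: float = 0.0,
) -> TitrationSeries:
    """Generate a titration of Gaussian emission spectra under ``truth``.

    Each spectrum is a Gaussian of width ``truth.sigma`` centered at
    ``truth.lambda_center`` whose amplitude follows the quenching law;
    additive Gaussian noise of sd ``truth.noise_sd`` is drawn from a stream
    seeded by ``truth.seed``, so ``noise_sd = 0`` is bit-reproducible.
    ``blank_level > 0`` attaches a constant buffer blank added to every
    spectrum.
    """
    concs = list(concs)
    if concs[0] != 0.0:
        raise ValueError("first concentration must be 0 (the F0 reference)")
    if not all(a < b for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be ascending")
    lo, hi, step = grid
    wl = np.arange(lo, hi + 0.5 * step, step)
    rng = np.random.default_rng(truth.seed)
    spectra = []
    for c in concs:
        amp = truth.F0_peak * truth.quench_factor(c)
        y = amp * np.exp(-0.5 * ((wl - truth.lambda_center) / truth.sigma) ** 2)
        y = y + blank_level
        if truth.noise_sd > 0:
            y = y + rng.normal(0.0, truth.noise_sd, size=wl.size)
        spectra.append(
            EmissionSpectrum(wavelengths=wl, intensities=y, temperature=T, pH=pH, quencher_conc=c)
        )
    blank = None
    if blank_level > 0:
        blank = EmissionSpectrum(
            wavelengths=wl,
            intensities=np.full(wl.size, blank_level),
            temperature=T,
            pH=pH,
            quencher_conc=0.0,
        )
    return TitrationSeries(spectra=tuple(spectra), blank=blank)


def generate_kb_series(truth: ThermoTruth) -> list[tuple[float, float]]:
    """Exact binding constants Kb(T) = exp(-dH/(R T) + dS/R).

    ``dH`` enters in kJ/mol and is converted to J/mol internally; the output
    is exactly log-linear in 1/T, so a van't Hoff fit recovers the truth to
    rounding error.
    """
    dh_j = truth.dH * 1000.0
    return [
        (T, float(np.exp(-dh_j / (R_GAS * T) + truth.dS / R_GAS)))
        for T in truth.temperatures
    ]


# ---------------------------------------------------------------------------
# Structural fixtures
# ---------------------------------------------------------------------------

# standard backbone geometry (angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_N_H = 120.8, 119.0


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF internal-to-Cartesian placement of atom d bonded to c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_chain(
    n_res: int, phi: float, psi: float, omega: float = 180.0, chain: str = "A"
) -> Structure:
    """Poly-alanine backbone (N, CA, C, O, amide H) at uniform (phi, psi, omega).

    Built by sequential internal-to-Cartesian placement with standard bond
    lengths and angles; every residue receives the requested torsions, so a
    helix (-57, -47), a beta strand (-120, 120) or any other conformation
    can be produced on demand for the structural metrics.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    atoms: list[Atom] = []

    def add(name, element, res_idx, coord):
        atoms.append(Atom(name, element, "ALA", res_idx, chain, np.asarray(coord, float)))

    # residue 1 seed frame: N at origin, CA on x, C in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])

    prev = {"N": n0, "CA": ca0, "C": c0}
    add("N", "N", 1, n0)
    add("CA", "C", 1, ca0)
    add("C", "C", 1, c0)

    for i in range(2, n_res + 1):
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        # carbonyl O of the previous residue: trans to the new N across C
        o_prev = _place(prev["N"], prev["CA"], prev["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        add("O", "O", i - 1, o_prev)
        # amide H of the new residue: anti to the previous carbonyl O
        h_i = _place(o_prev, prev["C"], n_i, _B_N_H, _A_C_N_H, 180.0)
        add("N", "N", i, n_i)
        add("H", "H", i, h_i)
        add("CA", "C", i, ca_i)
        add("C", "C", i, c_i)
        prev = {"N": n_i, "CA": ca_i, "C": c_i}

    # terminal carbonyl O (same psi convention keeps geometry uniform)
    o_last = _place(prev["N"], prev["CA"], prev["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    add("O", "O", n_res, o_last)

    order = {"N": 0, "H": 1, "CA": 2, "C": 3, "O": 4}
    atoms.sort(key=lambda a: (a.residue_index, order[a.name]))
    return Structure(tuple(atoms))


def euler_rotation(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix from z-y-x intrinsic Euler angles in degrees."""
    a, b, g = np.radians([alpha, beta, gamma])
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[1, 0, 0], [0, np.cos(g), -np.sin(g)], [0, np.sin(g), np.cos(g)]])
    return rz @ ry @ rx


def apply_rigid_motion(
    structure: Structure,
    rotation=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Rotate (Euler degrees, about the origin), translate, optionally jitter.

    Jitter is per-atom isotropic Gaussian displacement drawn under ``seed``;
    with ``jitter_sd = 0`` the motion is exactly rigid and superposition
    RMSD against the input is zero.
    """
    R = euler_rotation(*rotation)
    coords = structure.coords @ R.T + np.asarray(translation, float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
    return structure.with_coords(coords)


def make_antiparallel_sheet(
    n_res: int = 8,
    spacing: float = 4.85,
    registry_shift: float = 1.15,
    phi: float = -139.0,
    psi: float = 135.0,
) -> Structure:
    """Two antiparallel extended strands forming an idealized beta-sheet.

    The second strand is the first rotated 180 degrees about an in-plane
    axis perpendicular to the strand direction, offset by ``spacing``
    (angstrom, the canonical inter-strand distance is about 4.85) across
    the sheet and by ``registry_shift`` along the strand so the backbone
    N-H and C=O groups line up for inter-strand hydrogen bonding.  The
    default registry shift was calibrated once against the dipole H-bond
    criterion of the secondary-structure assigner.
    """
    s1 = build_ideal_chain(n_res, phi, psi, 180.0, chain="A")
    cas = np.array([a.coord for a in s1.atoms if a.name == "CA"])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    center = cas.mean(axis=0)
    tmp = np.array([0.0, 0.0, 1.0])
    perp1 = tmp - (tmp @ axis) * axis
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)

    a = np.pi  # 180 deg rotation about perp1 (Rodrigues)
    K = np.array(
        [[0, -perp1[2], perp1[1]], [perp1[2], 0, -perp1[0]], [-perp1[1], perp1[0], 0]]
    )
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    shift = spacing * perp2 + registry_shift * axis
    coords2 = (s1.coords - center) @ R.T + center + shift
    atoms2 = tuple(
        Atom(at.name, at.element, at.residue_name, at.residue_index + n_res, "B", c)
        for at, c in zip(s1.atoms, coords2)
    )
    return Structure(s1.atoms + atoms2)


def make_hbond_fixture(d_DA: float, angle_DHA: float) -> Structure:
    """Minimal N-H donor / C=O acceptor pair at exact distance and angle.

    Residue 1 carries the carbonyl acceptor, residue 2 the amide donor.
    Raises when no acceptor position realizes the requested (d_DA,
    angle_DHA) with an N-H bond of 1.01 A.
    """
    if d_DA <= 0 or not (0 < angle_DHA <= 180):
        raise ValueError("need d_DA > 0 and 0 < angle_DHA <= 180")
    r = _B_N_H
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([r, 0.0, 0.0])
    alpha = np.radians(180.0 - angle_DHA)
    # acceptor at H + t*(cos a, sin a, 0); |N - A| = d_DA
    ca_, cb, cc = 1.0, 2 * r * np.cos(alpha), r**2 - d_DA**2
    disc = cb**2 - 4 * ca_ * cc
    if disc < 0:
        raise ValueError("geometrically infeasible distance/angle combination")
    t = (-cb + np.sqrt(disc)) / 2
    if t <= 0:
        raise ValueError("geometrically infeasible distance/angle combination")
    o = h + t * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    # carbonyl C behind O, away from the donor
    away = o - n
    away /= np.linalg.norm(away)
    c = o + _B_C_O * away

    atoms = (
        Atom("C", "C", "GLY", 1, "A", c),
        Atom("O", "O", "GLY", 1, "A", o),
        Atom("N", "N", "GLY", 2, "A", n),
        Atom("H", "H", "GLY", 2, "A", h),
        Atom("CA", "C", "GLY", 2, "A", np.array([-0.5, -1.3, 0.0])),
    )
    return Structure(atoms)
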