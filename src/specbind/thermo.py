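"""Van't Hoff thermodynamics, driving-force classification, docking-energy
to dissociation-constant conversion.

Stage 2 of the inference chain.  Binding constants measured at two or more
temperatures are fit by ordinary least squares on the linear van't Hoff
form

    ln Kb = -dH/(R T) + dS/R,        R = 8.314 J/(mol K),

giving dH = -R * slope and dS = R * intercept; Gibbs energies follow from
dG = dH - T dS at each input temperature (dH carried in kJ/mol, dS in
J/(mol K), arithmetic done in J to keep the units honest).  The signs of
(dH, dS) classify the dominant interaction by the usual rules: negative dH
with positive dS points at electrostatics, both positive at hydrophobic
contacts, both negative at hydrogen bonding / van der Waals.

Docking scores are related to dissociation constants by Kd = exp(Eb/(R'T))
with R' in kcal/(mol K) — the convention docking engines use to print a Kd
next to a binding energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

R_GAS = 8.314  # J/(mol K)
R_KCAL = 1.987207e-3  # kcal/(mol K)

logger = logging.getLogger(__name__)


class DrivingForce(str, Enum):
    ELECTROSTATIC = "electrostatic"
    HYDROPHOBIC = "hydrophobic"
    HBOND_VDW = "hbond_vdw"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ThermoResult:
    dH: float  # kJ/mol
    dS: float  # J/(mol K)
    dH_se: float
    dS_se: float
    dG: dict  # T (K) -> kJ/mol
    r2: float
    driving_force: DrivingForce


@dataclass(frozen=True)
class DockPose:
    """One docking pose: score, derived dissociation constant, contact count."""

    Eb: float  # kcal/mol
    Kd: float  # mol/L
    contacts: int = 0

    def __post_init__(self):
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")


def gibbs_energy(dH: float, dS: float, T: float) -> float:
    """dG = dH - T dS with dH in kJ/mol and dS in J/(mol K); result kJ/mol."""
    if T <= 0:
        raise ValueError("T must be positive (kelvin)")
    return dH - T * dS / 1000.0


def classify_driving_force(dH: float, dS: float) -> DrivingForce:
    """Sign-rule classification of the dominant interaction; zero signs are
    indeterminate and map to unclassified.  Total: every pair gets a class."""
    if dH < 0 and dS > 0:
        return DrivingForce.ELECTROSTATIC
    if dH > 0 and dS > 0:
        return DrivingForce.HYDROPHOBIC
    if dH < 0 and dS < 0:
        return DrivingForce.HBOND_VDW
    return DrivingForce.UNCLASSIFIED


def fit_vant_hoff(points, weights=None) -> ThermoResult:
    """OLS of ln Kb on 1/T; dH = -R*slope (kJ/mol), dS = R*intercept.

    ``points`` is an iterable of (T in K, Kb in L/mol).  An optional
    ``weights`` vector enables a weighted fit (e.g. from Kb standard
    errors); the default is the unweighted fit appropriate to small
    temperature series.
    """
    pts = [(float(t), float(k)) for t, k in points]
    if any(k <= 0 for _, k in pts):
        raise ValueError("all Kb must be positive")
    temps = [t for t, _ in pts]
    if len(set(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    x = np.array([1.0 / t for t, _ in pts])
    y = np.array([np.log(k) for _, k in pts])

    if weights is not None:
        w = np.asarray(weights, float)
        W = w / w.sum()
        xb, yb = (W * x).sum(), (W * y).sum()
        sxx = (W * (x - xb) ** 2).sum()
        slope = float((W * (x - xb) * (y - yb)).sum() / sxx)
        intercept = float(yb - slope * xb)
        resid = y - intercept - slope * x
        dof = max(len(x) - 2, 1)
        s2 = float((W * resid**2).sum() * len(x) / dof)
        slope_se = float(np.sqrt(s2 / (len(x) * sxx)))
        intercept_se = float(np.sqrt(s2 * (1.0 / len(x) + xb**2 / (len(x) * sxx))))
        ss_tot = float((W * (y - yb) ** 2).sum())
        r2 = 1.0 - float((W * resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    else:
        if len(pts) == 2:
            # exact two-point line; SEs undefined
            slope = float((y[1] - y[0]) / (x[1] - x[0]))
            intercept = float(y[0] - slope * x[0])
            slope_se = intercept_se = float("nan")
            r2 = 1.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
            slope_se, intercept_se = float(fit.stderr), float(fit.intercept_stderr)
            r2 = float(fit.rvalue**2)

    dh_kj = -R_GAS * slope / 1000.0
    ds = R_GAS * intercept
    dg = {t: gibbs_energy(dh_kj, ds, t) for t in sorted(set(temps))}
    return ThermoResult(
        dH=dh_kj,
        dS=ds,
        dH_se=R_GAS * slope_se / 1000.0,
        dS_se=R_GAS * intercept_se,
        dG=dg,
        r2=min(max(r2, 0.0), 1.0) if np.isfinite(r2) else r2,
        driving_force=classify_driving_force(dh_kj, ds),
    )


def eb_to_kd(Eb: float, T: float = 298.15) -> float:
    """Dissociation constant (mol/L) from a docking binding energy (kcal/mol).

    Kd = exp(Eb/(R'T)): Eb = 0 gives 1 mol/L, more negative energies give
    tighter (smaller) Kd, and the map is strictly increasing and
    multiplicative in Eb at fixed T.
    """
    if T <= 0:
        raise ValueError("T must be positive (kelvin)")
    return float(np.exp(Eb / (R_KCAL * T)))


def run_thermo_stage(binding_results: dict) -> dict:
    """One van't Hoff fit per pH from a {(pH, T): BindingResult-or-Kb} map.

    Values may be BindingResult objects (their ``Kb`` attribute is used) or
    bare Kb floats.  A pH with fewer than two temperatures is skipped with a
    logged warning.
    """
    by_ph: dict[float, list[tuple[float, float]]] = {}
    for (ph, t), res in binding_results.items():
        kb = getattr(res, "Kb", res)
        by_ph.setdefault(ph, []).append((float(t), float(kb)))
    out: dict[float, ThermoResult] = {}
    for ph, pts in sorted(by_ph.items()):
        if len({t for t, _ in pts}) < 2:
            logger.warning("pH %.2f has a single temperature; van't Hoff fit skipped", ph)
            continue
        out[ph] = fit_vant_hoff(sorted(pts))
    return out
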