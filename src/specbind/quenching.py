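"""Stern–Volmer quenching analysis and double-log binding fits.

Stage 1 of the inference chain.  The quenching ratio F0/F against quencher
concentration [Q] is fit by ordinary least squares,

    F0/F = 1 + Ksv [Q],        Kq = Ksv / tau0,

and the bimolecular quenching rate Kq is compared with the diffusion-limited
maximum (about 2e10 L/(mol s)) to classify the mechanism: well above means a
ground-state complex (static quenching), well below means collisional
(dynamic).  Binding constant and apparent site number come from the
double-logarithmic plot,

    log10((F0 - F)/F) = log10 Kb + n log10 [Q].

Both models are linear in their transformed variables, so noiseless
generator output is recovered exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .spectra import TitrationSeries, extract_peak, subtract_blank

logger = logging.getLogger(__name__)

DEFAULT_TAU0 = 1e-8  # s, fluorophore lifetime without quencher
DIFFUSION_LIMIT = 2.0e10  # L/(mol s), maximum collisional quenching rate


class Mechanism(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


class QuenchingAbsentError(ValueError):
    """The titration shows no quenching (non-positive Stern-Volmer slope)."""


@dataclass(frozen=True)
class QuenchingResult:
    Ksv: float  # L/mol
    Ksv_se: float
    Kq: float  # L/(mol s)
    tau0: float  # s
    intercept: float  # diagnostic; ~1 for clean data
    r2: float
    mechanism: Mechanism


@dataclass(frozen=True)
class BindingResult:
    Kb: float  # L/mol
    n: float
    log10Kb_se: float
    n_se: float
    r2: float

    @property
    def stoichiometry(self) -> int:
        return int(round(self.n))


def _peak_intensities(series: TitrationSeries, window: float = 2.0):
    peaks = [extract_peak(s, window=window) for s in series.spectra]
    F = np.array([p.intensity for p in peaks])
    Q = series.concentrations
    return Q, F


def fit_stern_volmer(
    series: TitrationSeries,
    tau0: float = DEFAULT_TAU0,
    constrained_intercept: bool = False,
    threshold: float = DIFFUSION_LIMIT,
    peak_window: float = 2.0,
) -> QuenchingResult:
    """OLS fit of F0/F against [Q]; slope is Ksv, Kq = Ksv/tau0.

    The intercept is free by default and reported as a diagnostic (clean
    data gives ~1); ``constrained_intercept=True`` forces the literal
    one-parameter law through (0, 1).  A slope negative beyond two standard
    errors raises :class:`QuenchingAbsentError`.
    """
    Q, F = _peak_intensities(series, window=peak_window)
    if len(Q) < 3:
        raise ValueError("need >= 3 concentrations for a Stern-Volmer fit")
    F0 = F[0]
    y = F0 / F

    if constrained_intercept:
        x = Q
        slope = float(((y - 1.0) @ x) / (x @ x))
        resid = y - 1.0 - slope * x
        dof = max(len(x) - 1, 1)
        se = float(np.sqrt((resid @ resid) / dof / (x @ x)))
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid @ resid)) / ss_tot if ss_tot > 0 else 1.0
        intercept = 1.0
    else:
        fit = stats.linregress(Q, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        se = float(fit.stderr)
        r2 = float(fit.rvalue**2)

    if slope <= 0 and (se == 0 or slope < -2 * se) or np.allclose(y, y[0]):
        raise QuenchingAbsentError(
            f"no quenching detected: Stern-Volmer slope {slope:.3g} +- {se:.3g}"
        )
    kq = slope / tau0
    mech = classify_mechanism_values(kq, se / tau0, threshold)
    return QuenchingResult(
        Ksv=slope, Ksv_se=se, Kq=kq, tau0=tau0, intercept=intercept, r2=min(max(r2, 0.0), 1.0),
        mechanism=mech,
    )


def classify_mechanism_values(
    kq: float, kq_se: float = 0.0, threshold: float = DIFFUSION_LIMIT
) -> Mechanism:
    """Static above the diffusion limit, dynamic below, indeterminate within 1 SE."""
    if abs(kq - threshold) <= kq_se or kq == threshold:
        return Mechanism.INDETERMINATE
    return Mechanism.STATIC if kq > threshold else Mechanism.DYNAMIC


def classify_mechanism(result: QuenchingResult, threshold: float = DIFFUSION_LIMIT) -> Mechanism:
    return classify_mechanism_values(result.Kq, result.Ksv_se / result.tau0, threshold)


def fit_double_log(series: TitrationSeries, peak_window: float = 2.0) -> BindingResult:
    """OLS fit of log10((F0-F)/F) against log10 [Q].

    The zero-concentration point only supplies F0 and is excluded from the
    regression.  Any nonzero concentration with F >= F0 makes the left side
    undefined and is reported as an error naming the concentration.
    """
    Q, F = _peak_intensities(series, window=peak_window)
    F0 = F[0]
    Qn, Fn = Q[1:], F[1:]
    if len(Qn) < 3:
        raise ValueError("need >= 3 nonzero concentrations for a double-log fit")
    bad = Qn[Fn >= F0]
    if bad.size:
        raise ValueError(
            f"F >= F0 at quencher concentration(s) {', '.join(f'{b:g}' for b in bad)} mol/L; "
            "double-log transform undefined"
        )
    y = np.log10((F0 - Fn) / Fn)
    x = np.log10(Qn)
    fit = stats.linregress(x, y)
    return BindingResult(
        Kb=float(10.0**fit.intercept),
        n=float(fit.slope),
        log10Kb_se=float(fit.intercept_stderr),
        n_se=float(fit.stderr),
        r2=float(fit.rvalue**2),
    )


def analyze_titration(
    series: TitrationSeries,
    tau0: float = DEFAULT_TAU0,
    constrained_intercept: bool = False,
    threshold: float = DIFFUSION_LIMIT,
    peak_window: float = 2.0,
) -> tuple[QuenchingResult, BindingResult]:
    """Full stage-1 analysis: blank subtraction, peak extraction, both fits."""
    if series.blank is not None:
        series = subtract_blank(series)
    if len(series.spectra) <= 4:
        warnings.warn("titration has only a minimal number of points; fits are fragile")
    q = fit_stern_volmer(
        series, tau0=tau0, constrained_intercept=constrained_intercept,
        threshold=threshold, peak_window=peak_window,
    )
    b = fit_double_log(series, peak_window=peak_window)
    logger.info(
        "titration pH %.1f T %.0f K: Ksv=%.4g Kq=%.4g (%s), Kb=%.4g n=%.3f",
        series.pH, series.temperature, q.Ksv, q.Kq, q.mechanism.value, b.Kb, b.n,
    )
    return q, b
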