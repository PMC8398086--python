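"""Titration spectroscopy data model and I/O.

A fluorescence titration records the emission spectrum of a fixed protein
solution at a series of quencher (ligand) concentrations, all at one
temperature and pH.  The zero-concentration spectrum supplies the unquenched
intensity F0; the peak intensity of each subsequent spectrum supplies F.
Files are long-format delimited text with one row per
(concentration, wavelength) pair, so column order and row order carry no
information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved quencher_conc_M value marking buffer-blank rows in titration files.
BLANK_SENTINEL = -1.0

#: Exact header expected in titration files (long format).
TITRATION_COLUMNS = ["wavelength_nm", "intensity", "quencher_conc_M", "temperature_K", "pH"]


class SpectraError(ValueError):
    """Base error for titration data problems."""


class SchemaError(SpectraError):
    """File does not match the expected column schema."""


class ValidationError(SpectraError):
    """Data violates a titration-series invariant."""


class DegeneratePeakError(SpectraError):
    """Spectrum has no unique maximum (flat after smoothing)."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """One spectrum: intensity (a.u.) versus wavelength (nm).

    ``kind`` distinguishes fluorescence emission from UV-Vis absorbance;
    both share the same container.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    temperature: float  # K
    pH: float
    quencher_conc: float  # mol/L
    kind: str = "emission"  # "emission" | "absorbance"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValidationError("wavelengths and intensities must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValidationError("intensities must be finite")
        if self.quencher_conc < 0 and self.quencher_conc != BLANK_SENTINEL:
            raise ValidationError("quencher_conc must be >= 0")
        if self.kind not in ("emission", "absorbance"):
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")

    def __eq__(self, other):
        if not isinstance(other, EmissionSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.intensities, other.intensities)
            and (self.temperature, self.pH, self.quencher_conc, self.kind)
            == (other.temperature, other.pH, other.quencher_conc, other.kind)
        )


@dataclass(frozen=True)
class PeakReading:
    """Location and height of a spectral peak."""

    lambda_max: float  # nm
    intensity: float  # a.u.
    at_boundary: bool = False  # True when the maximum sat on the grid edge


@dataclass(frozen=True)
class TitrationSeries:
    """Emission spectra at ascending quencher concentrations, fixed T and pH.

    Invariants: at least 3 non-blank spectra, first at zero concentration
    (the F0 reference), all on one wavelength grid at one (T, pH).
    """

    spectra: tuple[EmissionSpectrum, ...]
    blank: EmissionSpectrum | None = None
    protein_conc: float = 0.2  # g/L

    def __post_init__(self):
        object.__setattr__(self, "spectra", tuple(self.spectra))
        sp = self.spectra
        if len(sp) < 3:
            raise ValidationError("a titration series needs >= 3 spectra")
        concs = [s.quencher_conc for s in sp]
        if concs[0] != 0.0:
            raise ValidationError(
                "first spectrum must have quencher_conc = 0 (the F0 reference)"
            )
        if not all(a < b for a, b in zip(concs, concs[1:])):
            raise ValidationError("quencher concentrations must be distinct and ascending")
        t0, ph0 = sp[0].temperature, sp[0].pH
        grid = sp[0].wavelengths
        for s in sp[1:]:
            if s.temperature != t0 or s.pH != ph0:
                raise ValidationError("all spectra in a series must share T and pH")
            if not np.array_equal(s.wavelengths, grid):
                raise ValidationError("all spectra must share one wavelength grid")
        if self.blank is not None and not np.array_equal(self.blank.wavelengths, grid):
            raise ValidationError("blank must share the series wavelength grid")

    @property
    def temperature(self) -> float:
        return self.spectra[0].temperature

    @property
    def pH(self) -> float:
        return self.spectra[0].pH

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.quencher_conc for s in self.spectra])


def load_titration(path, sep: str = ",") -> TitrationSeries:
    """Read a long-format titration file into a :class:`TitrationSeries`.

    The file must carry the header ``wavelength_nm,intensity,quencher_conc_M,
    temperature_K,pH``; lines starting with ``#`` are comments.  Rows with
    ``quencher_conc_M`` equal to the ``-1`` sentinel form the buffer blank.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"titration file missing column(s): {', '.join(missing)}")

    if df["temperature_K"].nunique() != 1:
        raise ValidationError("titration file mixes temperatures; one T per file")
    if df["pH"].nunique() != 1:
        raise ValidationError("titration file mixes pH values; one pH per file")
    dup = df.duplicated(subset=["quencher_conc_M", "wavelength_nm"])
    if dup.any():
        raise ValidationError("duplicate (concentration, wavelength) rows in titration file")

    temperature = float(df["temperature_K"].iloc[0])
    ph = float(df["pH"].iloc[0])

    blank = None
    spectra = []
    for conc, group in df.groupby("quencher_conc_M", sort=True):
        group = group.sort_values("wavelength_nm")
        spec = EmissionSpectrum(
            wavelengths=group["wavelength_nm"].to_numpy(float),
            intensities=group["intensity"].to_numpy(float),
            temperature=temperature,
            pH=ph,
            quencher_conc=float(conc),
        )
        if conc == BLANK_SENTINEL:
            blank = spec
        else:
            spectra.append(spec)

    if not spectra or spectra[0].quencher_conc != 0.0:
        raise ValidationError(
            "titration file lacks the zero-concentration spectrum that supplies F0"
        )
    return TitrationSeries(spectra=tuple(spectra), blank=blank)


def write_titration(series: TitrationSeries, path, sep: str = ",") -> None:
    """Write a series so that :func:`load_titration` reads back an equal one.

    Numerics go out at 12 significant digits, enough for a bit-stable
    text round trip of measurement-scale values.
    """
    rows = []
    everything = list(series.spectra)
    if series.blank is not None:
        everything.append(replace(series.blank, quencher_conc=BLANK_SENTINEL))
    for spec in everything:
        for wl, it in zip(spec.wavelengths, spec.intensities):
            rows.append((wl, it, spec.quencher_conc, spec.temperature, spec.pH))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# blank rows use quencher_conc_M = {BLANK_SENTINEL:g}\n")
        fh.write(",".join(TITRATION_COLUMNS).replace(",", sep) + "\n")
        for row in rows:
            fh.write(sep.join(f"{v:.12g}" for v in row) + "\n")


def subtract_blank(series: TitrationSeries) -> TitrationSeries:
    """Subtract the buffer blank from every spectrum, point by point.

    Without a blank this is a logged no-op; the blank is dropped from the
    returned series.
    """
    if series.blank is None:
        logger.warning("subtract_blank: series has no blank; returning input unchanged")
        return series
    corrected = tuple(
        replace(s, intensities=s.intensities - series.blank.intensities)
        for s in series.spectra
    )
    return TitrationSeries(spectra=corrected, blank=None, protein_conc=series.protein_conc)


def _moving_average(y: np.ndarray, half_width_pts: int) -> np.ndarray:
    if half_width_pts <= 0:
        return y
    w = 2 * half_width_pts + 1
    kernel = np.ones(w) / w
    # reflect-pad so edges keep full support
    padded = np.concatenate([y[half_width_pts:0:-1], y, y[-2 : -half_width_pts - 2 : -1]])
    return np.convolve(padded, kernel, mode="valid")


def extract_peak(
    spectrum: EmissionSpectrum, window: float = 2.0, tie_tol: float = 1e-12
) -> PeakReading:
    """Locate the spectral maximum with smoothing and parabolic refinement.

    The spectrum is smoothed by a centered moving average of half-width
    ``window`` (nm); the maximum is refined by a 3-point parabola through the
    smoothed neighbours.  Ties beyond ``tie_tol`` relative spread raise
    :class:`DegeneratePeakError`; a maximum on the grid edge is returned
    unrefined with ``at_boundary=True``.
    """
    wl, y = spectrum.wavelengths, spectrum.intensities
    if wl.size < 5:
        raise ValidationError("extract_peak needs >= 5 points")
    if window < 0:
        raise ValidationError("window must be >= 0")
    step = float(np.median(np.diff(wl)))
    half_pts = int(round(window / step))
    ys = _moving_average(y, half_pts)

    ymax = ys.max()
    span = ys.max() - ys.min()
    if span <= tie_tol * max(abs(ymax), 1.0):
        raise DegeneratePeakError("spectrum is flat after smoothing; no unique peak")
    candidates = np.flatnonzero(ys >= ymax - tie_tol * max(abs(ymax), 1.0))
    i = int(candidates[0])  # lowest wavelength among exact ties

    if i == 0 or i == ys.size - 1:
        return PeakReading(float(wl[i]), float(ys[i]), at_boundary=True)

    # 3-point parabolic interpolation on the smoothed curve
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return PeakReading(float(wl[i]), float(y1))
    delta = 0.5 * (y0 - y2) / denom
    lam = wl[i] + delta * (wl[i + 1] - wl[i])
    height = y1 - 0.25 * (y0 - y2) * delta
    return PeakReading(float(lam), float(height))


def uv_absorption_peaks(
    spectrum: EmissionSpectrum,
    expected: list[float],
    reference: EmissionSpectrum | None = None,
    search_window: float = 10.0,
) -> tuple[dict[float, PeakReading | None], bool | None]:
    """Find absorbance peaks near expected positions; flag hyperchromicity.

    For each expected wavelength the local maximum within ``search_window``
    nm is reported, or ``None`` when no interior local maximum exists there
    (an expected position outside the scanned range is simply missing, not an
    error).  When a lower-concentration ``reference`` spectrum is supplied the
    hyperchromicity flag records whether absorbance rose at the first found
    peak; otherwise the flag is ``None``.
    """
    if spectrum.kind != "absorbance":
        warnings.warn("uv_absorption_peaks called on a non-absorbance spectrum")
    wl, y = spectrum.wavelengths, spectrum.intensities
    found: dict[float, PeakReading | None] = {}
    for pos in expected:
        mask = np.abs(wl - pos) <= search_window
        if not mask.any():
            found[pos] = None
            continue
        idx = np.flatnonzero(mask)
        j = idx[np.argmax(y[idx])]
        # require an interior local maximum
        if 0 < j < wl.size - 1 and y[j] >= y[j - 1] and y[j] >= y[j + 1]:
            sub = EmissionSpectrum(
                wavelengths=wl,
                intensities=y,
                temperature=spectrum.temperature,
                pH=spectrum.pH,
                quencher_conc=max(spectrum.quencher_conc, 0.0),
                kind="absorbance",
            )
            try:
                # refine within the window only: parabolic step around j
                y0, y1, y2 = y[j - 1], y[j], y[j + 1]
                denom = y0 - 2 * y1 + y2
                delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
                lam = wl[j] + delta * (wl[min(j + 1, wl.size - 1)] - wl[j])
                found[pos] = PeakReading(float(lam), float(y1))
            except DegeneratePeakError:
                found[pos] = None
        else:
            found[pos] = None

    hyperchromic: bool | None = None
    if reference is not None:
        for pos, peak in found.items():
            if peak is None:
                continue
            ref_here = float(np.interp(peak.lambda_max, reference.wavelengths, reference.intensities))
            hyperchromic = peak.intensity > ref_here
            break
    return found, hyperchromic
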