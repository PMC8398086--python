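"""Titration I/O, blank handling and peak extraction."""

import numpy as np
import pytest
from dataclasses import replace

import specbind as sb
from specbind.spectra import (
    DegeneratePeakError,
    SchemaError,
    ValidationError,
    _moving_average,
)


def _gaussian_spectrum(center, conc=0.0, amp=1000.0, T=298.0, pH=7.4, kind="emission",
                       lo=300.0, hi=450.0):
    wl = np.arange(lo, hi + 0.5, 1.0)
    y = amp * np.exp(-0.5 * ((wl - center) / 25.0) ** 2)
    return sb.EmissionSpectrum(wl, y, temperature=T, pH=pH, quencher_conc=conc, kind=kind)


class TestRoundTrip:
    def test_write_then_load_is_identity(self, tmp_path, kbn_series):
        _, series = kbn_series
        path = tmp_path / "titr.csv"
        sb.write_titration(series, path)
        back = sb.load_titration(path)
        assert len(back.spectra) == len(series.spectra)
        # identity at the 12-significant-digit text precision
        for a, b in zip(series.spectra, back.spectra):
            np.testing.assert_array_equal(a.wavelengths, b.wavelengths)
            np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-11)
            assert b.quencher_conc == pytest.approx(a.quencher_conc, rel=1e-11)
            assert (a.temperature, a.pH) == (b.temperature, b.pH)
        assert back.blank is None

    def test_blank_survives_round_trip(self, tmp_path):
        spectra = [_gaussian_spectrum(337, c) for c in (0.0, 2e-6, 4e-6)]
        blank = replace(_gaussian_spectrum(337, 0.0, amp=5.0))
        series = sb.TitrationSeries(spectra, blank=blank)
        path = tmp_path / "t.csv"
        sb.write_titration(series, path)
        back = sb.load_titration(path)
        assert back.blank is not None
        np.testing.assert_allclose(back.blank.intensities, blank.intensities, rtol=1e-11)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,intensity\n300,1\n301,2\n")
        with pytest.raises(SchemaError, match="quencher_conc_M"):
            sb.load_titration(p)

    def test_missing_zero_concentration_names_f0(self, tmp_path, kbn_series):
        _, series = kbn_series
        path = tmp_path / "t.csv"
        sb.write_titration(sb.TitrationSeries(series.spectra), path)
        text = "\n".join(
            line for line in path.read_text().splitlines()
            if not line.split(",")[2:3] == ["0"]
        )
        path.write_text(text)
        with pytest.raises(ValidationError, match="F0"):
            sb.load_titration(path)

    def test_mixed_temperature_rejected(self, tmp_path):
        p = tmp_path / "mixed.csv"
        rows = ["wavelength_nm,intensity,quencher_conc_M,temperature_K,pH"]
        for t, c in ((298, 0.0), (305, 2e-6), (298, 4e-6)):
            for wl in range(300, 306):
                rows.append(f"{wl},{100 - wl % 7},{c},{t},7.4")
        p.write_text("\n".join(rows))
        with pytest.raises(ValidationError, match="temperature"):
            sb.load_titration(p)


class TestSeriesInvariants:
    def test_requires_three_spectra(self):
        with pytest.raises(ValidationError):
            sb.TitrationSeries([_gaussian_spectrum(337, 0.0), _gaussian_spectrum(337, 1e-6)])

    def test_requires_zero_first(self):
        spectra = [_gaussian_spectrum(337, c) for c in (1e-6, 2e-6, 3e-6)]
        with pytest.raises(ValidationError, match="F0"):
            sb.TitrationSeries(spectra)


class TestSubtractBlank:
    def test_constant_blank_shifts_intensities(self):
        spectra = [_gaussian_spectrum(337, c) for c in (0.0, 2e-6, 4e-6)]
        wl = spectra[0].wavelengths
        blank = sb.EmissionSpectrum(wl, np.full(wl.size, 5.0), 298.0, 7.4, 0.0)
        out = sb.subtract_blank(sb.TitrationSeries(spectra, blank=blank))
        for orig, corr in zip(spectra, out.spectra):
            np.testing.assert_allclose(corr.intensities, orig.intensities - 5.0)
        assert out.blank is None

    def test_zero_blank_is_identity(self):
        spectra = [_gaussian_spectrum(337, c) for c in (0.0, 2e-6, 4e-6)]
        wl = spectra[0].wavelengths
        blank = sb.EmissionSpectrum(wl, np.zeros(wl.size), 298.0, 7.4, 0.0)
        out = sb.subtract_blank(sb.TitrationSeries(spectra, blank=blank))
        for orig, corr in zip(spectra, out.spectra):
            np.testing.assert_array_equal(corr.intensities, orig.intensities)

    def test_subtraction_is_linear(self):
        spectra = [_gaussian_spectrum(337, c) for c in (0.0, 2e-6, 4e-6)]
        wl = spectra[0].wavelengths
        blank1 = sb.EmissionSpectrum(wl, np.full(wl.size, 3.0), 298.0, 7.4, 0.0)
        blank2 = sb.EmissionSpectrum(wl, np.full(wl.size, 6.0), 298.0, 7.4, 0.0)
        once_twice = sb.subtract_blank(
            sb.TitrationSeries(
                sb.subtract_blank(sb.TitrationSeries(spectra, blank=blank1)).spectra,
                blank=blank1,
            )
        )
        double = sb.subtract_blank(sb.TitrationSeries(spectra, blank=blank2))
        for a, b in zip(once_twice.spectra, double.spectra):
            np.testing.assert_allclose(a.intensities, b.intensities)

    def test_no_blank_is_noop(self):
        spectra = [_gaussian_spectrum(337, c) for c in (0.0, 2e-6, 4e-6)]
        series = sb.TitrationSeries(spectra)
        assert sb.subtract_blank(series) is series


class TestExtractPeak:
    @pytest.mark.parametrize("center", [337.0, 334.0])
    def test_gaussian_center_recovered(self, center):
        peak = sb.extract_peak(_gaussian_spectrum(center))
        assert peak.lambda_max == pytest.approx(center, abs=0.05)
        assert not peak.at_boundary

    def test_scale_invariance(self):
        spec = _gaussian_spectrum(337.0)
        p1 = sb.extract_peak(spec)
        p2 = sb.extract_peak(replace(spec, intensities=spec.intensities * 7.5))
        assert p2.lambda_max == pytest.approx(p1.lambda_max, abs=1e-12)
        assert p2.intensity == pytest.approx(7.5 * p1.intensity, rel=1e-12)

    def test_flat_spectrum_is_degenerate(self):
        wl = np.arange(300.0, 310.0)
        spec = sb.EmissionSpectrum(wl, np.ones(wl.size), 298.0, 7.4, 0.0)
        with pytest.raises(DegeneratePeakError):
            sb.extract_peak(spec)

    def test_boundary_peak_flagged(self):
        # monotone spectrum peaks at the last grid point
        wl = np.arange(300.0, 320.0)
        spec = sb.EmissionSpectrum(wl, np.linspace(1, 2, wl.size), 298.0, 7.4, 0.0)
        peak = sb.extract_peak(spec, window=0.0)
        assert peak.at_boundary and peak.lambda_max == wl[-1]

    def test_moving_average_preserves_length(self):
        y = np.arange(20.0)
        assert _moving_average(y, 3).size == y.size


class TestUVPeaks:
    def _absorbance(self, amp210=1.0, amp280=0.8, lo=190.0):
        wl = np.arange(lo, 451.0, 1.0)
        y = amp210 * np.exp(-0.5 * ((wl - 210) / 8) ** 2) + amp280 * np.exp(
            -0.5 * ((wl - 280) / 15) ** 2
        )
        return sb.EmissionSpectrum(wl, y, 298.0, 7.4, 0.0, kind="absorbance")

    def test_two_peaks_found(self):
        found, _ = sb.uv_absorption_peaks(self._absorbance(), [210.0, 280.0])
        assert found[210.0] is not None and found[280.0] is not None
        assert found[210.0].lambda_max == pytest.approx(210.0, abs=1.0)
        assert found[280.0].lambda_max == pytest.approx(280.0, abs=1.0)

    def test_hyperchromicity_flag(self):
        high = self._absorbance(amp280=1.0)
        low = self._absorbance(amp280=0.6)
        _, flag = sb.uv_absorption_peaks(high, [280.0], reference=low)
        assert flag is True

    def test_out_of_range_peak_reported_missing(self):
        found, _ = sb.uv_absorption_peaks(self._absorbance(lo=250.0), [210.0, 280.0])
        assert found[210.0] is None
        assert found[280.0] is not None
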