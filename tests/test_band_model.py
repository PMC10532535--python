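import numpy as np
import pytest

from phycoftir import (SampleMeta, Spectrum, builtin_library, canonical_grid,
                       classify_carrageenan, classify_colloid_family,
                       detect_peaks, match_bands, report_to_table)
from phycoftir.band_model import BandLibrary, BandReference, Peak, PeakList
from phycoftir.errors import ContractError

from conftest import gaussian

CARR = builtin_library("carrageenan")
FUC = builtin_library("fucoidan")
ALG = builtin_library("alginate")

# Positions measured on the commercial standards (used all through this file):
IOTA_STD = (1218.05, 1066.37, 967.89, 923.74, 901.51, 870.45, 844.70, 802.50)
KAPPA_STD = (1224.62, 1063.61, 970.00, 921.27, 874.26, 843.27)


def peaklist(positions, heights=None, window=(790.0, 1250.0), shoulders=None):
    heights = heights or [1.0] * len(positions)
    shoulders = shoulders or [False] * len(positions)
    pk = sorted(zip(positions, heights, shoulders))
    return PeakList(tuple(Peak(p, h, 0.0 if s else h, is_shoulder=s)
                          for p, h, s in pk), window)


class TestLibraries:
    def test_builtin_libraries_load(self):
        assert len(CARR) == 10 and CARR.version == "1.0"
        assert FUC.codes() == ["S=O", "O=S=O", "C-O-S"]
        assert [b.center for b in ALG] == [1600.0, 1410.0, 1081.0, 1026.0, 797.0]

    def test_every_standard_position_covered(self):
        # each observed standard position falls in exactly the intended window
        for pos, code in zip(IOTA_STD, ("S=O", "DA*", "G/D", "DA", "DA2S*",
                                        "G/D6S*", "G4S", "DA2S")):
            assert CARR.get(code).contains(pos), (code, pos)

    def test_duplicate_windows_rejected(self):
        b1 = BandReference("A", 900.0, (890.0, 910.0), frozenset({"iota"}))
        b2 = BandReference("B", 905.0, (890.0, 910.0), frozenset({"iota"}))
        with pytest.raises(ContractError):
            BandLibrary("x", "0", (b1, b2))

    def test_duplicate_codes_rejected(self):
        b1 = BandReference("A", 900.0, (890.0, 910.0), frozenset({"iota"}))
        b2 = BandReference("A", 955.0, (950.0, 960.0), frozenset({"iota"}))
        with pytest.raises(ContractError):
            BandLibrary("x", "0", (b1, b2))


class TestDetectPeaks:
    def test_single_gaussian(self, make_gaussian_spectrum):
        s = make_gaussian_spectrum([(930.0, 1.0, 10.0)])
        pl = detect_peaks(s)
        apexes = pl.apexes()
        assert len(apexes) == 1 and not pl.shoulders()
        assert apexes[0].position == pytest.approx(930.0, abs=0.1)

    def test_two_gaussians_against_dense_argmax_oracle(self, make_gaussian_spectrum):
        bands = [(905.0, 1.0, 10.0), (930.0, 1.0, 10.0)]
        s = make_gaussian_spectrum(bands)
        # oracle: apex positions of the analytic sum on a 1e-3 grid
        xd = np.arange(890.0, 945.0, 1e-3)
        yd = sum(gaussian(xd, c, h, f) for c, h, f in bands)
        dy = np.sign(np.diff(yd))
        flips = np.where(np.diff(dy) < 0)[0] + 1
        oracle = xd[flips]
        got = sorted(p.position for p in detect_peaks(s).apexes())
        assert len(got) == 2
        np.testing.assert_allclose(got, oracle, atol=0.2)

    def test_shoulder_against_second_derivative_oracle(self):
        # weak satellite on the flank of a broad main band: no local maximum,
        # but a second-derivative minimum near the satellite center
        g = canonical_grid(940, 1140)
        y = gaussian(g, 1022.0, 1.0, 60.0) + gaussian(g, 1066.0, 0.15, 20.0)
        xd = np.arange(940.0, 1140.0, 1e-3)
        yd = gaussian(xd, 1022.0, 1.0, 60.0) + gaussian(xd, 1066.0, 0.15, 20.0)
        assert np.sum(np.diff(np.sign(np.diff(yd))) < 0) == 1  # single apex
        d2 = np.gradient(np.gradient(yd, xd), xd)
        satellite_zone = (xd > 1040) & (xd < 1100)
        oracle = xd[satellite_zone][np.argmin(d2[satellite_zone])]
        pl = detect_peaks(Spectrum(g, y))
        assert len(pl.apexes()) == 1
        assert pl.apexes()[0].position == pytest.approx(1022.0, abs=1.0)
        sh = pl.shoulders()
        assert len(sh) == 1
        assert sh[0].position == pytest.approx(oracle, abs=2.0)

    @pytest.mark.parametrize("center", [805.0, 867.3, 905.0, 1022.0, 1240.0 - 20])
    @pytest.mark.parametrize("fwhm", [6.0, 12.0, 30.0])
    def test_position_error_below_half_grid_step(self, make_gaussian_spectrum,
                                                 center, fwhm):
        s = make_gaussian_spectrum([(center, 1.0, fwhm)])
        apexes = detect_peaks(s).apexes()
        step = s.grid_step()
        assert min(abs(p.position - center) for p in apexes) <= 0.5 * step

    def test_non_uniform_grid_rejected(self):
        w = np.concatenate([np.linspace(800, 900, 100), np.linspace(901, 1100, 50)])
        with pytest.raises(ContractError):
            detect_peaks(Spectrum(w, np.zeros(w.size)))


class TestMatchBands:
    def test_iota_standard_sulfate_band(self):
        rep = match_bands(peaklist([1218.05]), CARR)
        a = rep["S=O"]
        assert a.status == "matched" and a.position == pytest.approx(1218.05)

    def test_out_of_library_peak_changes_nothing(self):
        base = match_bands(peaklist([1218.05]), CARR)
        extra = match_bands(peaklist([700.0, 1218.05], window=(600.0, 1250.0)), CARR)
        assert {c: extra[c].status for c in CARR.codes()} == \
               {c: base[c].status for c in CARR.codes()}

    def test_kappa_standard_iota_and_nu_bands_absent(self):
        rep = match_bands(peaklist(list(KAPPA_STD)), CARR)
        for code in ("DA2S", "DA2S*", "G/D2S", "G/D6S"):
            assert rep[code].status == "absent", code
        for code in ("S=O", "DA*", "G/D", "DA", "G/D6S*", "G4S"):
            assert rep[code].status == "matched", code

    def test_matched_positions_inside_windows(self):
        rng = np.random.default_rng(7)
        pos = sorted(rng.uniform(795, 1245, 25))
        rep = match_bands(peaklist(pos), CARR)
        for code in CARR.codes():
            a = rep[code]
            if a.status != "absent":
                assert CARR.get(code).contains(a.position)

    def test_low_intensity_becomes_plus(self):
        rep = match_bands(peaklist([967.89, 923.74], heights=[1.0, 0.05]), CARR)
        assert rep["G/D"].status == "matched"
        assert rep["DA"].status == "present_low"

    def test_shoulder_preferred_for_shouldered_band(self):
        pl = peaklist([901.0, 905.0], heights=[0.3, 0.3],
                      shoulders=[True, False])
        rep = match_bands(pl, CARR)
        a = rep["DA2S*"]
        assert a.status == "matched" and a.is_shoulder
        assert a.position == pytest.approx(901.0)


class TestClassifyCarrageenan:
    def test_iota_standard_row(self):
        rep = match_bands(peaklist(list(IOTA_STD),
                                   heights=[1, .25, 1, .5, .25, .25, 1, .5]), CARR)
        prof = classify_carrageenan(rep)
        assert prof.dominant == "iota"
        assert prof.colloid_family == "carrageenan"

    def test_kappa_standard_row(self):
        rep = match_bands(peaklist(list(KAPPA_STD),
                                   heights=[1, .25, 1, .5, .25, 1]), CARR)
        assert classify_carrageenan(rep).dominant == "kappa"

    def test_true_nu_bands_give_mixture(self):
        # iota evidence plus genuine nu bands (825-830 / 815-820 region)
        rep = match_bands(peaklist([802.5, 817.5, 827.5, 844.7, 901.51, 923.74,
                                    967.89, 1218.05]), CARR)
        assert classify_carrageenan(rep).dominant == "mixture"

    def test_no_peaks_undetermined(self):
        rep = match_bands(peaklist([]), CARR)
        prof = classify_carrageenan(rep)
        assert prof.dominant == "undetermined"
        assert prof.colloid_family == "undetermined"

    def test_wrong_library_rejected(self):
        rep = match_bands(peaklist([1020.0], window=(900.0, 1100.0)), FUC)
        with pytest.raises(ContractError):
            classify_carrageenan(rep)


class TestClassifyFamily:
    def test_fucoidan_markers(self):
        pl = peaklist([1220.0, 1020.0, 820.0], window=(500.0, 1700.0))
        assert classify_colloid_family(pl, [CARR, FUC, ALG]).colloid_family == "fucoidan"

    def test_alginate_markers(self):
        pl = peaklist([1600.0, 1410.0, 1081.0, 1026.0, 797.0], window=(500.0, 1700.0))
        assert classify_colloid_family(pl, [CARR, FUC, ALG]).colloid_family == "alginate"

    def test_no_peaks_undetermined(self):
        pl = peaklist([], window=(500.0, 1700.0))
        assert classify_colloid_family(pl, [CARR, FUC, ALG]).colloid_family == "undetermined"

    def test_empty_library_list_rejected(self):
        with pytest.raises(ContractError):
            classify_colloid_family(peaklist([]), [])


class TestReportTable:
    def test_iota_row_rendering(self):
        rep = match_bands(peaklist(list(IOTA_STD)), CARR,
                          meta=SampleMeta(sample_id="IOTA Stand."))
        df = report_to_table([rep])
        row = df.loc["IOTA Stand."]
        assert row["S=O"] == "1218.05"
        assert row["DA2S"] == "802.50"
        assert row["G/D2S"] == "-" and row["G/D6S"] == "-"

    def test_empty_reports_header_only(self):
        assert report_to_table([]).empty

    def test_shoulder_match_renders_numeric(self):
        pl = peaklist([1066.4], heights=[0.3], shoulders=[True])
        rep = match_bands(pl, CARR)
        df = report_to_table([rep])
        assert df.iloc[0]["DA*"] == "1066.40"

    def test_mixed_libraries_rejected(self):
        r1 = match_bands(peaklist([1218.05]), CARR)
        r2 = match_bands(peaklist([1020.0], window=(900.0, 1100.0)), FUC)
        with pytest.raises(ContractError):
            report_to_table([r1, r2])
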