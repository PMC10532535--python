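import hashlib

import numpy as np
import pytest

from phycoftir import (CompositionProfile, analyze_spectrum, canonical_grid,
                       component_bandset, detect_peaks, match_bands,
                       builtin_library, pseudo_voigt, sargassum_2015,
                       simulate_seasonal_dataset, simulate_spectrum,
                       solieria_2014)
from phycoftir.preprocess import baseline_correct, crop
from phycoftir.errors import ContractError
from phycoftir.synthetic_data import SHIPPED_PROFILES, BandShape


class TestComponentBandsets:
    def test_iota_centers_match_standard_row(self):
        centers = [b.center for b in component_bandset("iota")]
        assert centers == [1218.05, 1066.37, 967.89, 923.74, 901.51, 870.45,
                           844.70, 802.50]

    def test_kappa_centers_match_standard_row(self):
        centers = [b.center for b in component_bandset("kappa")]
        assert centers == [1224.62, 1063.61, 970.00, 921.27, 874.26, 843.27]

    def test_fucoidan_markers(self):
        assert [b.center for b in component_bandset("fucoidan")] == [1220.0, 1020.0, 820.0]

    def test_alginate_markers(self):
        assert [b.center for b in component_bandset("alginate")] == \
            [1600.0, 1410.0, 1081.0, 1026.0, 797.0]

    def test_unknown_component_rejected(self):
        with pytest.raises(ContractError):
            component_bandset("agarose")

    def test_centers_lie_in_library_windows(self):
        lib = builtin_library("carrageenan")
        bands = component_bandset("iota", lib)
        assert all(any(b.contains(s.center) for b in lib) for s in bands)


class TestSimulateSpectrum:
    def test_zero_weights_zero_trace(self):
        with pytest.warns(UserWarning):
            s, planted = simulate_spectrum({"iota": 0.0}, canonical_grid(800, 900))
        assert not planted
        np.testing.assert_array_equal(s.absorbance, 0.0)

    def test_pseudo_voigt_height_normalized(self):
        b = BandShape(center=900.0, height=0.7, fwhm=12.0, eta=0.3)
        x = np.array([900.0, 906.0, 894.0])
        v = pseudo_voigt(x, b)
        assert v[0] == pytest.approx(0.7)
        assert v[1] == pytest.approx(v[2])          # symmetric
        assert v[1] == pytest.approx(0.35, rel=1e-6)  # half height at half width

    def test_seed_reproducibility(self):
        kw = dict(position_jitter_sd=0.5, height_cv=0.05, noise_sd=0.01,
                  baseline_drift_amplitude=0.02)
        a, _ = simulate_spectrum({"iota": 1.0}, seed=42, **kw)
        b, _ = simulate_spectrum({"iota": 1.0}, seed=42, **kw)
        c, _ = simulate_spectrum({"iota": 1.0}, seed=43, **kw)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
        assert not np.array_equal(a.absorbance, c.absorbance)

    @pytest.mark.parametrize("profile", sorted(SHIPPED_PROFILES))
    def test_planted_bands_recovered_noise_free(self, profile):
        window = (800.0, 1240.0) if profile in ("iota", "kappa") else (500.0, 1700.0)
        spec, planted = simulate_spectrum(SHIPPED_PROFILES[profile], seed=0)
        s = baseline_correct(crop(spec, window))
        pl = detect_peaks(s)
        positions = pl.positions()
        shoulder_centers = {b.center for c in ("iota", "kappa")
                            for b in component_bandset(c) if b.fwhm > 12.0}
        for band in planted:
            if not window[0] + 10 < band.center < window[1] - 10:
                continue
            if band.height < 0.05:  # amide background under weak weight
                continue
            tol = 0.5 if band.center not in shoulder_centers else 2.0
            assert np.min(np.abs(positions - band.center)) <= tol, band

    def test_ground_truth_returned(self):
        _, planted = simulate_spectrum({"fucoidan": 0.5}, seed=0)
        assert len(planted) == 3
        assert all(b.height <= 0.5 + 1e-9 for b in planted)


class TestMixtureMonotonicity:
    def test_nu_weight_raises_867_band(self):
        heights = []
        statuses = []
        rank = {"absent": 0, "present_low": 1, "matched": 2}
        for w in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            spec, _ = simulate_spectrum({"iota": 1.0, "nu": w}, seed=0)
            rep, _ = analyze_spectrum(spec, "carrageenan")
            a = rep["G/D6S*"]
            statuses.append(rank[a.status])
            if a.height is not None:
                heights.append(a.height)
        assert all(b > a for a, b in zip(heights, heights[1:]))
        assert all(b >= a for a, b in zip(statuses, statuses[1:]))


class TestSeasonalDataset:
    def test_design_shapes(self):
        sset, truth = simulate_seasonal_dataset(sargassum_2015(seed=0))
        assert len(sset) == 4 * 3
        assert truth["sample_id"].nunique() == 12
        months = {s.meta.month for s in sset}
        assert months == {2, 4, 6, 10}

    def test_dataset_determinism_hash(self):
        def digest(design):
            sset, _ = simulate_seasonal_dataset(design)
            h = hashlib.sha256()
            for s in sset:
                h.update(s.absorbance.tobytes())
            return h.hexdigest()

        assert digest(solieria_2014(seed=9)) == digest(solieria_2014(seed=9))
        assert digest(solieria_2014(seed=9)) != digest(solieria_2014(seed=10))

    def test_month_streams_independent(self):
        # dropping months never perturbs the remaining months' draws
        full = solieria_2014(seed=4)
        sub = type(full)(
            name=full.name, species=full.species, months=full.months[:3],
            profile_per_month=full.profile_per_month,
            n_replicates=full.n_replicates,
            position_jitter_sd=full.position_jitter_sd,
            height_cv=full.height_cv, noise_sd=full.noise_sd,
            baseline_drift_amplitude=full.baseline_drift_amplitude,
            seed=full.seed, grid=full.grid)
        s_full, _ = simulate_seasonal_dataset(full)
        s_sub, _ = simulate_seasonal_dataset(sub)
        for a, b in zip(s_sub, s_full):
            assert a.meta.sample_id == b.meta.sample_id
            np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_noise_free_single_replicate_identical(self):
        base = solieria_2014(seed=0)
        quiet = type(base)(
            name="quiet", species="x", months=((1, 2014), (2, 2014)),
            profile_per_month=base.profile_per_month, n_replicates=1,
            position_jitter_sd=0.0, height_cv=0.0, noise_sd=0.0,
            baseline_drift_amplitude=0.0, seed=0)
        a, _ = simulate_seasonal_dataset(quiet)
        b, _ = simulate_seasonal_dataset(quiet)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.absorbance, y.absorbance)

    def test_invalid_design_rejected(self):
        base = solieria_2014()
        with pytest.raises(ContractError):
            type(base)(name="bad", species="x", months=((1, 2014),),
                       profile_per_month={}, seed=0)
        with pytest.raises(ContractError):
            CompositionProfile({"iota": -1.0})
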