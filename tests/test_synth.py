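"""Synthetic-data generator: band models, kinetics, design and acquisition."""
import numpy as np
import pandas as pd
import pytest

from fermspec import (
    AcquisitionConfig,
    Band,
    ComponentLibrary,
    build_pure_spectrum,
    default_library,
    default_profiles,
    design_counts,
    screening_design,
    simulate_fermentation,
    synthesize_dataset,
)


class TestBands:
    def test_empty_band_list_gives_zero_spectrum(self):
        grid = np.arange(700.0, 1900.0, 2.0)
        assert np.all(build_pure_spectrum([], grid) == 0.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_pure_spectrum([Band(1035, 35, 1.0)], np.array([]))

    @pytest.mark.parametrize("shape", ["gaussian", "lorentzian"])
    def test_fwhm_definition(self, shape):
        """Height at centre, half height at centre +/- fwhm/2."""
        band = Band(1035.0, 35.0, 1.0, shape)
        grid = np.array([1035.0 - 17.5, 1035.0, 1035.0 + 17.5])
        spec = build_pure_spectrum([band], grid)
        assert spec[1] == pytest.approx(1.0)
        assert spec[0] == pytest.approx(0.5)
        assert spec[2] == pytest.approx(0.5)

    def test_band_outside_grid_warns_and_contributes_tail(self):
        grid = np.arange(700.0, 1901.0, 2.0)
        with pytest.warns(UserWarning, match="outside the grid"):
            spec = build_pure_spectrum([Band(3300.0, 400.0, 1.0)], grid)
        assert 0 < spec.max() < 1.0

    def test_glucose_absorbance_concentrated_in_fingerprint(self):
        """Numerically integrated default glucose absorbance: >99% of the
        area on a 1900-700 grid lies within 1250-850 cm^-1."""
        lib = default_library()
        grid = np.arange(700.0, 1900.0 + 0.5, 0.5)
        spec = lib.spectrum("glucose", grid)
        total = np.trapezoid(spec, grid)
        inner = (grid >= 850.0) & (grid <= 1250.0)
        assert np.trapezoid(spec[inner], grid[inner]) / total > 0.99

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            Band(1035, -1.0, 1.0)
        with pytest.raises(ValueError):
            Band(1035, 35.0, -0.1)
        with pytest.raises(ValueError):
            ComponentLibrary(components={"x": []})

    def test_default_library_molar_masses(self):
        lib = default_library()
        assert lib.molar("glucose", 80.0) == pytest.approx(0.444, abs=5e-4)
        assert lib.molar_mass["citric_acid"] == pytest.approx(192.12)


class TestKinetics:
    def test_zero_uptake_keeps_glucose_constant(self):
        prof = simulate_fermentation(uptake_rate=0.0, producer=False)
        assert all(p.glucose == pytest.approx(80.0) for p in prof)

    def test_producer_reaches_plateau_by_day_6(self):
        """Citric acid of a producer is within 5% of the 7.5 g/L plateau on
        every day from 6 through 12."""
        prof = simulate_fermentation(acid_plateau=7.5, producer=True)
        for p in prof:
            if p.day >= 6:
                assert p.citric_acid == pytest.approx(7.5, rel=0.05)

    def test_non_producer_emits_no_acid(self):
        prof = simulate_fermentation(producer=False)
        assert all(p.citric_acid == 0.0 for p in prof)

    def test_glucose_monotone_decay_from_initial(self):
        prof = simulate_fermentation()
        glucose = [p.glucose for p in prof]
        assert glucose[0] == pytest.approx(80.0)
        assert np.all(np.diff(glucose) <= 0)
        assert glucose[-1] == pytest.approx(8.0, rel=0.01)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_fermentation(uptake_rate=-0.1)
        with pytest.raises(ValueError):
            simulate_fermentation(acid_plateau=-1.0)
        with pytest.raises(ValueError):
            simulate_fermentation(days=0)

    def test_default_profiles_cover_design(self):
        prof = default_profiles()
        keys = {(p.strain, p.temperature, p.day) for p in prof}
        design = screening_design()
        sup = design[design.sample_type == "supernatant"]
        for row in sup.itertuples():
            assert (row.strain, row.temperature, row.day) in keys


class TestDesign:
    def test_printed_sample_and_spectrum_totals(self):
        counts = design_counts(include_biomass=True)
        assert counts == {
            "medium_samples": 6,
            "medium_spectra": 18,
            "supernatant_samples": 216,
            "supernatant_spectra": 648,
            "biomass_samples": 210,
            "biomass_spectra": 630,
        }

    def test_sample_keys_unique(self):
        design = screening_design(include_biomass=True)
        key = design[["strain", "temperature", "day", "well_replicate", "sample_type"]]
        assert not key.duplicated().any()
        assert (design.loc[design.day == 0, "sample_type"] == "medium").all()


class TestAcquisition:
    def test_noise_free_replicates_are_bit_identical(self, library, profiles):
        acq = AcquisitionConfig.hts(
            seed=3, noise_sd=0.0, pathlength_jitter_sd=0.0, baseline_drift_amplitude=0.0
        )
        ds, _ = synthesize_dataset(library, profiles, acq)
        for sid, idx in ds.metadata.groupby("sample_id").indices.items():
            block = ds.absorbance[idx]
            assert (block == block[0]).all(), sid

    def test_beer_lambert_superposition(self, library):
        """With noise off the generated spectrum is linear in the
        concentration vector (checked against the component spectra)."""
        from fermspec.kinetics import FermentationProfile

        acq = AcquisitionConfig.hts(
            seed=5, noise_sd=0.0, pathlength_jitter_sd=0.0,
            baseline_drift_amplitude=0.0, biological_cv=0.0,
            technical_replicates=1,
        )
        design = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "z"],
                "strain": ["S"] * 4,
                "temperature": [30.0] * 4,
                "day": [1, 2, 3, 4],
                "well_replicate": [1] * 4,
                "sample_type": ["supernatant"] * 4,
            }
        )
        rng = np.random.default_rng(11)
        g1, g2 = rng.uniform(5, 60, 2)
        c1, c2 = rng.uniform(0.5, 8, 2)
        profs = [
            FermentationProfile("S", 30.0, 1, g1, c1),
            FermentationProfile("S", 30.0, 2, g2, c2),
            FermentationProfile("S", 30.0, 3, g1 + g2, c1 + c2),
            FermentationProfile("S", 30.0, 4, 0.0, 0.0),
        ]
        ds, _ = synthesize_dataset(library, profs, acq, design)
        a, b, summed, zero = ds.absorbance
        np.testing.assert_allclose(summed - zero, (a - zero) + (b - zero), atol=1e-12)

    def test_doubling_citric_doubles_1725_contribution(self, library):
        from fermspec.kinetics import FermentationProfile

        acq = AcquisitionConfig.hts(
            seed=0, noise_sd=0.0, pathlength_jitter_sd=0.0,
            baseline_drift_amplitude=0.0, biological_cv=0.0,
            technical_replicates=1, dilution_factor=1.0,
        )
        design = pd.DataFrame(
            {
                "sample_id": ["a", "b", "z"],
                "strain": ["S"] * 3,
                "temperature": [30.0] * 3,
                "day": [1, 2, 3],
                "well_replicate": [1] * 3,
                "sample_type": ["supernatant"] * 3,
            }
        )
        profs = [
            FermentationProfile("S", 30.0, 1, 20.0, 4.0),
            FermentationProfile("S", 30.0, 2, 20.0, 8.0),
            FermentationProfile("S", 30.0, 3, 20.0, 0.0),
        ]
        ds, _ = synthesize_dataset(library, profs, acq, design)
        j = np.argmin(np.abs(ds.grid - 1725.0))
        single, double, none = ds.absorbance[:, j]
        assert double - none == pytest.approx(2.0 * (single - none), rel=1e-10)

    def test_end_cultivation_peak_parity(self, library):
        """A late dry-film spectrum with citric acid ~8.8 g/L and glucose
        ~8 g/L shows a 1725 cm^-1 peak of the same magnitude (within a
        factor 2) as the 1035 cm^-1 glucose peak."""
        from fermspec.kinetics import FermentationProfile

        acq = AcquisitionConfig.hts(
            seed=0, noise_sd=0.0, pathlength_jitter_sd=0.0,
            baseline_drift_amplitude=0.0, biological_cv=0.0, technical_replicates=1,
        )
        design = pd.DataFrame(
            {
                "sample_id": ["end"],
                "strain": ["S"],
                "temperature": [30.0],
                "day": [12],
                "well_replicate": [1],
                "sample_type": ["supernatant"],
            }
        )
        profs = [FermentationProfile("S", 30.0, 12, 8.0, 8.8)]
        ds, _ = synthesize_dataset(library, profs, acq, design)
        at = lambda wn: ds.absorbance[0, np.argmin(np.abs(ds.grid - wn))]
        ratio = at(1725.0) / at(1035.0)
        assert 0.5 <= ratio <= 2.0

    def test_hts_dilution_scales_fingerprint_absorbance(self, library, profiles):
        kwargs = dict(
            noise_sd=0.0, pathlength_jitter_sd=0.0, baseline_drift_amplitude=0.0,
            biological_cv=0.0, technical_replicates=1,
        )
        diluted, _ = synthesize_dataset(
            library, profiles, AcquisitionConfig.hts(seed=1, **kwargs)
        )
        neat, _ = synthesize_dataset(
            library, profiles,
            AcquisitionConfig.hts(seed=1, dilution_factor=1.0, **kwargs),
        )
        band = (diluted.grid >= 900.0) & (diluted.grid <= 1200.0)
        ratio = diluted.absorbance[:, band].mean() / neat.absorbance[:, band].mean()
        assert ratio == pytest.approx(0.1, rel=1e-10)

    def test_seed_determinism(self, library, profiles):
        a, ra = synthesize_dataset(library, profiles, AcquisitionConfig.hts(seed=42))
        b, rb = synthesize_dataset(library, profiles, AcquisitionConfig.hts(seed=42))
        c, _ = synthesize_dataset(library, profiles, AcquisitionConfig.hts(seed=43))
        assert a.absorbance.tobytes() == b.absorbance.tobytes()
        pd.testing.assert_frame_equal(ra, rb)
        assert a.absorbance.tobytes() != c.absorbance.tobytes()

    def test_water_dominates_atr_but_not_hts(self, atr_benchmark, hts_benchmark):
        atr, _ = atr_benchmark
        hts, _ = hts_benchmark
        atr_max_wn = atr.grid[np.argmax(atr.absorbance, axis=1)]
        hts_max_wn = hts.grid[np.argmax(hts.absorbance, axis=1)]
        assert np.all(np.abs(atr_max_wn - 3300.0) <= 200.0)
        assert not np.any(np.abs(hts_max_wn - 3300.0) <= 200.0)

    def test_benchmark_shape_and_reference_table(self, hts_benchmark):
        ds, refs = hts_benchmark
        assert ds.n_spectra == 666  # (216 + 6) samples x 3 technical replicates
        assert len(refs) == 222
        assert (refs.glucose >= 0).all() and (refs.citric_acid >= 0).all()
        nonproducer = refs[refs.strain.isin(["M. circinelloides", "U. isabellina"])]
        assert (nonproducer.citric_acid == 0).all()

    def test_missing_profile_raises(self, library):
        acq = AcquisitionConfig.hts(seed=0)
        with pytest.raises(KeyError, match="profile"):
            synthesize_dataset(library, [], acq)
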