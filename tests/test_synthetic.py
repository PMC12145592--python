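"""Band library, kinetics, rendering and campaign simulation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nirferm import (
    CONSTITUENTS,
    ConcentrationTable,
    KineticsParams,
    PureComponentLibrary,
    render_spectra,
    simulate_campaign,
    simulate_feasibility_design,
    simulate_fermentation_timecourse,
    simulate_reference_measurement,
    simulate_water_blanks,
)
from nirferm.errors import (
    DesignFailureError,
    LibraryMismatchError,
    ParameterError,
    SampleSizeError,
)
from nirferm.synthetic import (
    COMBINATION_REGION,
    OVERTONE_REGION,
    BandDefinition,
    CampaignConfig,
)
from conftest import make_conc


def _region_amplitude(bands, region):
    return sum(b.amplitude for b in bands if region[0] <= b.center <= region[1])


class TestDefaultLibrary:
    def test_every_constituent_has_bands_in_both_regions(self, library):
        for c in CONSTITUENTS:
            assert _region_amplitude(library.bands[c], OVERTONE_REGION) > 0
            assert _region_amplitude(library.bands[c], COMBINATION_REGION) > 0

    def test_combination_region_is_10x_overtone(self, library):
        for c in CONSTITUENTS:
            ratio = (_region_amplitude(library.bands[c], COMBINATION_REGION)
                     / _region_amplitude(library.bands[c], OVERTONE_REGION))
            assert ratio == pytest.approx(10.0)

    def test_products_absorb_more_strongly_than_sugars(self, library, profiles):
        nu = profiles["lab_at_line"].axis.values
        peaks = {c: library.render_component(c, nu).max() for c in CONSTITUENTS}
        for product in ("bdo_total", "acetoin"):
            for sugar in ("glucose", "xylose"):
                assert peaks[product] > peaks[sugar]

    def test_constituent_signatures_are_distinguishable(self, library, profiles):
        nu = profiles["lab_at_line"].axis.values
        rendered = {c: library.render_component(c, nu) for c in CONSTITUENTS}
        for i, a in enumerate(CONSTITUENTS):
            for b in CONSTITUENTS[i + 1:]:
                cos = np.dot(rendered[a], rendered[b]) / (
                    np.linalg.norm(rendered[a]) * np.linalg.norm(rendered[b]))
                assert cos < 1 - 1e-3

    def test_water_entry_required(self):
        with pytest.raises(ParameterError):
            PureComponentLibrary(bands={"glucose": (BandDefinition(4400, 50, 0.01),)})


class TestFeasibilityDesign:
    def test_range_and_decorrelation(self):
        conc = simulate_feasibility_design(n=40, c_max=60.0, seed=7, max_abs_corr=0.3)
        m = conc.matrix()
        assert m.shape == (40, 5)
        assert m.min() >= 0 and m.max() <= 60
        corr = np.corrcoef(m, rowvar=False)
        off = corr[np.triu_indices(5, k=1)]
        assert np.all(np.abs(off) <= 0.3)

    def test_deterministic_per_seed(self):
        a = simulate_feasibility_design(seed=3).matrix()
        b = simulate_feasibility_design(seed=3).matrix()
        c = simulate_feasibility_design(seed=4).matrix()
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_infeasible_constraint_raises(self):
        with pytest.raises(DesignFailureError):
            simulate_feasibility_design(n=5, max_abs_corr=1e-6, seed=0, max_tries=20)


class TestKinetics:
    def test_single_substrate_optimal_do(self):
        params = KineticsParams(xylose_0=0.0, feed_rate=0.0, do_fixed="optimal",
                                glucose_0=30.0, r_glucose=4.0, duration_h=20.0)
        track = simulate_fermentation_timecourse(params, seed=1).data
        g = track["glucose"].to_numpy()
        exhausted = np.flatnonzero(g == 0)
        first_zero = exhausted[0] if exhausted.size else len(g)
        assert np.all(np.diff(g[:first_zero + 1]) < 0)
        assert np.all(np.diff(track["bdo_total"].to_numpy()) >= 0)
        assert track["glycerol"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_do_deficient_makes_glycerol_dominate_acetoin(self):
        params = KineticsParams(do_fixed="low")
        track = simulate_fermentation_timecourse(params, seed=2).data
        assert track["glycerol"].iloc[-1] > track["acetoin"].iloc[-1]

    def test_do_excess_accumulates_acetoin(self):
        track = simulate_fermentation_timecourse(KineticsParams(do_fixed="high"), seed=2).data
        assert track["acetoin"].iloc[-1] > track["glycerol"].iloc[-1]

    def test_mass_balance_against_statewise_yields(self):
        params = KineticsParams()
        track = simulate_fermentation_timecourse(params, seed=5).data
        ds = np.diff(track["sugar_consumed"].to_numpy())
        states = track["do_state"].to_numpy()[:-1]
        cap = np.cumsum([sum(params.yields[s]) * d for s, d in zip(states, ds)])
        products = (track["bdo_total"] + track["acetoin"] + track["glycerol"]).to_numpy()[1:]
        assert np.all(products <= cap + 1e-9)

    def test_concentrations_never_negative_and_irreversible(self):
        for seed in range(5):
            track = simulate_fermentation_timecourse(KineticsParams(), seed=seed).data
            assert (track[CONSTITUENTS].to_numpy() >= 0).all()
            assert np.all(np.diff(track["glycerol"].to_numpy()) >= -1e-12)
            assert np.all(np.diff(track["bdo_total"].to_numpy()) >= -1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            KineticsParams(r_glucose=-1.0)


class TestRenderSpectra:
    def test_zero_concentrations_give_exact_water_term(self, library, profiles):
        prof = profiles["lab_at_line"].noiseless()
        conc = ConcentrationTable(pd.DataFrame(
            {"sample_id": ["A"], **{c: [0.0] for c in CONSTITUENTS}}))
        sp = render_spectra(conc, library, prof, seed=0)
        water = prof.pathlength_mm * library.render_component("water", prof.axis.values)
        assert np.allclose(sp.absorbance[0], water, atol=0, rtol=0)

    def test_beer_lambert_linearity(self, library, profiles):
        prof = profiles["lab_at_line"].noiseless()
        def render_gluc(c):
            conc = ConcentrationTable(pd.DataFrame(
                {"sample_id": ["A"], "glucose": [c],
                 **{k: [0.0] for k in CONSTITUENTS if k != "glucose"}}))
            return render_spectra(conc, library, prof, seed=0).absorbance[0]
        a0, a1, a2 = render_gluc(0.0), render_gluc(25.0), render_gluc(50.0)
        assert np.allclose(a2 - a0, 2 * (a1 - a0), atol=1e-12)

    def test_mixture_additivity(self, library, profiles):
        prof = profiles["lab_at_line"].noiseless()
        values = {"glucose": 20.0, "xylose": 10.0, "bdo_total": 30.0,
                  "acetoin": 5.0, "glycerol": 3.0}
        mix = ConcentrationTable(pd.DataFrame(
            {"sample_id": ["M"], **{k: [v] for k, v in values.items()}}))
        mixed = render_spectra(mix, library, prof, seed=0).absorbance[0]
        water = prof.pathlength_mm * library.render_component("water", prof.axis.values)
        total = np.zeros_like(water)
        for k, v in values.items():
            solo = ConcentrationTable(pd.DataFrame(
                {"sample_id": ["A"], k: [v],
                 **{c: [0.0] for c in CONSTITUENTS if c != k}}))
            total += render_spectra(solo, library, prof, seed=0).absorbance[0]
        assert np.allclose(mixed, total - 4 * water, atol=1e-10)

    def test_pathlength_proportionality(self, library, profiles):
        conc = make_conc(3, seed=9)
        thin = profiles["lab_at_line"].noiseless()
        thick = dataclasses.replace(thin, pathlength_mm=2.0)
        a_thin = render_spectra(conc, library, thin, seed=0).absorbance
        a_thick = render_spectra(conc, library, thick, seed=0).absorbance
        water = library.render_component("water", thin.axis.values)
        sig_thin = a_thin - 0.2 * water
        sig_thick = a_thick - 2.0 * water
        assert np.allclose(sig_thick, 10.0 * sig_thin, rtol=1e-9, atol=1e-12)

    def test_online_saturated_regions_clipped(self, library, profiles):
        prof = profiles["lab_on_line"]
        exact = dataclasses.replace(prof, rail_noise_sd=0.0)
        conc = make_conc(4, seed=2)
        sp = render_spectra(conc, library, exact, seed=3)
        nu = sp.axis.values
        limit = prof.saturation_limit
        for lo, hi in ((4800.0, 5400.0), (nu.min(), 4300.0)):
            region = sp.absorbance[:, (nu >= lo) & (nu <= hi)]
            assert np.all(region == limit)
        # with the default rail instability they still sit at the ceiling
        sp2 = render_spectra(conc, library, prof, seed=3)
        rail = prof.effective_rail_noise_sd()
        for lo, hi in ((4800.0, 5400.0), (nu.min(), 4300.0)):
            region = sp2.absorbance[:, (nu >= lo) & (nu <= hi)]
            assert np.all(np.abs(region - limit) < 6 * rail)

    def test_missing_library_entry_raises(self, profiles):
        lib = PureComponentLibrary(bands={
            "water": (BandDefinition(5150, 200, 9.0),),
            **{c: (BandDefinition(4400, 50, 0.01),)
               for c in CONSTITUENTS if c != "glucose"}})
        with pytest.raises(LibraryMismatchError):
            render_spectra(make_conc(2, seed=1), lib, profiles["lab_at_line"], seed=0)


class TestReferenceMeasurement:
    def test_zero_sd_is_identity(self):
        conc = make_conc(5, seed=1)
        out = simulate_reference_measurement(conc, base_sd=0.0, seed=0)
        assert np.array_equal(out.matrix(), conc.matrix())

    def test_glucose_dilution_inflates_error(self):
        df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(20000)],
                           "glucose": 90.0,
                           **{c: 0.0 for c in CONSTITUENTS if c != "glucose"}})
        conc = ConcentrationTable(df)
        out = simulate_reference_measurement(conc, base_sd=0.5, seed=1)
        err_sd = np.std(out.matrix()[:, 0] - 90.0)
        assert err_sd == pytest.approx(3 * 0.5, rel=0.05)

    def test_error_sd_matches_base_sd_in_calibration_range(self):
        df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(10000)],
                           "glucose": 20.0,
                           **{c: 0.0 for c in CONSTITUENTS if c != "glucose"}})
        out = simulate_reference_measurement(ConcentrationTable(df), base_sd=0.5, seed=2)
        err_sd = np.std(out.matrix()[:, 0] - 20.0)
        assert err_sd == pytest.approx(0.5, rel=0.05)


class TestWaterBlanksAndCampaign:
    def test_blank_count_and_axis(self, profiles):
        blanks = simulate_water_blanks(profiles["lab_at_line"], n=20, seed=0)
        assert blanks.n_samples == 20
        assert len(blanks.axis) == len(profiles["lab_at_line"].axis)

    def test_zero_noise_blanks_identical(self, profiles):
        blanks = simulate_water_blanks(profiles["lab_at_line"].noiseless(), n=4, seed=0)
        assert np.allclose(blanks.absorbance, blanks.absorbance[0])

    def test_blanks_deterministic(self, profiles):
        a = simulate_water_blanks(profiles["lab_at_line"], n=3, seed=5)
        b = simulate_water_blanks(profiles["lab_at_line"], n=3, seed=5)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_too_few_blanks_rejected(self, profiles):
        with pytest.raises(SampleSizeError):
            simulate_water_blanks(profiles["lab_at_line"], n=1, seed=0)

    def test_campaign_bookkeeping(self):
        camp = simulate_campaign(CampaignConfig(
            n_experiments=10, samples_per_experiment=8, seed=1, contamination_prob=0.0))
        assert camp.spectra.n_samples == 80
        assert len(camp.true_conc) == 80
        assert len(camp.measured_conc) == 80
        assert camp.spectra.meta["experiment_id"].nunique() == 10
        contaminants = camp.true_conc.data[["ethanol", "lactic_acid", "acetic_acid"]]
        assert (contaminants.to_numpy() == 0).all()

    def test_campaign_contamination_exercises_filter(self):
        camp = simulate_campaign(CampaignConfig(
            n_experiments=5, samples_per_experiment=6, seed=2,
            contamination_prob=1.0, contaminant_magnitude=5.0))
        df = camp.true_conc.data
        over = df[["ethanol", "lactic_acid", "acetic_acid"]].max(axis=1) > 2.5
        assert df.loc[over, "experiment_id"].nunique() == 5

    def test_campaign_deterministic(self):
        a = simulate_campaign(CampaignConfig(n_experiments=3, samples_per_experiment=4, seed=9))
        b = simulate_campaign(CampaignConfig(n_experiments=3, samples_per_experiment=4, seed=9))
        assert np.array_equal(a.spectra.absorbance, b.spectra.absorbance)
        assert np.array_equal(a.measured_conc.matrix(), b.measured_conc.matrix())
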