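import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import p31lipid as pl
import p31lipid.simulate as sim
from p31lipid.errors import ValidationError

from conftest import SMALL_PARAMS, safe_sigma, synth_spectrum


class TestAcquisitionParams:
    def test_defaults_match_quantitative_protocol(self):
        p = sim.AcquisitionParams()
        assert p.observe_freq == 324.0
        assert p.sw == 14.98
        assert p.n_complex == 3882
        assert p.recovery_delay == 8.4

    def test_sw_hz(self):
        assert sim.AcquisitionParams().sw_hz == pytest.approx(14.98 * 324.0)

    @pytest.mark.parametrize(
        "kw", [{"observe_freq": 0}, {"sw": -1}, {"n_complex": 1}]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValidationError):
            sim.AcquisitionParams(**kw)


class TestLipidComposition:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            pl.LipidComposition(fractions={"PC": 0.5, "PE": 0.4})

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValidationError):
            pl.LipidComposition(fractions={"PC": 1.2, "PE": -0.2})

    def test_cardiolipin_has_two_phosphorus(self):
        comp = pl.LipidComposition(fractions={"PC": 0.5, "CL": 0.5})
        assert comp.phosphorus_per_molecule["CL"] == 2
        assert comp.phosphorus_per_molecule["PC"] == 1
        assert comp.total_phosphorus() == pytest.approx(1.5)

    def test_phosphorus_shares(self):
        comp = pl.LipidComposition(fractions={"PC": 0.5, "CL": 0.5})
        shares = comp.phosphorus_shares()
        assert shares["CL"] == pytest.approx(2.0 / 3.0)


class TestSynthesizeFid:
    def test_deterministic_for_fixed_seed(self):
        comp = pl.LipidComposition(fractions={"PC": 1.0})
        res = sim.default_resonances(["PC"])
        a = pl.synthesize_fid(comp, res, params=SMALL_PARAMS, noise_sigma=0.5, seed=42)
        b = pl.synthesize_fid(comp, res, params=SMALL_PARAMS, noise_sigma=0.5, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        comp = pl.LipidComposition(fractions={"PC": 1.0})
        res = sim.default_resonances(["PC"])
        a = pl.synthesize_fid(comp, res, params=SMALL_PARAMS, noise_sigma=0.5, seed=1)
        b = pl.synthesize_fid(comp, res, params=SMALL_PARAMS, noise_sigma=0.5, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_single_pc_gives_single_peak_at_zero(self):
        spec = synth_spectrum({"PC": 1.0}, calibrate=True)
        peaks = pl.pick_peaks(spec, safe_sigma(spec))
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx(0.0, abs=spec.axis_step)

    def test_snr_doubles_with_mass(self):
        # oracle: S/N linear in signal amplitude at fixed noise realization
        def sm_snr(mass):
            spec = synth_spectrum(
                {"PC": 0.9, "SM": 0.1}, mass_mg=mass,
                noise_sigma=sim.DEFAULT_NOISE_SIGMA, seed=5,
            )
            sigma = pl.estimate_noise(spec)
            fit = pl.fit_lineshapes(
                spec, pl.pick_peaks(spec, sigma), shape_mode="lorentzian"
            )
            peak = min(fit.peaks, key=lambda p: abs(p.center - 0.825))
            return peak.height / sigma

        ratio = sm_snr(8.0) / sm_snr(4.0)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_cl_counts_two_phosphorus(self):
        spec = synth_spectrum({"PC": 0.5, "CL": 0.5})
        fit = pl.fit_lineshapes(
            spec, pl.pick_peaks(spec, safe_sigma(spec)), shape_mode="lorentzian"
        )
        areas = {round(p.center, 2): p.area for p in fit.peaks}
        assert areas[0.38] / areas[0.0] == pytest.approx(2.0, rel=0.01)

    def test_class_without_resonance_rejected(self):
        comp = pl.LipidComposition(fractions={"PC": 0.5, "SM": 0.5})
        with pytest.raises(ValidationError):
            pl.synthesize_fid(comp, sim.default_resonances(["PC"]))

    def test_negative_mass_rejected(self):
        comp = pl.LipidComposition(fractions={"PC": 1.0})
        with pytest.raises(ValidationError):
            pl.synthesize_fid(comp, sim.default_resonances(["PC"]), mass_mg=-1)

    def test_weights_must_sum_to_one_per_class(self):
        comp = pl.LipidComposition(fractions={"PC": 1.0})
        res = [sim.ResonanceSpec("PC", 0.0, relative_weight=0.5)]
        with pytest.raises(ValidationError):
            pl.synthesize_fid(comp, res)

    def test_signal_linearity_through_pipeline(self):
        # doubling mass doubles every noise-free peak area
        def areas(mass):
            spec = synth_spectrum({"PC": 0.6, "SM": 0.4}, mass_mg=mass)
            fit = pl.fit_lineshapes(
                spec, pl.pick_peaks(spec, safe_sigma(spec)),
                shape_mode="lorentzian",
            )
            return {round(p.center, 2): p.area for p in fit.peaks}

        a4, a8 = areas(4.0), areas(8.0)
        for center, area in a4.items():
            assert a8[center] / area == pytest.approx(2.0, rel=0.01)


class TestConcentrationShifts:
    def test_reference_mass_is_identity(self):
        model = sim.ConcentrationShiftModel()
        res = sim.default_resonances(["PC", "PE", "PA"])
        out = sim.apply_concentration_shifts(res, model, model.mass_ref)
        assert [r.center_ppm for r in out] == [r.center_ppm for r in res]

    def test_pe_moves_downfield_with_mass(self):
        model = sim.ConcentrationShiftModel()
        res = [sim.ResonanceSpec("PE", 0.55)]
        at32 = sim.apply_concentration_shifts(res, model, 32.0)[0].center_ppm
        at1 = sim.apply_concentration_shifts(res, model, 1.0)[0].center_ppm
        assert at32 > at1

    def test_pa_lpa_move_upfield(self):
        model = sim.ConcentrationShiftModel()
        for cls, center in [("PA", 5.3), ("LPA", 6.0)]:
            res = [sim.ResonanceSpec(cls, center)]
            at32 = sim.apply_concentration_shifts(res, model, 32.0)[0].center_ppm
            assert at32 < center

    def test_lpc_not_concentration_dependent(self):
        model = sim.ConcentrationShiftModel()
        res = [sim.ResonanceSpec("LPC", 0.445)]
        at1 = sim.apply_concentration_shifts(res, model, 1.0)[0].center_ppm
        at32 = sim.apply_concentration_shifts(res, model, 32.0)[0].center_ppm
        assert at1 == at32 == 0.445

    def test_pc_never_moves(self):
        model = sim.ConcentrationShiftModel(slopes={"PE": 0.01, "PC": 0.0})
        res = [sim.ResonanceSpec("PC", 0.0)]
        assert sim.apply_concentration_shifts(res, model, 32.0)[0].center_ppm == 0.0

    def test_wrong_sign_slopes_rejected(self):
        with pytest.raises(ValidationError):
            sim.ConcentrationShiftModel(slopes={"PE": -0.01})
        with pytest.raises(ValidationError):
            sim.ConcentrationShiftModel(slopes={"PA": 0.01})
        with pytest.raises(ValidationError):
            sim.ConcentrationShiftModel(slopes={"LPC": 0.01})


class TestAgeing:
    def test_age_zero_is_identity(self):
        comp = pl.LipidComposition(fractions={"PC": 0.8, "LPC": 0.2})
        out = sim.apply_ageing(comp, sim.AgeingModel(), 0.0)
        assert out.fractions == comp.fractions

    def test_default_gain_is_55_percent(self):
        comp = pl.LipidComposition(fractions={"PC": 0.8, "LPC": 0.1, "SM": 0.1})
        model = sim.AgeingModel()
        at_ref = sim.apply_ageing(comp, model, model.t_ref_hours)
        at_late = sim.apply_ageing(comp, model, model.t_late_days * 24.0)
        r_ref = at_ref.fractions["LPC"] / at_ref.fractions["PC"]
        r_late = at_late.fractions["LPC"] / at_late.fractions["PC"]
        assert r_late / r_ref - 1.0 == pytest.approx(0.55, abs=1e-9)
        assert 0.50 <= r_late / r_ref - 1.0 <= 0.60

    def test_total_phosphorus_conserved_exactly(self):
        comp = pl.LipidComposition(
            fractions={"PC": 0.5, "LPC": 0.1, "CL": 0.2, "SM": 0.2}
        )
        aged = sim.apply_ageing(comp, sim.AgeingModel(), 300.0)
        assert aged.total_phosphorus() == pytest.approx(
            comp.total_phosphorus(), abs=1e-12
        )

    def test_other_classes_untouched(self):
        comp = pl.LipidComposition(fractions={"PC": 0.6, "LPC": 0.1, "SM": 0.3})
        aged = sim.apply_ageing(comp, sim.AgeingModel(), 200.0)
        assert aged.fractions["SM"] == comp.fractions["SM"]

    def test_ratio_monotone_in_time(self):
        comp = pl.LipidComposition(fractions={"PC": 0.8, "LPC": 0.2})
        model = sim.AgeingModel()
        ratios = [
            sim.apply_ageing(comp, model, t).fractions["LPC"]
            / sim.apply_ageing(comp, model, t).fractions["PC"]
            for t in (0.0, 48.0, 200.0, 504.0)
        ]
        assert ratios == sorted(ratios)

    def test_missing_pc_rejected(self):
        comp = pl.LipidComposition(fractions={"SM": 1.0})
        with pytest.raises(ValidationError):
            sim.apply_ageing(comp, sim.AgeingModel(), 48.0)

    def test_zero_lpc_with_positive_gain_rejected(self):
        comp = pl.LipidComposition(fractions={"PC": 1.0})
        with pytest.raises(ValidationError):
            sim.apply_ageing(comp, sim.AgeingModel(), 48.0)

    @given(
        pc=st.floats(min_value=0.2, max_value=0.8),
        lpc=st.floats(min_value=0.01, max_value=0.2),
        age=st.floats(min_value=0.0, max_value=2000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, pc, lpc, age):
        other = 1.0 - pc - lpc
        comp = pl.LipidComposition(fractions={"PC": pc, "LPC": lpc, "SM": other})
        aged = sim.apply_ageing(comp, sim.AgeingModel(), age)
        assert aged.total_phosphorus() == pytest.approx(
            comp.total_phosphorus(), abs=1e-9
        )
        assert all(f >= 0 for f in aged.fractions.values())


class TestAdducts:
    def test_pc_offset_always_zero(self):
        model = sim.AdductModel()
        res = [sim.ResonanceSpec("PC", 0.0)]
        for adduct in model.offsets:
            out = sim.apply_adducts(res, model, adduct, 10.0)
            assert out[0].center_ppm == 0.0

    def test_sodium_moves_sentinel_classes(self):
        model = sim.AdductModel()
        res = sim.default_resonances(["PE", "PA", "LPA", "PI"])
        out = sim.apply_adducts(res, model, "Na+", 10.0)
        for before, after in zip(res, out):
            assert after.center_ppm != before.center_ppm

    def test_guanidinium_scales_with_amount(self):
        model = sim.AdductModel()
        res = [sim.ResonanceSpec("PA", 5.3)]
        off10 = sim.apply_adducts(res, model, "guanidinium", 10.0)[0].center_ppm - 5.3
        off50 = sim.apply_adducts(res, model, "guanidinium", 50.0)[0].center_ppm - 5.3
        assert off50 == pytest.approx(5.0 * off10)

    def test_guanidinium_zero_amount_is_identity(self):
        model = sim.AdductModel()
        res = sim.default_resonances(["PA", "PE", "PC"])
        out = sim.apply_adducts(res, model, "guanidinium", 0.0)
        assert [r.center_ppm for r in out] == [r.center_ppm for r in res]

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValidationError):
            sim.apply_adducts(
                [sim.ResonanceSpec("PA", 5.3)], sim.AdductModel(), "K+", 10.0
            )

    def test_pc_offset_in_model_rejected(self):
        with pytest.raises(ValidationError):
            sim.AdductModel(offsets={"Na+": {"PC": 0.05}})
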