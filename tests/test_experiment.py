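import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpcalib import SimConfig
from fpcalib.experiment import (
    AutofluorModel,
    QuenchModel,
    autofluorescence_points,
    blank_od,
    correct_quench,
    fit_autofluorescence,
    fit_quench_model,
    od_ratio_analysis,
    od_to_cell_volume,
    process_plate,
)
from fpcalib.model import ConversionFactor, ODCalibration
from fpcalib.synthetic import sim_growth_experiment, sim_mixing_assay


def growth_setup(cfg, induced=True):
    tidy, truth, meta = sim_growth_experiment(cfg, induced=induced)
    quench = QuenchModel(k_per_od=cfg.quench_k_per_od)
    auto = fit_autofluorescence(
        autofluorescence_points(
            tidy, meta["control_wells"], meta["media_blank_wells"], meta["pathlength_cm"]
        )
    )
    cf = ConversionFactor(
        fp_name=cfg.fp_name, cf_rfu_per_molecule=meta["true_cf"], gain=meta["gain"]
    )
    odcal = ODCalibration(od_wavelength=600, particles_per_od_cm=meta["pems_per_od"])
    return tidy, truth, meta, cf, odcal, auto, quench


class TestBlankOD:
    def make_tidy(self, values, blank=0.04):
        rows = []
        for t, v in enumerate(values):
            rows.append({"well": "A1", "time": float(t), "measure": "od600", "value": v})
            rows.append({"well": "C1", "time": float(t), "measure": "od600", "value": blank})
        return pd.DataFrame(rows)

    def test_sample_equal_blank_gives_zero(self):
        out = blank_od(self.make_tidy([0.04, 0.04]), ["C1"], 1.0)
        assert np.allclose(out["od_per_cm"], 0.0)

    def test_arithmetic(self):
        out = blank_od(self.make_tidy([0.54]), ["C1"], 0.5)
        assert out["od_per_cm"].item() == pytest.approx(1.0)

    def test_negative_floored_and_flagged(self):
        out = blank_od(self.make_tidy([0.02]), ["C1"], 1.0)
        assert out["od_per_cm"].item() == 0.0 and out["od_floored"].item()

    def test_missing_blanks_error(self):
        with pytest.raises(ValueError, match="blank"):
            blank_od(self.make_tidy([0.5]), ["Z9"], 1.0)

    def test_simulator_track_recovered_within_noise(self):
        cfg = SimConfig(seed=31, growth_od_noise_sd=0.002, rfu_cv=0.0)
        tidy, truth, meta = sim_growth_experiment(cfg)
        out = blank_od(tidy, meta["media_blank_wells"], meta["pathlength_cm"])
        m = out.merge(truth, on=["well", "time"])
        resid = m["od_per_cm"] - m["od600_per_cm"]
        assert np.abs(resid).max() < 6 * 0.002


class TestAutofluorescence:
    def test_zero_control_gives_zero_model(self):
        model = fit_autofluorescence([(0.1 * i, 0.0) for i in range(6)])
        assert model.predict(0.3) == 0.0

    def test_linear_control(self):
        model = fit_autofluorescence([(0.1 * i, 10.0 * i) for i in range(6)])
        assert model.predict(0.3) == pytest.approx(30.0)

    def test_prediction_clamped_to_range(self):
        model = fit_autofluorescence([(0.1 * i, 10.0 * i) for i in range(6)])
        assert model.predict(5.0) == pytest.approx(50.0)

    def test_non_monotone_input_isotonically_repaired(self):
        pts = [(0.0, 0.0), (0.1, 12.0), (0.2, 8.0), (0.3, 30.0), (0.4, 40.0)]
        model = fit_autofluorescence(pts)
        assert model.isotonic_applied
        assert np.all(np.diff(model.rfu_points) >= 0)

    def test_saturating_curve_recovered_within_5pct(self):
        od = np.linspace(0.01, 2.0, 40)
        rfu = 200.0 * od / (0.5 + od)
        model = fit_autofluorescence(list(zip(od, rfu)))
        probe = np.linspace(0.05, 1.9, 17)
        np.testing.assert_allclose(model.predict(probe), 200.0 * probe / (0.5 + probe), rtol=0.05)


class TestQuenchModel:
    def test_no_quenching_fits_k_zero(self):
        rows = [(od, 100.0, 100.0) for od in (0.0, 0.5, 1.0, 2.0)]
        model = fit_quench_model(rows)
        assert model.k_per_od == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_exponential_recovered(self):
        cfg = SimConfig(seed=41, rfu_cv=0.0, quench_k_per_od=0.178)
        model = fit_quench_model(sim_mixing_assay(cfg))
        assert model.k_per_od == pytest.approx(0.178, abs=1e-6)

    def test_retained_fraction_at_zero_od_is_one(self):
        model = QuenchModel(k_per_od=0.7)
        assert model.retained_fraction(0.0) == 1.0

    def test_correction_definition(self):
        model = QuenchModel(k_per_od=np.log(1 / 0.7))
        assert correct_quench(70.0, 1.0, model) == pytest.approx(100.0)
        assert correct_quench(70.0, 0.0, model) == pytest.approx(70.0)

    def test_quench_then_correct_round_trip(self):
        model = QuenchModel(k_per_od=0.178)
        od = np.linspace(0, 2, 9)
        rfu = 1e4 * np.exp(-0.178 * od)
        np.testing.assert_allclose(correct_quench(rfu, od, model), 1e4, rtol=1e-9)

    def test_extrapolation_floor_refused(self):
        model = QuenchModel(k_per_od=2.0)
        with pytest.raises(ValueError, match="retained fraction"):
            correct_quench(10.0, 5.0, model)

    @given(
        k=st.floats(0.0, 1.0),
        ods=st.lists(st.floats(0.0, 2.0), min_size=4, max_size=10, unique=True),
    )
    @settings(max_examples=40, deadline=None)
    def test_fitted_model_invariants_on_random_valid_inputs(self, k, ods):
        """retained(0) = 1 and monotone non-increase for any valid fit."""
        rows = [(od, 100.0 * np.exp(-k * od), 100.0) for od in ods]
        if len({round(o, 6) for o in ods}) < 4:
            return
        model = fit_quench_model(rows)
        grid = np.linspace(0, 2, 50)
        vals = model.retained_fraction(grid)
        assert vals[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals > 0) & (vals <= 1.0 + 1e-12))


class TestCellVolume:
    def test_reference_constant(self):
        """One OD600/cm in 1 ml of culture is ~3.6 ul of cells."""
        assert od_to_cell_volume(1.0, 1.0) == pytest.approx(3.6)

    def test_zero(self):
        assert od_to_cell_volume(0.0, 1.0) == 0.0

    def test_scaling(self):
        assert od_to_cell_volume(0.5, 0.2) == pytest.approx(0.36)


class TestProcessPlate:
    def test_noiseless_constant_expression_recovered(self, noiseless_cfg):
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        res = process_plate(
            tidy, cf, odcal, auto, quench, meta["culture_volume_ul"],
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        ok = res[~res["few_cells"] & res["well"].isin(meta["sample_wells"])]
        m = ok.merge(truth, on=["well", "time"], suffixes=("", "_true"))
        np.testing.assert_allclose(
            m["molecules_per_cell"], m["molecules_per_cell_true"], rtol=0.02
        )

    def test_uninduced_fixture_near_zero(self, noiseless_cfg):
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg, induced=False)
        res = process_plate(
            tidy, cf, odcal, auto, quench, meta["culture_volume_ul"],
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        ok = res[~res["few_cells"] & res["well"].isin(meta["sample_wells"])]
        assert np.nanmax(np.abs(ok["molecules_per_cell"])) < 1.0

    def test_unit_chain_conservation(self, noiseless_cfg):
        """molecules_per_cell x cells == mefp for every unflagged row."""
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        res = process_plate(
            tidy, cf, odcal, auto, quench, meta["culture_volume_ul"],
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        ok = res[~res["few_cells"]]
        np.testing.assert_allclose(ok["molecules_per_cell"] * ok["cells"], ok["mefp"], rtol=1e-12)

    def test_molar_concentration_consistent_with_mefp_and_cell_volume(self, noiseless_cfg):
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        res = process_plate(
            tidy, cf, odcal, auto, quench, meta["culture_volume_ul"],
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        ok = res[res["od_per_cm"] > 0]
        vol_l = od_to_cell_volume(ok["od_per_cm"], meta["culture_volume_ul"] / 1000.0) * 1e-6
        np.testing.assert_allclose(
            ok["conc_M"], ok["mefp"] / (6.02214076e23 * vol_l), rtol=1e-9
        )

    def test_pipeline_inversion_returns_original_rfu(self, noiseless_cfg):
        """mefp·cf re-quenched plus autofluorescence reproduces the raw RFU."""
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        res = process_plate(
            tidy, cf, odcal, auto, quench, meta["culture_volume_ul"],
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        fluor = tidy[(tidy["measure"] == "fluorescence")][["well", "time", "value"]]
        m = res.merge(fluor, on=["well", "time"])
        rebuilt = (
            m["mefp"] * cf.cf_rfu_per_molecule
            * quench.retained_fraction(m["od_per_cm"].to_numpy())
            + auto.predict(m["od_per_cm"].to_numpy())
        )
        np.testing.assert_allclose(rebuilt, m["value"], rtol=1e-9)

    def test_disabling_quench_correction_biases_low_by_retained_fraction(self, noiseless_cfg):
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        res_off = process_plate(
            tidy, cf, odcal, auto, QuenchModel(k_per_od=0.0), meta["culture_volume_ul"],
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        ok = res_off[~res_off["few_cells"] & res_off["well"].isin(meta["sample_wells"])]
        m = ok.merge(truth, on=["well", "time"], suffixes=("", "_true"))
        expected = m["molecules_per_cell_true"] * np.exp(
            -noiseless_cfg.quench_k_per_od * m["od600_per_cm"]
        )
        np.testing.assert_allclose(m["molecules_per_cell"], expected, rtol=1e-6)

    def test_intensive_concentration_under_volume_change(self, noiseless_cfg):
        """conc_M does not depend on the assumed culture volume."""
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        r1 = process_plate(
            tidy, cf, odcal, auto, quench, 200.0,
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        r2 = process_plate(
            tidy, cf, odcal, auto, quench, 400.0,
            meta["media_blank_wells"], meta["pathlength_cm"],
        )
        ok = r1["od_per_cm"] > 0
        np.testing.assert_allclose(r1.loc[ok, "conc_M"], 2 * r2.loc[ok, "conc_M"], rtol=1e-9)

    def test_calibration_instrument_mismatch_errors(self, noiseless_cfg):
        tidy, truth, meta, cf, odcal, auto, quench = growth_setup(noiseless_cfg)
        bad = odcal.model_copy(update={"instrument": "other"})
        with pytest.raises(ValueError, match="instrument"):
            process_plate(
                tidy, cf, bad, auto, quench, 200.0,
                meta["media_blank_wells"], meta["pathlength_cm"],
            )


class TestODRatioAnalysis:
    def test_reference_relation_recovered_with_noise(self):
        cfg = SimConfig(seed=51, growth_od_noise_sd=0.005, rfu_cv=0.0)
        tidy, _, meta = sim_growth_experiment(cfg, induced=False)
        res = od_ratio_analysis(
            tidy, meta["sample_wells"] + meta["control_wells"],
            media_blank_wells=meta["media_blank_wells"],
            pathlength_cm=meta["pathlength_cm"],
        )
        assert res.slope == pytest.approx(1.30, abs=0.02)
        assert res.intercept == pytest.approx(-0.02, abs=0.005)

    def test_reference_wells_self_error_near_one(self):
        cfg = SimConfig(seed=52, growth_od_noise_sd=0.005, rfu_cv=0.0)
        tidy, _, meta = sim_growth_experiment(cfg, induced=False)
        res = od_ratio_analysis(
            tidy, meta["sample_wells"],
            media_blank_wells=meta["media_blank_wells"],
            pathlength_cm=meta["pathlength_cm"],
        )
        ref = res.errors[res.errors["well"].isin(meta["sample_wells"])]
        big = ref[ref["od700"] > 0.2]  # ratio unstable near zero OD
        assert big["od600_error"].mean() == pytest.approx(1.0, abs=0.02)

    def test_od600_inflation_detected(self):
        """Wells whose OD600 is inflated 5% read a median error near 1.05."""
        cfg = SimConfig(seed=53, growth_od_noise_sd=0.0, rfu_cv=0.0)
        tidy, _, meta = sim_growth_experiment(cfg, induced=False)
        inflated = tidy.copy()
        sel = (inflated["measure"] == "od600") & inflated["well"].isin(["A1", "A2", "A3"])
        blanked = inflated.loc[sel, "value"] - cfg.media_blank_od
        inflated.loc[sel, "value"] = cfg.media_blank_od + blanked * 1.05
        res = od_ratio_analysis(
            inflated, meta["control_wells"],
            media_blank_wells=meta["media_blank_wells"],
            pathlength_cm=meta["pathlength_cm"],
        )
        err = res.errors[res.errors["well"].isin(["A1", "A2", "A3"])]
        assert err[err["od700"] > 0.1]["od600_error"].median() == pytest.approx(1.05, abs=0.01)

    def test_too_few_reference_points_errors(self):
        rows = []
        for t in range(3):
            rows.append({"well": "A1", "time": float(t), "measure": "od600", "value": 0.5})
            rows.append({"well": "A1", "time": float(t), "measure": "od700", "value": 0.4})
        with pytest.raises(ValueError, match="reference"):
            od_ratio_analysis(pd.DataFrame(rows), ["A1"])
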