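import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinselect import (
    CompetitiveKiRegression,
    KineticAssay,
    LineweaverBurkRegression,
    cheng_prusoff,
    fit_ic50,
    fit_ki_replot,
    fit_lineweaver_burk,
    ic50_from_ki,
    mm_velocity,
    read_dose_response_csv,
    read_kinetics_csv,
    residual_activity_curve,
)
from kinselect.kinetics import (
    DesignError,
    NoInhibitionError,
    NonHyperbolicDataError,
    UnidentifiableError,
)
from kinselect.simulate import KineticSimSpec, simulate_kinetic_assay

S_GRID = (5.0, 10.0, 20.0, 40.0, 80.0)
I_GRID = (0.0, 0.05, 0.1, 0.2)


def noiseless_assay(Vmax=1.0, Km=13.0, Ki=0.058, S_grid=S_GRID, I_grid=I_GRID):
    return simulate_kinetic_assay(
        KineticSimSpec(Vmax=Vmax, Km=Km, Ki=Ki, S_grid=S_grid, I_grid=I_grid,
                       replicates=1, cv=0.0)
    )


class TestMMVelocity:
    def test_half_saturation(self):
        assert mm_velocity(2, 10, 10) == pytest.approx(1.0)

    def test_inhibitor_at_ki_doubles_apparent_km(self):
        assert mm_velocity(2, 10, 20, I=0.5, Ki=0.5) == pytest.approx(1.0)

    def test_monotone_vanishing_in_inhibitor(self):
        I = np.array([0, 1, 10, 100, 1e6])
        v = mm_velocity(2, 10, 10, I=I, Ki=0.5)
        assert np.all(np.diff(v) < 0) and v[-1] < 1e-4

    @pytest.mark.parametrize("kw", [{"Vmax": 0}, {"Km": -1}, {"Ki": 0}, {"S": 0}])
    def test_nonpositive_parameters_rejected(self, kw):
        params = {"Vmax": 2.0, "Km": 10.0, "S": 10.0, "I": 0.0, "Ki": 1.0, **kw}
        with pytest.raises(ValueError):
            mm_velocity(**params)


class TestLineweaverBurk:
    def test_exact_inversion_noiseless(self):
        S = np.array([2.5, 5, 10, 20, 40])
        v = mm_velocity(2, 10, S)
        fit = LineweaverBurkRegression().fit(S, v)
        assert fit.Km_ == pytest.approx(10, rel=1e-9)
        assert fit.Vmax_ == pytest.approx(2, rel=1e-9)

    def test_competitive_signature_km_app(self):
        assay = noiseless_assay(Vmax=2.0, Km=10.0, Ki=0.5, I_grid=(0.0, 0.5))
        fit = fit_lineweaver_burk(assay, 0.5)
        assert fit.Km == pytest.approx(20, rel=1e-9)  # (1 + I/Ki) = 2
        assert fit.Vmax == pytest.approx(2, rel=1e-9)  # Vmax untouched

    def test_direct_fit_agrees_on_noiseless_data(self, rng):
        for _ in range(10):
            Vmax, Km = rng.uniform(0.5, 5), rng.uniform(2, 50)
            S = np.array(S_GRID)
            v = mm_velocity(Vmax, Km, S)
            lb = LineweaverBurkRegression().fit(S, v)
            nl = LineweaverBurkRegression(method="direct").fit(S, v)
            assert nl.Km_ == pytest.approx(lb.Km_, rel=1e-6)
            assert nl.Vmax_ == pytest.approx(lb.Vmax_, rel=1e-6)

    def test_too_few_substrate_levels(self):
        with pytest.raises(DesignError):
            LineweaverBurkRegression().fit([5, 10], [0.2, 0.4])

    def test_non_hyperbolic_data_rejected(self):
        # superlinear v(S): reciprocal line has a negative intercept
        with pytest.raises(NonHyperbolicDataError):
            LineweaverBurkRegression().fit([1, 2, 4], [1, 4, 20])

    def test_predict_on_fitted_hyperbola(self):
        S = np.array(S_GRID)
        fit = LineweaverBurkRegression().fit(S, mm_velocity(1.5, 8, S))
        assert fit.predict([8]) == pytest.approx([0.75], rel=1e-9)


class TestKiReplot:
    def test_exact_inversion_noiseless(self):
        assay = noiseless_assay(Vmax=1.0, Km=13.0, Ki=0.058)
        fit = fit_ki_replot(assay)
        assert fit.Ki == pytest.approx(0.058, rel=1e-9)
        assert fit.replot_intercept == pytest.approx(13.0, rel=1e-9)  # Km/Vmax at I=0

    def test_replot_slope_is_affine_in_inhibitor(self):
        assay = noiseless_assay(Vmax=2.0, Km=10.0, Ki=0.5)
        est = CompetitiveKiRegression().fit(assay)
        slopes = np.array([f.slope for f in est.per_conc_fits_])
        expected = (10.0 / 2.0) * (1 + np.array(I_GRID) / 0.5)
        assert np.allclose(slopes, expected, rtol=1e-9)

    def test_no_inhibition_detected(self):
        # identical velocities at every inhibitor concentration
        rows = [
            {"substrate_uM": S, "inhibitor_uM": I, "replicate": 1,
             "velocity": mm_velocity(1.0, 13.0, S)}
            for I in I_GRID for S in S_GRID
        ]
        assay = KineticAssay(pd.DataFrame(rows))
        with pytest.raises(NoInhibitionError):
            fit_ki_replot(assay)

    def test_needs_multiple_inhibitor_concentrations(self):
        assay = noiseless_assay(I_grid=(0.0,))
        with pytest.raises(DesignError):
            fit_ki_replot(assay)

    def test_assay_requires_uninhibited_control(self):
        rows = [
            {"substrate_uM": S, "inhibitor_uM": 0.1, "replicate": 1, "velocity": 1.0}
            for S in S_GRID
        ]
        with pytest.raises(DesignError, match="control"):
            KineticAssay(pd.DataFrame(rows))


class TestIC50:
    def test_exact_inversion_noiseless(self):
        I = np.array([0.01, 0.05, 0.15, 0.5, 1.5])
        dose = pd.DataFrame(
            {"inhibitor_uM": I, "activity_percent": 100 / (1 + I / 0.15)}
        )
        assert fit_ic50(dose).IC50 == pytest.approx(0.15, rel=1e-9)

    def test_flat_curve_unidentifiable(self):
        dose = pd.DataFrame(
            {"inhibitor_uM": [0.01, 0.1, 1, 10], "activity_percent": [100.0] * 4}
        )
        with pytest.raises(UnidentifiableError):
            fit_ic50(dose)

    def test_too_few_concentrations(self):
        dose = pd.DataFrame({"inhibitor_uM": [0.1, 1, 10], "activity_percent": [90, 50, 10]})
        with pytest.raises(DesignError):
            fit_ic50(dose)

    def test_equivalence_with_competitive_residual_activity(self):
        # a(I) from the competitive MM law is the h=1 logistic with
        # midpoint Ki·(1+S/Km)
        Km, S, Ki = 13.0, 20.0, 0.675
        dose = residual_activity_curve(Km, S, Ki, [0.05, 0.2, 0.675, 2, 5, 20])
        assert fit_ic50(dose).IC50 == pytest.approx(Ki * (1 + S / Km), rel=1e-6)

    def test_free_hill_slope_recovers_steeper_curve(self):
        I = np.array([0.01, 0.03, 0.1, 0.3, 1.0])
        a = 100 / (1 + (I / 0.1) ** 2)
        dose = pd.DataFrame({"inhibitor_uM": I, "activity_percent": a})
        fit = fit_ic50(dose, hill_slope=None)
        assert fit.IC50 == pytest.approx(0.1, rel=1e-6)
        assert fit.hill_slope == pytest.approx(2.0, rel=1e-6)


class TestChengPrusoff:
    def test_substrate_at_km_halves(self):
        assert cheng_prusoff(2.0, S=10.0, Km=10.0) == pytest.approx(1.0)

    def test_no_substrate_means_identity(self):
        assert cheng_prusoff(0.15, S=0.0, Km=13.0) == 0.15

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(1e-3, 1e3), st.floats(0, 1e3), st.floats(1e-3, 1e3)
    )
    def test_round_trip_identity(self, Ki, S, Km):
        assert cheng_prusoff(ic50_from_ki(Ki, S, Km), S, Km) == pytest.approx(
            Ki, rel=1e-12
        )

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            cheng_prusoff(1.0, 10.0, 0.0)


class TestResidualActivityCurve:
    def test_control_and_midpoint(self):
        Km, S, Ki = 13.0, 20.0, 0.058
        ic50 = ic50_from_ki(Ki, S, Km)
        curve = residual_activity_curve(Km, S, Ki, [0.0, ic50])
        assert curve["activity_percent"].iloc[0] == pytest.approx(100.0)
        assert curve["activity_percent"].iloc[1] == pytest.approx(50.0)

    def test_strong_inhibition_regime_at_panel_concentration(self):
        # at 1 µM and holoenzyme-like parameters the model sits deep in
        # the inhibited regime, consistent with a ~10 % panel readout
        curve = residual_activity_curve(13.0, 20.0, 0.058, [1.0])
        assert curve["activity_percent"].iloc[0] < 20.0


class TestIO:
    def test_kinetics_csv_round_trip(self, tmp_path):
        assay = noiseless_assay()
        path = tmp_path / "assay.csv"
        assay.to_csv(path)
        back = read_kinetics_csv(path)
        pd.testing.assert_frame_equal(back.data, assay.data)

    def test_dose_csv_requires_columns(self, tmp_path):
        path = tmp_path / "dose.csv"
        pd.DataFrame({"conc": [1], "act": [50]}).to_csv(path, index=False)
        with pytest.raises(DesignError):
            read_dose_response_csv(path)
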