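"""Rate law, replot chain, global fitting and dose-response tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bindkin as bk
from bindkin.kinetics import (
    INHIBITOR_COL,
    SUBSTRATE_COL,
    VELOCITY_COL,
    MODEL_LINEAR_MIXED,
    MODEL_PARTIAL_MIXED,
    MODEL_PURE_NC,
)
from conftest import noiseless_kinetics


class TestVelocity:
    def test_no_inhibitor_is_michaelis_menten(self, linear_mixed_params):
        p = linear_mixed_params
        S = 250.0
        assert bk.velocity(p, S, 0.0) == pytest.approx(p.Vmax * S / (p.Km + S))

    def test_pure_noncompetitive_closed_form(self):
        # S = Km halves the MM term, I = Ki halves it again: v = Vmax/4
        p = bk.KineticParameters(100.0, 100.0, 5.0, 5.0, 0.0)
        assert bk.velocity(p, 100.0, 5.0) == pytest.approx(25.0)

    def test_high_substrate_limit(self, linear_mixed_params):
        p = linear_mixed_params
        I = 10.0
        limit = p.Vmax / (1.0 + I / p.Ki_prime)
        assert bk.velocity(p, 1e6 * p.Km, I) == pytest.approx(limit, rel=1e-3)

    @given(
        I1=st.floats(0.0, 50.0), dI=st.floats(0.1, 50.0), S=st.floats(1.0, 1000.0)
    )
    def test_strictly_decreasing_in_inhibitor(self, I1, dI, S):
        p = bk.KineticParameters(100.0, 100.0, 3.67, 4.97, 0.3)
        assert bk.velocity(p, S, I1 + dI) < bk.velocity(p, S, I1)

    @given(S=st.floats(1.0, 1e5), factor=st.floats(1.01, 100.0))
    def test_strictly_increasing_and_saturating_in_substrate(self, S, factor):
        p = bk.KineticParameters(100.0, 100.0, 3.67, 4.97, 0.0)
        assert bk.velocity(p, S * factor, 5.0) > bk.velocity(p, S, 5.0)
        assert bk.velocity(p, S, 5.0) < p.Vmax

    def test_noncompetitive_collapse_on_grid(self):
        p = bk.KineticParameters(100.0, 100.0, 7.5, 7.5, 0.0)
        for S in (10.0, 100.0, 1000.0):
            v0 = p.Vmax * S / (p.Km + S)
            for I in (0.0, 2.0, 7.5, 30.0):
                assert bk.velocity(p, S, I) == pytest.approx(v0 / (1 + I / p.Ki))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(bk.InputError):
            bk.KineticParameters(100.0, -1.0, 5.0, 5.0)
        with pytest.raises(bk.InputError):
            bk.KineticParameters(100.0, 100.0, 5.0, 5.0, b=1.0)


class TestLineweaverBurk:
    def test_uninhibited_group_recovers_mm_reciprocal(self):
        p = bk.KineticParameters(100.0, 100.0, 5.0, 10.0, 0.0)
        df = noiseless_kinetics(p, substrate_grid=(20.0, 50.0, 100.0, 200.0, 500.0),
                                inhibitor_grid=(0.0, 2.5, 5.0))
        replots = bk.lineweaver_burk(df)
        base = replots.row(0.0)
        assert base["slope"] == pytest.approx(p.Km / p.Vmax)
        assert base["intercept"] == pytest.approx(1.0 / p.Vmax)
        assert base["r2"] == pytest.approx(1.0)

    def test_slope_ratio_follows_one_plus_i_over_ki(self):
        p = bk.KineticParameters(100.0, 100.0, 5.0, 10.0, 0.0)
        df = noiseless_kinetics(p, substrate_grid=(20.0, 50.0, 100.0, 200.0, 500.0),
                                inhibitor_grid=(0.0, 2.5, 5.0))
        replots = bk.lineweaver_burk(df)
        ratio = replots.row(5.0)["slope"] / replots.row(0.0)["slope"]
        assert ratio == pytest.approx(2.0, rel=1e-10)

    def test_secondary_slope_replot_exactly_linear(self, linear_mixed_params):
        df = noiseless_kinetics(linear_mixed_params)
        replots = bk.lineweaver_burk(df)
        I = replots.primary[INHIBITOR_COL]
        slopes = replots.primary["slope"]
        lin = np.polyfit(I, slopes, 1)
        assert np.allclose(np.polyval(lin, I), slopes, rtol=1e-8)

    def test_small_group_skipped_with_warning(self, linear_mixed_params):
        df = noiseless_kinetics(linear_mixed_params)
        extra = pd.DataFrame(
            {SUBSTRATE_COL: [100.0], INHIBITOR_COL: [99.0], VELOCITY_COL: [1.0],
             "replicate": [1]}
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            replots = bk.lineweaver_burk(pd.concat([df, extra], ignore_index=True))
        assert 99.0 not in replots.primary[INHIBITOR_COL].to_numpy()

    def test_missing_uninhibited_group_rejected(self, linear_mixed_params):
        df = noiseless_kinetics(linear_mixed_params)
        df = df[df[INHIBITOR_COL] > 0]
        with pytest.raises(bk.InputError):
            bk.lineweaver_burk(df)

    def test_nonpositive_velocity_rejected(self, linear_mixed_params):
        df = noiseless_kinetics(linear_mixed_params).copy()
        df.loc[0, VELOCITY_COL] = 0.0
        with pytest.raises(bk.InputError):
            bk.lineweaver_burk(df)


class TestSecondaryClassification:
    def test_noiseless_linear_mixed_is_linear(self, linear_mixed_params):
        replots = bk.lineweaver_burk(noiseless_kinetics(linear_mixed_params))
        assert bk.classify_secondary(replots).verdict == "linear"

    def test_noiseless_partial_mixed_is_nonlinear(self, partial_mixed_params):
        # note: curvature power vanishes when b*Ki ~ Ki' (slope(I) nearly
        # constant); this instance (b=0.3) is safely away from that ridge
        replots = bk.lineweaver_burk(noiseless_kinetics(partial_mixed_params))
        cls = bk.classify_secondary(replots)
        assert cls.verdict == "nonlinear"
        assert cls.slope_verdict == "nonlinear"

    def test_three_inhibitor_levels_inconclusive(self, linear_mixed_params):
        df = noiseless_kinetics(linear_mixed_params, inhibitor_grid=(0.0, 5.0, 10.0))
        cls = bk.classify_secondary(bk.lineweaver_burk(df))
        assert cls.verdict == "inconclusive"


class TestTertiaryReplot:
    def test_partial_mixed_roundtrip_within_one_percent(self, partial_mixed_params):
        p = partial_mixed_params
        replots = bk.lineweaver_burk(noiseless_kinetics(p))
        fit = bk.tertiary_replot_fit(replots)
        assert fit.Ki == pytest.approx(p.Ki, rel=0.01)
        assert fit.Ki_prime == pytest.approx(p.Ki_prime, rel=0.01)
        assert fit.b == pytest.approx(p.b, rel=0.01)

    def test_linear_mixed_limit_recovers_ki(self, linear_mixed_params):
        replots = bk.lineweaver_burk(noiseless_kinetics(linear_mixed_params))
        fit = bk.tertiary_replot_fit(replots)
        assert fit.Ki == pytest.approx(linear_mixed_params.Ki, rel=0.01)
        assert fit.Ki_prime == pytest.approx(linear_mixed_params.Ki_prime, rel=0.01)

    def test_sign_change_in_deltas_rejected(self):
        primary = pd.DataFrame(
            {INHIBITOR_COL: [0.0, 1.0, 2.0, 4.0],
             "slope": [1.0, 1.5, 0.8, 1.9],  # delta changes sign
             "intercept": [0.01, 0.02, 0.03, 0.05],
             "r2": [1.0] * 4, "n_points": [5] * 4}
        )
        tert = pd.DataFrame(
            {INHIBITOR_COL: [1.0, 2.0, 4.0],
             "inv_I": [1.0, 0.5, 0.25],
             "inv_dslope": [2.0, -5.0, 1.11],
             "inv_dintercept": [100.0, 50.0, 25.0]}
        )
        with pytest.raises(bk.InputError):
            bk.tertiary_replot_fit(bk.ReplotSet(primary=primary, tertiary=tert))


class TestGlobalFit:
    def test_noiseless_pure_noncompetitive_exact_recovery(self):
        p = bk.KineticParameters(100.0, 100.0, 9.55, 9.55, 0.0)
        df = noiseless_kinetics(p)
        fit = bk.global_fit(df, model=MODEL_PURE_NC)
        assert fit.parameters.Ki == pytest.approx(9.55, rel=1e-6)
        assert fit.parameters.Vmax == pytest.approx(100.0, rel=1e-6)
        assert fit.parameters.Km == pytest.approx(100.0, rel=1e-6)

    def test_noiseless_partial_mixed_exact_recovery(self, partial_mixed_params):
        df = noiseless_kinetics(partial_mixed_params)
        fit = bk.global_fit(df, model=MODEL_PARTIAL_MIXED)
        assert fit.parameters.Ki == pytest.approx(3.69, rel=1e-5)
        assert fit.parameters.Ki_prime == pytest.approx(1.45, rel=1e-5)
        assert fit.parameters.b == pytest.approx(0.3, rel=1e-4)

    def test_replot_and_global_fit_agree_on_noiseless_linear_data(
        self, linear_mixed_params
    ):
        df = noiseless_kinetics(linear_mixed_params)
        fit = bk.global_fit(df, model=MODEL_LINEAR_MIXED)
        replot_fit = bk.tertiary_replot_fit(bk.lineweaver_burk(df))
        assert fit.parameters.Ki == pytest.approx(replot_fit.Ki, rel=1e-5)
        assert fit.parameters.Ki_prime == pytest.approx(replot_fit.Ki_prime, rel=1e-5)

    def test_auto_labels_models_from_secondary_replots(
        self, linear_mixed_params, partial_mixed_params
    ):
        fit_lin = bk.global_fit(noiseless_kinetics(linear_mixed_params), model="auto")
        assert fit_lin.model == MODEL_LINEAR_MIXED
        assert fit_lin.classification.verdict == "linear"
        fit_par = bk.global_fit(noiseless_kinetics(partial_mixed_params), model="auto")
        assert fit_par.model == MODEL_PARTIAL_MIXED

    def test_auto_collapses_to_pure_noncompetitive(self):
        p = bk.KineticParameters(100.0, 100.0, 9.55, 9.55, 0.0)
        spec = bk.KineticGeneratorSpec(params=p, noise_cv=0.02, replicates=3, seed=4)
        fit = bk.global_fit(bk.gen_kinetic_data(spec), model="auto")
        assert fit.model == MODEL_PURE_NC
        assert fit.parameters.Ki == pytest.approx(9.55, rel=0.25)

    def test_degenerate_velocities_rejected(self):
        df = pd.DataFrame(
            {SUBSTRATE_COL: [20.0, 50.0, 100.0] * 2,
             INHIBITOR_COL: [0.0] * 3 + [5.0] * 3,
             VELOCITY_COL: [1.0] * 6, "replicate": [1] * 6}
        )
        with pytest.raises(bk.FitError):
            bk.global_fit(df, model=MODEL_LINEAR_MIXED)

    def test_standard_errors_reported_for_noisy_fit(self, linear_mixed_params):
        spec = bk.KineticGeneratorSpec(
            params=linear_mixed_params, noise_cv=0.02, replicates=3, seed=9
        )
        fit = bk.global_fit(bk.gen_kinetic_data(spec), model=MODEL_LINEAR_MIXED)
        assert set(fit.standard_errors) == {"Vmax", "Km", "Ki", "Ki_prime"}
        assert all(v > 0 for v in fit.standard_errors.values())


class TestDoseResponse:
    @staticmethod
    def four_pl(c, ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)

    def test_noiseless_roundtrip_four_significant_digits(self):
        conc = np.logspace(-1, 2, 9)
        resp = self.four_pl(conc, 5.45, 1.0, 100.0, 0.0)
        df = pd.DataFrame({"conc_uM": conc, "response_pct": resp})
        fit = bk.fit_ic50(df)
        assert fit.ic50 == pytest.approx(5.45, rel=1e-4)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-3)

    def test_constrained_plateaus(self):
        conc = np.logspace(-1, 2, 7)
        resp = self.four_pl(conc, 11.17, 1.2, 100.0, 0.0)
        df = pd.DataFrame({"conc_uM": conc, "response_pct": resp})
        fit = bk.fit_ic50(df, constrain=(100.0, 0.0))
        assert fit.ic50 == pytest.approx(11.17, rel=1e-4)
        assert fit.top == 100.0 and fit.bottom == 0.0

    def test_pure_noncompetitive_activity_gives_ic50_equal_ki(self):
        # residual activity v/v0 = 1/(1 + I/Ki) at any substrate concentration
        p = bk.KineticParameters(100.0, 100.0, 19.53, 19.53, 0.0)
        conc = np.logspace(-0.5, 2.5, 9)
        ic50s = []
        for S in (0.1 * p.Km, p.Km, 10 * p.Km):
            v0 = bk.velocity(p, S, 0.0)
            resp = 100.0 * np.array([bk.velocity(p, S, I) for I in conc]) / v0
            fit = bk.fit_ic50(pd.DataFrame({"conc_uM": conc, "response_pct": resp}))
            ic50s.append(fit.ic50)
        assert all(ic == pytest.approx(p.Ki, rel=0.01) for ic in ic50s)
        assert (max(ic50s) - min(ic50s)) / min(ic50s) < 0.01

    def test_flat_responses_rejected(self):
        df = pd.DataFrame({"conc_uM": np.logspace(0, 2, 6), "response_pct": 100.0})
        with pytest.raises(bk.FitError):
            bk.fit_ic50(df)

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame({"conc_uM": [1.0, 2.0, 4.0], "response_pct": [90, 50, 10]})
        with pytest.raises(bk.InputError):
            bk.fit_ic50(df)


class TestAssayHelpers:
    def test_percent_inhibition_bounds(self):
        assert bk.percent_inhibition(2.0, 0.0) == 100.0
        assert bk.percent_inhibition(2.0, 2.0) == 0.0
        assert bk.percent_inhibition(2.0, 0.109) == pytest.approx(94.55)

    def test_activation_warns(self):
        with pytest.warns(UserWarning):
            assert bk.percent_inhibition(1.0, 1.5) == pytest.approx(-50.0)

    def test_activity_from_absorbance_scaling(self):
        # dA = 0.0096/min at eps 9600, 1 cm, 1 mL -> 1e-6 M/min * 1 mL = 1e-3 U
        assert bk.activity_from_absorbance(0.0096, 9600.0, 1.0, 1e-3) == pytest.approx(
            0.001
        )
        assert bk.activity_from_absorbance(0.0, 9600.0, 1.0, 1e-3) == 0.0
        assert bk.activity_from_absorbance(9.6, 9600.0, 1.0, 1.0) == pytest.approx(
            1000.0
        )
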