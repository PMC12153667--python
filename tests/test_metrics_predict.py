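import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from odbatools.modeling import (
    ModelSpec,
    compute_icc,
    compute_mcc,
    fit_lmm_ar1,
    k_fold_cv,
    plasticity_surface,
    predict_daily_odba,
)
from odbatools.modeling.lmm import ModelFit
from odbatools.modeling.metrics import VarianceDecomposition


class TestIcc:
    @pytest.mark.parametrize("vi,vr,expected", [
        (0.0, 1.0, 0.0), (2.0, 2.0, 0.5), (2.0, 6.0, 0.25), (3.0, 1.0, 0.75)])
    def test_known_ratios(self, vi, vr, expected):
        assert compute_icc(vi, vr) == pytest.approx(expected)
        assert VarianceDecomposition(vi, vr).icc == pytest.approx(expected)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            compute_icc(0.0, 0.0)
        with pytest.raises(ValueError):
            compute_icc(-1.0, 1.0)

    @given(vi=st.floats(0, 100), vr=st.floats(1e-6, 100))
    @settings(max_examples=50, deadline=None)
    def test_always_in_unit_interval(self, vi, vr):
        assert 0.0 <= compute_icc(vi, vr) <= 1.0


class TestMcc:
    def test_perfect_classifier(self):
        assert compute_mcc(tp=50, tn=50, fp=0, fn=0) == 1.0

    def test_perfectly_inverted_classifier(self):
        assert compute_mcc(tp=0, tn=0, fp=50, fn=50) == -1.0

    def test_no_association(self):
        assert compute_mcc(25, 25, 25, 25) == 0.0

    def test_degenerate_margin_returns_zero(self):
        assert compute_mcc(tp=10, tn=0, fp=10, fn=0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_mcc(-1, 1, 1, 1)

    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_matches_sklearn(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        from sklearn.metrics import matthews_corrcoef
        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        assert compute_mcc(tp, tn, fp, fn) == pytest.approx(
            matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestKFoldCv:
    def test_separable_data_near_perfect(self, small_study):
        data = small_study["data"].copy()
        # labels fully determined by the circadian phase
        data["active"] = (data["hour"].between(20, 23)
                          | data["hour"].between(2, 6)).astype(int)
        spec = ModelSpec(response="active", ar1=False, n_knots=10)
        cv = k_fold_cv(data, spec, k=5, seed=3)
        assert cv["accuracy_mean"] >= 0.99

    def test_permuted_labels_have_no_skill(self, small_study):
        data = small_study["data"].copy()
        rng = np.random.default_rng(17)
        data["active"] = rng.permutation(data["active"].to_numpy())
        spec = ModelSpec(response="active", fixed_terms=("Temp",), ar1=False,
                         n_knots=10)
        cv = k_fold_cv(data, spec, k=5, seed=4)
        assert cv["mcc_mean"] == pytest.approx(0.0, abs=0.05)

    def test_k_below_two_rejected(self, small_study):
        with pytest.raises(ValueError):
            k_fold_cv(small_study["data"],
                      ModelSpec(response="active", ar1=False), k=1)


def _flat_fit(c: float, n_knots: int = 4) -> ModelFit:
    """Hand-built fit: intercept c, zero spline coefficients."""
    spec = ModelSpec(fixed_terms=(), n_knots=n_knots, ar1=False)
    names = ["Intercept"] + [f"s(hour).{k}" for k in range(1, n_knots)]
    p = len(names)
    return ModelFit(
        kind="lmm_ar1", spec=spec, design_names=names,
        beta=pd.Series([c] + [0.0] * (p - 1), index=names),
        se=pd.Series(np.zeros(p), index=names), vcov=np.zeros((p, p)),
        sigma_individual=0.0, sigma_resid=1.0, rho=0.0, loglik=0.0, aic=0.0,
        n_obs=0, n_params=p, r2=0.0, converged=True, boundary=False,
        blups=pd.DataFrame(), fitted=np.array([]))


class TestPredictDaily:
    def test_flat_model_closed_form(self):
        fit = _flat_fit(c=2.0)
        scen = pd.DataFrame({"hour": np.arange(24.0)})
        pred = predict_daily_odba(fit, scen)
        assert pred["total"] == pytest.approx(24 * 2**2.0, rel=1e-12)
        assert pred["se"] == 0.0

    def test_purity(self, small_study):
        spec = ModelSpec(fixed_terms=("Temp", "Temp2", "BCI", "BCI_x_Temp"),
                         ar1=True, n_knots=10)
        fit = fit_lmm_ar1(small_study["data"], spec)
        scen = pd.DataFrame({"hour": np.arange(24.0), "Temp": 0.3, "BCI": -0.5})
        a = predict_daily_odba(fit, scen)
        b = predict_daily_odba(fit, scen)
        assert a["total"] == b["total"] and a["se"] == b["se"]

    def test_missing_covariate_rejected(self, small_study):
        spec = ModelSpec(fixed_terms=("Temp", "Temp2"), ar1=True, n_knots=10)
        fit = fit_lmm_ar1(small_study["data"], spec)
        with pytest.raises(KeyError, match="Temp"):
            predict_daily_odba(fit, pd.DataFrame({"hour": np.arange(24.0)}))

    def test_delta_method_matches_monte_carlo(self, small_study, rng):
        spec = ModelSpec(fixed_terms=("Temp", "Temp2"), ar1=True, n_knots=10)
        fit = fit_lmm_ar1(small_study["data"], spec)
        scen = pd.DataFrame({"hour": np.arange(24.0), "Temp": 0.5})
        pred = predict_daily_odba(fit, scen)
        from odbatools.modeling.design import build_design
        X, _ = build_design(scen, spec, check_standardized=False)
        draws = rng.multivariate_normal(fit.beta.to_numpy(), fit.vcov, size=4000)
        totals = (2.0 ** (draws @ X.T)).sum(axis=1)
        assert pred["total"] == pytest.approx(totals.mean(), rel=0.02)
        assert pred["se"] == pytest.approx(totals.std(ddof=1), rel=0.3)


class TestPlasticity:
    @pytest.fixture(scope="class")
    def interaction_fit(self, small_study):
        spec = ModelSpec(fixed_terms=("Temp", "Temp2", "BCI", "BCI_x_Temp"),
                         ar1=True, n_knots=10)
        return fit_lmm_ar1(small_study["data"], spec)

    def test_zero_interaction_gives_parallel_log_curves(self, interaction_fit):
        fit = interaction_fit
        # graft a zero-interaction coefficient vector onto the fitted design
        beta = fit.beta.copy()
        beta["BCI_x_Temp"] = 0.0
        fit_zero = ModelFit(**{**fit.__dict__, "beta": beta})
        surf = plasticity_surface(fit_zero, {"lo": -1.0, "hi": 1.0},
                                  np.linspace(-1, 1, 5))
        wide = surf.pivot(index="temp", columns="bci_label", values="daily_odba")
        gaps = np.log2(wide["hi"]) - np.log2(wide["lo"])
        np.testing.assert_allclose(gaps, gaps.iloc[0], atol=1e-9)

    def test_positive_interaction_steepens_high_bci(self, interaction_fit):
        # generator interaction is +0.2: high-BCI curve responds more to Temp
        surf = plasticity_surface(interaction_fit, {"lo": -1.0, "hi": 1.0},
                                  np.linspace(-1, 1, 5))
        wide = surf.pivot(index="temp", columns="bci_label", values="daily_odba")
        slope_hi = np.polyfit(wide.index, np.log2(wide["hi"]), 1)[0]
        slope_lo = np.polyfit(wide.index, np.log2(wide["lo"]), 1)[0]
        assert slope_hi > slope_lo

    def test_single_point_grid_equals_daily_prediction(self, interaction_fit):
        surf = plasticity_surface(interaction_fit, {"q50": 0.2}, np.array([0.1]))
        scen = pd.DataFrame({"hour": np.arange(24.0), "Temp": 0.1, "BCI": 0.2})
        pred = predict_daily_odba(interaction_fit, scen)
        assert surf["daily_odba"].iloc[0] == pytest.approx(pred["total"], rel=1e-12)

    def test_missing_interaction_rejected(self, small_study):
        spec = ModelSpec(fixed_terms=("Temp",), ar1=True, n_knots=10)
        fit = fit_lmm_ar1(small_study["data"], spec)
        with pytest.raises(ValueError, match="BCI_x_Temp"):
            plasticity_surface(fit, {"q": 0.0}, np.array([0.0]))
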