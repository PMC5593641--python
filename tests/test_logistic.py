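import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit as logit_fn

import celldx as cx
from conftest import pairwise_concordance_auc
from _reference import ALL_CELLS_MODEL, EPITHELIAL_MODEL


def binary_table(x, y, markers=None):
    markers = markers or [f"m{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=markers)
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(x))])
    df.insert(1, "patient_id", "P1")
    df.insert(2, "phase", "biopsy1")
    df.insert(3, "frame_id", "f0")
    df.insert(4, "compartment", "E")
    df.insert(5, "path_category", np.where(np.asarray(y, bool), "AC", "B"))
    df.insert(6, "gleason_group", "unknown")
    return cx.CellTable(df, tuple(markers), {"log_transformed": True})


class TestFit:
    def test_intercept_only_closed_form(self):
        """With a predictor carrying no signal (balanced by construction) the
        intercept MLE is exactly logit(prevalence) and the slope is zero."""
        x = np.r_[np.full(500, -1.0), np.full(500, 1.0)].reshape(-1, 1)
        y = np.zeros(1000)
        y[:150] = 1  # 30% positives in the x=-1 half
        y[500:650] = 1  # and in the x=+1 half
        fit = cx.fit_logistic(binary_table(x, y))
        assert fit.beta[0] == pytest.approx(logit_fn(0.3), abs=1e-8)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels_to_1e6_relative(self, dev_val):
        sm = pytest.importorskip("statsmodels.api")
        dev, _ = dev_val
        sub = cx.filter_compartment(dev, ["E"])
        fit = cx.fit_logistic(sub)
        x = sm.add_constant(sub.intensity_matrix())
        y = cx.aberrant_by_pathology(sub).astype(float)
        ref = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        assert fit.beta == pytest.approx(ref.params, rel=1e-6)
        assert fit.se_beta == pytest.approx(ref.bse, rel=1e-4)

    def test_parameter_recovery_within_3_se(self):
        truth = np.r_[
            np.log(EPITHELIAL_MODEL["_cons"][0]),
            [np.log(EPITHELIAL_MODEL[f"ln{m}"][0]) for m in cx.PANEL_I],
        ]
        table = cx.generate_logistic_table(truth, 50_000, seed=11)
        fit = cx.fit_logistic(table)
        assert np.all(np.abs(fit.beta - truth) <= 3 * fit.se_beta)

    def test_single_class_outcome_rejected(self):
        x = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(cx.DefinitionError, match="single class"):
            cx.fit_logistic(binary_table(x, np.ones(50)))

    def test_complete_separation_raises(self):
        x = np.linspace(-2, 2, 200).reshape(-1, 1)
        y = (x[:, 0] > 0).astype(float)
        with pytest.raises(cx.SeparationError):
            cx.fit_logistic(binary_table(x, y))

    def test_raw_intensity_table_rejected(self, cohort_table):
        with pytest.raises(cx.DefinitionError, match="log-transformed"):
            cx.fit_logistic(cohort_table)

    def test_fitted_probabilities_sum_to_positive_count(self, epithelial_fit, dev_val):
        """Score equation for models with intercept: sum(p_i) = n_positive."""
        dev, _ = dev_val
        sub = cx.filter_compartment(dev, ["E"])
        probs = cx.predict_prob(epithelial_fit, sub)
        assert probs.prob.sum() == pytest.approx(cx.aberrant_by_pathology(sub).sum(), abs=1e-4)

    def test_json_roundtrip(self, epithelial_fit, tmp_path):
        path = tmp_path / "model.json"
        epithelial_fit.to_json(path)
        back = cx.LogisticFit.from_json(path)
        assert back.beta == pytest.approx(epithelial_fit.beta)
        assert back.marker_names == epithelial_fit.marker_names


class TestUnivariatePanel:
    def test_returns_one_fit_per_marker(self, dev_val):
        dev, _ = dev_val
        fits = cx.fit_univariate_panel(cx.filter_compartment(dev, ["E"]))
        assert [f.marker_names for f in fits] == [(m,) for m in cx.PANEL_I]
        assert all(len(f.beta) == 2 for f in fits)

    def test_type_I_error_control_under_null(self):
        """A marker independent of the outcome is flagged |z|>=1.96 in <=10%
        of replicates."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.normal(size=(400, 1))
            y = rng.random(400) < 0.5
            fit = cx.fit_logistic(binary_table(x, y))
            z = fit.beta[1] / fit.se_beta[1]
            hits += abs(z) >= 1.96
        assert hits <= 0.10 * n_rep

    def test_near_perfect_marker_gives_auc_near_one(self):
        rng = np.random.default_rng(4)
        y = rng.random(500) < 0.5
        x = (y + rng.normal(scale=0.3, size=500)).reshape(-1, 1)
        fits = cx.fit_univariate_panel(binary_table(x, y))
        probs = cx.predict_prob(fits[0], binary_table(x, y))
        assert cx.roc_auc(probs, y).auc > 0.95


class TestCoefficientReport:
    def test_null_coefficient(self):
        rep = cx.coefficient_report_from_printed([1.0], [1.0], ["x"])
        row = rep.loc["x"]
        assert row.odds_ratio == 1.0 and row.z == 0.0
        assert row.ci_low == pytest.approx(np.exp(-cx.CI_MULTIPLIER))
        assert row.ci_high == pytest.approx(np.exp(cx.CI_MULTIPLIER))

    @pytest.mark.parametrize("model", [EPITHELIAL_MODEL, ALL_CELLS_MODEL],
                             ids=["epithelial", "all_cells"])
    def test_published_tables_internally_consistent(self, model):
        """z and 95% CI re-derived from the printed (OR, SE) pairs agree with
        the printed columns (z to one unit in the second decimal, CI to
        2e-4 relative: the inputs themselves are rounded to 7 digits)."""
        ors = [model[t][0] for t in model]
        ses = [model[t][1] for t in model]
        rep = cx.coefficient_report_from_printed(ors, ses, list(model))
        for term, (or_, se, z, lo, hi) in model.items():
            assert rep.loc[term, "z"] == pytest.approx(z, abs=0.01)
            assert rep.loc[term, "ci_low"] == pytest.approx(lo, rel=2e-4)
            assert rep.loc[term, "ci_high"] == pytest.approx(hi, rel=2e-4)

    def test_report_from_fit_consistent_with_delta_method(self, epithelial_fit):
        rep = cx.coefficient_report(epithelial_fit)
        beta = epithelial_fit.beta
        se = epithelial_fit.se_beta
        assert rep.loc["lnDAPI", "odds_ratio"] == pytest.approx(np.exp(beta[1]))
        assert rep.loc["lnDAPI", "se_or"] == pytest.approx(np.exp(beta[1]) * se[1])
        assert rep.loc["_cons", "z"] == pytest.approx(beta[0] / se[0])
        assert np.all(rep.ci_low < rep.odds_ratio) and np.all(rep.odds_ratio < rep.ci_high)
        assert np.all(np.sign(rep.z) == np.sign(np.log(rep.odds_ratio)))

    def test_nonpositive_or_rejected(self):
        with pytest.raises(cx.DefinitionError):
            cx.coefficient_report_from_printed([-1.0], [0.1])


class TestPrediction:
    def test_zero_slopes_give_half(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        t = binary_table(x, np.r_[np.ones(10), np.zeros(10)])
        fit = cx.LogisticFit(np.zeros(3), np.eye(3), t.marker_names, 20, True, 0, 0.0)
        assert cx.predict_prob(fit, t).prob == pytest.approx(0.5)

    def test_published_coefficients_direct_formula_oracle(self):
        """Probabilities from the printed epithelial model equal a hand-rolled
        inverse-logit evaluation to 1e-10."""
        beta = np.r_[
            np.log(EPITHELIAL_MODEL["_cons"][0]),
            [np.log(EPITHELIAL_MODEL[f"ln{m}"][0]) for m in cx.PANEL_I],
        ]
        rng = np.random.default_rng(3)
        x = rng.normal(loc=[6.8, 5.5, 6.2, 5.9], scale=0.5, size=(10, 4))
        t = binary_table(x, np.zeros(10) + (np.arange(10) % 2), list(cx.PANEL_I))
        fit = cx.LogisticFit(beta, np.eye(5), tuple(cx.PANEL_I), 10, True, 0, 0.0)
        probs = cx.predict_prob(fit, t)
        expected = 1.0 / (1.0 + np.exp(-(beta[0] + x @ beta[1:])))
        assert probs.prob == pytest.approx(expected, abs=1e-10)
        assert np.all((probs.prob >= 0) & (probs.prob <= 1))

    def test_probability_monotone_in_linear_predictor(self):
        eta = np.linspace(-30, 30, 100)
        assert np.all(np.diff(expit(eta)) >= 0)
        assert expit(eta[-1]) > 0.999999


class TestCutoffScan:
    def test_exactly_21_rows_and_monotone(self, epithelial_fit, dev_val):
        _, val = dev_val
        probs = cx.predict_prob(epithelial_fit, val)
        scan = cx.cutoff_scan(probs, cx.aberrant_by_pathology(val))
        assert len(scan) == 21
        assert scan.cutoff.tolist() == pytest.approx(np.arange(21) * 0.05)
        assert np.all(np.diff(scan.sensitivity) <= 0)
        assert np.all(np.diff(scan.specificity) >= 0)

    def test_perfect_separation_and_tie_rule(self):
        scores = np.r_[np.full(5, 0.1), np.full(5, 0.9)]
        truth = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        scan = cx.cutoff_scan(scores, truth)
        inside = scan[(scan.cutoff > 0.1) & (scan.cutoff <= 0.9)]
        assert np.all(inside.sensitivity == 1.0) and np.all(inside.specificity == 1.0)
        # ties on the Youden index resolve to the smallest cutoff
        assert cx.select_cutoff(scan) == 0.15

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        scores = rng.random(1000)
        truth = rng.random(1000) < 0.4
        scan = cx.cutoff_scan(scores, truth)
        for _, row in scan.iterrows():
            pred = scores >= row.cutoff
            tp = np.sum(pred & truth)
            tn = np.sum(~pred & ~truth)
            assert row.sensitivity == pytest.approx(tp / truth.sum())
            assert row.specificity == pytest.approx(tn / (~truth).sum())
            assert row.percent_correct == pytest.approx((tp + tn) / 1000)

    def test_single_class_truth_rejected(self):
        with pytest.raises(cx.DefinitionError, match="both classes"):
            cx.cutoff_scan(np.array([0.2, 0.8]), np.array([True, True]))


class TestROC:
    def test_perfect_separation_auc_one(self):
        truth = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        assert cx.roc_auc(np.r_[np.zeros(5), np.ones(5)], truth).auc == 1.0

    def test_all_identical_scores_auc_half(self):
        truth = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        assert cx.roc_auc(np.full(10, 0.7), truth).auc == 0.5

    def test_equals_exhaustive_pairwise_concordance(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            scores = rng.integers(0, 10, size=30) / 10.0  # ties likely
            truth = rng.random(30) < 0.5
            if truth.all() or not truth.any():
                continue
            assert cx.roc_auc(scores, truth).auc == pytest.approx(
                pairwise_concordance_auc(scores, truth), abs=1e-12
            )

    def test_matches_sklearn(self, epithelial_fit, dev_val):
        skm = pytest.importorskip("sklearn.metrics")
        _, val = dev_val
        probs = cx.predict_prob(epithelial_fit, val)
        truth = cx.aberrant_by_pathology(val)
        assert cx.roc_auc(probs, truth).auc == pytest.approx(
            skm.roc_auc_score(truth, probs.prob), abs=1e-12
        )

    def test_curve_starts_and_ends_at_corners_and_is_monotone(self, epithelial_fit, dev_val):
        _, val = dev_val
        roc = cx.roc_auc(cx.predict_prob(epithelial_fit, val), cx.aberrant_by_pathology(val))
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(50)
        truth = rng.random(50) < 0.5
        if truth.all() or not truth.any():
            return
        base = cx.roc_auc(scores, truth).auc
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert cx.roc_auc(f(scores), truth).auc == pytest.approx(base, abs=1e-12)


@pytest.mark.parametrize(
    "auc, band",
    [
        (0.5, "none"),
        (0.95, "outstanding"),
        (0.75, "acceptable"),
        (0.85, "excellent"),
        (0.9, "excellent"),
        (0.7, "poor"),
        (0.3, "worse-than-chance"),
        (1.0, "outstanding"),
    ],
)
def test_discrimination_bands(auc, band):
    assert cx.discrimination_band(auc) == band


def test_discrimination_band_rejects_out_of_range():
    with pytest.raises(cx.DefinitionError):
        cx.discrimination_band(1.2)
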