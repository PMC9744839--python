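"""PLSR model, CSF calling, mutation/knockdown/CNV validation statistics."""

import numpy as np
import pandas as pd
import pytest

from embryosplice.regulators import (
    PlsrModel,
    call_csfs,
    cnv_stratified_gain,
    compare_effect_coefficients,
    compare_knockdown_fractions,
    filter_nonsense,
    fit_plsr,
    knockdown_response,
    mutation_effect,
    predict_median_ep,
)


def _toy_regression(seed=0, n=10, p=5, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(p, n))
    beta = rng.normal(size=p)
    y = beta @ x + noise * rng.normal(size=n)
    expr = pd.DataFrame(x, index=[f"F{i}" for i in range(p)], columns=[f"s{i}" for i in range(n)])
    return expr, pd.Series(y, index=expr.columns)


class TestFitPlsr:
    def test_full_components_match_least_squares(self):
        # noiseless full-rank 10x5: PLS with all components = OLS
        expr, y = _toy_regression()
        model = fit_plsr(expr, y, max_components=5)
        x = expr.to_numpy().T
        x1 = np.column_stack([np.ones(len(y)), x])
        ols = np.linalg.lstsq(x1, y.to_numpy(), rcond=None)[0][1:]
        assert model.n_components == 5
        np.testing.assert_allclose(model.coef.to_numpy(), ols, atol=1e-8)

    def test_predict_training_reproduces_fit(self):
        expr, y = _toy_regression(1, noise=0.1)
        model = fit_plsr(expr, y, max_components=3)
        pred = predict_median_ep(model, expr)
        # prediction = the model's own linear map; re-applying it must agree
        xz = (expr.to_numpy().T - model.x_mean.to_numpy()) / model.x_sd.to_numpy()
        manual = model.y_mean + xz @ (model.coef * model.x_sd).to_numpy()
        np.testing.assert_allclose(pred.to_numpy(), manual, atol=1e-10)

    def test_sample_permutation_invariance(self):
        expr, y = _toy_regression(2, n=12, noise=0.2)
        model_a = fit_plsr(expr, y, max_components=3)
        perm = ["s5", "s0", "s11", "s3", "s7", "s1", "s9", "s2", "s10", "s4", "s8", "s6"]
        model_b = fit_plsr(expr[perm], y[perm], max_components=3)
        np.testing.assert_allclose(model_a.coef, model_b.coef, atol=1e-8)

    def test_affine_rescaling_invariant_predictions(self):
        expr, y = _toy_regression(3, n=14, noise=0.1)
        model_a = fit_plsr(expr, y)
        scaled = expr * 7.0 + 3.0
        model_b = fit_plsr(scaled, y)
        np.testing.assert_allclose(
            predict_median_ep(model_a, expr).to_numpy(),
            predict_median_ep(model_b, scaled).to_numpy(),
            atol=1e-8,
        )

    def test_single_informative_factor_identified(self):
        rng = np.random.default_rng(4)
        n = 20
        x = rng.normal(size=(6, n)) * 0.05
        x[2] = np.linspace(0, 1, n)
        y = pd.Series(2.0 * x[2], index=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame(x, index=[f"F{i}" for i in range(6)], columns=y.index)
        model = fit_plsr(expr, y)
        assert model.coef.idxmax() == "F2"
        assert model.q["F2"] < 0.05

    def test_zero_variance_factor_dropped(self):
        expr, y = _toy_regression(5, noise=0.1)
        expr.loc["F0"] = 1.0
        model = fit_plsr(expr, y)
        assert "F0" not in model.factors

    def test_too_few_samples_rejected(self):
        expr, y = _toy_regression(6, n=5)
        with pytest.raises(ValueError, match=">= 8"):
            fit_plsr(expr, y)

    def test_constant_response_rejected(self):
        expr, _ = _toy_regression(7)
        y = pd.Series(np.ones(10), index=expr.columns)
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(expr, y)

    def test_q_at_least_p(self):
        expr, y = _toy_regression(8, n=15, noise=0.3)
        model = fit_plsr(expr, y)
        assert (model.q >= model.p - 1e-12).all()

    def test_json_roundtrip(self, tmp_path):
        expr, y = _toy_regression(9, noise=0.1)
        model = fit_plsr(expr, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PlsrModel.from_json(path)
        np.testing.assert_allclose(model.coef, loaded.coef)
        assert model.n_components == loaded.n_components
        np.testing.assert_allclose(
            predict_median_ep(model, expr), predict_median_ep(loaded, expr)
        )


class TestCallCsfs:
    def _model(self, coef, q):
        idx = pd.Index([f"F{i}" for i in range(len(coef))])
        s = lambda v: pd.Series(v, index=idx, dtype=float)
        return PlsrModel(
            factors=list(idx), coef=s(coef), coef_std=s(coef), p=s(q), q=s(q),
            x_mean=s(np.zeros(len(coef))), x_sd=s(np.ones(len(coef))),
            y_mean=0.0, n_components=1,
        )

    def test_sign_rule(self):
        call = call_csfs(self._model([1.0, -2.0, 0.5], [0.001, 0.001, 0.2]))
        assert call.csf_set == {"F0"}  # F1 negative, F2 not significant

    def test_rank_by_coefficient(self):
        call = call_csfs(self._model([0.5, 2.0, 1.0], [0.01, 0.01, 0.01]))
        assert call.top == ["F1", "F2", "F0"]

    def test_top_k_truncation_and_overflow(self):
        model = self._model([3.0, 2.0, 1.0], [0.01, 0.01, 0.01])
        assert call_csfs(model, top_k=2).top == ["F0", "F1"]
        assert call_csfs(model, top_k=10).top == ["F0", "F1", "F2"]

    def test_no_csf_warning_empty(self):
        call = call_csfs(self._model([-1.0, -2.0], [0.001, 0.001]))
        assert call.csf_set == set()
        assert call.top == []


class TestPredict:
    def test_missing_factors_listed(self):
        expr, y = _toy_regression(10, noise=0.1)
        model = fit_plsr(expr, y)
        with pytest.raises(KeyError, match="F0"):
            predict_median_ep(model, expr.drop(index="F0"))

    def test_constant_input_constant_output(self):
        expr, y = _toy_regression(11, noise=0.1)
        model = fit_plsr(expr, y)
        zeros = pd.DataFrame(0.0, index=expr.index, columns=["a", "b"])
        pred = predict_median_ep(model, zeros)
        assert pred["a"] == pytest.approx(pred["b"])
        expected = model.y_mean - float(model.coef @ model.x_mean)
        assert pred["a"] == pytest.approx(expected)


class TestMutationEffect:
    def _setup(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.normal(size=(6, 30)), index=[f"F{i}" for i in range(6)], columns=samples
        )
        median_ep = pd.Series(rng.uniform(0.35, 0.45, 30), index=samples)
        return expr, median_ep

    def test_exact_duplicates_matched_first(self):
        expr, median_ep = self._setup()
        expr["s1"] = expr["s0"]  # background duplicate of the mutant
        effects = mutation_effect(median_ep, expr, {"F0": {"s0"}}, k=1)
        # the matched background of s0 must be its duplicate s1
        assert effects.loc["F0", "background_median_ep"] == pytest.approx(median_ep["s1"])

    def test_equal_medians_untestable(self):
        expr, median_ep = self._setup()
        median_ep[:] = 0.4
        effects = mutation_effect(median_ep, expr, {"F0": {"s0", "s1"}})
        assert effects.loc["F0", "class"] == "untestable"

    def test_discard_on_variable_background(self):
        expr, median_ep = self._setup()
        rng = np.random.default_rng(1)
        median_ep[:] = rng.uniform(0, 1, 30)  # wildly variable cohort
        effects = mutation_effect(median_ep, expr, {"F0": {"s0"}}, sd_max=0.05)
        assert effects.loc["F0", "class"] == "discarded"

    def test_background_order_invariance(self):
        expr, median_ep = self._setup()
        muts = {"F0": {"s0", "s3"}}
        a = mutation_effect(median_ep, expr, muts)
        perm = list(reversed(expr.columns))
        b = mutation_effect(median_ep[perm], expr[perm], muts)
        pd.testing.assert_frame_equal(a, b)

    def test_no_background_rejected(self):
        expr, median_ep = self._setup()
        with pytest.raises(ValueError, match="background"):
            mutation_effect(median_ep, expr, {"F0": set(expr.columns)})

    def test_absolute_mode(self):
        expr, median_ep = self._setup()
        median_ep["s0"] = median_ep.drop("s0").median() + 0.2
        eff = mutation_effect(median_ep, expr, {"F0": {"s0"}}, delta_mode="absolute", delta=0.1)
        assert eff.loc["F0", "class"] == "increased"
        assert eff.loc["F0", "delta"] == pytest.approx(0.2, abs=0.05)

    def test_unknown_mode_rejected(self):
        expr, median_ep = self._setup()
        with pytest.raises(ValueError):
            mutation_effect(median_ep, expr, {}, delta_mode="fancy")

    def test_filter_nonsense_whitelist(self):
        table = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "gene": ["F1", "F1", "F2"],
                "variant_class": ["Nonsense_Mutation", "Missense_Mutation", "Frame_Shift_Del"],
            }
        )
        muts = filter_nonsense(table)
        assert muts == {"F1": {"s1"}, "F2": {"s3"}}


class TestCompareEffects:
    def _model(self, coef):
        idx = pd.Index(list(coef))
        s = pd.Series(coef, dtype=float)
        return PlsrModel(
            factors=list(idx), coef=s, coef_std=s.copy(), p=s * 0, q=s * 0,
            x_mean=s * 0, x_sd=s * 0 + 1, y_mean=0.0, n_components=1,
        )

    def _effects(self, classes):
        return pd.DataFrame({"class": pd.Series(classes)}, dtype=object)

    def test_separated_groups_significant(self):
        coef = {f"D{i}": 1.0 + 0.1 * i for i in range(5)}
        coef.update({f"I{i}": -1.0 - 0.1 * i for i in range(5)})
        classes = {f"D{i}": "decreased" for i in range(5)}
        classes.update({f"I{i}": "increased" for i in range(5)})
        out = compare_effect_coefficients(self._effects(classes), self._model(coef))
        assert out["p"] < 0.05
        assert out["median_coef_decreased"] > out["median_coef_increased"]

    def test_identical_groups_nonsignificant(self):
        coef = {"A": 1.0, "B": 2.0, "C": 1.0, "D": 2.0}
        classes = {"A": "decreased", "B": "decreased", "C": "increased", "D": "increased"}
        out = compare_effect_coefficients(self._effects(classes), self._model(coef))
        assert out["p"] > 0.5

    def test_empty_group_skipped(self):
        out = compare_effect_coefficients(
            self._effects({"A": "decreased"}), self._model({"A": 1.0})
        )
        assert np.isnan(out["p"])

    def test_size_one_groups_flagged(self):
        out = compare_effect_coefficients(
            self._effects({"A": "decreased", "B": "increased"}),
            self._model({"A": 1.0, "B": -1.0}),
        )
        assert np.isfinite(out["p"])
        assert out["low_power"]


class TestKnockdown:
    def _assay(self, n_events=50, dpsi=-0.2, eff=0.8):
        rng = np.random.default_rng(0)
        events = [f"E{i}" for i in range(n_events)]
        ctrl = pd.DataFrame(
            rng.uniform(0.4, 0.6, (n_events, 4)), index=events,
            columns=[f"c{i}" for i in range(4)],
        )
        base = ctrl.mean(axis=1)
        kd = {
            "HIT": pd.DataFrame(
                {"kd_rep1": base + dpsi, "kd_rep2": base + dpsi}, index=events
            ),
            "MISS": pd.DataFrame({"kd_rep1": base, "kd_rep2": base}, index=events),
        }
        expr = pd.DataFrame(
            {"control_mean": [10.0, 10.0], "kd_rep1": [10 * (1 - eff)] * 2,
             "kd_rep2": [10 * (1 - eff)] * 2},
            index=["HIT", "MISS"],
        )
        return ctrl, kd, expr, set(events)

    def test_planted_effect_full_fraction(self):
        ctrl, kd, expr, ep = self._assay()
        out = knockdown_response(ctrl, kd, expr, ep)
        assert out.loc["HIT", "fraction_decreased"] == pytest.approx(1.0)
        assert out.loc["MISS", "fraction_decreased"] == pytest.approx(0.0)

    def test_failed_expression_check_excluded(self):
        ctrl, kd, expr, ep = self._assay()
        expr.loc["HIT", ["kd_rep1", "kd_rep2"]] = 8.0  # only 20% knockdown
        out = knockdown_response(ctrl, kd, expr, ep)
        assert "HIT" not in out.index

    def test_zero_effect_zero_delta(self):
        ctrl, kd, expr, ep = self._assay(dpsi=0.0)
        out = knockdown_response(ctrl, kd, expr, ep)
        assert out.loc["HIT", "fraction_decreased"] == 0.0

    def test_comparison_one_sided(self):
        frac = pd.DataFrame(
            {"n_ep_tested": [50] * 8,
             "fraction_decreased": [0.9, 0.8, 0.85, 0.95, 0.05, 0.1, 0.0, 0.2]},
            index=["c1", "c2", "c3", "c4", "n1", "n2", "n3", "n4"],
        )
        out = compare_knockdown_fractions(frac, {"c1", "c2", "c3", "c4"})
        assert out["p"] < 0.05


class TestCnvStrata:
    def test_all_zero_cnv(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.normal(size=(4, 30)), index=[f"F{i}" for i in range(4)], columns=samples
        )
        cnv = pd.DataFrame(0, index=expr.index, columns=samples)
        table, res = cnv_stratified_gain(expr, cnv, {"F0", "F1"})
        assert (table.to_numpy() == 0).all()
        assert res["p"] == pytest.approx(1.0)

    def test_degenerate_strata_are_raw_values(self):
        samples = [f"s{i}" for i in range(3)]
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["F0"], columns=samples)
        cnv = pd.DataFrame([[1, 0, -1]], index=["F0"], columns=samples)
        table, _ = cnv_stratified_gain(expr, cnv, {"F0"}, n_strata=3)
        assert table.loc["F0"].tolist() == [1.0, 0.0, -1.0]

    def test_invalid_cnv_values_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["F0"], columns=["a", "b"])
        cnv = pd.DataFrame([[2, 0]], index=["F0"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cnv_stratified_gain(expr, cnv, {"F0"})

    def test_planted_gain_recovered(self, world):
        dev, can, ann, reg = world
        truth = dev.truth
        tumor_ids = can.meta.index[can.meta["cohort"] == "tumor"].tolist()
        expr = np.log2(can.expr.loc[truth.sf_ids, tumor_ids] + 1.0)
        table, res = cnv_stratified_gain(expr, can.cnv[tumor_ids], truth.csf_set)
        assert res["mean_high"] > res["mean_low"]
        assert res["p"] < 0.05


class TestEndToEndRecovery:
    def test_csf_recovery_and_prediction(self, world):
        dev, can, ann, reg = world
        truth = dev.truth
        sf_dev = np.log2(dev.expr.loc[truth.sf_ids] + 1.0)
        ep = sorted(truth.events_with_label("EP"))
        model = fit_plsr(sf_dev, dev.psi.loc[ep].median(axis=0))
        # planted CSFs rank above non-CSFs by standardized coefficient
        scores = model.coef_std
        csf_scores = scores[[f for f in scores.index if f in truth.csf_set]]
        ncsf_scores = scores[[f for f in scores.index if f not in truth.csf_set]]
        wins = (csf_scores.to_numpy()[:, None] > ncsf_scores.to_numpy()[None, :]).mean()
        assert wins >= 0.9
        # cross-cohort prediction on unmutated tumors
        mutated = set().union(*truth.mutated_samples.values())
        tumor_ids = [
            s for s in can.meta.index[can.meta["cohort"] == "tumor"] if s not in mutated
        ]
        pred = predict_median_ep(model, np.log2(can.expr.loc[truth.sf_ids, tumor_ids] + 1.0))
        actual = can.psi.loc[ep, tumor_ids].median(axis=0)
        assert np.corrcoef(pred, actual)[0, 1] >= 0.8

    def test_mutation_recovery(self, world):
        dev, can, ann, reg = world
        truth = dev.truth
        tumor_ids = can.meta.index[can.meta["cohort"] == "tumor"].tolist()
        ep = sorted(truth.events_with_label("EP"))
        muts = filter_nonsense(can.mutations)
        effects = mutation_effect(
            can.psi.loc[ep, tumor_ids].median(axis=0),
            np.log2(can.expr.loc[truth.sf_ids, tumor_ids] + 1.0),
            muts,
        )
        drivers = [f for f in muts if f in truth.driver_weights]
        n_dec = sum(effects.loc[f, "class"] == "decreased" for f in drivers)
        assert n_dec / len(drivers) >= 0.5
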