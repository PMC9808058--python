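"""Risk score, median split, KM/log-rank and the Spearman feature screen."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repsig import (
    MedianSplitLogrankScreen,
    RiskModel,
    RiskScorer,
    SpearmanScreen,
    SurvivalData,
    SurvivalSimConfig,
    dichotomize_by_median,
    generate_expression_survival,
    km_estimate,
    logrank_test,
    risk_score,
    screen_survival_genes,
    spearman_screen,
)

from _oracles import km_product_limit, logrank_bruteforce


def _surv(times, events, prefix="s") -> SurvivalData:
    idx = pd.Index([f"{prefix}{i}" for i in range(len(times))], name="sample")
    return SurvivalData(pd.DataFrame({"time": times, "event": events}, index=idx))


class TestSurvivalData:
    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError, match="time"):
            _surv([1.0, 0.0], [1, 1])

    def test_non_binary_event_rejected(self):
        with pytest.raises(ValueError, match="event"):
            _surv([1.0, 2.0], [1, 2])


class TestKMEstimate:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at([0.5, 10.0]).tolist() == [1.0, 1.0]

    def test_two_events_product_limit_by_hand(self):
        curve = km_estimate(_surv([1, 2], [1, 1]))
        assert curve.survival_at([1]).item() == pytest.approx(0.5)
        assert curve.survival_at([2]).item() == pytest.approx(0.0)

    def test_censoring_between_events(self):
        # events at 1 and 3, censored at 2 and 4:
        # S(1) = 1 - 1/4 = 0.75; S(3) = 0.75 * (1 - 1/2) = 0.375
        curve = km_estimate(_surv([1, 2, 3, 4], [1, 0, 1, 0]))
        np.testing.assert_allclose(curve.survival, [0.75, 0.375])
        np.testing.assert_allclose(curve.at_risk, [4, 2])

    def test_no_censoring_equals_empirical_survivor_fraction(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=50).round(1) + 0.1
        curve = km_estimate(_surv(times, np.ones(50, dtype=int)))
        for t in [1.0, 5.0, 20.0]:
            assert curve.survival_at([t]).item() == pytest.approx((times > t).mean())

    def test_matches_product_limit_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 30))
            times = rng.integers(1, 15, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            curve = km_estimate(_surv(times, events))
            t_oracle, s_oracle = km_product_limit(times, events)
            np.testing.assert_allclose(curve.event_times, t_oracle)
            np.testing.assert_allclose(curve.survival, s_oracle, atol=1e-12)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        surv = _surv([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=surv.sample_ids)
        res = logrank_test(surv, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_separated_groups_match_hand_computation(self):
        # group A events at 1, 2; group B events at 3, 4; no censoring.
        # By hand over the four event times: O_A = 2, E_A = 5/6,
        # V = 1/4 + 2/9 = 17/36, chi2 = (7/6)^2 / (17/36) = 49/17.
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"], index=surv.sample_ids)
        res = logrank_test(surv, groups)
        assert res.statistic == pytest.approx(49 / 17, rel=1e-12)
        chi2, p = logrank_bruteforce(surv.time, surv.event,
                                     np.array([True, True, False, False]))
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_matches_bruteforce_with_censoring(self):
        rng = np.random.default_rng(17)
        times = rng.integers(1, 20, size=60).astype(float)
        events = rng.integers(0, 2, size=60)
        mask = rng.random(60) < 0.5
        surv = _surv(times, events)
        groups = pd.Series(np.where(mask, "high", "low"), index=surv.sample_ids)
        res = logrank_test(surv, groups)
        chi2, p = logrank_bruteforce(times, events, mask)
        assert res.statistic == pytest.approx(chi2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_group_relabeling_and_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(23)
        times = rng.exponential(5, 40) + 0.01
        events = rng.integers(0, 2, 40)
        surv = _surv(times, events)
        groups = pd.Series(np.where(rng.random(40) < 0.5, "high", "low"),
                           index=surv.sample_ids)
        base = logrank_test(surv, groups)
        swapped = groups.map({"high": "low", "low": "high"})
        assert logrank_test(surv, swapped).statistic == pytest.approx(base.statistic)
        transformed = _surv(np.exp(times / times.max()), events)
        assert logrank_test(transformed, groups).statistic == pytest.approx(base.statistic)

    def test_empty_group_rejected(self):
        surv = _surv([1, 2, 3], [1, 1, 1])
        groups = pd.Series(["high", "high", "high"], index=surv.sample_ids)
        with pytest.raises(ValueError):
            logrank_test(surv, groups)


class TestRiskScore:
    def _expr(self, arr, genes, samples):
        return pd.DataFrame(arr, index=genes, columns=samples)

    def test_zero_coefficients_zero_scores(self):
        expr = self._expr([[1.0, 2.0]], ["g1"], ["s1", "s2"])
        scores = risk_score(expr, RiskModel(pd.Series({"g1": 0.0})))
        assert (scores == 0).all()

    def test_hand_arithmetic(self):
        expr = self._expr([[3.0], [4.0], [1.0]], ["g0", "g1", "g2"], ["s1"])
        model = RiskModel(pd.Series({"g1": 0.5, "g2": -1.0}))
        assert risk_score(expr, model)["s1"] == pytest.approx(0.5 * 4 - 1.0 * 1)
        single = RiskModel(pd.Series({"g0": 2.0}))
        assert risk_score(expr, single)["s1"] == pytest.approx(6.0)

    def test_missing_model_gene_listed_in_error(self):
        expr = self._expr([[1.0]], ["g1"], ["s1"])
        with pytest.raises(KeyError, match="gX"):
            risk_score(expr, RiskModel(pd.Series({"g1": 1.0, "gX": 2.0})))

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(scale=st.floats(-5, 5, allow_nan=False),
           coefs=st.lists(st.floats(-3, 3, width=32), min_size=1, max_size=5))
    def test_linearity_in_coefficients(self, scale, coefs):
        genes = [f"g{i}" for i in range(len(coefs))]
        rng = np.random.default_rng(1)
        expr = self._expr(rng.normal(size=(len(coefs), 6)), genes,
                          [f"s{i}" for i in range(6)])
        base = risk_score(expr, RiskModel(pd.Series(coefs, index=genes)))
        scaled = risk_score(expr, RiskModel(pd.Series(np.array(coefs) * scale, index=genes)))
        np.testing.assert_allclose(scaled, base * scale, atol=1e-9)


class TestDichotomize:
    def test_odd_count_tie_goes_low(self):
        groups = dichotomize_by_median(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert groups.to_dict() == {"a": "low", "b": "low", "c": "high"}

    def test_even_count_half_split(self):
        groups = dichotomize_by_median(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}))
        assert sorted(groups[groups == "high"].index) == ["c", "d"]

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            dichotomize_by_median(pd.Series({"a": 5.0, "b": 5.0, "c": 5.0}))


class TestScreen:
    def test_constant_gene_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(20)]
        expr = pd.DataFrame(
            np.vstack([np.full(20, 7.0), rng.normal(size=20)]),
            index=["flat", "varies"], columns=samples)
        surv = _surv(rng.exponential(5, 20) + 0.1, rng.integers(0, 2, 20))
        with caplog.at_level(logging.WARNING):
            report = screen_survival_genes(expr, surv)
        assert "flat" not in report.index
        assert "varies" in report.index

    def test_planted_hazard_gene_detected(self):
        hits = 0
        for seed in range(20):
            cfg = SurvivalSimConfig(seed=seed, n_samples=400, n_genes=5,
                                    signature_coefficients={"gene000": 0.63})
            expr, surv, _, _ = generate_expression_survival(cfg)
            report = screen_survival_genes(expr, surv)
            hits += bool(report.loc["gene000", "selected"])
        assert hits >= 19

    def test_bh_correction_is_less_permissive(self):
        cfg = SurvivalSimConfig(seed=3, n_samples=100, n_genes=30,
                                signature_coefficients={"gene000": 0.0})
        expr, surv, _, _ = generate_expression_survival(cfg)
        raw = screen_survival_genes(expr, surv, correction="none")
        bh = screen_survival_genes(expr, surv, correction="BH")
        assert bh["selected"].sum() <= raw["selected"].sum()
        assert (bh["p_adjusted"] >= bh["p_value"] - 1e-12).all()


class TestSpearmanScreen:
    def test_identical_and_reversed_features_pass(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        features = pd.DataFrame(
            [scores.to_numpy(), -scores.to_numpy()],
            index=["same", "reversed"], columns=scores.index)
        report = spearman_screen(scores, features)
        assert report.loc["same", "rho"] == pytest.approx(1.0)
        assert report.loc["reversed", "rho"] == pytest.approx(-1.0)
        assert report["selected"].all()

    def test_constant_feature_skipped(self, caplog):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        features = pd.DataFrame([[5.0] * 4], index=["flat"], columns=scores.index)
        with caplog.at_level(logging.WARNING):
            report = spearman_screen(scores, features)
        assert report.empty

    def test_too_few_observations_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        features = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=["a", "b"])
        with pytest.raises(ValueError):
            spearman_screen(scores, features)


class TestEstimators:
    def test_screen_scorer_spearman_chain(self):
        cfg = SurvivalSimConfig(seed=0)
        expr, surv, model, feats = generate_expression_survival(cfg)
        X = expr.T  # samples x genes

        screen = MedianSplitLogrankScreen(alpha=0.05).fit(X, surv)
        assert "gene000" in screen.selected_genes_
        assert screen.transform(X).shape[1] == len(screen.selected_genes_)

        scorer = RiskScorer(model).fit(X)
        scores = scorer.predict(X)
        np.testing.assert_allclose(scores, risk_score(expr, model))
        groups = scorer.predict_group(X)
        assert set(groups.unique()) == {"high", "low"}

        sp = SpearmanScreen().fit(feats.T, scores)
        assert "feature000" in sp.selected_features_

    def test_planted_effect_direction_high_arm_below_low(self):
        cfg = SurvivalSimConfig(seed=7)
        expr, surv, model, _ = generate_expression_survival(cfg)
        scores = risk_score(expr, model)
        groups = dichotomize_by_median(scores)
        high = km_estimate(surv.subset(groups.index[groups == "high"]))
        low = km_estimate(surv.subset(groups.index[groups == "low"]))
        quartiles = np.quantile(surv.time, [0.25, 0.5, 0.75])
        assert (high.survival_at(quartiles) < low.survival_at(quartiles)).all()
        assert logrank_test(surv, groups).p_value < 1e-3
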