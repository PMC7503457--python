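"""Tests of Cox element fits, the composite risk score and survival splits."""

import numpy as np
import pandas as pd
import pytest

from lncperturb.exceptions import DataError
from lncperturb.prognosis import (
    CATEGORY_FUNCTIONS_TOGETHER,
    CATEGORY_NOT_SIGNIFICANT,
    CATEGORY_TRIPLET_SIGNIFICANT,
    RiskModel,
    classify_signature,
    element_cox,
    evaluate_triplet,
    km_table,
    logrank,
    single_gene_signature,
    split_by_mean,
    triplet_risk_score,
)
from lncperturb.synthetic import generate_survival

from conftest import make_layer


def srs(values, prefix="S"):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=[f"{prefix}{i + 1:03d}" for i in range(len(values))],
    )


def survival_from(expr: pd.Series, coeff: float, seed: int = 0,
                  censor: float = 0.2) -> pd.DataFrame:
    frame = expr.rename("x").to_frame()
    return generate_survival(frame, (coeff,), censor, seed=seed)


class TestTripletRiskScore:
    def test_arithmetic(self):
        score = triplet_risk_score((1, -1, 0.5), srs([2]), srs([1]), srs([4]))
        assert score.iloc[0] == pytest.approx(3.0)

    def test_zero_coefficients(self):
        score = triplet_risk_score((0, 0, 0), srs([2, 3]), srs([1, 5]), srs([4, 6]))
        assert (score == 0).all()

    def test_linearity_in_coefficients(self):
        lnc, mir, mrna = srs([2, 1, 7]), srs([1, 3, 2]), srs([4, 2, 5])
        base = triplet_risk_score((1, -1, 0.5), lnc, mir, mrna)
        scaled = triplet_risk_score((3, -3, 1.5), lnc, mir, mrna)
        np.testing.assert_allclose(scaled, 3 * base)


class TestSplitByMean:
    def test_basic_split(self):
        groups = split_by_mean(srs([1, 2, 3, 4]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_score_at_mean_goes_low(self):
        groups = split_by_mean(srs([1, 2, 3]))  # mean = 2
        assert groups.iloc[1] == "low"

    def test_two_samples(self):
        groups = split_by_mean(srs([0, 10]))
        assert sorted(groups) == ["high", "low"]

    def test_constant_scores_error(self):
        with pytest.raises(DataError, match="degenerate"):
            split_by_mean(srs([2, 2, 2]))

    def test_shift_invariance(self):
        scores = srs([1, 5, 2, 9, 3])
        pd.testing.assert_series_equal(
            split_by_mean(scores), split_by_mean(scores + 100)
        )


class TestClassifySignature:
    def _model(self, logrank_p, element_p):
        return RiskModel(
            "l", "m", "r", 1.0, -1.0, 0.5,
            risk_score=srs([1, 2]), group=pd.Series(["low", "high"]),
            logrank_p=logrank_p, element_cox_p=element_p,
        )

    def test_joint_only_significant(self):
        model = self._model(0.01, (0.90, 0.67, 0.08))
        assert classify_signature(model) == CATEGORY_FUNCTIONS_TOGETHER

    def test_element_also_significant(self):
        model = self._model(0.01, (0.001, 0.67, 0.08))
        assert classify_signature(model) == CATEGORY_TRIPLET_SIGNIFICANT

    def test_not_significant(self):
        model = self._model(0.2, (0.90, 0.67, 0.08))
        assert classify_signature(model) == CATEGORY_NOT_SIGNIFICANT


class TestElementCox:
    def test_positive_effect_classified_risk(self):
        rng = np.random.default_rng(0)
        expr = srs(rng.standard_normal(300))
        surv = survival_from(expr, 1.0, seed=1)
        res = element_cox(expr, surv)
        assert res.coefficient > 0
        assert res.classification == "risk"
        assert res.p < 0.01

    def test_negative_effect_classified_protective(self):
        rng = np.random.default_rng(1)
        expr = srs(rng.standard_normal(300))
        surv = survival_from(expr, -1.0, seed=2)
        assert element_cox(expr, surv).classification == "protective"

    def test_constant_expression_error(self):
        surv = survival_from(srs(np.arange(10.0)), 0.0, seed=3)
        with pytest.raises(DataError, match="constant"):
            element_cox(srs([2.0] * 10), surv)

    def test_too_few_events_error(self):
        expr = srs(np.arange(10.0))
        surv = pd.DataFrame(
            {"time": np.arange(1.0, 11.0), "event": [1] + [0] * 9}, index=expr.index
        )
        with pytest.raises(DataError, match="events"):
            element_cox(expr, surv)


class TestLogrank:
    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(2)
        n = 150
        times = np.concatenate([
            rng.exponential(1000, n), rng.exponential(1000 / 3, n)
        ])
        groups = pd.Series(
            ["low"] * n + ["high"] * n,
            index=[f"S{i}" for i in range(2 * n)], name="group",
        )
        surv = pd.DataFrame(
            {"time": times, "event": np.ones(2 * n, dtype=int)}, index=groups.index
        )
        assert logrank(groups, surv) < 0.01

    def test_single_group_error(self):
        groups = pd.Series(["low"] * 10, index=[f"S{i}" for i in range(10)])
        surv = pd.DataFrame(
            {"time": np.arange(1.0, 11.0), "event": np.ones(10, dtype=int)},
            index=groups.index,
        )
        with pytest.raises(DataError, match="2 groups"):
            logrank(groups, surv)

    def test_heavy_censoring_handled(self):
        groups = pd.Series(
            ["low"] * 10 + ["high"] * 10, index=[f"S{i}" for i in range(20)]
        )
        surv = pd.DataFrame(
            {"time": np.full(20, 0.001), "event": [1] + [0] * 19}, index=groups.index
        )
        p = logrank(groups, surv)
        assert np.isfinite(p) and 0 <= p <= 1


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        """6 samples, times 1..6, censored at 3 and 5:
        S(1)=5/6, S(2)=4/6, S(4)=4/9, S(6)=0."""
        groups = pd.Series(["a"] * 6, index=[f"S{i}" for i in range(6)])
        surv = pd.DataFrame(
            {"time": [1, 2, 3, 4, 5, 6], "event": [1, 1, 0, 1, 0, 1]},
            index=groups.index,
        )
        table = km_table(groups, surv).set_index("time")["survival"]
        assert table.loc[0.0] == pytest.approx(1.0)
        assert table.loc[1.0] == pytest.approx(5 / 6)
        assert table.loc[2.0] == pytest.approx(4 / 6)
        assert table.loc[4.0] == pytest.approx(4 / 6 * (2 / 3))
        assert table.loc[6.0] == pytest.approx(0.0)

    def test_single_gene_signature_strong_effect(self):
        rng = np.random.default_rng(4)
        expr = srs(rng.standard_normal(200))
        surv = survival_from(expr, 1.5, seed=5)
        p, km = single_gene_signature(expr, surv)
        assert p < 0.05
        # survival estimate is 1.0 before the first event in each group
        for _, sub in km.groupby("group"):
            assert sub.sort_values("time")["survival"].iloc[0] == pytest.approx(1.0)


class TestEvaluateTriplet:
    def _layers_and_survival(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        lnc = np.clip(5 + rng.standard_normal(n), 0, None)
        mir = np.clip(5 + rng.standard_normal(n), 0, None)
        mrna = np.clip(5 + rng.standard_normal(n), 0, None)
        samples = [f"S{i + 1:03d}" for i in range(n)]
        layers = (
            make_layer([lnc], "lncRNA", genes=["l1"], samples=samples),
            make_layer([mir], "miRNA", genes=["m1"], samples=samples),
            make_layer([mrna], "mRNA", genes=["r1"], samples=samples),
        )
        expr = pd.DataFrame(
            {"lnc": lnc, "mir": mir, "mrna": mrna}, index=samples
        )
        surv = generate_survival(expr, (1.0, -1.0, 0.5), 0.2, seed=seed + 1)
        return layers, surv

    def test_joint_mode_recovers_signal(self):
        layers, surv = self._layers_and_survival()
        model = evaluate_triplet("l1", "m1", "r1", *layers, surv, cox_mode="joint")
        assert model.logrank_p < 0.01
        assert model.alpha > 0 and model.beta < 0 and model.gamma > 0
        assert model.category in (
            CATEGORY_TRIPLET_SIGNIFICANT, CATEGORY_FUNCTIONS_TOGETHER
        )

    def test_univariate_mode_uses_element_coefficients(self):
        layers, surv = self._layers_and_survival(seed=7)
        model = evaluate_triplet("l1", "m1", "r1", *layers, surv,
                                 cox_mode="univariate")
        lnc = layers[0].gene("l1").rename("lnc")
        assert model.alpha == pytest.approx(
            element_cox(lnc, surv).coefficient, abs=1e-9
        )

    def test_risk_score_matches_linear_combination(self):
        layers, surv = self._layers_and_survival(seed=3)
        model = evaluate_triplet("l1", "m1", "r1", *layers, surv)
        manual = (
            model.alpha * layers[0].gene("l1")
            + model.beta * layers[1].gene("m1")
            + model.gamma * layers[2].gene("r1")
        )
        np.testing.assert_allclose(model.risk_score, manual)
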