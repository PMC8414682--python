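import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bloodtrac as bt
from bloodtrac.datatypes import ValidationError
from bloodtrac.scoring import (
    ConfusionMatrix,
    Orientation,
    c_statistic,
    clinical_risk,
    composite_score,
    confusion_from_predictive_values,
    confusion_metrics,
    load_risk_table,
    pls_da,
    score_on_covariate,
)

RISK_TABLE = Path(__file__).resolve().parent.parent / "examples" / "toy_risk_points.yaml"


def _rpkm(arr, tids, sids):
    return bt.ExpressionMatrix(
        pd.DataFrame(np.asarray(arr, float), index=tids, columns=sids), "RPKM"
    )


class TestCompositeScore:
    def test_hand_arithmetic(self):
        m = _rpkm([[2, 4], [10, 30]], ["T1", "T2"], ["s1", "s2"])
        panel = bt.GeneSet("P", "d", frozenset({"T1", "T2"}))
        cs = composite_score(m, panel)
        assert cs.scores["s1"] == pytest.approx((2 / 3 + 0.5) / 2)
        assert cs.scores["s2"] == pytest.approx((4 / 3 + 1.5) / 2)

    def test_cohort_average_scores_one(self):
        m = _rpkm([[5, 5, 5], [9, 9, 9]], ["T1", "T2"], ["a", "b", "c"])
        cs = composite_score(m, bt.GeneSet("P", "d", frozenset({"T1", "T2"})))
        np.testing.assert_allclose(cs.scores.to_numpy(), 1.0)

    def test_single_transcript_panel_reduces_to_ratio(self):
        m = _rpkm([[2, 6]], ["T1"], ["a", "b"])
        cs = composite_score(m, bt.GeneSet("P", "d", frozenset({"T1"})))
        np.testing.assert_allclose(cs.scores.to_numpy(), [0.5, 1.5])

    @given(st.floats(0.01, 100, allow_nan=False))
    def test_invariant_to_rescaling_one_transcript(self, c):
        base = np.array([[2.0, 4.0], [10.0, 30.0]])
        panel = bt.GeneSet("P", "d", frozenset({"T1", "T2"}))
        plain = composite_score(
            _rpkm(base, ["T1", "T2"], ["s1", "s2"]), panel
        ).scores
        scaled = base.copy()
        scaled[0] *= c
        rescaled = composite_score(
            _rpkm(scaled, ["T1", "T2"], ["s1", "s2"]), panel
        ).scores
        np.testing.assert_allclose(plain.to_numpy(), rescaled.to_numpy(), rtol=1e-9)

    def test_missing_symbol_named(self):
        m = _rpkm([[1, 2]], ["T1"], ["a", "b"])
        with pytest.raises(ValidationError, match="T9"):
            composite_score(m, bt.GeneSet("P", "d", frozenset({"T1", "T9"})))

    def test_zero_mean_transcript_rejected(self):
        m = _rpkm([[0, 0]], ["T1"], ["a", "b"])
        with pytest.raises(ValidationError, match="zero cohort mean"):
            composite_score(m, bt.GeneSet("P", "d", frozenset({"T1"})))


def _auc_oracle(scores, labels):
    """Brute-force pair counting with ties at ½."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert c_statistic([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_small_example_quarter(self):
        assert c_statistic([1, 3, 2, 4], [1, 1, 0, 0]) == pytest.approx(0.25)

    def test_orientation_flip(self):
        up = c_statistic([1, 3, 2, 4], [1, 1, 0, 0], Orientation.higher_is_disease)
        down = c_statistic([1, 3, 2, 4], [1, 1, 0, 0], Orientation.lower_is_disease)
        assert up + down == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            c_statistic([1, 2], [1, 1])

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=200).filter(
            lambda xs: len(set(xs)) >= 1
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_pair_counting_oracle(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert c_statistic(scores, labels) == pytest.approx(
            _auc_oracle(scores, labels), abs=1e-12
        )


class TestConfusion:
    def test_reconstructed_matrix_metrics(self):
        cm = ConfusionMatrix(tp=41, fp=7, fn=12, tn=36)
        m = confusion_metrics(cm)
        assert round(100 * m["sensitivity"], 1) == 77.4
        assert round(100 * m["specificity"], 1) == 83.7
        assert round(100 * m["accuracy"], 1) == 80.2
        assert round(100 * m["ppv"], 1) == 85.4
        assert round(100 * m["npv"], 1) == 75.0

    def test_degenerate_metrics_missing_not_zero(self):
        m = confusion_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=0))
        assert m["sensitivity"] == 1.0 and m["ppv"] == 1.0
        assert m["specificity"] is None and m["npv"] is None

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fp=0, fn=0, tn=10))
        assert all(v == 1.0 for v in m.values())

    @pytest.mark.parametrize(
        "ppv, npv, npos, nneg, expected",
        [
            (0.854, 0.750, 48, 48, (41, 7, 12, 36)),
            (1.0, 1.0, 5, 5, (5, 0, 0, 5)),
            (0.5, 1.0, 2, 0, (1, 1, 0, 0)),
        ],
    )
    def test_inversion_from_predictive_values(self, ppv, npv, npos, nneg, expected):
        cm = confusion_from_predictive_values(ppv, npv, npos, nneg)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 60), st.integers(1, 60))
    def test_roundtrip_up_to_rounding_granularity(self, ppv, npv, npos, nneg):
        cm = confusion_from_predictive_values(ppv, npv, npos, nneg)
        m = confusion_metrics(cm)
        assert abs(m["ppv"] - ppv) <= 0.5 / npos + 1e-12
        assert abs(m["npv"] - npv) <= 0.5 / nneg + 1e-12


class TestClinicalRisk:
    def _patient(self, sid="p1", **cov):
        base = dict(age=45, sex="F", symptom_type="noncardiac", diabetes=0,
                    hypertension=0, family_history=0, smoking=0)
        base.update(cov)
        return bt.SampleRecord(sid, "LOW", 1000, base)

    def test_reference_level_scores_age_band_only(self):
        table = load_risk_table(RISK_TABLE)
        out = clinical_risk([self._patient(age=30)], table)
        assert out.loc["p1", "points"] == 0.0
        assert out.loc["p1", "risk_class"] == "low"

    def test_additivity(self):
        table = load_risk_table(RISK_TABLE)
        p = self._patient(age=30, diabetes=1, smoking=1, hypertension=1)
        out = clinical_risk([p], table)
        assert out.loc["p1", "points"] == 3.0

    def test_missing_covariate_flagged_not_zero(self):
        table = load_risk_table(RISK_TABLE)
        p = self._patient()
        del p.covariates["diabetes"]
        out = clinical_risk([p], table)
        assert np.isnan(out.loc["p1", "points"])
        assert "diabetes" in out.loc["p1", "missing"]

    def test_age_bands_monotone(self):
        table = load_risk_table(RISK_TABLE)
        pts = [
            clinical_risk([self._patient(age=a)], table)["points"].iloc[0]
            for a in (30, 45, 55, 65, 80)
        ]
        assert pts == sorted(pts)


class TestPlsDa:
    @staticmethod
    def _clouds(n=40, p=20, delta=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, :3] += delta
        return X, y

    def test_separable_clouds_train_perfect(self):
        X, y = self._clouds()
        out = pls_da(X, y, n_components=2, seed=0)
        assert out["train"]["overall"] == 1.0
        assert out["cv"]["overall"] > 0.9

    def test_duplicating_predictors_changes_nothing(self):
        X, y = self._clouds()
        a = pls_da(X, y, n_components=2, seed=0)
        b = pls_da(np.hstack([X, X]), y, n_components=2, seed=0)
        assert a["train"] == b["train"]
        assert a["cv"] == b["cv"]

    def test_permutation_null_centers_on_chance(self):
        rng = np.random.default_rng(12345)
        X, _ = self._clouds(n=40, p=10, delta=0.0, seed=3)
        accs = []
        for _ in range(200):
            y = rng.permutation(np.repeat([0, 1], 20))
            accs.append(pls_da(X, y, n_components=2, n_folds=5, seed=0)["cv"]["overall"])
        mean = float(np.mean(accs))
        sem = float(np.std(accs, ddof=1) / np.sqrt(len(accs)))
        assert abs(mean - 0.5) < 3 * sem

    def test_excess_components_rejected(self):
        X, y = self._clouds(n=10, p=4)
        with pytest.raises(ValidationError):
            pls_da(X, y, n_components=5)


class TestScoreOnCovariate:
    def test_exact_line(self):
        out = score_on_covariate([2, 4, 6, 8], [1, 2, 3, 4])
        assert out["slope"] == pytest.approx(2.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_hand_r_squared(self):
        out = score_on_covariate([1, 3, 2, 4], [1, 2, 3, 4])
        assert out["r_squared"] == pytest.approx(0.64)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = [
            score_on_covariate(rng.normal(size=20), rng.normal(size=20))["p"]
            for _ in range(500)
        ]
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            score_on_covariate([1, 2, 3], [5, 5, 5])
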