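"""Logistic modeling: closed forms, recovery, selection, cross-checks."""

import numpy as np
import pandas as pd
import pytest

from dectrod import (
    Candidate,
    LogisticModelSpec,
    fit_logistic,
    forward_select,
    rod_transform,
    univariable_screen,
)
from dectrod.modeling import (
    CollinearityError,
    ModelError,
    likelihood_ratio_test,
)


def _expand_2x2(n11, n01, n10, n00):
    """Binary predictor/outcome dataset from cell counts (x, y)."""
    x = np.concatenate([np.ones(n11), np.zeros(n01), np.ones(n10), np.zeros(n00)])
    y = np.concatenate([np.ones(n11 + n01), np.zeros(n10 + n00)])
    return x[:, None], y


class TestRodTransform:
    @pytest.mark.parametrize("rod, expected", [(0.0, 10.0), (1.0, 0.0), (0.105, 8.95)])
    def test_values(self, rod, expected):
        assert rod_transform(rod) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rod_transform(-0.1)

    def test_vectorized(self):
        np.testing.assert_allclose(rod_transform([0.0, 0.5]), [10.0, 5.0])


class TestFitLogistic:
    def test_saturated_2x2_equals_cross_product_ratio(self):
        # hilum-absence x metastasis counts from the study
        X, y = _expand_2x2(24, 15, 10, 88)
        fit = fit_logistic(X, y, names=["hilum_absent"])
        assert fit.converged
        assert fit.odds_ratio[1] == pytest.approx(24 * 88 / (15 * 10), abs=1e-6)

    def test_null_recovery_large_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10_000)
        y = rng.random(10_000) < 0.3  # independent of x
        fit = fit_logistic(x[:, None], y.astype(float))
        assert 0.95 < fit.odds_ratio[1] < 1.05

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(x[:, None], y)
        assert abs(fit.coef[0] - (-1.0)) < 3 * fit.se[0]
        assert abs(fit.coef[1] - 0.8) < 3 * fit.se[1]
        assert fit.ci_low[1] < fit.odds_ratio[1] < fit.ci_high[1]

    def test_loglik_monotone_and_probabilities_bounded(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(300, 2))
        y = (rng.random(300) < 0.4).astype(float)
        fit = fit_logistic(x, y)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert fit.log_likelihood <= 0

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        x = rng.normal(size=(400, 2))
        eta = -0.5 + 0.7 * x[:, 0] - 0.3 * x[:, 1]
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)
        assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-9)

    def test_complete_separation_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1], float)
        fit = fit_logistic(x, y)
        assert not fit.converged

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(CollinearityError, match="'a' and 'b'"):
            fit_logistic(X, y)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ModelError, match="constant"):
            fit_logistic(np.ones((50, 1)), np.tile([0.0, 1.0], 25))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ModelError):
            fit_logistic(np.arange(10.0)[:, None], np.zeros(10))


class TestScreenAndSelect:
    def test_threshold_one_passes_all_sorted(self, small_cohort):
        cands = [
            Candidate("rod_att40"),
            Candidate("node_short_mm"),
            Candidate("hilum_present", "categorical"),
        ]
        res = univariable_screen(small_cohort, cands, threshold=1.0)
        assert [c.name for c, _ in res] != []
        ps = [p for _, p in res]
        assert ps == sorted(ps)
        assert len(res) == 3

    def test_default_cohort_screen_passes_rod_and_diameter(self, derived_10k):
        cands = [Candidate("rod_att40"), Candidate("node_short_mm")]
        res = univariable_screen(derived_10k, cands, threshold=0.001)
        assert {c.name for c, _ in res} == {"rod_att40", "node_short_mm"}

    def test_noise_candidates_rarely_pass_strict_screen(self):
        rng = np.random.default_rng(17)
        passed = total = 0
        for _ in range(300):
            df = pd.DataFrame(
                {"group": np.repeat([0, 1], [98, 39]), "noise": rng.normal(size=137)}
            )
            res = univariable_screen(df, [Candidate("noise")], threshold=0.001)
            passed += len(res)
            total += 1
        assert passed / total < 0.02  # nominal rate 0.001

    def test_single_candidate_selected(self, derived_10k):
        spec = LogisticModelSpec(
            outcome="group", candidates=(Candidate("node_short_mm"),)
        )
        selected, fit, trace = forward_select(spec, derived_10k)
        assert selected == ["node_short_mm"]
        assert "node_short_mm" in fit.terms

    def test_duplicate_candidate_rejected_as_collinear(self, derived_10k):
        df = derived_10k.assign(short_copy=derived_10k["node_short_mm"])
        spec = LogisticModelSpec(
            outcome="group",
            candidates=(Candidate("node_short_mm"), Candidate("short_copy")),
        )
        selected, _, trace = forward_select(spec, df)
        assert selected == ["node_short_mm"]
        rejected = [t for t in trace if t["candidate"] == "short_copy"]
        assert rejected and rejected[0]["action"] == "rejected"

    def test_no_candidate_passing_gives_empty_model(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"group": np.repeat([0, 1], [60, 40]), "noise": rng.normal(size=100)}
        )
        spec = LogisticModelSpec(outcome="group", candidates=(Candidate("noise"),))
        selected, fit, trace = forward_select(spec, df)
        assert selected == []
        assert fit.terms == ("intercept",)
        assert trace[-1]["action"] == "empty-model"

    def test_events_per_variable_cap(self, derived_10k):
        # 10 correlated-with-outcome candidates but only floor(events/10) slots
        df = derived_10k.head(60).copy()  # ~17 events -> cap 1
        spec = LogisticModelSpec(
            outcome="group",
            candidates=(Candidate("node_short_mm"), Candidate("rod_att40")),
            entry_threshold=1.0,
        )
        selected, _, _ = forward_select(spec, df)
        events = int(min((df["group"] == 1).sum(), (df["group"] == 0).sum()))
        assert len(selected) <= max(events // 10, 1)

    def test_rod_transform_flips_association_sign(self, derived_10k):
        y = derived_10k["group"].to_numpy(float)
        raw = fit_logistic(derived_10k[["rod_att40"]], y)
        trans = fit_logistic(
            pd.DataFrame({"rod_t": rod_transform(derived_10k["rod_att40"].to_numpy())}), y
        )
        assert raw.coef[1] < 0 < trans.coef[1]
        assert trans.odds_ratio[1] > 1  # direction of the published OR (2.00)


class TestLikelihoodRatio:
    def test_lrt_of_added_noise_is_uniformish(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        base = fit_logistic(x[:, None], y, names=["x"])
        ps = []
        for _ in range(60):
            z = rng.normal(size=n)
            full = fit_logistic(np.column_stack([x, z]), y, names=["x", "z"])
            ps.append(likelihood_ratio_test(full, base))
        frac = np.mean(np.asarray(ps) < 0.05)
        assert frac < 0.2
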