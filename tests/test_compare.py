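"""Super learner, TMLE, bootstrap inference, Holm adjustment."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mabpk import (
    EffectSpec,
    SuperLearner,
    bootstrap_inference,
    holm_adjust,
    simulate_feature_table,
    tmle_ate,
)
from mabpk.compare import TMLEConfig
from mabpk.errors import ConfigError, EstimationError

FAST = TMLEConfig(runs=1, folds=5, library_q=("glm", "mean"),
                  library_g=("glm", "mean"), seed=0)


class TestHolm:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(holm_adjust([0.001, 0.02, 0.04]),
                                   [0.003, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(11)
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestSuperLearner:
    def test_constant_outcome_mean_learner_dominates(self, rng):
        X = rng.normal(size=(80, 3))
        y = np.full(80, 2.5)
        sl = SuperLearner(library=("glm", "mean"), folds=5, random_state=1).fit(X, y)
        np.testing.assert_allclose(sl.predict(X), 2.5, atol=1e-8)

    def test_linear_outcome_linear_learners_win(self, rng):
        X = rng.normal(size=(100, 3))
        y = X @ [1.0, -2.0, 0.5] + 3.0
        sl = SuperLearner(folds=5, random_state=2).fit(X, y)
        linear = {"glm", "step", "lasso"}
        w_linear = sum(w for n, w in zip(sl.names_, sl.weights_) if n in linear)
        assert w_linear > 0.9
        assert min(sl.cv_risk_[n] for n in linear if n in sl.cv_risk_) < 1e-10

    def test_stacked_risk_not_worse_than_best_single(self, rng):
        X = rng.normal(size=(120, 4))
        y = np.sin(X[:, 0]) + 0.3 * rng.normal(size=120)
        sl = SuperLearner(folds=5, random_state=3).fit(X, y)
        assert sl.cv_risk_stacked_ <= min(sl.cv_risk_.values()) * 1.05 + 1e-9

    def test_binomial_predictions_are_probabilities(self, rng):
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] + rng.normal(size=100) > 0).astype(float)
        sl = SuperLearner(library=("glm", "mars", "mean"), family="binomial",
                          folds=5, random_state=4).fit(X, y)
        p = sl.predict(X)
        assert np.all((p > 0) & (p < 1))

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(90, 3))
        y = X[:, 0] + rng.normal(size=90)
        s1 = SuperLearner(library=("glm", "rf", "mean"), folds=5, random_state=5).fit(X, y)
        s2 = SuperLearner(library=("glm", "rf", "mean"), folds=5, random_state=5).fit(X, y)
        np.testing.assert_array_equal(s1.predict(X), s2.predict(X))

    def test_failing_learner_dropped_with_warning(self, rng, monkeypatch):
        import mabpk.compare as cmp

        orig = cmp._make_learner

        def broken(name, family, seed):
            if name == "mars":
                raise RuntimeError("boom")
            return orig(name, family, seed)

        monkeypatch.setattr(cmp, "_make_learner", broken)
        X = rng.normal(size=(60, 2))
        y = X[:, 0]
        with pytest.warns(UserWarning, match="mars"):
            sl = SuperLearner(library=("glm", "mars", "mean"), folds=5,
                              random_state=6).fit(X, y)
        assert "mars" not in sl.names_
        assert sl.weights_.sum() == pytest.approx(1.0)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ConfigError):
            SuperLearner(folds=10).fit(rng.normal(size=(12, 2)), rng.normal(size=12))


class TestTmleAte:
    def test_no_confounding_matches_unadjusted_difference(self, rng):
        n = 300
        W = pd.DataFrame(dict(weight=rng.normal(74, 12, n), crcl=rng.normal(120, 25, n),
                              age=rng.normal(30, 8, n),
                              sex=rng.choice(["female", "male"], n)))
        A = rng.integers(0, 2, n)
        y = np.exp(rng.normal(1.0, 0.3, n) + 0.2 * A)
        res = tmle_ate(pd.DataFrame({"f": y}), A, W, FAST)
        unadj = np.log(y[A == 1]).mean() - np.log(y[A == 0]).mean()
        assert res.ate[0] == pytest.approx(unadj, abs=0.02)

    def test_null_simulation_centred_at_one(self):
        ratios = []
        for seed in range(9):
            tab = simulate_feature_table(n_single=200, n_combination=150,
                                         covariate_effects=None, seed=seed)
            A = (tab.group == "combination").astype(int).to_numpy()
            res = tmle_ate(tab[["CL"]], A, tab[["weight", "crcl", "age", "sex"]], FAST)
            ratios.append(res.ratio[0])
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)

    def test_recovers_injected_vc_effect_under_confounding(self):
        cfg = TMLEConfig(runs=2, folds=5, seed=11,
                         library_q=("glm", "step", "mars", "mean"),
                         library_g=("glm", "mean"))
        ratios = []
        for seed in (1, 2, 3):
            tab = simulate_feature_table(effect=EffectSpec(Vc_ratio=1.25), seed=seed)
            A = (tab.group == "combination").astype(int).to_numpy()
            res = tmle_ate(tab[["Vc"]], A, tab[["weight", "crcl", "age", "sex"]], cfg)
            ratios.append(res.ratio[0])
        assert np.median(ratios) == pytest.approx(1.25, abs=0.08)

    def test_ratio_consistency(self):
        tab = simulate_feature_table(n_single=40, n_combination=30, seed=4)
        A = (tab.group == "combination").astype(int).to_numpy()
        res = tmle_ate(tab[["Vc", "CL"]], A, tab[["weight", "crcl", "age", "sex"]], FAST)
        for _, row in res.iterrows():
            assert row.ratio == pytest.approx(np.exp(row.psi1 - row.psi0), rel=1e-12)

    def test_single_group_rejected(self, rng):
        W = pd.DataFrame(dict(w=rng.normal(size=30)))
        with pytest.raises(EstimationError):
            tmle_ate(pd.DataFrame({"f": np.exp(rng.normal(size=30))}),
                     np.ones(30, dtype=int), W, FAST)


class TestBootstrap:
    @staticmethod
    def _table(seed=5, n1=40, n0=30, effect=EffectSpec()):
        tab = simulate_feature_table(n_single=n0, n_combination=n1, effect=effect,
                                     seed=seed)
        A = (tab.group == "combination").astype(int).to_numpy()
        return tab, A, tab[["weight", "crcl", "age", "sex"]]

    def test_degenerate_features_zero_width(self, rng):
        n = 40
        A = np.array([0, 1] * (n // 2))
        W = pd.DataFrame(dict(w=rng.normal(size=n)))
        const = pd.DataFrame({"f": np.full(n, 3.0)})
        res = bootstrap_inference(const, A, W, B=10, seed=1, config=FAST)
        assert res[0].ci95[0] == pytest.approx(res[0].ci95[1])
        assert res[0].p_unadj == 1.0

    def test_determinism_and_invariants(self):
        tab, A, W = self._table()
        out = tab[["Vc", "CL"]]
        r1 = bootstrap_inference(out, A, W, B=20, seed=7, config=FAST)
        r2 = bootstrap_inference(out, A, W, B=20, seed=7, config=FAST)
        for a, b in zip(r1, r2):
            assert a.ci95 == b.ci95 and a.p_unadj == b.p_unadj
        for r in r1:
            assert r.ci95[0] <= r.ratio <= r.ci95[1]
            assert r.p_holm >= r.p_unadj - 1e-12
            assert r.ratio > 0

    def test_null_coverage_small(self):
        covered = 0
        reps = 8
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(reps):
                tab, A, W = self._table(seed=20 + seed, n1=30, n0=30)
                res = bootstrap_inference(tab[["CL"]], A, W, B=40,
                                          seed=100 + seed, config=FAST)
                lo, hi = res[0].ci95
                covered += lo <= 1.0 <= hi
        assert covered >= reps - 2  # ~95% nominal; allow small-sample slack
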