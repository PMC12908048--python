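"""Logistic fits, screening, AUC and the bootstrap optimism correction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from dysbiom import ModelSpec, ValidationError, auc, bootstrap_optimism, fit_logistic, univariate_screen


def make_2x2_data():
    # outcome=1: 20 with x=1, 10 with x=0; outcome=0: 10 with x=1, 20 with x=0
    y = [1] * 30 + [0] * 30
    x = [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20
    return pd.DataFrame({"y": y, "x": x}, dtype=float)


class TestFitLogistic:
    def test_log_odds_ratio_identity(self):
        fit = fit_logistic(make_2x2_data(), "y", ["x"])
        assert fit.params[1] == pytest.approx(np.log(4), abs=1e-8)

    def test_intercept_only_prevalence(self):
        y = np.r_[np.ones(37), np.zeros(43)]
        df = pd.DataFrame({"y": y})
        fit = fit_logistic(df, "y", [])
        assert fit.params[0] == pytest.approx(np.log(37 / 43), abs=1e-10)

    def test_matches_statsmodels_on_random_data(self, rng):
        for _ in range(5):
            X = rng.normal(size=(120, 3)) * [1.0, 50.0, 0.02]
            beta = np.array([0.3, -0.8, 0.02, 25.0])
            eta = beta[0] + X @ beta[1:]
            y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() < 10 or y.sum() > 110:
                continue
            df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(y=y)
            ours = fit_logistic(df, "y", ["a", "b", "c"])
            theirs = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            assert np.allclose(ours.params, theirs.params, atol=1e-6)
            assert np.allclose(ours.bse, theirs.bse, rtol=1e-4)
            assert np.allclose(ours.pvalues, theirs.pvalues, atol=1e-6)

    def test_separation_falls_back_to_ridge(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        df = pd.DataFrame({"y": y, "x": np.r_[np.arange(20.0), 100 + np.arange(20.0)]})
        fit = fit_logistic(df, "y", ["x"])
        assert fit.penalized
        assert fit.ridge_lambda > 0
        assert np.isfinite(fit.params).all()

    def test_null_pvalues_roughly_uniform(self):
        """Wald p of a pure-noise predictor is uniform under the null."""
        ps = []
        for rep in range(200):
            r = np.random.default_rng(700 + rep)
            df = pd.DataFrame({"y": r.integers(0, 2, 100).astype(float), "x": r.normal(size=100)})
            ps.append(fit_logistic(df, "y", ["x"]).pvalues[1])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 2.0, 1.0], "x": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError, match="binary"):
            fit_logistic(df, "y", ["x"])


class TestScreen:
    def test_alpha_one_selects_everything(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        df["y"] = rng.integers(0, 2, 60).astype(float)
        spec = ModelSpec("y", list("abcd"), screen_alpha=1.0)
        assert univariate_screen(df, spec) == list("abcd")

    def test_perfect_predictor_selected_via_separation(self, rng):
        y = rng.integers(0, 2, 40).astype(float)
        df = pd.DataFrame({"y": y, "mirror": y, "noise": rng.normal(size=40)})
        records = []
        sel = univariate_screen(df, ModelSpec("y", ["mirror", "noise"]), records=records)
        assert "mirror" in sel
        assert any(r.get("status") == "separation" for r in records)

    def test_zero_variance_skipped_with_record(self, rng):
        df = pd.DataFrame({"y": rng.integers(0, 2, 40).astype(float),
                           "flat": np.ones(40), "x": rng.normal(size=40)})
        records = []
        sel = univariate_screen(df, ModelSpec("y", ["flat", "x"]), records=records)
        assert "flat" not in sel
        assert records[0]["status"] == "skipped_zero_variance"

    def test_noise_selection_rate_near_alpha(self):
        """A pure-noise predictor passes the p<0.10 screen about 10% of the
        time (binomial band over 500 replicates)."""
        hits = 0
        n_rep = 500
        for rep in range(n_rep):
            r = np.random.default_rng(2000 + rep)
            df = pd.DataFrame({"y": np.r_[np.ones(100), np.zeros(100)],
                               "x": r.normal(size=200)})
            hits += bool(univariate_screen(df, ModelSpec("y", ["x"])))
        rate = hits / n_rep
        band = 2.576 * np.sqrt(0.1 * 0.9 / n_rep)
        assert abs(rate - 0.10) <= band

    def test_outcome_among_candidates_rejected(self):
        with pytest.raises(ValidationError, match="outcome"):
            ModelSpec("y", ["x", "y"]).validate()


class TestAuc:
    def test_extremes_and_ties(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_pair_counting_example(self):
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_matches_sklearn_on_random_scores(self, rng):
        for _ in range(20):
            s = rng.normal(size=50).round(1)  # rounding forces ties
            y = rng.integers(0, 2, 50)
            if y.sum() in (0, 50):
                continue
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_complement_invariant(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        assert auc(s, y) + auc(-s, y) == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError, match="classes"):
            auc([1, 2, 3], [1, 1, 1])


class TestBootstrapOptimism:
    def _noise_data(self, seed=0, n=80, p=6):
        r = np.random.default_rng(seed)
        df = pd.DataFrame(r.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        df["y"] = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        return df, ModelSpec("y", [f"x{i}" for i in range(p)])

    def test_identity_resample_gives_zero_optimism(self):
        df, spec = self._noise_data(seed=3)
        res = bootstrap_optimism(df, spec, n_boot=1, seed=0,
                                 _index_sampler=lambda rng, m: np.arange(m))
        assert res.optimism == pytest.approx(0.0, abs=1e-12)
        assert res.corrected_auc == pytest.approx(res.apparent_auc)

    def test_determinism(self):
        df, spec = self._noise_data(seed=4)
        a = bootstrap_optimism(df, spec, n_boot=30, seed=9)
        b = bootstrap_optimism(df, spec, n_boot=30, seed=9)
        assert a.apparent_auc == b.apparent_auc
        assert a.optimism == b.optimism
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_corrected_identity_and_ci_ordering(self):
        df, spec = self._noise_data(seed=5)
        res = bootstrap_optimism(df, spec, n_boot=50, seed=2)
        assert res.corrected_auc == pytest.approx(res.apparent_auc - res.optimism, abs=1e-12)
        assert res.ci_low <= res.corrected_auc <= res.ci_high

    def test_screening_inside_loop_raises_optimism_estimate(self):
        """Re-screening inside each resample captures selection uncertainty:
        freezing the full-data selection underestimates optimism on noise."""
        from dysbiom.prognosis import _screen_fit_score, auc as _auc, fit_logistic as _fit

        inside_gt_outside = 0
        for rep in range(10):
            df, spec = self._noise_data(seed=100 + rep, n=80, p=8)
            res = bootstrap_optimism(df, spec, n_boot=100, seed=rep)

            # frozen-selection variant: screen once on the full data
            sel = univariate_screen(df, spec)
            y = df["y"].to_numpy()
            rng = np.random.default_rng(rep)
            opts = []
            for _ in range(100):
                while True:
                    idx = rng.integers(0, len(df), len(df))
                    if 0 < y[idx].sum() < len(idx):
                        break
                boot = df.iloc[idx]
                if sel:
                    fit_b = _fit(boot, "y", sel)
                    a_boot = _auc(fit_b.predict(boot[sel].to_numpy(float)), y[idx])
                    a_test = _auc(fit_b.predict(df[sel].to_numpy(float)), y)
                else:
                    a_boot = a_test = 0.5
                opts.append(a_boot - a_test)
            inside_gt_outside += res.optimism > np.mean(opts)
        assert inside_gt_outside >= 8

    def test_optimism_positive_under_null(self):
        """Mean optimism over replicates is positive on pure-noise data."""
        total = 0.0
        for rep in range(20):
            df, spec = self._noise_data(seed=300 + rep)
            total += bootstrap_optimism(df, spec, n_boot=40, seed=rep).optimism
        assert total / 20 > 0
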