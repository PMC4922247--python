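"""Mixed-model oracles: closed forms, cross-checks and recovery."""

import numpy as np
import pandas as pd
import pytest

from scopetrack.lmm import (
    HetVarMixedLM,
    HetVarMixedLMResults,
    inverse_transform_response,
    lrt,
    model_select,
    transform_response,
)
from conftest import make_lmm_dataset


class TestTransform:
    def test_u_inst_log_shift(self):
        assert transform_response(0.9, "u_inst") == pytest.approx(0.0, abs=1e-15)

    def test_other_measures_pass_through(self):
        y = np.array([1.0, -5.0, 300.0])
        assert np.array_equal(transform_response(y, "a_day"), y)

    def test_round_trip(self):
        y = np.array([0.01, 0.5, 2.0])
        back = inverse_transform_response(transform_response(y, "u_inst"), "u_inst")
        assert np.allclose(back, y, atol=1e-12)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            transform_response(np.array([-0.1]), "u_inst")


def anova_ml_oracle(y: np.ndarray, groups: np.ndarray):
    """Closed-form ML for the balanced one-way random-effects model.

    With J groups of size n:  sigma_e^2 = SSW / (J(n-1)),
    lambda = sigma_e^2 + n sigma_a^2 = SSB / J  (ML divides by J),
    mu = grand mean.
    """
    labels = np.unique(groups)
    J = len(labels)
    n = len(y) // J
    gm = y.mean()
    means = np.array([y[groups == g].mean() for g in labels])
    ssw = sum(np.sum((y[groups == g] - m) ** 2) for g, m in zip(labels, means))
    ssb = n * np.sum((means - gm) ** 2)
    sigma_e2 = ssw / (J * (n - 1))
    lam = ssb / J
    sigma_a2 = max((lam - sigma_e2) / n, 0.0)
    # profiled ML log-likelihood at the closed-form optimum
    ll = -0.5 * (
        len(y) * np.log(2 * np.pi)
        + J * (n - 1) * np.log(sigma_e2)
        + J * np.log(sigma_e2 + n * sigma_a2)
        + ssw / sigma_e2
        + ssb / (sigma_e2 + n * sigma_a2)
    )
    return gm, sigma_a2, sigma_e2, ll


class TestFitOracles:
    def test_balanced_equal_variance_matches_anova_closed_form(self):
        rng = np.random.default_rng(10)
        J, n = 8, 6
        groups = np.repeat(np.arange(J), n)
        y = 50.0 + rng.normal(0, 12.0, J)[groups] + rng.normal(0, 5.0, J * n)
        df = pd.DataFrame({"fish_id": groups, "y": y})
        res = HetVarMixedLM.from_dataframe(df, "y", []).fit(
            "ml", equal_variances=True
        )
        mu, sa2, se2, ll = anova_ml_oracle(y, groups)
        assert res.params["intercept"] == pytest.approx(mu, abs=1e-6)
        assert res.sigma_a**2 == pytest.approx(sa2, rel=1e-5)
        assert res.sigma_j.iloc[0] ** 2 == pytest.approx(se2, rel=1e-5)
        assert res.llf == pytest.approx(ll, abs=1e-6)

    def test_equal_variance_fit_agrees_with_statsmodels(self):
        """Independent cross-check: ML loglik matches MixedLM within 1e-4."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(11)
        df = make_lmm_dataset(rng, n_fish=10, n_obs=7,
                              sigma_j_values=(80.0,))
        ours = HetVarMixedLM.from_dataframe(df, "y", ["fl"]).fit(
            "ml", equal_variances=True
        )
        theirs = smf.mixedlm("y ~ fl", df, groups=df["fish_id"]).fit(reml=False)
        assert ours.llf == pytest.approx(theirs.llf, abs=1e-4)
        assert ours.params["fl"] == pytest.approx(theirs.params["fl"], abs=1e-3)

    def test_constant_response_degenerates_cleanly(self):
        df = pd.DataFrame(
            {
                "fish_id": np.repeat(np.arange(4), 5),
                "fl": np.repeat([14.0, 15.0, 16.0, 17.0], 5),
                "y": 3.0,
            }
        )
        res = HetVarMixedLM.from_dataframe(df, "y", ["fl"]).fit("ml")
        assert res.params["fl"] == pytest.approx(0.0, abs=1e-8)
        assert res.sigma_a < 1e-6

    def test_heterogeneous_variances_recovered(self):
        rng = np.random.default_rng(12)
        df = make_lmm_dataset(rng, n_fish=12, n_obs=60, sigma_a=100.0)
        res = HetVarMixedLM.from_dataframe(df, "y", ["fl"]).fit("ml")
        truth = df.groupby("fish_id")["sigma_j_true"].first()
        rel = np.abs(res.sigma_j - truth) / truth
        assert rel.median() < 0.15

    def test_variance_identifiability_guard(self):
        df = pd.DataFrame({"fish_id": [0, 1, 2], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            HetVarMixedLM.from_dataframe(df, "y", [])


class TestICC:
    def _results_with(self, sigma_a, sigma_j):
        rng = np.random.default_rng(0)
        df = make_lmm_dataset(rng, n_fish=4, n_obs=4)
        model = HetVarMixedLM.from_dataframe(df, "y", [])
        res = model.fit("ml")
        res.sigma_a = sigma_a
        res.sigma_j = pd.Series(sigma_j, index=model.group_labels)
        return res

    def test_equal_variances_give_half(self):
        res = self._results_with(50.0, [50.0, 50.0, 50.0, 50.0])
        assert np.allclose(res.icc, 0.5, atol=1e-12)

    def test_no_between_fish_variance_gives_zero(self):
        res = self._results_with(0.0, [50.0, 60.0, 70.0, 80.0])
        assert np.allclose(res.icc, 0.0, atol=1e-12)

    def test_icc_decreasing_in_residual_sd(self):
        res = self._results_with(100.0, [10.0, 50.0, 200.0, 1000.0])
        assert np.all(np.diff(res.icc.to_numpy()) < 0)
        assert ((res.icc >= 0) & (res.icc <= 1)).all()

    def test_recovery_at_known_variance_components(self):
        """Median recovered ICCs near 0.8 / 0.2 truth at sigma_a=100."""
        rng = np.random.default_rng(13)
        lo, hi = [], []
        for _ in range(10):
            df = make_lmm_dataset(rng, n_fish=16, n_obs=12, sigma_a=100.0)
            res = HetVarMixedLM.from_dataframe(df, "y", ["fl"]).fit(
                "ml", n_starts=1
            )
            truth = df.groupby("fish_id")["sigma_j_true"].first()
            hi += list(res.icc[truth == 50.0])
            lo += list(res.icc[truth == 200.0])
        assert np.median(hi) == pytest.approx(100**2 / (100**2 + 50**2), abs=0.1)
        assert np.median(lo) == pytest.approx(100**2 / (100**2 + 200**2), abs=0.1)


@pytest.fixture(scope="module")
def selection():
    rng = np.random.default_rng(14)
    df = make_lmm_dataset(rng, n_fish=16, n_obs=12)
    df = df.rename(columns={"x": "fr", "y": "value"})
    for col in ("smr", "mmr"):
        df[col] = df.groupby("fish_id")["fl"].transform("first") * 0.0 + \
            rng.normal(size=len(df))
        df[col] = df.groupby("fish_id")[col].transform("first")
    return model_select(
        df,
        response="value",
        measure="a_day",
        candidates={"M1a": "fr", "M1b": "smr", "M1c": "mmr"},
        seed=0,
    )


class TestModelSelection:
    def test_nesting_orders_logliks(self, selection):
        tab = selection.table.set_index("model")
        for name in ("M1a", "M1b", "M1c"):
            assert tab.loc[name, "loglik"] >= tab.loc["M1", "loglik"] - 1e-6
        assert tab.loc["M1", "loglik"] >= tab.loc["M0", "loglik"] - 1e-6

    def test_lrt_nonnegative_and_consistent(self, selection):
        tab = selection.table.set_index("model")
        assert (tab["lrt_stat"].dropna() >= 0).all()
        assert tab.loc["M1a", "lrt_stat"] == pytest.approx(
            2.0 * (tab.loc["M1a", "loglik"] - tab.loc["M1", "loglik"]), abs=1e-8
        )

    def test_best_model_has_zero_delta_aic(self, selection):
        tab = selection.table.set_index("model")
        assert tab.loc[selection.best_name, "delta_aic"] == pytest.approx(0.0)
        assert selection.best_reml.method == "reml"

    def test_true_fl_effect_detected(self):
        """With a strong FL effect and a null X, M1-family beats M0."""
        rng = np.random.default_rng(15)
        wins = 0
        for _ in range(10):
            df = make_lmm_dataset(rng, n_fish=16, n_obs=12, beta_fl=60.0,
                                  sigma_a=50.0)
            df = df.rename(columns={"x": "fr", "y": "value"})
            sel = model_select(df, "value", "a_day",
                               candidates={"M1a": "fr"}, seed=0)
            wins += sel.best_name != "M0"
        assert wins >= 8
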