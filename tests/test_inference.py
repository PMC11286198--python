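import numpy as np
import pandas as pd
import pytest
from scipy.special import polygamma

from beescape.glmm import NegativeBinomialGLMM
from beescape.inference import (
    InferenceError,
    TwoSDScaler,
    aicc,
    all_subsets_selection,
    build_design,
    effect_translation,
    enumerate_marginal_subsets,
    family_comparison,
    r2_nakagawa,
    standardize_2sd,
    vif,
)


class TestTwoSDStandardization:
    def test_analytic_two_point_case(self):
        # sd of {0,1} is 1/sqrt(2); (x - 0.5)/(2 sd) = -+ 1/(4 sd)
        z, meta = standardize_2sd([0.0, 1.0])
        sd = np.std([0.0, 1.0], ddof=1)
        assert z == pytest.approx([(0 - 0.5) / (2 * sd), (1 - 0.5) / (2 * sd)])
        assert np.std(z, ddof=1) == pytest.approx(0.5, abs=1e-15)

    def test_output_mean_zero_sd_half(self, rng):
        x = rng.normal(3.0, 7.0, 500)
        z, meta = standardize_2sd(x)
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(0.5, abs=1e-12)

    def test_inverse_transform_roundtrip(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=100), "b": rng.exponential(size=100)})
        sc = TwoSDScaler().fit(x)
        back = sc.inverse_transform(sc.transform(x))
        assert np.allclose(back, x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(InferenceError, match="constant"):
            TwoSDScaler().fit(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestAicc:
    def test_hand_computed_value(self):
        # logLik=-100, k=3, n=100 -> AIC=206, AICc=206.25
        aic = -2 * (-100.0) + 2 * 3
        assert aic == 206.0
        assert aicc(aic, 3, 100) == pytest.approx(206.25)

    def test_limit_to_aic_for_large_n(self):
        assert aicc(206.0, 3, 10**6) - 206.0 < 1e-3

    def test_k_zero_equals_aic(self):
        assert aicc(123.4, 0, 50) == 123.4

    def test_small_n_rejected(self):
        with pytest.raises(InferenceError):
            aicc(100.0, 5, 6)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)}
        )
        assert np.allclose(vif(X), 1.0, atol=1e-8)

    def test_duplicated_column_infinite(self):
        x = np.arange(10.0)
        out = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out).all()

    def test_known_correlation_closed_form(self, rng):
        # construct an exact empirical correlation of 0.9
        n = 2000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - a * (a @ b) / (a @ a)
        b = (b - b.mean()) / b.std()
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        out = vif(pd.DataFrame({"a": a, "b": x2}))
        assert out["a"] == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-6)


class TestMarginalSubsets:
    def test_two_mains_one_interaction(self):
        subs = enumerate_marginal_subsets(["A", "B", "A:B"])
        assert set(map(frozenset, subs)) == {
            frozenset(), frozenset({"A"}), frozenset({"B"}),
            frozenset({"A", "B"}), frozenset({"A", "B", "A:B"}),
        }
        # brute-force oracle: filter all subsets by marginality
        import itertools

        brute = [
            s
            for r in range(4)
            for s in itertools.combinations(["A", "B", "A:B"], r)
            if all(p in s for t in s if ":" in t for p in t.split(":"))
        ]
        assert len(subs) == len(brute) == 5

    def test_global_model_candidate_count(self):
        terms = ["m", "p", "l", "a", "m:p", "m:l"]
        subs = enumerate_marginal_subsets(terms)
        import itertools

        brute = [
            s
            for r in range(len(terms) + 1)
            for s in itertools.combinations(terms, r)
            if all(p in s for t in s if ":" in t for p in t.split(":"))
        ]
        assert len(subs) == len(brute) == 26
        assert () in subs  # intercept-only always enumerated
        assert len(set(subs)) == len(subs)  # no duplicates

    def test_orphan_interaction_rejected(self):
        with pytest.raises(InferenceError, match="A:B"):
            enumerate_marginal_subsets(["A", "A:B"])


@pytest.fixture(scope="module")
def sel_fit(small_data):
    f = small_data["frame"]
    y = f["count"].to_numpy()
    off = np.log(f["effort_h"].to_numpy())
    table, fits = all_subsets_selection(
        f, y, small_data["global_terms"], groups=f["bee_species"].to_numpy(),
        offset=off, family="nb2", n_quad=3, n_restarts=1, seed=0,
    )
    return table, fits, f, y, off


class TestSelection:
    def test_table_invariants(self, sel_fit):
        table, fits, *_ = sel_fit
        conv = table[table["converged"]]
        assert (conv["aicc"].diff().dropna() >= 0).all()  # sorted ascending
        assert table["best"].sum() == 1  # exactly one best
        assert conv["delta_aicc"].iloc[0] == pytest.approx(0.0)
        assert len(table) == 26

    def test_best_is_most_parsimonious_in_window(self, sel_fit):
        table, *_ = sel_fit
        window = table[table["in_window"] & table["converged"]]
        best = table[table["best"]].iloc[0]
        assert best["k"] == window["k"].min()


class TestFamilyComparison:
    def test_nb2_beats_poisson_on_overdispersed_counts(self, preset_data):
        # at study scale with theta = 2 truth, NB2 must rank first on AICc
        f = preset_data["frame"]
        y = f["count"].to_numpy()
        off = np.log(f["effort_h"].to_numpy())
        table, fits = family_comparison(
            f, y, list(preset_data["global_terms"]),
            groups=f["bee_species"].to_numpy(), offset=off,
            zero_inflation=(False,), n_quad=3, n_restarts=1, seed=0,
        )
        assert table.iloc[0]["family"] == "nb2"


class TestR2Nakagawa:
    def _fit(self, small_data):
        f = small_data["frame"]
        X = build_design(f, tuple(small_data["global_terms"]))
        off = np.log(f["effort_h"].to_numpy())
        m = NegativeBinomialGLMM(n_restarts=1, n_quad=5, seed=0).fit(
            X, f["count"].to_numpy(), groups=f["bee_species"].to_numpy(),
            offset=off)
        return m, X, off

    def test_formula_oracle(self, small_data):
        """Independent recomputation of the variance decomposition."""
        m, X, off = self._fit(small_data)
        marg, cond = r2_nakagawa(m, X, offset=off)
        D = np.column_stack([np.ones(len(X)), X.to_numpy()])
        eta = D @ m.coef_.to_numpy()
        var_f = np.var(eta)
        sig2_re = m.sigma_re_**2
        mu_bar = np.mean(np.exp(off + eta + 0.5 * sig2_re))
        sig2_obs = polygamma(1, 1.0 / (1.0 / mu_bar + 1.0 / m.theta_))
        denom = var_f + sig2_re + sig2_obs
        assert marg == pytest.approx(var_f / denom, abs=1e-6)
        assert cond == pytest.approx((var_f + sig2_re) / denom, abs=1e-6)

    def test_zero_slopes_zero_marginal(self, rng):
        y = rng.poisson(1.0, 200)
        g = np.repeat(np.arange(20), 10)
        x = pd.DataFrame({"z": np.zeros(200) + rng.normal(0, 1e-12, 200)})
        m = NegativeBinomialGLMM(family="poisson", n_restarts=1, seed=0).fit(
            x, y, groups=g)
        m.coef_.iloc[1] = 0.0  # exactly null slope
        marg, cond = r2_nakagawa(m, x)
        assert marg == pytest.approx(0.0, abs=1e-12)

    def test_sigma_zero_conditional_equals_marginal(self, small_data):
        f = small_data["frame"]
        X = build_design(f, tuple(small_data["global_terms"]))
        off = np.log(f["effort_h"].to_numpy())
        m = NegativeBinomialGLMM(random_intercept=False, seed=0).fit(
            X, f["count"].to_numpy(), offset=off)
        marg, cond = r2_nakagawa(m, X, offset=off)
        assert cond == pytest.approx(marg, abs=1e-12)

    def test_lognormal_option_differs_but_close(self, small_data):
        m, X, off = self._fit(small_data)
        t_m, _ = r2_nakagawa(m, X, offset=off, method="trigamma")
        l_m, _ = r2_nakagawa(m, X, offset=off, method="lognormal")
        assert t_m != l_m
        assert t_m == pytest.approx(l_m, rel=0.5)


class TestEffectTranslation:
    def test_closed_form_oracle(self, small_data):
        """Hand-computed prediction difference over the observed range."""
        f = small_data["frame"]
        X = build_design(f, tuple(small_data["global_terms"]))
        off = np.log(f["effort_h"].to_numpy())
        y = f["count"].to_numpy()
        m = NegativeBinomialGLMM(n_restarts=1, n_quad=5, seed=0).fit(
            X, y, groups=f["bee_species"].to_numpy(), offset=off)
        got = effect_translation(m, f, y, f["effort_h"], "z_landscape",
                                 mass_level="+1sd")
        b = m.coef_
        lo, hi = f["z_landscape"].min(), f["z_landscape"].max()
        zm = 0.5
        eta = lambda v: (b["Intercept"] + b["z_ln_mass"] * zm
                         + b["z_landscape"] * v
                         + b["z_ln_mass:z_landscape"] * zm * v)
        rate = f["count"] / f["effort_h"]
        expected = 100.0 * (np.exp(eta(hi)) - np.exp(eta(lo))) / (
            rate.max() - rate.min())
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_coefficient_zero_percent(self, small_data):
        f = small_data["frame"]
        X = build_design(f, ("z_landscape",))
        y = f["count"].to_numpy()
        m = NegativeBinomialGLMM(family="poisson", random_intercept=False,
                                 seed=0).fit(X, y)
        m.coef_["z_landscape"] = 0.0
        got = effect_translation(m, f, y, f["effort_h"], "z_landscape")
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_positive_coefficient_positive_percent(self, small_data):
        f = small_data["frame"]
        X = build_design(f, ("z_landscape",))
        y = f["count"].to_numpy()
        m = NegativeBinomialGLMM(family="poisson", random_intercept=False,
                                 seed=0).fit(X, y)
        m.coef_["z_landscape"] = abs(m.coef_["z_landscape"]) + 0.1
        assert effect_translation(m, f, y, f["effort_h"], "z_landscape") > 0

    def test_absent_predictor_rejected(self, small_data):
        f = small_data["frame"]
        X = build_design(f, ("z_landscape",))
        y = f["count"].to_numpy()
        m = NegativeBinomialGLMM(family="poisson", random_intercept=False,
                                 seed=0).fit(X, y)
        with pytest.raises(InferenceError, match="z_patch"):
            effect_translation(m, f, y, f["effort_h"], "z_patch")
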