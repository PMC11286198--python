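"""Model-frame construction, standardization, and multimodel inference.

Continuous predictors are mean-centred and divided by two standard
deviations (so a binary predictor and a standardized continuous one move
the response on comparable scales); the resulting columns have s.d. 0.5.
Candidate models are all subsets of the global fixed-effect terms that
respect marginality (an interaction enters only with both of its main
effects), ranked by AICc; within the window of equivalent support
(default 2 AICc units) the model with fewest parameters is 'best'.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import polygamma
from sklearn.base import BaseEstimator, TransformerMixin

from .glmm import GLMMError, NegativeBinomialGLMM


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# 2-SD standardization


class TwoSDScaler(TransformerMixin, BaseEstimator):
    """Standardize columns to (x - mean) / (2 * sd); output s.d. is 0.5."""

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.means_ = X.mean(axis=0).to_numpy(dtype=float)
        self.sds_ = X.std(axis=0, ddof=1).to_numpy(dtype=float)
        bad = [c for c, s in zip(self.columns_, self.sds_) if not s > 0]
        if bad:
            raise InferenceError(f"constant column(s) cannot be standardized: {bad}")
        return self

    def transform(self, X):
        X = pd.DataFrame(X)[self.columns_]
        out = (X - self.means_) / (2.0 * self.sds_)
        return out

    def inverse_transform(self, Z):
        Z = pd.DataFrame(Z)[self.columns_]
        return Z * (2.0 * self.sds_) + self.means_


def standardize_2sd(values) -> tuple[np.ndarray, dict]:
    """Functional form of :class:`TwoSDScaler` for a single column."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise InferenceError("constant input cannot be standardized")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return (x - mean) / (2.0 * sd), {"mean": mean, "sd": sd}


# ---------------------------------------------------------------------------
# Information criteria, collinearity, R^2


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise InferenceError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column (main effects only).

    VIF_j = 1/(1 - R^2_j) from regressing column j on the remaining columns
    plus an intercept.  Perfectly collinear columns report ``inf``.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise InferenceError("VIF needs at least 2 columns")
    if (X.std(axis=0, ddof=0) == 0).any():
        raise InferenceError("VIF undefined with a constant column")
    out = {}
    M = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        yj = M[:, j]
        others = np.column_stack(
            [np.ones(len(M))] + [M[:, i] for i in range(M.shape[1]) if i != j]
        )
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def r2_nakagawa(
    model: NegativeBinomialGLMM,
    X,
    offset=None,
    method: str = "trigamma",
) -> tuple[float, float]:
    """Marginal and conditional R^2 for a log-link count GLMM.

    marginal    = var_f / (var_f + sigma_re^2 + sigma_obs^2)
    conditional = (var_f + sigma_re^2) / (same denominator)

    var_f is the variance of the fixed-effect linear predictor (offset
    excluded).  The observation-level variance on the latent log scale uses
    the trigamma method by default, psi_1(1/(1/mu_bar + 1/theta)) for NB2
    and psi_1(mu_bar) for Poisson, with the lognormal approximation
    ln(1 + 1/mu_bar + 1/theta) as an option.  mu_bar is the mean marginal
    expectation exp(offset + X beta + sigma_re^2/2) averaged over rows.
    """
    if not hasattr(model, "coef_"):
        raise InferenceError("model must be fitted")
    if isinstance(X, pd.DataFrame):
        Xm = X[model.feature_names_in_].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
    design = np.column_stack([np.ones(len(Xm)), Xm])
    beta = model.coef_.to_numpy()
    eta_fixed = design @ beta
    offset = np.zeros(len(Xm)) if offset is None else np.asarray(offset, float)
    var_f = float(np.var(eta_fixed))
    sig2_re = float(model.sigma_re_**2)
    mu_bar = float(np.mean(np.exp(offset + eta_fixed + 0.5 * sig2_re)))
    if mu_bar <= 0:
        raise InferenceError("non-positive mean expectation")
    inv = 1.0 / mu_bar
    if model.family == "nb2":
        inv += 1.0 / model.theta_
    if method == "trigamma":
        sig2_obs = float(polygamma(1, 1.0 / inv))
    elif method == "lognormal":
        sig2_obs = float(np.log1p(inv))
    else:
        raise InferenceError(f"unknown method {method!r}")
    if sig2_obs <= 0:
        raise InferenceError("non-positive observation-level variance")
    denom = var_f + sig2_re + sig2_obs
    return var_f / denom, (var_f + sig2_re) / denom


# ---------------------------------------------------------------------------
# All-subsets AICc selection with marginality


def _interaction_parts(term: str) -> list[str]:
    return term.split(":")


def enumerate_marginal_subsets(terms: list[str]) -> list[tuple[str, ...]]:
    """All term subsets where every interaction has both main effects.

    The intercept-only model is the empty tuple and is always included.
    Order is deterministic: by subset size, then original term order.
    """
    mains = [t for t in terms if ":" not in t]
    inters = [t for t in terms if ":" in t]
    for it in inters:
        for part in _interaction_parts(it):
            if part not in mains:
                raise InferenceError(
                    f"interaction {it!r} lacks main effect {part!r} in the "
                    "global term list"
                )
    subsets = []
    for r_m in range(len(mains) + 1):
        for main_sub in itertools.combinations(mains, r_m):
            ok_inters = [
                it for it in inters
                if all(p in main_sub for p in _interaction_parts(it))
            ]
            for r_i in range(len(ok_inters) + 1):
                for int_sub in itertools.combinations(ok_inters, r_i):
                    subsets.append(tuple(main_sub) + tuple(int_sub))
    subsets.sort(key=lambda s: (len(s), [terms.index(t) for t in s]))
    return subsets


def build_design(frame: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design columns for a term subset; interactions are column products."""
    cols = {}
    for t in terms:
        if ":" in t:
            a, b = _interaction_parts(t)
            cols[t] = frame[a] * frame[b]
        else:
            cols[t] = frame[t]
    return pd.DataFrame(cols, index=frame.index)


def all_subsets_selection(
    frame: pd.DataFrame,
    y,
    global_terms: list[str],
    groups=None,
    offset=None,
    window: float = 2.0,
    **estimator_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], NegativeBinomialGLMM]]:
    """Fit every marginality-respecting subset of *global_terms*, rank by AICc.

    Returns the selection table (ascending AICc; exactly one best-model
    flag: fewest parameters within the AICc window, ties broken by lower
    AICc) and the fitted models keyed by term tuple.  Candidates whose
    optimizer fails to converge are excluded from ranking and flagged.
    """
    subsets = enumerate_marginal_subsets(list(global_terms))
    fits: dict[tuple[str, ...], NegativeBinomialGLMM] = {}
    rows = []
    for terms in subsets:
        X = build_design(frame, terms)
        model = NegativeBinomialGLMM(**estimator_kwargs)
        try:
            model.fit(X, y, groups=groups, offset=offset)
            ok = model.converged_
        except (GLMMError, np.linalg.LinAlgError):
            ok = False
        if ok:
            fits[terms] = model
            rows.append(
                {"model": " + ".join(terms) if terms else "(intercept only)",
                 "terms": terms, "k": model.k_, "loglik": model.loglik_,
                 "aicc": model.aicc_, "converged": True}
            )
        else:
            rows.append(
                {"model": " + ".join(terms) if terms else "(intercept only)",
                 "terms": terms, "k": np.nan, "loglik": np.nan,
                 "aicc": np.nan, "converged": False}
            )
    table = pd.DataFrame(rows)
    ranked = table[table["converged"]].sort_values("aicc", kind="mergesort")
    if len(ranked) == 0:
        raise InferenceError("no candidate model converged")
    best_aicc = float(ranked["aicc"].iloc[0])
    table["delta_aicc"] = table["aicc"] - best_aicc
    table["in_window"] = table["delta_aicc"] <= window
    window_set = table[table["in_window"] & table["converged"]]
    best_idx = window_set.sort_values(["k", "aicc"], kind="mergesort").index[0]
    table["best"] = False
    table.loc[best_idx, "best"] = True
    table = table.sort_values(
        ["converged", "aicc"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table, fits


def family_comparison(
    frame: pd.DataFrame,
    y,
    terms: list[str],
    groups=None,
    offset=None,
    families=("nb2", "poisson"),
    zero_inflation=(False, True),
    **estimator_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit the global model under each error family x zero-inflation flag.

    Returns an AICc-ranked table; the most parsimonious family within the
    data's support is the one to carry into model selection.
    """
    X = build_design(frame, tuple(terms))
    rows, fits = [], {}
    for fam in families:
        for zi in zero_inflation:
            model = NegativeBinomialGLMM(
                family=fam, zero_inflated=zi, **estimator_kwargs
            )
            key = f"{fam}{'_zi' if zi else ''}"
            try:
                model.fit(X, y, groups=groups, offset=offset)
                fits[key] = model
                rows.append(
                    {"family": fam, "zero_inflated": zi, "k": model.k_,
                     "loglik": model.loglik_, "aic": model.aic_,
                     "aicc": model.aicc_, "converged": model.converged_}
                )
            except (GLMMError, np.linalg.LinAlgError) as err:
                rows.append(
                    {"family": fam, "zero_inflated": zi, "k": np.nan,
                     "loglik": np.nan, "aic": np.nan, "aicc": np.nan,
                     "converged": False, "error": str(err)}
                )
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(
        drop=True
    )
    return table, fits


# ---------------------------------------------------------------------------
# Effect translation to percent of the observed capture-rate range


def effect_translation(
    model: NegativeBinomialGLMM,
    frame: pd.DataFrame,
    y,
    effort_h,
    predictor: str,
    mass_term: str = "z_ln_mass",
    mass_level: str = "mean",
) -> float:
    """Translate a fitted effect into percent of the observed rate range.

    Predicts the mean capture rate (counts per survey hour, random effect at
    zero) at the observed minimum and maximum of *predictor*, holding other
    covariates at their means (0 on the 2-SD standardized scale) and the
    body-mass term at ``mean`` (0), ``+1sd`` (+0.5) or ``-1sd`` (-0.5).
    Interactions are recomputed consistently.  Returns

        100 * (rate_at_max - rate_at_min) / (max - min observed rate)

    where the observed rate is count/effort per species x site cell.
    """
    terms = model.feature_names_in_
    if predictor not in terms:
        raise InferenceError(f"predictor {predictor!r} not in the fitted model")
    levels = {"mean": 0.0, "+1sd": 0.5, "-1sd": -0.5}
    if mass_level not in levels:
        raise InferenceError(f"mass_level must be one of {sorted(levels)}")
    z_mass = levels[mass_level]
    lo, hi = float(frame[predictor].min()), float(frame[predictor].max())

    def _row(value: float) -> pd.DataFrame:
        base = {}
        for t in terms:
            if ":" in t:
                continue
            if t == predictor:
                base[t] = value
            elif t == mass_term:
                base[t] = z_mass
            else:
                base[t] = 0.0
        for t in terms:
            if ":" in t:
                a, b = t.split(":")
                base[t] = base.get(a, 0.0) * base.get(b, 0.0)
        return pd.DataFrame([base])[list(terms)]

    rate_lo = float(model.predict(_row(lo))[0])
    rate_hi = float(model.predict(_row(hi))[0])
    observed = np.asarray(y, float) / np.asarray(effort_h, float)
    obs_range = float(observed.max() - observed.min())
    if obs_range <= 0:
        raise InferenceError("observed capture rates have zero range")
    return 100.0 * (rate_hi - rate_lo) / obs_range
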