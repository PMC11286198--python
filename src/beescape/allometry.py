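"""Allometric estimation of bee dry body mass from body length.

Bee dry mass (mg) is predicted from body length (mm) with a log-log
allometric model including additive taxonomic-family and sex terms:

    ln(mass) = a + b * ln(length) + family offset + sex offset

Family stands in for phylogeny; sex captures the female-biased size
dimorphism common in bees.  Reference levels are the alphabetically first
family and ``female``, whose offsets are zero by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .io import SEXES


class AllometryError(ValueError):
    pass


_REQUIRED = ("length_mm", "family", "sex")


def _check_frame(X: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise AllometryError("X must be a DataFrame with columns "
                             f"{_REQUIRED}")
    missing = [c for c in _REQUIRED if c not in X.columns]
    if missing:
        raise AllometryError(f"X is missing column(s) {missing}")
    if (X["length_mm"] <= 0).any():
        raise AllometryError("body lengths must be strictly positive")
    bad_sex = set(X["sex"]) - set(SEXES)
    if bad_sex:
        raise AllometryError(f"unknown sex level(s): {sorted(bad_sex)}")
    return X


class AllometricMassModel(RegressorMixin, BaseEstimator):
    """Log-log OLS allometry: ln(mass) ~ ln(length) + family + sex.

    Parameters
    ----------
    coefficients : dict or None
        Optional pre-specified model ``{"intercept": a, "slope": b,
        "family_offsets": {...}, "sex_offset": m, "resid_sd": s}`` (all on
        the natural-log mg scale; ``sex_offset`` is the male offset).  When
        given, the model is usable without calling :meth:`fit`.

    Attributes
    ----------
    intercept_, slope_ : float
    family_offsets_ : dict[str, float]
        Additive offsets per family; the reference family maps to 0.0.
    sex_offset_ : float
        Additive offset for males (females are the reference).
    resid_sd_ : float
        Residual standard deviation on the ln-mass scale.
    """

    def __init__(self, coefficients: dict | None = None):
        self.coefficients = coefficients
        if coefficients is not None:
            self._adopt(coefficients)

    def _adopt(self, c: dict) -> None:
        self.intercept_ = float(c["intercept"])
        self.slope_ = float(c["slope"])
        self.family_offsets_ = dict(c.get("family_offsets", {}))
        self.sex_offset_ = float(c.get("sex_offset", 0.0))
        self.resid_sd_ = float(c.get("resid_sd", float("nan")))

    def fit(self, X: pd.DataFrame, y) -> "AllometricMassModel":
        """Fit by OLS on ln(mass); *y* is dry mass in mg."""
        X = _check_frame(X)
        y = np.asarray(y, dtype=float)
        if (y <= 0).any():
            raise AllometryError("masses must be strictly positive")
        if len(y) != len(X):
            raise AllometryError("X and y length mismatch")
        families = sorted(set(X["family"]))
        ref = families[0]
        n, extra = len(X), families[1:]
        cols = {"intercept": np.ones(n), "ln_length": np.log(X["length_mm"].to_numpy(float))}
        for fam in extra:
            cols[f"family[{fam}]"] = (X["family"] == fam).to_numpy(float)
        cols["sex[male]"] = (X["sex"] == "male").to_numpy(float)
        D = np.column_stack(list(cols.values()))
        if len(np.unique(np.log(X["length_mm"].to_numpy(float)))) < 2:
            raise AllometryError("need at least 2 distinct lengths to fit")
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # drop an all-constant sex column when only one sex observed
            keep = [i for i, name in enumerate(cols)
                    if not (name == "sex[male]" and len(set(X["sex"])) == 1)]
            D = D[:, keep]
            names = [list(cols)[i] for i in keep]
            if np.linalg.matrix_rank(D) < D.shape[1]:
                raise AllometryError("rank-deficient design: no unique OLS solution")
        else:
            names = list(cols)
        beta, *_ = np.linalg.lstsq(D, np.log(y), rcond=None)
        coef = dict(zip(names, beta))
        self.intercept_ = float(coef["intercept"])
        self.slope_ = float(coef["ln_length"])
        self.family_offsets_ = {ref: 0.0}
        for fam in extra:
            self.family_offsets_[fam] = float(coef[f"family[{fam}]"])
        self.sex_offset_ = float(coef.get("sex[male]", 0.0))
        resid = np.log(y) - D @ beta
        dof = max(n - D.shape[1], 1)
        self.resid_sd_ = float(np.sqrt(resid @ resid / dof))
        self.n_obs_ = n
        self.reference_family_ = ref
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted dry mass (mg) per specimen row."""
        if not hasattr(self, "intercept_"):
            raise AllometryError("model is neither fitted nor given coefficients")
        X = _check_frame(X)
        unknown = set(X["family"]) - set(self.family_offsets_)
        if unknown:
            raise AllometryError(f"unknown family level(s): {sorted(unknown)}")
        fam_off = X["family"].map(self.family_offsets_).to_numpy(float)
        sex_off = np.where(X["sex"].to_numpy() == "male", self.sex_offset_, 0.0)
        ln_mass = (
            self.intercept_
            + self.slope_ * np.log(X["length_mm"].to_numpy(float))
            + fam_off
            + sex_off
        )
        return np.exp(ln_mass)


def predict_mass(measurements: pd.DataFrame, model: AllometricMassModel) -> pd.DataFrame:
    """Attach predicted dry mass (mg) to a specimen table."""
    out = measurements.copy()
    out["mass_mg"] = model.predict(measurements)
    return out


def species_mean_mass(predicted: pd.DataFrame, cap_per_sex: int = 10) -> pd.DataFrame:
    """Species-level mean dry mass over at most *cap_per_sex* specimens per sex.

    Specimens beyond the cap (in input order) are excluded, mirroring a
    measurement protocol of up to 10 females and 10 males per species.  The
    s.e. is across included specimens, NaN for a single specimen.
    """
    if "mass_mg" not in predicted.columns:
        raise AllometryError("expected a 'mass_mg' column; run predict_mass first")
    capped = (
        predicted.groupby(["species", "sex"], sort=False, group_keys=False)
        .head(cap_per_sex)
    )
    rows = []
    for sp, grp in capped.groupby("species", sort=True):
        m = grp["mass_mg"].to_numpy(float)
        se = float(np.std(m, ddof=1) / np.sqrt(len(m))) if len(m) > 1 else float("nan")
        rows.append(
            {"species": sp, "n_measured": len(m),
             "mass_mg_mean": float(m.mean()), "mass_mg_se": se}
        )
    return pd.DataFrame(rows)
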