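"""Beta regression of percent-spliced-in on structural and motif features.

PSI lives on [0, 1], so models are fit by maximum likelihood under a
Beta distribution in the mean-precision parameterization: PSI_i ~
Beta(mu_i * phi, (1 - mu_i) * phi) with logit(mu_i) = x_i' beta.  Seven
model formulas are supported:

======================  ====================================================
``structure``           PSI ~ Mean(X) + SD(X) + Skew(X) + Kurtosis(X)
``mfe``                 PSI ~ Y                  (MFE unfolding cost)
``splice_site``         PSI ~ SS
``sre``                 PSI ~ E + S + SS
``rbp``                 PSI ~ Ex + In
``interactive``         PSI ~ [structure block] * (isSynonymous+isIntronic)
                              + [E + S + SS] * isNonSynonymous
``additive``            PSI ~ [structure block] + [E + S + SS]
======================  ====================================================

where X is the ensemble of unfolding costs of the footprint region, E/S
are the enhancer/silencer aggregates, SS the donor-site strength change
and Ex/In the exclusion/inclusion RBP aggregates.  The interactive model
gates the structure block to synonymous/intronic variants and the motif
block to non-synonymous ones, exactly as written (products only, no
ungated main effects).

Exact-boundary observations (PSI of exactly 0 or 1) are moved to the
Smithson-Verkuilen images of the boundaries, 0.5/n and (n-0.5)/n, before
fitting; interior responses are untouched.  `BetaRegression` is a
scikit-learn estimator and composes with
sklearn model selection; `fit_beta_regression` / `predict_psi` /
`bootstrap_r2` are the functional surface over it.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

STRUCTURE_TERMS = ("mean_dg", "sd_dg", "skew_dg", "kurt_dg")
SRE_TERMS = ("enhancer", "silencer", "delta_ss")
FLAG_COLUMNS = ("is_non_synonymous", "is_synonymous", "is_intronic")

FORMULAS = ("structure", "mfe", "splice_site", "sre", "rbp",
            "interactive", "additive")


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimizer fails to converge."""


def design_matrix(X: pd.DataFrame, formula: str
                  ) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) and column names for a formula."""
    if formula not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}")
    cols: list[tuple[str, np.ndarray]] = []

    def col(name):
        if name not in X.columns:
            raise KeyError(f"feature {name!r} missing for formula "
                           f"{formula!r}")
        return X[name].to_numpy(float)

    if formula == "structure":
        cols = [(t, col(t)) for t in STRUCTURE_TERMS]
    elif formula == "mfe":
        cols = [("mfe_dg", col("mfe_dg"))]
    elif formula == "splice_site":
        cols = [("delta_ss", col("delta_ss"))]
    elif formula == "sre":
        cols = [(t, col(t)) for t in ("enhancer", "silencer", "delta_ss")]
    elif formula == "rbp":
        cols = [("rbp_ex", col("rbp_ex")), ("rbp_in", col("rbp_in"))]
    elif formula == "additive":
        cols = [(t, col(t)) for t in STRUCTURE_TERMS + SRE_TERMS]
    else:  # interactive
        gate_struct = col("is_synonymous") + col("is_intronic")
        gate_sre = col("is_non_synonymous")
        cols = [(f"{t}:syn_intronic", col(t) * gate_struct)
                for t in STRUCTURE_TERMS]
        cols += [(f"{t}:non_synonymous", col(t) * gate_sre)
                 for t in SRE_TERMS]
    names = ["intercept"] + [n for n, _ in cols]
    mat = np.column_stack([np.ones(len(X))] + [v for _, v in cols])
    return mat, names


def squeeze_boundaries(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Move exact-boundary responses inside (0, 1).

    Values of exactly 0 or 1 are replaced by the Smithson-Verkuilen
    images of the boundaries, 0.5/n and (n-0.5)/n; interior values are
    left untouched so the likelihood of well-behaved observations is
    exact.
    """
    y = np.asarray(y, float).copy()
    n = len(y) if n is None else n
    y[y <= 0.0] = 0.5 / n
    y[y >= 1.0] = (n - 0.5) / n
    return y


class BetaRegression(RegressorMixin, BaseEstimator):
    """Beta regression with logit mean link and constant precision.

    Parameters
    ----------
    formula : str
        One of the supported model formulas (see module docstring).
    squeeze : bool
        Apply the boundary squeeze before fitting (default True).

    Attributes
    ----------
    coef_ : ndarray
        Mean-model coefficients (intercept first) on the logit scale.
    coef_se_ : ndarray
        Asymptotic standard errors of ``coef_``.
    coef_names_ : list of str
    phi_ : float
        Precision of the Beta distribution.
    loglik_ : float
        Maximized log-likelihood.
    """

    def __init__(self, formula: str = "interactive", squeeze: bool = True):
        self.formula = formula
        self.squeeze = squeeze

    def fit(self, X: pd.DataFrame, y):
        from statsmodels.othermod.betareg import BetaModel

        X = pd.DataFrame(X)
        y = np.asarray(y, float)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("PSI values must lie in [0, 1]")
        mat, names = design_matrix(X, self.formula)
        if len(y) < mat.shape[1] + 2:
            raise ValueError(
                f"need at least {mat.shape[1] + 2} observations for "
                f"{self.formula!r}, got {len(y)}")
        y_fit = squeeze_boundaries(y) if self.squeeze else y
        if np.any((y_fit <= 0) | (y_fit >= 1)):
            raise ValueError("responses must be strictly inside (0,1); "
                             "enable squeeze for boundary PSIs")
        # drop constant (all-zero) predictors to keep the information
        # matrix invertible; their coefficients are reported as 0
        keep = [0] + [k for k in range(1, mat.shape[1])
                      if np.ptp(mat[:, k]) > 0]
        dropped = [names[k] for k in range(mat.shape[1]) if k not in keep]
        if dropped:
            warnings.warn("dropping constant predictors: "
                          + ", ".join(dropped), stacklevel=2)
        sub = mat[:, keep]
        model = BetaModel(y_fit, sub,
                          exog_precision=np.ones((len(y_fit), 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=500, disp=False)
            retvals = getattr(res, "mle_retvals", {}) or {}
            # Near-deterministic responses make the likelihood unbounded
            # in the precision; restart the simplex until the mean
            # coefficients stabilize even if the precision keeps climbing.
            stable = False
            for _ in range(4):
                if retvals.get("converged", True):
                    break
                prev = res.params.copy()
                res = model.fit(start_params=res.params, method="nm",
                                maxiter=5000, disp=False)
                retvals = getattr(res, "mle_retvals", {}) or {}
                k_mean = sub.shape[1]
                if np.max(np.abs(res.params[:k_mean]
                                 - prev[:k_mean])) < 1e-7:
                    stable = True
                    break
        if not retvals.get("converged", True):
            if stable:
                warnings.warn("precision unbounded (near-deterministic "
                              "response); mean coefficients converged",
                              stacklevel=2)
            else:
                raise ConvergenceError(
                    f"beta regression did not converge: {retvals}")
        k = sub.shape[1]
        coef = np.zeros(mat.shape[1])
        se = np.full(mat.shape[1], np.nan)
        coef[keep] = res.params[:k]
        se[keep] = res.bse[:k]
        self.coef_ = coef
        self.coef_se_ = se
        self.coef_names_ = names
        self.phi_ = float(np.exp(res.params[k]))
        self.loglik_ = float(res.llf)
        self.n_obs_ = len(y_fit)
        self._result = res
        return self

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        mat, names = design_matrix(pd.DataFrame(X), self.formula)
        if names != self.coef_names_:
            raise ValueError("feature columns do not match the fit")
        return mat @ self.coef_

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted PSI, strictly inside (0, 1)."""
        eta = self.linear_predictor(X)
        return expit(eta)

    def coefficients(self) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        return pd.DataFrame({"term": self.coef_names_, "coef": self.coef_,
                             "se": self.coef_se_})

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {"formula": self.formula,
                "coefficients": dict(zip(self.coef_names_, self.coef_)),
                "standard_errors": dict(zip(self.coef_names_,
                                            self.coef_se_)),
                "phi": self.phi_, "log_likelihood": self.loglik_,
                "n_obs": self.n_obs_}


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_beta_regression(panel: pd.DataFrame, formula: str
                        ) -> BetaRegression:
    """Fit one of the named formulas to a mutation panel.

    The panel must carry a ``psi`` column plus the features the formula
    needs.
    """
    est = BetaRegression(formula=formula)
    return est.fit(panel, panel["psi"].to_numpy(float))


def predict_psi(fit: BetaRegression, features) -> np.ndarray | float:
    """Predicted PSI for a feature row or table."""
    single = isinstance(features, (dict, pd.Series))
    df = pd.DataFrame([features] if single else features)
    out = fit.predict(df)
    return float(out[0]) if single else out


def _pearson_r2(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if np.std(y_true) < 1e-12 or np.std(y_pred) < 1e-12:
        return np.nan
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


def bootstrap_r2(panel: pd.DataFrame, formula: str,
                 fraction: float = 0.7, reps: int = 10,
                 seed: int = 0, held_out: bool = False) -> pd.DataFrame:
    """Subsample-without-replacement bootstrap of prediction accuracy.

    Each replicate samples ``ceil(fraction * n)`` rows without
    replacement, fits the formula and computes squared Pearson
    correlations between observed and predicted PSI on the training
    sample (or, with ``held_out=True``, on the remaining rows) overall
    and within each mutation category.  Categories with constant PSI in
    a replicate are reported as NaN.
    """
    rng = np.random.default_rng(seed)
    n = len(panel)
    size = int(np.ceil(fraction * n))
    rows = []
    for rep in range(reps):
        idx = rng.choice(n, size=size, replace=False)
        train = panel.iloc[idx]
        eval_set = panel.iloc[np.setdiff1d(np.arange(n), idx)] \
            if held_out else train
        fit = fit_beta_regression(train, formula)
        pred = fit.predict(eval_set)
        row = {"replicate": rep,
               "overall": _pearson_r2(eval_set["psi"], pred)}
        for cat, grp in eval_set.groupby("category"):
            row[str(cat)] = _pearson_r2(
                grp["psi"], fit.predict(grp))
        rows.append(row)
    return pd.DataFrame(rows)
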