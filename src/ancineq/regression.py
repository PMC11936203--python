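"""Weighted multivariable logistic regression and average marginal effects.

The fit is a maximum-likelihood binomial GLM with per-record weights entering
the log-likelihood (statsmodels ``freq_weights``), reported as adjusted odds
ratios with Wald 95% CIs.  Average marginal effects linearize the fit on the
probability scale for the concentration-index decomposition.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import variables as V


def build_design(
    records: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dummy-coded design matrix, first listed category as reference.

    Returns the design (columns named ``var=label``, no constant) and a map
    of variable name -> reference label.
    """
    cols: dict[str, np.ndarray] = {}
    reference: dict[str, str] = {}
    for var in variables:
        if var not in records.columns:
            raise KeyError(var)
        values = records[var].to_numpy()
        if np.isnan(np.asarray(values, dtype=float)).any():
            raise ValueError(f"{var}: missing values in design; filter first")
        labels = V.CATEGORIES[var]
        reference[var] = labels[0]
        for code, label in zip(V.codes(var)[1:], labels[1:]):
            cols[V.term_name(var, label)] = (values == code).astype(float)
    return pd.DataFrame(cols, index=records.index), reference


@dataclasses.dataclass
class LogitFit:
    """Fitted weighted logit with everything downstream stages need."""

    params: pd.Series  # log-odds, incl. "intercept"
    bse: pd.Series
    conf_int: pd.DataFrame  # columns low/high, log-odds scale
    loglik: float
    n_obs: int
    weighted_n: float
    reference: dict[str, str]
    fitted_p: np.ndarray
    design: pd.DataFrame  # without constant
    weights: np.ndarray
    y: np.ndarray

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    def odds_ratios(self) -> pd.DataFrame:
        """aOR table (exponentiated coefficients and CI bounds)."""
        out = pd.DataFrame(
            {
                "aOR": np.exp(self.params),
                "ci_low": np.exp(self.conf_int["low"]),
                "ci_high": np.exp(self.conf_int["high"]),
                "coef": self.params,
                "se": self.bse,
            }
        )
        return out.drop(index="intercept")


@dataclasses.dataclass
class MarginalEffects:
    """Average marginal effects, covariate means and outcome mean."""

    ame: pd.Series  # probability-scale effect per design column
    xbar: pd.Series  # weighted covariate means
    mu: float  # weighted outcome mean

    def __post_init__(self) -> None:
        if not (self.ame.abs() <= 1 + 1e-12).all():
            raise ValueError("marginal effects must lie in [-1, 1]")


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    # the MLE diverges whenever a dummy's 2x2 table with y has an empty cell
    for name in X.columns:
        on = X[name].to_numpy() == 1
        if on.any() and y[on].min() == y[on].max():
            raise ValueError(
                f"separation: category {name!r} perfectly predicts the outcome"
            )


def fit_weighted_logit(
    records: pd.DataFrame,
    variables: list[str],
    outcome: str = V.OUTCOME,
    weight: str = V.WEIGHT_POOLED,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogitFit:
    """Weighted ML logistic fit over dummy-coded categorical variables."""
    X, reference = build_design(records, variables)
    y = records[outcome].to_numpy(dtype=float)
    w = records[weight].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome has missing values; filter first")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary")
    _check_separation(X, y.astype(int))
    exog = sm.add_constant(X, prepend=True, has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=w)
    res = model.fit(tol=tol, maxiter=maxiter)
    if not res.converged:
        raise RuntimeError("weighted logit did not converge")
    names = ["intercept", *X.columns]
    params = pd.Series(res.params.to_numpy(), index=names)
    bse = pd.Series(res.bse.to_numpy(), index=names)
    ci = res.conf_int()
    conf = pd.DataFrame(
        {"low": ci.iloc[:, 0].to_numpy(), "high": ci.iloc[:, 1].to_numpy()},
        index=names,
    )
    return LogitFit(
        params=params,
        bse=bse,
        conf_int=conf,
        loglik=float(res.llf),
        n_obs=int(len(y)),
        weighted_n=float(w.sum()),
        reference=reference,
        fitted_p=np.asarray(res.fittedvalues, dtype=float),
        design=X,
        weights=w,
        y=y,
    )


def average_marginal_effects(fit: LogitFit) -> MarginalEffects:
    """AME per design column: beta_k x weighted mean of p(1-p).

    Also returns the weighted covariate means and the weighted outcome mean,
    all on the estimation sample.
    """
    w = fit.weights
    wsum = w.sum()
    scale = float((w * fit.fitted_p * (1 - fit.fitted_p)).sum() / wsum)
    betas = fit.params.drop("intercept")
    ame = betas * scale
    xbar = pd.Series(
        {c: float((w * fit.design[c].to_numpy()).sum() / wsum) for c in fit.design},
    )
    mu = float((w * fit.y).sum() / wsum)
    return MarginalEffects(ame=ame, xbar=xbar, mu=mu)


def predicted_probability_difference(
    fit: LogitFit, column: str
) -> float:
    """Finite-difference AME oracle: weighted mean of p(x=1) - p(x=0).

    Diagnostic alternative to the derivative-based AME for a single dummy.
    """
    X1 = fit.design.copy()
    X0 = fit.design.copy()
    X1[column] = 1.0
    X0[column] = 0.0
    beta = fit.params
    from scipy.special import expit

    lp1 = beta["intercept"] + X1.to_numpy() @ beta.drop("intercept").to_numpy()
    lp0 = beta["intercept"] + X0.to_numpy() @ beta.drop("intercept").to_numpy()
    w = fit.weights
    return float((w * (expit(lp1) - expit(lp0))).sum() / w.sum())
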