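"""Weighted prevalence estimates and Table-2-style cross-tabulations."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from . import variables as V


@dataclasses.dataclass
class PrevalenceEstimate:
    """Weighted percentage with a logit-Wald CI on the effective sample size."""

    stratum: str
    estimate: float  # percent
    ci_low: float
    ci_high: float
    weighted_n: float
    unweighted_n: int

    def __post_init__(self) -> None:
        if not np.isnan(self.estimate):
            if not (0 <= self.ci_low <= self.estimate <= self.ci_high <= 100):
                raise ValueError(
                    f"invalid interval for {self.stratum!r}: "
                    f"{self.ci_low} <= {self.estimate} <= {self.ci_high}"
                )


def _kish_neff(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / (w * w).sum())


def weighted_prevalence(
    y, w, stratum: str = "overall", alpha: float = 0.05
) -> PrevalenceEstimate:
    """Weighted prevalence (%) of a binary outcome with a 95% CI.

    CI: Wald interval on the logit scale with Kish effective sample size
    n_eff = (sum w)^2 / sum w^2, back-transformed.  Degenerate proportions
    (0 or 1) collapse to a point interval by convention.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    p = float((w * y).sum() / w.sum())
    neff = _kish_neff(w)
    if p in (0.0, 1.0):
        lo = hi = p
    else:
        se_logit = np.sqrt(1.0 / (neff * p * (1 - p)))
        z = norm.ppf(1 - alpha / 2)
        lo = float(expit(logit(p) - z * se_logit))
        hi = float(expit(logit(p) + z * se_logit))
    return PrevalenceEstimate(
        stratum=stratum,
        estimate=100 * p,
        ci_low=100 * lo,
        ci_high=100 * hi,
        weighted_n=float(w.sum()),
        unweighted_n=int(y.size),
    )


def crosstab(
    records: pd.DataFrame,
    factor: str,
    outcome: str = V.OUTCOME,
    weight: str = V.WEIGHT_POOLED,
) -> pd.DataFrame:
    """Per-category weighted prevalence plus level shares n (%).

    One row per category of ``factor`` in its documented order; empty levels
    are reported with zero n and a missing estimate.
    """
    if factor not in records.columns:
        raise KeyError(factor)
    y_all = records[outcome].to_numpy(dtype=float)
    w_all = records[weight].to_numpy(dtype=float)
    total_w = w_all.sum()
    level_codes = V.codes(factor) if factor in V.CATEGORIES else sorted(
        pd.unique(records[factor].dropna())
    )
    rows = []
    for code in level_codes:
        label = (
            V.label_of(factor, code) if factor in V.CATEGORIES else str(code)
        )
        mask = records[factor].to_numpy() == code
        if not mask.any():
            rows.append(
                {
                    "variable": factor,
                    "category": label,
                    "n": 0,
                    "share_pct": 0.0,
                    "prevalence_pct": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "weighted_n": 0.0,
                }
            )
            continue
        est = weighted_prevalence(y_all[mask], w_all[mask], stratum=label)
        rows.append(
            {
                "variable": factor,
                "category": label,
                "n": int(mask.sum()),
                "share_pct": 100 * w_all[mask].sum() / total_w,
                "prevalence_pct": est.estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "weighted_n": est.weighted_n,
            }
        )
    return pd.DataFrame(rows)


def descriptive_table(
    records: pd.DataFrame,
    factors: list[str] | None = None,
    outcome: str = V.OUTCOME,
    weight: str = V.WEIGHT_POOLED,
) -> pd.DataFrame:
    """Stacked cross-tabulation over the standard variable list."""
    if factors is None:
        factors = ["wealth_quintile", "education", *[
            v for v in V.COVARIATES if v not in ("wealth_quintile", "education")
        ]]
        factors = [f for f in dict.fromkeys(factors) if f in records.columns]
    parts = [crosstab(records, f, outcome=outcome, weight=weight) for f in factors]
    return pd.concat(parts, ignore_index=True)
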