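"""Weighted fractional ranks, concentration curves and concentration indices.

The concentration index is computed with the convenient-covariance formula

    C = 2 * cov_w(y, r) / mean_w(y)

where ``r`` is the weighted fractional (mid-)rank of the socio-economic
stratifier.  Positive C means the outcome is concentrated among the
higher-ranked (richer / more educated).  Standard errors come from the
convenient regression of ``2 * var_w(r) * y / mu`` on ``r`` with
heteroskedasticity-robust variance.

Tied stratifier values — the norm for quintile and education categories —
share a weighted mid-rank block, which makes the ranks deterministic and
invariant to input order.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import variables as V

#: optional rescalings of the standard index for a bounded (binary) outcome,
#: exposed as labelled diagnostics only — the headline index is uncorrected
BINARY_CORRECTIONS = ("wagstaff", "erreygers")


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float((w * x).sum() / w.sum())


def _wcov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Population-form weighted covariance."""
    xm = _wmean(x, w)
    ym = _wmean(y, w)
    return float((w * (x - xm) * (y - ym)).sum() / w.sum())


@dataclasses.dataclass
class RankedOutcome:
    """Records ranked by a stratifier: fractional ranks plus outcome/weights."""

    rank: np.ndarray  # r_i in (0, 1)
    y: np.ndarray
    w: np.ndarray
    stratifier: np.ndarray  # the ordinal values the ranks derive from
    name: str = "stratifier"

    def __post_init__(self) -> None:
        r, w = self.rank, self.w
        if (r <= 0).any() or (r >= 1).any():
            raise ValueError("fractional ranks must lie strictly in (0, 1)")
        if abs(_wmean(r, w) - 0.5) > 1e-9:
            raise ValueError("weighted mean fractional rank must equal 0.5")


def fractional_rank(
    stratifier,
    w,
    y=None,
    name: str = "stratifier",
) -> RankedOutcome:
    """Weighted fractional mid-ranks of an ordinal stratifier.

    Tied values form a block; every member receives
    ``(W_below + W_block / 2) / W``.  The result keeps the original record
    order, so ranks stay attached to their records.
    """
    s = np.asarray(stratifier, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if np.isnan(s).any():
        raise ValueError("stratifier has missing values")
    uniq, inverse = np.unique(s, return_inverse=True)
    if uniq.size < 2 and s.size > 1:
        raise ValueError(
            "constant stratifier: fractional rank (and any inequality "
            "measure over it) is undefined"
        )
    W = w.sum()
    block_w = np.bincount(inverse, weights=w)
    below = np.concatenate([[0.0], np.cumsum(block_w)[:-1]])
    mid = (below + 0.5 * block_w) / W
    rank = mid[inverse]
    yarr = None if y is None else np.asarray(y, dtype=float)
    if yarr is None:
        yarr = np.zeros_like(s)
    return RankedOutcome(rank=rank, y=yarr, w=w, stratifier=s, name=name)


@dataclasses.dataclass
class ConcentrationResult:
    """CIX with its uncertainty and the concentration-curve coordinates."""

    stratifier: str
    group: str  # "pooled" or a country id
    cix: float
    se: float
    p_value: float
    curve: pd.DataFrame  # columns: cum_pop_share, cum_outcome_share

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.cix <= 1 + 1e-9:
            raise ValueError(f"concentration index out of [-1, 1]: {self.cix}")

    def p_value_text(self, floor: float = 1e-4) -> str:
        """Rendered p-value with the conventional '< 0.0001' floor."""
        return "< 0.0001" if self.p_value < floor else f"{self.p_value:.4f}"


def concentration_index(ranked: RankedOutcome) -> float:
    """Convenient-covariance concentration index, C = 2 cov_w(y, r) / mu."""
    mu = _wmean(ranked.y, ranked.w)
    if mu <= 0:
        raise ValueError("outcome mean must be positive for a concentration index")
    return 2.0 * _wcov(ranked.y, ranked.rank, ranked.w) / mu


def corrected_index(ranked: RankedOutcome, kind: str) -> float:
    """Bounded-outcome rescalings of the standard index (diagnostic only)."""
    c = concentration_index(ranked)
    mu = _wmean(ranked.y, ranked.w)
    if kind == "wagstaff":
        if mu >= 1:
            raise ValueError("Wagstaff correction undefined at mu >= 1")
        return c / (1.0 - mu)
    if kind == "erreygers":
        return 4.0 * mu * c
    raise ValueError(f"unknown correction {kind!r}; choose from {BINARY_CORRECTIONS}")


def concentration_curve(ranked: RankedOutcome) -> pd.DataFrame:
    """Cumulative outcome share against cumulative population share.

    One point per stratifier block in ascending order, prepended with (0, 0).
    """
    total_y = (ranked.w * ranked.y).sum()
    if total_y <= 0:
        raise ValueError("zero weighted outcome total: curve undefined")
    _, inverse = np.unique(ranked.stratifier, return_inverse=True)
    W = ranked.w.sum()
    block_w = np.bincount(inverse, weights=ranked.w)
    block_y = np.bincount(inverse, weights=ranked.w * ranked.y)
    pop = np.concatenate([[0.0], np.cumsum(block_w) / W])
    out = np.concatenate([[0.0], np.cumsum(block_y) / total_y])
    return pd.DataFrame({"cum_pop_share": pop, "cum_outcome_share": out})


def cix_significance(ranked: RankedOutcome, robust: str = "HC1") -> tuple[float, float]:
    """Standard error and two-sided p-value for the concentration index.

    Convenient regression: WLS of ``2 var_w(r) * y / mu`` on the fractional
    rank with the record weights; the slope equals C exactly, and its
    heteroskedasticity-robust standard error provides the test against C=0.
    """
    n = ranked.y.size
    if n < 10:
        raise ValueError("need at least 10 records for a significance test")
    r, y, w = ranked.rank, ranked.y, ranked.w
    mu = _wmean(y, w)
    if mu <= 0:
        raise ValueError("outcome mean must be positive")
    var_r = _wcov(r, r, w)
    if var_r <= 0:
        raise ValueError("degenerate rank variance")
    lhs = 2.0 * var_r * y / mu
    X = np.column_stack([np.ones(n), r])
    XtWX = X.T @ (X * w[:, None])
    bread = np.linalg.inv(XtWX)
    beta = bread @ (X.T @ (w * lhs))
    resid = lhs - X @ beta
    score = X * (w * resid)[:, None]  # per-record estimating-equation score
    cov = bread @ (score.T @ score) @ bread
    if robust == "HC1":
        cov = cov * n / (n - X.shape[1])
    se = float(np.sqrt(cov[1, 1]))
    if se <= 0 or not np.isfinite(se):
        raise ValueError("degenerate variance in the convenient regression")
    z = beta[1] / se
    p = 2.0 * float(norm.sf(abs(z)))
    return se, p


def analyze(
    stratifier,
    y,
    w,
    name: str = "stratifier",
    group: str = "pooled",
) -> ConcentrationResult:
    """Rank, index, significance and curve in one step."""
    ranked = fractional_rank(stratifier, w, y=y, name=name)
    c = concentration_index(ranked)
    se, p = cix_significance(ranked)
    curve = concentration_curve(ranked)
    return ConcentrationResult(
        stratifier=name, group=group, cix=c, se=se, p_value=p, curve=curve
    )


def cix_by_group(
    records: pd.DataFrame,
    stratifier: str,
    outcome: str = V.OUTCOME,
    weight: str = V.WEIGHT_POOLED,
    group: str = V.COUNTRY,
) -> list[ConcentrationResult]:
    """Per-group concentration results (ranks recomputed within group),
    with the pooled result appended last."""
    results: list[ConcentrationResult] = []
    for gval, part in records.groupby(group, sort=True):
        y = part[outcome].to_numpy(dtype=float)
        w = part[weight].to_numpy(dtype=float)
        if (w * y).sum() <= 0:
            warnings.warn(f"group {gval!r} has zero outcome mass; skipped")
            continue
        try:
            results.append(
                analyze(part[stratifier].to_numpy(), y, w, name=stratifier,
                        group=str(gval))
            )
        except ValueError as exc:
            warnings.warn(f"group {gval!r} skipped: {exc}")
    results.append(
        analyze(
            records[stratifier].to_numpy(),
            records[outcome].to_numpy(dtype=float),
            records[weight].to_numpy(dtype=float),
            name=stratifier,
            group="pooled",
        )
    )
    return results
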