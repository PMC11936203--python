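"""Best-subset covariate selection by AIC and VIF multicollinearity screen."""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from . import variables as V
from .regression import build_design, fit_weighted_logit


@dataclasses.dataclass
class SelectionResult:
    candidates: list[tuple[str, ...]]
    aic: list[float]
    selected: tuple[str, ...]
    vif: pd.Series | None = None

    def __post_init__(self) -> None:
        best = min(self.aic)
        idx = self.candidates.index(self.selected)
        if self.aic[idx] > best + 1e-9:
            raise ValueError("selected group does not attain the minimum AIC")

    def vif_summary(self) -> dict[str, float]:
        if self.vif is None:
            raise ValueError("no VIF computed")
        return {
            "mean": float(self.vif.mean()),
            "min": float(self.vif.min()),
            "max": float(self.vif.max()),
        }

    def to_dict(self) -> dict:
        out = {
            "candidates": [list(c) for c in self.candidates],
            "aic": self.aic,
            "selected": list(self.selected),
        }
        if self.vif is not None:
            out["vif"] = {k: float(v) for k, v in self.vif.items()}
            out["vif_summary"] = self.vif_summary()
        return out


def all_subsets(
    variables: Sequence[str], max_size: int | None = None, cap: int = 4096
) -> list[tuple[str, ...]]:
    """Every non-empty subset up to ``max_size``, guarded by a count cap."""
    max_size = max_size or len(variables)
    subsets = []
    for k in range(1, max_size + 1):
        subsets.extend(itertools.combinations(variables, k))
        if len(subsets) > cap:
            raise ValueError(
                f"candidate count exceeds cap ({cap}); restrict max_size"
            )
    return subsets


def best_subset_aic(
    records: pd.DataFrame,
    candidates: Sequence[Sequence[str]],
    outcome: str = V.OUTCOME,
    weight: str = V.WEIGHT_POOLED,
) -> SelectionResult:
    """Fit each candidate variable group and pick the minimum-AIC group.

    All candidates must fit on the same estimation sample; rows missing any
    variable appearing in any candidate trigger an error so the caller runs
    the complete-case filter first.  Ties break toward the smaller group.
    """
    if not candidates:
        raise ValueError("no candidate groups")
    cand = [tuple(c) for c in candidates]
    involved = sorted({v for group in cand for v in group})
    missing = records[involved].isna().any()
    if missing.any():
        bad = list(missing[missing].index)
        raise ValueError(
            f"differential missingness in {bad}; apply complete-case "
            "filtering before selection so all candidates share one sample"
        )
    aics = []
    for group in cand:
        fit = fit_weighted_logit(records, list(group), outcome=outcome, weight=weight)
        aics.append(fit.aic)
    # ties toward the smaller group: sort by (AIC, group size, order)
    order = sorted(range(len(cand)), key=lambda i: (aics[i], len(cand[i]), i))
    best = cand[order[0]]
    fit = fit_weighted_logit(records, list(best), outcome=outcome, weight=weight)
    vifs = vif(fit.design, records[weight].to_numpy()) if fit.design.shape[1] >= 2 else None
    return SelectionResult(candidates=cand, aic=aics, selected=best, vif=vifs)


def vif(design: pd.DataFrame, weights: np.ndarray | None = None) -> pd.Series:
    """Variance inflation factor per design column.

    VIF_j = 1 / (1 - R^2_j) from the weighted least-squares regression of
    column j on the remaining columns plus a constant.  Perfectly collinear
    columns get ``inf``.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least 2 covariates for VIF")
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    if (X.std(axis=0) == 0).any():
        const = [c for c, s in zip(design.columns, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant design columns: {const}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        Z = np.column_stack([np.ones(n), others])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Z * sw[:, None], yj * sw, rcond=None)
        resid = yj - Z @ beta
        ybar = (w * yj).sum() / w.sum()
        sst = (w * (yj - ybar) ** 2).sum()
        sse = (w * resid**2).sum()
        r2 = 1.0 - sse / sst
        out[name] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    series = pd.Series(out)
    if np.isinf(series).any():
        collinear = list(series[np.isinf(series)].index)
        import warnings

        warnings.warn(f"perfect collinearity in columns: {collinear}")
    return series


def vif_for_variables(
    records: pd.DataFrame,
    variables: Sequence[str],
    weight: str = V.WEIGHT_POOLED,
) -> pd.Series:
    """VIF on the dummy-coded design of the given categorical variables."""
    design, _ = build_design(records, list(variables))
    return vif(design, records[weight].to_numpy())
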