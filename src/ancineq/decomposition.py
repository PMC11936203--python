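"""Decomposition of the concentration index into covariate contributions.

Each non-reference covariate category contributes

    a_k = eta_k * C_k,   eta_k = beta_k^m * xbar_k / mu

where ``beta_k^m`` is the average marginal effect of the category dummy,
``xbar_k`` its weighted mean, ``mu`` the weighted outcome mean and ``C_k``
the category's concentration index over the SAME fractional ranks as the
outcome index.  The residual is defined by closure,
``C_total - sum_k a_k``, so the additive identity holds exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inequality import RankedOutcome, _wcov, _wmean, concentration_index
from .regression import MarginalEffects


def elasticity(beta_m: float, xbar: float, mu: float) -> float:
    """eta_k = beta_k^m * xbar_k / mu."""
    if mu <= 0:
        raise ValueError("outcome mean must be positive")
    return beta_m * xbar / mu


def covariate_cix(x, ranked: RankedOutcome) -> float:
    """Concentration index of a covariate over the outcome's ranks.

    C_k = 2 cov_w(x_k, r) / xbar_k, using the same ranks (and weights) as
    the outcome concentration index.
    """
    x = np.asarray(x, dtype=float)
    xbar = _wmean(x, ranked.w)
    if xbar <= 0:
        raise ValueError("empty covariate category: concentration index undefined")
    return 2.0 * _wcov(x, ranked.rank, ranked.w) / xbar


@dataclasses.dataclass
class DecompositionRow:
    variable: str
    category: str
    elasticity: float
    cix: float
    absolute: float
    percentage: float | None  # None when C_total == 0

    def __post_init__(self) -> None:
        expected = self.elasticity * self.cix
        if abs(self.absolute - expected) > 1e-12:
            raise ValueError("absolute contribution must equal elasticity x CIX")


@dataclasses.dataclass
class DecompositionTable:
    stratifier: str
    rows: list[DecompositionRow]
    c_total: float
    residual: float

    def __post_init__(self) -> None:
        closure = sum(r.absolute for r in self.rows) + self.residual
        if abs(closure - self.c_total) > 1e-12:
            raise ValueError("decomposition does not close to the total index")

    @property
    def residual_percentage(self) -> float | None:
        if self.c_total == 0:
            return None
        return 100.0 * self.residual / self.c_total

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "category": r.category,
                    "elasticity": r.elasticity,
                    "concentration_index": r.cix,
                    "absolute_contribution": r.absolute,
                    "percentage_contribution": r.percentage,
                }
                for r in self.rows
            ]
        )
        return frame

    def percentages(self) -> dict[str, float]:
        """Row label -> percentage contribution (for aggregation)."""
        if self.c_total == 0:
            raise ValueError("percentages undefined when the total index is zero")
        return {f"{r.variable}={r.category}": r.percentage for r in self.rows}


def decompose(
    effects: MarginalEffects,
    ranked: RankedOutcome,
    design: pd.DataFrame,
    stratifier: str = "stratifier",
) -> DecompositionTable:
    """Per-category contributions to the outcome concentration index.

    ``design`` must be the dummy design of the fitted model on the SAME
    records (and order) as ``ranked``.
    """
    if len(design) != ranked.y.size:
        raise ValueError("estimation sample and ranking sample differ in size")
    c_total = concentration_index(ranked)
    if c_total == 0:
        warnings.warn(
            "total concentration index is zero: percentage contributions "
            "are undefined; reporting absolute contributions only"
        )
    rows: list[DecompositionRow] = []
    for name in effects.ame.index:
        var, _, category = name.partition("=")
        eta = elasticity(float(effects.ame[name]), float(effects.xbar[name]),
                         effects.mu)
        ck = covariate_cix(design[name].to_numpy(), ranked)
        a = eta * ck
        pct = None if c_total == 0 else 100.0 * a / c_total
        rows.append(
            DecompositionRow(
                variable=var, category=category, elasticity=eta, cix=ck,
                absolute=a, percentage=pct,
            )
        )
    residual = c_total - sum(r.absolute for r in rows)
    return DecompositionTable(
        stratifier=stratifier, rows=rows, c_total=c_total, residual=residual
    )


def residual_error_index(
    effects: MarginalEffects, ranked: RankedOutcome, design: pd.DataFrame
) -> float:
    """Generalized concentration index of the linearized-model error.

    Diagnostic alternative to the closure residual: under an exactly linear
    model the two coincide.
    """
    lp = effects.mu + (
        (design.to_numpy() - effects.xbar.to_numpy()[None, :])
        @ effects.ame.to_numpy()
    )
    eps = ranked.y - lp
    return 2.0 * _wcov(eps, ranked.rank, ranked.w) / effects.mu


def aggregate_contributions(
    percentages: Mapping[str, float] | DecompositionTable,
    grouping: Mapping[str, Sequence[str]],
    rounding: str | None = None,
) -> dict[str, float]:
    """Sum percentage contributions over named groups of row labels.

    ``grouping`` maps a group name to the row labels it covers; a label may
    appear in at most one group.  ``rounding`` is ``None`` (exact), ``"2dp"``
    or ``"int"``.
    """
    if isinstance(percentages, DecompositionTable):
        percentages = percentages.percentages()
    seen: set[str] = set()
    for name, labels in grouping.items():
        for lab in labels:
            if lab in seen:
                raise ValueError(f"category {lab!r} referenced twice in grouping")
            seen.add(lab)
            if lab not in percentages:
                raise KeyError(f"unknown row label {lab!r} in group {name!r}")
    out: dict[str, float] = {}
    for name, labels in grouping.items():
        total = float(sum(percentages[lab] for lab in labels))
        if rounding == "2dp":
            total = round(total, 2)
        elif rounding == "int":
            total = float(round(total))
        elif rounding is not None:
            raise ValueError(f"unknown rounding mode {rounding!r}")
        out[name] = total
    return out
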