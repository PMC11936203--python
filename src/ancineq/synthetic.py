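"""Synthetic multi-country survey generator with known ground truth.

Every record is one woman (one household).  A latent standard-normal
affluence scalar per household drives binary asset indicators, the ordinal
education draw (proportional odds) and, optionally, a handful of binary
covariates; the first principal component of the asset table is cut into
weighted quintiles to give the wealth index.  The binary outcome is drawn
from a logistic model over the categorical covariates, with the intercept
calibratable by bisection to hit a target weighted prevalence.

Each stage consumes its own reproducible stream derived from the master seed
by a fixed sub-seed offset, so a stage rerun with the same spec is
bit-reproducible regardless of what ran before it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import variables as V

_STAGE_OFFSET = {
    "assets": 11,
    "weights": 23,
    "education": 37,
    "covariates": 41,
    "outcome": 53,
    "visits": 67,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE_OFFSET[stage]])


# default category distributions for covariates not driven by the wealth model
# (shares sum to 1 within each variable)
DEFAULT_CATEGORY_PROBS: dict[str, list[float]] = {
    "age_group": [0.076, 0.213, 0.252, 0.205, 0.155, 0.074, 0.025],
    "employed": [0.368, 0.632],
    "marital_status": [0.082, 0.719, 0.140, 0.011, 0.019, 0.029],
    "parity": [0.216, 0.487, 0.297],
    "insurance": [0.890, 0.110],
    "media_tv": [0.551, 0.449],
    "media_radio": [0.475, 0.525],
    "media_newspaper": [0.883, 0.117],
    "media_internet": [0.810, 0.190],
    "barrier_permission": [0.797, 0.203],
    "barrier_distance": [0.638, 0.362],
    "barrier_money": [0.459, 0.541],
    "barrier_alone": [0.784, 0.216],
    "head_female": [0.809, 0.191],
    "rural": [0.395, 0.605],
}

# marginal education shares at affluence = 0; turned into proportional-odds
# cutpoints inside simulate_women
DEFAULT_EDUCATION_PROBS = [0.42, 0.174, 0.082, 0.205, 0.072, 0.047]

# log-odds shift of "1" per SD of affluence, for binary covariates tied to
# household affluence (rural residence is poorer, media access richer)
DEFAULT_AFFLUENCE_LOADS: dict[str, float] = {
    "rural": -1.0,
    "media_tv": 0.9,
    "media_internet": 0.9,
    "media_newspaper": 0.5,
    "barrier_money": -0.5,
    "barrier_distance": -0.5,
}


def default_outcome_coefs() -> dict[str, float]:
    """Log-odds coefficients for every non-reference category (reference = 0).

    Positive gradients over wealth and education; modest effects elsewhere.
    """
    coefs: dict[str, float] = {"intercept": -3.0}
    gradients = {
        "wealth_quintile": [0.25, 0.50, 0.80, 1.10],
        "education": [0.10, 0.35, 0.60, 1.30, 1.80],
        "age_group": [0.25, 0.45, 0.55, 0.55, 0.45, 0.10],
        "employed": [0.50],
        "marital_status": [-0.05, -0.05, 0.10, -0.60, -0.25],
        "parity": [0.00, -0.35],
        "insurance": [-0.70],
        "media_tv": [0.10],
        "media_radio": [0.05],
        "media_newspaper": [-0.15],
        "media_internet": [0.10],
        "barrier_permission": [-0.10],
        "barrier_distance": [-0.20],
        "barrier_money": [-0.10],
        "barrier_alone": [-0.05],
        "head_female": [0.05],
        "rural": [-0.50],
    }
    for var, betas in gradients.items():
        for label, beta in zip(V.CATEGORIES[var][1:], betas):
            coefs[V.term_name(var, label)] = beta
    return coefs


@dataclasses.dataclass(frozen=True)
class CountrySpec:
    """One simulated survey: sample size and female-population total."""

    country: str
    n_women: int
    total_population: int

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError(f"{self.country}: n_women must be >= 1")
        if self.total_population < self.n_women:
            raise ValueError(f"{self.country}: total_population < n_women")


@dataclasses.dataclass
class PopulationSpec:
    countries: list[CountrySpec]
    outcome_coefs: dict[str, float] = dataclasses.field(
        default_factory=default_outcome_coefs
    )
    n_assets: int = 10
    asset_load: float | Sequence[float] = 1.0
    edu_gradient: float = 1.1
    weight_dispersion: float = 0.3
    category_probs: dict[str, list[float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    education_probs: list[float] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_EDUCATION_PROBS)
    )
    affluence_loads: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_AFFLUENCE_LOADS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.countries:
            raise ValueError("at least one country required")
        if self.n_assets < 2:
            raise ValueError("n_assets must be >= 2")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        loads = np.asarray(self.asset_loads())
        if np.all(loads == 0):
            raise ValueError(
                "asset_load is identically zero: assets carry no affluence "
                "signal and the wealth index would be uninformative"
            )
        if not (0 <= loads).all() or not (loads <= 1).all():
            raise ValueError("asset loadings must lie in [0, 1]")

    def asset_loads(self) -> np.ndarray:
        """Per-asset loadings broadcast to length ``n_assets``."""
        loads = np.broadcast_to(
            np.asarray(self.asset_load, dtype=float), (self.n_assets,)
        )
        return np.array(loads)

    @property
    def n_total(self) -> int:
        return sum(c.n_women for c in self.countries)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["countries"] = [dataclasses.asdict(c) for c in self.countries]
        if isinstance(d["asset_load"], np.ndarray):
            d["asset_load"] = d["asset_load"].tolist()
        return d


@dataclasses.dataclass
class AssetMatrix:
    """Binary household x asset table plus the generating latent affluence."""

    assets: pd.DataFrame  # int8, columns asset_00..; index = household_id
    affluence: np.ndarray  # ground truth, same order as rows
    country: np.ndarray  # per-household country code

    def __post_init__(self) -> None:
        vals = self.assets.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("asset entries must be 0/1")


@dataclasses.dataclass
class SyntheticSurvey:
    """Woman-level records plus generator ground truth."""

    women: pd.DataFrame
    affluence: np.ndarray
    spec: PopulationSpec


def simulate_assets(spec: PopulationSpec) -> AssetMatrix:
    """Draw the binary asset table from the latent-affluence model.

    Asset j of a household with affluence ``a`` is Bernoulli with probability
    ``expit(4 * load_j * a + offset_j)``; offsets are spread over [-1, 1] so
    asset prevalences differ.
    """
    rng = _rng(spec.seed, "assets")
    n = spec.n_total
    affluence = rng.standard_normal(n)
    loads = spec.asset_loads()
    offsets = np.linspace(-1.0, 1.0, spec.n_assets)
    # scale 4 keeps single assets informative without saturating
    probs = expit(4.0 * affluence[:, None] * loads[None, :] + offsets[None, :])
    mat = (rng.random((n, spec.n_assets)) < probs).astype(np.int8)
    country = np.concatenate(
        [np.repeat(c.country, c.n_women) for c in spec.countries]
    )
    frame = pd.DataFrame(
        mat,
        columns=[f"asset_{j:02d}" for j in range(spec.n_assets)],
        index=pd.RangeIndex(n, name="household_id"),
    )
    return AssetMatrix(assets=frame, affluence=affluence, country=country)


def score_wealth_pca(
    assets: AssetMatrix | pd.DataFrame, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """First-principal-component wealth score and weighted quintile labels.

    Returns ``(score, quintile)`` where quintile codes are 1 (poorest) to
    5 (richest).  The score sign is oriented so that it correlates positively
    with the household asset count.  The quintile split is a weighted
    five-way cut of the score distribution.
    """
    table = assets.assets if isinstance(assets, AssetMatrix) else assets
    X = np.asarray(table, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 households to form quintiles")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all asset columns are constant; PCA score undefined")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # first right-singular vector of the standardized table = leading PC
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = Z @ vt[0]
    if np.corrcoef(score, X.sum(axis=1))[0, 1] < 0:
        score = -score

    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    # weighted mid-rank per tied score block, so ties share a quintile and
    # the assignment is deterministic and order-invariant
    _, inverse = np.unique(score, return_inverse=True)
    block_w = np.bincount(inverse, weights=w)
    below = np.concatenate([[0.0], np.cumsum(block_w)[:-1]])
    mid = (below + 0.5 * block_w) / w.sum()
    frac = mid[inverse]
    # blocks sitting exactly on a cut go toward the middle quintile, which
    # keeps the assignment symmetric under score negation
    quintile = (
        1
        + (frac >= 0.2).astype(np.int64)
        + (frac >= 0.4).astype(np.int64)
        + (frac > 0.6).astype(np.int64)
        + (frac > 0.8).astype(np.int64)
    )
    return score, quintile


def _draw_categorical(rng: np.random.Generator, probs: Sequence[float], n: int,
                      one_based: bool) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    draw = rng.choice(len(p), size=n, p=p)
    return draw + 1 if one_based else draw


def simulate_women(spec: PopulationSpec) -> SyntheticSurvey:
    """One record per woman: weight, wealth quintile, education, covariates."""
    assets = simulate_assets(spec)
    a = assets.affluence
    n = spec.n_total
    _, quintile = score_wealth_pca(assets)

    rng_w = _rng(spec.seed, "weights")
    cv = spec.weight_dispersion
    if cv == 0:
        raw = np.ones(n)
    else:
        sigma2 = np.log1p(cv * cv)
        raw = rng_w.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    v005 = np.maximum(np.rint(raw * 1_000_000).astype(np.int64), 1)

    rng_e = _rng(spec.seed, "education")
    cum = np.cumsum(spec.education_probs)[:-1]
    cutpoints = logit(np.clip(cum, 1e-12, 1 - 1e-12))
    # proportional odds: P(edu <= j | a) = expit(c_j - g * a)
    cdf = expit(cutpoints[None, :] - spec.edu_gradient * a[:, None])
    u = rng_e.random(n)
    education = 1 + (u[:, None] > cdf).sum(axis=1)

    rng_c = _rng(spec.seed, "covariates")
    cols: dict[str, np.ndarray] = {}
    for var in V.COVARIATES:
        if var in ("wealth_quintile", "education"):
            continue
        probs = spec.category_probs[var]
        load = spec.affluence_loads.get(var, 0.0)
        if load != 0.0 and len(probs) == 2:
            p1 = expit(logit(np.clip(probs[1], 1e-9, 1 - 1e-9)) + load * a)
            cols[var] = (rng_c.random(n) < p1).astype(np.int64)
        else:
            cols[var] = _draw_categorical(rng_c, probs, n, var in V.ONE_BASED)

    women = pd.DataFrame(
        {
            V.COUNTRY: assets.country,
            V.WEIGHT_RAW: v005,
            "wealth_quintile": quintile,
            "education": education,
            **cols,
            V.ELIGIBLE: np.ones(n, dtype=np.int64),
        }
    )
    return SyntheticSurvey(women=women, affluence=a, spec=spec)


def _linear_predictor(women: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    lp = np.full(len(women), float(coefs.get("intercept", 0.0)))
    for var in V.COVARIATES:
        col = women[var].to_numpy()
        for code, label in zip(V.codes(var), V.CATEGORIES[var]):
            if label == V.CATEGORIES[var][0]:
                continue  # reference level
            mask = col == code
            if not mask.any():
                continue
            key = V.term_name(var, label)
            if key not in coefs:
                raise ValueError(f"no outcome coefficient for observed category {key!r}")
            lp[mask] += coefs[key]
    return lp


def simulate_outcome(survey: SyntheticSurvey,
                     spec: PopulationSpec | None = None) -> SyntheticSurvey:
    """Attach the binary outcome and a consistent integer visit count."""
    spec = spec or survey.spec
    women = survey.women.copy()
    lp = _linear_predictor(women, spec.outcome_coefs)
    p = expit(lp)
    rng_o = _rng(spec.seed, "outcome")
    y = (rng_o.random(len(women)) < p).astype(np.int64)
    rng_v = _rng(spec.seed, "visits")
    # visit count only needs to respect the 8+ dichotomy
    visits = np.where(
        y == 1,
        rng_v.integers(8, 13, size=len(women)),
        rng_v.integers(0, 8, size=len(women)),
    )
    women[V.OUTCOME] = y
    women[V.VISITS] = visits
    return SyntheticSurvey(women=women, affluence=survey.affluence, spec=spec)


def pooled_weights_of(spec: PopulationSpec, women: pd.DataFrame) -> np.ndarray:
    """De-normalized pooled weight implied by the spec's country populations."""
    factor = {
        c.country: c.total_population / c.n_women for c in spec.countries
    }
    pw = women[V.WEIGHT_RAW].to_numpy() / 1_000_000
    return pw * women[V.COUNTRY].map(factor).to_numpy()


def calibrate_intercept(
    spec: PopulationSpec, target: float = 0.09, tol: float = 1e-6
) -> float:
    """Bisect the intercept so pooled weighted prevalence hits ``target``.

    Uses the spec's own seeded pilot simulation; deterministic for a given
    spec.  Only the intercept is varied — covariate draws are unaffected.
    """
    if not 0 < target < 1:
        raise ValueError("target prevalence must be in (0, 1)")
    survey = simulate_women(spec)
    coefs = dict(spec.outcome_coefs)
    coefs["intercept"] = 0.0
    lp = _linear_predictor(survey.women, coefs)
    w = pooled_weights_of(spec, survey.women)
    w = w / w.sum()

    def prev(b0: float) -> float:
        return float(w @ expit(b0 + lp))

    lo, hi = -30.0, 30.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_spec(
    seed: int = 0,
    n_per_country: int = 2500,
    target_prevalence: float | None = 0.09,
) -> PopulationSpec:
    """Four-country default spec; intercept calibrated to the target prevalence."""
    countries = [
        CountrySpec("AA", n_per_country, n_per_country * 400),
        CountrySpec("BB", n_per_country, n_per_country * 250),
        CountrySpec("CC", n_per_country, n_per_country * 150),
        CountrySpec("DD", n_per_country, n_per_country * 600),
    ]
    spec = PopulationSpec(countries=countries, seed=seed)
    if target_prevalence is not None:
        spec.outcome_coefs["intercept"] = calibrate_intercept(
            spec, target=target_prevalence
        )
    return spec


def write_fixture(survey: SyntheticSurvey, outdir: str | Path) -> dict[str, Path]:
    """Write the survey CSV plus a ground-truth JSON; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "women.csv"
    truth_path = outdir / "truth.json"
    survey.women.to_csv(csv_path, index=False, lineterminator="\n")
    truth = {
        "spec": survey.spec.to_dict(),
        "n_records": int(len(survey.women)),
    }
    if V.OUTCOME in survey.women:
        w = pooled_weights_of(survey.spec, survey.women)
        y = survey.women[V.OUTCOME].to_numpy()
        truth["weighted_prevalence"] = float((w * y).sum() / w.sum())
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"women": csv_path, "truth": truth_path}
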