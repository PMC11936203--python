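"""Survey ingestion: recoding, weight derivation/de-normalization, pooling.

Records live in a pandas DataFrame with the integer-coded schema of
:mod:`ancineq.variables`; missing values are NaN.  Raw per-woman weights are
``v005``-style (scaled by 1e6); pooled weights rescale each country by its
female-population / sample ratio so multi-country estimates reflect
population sizes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import variables as V

WEIGHT_SCALE = 1_000_000

#: visit-count codes treated as "don't know" on read
DONT_KNOW_VISITS = (98, 99)


@dataclasses.dataclass(frozen=True)
class CountryMeta:
    """Survey metadata needed to de-normalize weights for pooling."""

    country: str
    total_population: int  # women aged 15-49 at survey time
    sample_n: int | None = None  # eligible women; inferred from data if None


@dataclasses.dataclass
class PooledDataset:
    """Appended multi-country records with de-normalized pooled weights."""

    records: pd.DataFrame  # includes WEIGHT_POOLED column
    meta: dict[str, CountryMeta]

    def __post_init__(self) -> None:
        w = self.records[V.WEIGHT_POOLED]
        if (w <= 0).any():
            raise ValueError("pooled weights must all be positive")

    @property
    def weights(self) -> np.ndarray:
        return self.records[V.WEIGHT_POOLED].to_numpy()

    def country_shares(self) -> pd.Series:
        """Weighted share (%) of each country in the pooled population."""
        by = self.records.groupby(V.COUNTRY)[V.WEIGHT_POOLED].sum()
        return 100 * by / by.sum()


def recode_anc(anc_visits):
    """Dichotomize visit counts: 1 iff >= 8 visits; NaN propagates.

    Accepts a scalar or an array/Series; rejects negative or fractional
    counts.
    """
    arr = np.asarray(anc_visits, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if (vals < 0).any():
        raise ValueError("visit counts must be non-negative")
    if not np.equal(np.mod(vals, 1), 0).all():
        raise ValueError("visit counts must be integers")
    out = np.where(arr >= 8, 1.0, 0.0)
    out[~finite] = np.nan
    if np.isscalar(anc_visits) or np.ndim(anc_visits) == 0:
        return float(out) if np.isfinite(out) else np.nan
    if isinstance(anc_visits, pd.Series):
        return pd.Series(out, index=anc_visits.index, name=V.OUTCOME)
    return out


def derive_weight(v005):
    """Per-woman weight from the raw v005-style variable: v005 / 1e6."""
    arr = np.asarray(v005, dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("v005 must be positive and finite (invalid sampling weight)")
    out = arr / WEIGHT_SCALE
    return float(out) if np.ndim(v005) == 0 else out


def denormalize_weight(pw, total_pop: float, sample_n: float):
    """Pooled weight: per-woman weight x (population / eligible sample)."""
    if sample_n < 1:
        raise ValueError("sample_n must be >= 1")
    if total_pop < sample_n:
        raise ValueError("total_pop must be >= sample_n")
    arr = np.asarray(pw, dtype=float)
    if (arr <= 0).any():
        raise ValueError("per-woman weights must be positive")
    out = arr * (float(total_pop) / float(sample_n))
    return float(out) if np.ndim(pw) == 0 else out


def filter_eligible(
    records: pd.DataFrame,
    required: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Complete-case filter plus the recent-birth eligibility flag.

    Returns the retained rows and a per-variable exclusion count log (a row
    missing several variables is counted once per variable; the
    ``recent_birth`` key counts rows dropped by the eligibility flag).
    """
    if required is None:
        required = [V.OUTCOME, "wealth_quintile", "education", *V.COVARIATES]
        required = [c for c in dict.fromkeys(required) if c in records.columns]
    log: dict[str, int] = {}
    mask = pd.Series(True, index=records.index)
    if V.ELIGIBLE in records.columns:
        ok = records[V.ELIGIBLE] == 1
        log[V.ELIGIBLE] = int((~ok).sum())
        mask &= ok
    for col in required:
        missing = records[col].isna()
        log[col] = int((missing & mask).sum())
        mask &= ~missing
    kept = records.loc[mask].copy()
    if kept.empty:
        raise ValueError("no records remain after eligibility filtering")
    return kept, log


def _check_schemas(surveys: Iterable[pd.DataFrame]) -> list[str]:
    frames = list(surveys)
    cols = [tuple(sorted(f.columns)) for f in frames]
    if len(set(cols)) > 1:
        raise ValueError(f"schemas differ across countries: {sorted(set(cols))}")
    mismatches = []
    for var in V.CATEGORIES:
        allowed = set(V.codes(var))
        for f in frames:
            if var not in f.columns:
                continue
            seen = set(pd.unique(f[var].dropna()))
            bad = seen - allowed
            if bad:
                mismatches.append(f"{var}: unexpected codes {sorted(bad)}")
    if mismatches:
        raise ValueError("conflicting category codings: " + "; ".join(mismatches))
    return [str(c) for c in frames[0].columns] if frames else []


def pool_surveys(
    surveys: Mapping[str, pd.DataFrame],
    meta: Mapping[str, CountryMeta],
) -> PooledDataset:
    """Append country surveys and attach de-normalized pooled weights."""
    if not surveys:
        raise ValueError("no surveys to pool")
    missing_meta = set(surveys) - set(meta)
    if missing_meta:
        raise ValueError(f"missing country metadata for: {sorted(missing_meta)}")
    _check_schemas(surveys.values())
    parts = []
    resolved: dict[str, CountryMeta] = {}
    for country, frame in surveys.items():
        m = meta[country]
        sample_n = m.sample_n if m.sample_n is not None else len(frame)
        resolved[country] = CountryMeta(country, m.total_population, sample_n)
        part = frame.copy()
        part[V.COUNTRY] = country
        pw = derive_weight(part[V.WEIGHT_RAW].to_numpy())
        part[V.WEIGHT_POOLED] = denormalize_weight(pw, m.total_population, sample_n)
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    return PooledDataset(records=pooled, meta=resolved)


# ---------------------------------------------------------------------------
# I/O

def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV, mapping don't-know visit codes to missing."""
    frame = pd.read_csv(path)
    if V.VISITS in frame.columns:
        frame[V.VISITS] = frame[V.VISITS].replace(list(DONT_KNOW_VISITS), np.nan)
    if V.OUTCOME not in frame.columns and V.VISITS in frame.columns:
        frame[V.OUTCOME] = recode_anc(frame[V.VISITS])
    return frame


def read_survey_stata(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a Stata-format recode file, renaming columns to the schema."""
    frame = pd.read_stata(path, convert_categoricals=False)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    if V.VISITS in frame.columns:
        frame[V.VISITS] = frame[V.VISITS].replace(list(DONT_KNOW_VISITS), np.nan)
    if V.OUTCOME not in frame.columns and V.VISITS in frame.columns:
        frame[V.OUTCOME] = recode_anc(frame[V.VISITS])
    return frame


def write_pooled_csv(pooled: PooledDataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pooled.records.to_csv(path, index=False, lineterminator="\n")
    return path


def read_pooled_csv(
    path: str | Path, meta: Mapping[str, CountryMeta] | None = None
) -> PooledDataset:
    frame = pd.read_csv(path)
    if V.WEIGHT_POOLED not in frame.columns:
        raise ValueError(f"{path}: not a pooled file (missing {V.WEIGHT_POOLED})")
    if meta is None:
        meta = {
            c: CountryMeta(c, total_population=int(g[V.WEIGHT_POOLED].sum()),
                           sample_n=len(g))
            for c, g in frame.groupby(V.COUNTRY)
        }
    return PooledDataset(records=frame, meta=dict(meta))
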