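"""Category metadata shared across the pipeline.

Every categorical variable is stored as an integer code column.  Ordered
multi-level variables (wealth quintile, education, age band, marital status,
parity) are coded 1..k in the order listed here; binary indicators are coded
0/1.  The first listed category of each variable is the reference level for
dummy coding, and the listed order of ``wealth_quintile`` (poorest -> richest)
and ``education`` (no education -> higher) is the ranking order used by the
inequality stage, so do not reorder these lists.
"""

from __future__ import annotations

# variable name -> ordered category labels (first = reference level)
CATEGORIES: dict[str, list[str]] = {
    "wealth_quintile": ["poorest", "poorer", "middle", "richer", "richest"],
    "education": [
        "no education",
        "incomplete primary",
        "complete primary",
        "incomplete secondary",
        "complete secondary",
        "higher",
    ],
    "age_group": ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"],
    "employed": ["no", "yes"],
    "marital_status": [
        "never in union",
        "married",
        "cohabiting",
        "widowed",
        "divorced",
        "separated",
    ],
    "parity": ["one", "two-four", "five or more"],
    "insurance": ["no", "yes"],
    "media_tv": ["no", "yes"],
    "media_radio": ["no", "yes"],
    "media_newspaper": ["no", "yes"],
    "media_internet": ["no", "yes"],
    "barrier_permission": ["not a big problem", "big problem"],
    "barrier_distance": ["not a big problem", "big problem"],
    "barrier_money": ["not a big problem", "big problem"],
    "barrier_alone": ["not a big problem", "big problem"],
    "head_female": ["male", "female"],
    "rural": ["urban", "rural"],
}

#: variables coded 1..k (ordered); everything else in CATEGORIES is 0/1
ONE_BASED = {"wealth_quintile", "education", "age_group", "marital_status", "parity"}

#: covariates of the regression stage, in reporting order
COVARIATES: list[str] = [
    "age_group",
    "education",
    "employed",
    "marital_status",
    "parity",
    "insurance",
    "media_tv",
    "media_radio",
    "media_newspaper",
    "media_internet",
    "barrier_permission",
    "barrier_distance",
    "barrier_money",
    "barrier_alone",
    "head_female",
    "wealth_quintile",
    "rural",
]

#: the two inequality stratifiers, each an ordered code column
STRATIFIERS = {"wealth": "wealth_quintile", "education": "education"}

OUTCOME = "anc8"
VISITS = "anc_visits"
WEIGHT_RAW = "v005"
WEIGHT_POOLED = "wpool"
COUNTRY = "country"
ELIGIBLE = "recent_birth"


def codes(var: str) -> list[int]:
    """Integer codes for ``var`` in category order."""
    n = len(CATEGORIES[var])
    return list(range(1, n + 1)) if var in ONE_BASED else list(range(n))


def code_of(var: str, label: str) -> int:
    """Integer code of ``label`` within ``var``."""
    idx = CATEGORIES[var].index(label)
    return idx + 1 if var in ONE_BASED else idx


def label_of(var: str, code: int) -> str:
    """Category label for an integer code of ``var``."""
    idx = code - 1 if var in ONE_BASED else code
    labels = CATEGORIES[var]
    if not 0 <= idx < len(labels):
        raise ValueError(f"code {code} out of range for {var!r}")
    return labels[idx]


def term_name(var: str, label: str) -> str:
    """Canonical design-column / coefficient name, e.g. ``wealth_quintile=richest``."""
    return f"{var}={label}"
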