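"""Published decomposition-table entries used as regression-test inputs.

These are the printed per-row percentage (and absolute) contributions of the
published wealth-related and education-based decomposition tables for the
pooled 15-country analysis.  They are inputs to the aggregation arithmetic
(:func:`ancineq.decomposition.aggregate_contributions`), not outputs of this
package; the underlying microdata are restricted, so the row values cannot be
recomputed here.

Note: in the published education-based table the category labels are shifted
one row against the values (the reference row carries the first value).  The
labels below follow the alignment in which the first category of each block
is the reference, consistent with the wealth-related table; only sums and
maxima over blocks are consumed downstream, which are unaffected by the
label alignment.
"""

from __future__ import annotations

#: total concentration indices of the pooled analysis
WEALTH_C_TOTAL = 0.30
EDUCATION_C_TOTAL = 0.33

#: row label -> printed percentage contribution, wealth-ranked decomposition
WEALTH_DECOMP_PCT: dict[str, float] = {
    "wealth_quintile=poorer": -1.478,
    "wealth_quintile=middle": 0.392,
    "wealth_quintile=richer": 4.466,
    "wealth_quintile=richest": 8.756,
    "age_group=20-24": -0.005,
    "age_group=25-29": 0.112,
    "age_group=30-34": 0.345,
    "age_group=35-39": 0.146,
    "age_group=40-44": -0.219,
    "age_group=45-49": -0.168,
    "education=incomplete primary": -0.117,
    "education=complete primary": 0.129,
    "education=incomplete secondary": 2.607,
    "education=complete secondary": 4.810,
    "education=higher": 5.100,
    "employed=yes": -0.166,
    "marital_status=married": 0.001,
    "marital_status=cohabiting": -0.039,
    "marital_status=widowed": -0.020,
    "marital_status=divorced": 0.013,
    "marital_status=separated": 0.023,
    "parity=two-four": -0.089,
    "parity=five or more": 1.555,
    "insurance=yes": -1.327,
    "media_newspaper=yes": -0.680,
    "media_radio=yes": -0.023,
    "media_internet=yes": -0.295,
    "barrier_permission=big problem": 0.163,
    "barrier_distance=big problem": -0.442,
    "head_female=female": 0.039,
    "rural=rural": 7.636,
}

#: row label -> printed absolute contribution, wealth-ranked decomposition
WEALTH_DECOMP_ABS: dict[str, float] = {
    "wealth_quintile=poorer": -0.004,
    "wealth_quintile=middle": 0.001,
    "wealth_quintile=richer": 0.014,
    "wealth_quintile=richest": 0.027,
    "age_group=20-24": 0.000,
    "age_group=25-29": 0.000,
    "age_group=30-34": 0.001,
    "age_group=35-39": 0.000,
    "age_group=40-44": -0.001,
    "age_group=45-49": -0.001,
    "education=incomplete primary": 0.000,
    "education=complete primary": 0.000,
    "education=incomplete secondary": 0.008,
    "education=complete secondary": 0.015,
    "education=higher": 0.016,
    "employed=yes": -0.001,
    "marital_status=married": 0.000,
    "marital_status=cohabiting": 0.000,
    "marital_status=widowed": 0.000,
    "marital_status=divorced": 0.000,
    "marital_status=separated": 0.000,
    "parity=two-four": 0.000,
    "parity=five or more": 0.005,
    "insurance=yes": -0.004,
    "media_newspaper=yes": -0.002,
    "media_radio=yes": 0.000,
    "media_internet=yes": 0.000,
    "barrier_permission=big problem": 0.000,
    "barrier_distance=big problem": -0.001,
    "head_female=female": 0.000,
    "rural=rural": 0.023,
}

#: printed residual of the wealth-ranked decomposition
WEALTH_RESIDUAL = 0.209

#: row label -> printed percentage contribution, education-ranked decomposition
EDUCATION_DECOMP_PCT: dict[str, float] = {
    "education=incomplete primary": 0.013,
    "education=complete primary": 0.736,
    "education=incomplete secondary": 5.926,
    "education=complete secondary": 8.017,
    "education=higher": 6.741,
    "age_group=20-24": 0.026,
    "age_group=25-29": 0.207,
    "age_group=30-34": -0.032,
    "age_group=35-39": -0.680,
    "age_group=40-44": -0.676,
    "age_group=45-49": -0.266,
    "employed=yes": -0.091,
    "marital_status=married": 0.015,
    "marital_status=cohabiting": 0.077,
    "marital_status=widowed": -0.021,
    "marital_status=divorced": -0.093,
    "marital_status=separated": -0.114,
    "parity=two-four": -0.085,
    "parity=five or more": 2.222,
    "insurance=yes": -2.697,
    "media_newspaper=yes": -0.920,
    "media_radio=yes": -0.015,
    "media_internet=yes": -0.287,
    "barrier_permission=big problem": 0.150,
    "barrier_distance=big problem": -0.238,
    "wealth_quintile=poorer": -0.662,
    "wealth_quintile=middle": -0.133,
    "wealth_quintile=richer": 1.441,
    "wealth_quintile=richest": 4.284,
    "head_female=female": 0.143,
    "rural=rural": 4.350,
}

#: printed residual of the education-ranked decomposition
EDUCATION_RESIDUAL = 0.230


def block(table: dict[str, float], variable: str) -> list[str]:
    """Row labels of one variable block, in table order."""
    prefix = f"{variable}="
    return [k for k in table if k.startswith(prefix)]
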