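"""Published reference estimates for US outpatient prescriptions, 2016-2021.

Prescription-level prevalence of indicated and contraindicated use in the
non-institutionalised American population, as published from linked
household-survey (MEPS) and drug-label (DrugCentral/SNOMED) data.  The rows
are reproduced here at their printed precision so the package's aggregation
algebra can be checked for internal consistency against them: subgroup Ns
recombine to the overall prescription count, subgroup percentages recombine
(N-weighted) to the overall percentage, and the contraindication rates among
indicated and off-label prescriptions mix back to the overall
contraindication rate.

Note: only the sex, race and survey-year partitions sum exactly to the
overall N in the published table; the education, age, approval-year and
insurance breakdowns cover a slightly smaller subset.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_prevalence",
    "HEADLINE_RATES",
    "CONTRA_RATE_BY_INDICATION",
]

_COLUMNS = ("grouping_variable", "category", "n_rx", "pct_indic_narrow",
            "pct_indic_broad", "pct_contraindicated", "pct_indic_not_contra")

_ROWS = [
    ("All", "-", 1_655_101, 56.5, 75.09, 54.34, 32.92),
    ("sex", "male", 697_174, 56.72, 75.17, 53.14, 33.73),
    ("sex", "female", 957_927, 56.33, 75.03, 55.2, 32.33),
    ("education", "missing", 11_158, 54.48, 72.52, 40.9, 40.95),
    ("education", "0-11", 333_066, 55.22, 74.92, 54.46, 32.55),
    ("education", "12", 517_288, 56.15, 75.12, 56.03, 31.45),
    ("education", "13+", 107_486, 56.03, 75.25, 56.71, 32.01),
    ("education", "18+", 666_574, 57.52, 75.18, 53.3, 33.9),
    ("age_group", "0-17", 39_628, 56.43, 73.6, 20.03, 58.11),
    ("age_group", "18-44", 278_849, 54.3, 71.31, 46.02, 37.76),
    ("age_group", "45-64", 702_388, 56.85, 75.49, 55.53, 32.48),
    ("age_group", "65-84", 568_400, 57.5, 76.79, 58.46, 30.13),
    ("age_group", "85+", 60_475, 52.92, 72.3, 57.27, 29.11),
    ("race", "White", 1_256_808, 56.22, 74.86, 54.45, 32.83),
    ("race", "Black", 272_257, 57.62, 75.79, 54.85, 32.18),
    ("race", "American Indian-Alaska", 15_348, 51.88, 74.71, 58.18, 29.91),
    ("race", "Asian", 51_263, 61.82, 77.7, 46.35, 39.98),
    ("race", "Multiple", 59_425, 54.09, 74.7, 55.33, 32.91),
    ("year", "2016", 288_469, 56.72, 72.76, 47.37, 37.42),
    ("year", "2017", 291_290, 54.29, 71.15, 46.86, 36.83),
    ("year", "2018", 297_588, 54.51, 75.61, 57.55, 30.54),
    ("year", "2019", 265_693, 55.73, 76.41, 59.44, 29.58),
    ("year", "2020", 251_225, 57.9, 77.06, 58.73, 30.46),
    ("year", "2021", 260_836, 60.36, 77.97, 56.68, 32.42),
    ("approval_year_group", "1941-1978", 424_017, 42.13, 66.95, 64.56, 20.96),
    ("approval_year_group", "1979-1991", 381_966, 67.09, 83.78, 55.67, 35.42),
    ("approval_year_group", "1992-1997", 431_967, 60.58, 76.57, 53.79, 33.64),
    ("approval_year_group", "1998-2018", 388_135, 57.23, 73.78, 42.46, 42.71),
    ("medicare", "Medicare", 534_965, 56.72, 76.07, 58.61, 29.92),
    ("medicare", "No Medicare", 1_091_120, 56.39, 74.61, 52.24, 34.38),
    ("medicaid", "Medicaid", 279_757, 54.11, 74.99, 52.76, 34.06),
    ("medicaid", "No Medicaid", 1_346_328, 56.99, 75.11, 54.66, 32.68),
]

#: headline prevalence rates (percent of prescriptions)
HEADLINE_RATES = {
    "pct_indic_broad": 75.0,
    "pct_offlabel": 25.0,
    "pct_contraindicated": 54.0,
    "pct_indic_not_contra": 33.0,
}

#: contraindication rate (percent) among broad-indicated vs off-label events
CONTRA_RATE_BY_INDICATION = {"indicated": 56.2, "offlabel": 48.8}


def reference_prevalence(grouping: str | None = None) -> pd.DataFrame:
    """The published prevalence rows, optionally filtered to one grouper."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    if grouping is not None:
        df = df[df["grouping_variable"] == grouping].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"no reference rows for grouping {grouping!r}")
    return df
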