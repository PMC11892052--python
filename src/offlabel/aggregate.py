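"""Prevalence tables, therapeutic-class rates and median-split comparisons.

Prescription-level prevalence tables report, for each category of a grouping
variable (sex, education, age group, race, survey year, FDA approval-year
group, insurance), the number of in-scope prescriptions and the percentage
that were narrow-indicated, broad-indicated, contraindicated, and indicated
but not contraindicated.  Percentages are simple indicator means x 100; they
satisfy the exact recombination identity

    overall_pct = sum_i(n_i * pct_i) / sum_i(n_i)

for any variable that partitions the prescriptions, which is also the basis
of the published-table consistency checks in :mod:`offlabel.reference`.

Median-split comparisons divide persons at the median of an exposure
fraction (ties go to the low group: <= median vs > median) and compare
outcome means with Welch's unequal-variance two-sample t-test.  Total
expenditure is compared on the log scale, log(expenditure + 1).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .knowledge_base import KnowledgeBase
from .survey import BINARY_OUTCOMES, COUNT_OUTCOMES, SurveyDataset

__all__ = [
    "AGE_GROUP_EDGES",
    "APPROVAL_GROUP_EDGES",
    "DEFAULT_COMPARE_OUTCOMES",
    "build_rx_table",
    "prevalence_table",
    "therapeutic_class_rates",
    "median_split_compare",
    "weighted_overall",
    "mixture_rate",
]

PCT_COLUMNS = {
    "indic_narrow": "pct_indic_narrow",
    "indic_broad": "pct_indic_broad",
    "contraindicated": "pct_contraindicated",
    "indic_not_contra": "pct_indic_not_contra",
}

#: age-group bins used in the stratified prevalence table
AGE_GROUP_EDGES = ((0, 17), (18, 44), (45, 64), (65, 84), (85, 200))
#: FDA approval-year bins
APPROVAL_GROUP_EDGES = ((1900, 1978), (1979, 1991), (1992, 1997), (1998, 2025))

DEFAULT_GROUPERS = ("sex", "education", "age_group", "race", "year",
                    "approval_year_group", "medicare", "medicaid")

#: outcome columns compared in the median-split table (expenditure is
#: transformed to ztotexp = log(total_expenditure + 1) before comparison)
DEFAULT_COMPARE_OUTCOMES = ("ztotexp",) + COUNT_OUTCOMES + BINARY_OUTCOMES


def _bin_label(value: int, edges) -> str:
    for lo, hi in edges:
        if lo <= value <= hi:
            return f"{lo}-{hi}" if hi < 200 else f"{lo}+"
    return "unknown"


def build_rx_table(classifications: pd.DataFrame, ds: SurveyDataset,
                   kb: KnowledgeBase | None = None) -> pd.DataFrame:
    """In-scope prescriptions with indicators, person attributes and drug
    approval-year groups merged on — the input to the prevalence tables."""
    rx = classifications[classifications["in_scope"] == 1].merge(
        ds.prescriptions[["rx_id", "therapeutic_class"]], on="rx_id", how="left"
    ).merge(
        ds.persons[["person_id", "year", "sex", "age", "education", "race",
                    "medicare", "medicaid"]],
        on=["person_id", "year"], how="left",
    )
    rx["age_group"] = rx["age"].astype(int).map(lambda a: _bin_label(a, AGE_GROUP_EDGES))
    if kb is not None:
        years = {d: rec.approval_year for d, rec in kb.drugs.items()}
        rx["approval_year"] = rx["drug_id"].map(years)
        rx["approval_year_group"] = rx["approval_year"].map(
            lambda y: _bin_label(int(y), APPROVAL_GROUP_EDGES))
    return rx


def _rate_row(grouping: str, category: str, sub: pd.DataFrame) -> dict:
    row = {"grouping_variable": grouping, "category": category,
           "n_rx": int(len(sub))}
    for ind, pct in PCT_COLUMNS.items():
        row[pct] = float(100.0 * sub[ind].mean()) if len(sub) else float("nan")
    return row


def prevalence_table(classifications: pd.DataFrame, ds: SurveyDataset,
                     groupers: Sequence[str] = DEFAULT_GROUPERS,
                     kb: KnowledgeBase | None = None) -> pd.DataFrame:
    """One prevalence row per (grouper, category) plus an overall row."""
    rx = build_rx_table(classifications, ds, kb)
    rows = [_rate_row("All", "-", rx)]
    for grouper in groupers:
        if grouper not in rx.columns:
            raise ConfigError(
                f"unknown grouping variable {grouper!r}; available: "
                f"{sorted(set(rx.columns) - set(classifications.columns))}"
            )
        for category, sub in rx.groupby(grouper, sort=True):
            rows.append(_rate_row(grouper, str(category), sub))
    return pd.DataFrame(rows)


def therapeutic_class_rates(classifications: pd.DataFrame,
                            ds: SurveyDataset) -> pd.DataFrame:
    """Prevalence rows keyed by therapeutic class, descending by volume.

    Prescriptions with an empty class label are grouped under
    ``"unclassified"``.
    """
    rx = build_rx_table(classifications, ds)
    label = rx["therapeutic_class"].fillna("").replace("", "unclassified")
    rows = [_rate_row("therapeutic_class", str(cat), sub)
            for cat, sub in rx.groupby(label, sort=True)]
    out = pd.DataFrame(rows)
    return out.sort_values(["n_rx", "category"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def weighted_overall(ns: Iterable[float], pcts: Iterable[float]) -> float:
    """Recombine subgroup percentages into the overall: sum(n*pct)/sum(n)."""
    ns = np.asarray(list(ns), dtype=float)
    pcts = np.asarray(list(pcts), dtype=float)
    return float((ns * pcts).sum() / ns.sum())


def mixture_rate(share_a: float, rate_a: float, rate_b: float) -> float:
    """Law-of-total-probability mixture: share_a*rate_a + (1-share_a)*rate_b."""
    return share_a * rate_a + (1.0 - share_a) * rate_b


def median_split_compare(
    exposures: pd.DataFrame,
    persons: pd.DataFrame,
    split_var: str = "frac_indicated",
    outcome_vars: Sequence[str] = DEFAULT_COMPARE_OUTCOMES,
) -> pd.DataFrame:
    """Compare outcome means below/above the median of an exposure fraction.

    Persons exactly at the median go to the low group.  Returns one row per
    outcome with the two group means, difference (low - high) and the Welch
    t-test p-value.
    """
    if split_var not in ("frac_indicated", "frac_contraindicated"):
        raise ConfigError(f"split_var must be an exposure fraction, got {split_var!r}")
    data = exposures.merge(persons, on=["person_id", "year"], how="inner").copy()
    data["ztotexp"] = np.log1p(data["total_expenditure"].astype(float))
    med = float(data[split_var].median())
    low = data[data[split_var] <= med]
    high = data[data[split_var] > med]
    if len(low) < 2 or len(high) < 2:
        warnings.warn(
            f"degenerate median split on {split_var!r} (median={med:.4g}): "
            f"group sizes {len(low)}/{len(high)}", stacklevel=2)
    rows = []
    for var in outcome_vars:
        a = low[var].astype(float).to_numpy()
        b = high[var].astype(float).to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            t_res = stats.ttest_ind(a, b, equal_var=False)
            p = float(t_res.pvalue)
        else:
            p = float("nan")
        mean_low = float(a.mean()) if len(a) else float("nan")
        mean_high = float(b.mean()) if len(b) else float("nan")
        rows.append({"variable": var, "split_var": split_var, "median": med,
                     "n_low": len(a), "n_high": len(b),
                     "mean_low": mean_low, "mean_high": mean_high,
                     "difference": mean_low - mean_high, "p_value": p})
    return pd.DataFrame(rows)
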