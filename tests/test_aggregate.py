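"""Prevalence tables, recombination algebra and median-split comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from offlabel.aggregate import (median_split_compare, mixture_rate,
                                prevalence_table, therapeutic_class_rates,
                                weighted_overall)
from offlabel.classify import classify_all, person_exposures
from offlabel.errors import ConfigError


def _small_cls(micro_kb):
    ds = make_dataset(
        persons=[{"person_id": "p1"}],
        conditions=[("c1", "p1", 2018, "E11", 1)],
        prescriptions=[(f"r{i}", "p1", 2018, d, t, "") for i, (d, t) in
                       enumerate([("d1", "a"), ("d2", "a"), ("d1", ""),
                                  ("d1", "b")])],
        links=[])
    cls, _ = classify_all(micro_kb, ds)
    return cls, ds


def test_overall_percentage_is_indicator_mean(micro_kb):
    cls, ds = _small_cls(micro_kb)
    table = prevalence_table(cls, ds, groupers=())
    overall = table.iloc[0]
    # broad = (1, 0, 1, 1) over the four prescriptions
    assert overall["pct_indic_broad"] == pytest.approx(75.0)
    assert overall["n_rx"] == 4


def test_unknown_grouper_is_config_error(micro_kb):
    cls, ds = _small_cls(micro_kb)
    with pytest.raises(ConfigError, match="shoe_size"):
        prevalence_table(cls, ds, groupers=("shoe_size",))


def test_subgroup_rows_recombine_to_overall(paperlike_sim):
    """For any partitioning grouper, sum(n_i * pct_i) / sum(n_i) equals the
    overall percentage before rounding."""
    sim = paperlike_sim
    cls, _ = classify_all(sim.kb, sim.dataset)
    table = prevalence_table(cls, sim.dataset,
                             groupers=("sex", "race", "year"), kb=sim.kb)
    overall = table[table["grouping_variable"] == "All"].iloc[0]
    for grouper in ("sex", "race", "year"):
        rows = table[table["grouping_variable"] == grouper]
        assert rows["n_rx"].sum() == overall["n_rx"]
        for pct in ("pct_indic_narrow", "pct_indic_broad",
                    "pct_contraindicated", "pct_indic_not_contra"):
            recombined = weighted_overall(rows["n_rx"], rows[pct])
            assert recombined == pytest.approx(overall[pct], abs=1e-9)


def test_contraindication_rate_is_mixture_over_indication_status(paperlike_sim):
    """Law of total probability: the overall contraindicated share equals
    the mixture of its rates among indicated and off-label prescriptions."""
    sim = paperlike_sim
    cls, _ = classify_all(sim.kb, sim.dataset)
    scope = cls[cls["in_scope"] == 1]
    share_ind = scope["indic_broad"].mean()
    rate_ind = scope.loc[scope["indic_broad"] == 1, "contraindicated"].mean()
    rate_off = scope.loc[scope["indic_broad"] == 0, "contraindicated"].mean()
    assert mixture_rate(share_ind, rate_ind, rate_off) == pytest.approx(
        scope["contraindicated"].mean(), abs=1e-12)


def test_therapeutic_class_rates_groupby_and_unclassified(micro_kb):
    cls, ds = _small_cls(micro_kb)
    rows = therapeutic_class_rates(cls, ds).set_index("category")
    assert set(rows.index) == {"a", "b", "unclassified"}
    assert rows.loc["a", "n_rx"] == 2
    # descending by volume
    assert list(rows["n_rx"]) == sorted(rows["n_rx"], reverse=True)
    # per-class recomputation: class "a" holds r0 (d1: broad) and r1 (d2: not)
    assert rows.loc["a", "pct_indic_broad"] == pytest.approx(50.0)


def test_single_class_row_matches_overall(paperlike_sim):
    sim = paperlike_sim
    cls, _ = classify_all(sim.kb, sim.dataset)
    one = cls.merge(sim.dataset.prescriptions[["rx_id", "therapeutic_class"]],
                    on="rx_id")
    keep = one["therapeutic_class"] == "class_03"
    sub_cls = cls[keep.values].reset_index(drop=True)
    rows = therapeutic_class_rates(sub_cls, sim.dataset)
    assert len(rows) == 1
    scope = sub_cls[sub_cls["in_scope"] == 1]
    assert rows.iloc[0]["pct_indic_broad"] == pytest.approx(
        100 * scope["indic_broad"].mean())


def _persons_frame(values, outcome="ANYLMT"):
    rows = []
    for i, (split, y) in enumerate(values):
        rows.append({"person_id": f"p{i}", "year": 2018, outcome: y})
    return rows


def test_median_split_identical_groups_gives_zero_difference():
    expo = pd.DataFrame({
        "person_id": [f"p{i}" for i in range(8)], "year": 2018,
        "frac_indicated": [0.0, 0.0, 0.2, 0.2, 0.8, 0.8, 1.0, 1.0],
        "frac_contraindicated": 0.5, "n_rx": 1,
        "frac_offlabel": 0.5, "mean_approval_year": 2000.0})
    persons = pd.DataFrame([
        dict(person_id=f"p{i}", year=2018, total_expenditure=0.0,
             ANYLMT=[0, 1, 0, 1, 0, 1, 0, 1][i]) for i in range(8)])
    out = median_split_compare(expo, persons, "frac_indicated", ("ANYLMT",))
    row = out.iloc[0]
    assert row["difference"] == pytest.approx(0.0)
    assert row["p_value"] == pytest.approx(1.0)


def test_median_split_against_hand_computed_welch():
    """Six persons, groups (0,1,1) vs (3,4,5): Welch statistic and p-value
    from the textbook formula."""
    expo = pd.DataFrame({
        "person_id": [f"p{i}" for i in range(6)], "year": 2018,
        "frac_contraindicated": [0.0, 0.1, 0.2, 0.8, 0.9, 1.0],
        "frac_indicated": 0.5, "frac_offlabel": 0.5, "n_rx": 1,
        "mean_approval_year": 2000.0})
    ys = [0.0, 1.0, 1.0, 3.0, 4.0, 5.0]
    persons = pd.DataFrame([
        dict(person_id=f"p{i}", year=2018, total_expenditure=0.0, obtotv=ys[i])
        for i in range(6)])
    out = median_split_compare(expo, persons, "frac_contraindicated",
                               ("obtotv",)).iloc[0]

    a, b = np.array(ys[:3]), np.array(ys[3:])
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
    from scipy import stats
    p = 2 * stats.t.sf(abs(t), df)
    assert out["difference"] == pytest.approx(a.mean() - b.mean())
    assert out["p_value"] == pytest.approx(p, rel=1e-12)


def test_median_split_sign_pattern_on_simulated_data(paperlike_sim):
    """The generator plants harmful contraindicated use, so ANYLMT must be
    more common above the contraindicated-use median."""
    sim = paperlike_sim
    cls, _ = classify_all(sim.kb, sim.dataset)
    expo = person_exposures(cls, sim.dataset, sim.kb)
    out = median_split_compare(expo, sim.dataset.persons,
                               "frac_contraindicated", ("ANYLMT",)).iloc[0]
    assert out["mean_high"] > out["mean_low"]
    assert out["difference"] < 0


def test_expenditure_compared_on_log_scale(paperlike_sim):
    sim = paperlike_sim
    cls, _ = classify_all(sim.kb, sim.dataset)
    expo = person_exposures(cls, sim.dataset, sim.kb)
    out = median_split_compare(expo, sim.dataset.persons, "frac_indicated",
                               ("ztotexp",)).set_index("variable")
    merged = expo.merge(sim.dataset.persons, on=["person_id", "year"])
    med = merged["frac_indicated"].median()
    low = merged[merged["frac_indicated"] <= med]
    assert out.loc["ztotexp", "mean_low"] == pytest.approx(
        np.log1p(low["total_expenditure"]).mean())


def test_swapping_groups_flips_difference_sign(paperlike_sim):
    sim = paperlike_sim
    cls, _ = classify_all(sim.kb, sim.dataset)
    expo = person_exposures(cls, sim.dataset, sim.kb).reset_index(drop=True)
    # even count + deterministic jitter: no observation sits exactly at the
    # median, so complementing the split variable exactly swaps the groups
    if len(expo) % 2:
        expo = expo.iloc[:-1].copy()
    expo["frac_contraindicated"] += 1e-9 * np.arange(len(expo))
    out = median_split_compare(expo, sim.dataset.persons,
                               "frac_contraindicated", ("ANYLMT", "obtotv"))
    flipped = expo.copy()
    flipped["frac_contraindicated"] = 1.0 - flipped["frac_contraindicated"]
    out2 = median_split_compare(flipped, sim.dataset.persons,
                                "frac_contraindicated", ("ANYLMT", "obtotv"))
    for var in ("ANYLMT", "obtotv"):
        d1 = out.set_index("variable").loc[var]
        d2 = out2.set_index("variable").loc[var]
        assert d1["difference"] == pytest.approx(-d2["difference"], rel=1e-6)
        assert d1["p_value"] == pytest.approx(d2["p_value"], rel=1e-6)
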