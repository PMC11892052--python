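"""Synthetic knowledge-base and survey data with known ground truth.

Every stage of the pipeline is testable without licensed data extracts: this
module emits the exact file layouts the :mod:`knowledge_base` and
:mod:`survey` readers consume, together with a ground-truth sidecar holding
the true per-prescription indicators, per-person exposures and outcome-model
coefficients.

What the generator emulates
---------------------------
* a drug universe with FDA approval years and per-drug Poisson-sized sets of
  indicated / contraindicated 3-character disease codes, distributed as
  SNOMED-style concept pairs plus a one-to-many concept -> ICD-10-CM map;
* persons with demographics, a Poisson number of current conditions, and a
  zero-truncated-Poisson number of prescription events;
* prescribing behaviour: with probability ``p_indicated_prescribing`` a
  prescription is drawn *indicated* — a drug approved for one of the
  person's conditions, linked to that condition with probability
  ``p_link_narrow`` — otherwise *off-label*, drawn uniformly from drugs not
  indicated for any of the person's conditions.  Contraindication status is
  never sampled directly: it emerges from the overlap between the person's
  conditions and the chosen drug's contraindication set, so the correlation
  structure between indicators is organic;
* binary health-status outcomes from a clipped linear-probability link in
  the person's true exposure fractions plus per-condition effects (drawn
  once per code from a zero-mean normal — the confounding that the
  condition-dummy control block must absorb); log-normal expenditure and
  Poisson visit counts from the same linear index.

The default ``preset_paperlike`` configuration is calibrated so the emitted
prescription mix lands near 75% broad-indicated / 54% contraindicated / 33%
indicated-but-not-contraindicated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .errors import ConfigError
from .knowledge_base import (ConceptMapEntry, DrugRecord, KnowledgeBase,
                             build_knowledge_base, write_knowledge_base)
from .survey import (BINARY_OUTCOMES, CONDITION_COLUMNS, LINK_COLUMNS,
                     PERSON_COLUMNS, PRESCRIPTION_COLUMNS, SurveyDataset,
                     write_survey)

__all__ = [
    "OutcomeSpec",
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedData",
    "default_outcome_specs",
    "generate",
    "expected_rates",
    "preset_paperlike",
    "preset_effect_recovery",
    "effect_recovery_study",
    "dml_confounding_study",
]


class OutcomeSpec(BaseModel):
    """Data-generating model for one person-level outcome."""

    kind: str = "bernoulli"          # bernoulli | lognormal | poisson
    intercept: float = 0.3
    beta_contra: float = 0.04
    beta_indic: float = -0.03
    link: str = "linear"             # bernoulli only: linear | logit
    sd: float = 1.0                  # lognormal noise scale

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("bernoulli", "lognormal", "poisson"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.link not in ("linear", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        return self


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """Outcome models: intercepts near the levels seen in US survey data,
    harmful contraindicated use (positive betas on limitations/utilisation)
    and beneficial indicated use (negative betas)."""
    base = {
        "ANYLMT": (0.32, 0.04, -0.03),
        "ACTLIM31": (0.16, 0.02, -0.02),
        "UNABLE31": (0.10, 0.02, -0.02),
        "WLKLIM31": (0.21, 0.02, -0.02),
        "WRKLIM31": (0.14, 0.02, -0.02),
        "SCHLIM31": (0.07, 0.01, -0.01),
        "HSELIM31": (0.10, 0.02, -0.02),
        "SOCLIM31": (0.09, 0.02, -0.01),
        "COGLIM31": (0.08, 0.01, -0.01),
    }
    out = {name: OutcomeSpec(kind="bernoulli", intercept=i, beta_contra=bc,
                             beta_indic=bi)
           for name, (i, bc, bi) in base.items()}
    out["total_expenditure"] = OutcomeSpec(kind="lognormal", intercept=7.6,
                                           beta_contra=0.3, beta_indic=-0.15,
                                           sd=1.2)
    out["ipdis"] = OutcomeSpec(kind="poisson", intercept=-2.0,
                               beta_contra=0.4, beta_indic=-0.3)
    out["ertot"] = OutcomeSpec(kind="poisson", intercept=-1.2,
                               beta_contra=0.4, beta_indic=-0.3)
    out["obtotv"] = OutcomeSpec(kind="poisson", intercept=2.0,
                                beta_contra=0.3, beta_indic=-0.2)
    return out


class GeneratorConfig(BaseModel):
    """All the dials of the synthetic world; seeded and fully reproducible."""

    seed: int = 0
    n_persons: int = 5000
    n_drugs: int = 150
    n_condition_codes: int = 60
    mean_conditions_per_person: float = 4.0
    min_conditions_per_person: int = 0
    mean_rx_per_person: float = 12.0        # zero-truncated Poisson rate
    indication_density: float = 2.5         # per-drug Poisson rate of codes
    contraindication_density: float = 11.7
    p_indicated_prescribing: float = 0.764
    p_link_narrow: float = 0.75             # indicated rx linked to its condition
    p_link_offlabel: float = 0.5            # off-label rx linked to a random condition
    p_unknown_drug: float = 0.0             # rx for a drug outside the knowledge base
    n_unmapped_concept_pairs: int = 0
    approval_year_range: tuple[int, int] = (1941, 2018)
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021)
    condition_effect_scale: float = 0.04
    outcomes: dict[str, OutcomeSpec] = Field(default_factory=default_outcome_specs)

    @model_validator(mode="after")
    def _feasible(self):
        for name in ("p_indicated_prescribing", "p_link_narrow",
                     "p_link_offlabel", "p_unknown_drug"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.mean_rx_per_person <= 0 or self.mean_conditions_per_person < 0:
            raise ValueError("rates must be positive")
        if self.n_condition_codes < 1 or self.n_condition_codes > 2000:
            raise ValueError("n_condition_codes outside [1, 2000]")
        if self.p_indicated_prescribing > 0 and self.indication_density <= 0:
            raise ValueError(
                "indicated prescribing demanded (p_indicated_prescribing > 0) "
                "but indication_density is 0: no drug can be indicated")
        y0, y1 = self.approval_year_range
        if not (1900 <= y0 <= y1 <= 2025):
            raise ValueError("approval_year_range outside [1900, 2025]")
        return self


@dataclass
class GroundTruth:
    """True indicators, exposures and coefficients, by construction."""

    rx: pd.DataFrame            # rx_id + four indicators + in_scope
    persons: pd.DataFrame       # person-year true exposure fractions
    coefficients: dict          # outcome -> {kind, intercept, beta_contra, beta_indic}


@dataclass
class SimulatedData:
    """In-memory simulation products plus (optionally) the emitted files."""

    config: GeneratorConfig
    kb: KnowledgeBase
    drugs: list
    concept_pairs: list
    concept_map: list
    dataset: SurveyDataset
    truth: GroundTruth
    paths: dict


def _condition_codes(n: int) -> list[str]:
    return [f"{chr(ord('A') + i // 100)}{i % 100:02d}" for i in range(n)]


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson via inverse-CDF on the truncated uniform."""
    u = rng.uniform(stats.poisson.cdf(0, lam), 1.0, size)
    return stats.poisson.ppf(u, lam).astype(int)


def generate(config: GeneratorConfig, out_dir: str | Path | None = None) -> SimulatedData:
    """Run the generator; optionally write all files under ``out_dir``.

    Same seed -> byte-identical files.  The emitted files parse through the
    package readers, and classifying them reproduces the ground-truth
    indicators exactly (classification is deterministic set algebra).
    """
    rng = np.random.default_rng(config.seed)
    codes = _condition_codes(config.n_condition_codes)
    n_codes = len(codes)

    # ---- drugs and their indication / contraindication code sets ----------
    y0, y1 = config.approval_year_range
    drugs = [DrugRecord(f"D{i:04d}", f"ingredient {i:04d}",
                        int(rng.integers(y0, y1 + 1)))
             for i in range(config.n_drugs)]
    ind_sets: dict[str, frozenset[str]] = {}
    contra_sets: dict[str, frozenset[str]] = {}
    for d in drugs:
        k_ind = min(int(rng.poisson(config.indication_density)), n_codes)
        k_con = min(int(rng.poisson(config.contraindication_density)), n_codes)
        ind_sets[d.drug_id] = frozenset(
            codes[j] for j in rng.choice(n_codes, k_ind, replace=False))
        contra_sets[d.drug_id] = frozenset(
            codes[j] for j in rng.choice(n_codes, k_con, replace=False))
    if config.p_indicated_prescribing > 0 and not any(ind_sets.values()):
        raise ConfigError("no drug received any indication; indicated "
                          "prescribing is infeasible under this configuration")

    # SNOMED-style intermediates: one concept per category code, mapping to
    # two full-precision ICD-10-CM codes that truncate back to it
    code_concept = {c: f"SCT{i:05d}" for i, c in enumerate(codes)}
    concept_map = [ConceptMapEntry(code_concept[c], (f"{c}.0", f"{c}.9"))
                   for c in codes]
    concept_pairs: list[tuple[str, str, str]] = []
    for d in drugs:
        for c in sorted(ind_sets[d.drug_id]):
            concept_pairs.append((d.drug_id, code_concept[c], "indication"))
        for c in sorted(contra_sets[d.drug_id]):
            concept_pairs.append((d.drug_id, code_concept[c], "contraindication"))
    for j in range(config.n_unmapped_concept_pairs):
        concept_pairs.append((drugs[0].drug_id, f"SCTX{j:04d}", "indication"))

    kb = build_knowledge_base(drugs, concept_pairs, concept_map)

    # drug lookup helpers for the prescriber
    drug_ids = [d.drug_id for d in drugs]
    drugs_for_code: dict[str, list[int]] = {c: [] for c in codes}
    for i, did in enumerate(drug_ids):
        for c in ind_sets[did]:
            drugs_for_code[c].append(i)
    class_of_drug = {did: f"class_{rng.integers(0, 10):02d}" for did in drug_ids}

    # ---- persons -----------------------------------------------------------
    n = config.n_persons
    person_ids = [f"P{i:06d}" for i in range(n)]
    years = rng.choice(config.years, n)
    sex = rng.choice(["male", "female"], n, p=[0.47, 0.53])
    age = rng.integers(18, 86, n)
    education = rng.choice(["missing", "0-11", "12", "13+", "18+"], n,
                           p=[0.02, 0.12, 0.30, 0.26, 0.30])
    race = rng.choice(
        ["White", "Black", "American Indian-Alaska", "Asian", "Multiple"], n,
        p=[0.72, 0.13, 0.01, 0.06, 0.08])
    medicare = (rng.random(n) < np.where(age >= 65, 0.95, 0.05)).astype(int)
    medicaid = (rng.random(n) < 0.20).astype(int)
    weight = np.round(np.exp(rng.normal(9.0, 0.5, n)), 2)

    k_cond = rng.poisson(config.mean_conditions_per_person, n)
    k_cond = np.maximum(k_cond, config.min_conditions_per_person)
    k_cond = np.minimum(k_cond, n_codes)
    person_codes: list[list[str]] = []
    cond_rows = []
    serial = 0
    for i in range(n):
        chosen = sorted(codes[j] for j in rng.choice(n_codes, k_cond[i],
                                                     replace=False))
        person_codes.append(chosen)
        for c in chosen:
            cond_rows.append((f"C{serial:07d}", person_ids[i], int(years[i]), c, 1))
            serial += 1
    conditions = pd.DataFrame(cond_rows, columns=CONDITION_COLUMNS)
    cond_id_of = {(r[1], r[3]): r[0] for r in cond_rows}

    # ---- prescriptions -----------------------------------------------------
    n_rx = _zt_poisson(rng, config.mean_rx_per_person, n)
    rx_rows, link_rows, truth_rows = [], [], []
    serial = 0
    for i in range(n):
        pid, year = person_ids[i], int(years[i])
        pset = frozenset(person_codes[i])
        eligible = [c for c in person_codes[i] if drugs_for_code[c]]
        # off-label pool: drugs not indicated for any of the person's conditions
        pool = [j for j, did in enumerate(drug_ids) if not (ind_sets[did] & pset)]
        for _ in range(int(n_rx[i])):
            rx_id = f"R{serial:07d}"
            serial += 1
            linked: list[str] = []
            if rng.random() < config.p_unknown_drug:
                drug_id, in_scope = f"X{rng.integers(0, 1000):03d}", 0
            elif eligible and rng.random() < config.p_indicated_prescribing:
                c = eligible[rng.integers(0, len(eligible))]
                drug_id = drug_ids[drugs_for_code[c][
                    rng.integers(0, len(drugs_for_code[c]))]]
                in_scope = 1
                if rng.random() < config.p_link_narrow:
                    linked = [c]
            else:
                cand = pool if pool else list(range(len(drug_ids)))
                drug_id = drug_ids[cand[rng.integers(0, len(cand))]]
                in_scope = 1
                if person_codes[i] and rng.random() < config.p_link_offlabel:
                    linked = [person_codes[i][rng.integers(0, len(person_codes[i]))]]
            tclass = class_of_drug.get(drug_id, "")
            ndc = f"{rng.integers(0, 10**11):011d}"
            rx_rows.append((rx_id, pid, year, drug_id, tclass, ndc))
            for c in linked:
                link_rows.append((rx_id, cond_id_of[(pid, c)]))
            # ground truth by direct set algebra
            if in_scope:
                ind = ind_sets[drug_id]
                con = contra_sets[drug_id]
                narrow = int(bool(frozenset(linked) & ind))
                broad = int(bool(pset & ind))
                contra = int(bool(pset & con))
                truth_rows.append((rx_id, pid, year, drug_id, narrow, broad,
                                   contra, broad * (1 - contra), 1))
            else:
                truth_rows.append((rx_id, pid, year, drug_id, 0, 0, 0, 0, 0))

    prescriptions = pd.DataFrame(rx_rows, columns=PRESCRIPTION_COLUMNS)
    links = pd.DataFrame(link_rows, columns=LINK_COLUMNS)
    truth_rx = pd.DataFrame(
        truth_rows,
        columns=["rx_id", "person_id", "year", "drug_id", "indic_narrow",
                 "indic_broad", "contraindicated", "indic_not_contra", "in_scope"])

    # ---- true person exposures --------------------------------------------
    scope = truth_rx[truth_rx["in_scope"] == 1].copy()
    approval = {d.drug_id: d.approval_year for d in drugs}
    scope["approval_year"] = scope["drug_id"].map(approval)
    truth_persons = scope.groupby(["person_id", "year"], sort=True).agg(
        n_rx=("rx_id", "size"),
        frac_indicated=("indic_broad", "mean"),
        frac_contraindicated=("contraindicated", "mean"),
        mean_approval_year=("approval_year", "mean"),
    ).reset_index()
    truth_persons["frac_offlabel"] = 1.0 - truth_persons["frac_indicated"]

    # ---- outcomes ----------------------------------------------------------
    delta = rng.normal(0.0, config.condition_effect_scale, n_codes)
    delta_of = dict(zip(codes, delta))
    cond_effect = np.array([sum(delta_of[c] for c in person_codes[i])
                            for i in range(n)])
    expo = truth_persons.set_index("person_id")
    frac_c = np.array([expo["frac_contraindicated"].get(p, 0.0) for p in person_ids])
    frac_i = np.array([expo["frac_indicated"].get(p, 0.0) for p in person_ids])

    outcome_cols: dict[str, np.ndarray] = {}
    for name, spec in config.outcomes.items():
        index = (spec.intercept + spec.beta_contra * frac_c
                 + spec.beta_indic * frac_i + cond_effect)
        if spec.kind == "bernoulli":
            if spec.link == "logit":
                p = 1.0 / (1.0 + np.exp(-index))
            else:
                p = np.clip(index, 0.01, 0.99)
            outcome_cols[name] = rng.binomial(1, p)
        elif spec.kind == "lognormal":
            outcome_cols[name] = np.round(np.maximum(
                np.expm1(index + rng.normal(0.0, spec.sd, n)), 0.0), 2)
        else:  # poisson
            outcome_cols[name] = rng.poisson(np.exp(index))

    persons = pd.DataFrame({
        "person_id": person_ids, "year": years.astype(int), "sex": sex,
        "age": age, "education": education, "race": race,
        "medicare": medicare, "medicaid": medicaid, "weight": weight,
        "total_expenditure": outcome_cols.get("total_expenditure",
                                              np.zeros(n)),
        **{c: outcome_cols.get(c, np.zeros(n, dtype=int))
           for c in ("ipdis", "ertot", "obtotv")},
        **{c: outcome_cols.get(c, np.zeros(n, dtype=int))
           for c in BINARY_OUTCOMES},
    })[list(PERSON_COLUMNS)]

    dataset = SurveyDataset(persons, conditions, prescriptions, links).validate()
    coefficients = {name: {"kind": s.kind, "link": s.link,
                           "intercept": s.intercept,
                           "beta_contra": s.beta_contra,
                           "beta_indic": s.beta_indic}
                    for name, s in config.outcomes.items()}
    truth = GroundTruth(truth_rx, truth_persons, coefficients)

    paths: dict = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = write_survey(dataset, out)
        pd.DataFrame([(d.drug_id, d.ingredient_name, d.approval_year)
                      for d in drugs],
                     columns=["drug_id", "ingredient_name", "approval_year"]
                     ).to_csv(out / "drugs.csv", index=False)
        pd.DataFrame(concept_pairs,
                     columns=["drug_id", "snomed_id", "relation"]
                     ).to_csv(out / "concept_pairs.csv", index=False)
        pd.DataFrame([(e.snomed_id, t) for e in concept_map
                      for t in e.icd10_targets],
                     columns=["snomed_id", "icd10_code"]
                     ).to_csv(out / "concept_map.csv", index=False)
        write_knowledge_base(kb, out / "knowledge_base_pairs.csv",
                             out / "knowledge_base_qc.json")
        truth_rx.to_csv(out / "ground_truth_rx.csv", index=False)
        truth_persons.to_csv(out / "ground_truth_persons.csv", index=False,
                             float_format="%.10g")
        (out / "ground_truth.json").write_text(json.dumps(
            {"coefficients": coefficients,
             "config": json.loads(config.model_dump_json())}, indent=2,
            sort_keys=True))
        paths.update({"drugs": out / "drugs.csv",
                      "concept_pairs": out / "concept_pairs.csv",
                      "concept_map": out / "concept_map.csv",
                      "knowledge_base_pairs": out / "knowledge_base_pairs.csv"})
    return SimulatedData(config, kb, drugs, concept_pairs, concept_map,
                         dataset, truth, paths)


# ---------------------------------------------------------------------------
# analytic rate expectations

def expected_rates(config: GeneratorConfig) -> dict[str, float]:
    """Config-implied prevalence expectations (percent, among in-scope
    prescriptions), in expectation over the random drug code-sets.

    Assumes every condition code is indicated for at least one drug (holds
    with high probability when n_drugs x indication_density >> codes) and
    marginalises the drug contraindication-set size over its Poisson law, so
    a single realised drug universe adds cluster noise around these values.
    """
    C = config.n_condition_codes
    kmax = max(int(stats.poisson.ppf(1 - 1e-9, config.mean_conditions_per_person)), 2)
    ks = np.arange(0, min(kmax + 1, C + 1))
    pk = stats.poisson.pmf(ks, config.mean_conditions_per_person)
    if config.min_conditions_per_person > 0:
        m = config.min_conditions_per_person
        pk[m] += pk[:m].sum()
        pk[:m] = 0.0
    pk /= pk.sum()

    mmax = max(int(stats.poisson.ppf(1 - 1e-9, config.contraindication_density)), 2)
    ms = np.arange(0, min(mmax + 1, C + 1))
    pm = stats.poisson.pmf(ms, config.contraindication_density)
    pm /= pm.sum()

    def p_overlap(k: int, m: int) -> float:
        if k == 0 or m == 0:
            return 0.0
        out = 1.0
        for t in range(m):
            out *= max(C - k - t, 0) / (C - t)
        return 1.0 - out

    overlap = np.array([[p_overlap(int(k), int(m)) for m in ms] for k in ks])
    contra_by_k = overlap @ pm                      # P(contra | K = k)

    p_k_pos = pk[1:].sum()
    pk_trunc = np.where(ks >= 1, pk, 0.0)
    pk_trunc = pk_trunc / pk_trunc.sum() if p_k_pos > 0 else pk_trunc
    p_ind = config.p_indicated_prescribing
    broad = p_ind * p_k_pos
    # off-label events: all K=0 events plus (1 - p_ind) of the K>=1 events
    w_off = np.where(ks == 0, pk, (1 - p_ind) * pk)
    w_off = w_off / w_off.sum() if w_off.sum() > 0 else w_off
    contra_ind = float(pk_trunc @ contra_by_k)
    contra_off = float(w_off @ contra_by_k)
    contra = broad * contra_ind + (1 - broad) * contra_off
    return {
        "pct_indic_narrow": 100 * broad * config.p_link_narrow,
        "pct_indic_broad": 100 * broad,
        "pct_contraindicated": 100 * contra,
        "pct_indic_not_contra": 100 * broad * (1 - contra_ind),
    }


# ---------------------------------------------------------------------------
# presets

def preset_paperlike(seed: int = 1, n_persons: int = 5000) -> GeneratorConfig:
    """Configuration calibrated to the published headline prescription mix
    (~75% broad-indicated, ~54% contraindicated, ~33% optimal use)."""
    return GeneratorConfig(seed=seed, n_persons=n_persons, n_drugs=150,
                           n_condition_codes=60,
                           mean_conditions_per_person=4.0,
                           mean_rx_per_person=12.0,
                           indication_density=2.5,
                           contraindication_density=11.7,
                           p_indicated_prescribing=0.764,
                           p_link_narrow=0.75,
                           p_unknown_drug=0.02)


def preset_effect_recovery(seed: int = 1, n_persons: int = 5000,
                           beta_contra: float = 0.04,
                           beta_indic: float = -0.03) -> GeneratorConfig:
    """Conditions for the effect-recovery studies: mostly single-prescription
    persons and a balanced indicated share (so the person-level exposure
    fractions carry close to the maximal variance a [0, 1] exposure allows),
    with the betas planted on a low-prevalence limitation outcome whose
    Bernoulli noise floor leaves them identifiable at n = 5000."""
    outcomes = default_outcome_specs()
    outcomes["UNABLE31"] = OutcomeSpec(kind="bernoulli", intercept=0.10,
                                       beta_contra=beta_contra,
                                       beta_indic=beta_indic)
    return GeneratorConfig(seed=seed, n_persons=n_persons, n_drugs=100,
                           n_condition_codes=40,
                           mean_conditions_per_person=2.5,
                           mean_rx_per_person=0.5,
                           indication_density=2.5,
                           contraindication_density=13.0,
                           p_indicated_prescribing=0.5,
                           condition_effect_scale=0.02,
                           outcomes=outcomes)


# ---------------------------------------------------------------------------
# simulation studies

def effect_recovery_study(n_replicates: int = 100, n_persons: int = 5000,
                          seed: int = 1,
                          estimators: tuple[str, ...] = ("lpm", "probit"),
                          outcome: str = "UNABLE31") -> dict:
    """Replicate generate -> classify -> regress and score CI coverage of
    the true betas and agreement with the expected sign pattern
    (contraindicated positive, indicated negative)."""
    from .classify import classify_all, person_exposures
    from .inference import ModelSpec, build_analysis_table, fit_lpm, fit_probit

    fitters = {"lpm": fit_lpm, "probit": fit_probit}
    tally = {(est, expo): {"cover": 0, "sign": 0, "est_sum": 0.0}
             for est in estimators
             for expo in ("frac_contraindicated", "frac_indicated")}
    pattern = {est: 0 for est in estimators}
    for r in range(n_replicates):
        config = preset_effect_recovery(seed=seed + r, n_persons=n_persons)
        sim = generate(config)
        truth = {"frac_contraindicated": config.outcomes[outcome].beta_contra,
                 "frac_indicated": config.outcomes[outcome].beta_indic}
        cls, _ = classify_all(sim.kb, sim.dataset)
        expo = person_exposures(cls, sim.dataset, sim.kb)
        table = build_analysis_table(expo, sim.dataset)
        spec = ModelSpec(outcome=outcome)
        for est in estimators:
            signs_ok = True
            for res in fitters[est](spec, table):
                t = tally[(est, res.exposure)]
                b = truth[res.exposure]
                t["cover"] += int(res.ci_low <= b <= res.ci_high)
                ok = bool(np.sign(res.estimate) == np.sign(b))
                t["sign"] += int(ok)
                signs_ok = signs_ok and ok
                t["est_sum"] += res.estimate
            pattern[est] += int(signs_ok)
    out = {"n_replicates": n_replicates, "n_persons": n_persons,
           "truth": {"frac_contraindicated":
                     preset_effect_recovery().outcomes[outcome].beta_contra,
                     "frac_indicated":
                     preset_effect_recovery().outcomes[outcome].beta_indic}}
    for (est, expo_name), t in tally.items():
        out[f"{est}_{expo_name}"] = {
            "coverage": t["cover"] / n_replicates,
            "sign_agreement": t["sign"] / n_replicates,
            "mean_estimate": t["est_sum"] / n_replicates,
        }
    for est in estimators:
        out[f"{est}_sign_pattern"] = pattern[est] / n_replicates
    return out


def _confounded_dgp(rng: np.random.Generator, n: int, theta: float = 0.5):
    """Partially linear DGP with smooth nonlinear confounding: the exposure
    and the outcome share sin / quadratic functions of the covariates, so a
    linear regression of Y on (D, X) is biased."""
    X = rng.uniform(-1, 1, size=(n, 3))
    m = np.sin(np.pi * X[:, 0]) + 0.5 * X[:, 1] ** 2
    g = 2.0 * np.sin(np.pi * X[:, 0]) + X[:, 1] ** 2
    D = m + rng.normal(0, 1.0, n)
    Y = theta * D + g + rng.normal(0, 1.0, n)
    return X, D, Y


def dml_confounding_study(n_replicates: int = 100, n: int = 2000,
                          seed: int = 1, theta: float = 0.5,
                          learner_params: Mapping | None = None) -> dict:
    """Compare naive OLS with cross-fitted forest DML under nonlinear
    confounding: bias of each and DML CI coverage of the true effect."""
    from .inference import ModelSpec, fit_dml_plr, fit_lpm

    learner_params = dict(learner_params or
                          {"n_estimators": 100, "min_samples_leaf": 10})
    naive_err, dml_err, cover = [], [], 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        X, D, Y = _confounded_dgp(rng, n, theta)
        data = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        data["d"] = D
        data["y"] = Y
        spec = ModelSpec(outcome="y", exposures=("d",), condition_dummies=False,
                         age_dummies=False, sex=False, education=False,
                         race=False, year_dummies=False,
                         rx_count_dummies=False, mean_approval_year=False,
                         extra_controls=("x0", "x1", "x2"))
        # naive benchmark: OLS of y on d plus the covariates entered linearly
        naive = fit_lpm(spec, data)[0]
        dml = fit_dml_plr(spec, data, learner="random_forest",
                          n_folds=5, seed=seed + r,
                          learner_params=learner_params)[0]
        naive_err.append(naive.estimate - theta)
        dml_err.append(dml.estimate - theta)
        cover += int(dml.ci_low <= theta <= dml.ci_high)
    return {
        "n_replicates": n_replicates, "n": n, "theta": theta,
        "naive_bias": float(np.mean(naive_err)),
        "dml_bias": float(np.mean(dml_err)),
        "bias_ratio": float(abs(np.mean(dml_err)) / abs(np.mean(naive_err))),
        "dml_coverage": cover / n_replicates,
    }
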