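"""Shared fixtures: hand-built micro knowledge base and a seeded simulation."""

import pandas as pd
import pytest

from offlabel.knowledge_base import (ConceptMapEntry, DrugRecord,
                                     build_knowledge_base)
from offlabel.simulate import generate, preset_paperlike
from offlabel.survey import (BINARY_OUTCOMES, COUNT_OUTCOMES, SurveyDataset)


@pytest.fixture
def micro_kb():
    """Two drugs: metformin-like (E11 indicated, N18 contraindicated) and a
    drug with indications only."""
    drugs = [DrugRecord("d1", "metformin", 1995),
             DrugRecord("d2", "lisinopril", 1988)]
    cmap = [ConceptMapEntry("s_e11", ("E11.9", "E11.65")),
            ConceptMapEntry("s_n18", ("N18.3",)),
            ConceptMapEntry("s_i10", ("I10",)),
            ConceptMapEntry("s_k21", ("K21.0",))]
    pairs = [("d1", "s_e11", "indication"),
             ("d1", "s_n18", "contraindication"),
             ("d2", "s_i10", "indication"),
             ("d2", "s_k21", "indication")]
    return build_knowledge_base(drugs, pairs, cmap)


def make_person(person_id="p1", year=2018, **overrides):
    row = {"person_id": person_id, "year": year, "sex": "female", "age": 60,
           "education": "12", "race": "White", "medicare": 0, "medicaid": 0,
           "weight": 1000.0, "total_expenditure": 1200.0}
    row.update({c: 0 for c in COUNT_OUTCOMES})
    row.update({c: 0 for c in BINARY_OUTCOMES})
    row.update(overrides)
    return row


def make_dataset(persons, conditions, prescriptions, links) -> SurveyDataset:
    """Build a validated dataset from row dicts / tuples."""
    p = pd.DataFrame([make_person(**r) if isinstance(r, dict) else r
                      for r in persons])
    c = pd.DataFrame(conditions, columns=["condition_id", "person_id", "year",
                                          "icd10_3", "is_current"])
    rx = pd.DataFrame(prescriptions,
                      columns=["rx_id", "person_id", "year", "drug_id",
                               "therapeutic_class", "ndc"])
    lk = pd.DataFrame(links, columns=["rx_id", "condition_id"])
    return SurveyDataset(p, c, rx, lk).validate()


@pytest.fixture
def micro_dataset():
    """One woman with diabetes (E11, linked) and kidney disease (N18)."""
    return make_dataset(
        persons=[{"person_id": "p1"}, {"person_id": "p2"}],
        conditions=[("c1", "p1", 2018, "E11", 1),
                    ("c2", "p1", 2018, "N18", 1),
                    ("c3", "p2", 2018, "I10", 0)],
        prescriptions=[("r1", "p1", 2018, "d1", "metabolic", ""),
                       ("r2", "p1", 2018, "d2", "cardiovascular", ""),
                       ("r3", "p2", 2018, "d9", "", "")],
        links=[("r1", "c1")],
    )


@pytest.fixture(scope="session")
def paperlike_sim():
    """One calibrated simulation shared by read-only tests."""
    return generate(preset_paperlike(seed=7, n_persons=1500))
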