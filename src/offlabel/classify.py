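"""Per-prescription use indicators and person-level exposure fractions.

The core procedure: every prescription event is screened against the drug
knowledge base and the patient's recorded conditions, producing four 0/1
indicators —

* ``indic_narrow``  — the condition *linked to the prescription event*
  matches an approved indication of the drug;
* ``indic_broad``   — *any* condition recorded for the patient in the survey
  year matches an approved indication (its complement is off-label use);
* ``contraindicated`` — any recorded condition is a contraindication of the
  drug;
* ``indic_not_contra`` — broad-indicated AND not contraindicated (the
  "optimal use" measure).

All matching is exact intersection of 3-character ICD-10 category sets, so
``indic_narrow <= indic_broad`` whenever linked conditions are a subset of
the person's conditions.  Prescriptions for drugs absent from the knowledge
base are flagged out of scope (``in_scope = 0``) with all-zero indicators and
are excluded from denominators downstream; a flag allows counting them as
off-label instead for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .knowledge_base import KnowledgeBase
from .survey import SurveyDataset

__all__ = [
    "INDICATOR_COLUMNS",
    "PrescriptionClassification",
    "classify_prescription",
    "classify_all",
    "person_exposures",
]

INDICATOR_COLUMNS = ("indic_narrow", "indic_broad", "contraindicated",
                     "indic_not_contra")


@dataclass(frozen=True)
class PrescriptionClassification:
    rx_id: str
    indic_narrow: int
    indic_broad: int
    contraindicated: int
    indic_not_contra: int
    in_scope: int


def classify_prescription(
    kb: KnowledgeBase,
    linked_codes: Iterable[str],
    person_codes: Iterable[str],
    drug_id: str,
    rx_id: str = "",
) -> PrescriptionClassification:
    """Classify one prescription from its drug and the patient's conditions."""
    if drug_id not in kb:
        return PrescriptionClassification(rx_id, 0, 0, 0, 0, 0)
    linked = frozenset(linked_codes)
    person = frozenset(person_codes)
    ind = kb.indications.get(drug_id, frozenset())
    contra = kb.contraindications.get(drug_id, frozenset())
    narrow = int(bool(linked & ind))
    broad = int(bool(person & ind))
    contraindicated = int(bool(person & contra))
    return PrescriptionClassification(
        rx_id, narrow, broad, contraindicated,
        broad * (1 - contraindicated), 1,
    )


def classify_all(
    kb: KnowledgeBase,
    ds: SurveyDataset,
    current_only: bool = True,
    unknown_drug_as_offlabel: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Classify every prescription event in the dataset.

    Returns a frame with one row per prescription (rx_id, person_id, year,
    drug_id, the four indicators, in_scope) plus a QC dict with exclusion
    counts and indicator prevalences among in-scope events.

    ``unknown_drug_as_offlabel=True`` keeps prescriptions for drugs absent
    from the knowledge base in scope as off-label, not-contraindicated
    events (sensitivity analysis); the default excludes them.
    """
    rx = ds.prescriptions
    person_codes = ds.person_codes_map(current_only=current_only)
    linked_map = ds.rx_linked_map()
    empty = frozenset()

    rows = np.zeros((len(rx), 5), dtype=np.int8)
    for i, (rx_id, pid, year, drug_id) in enumerate(
        zip(rx["rx_id"], rx["person_id"], rx["year"].astype(int), rx["drug_id"])
    ):
        if drug_id in kb:
            person = person_codes.get((pid, year), empty)
            linked = linked_map.get(rx_id, empty)
            ind = kb.indications.get(drug_id, empty)
            contra = kb.contraindications.get(drug_id, empty)
            narrow = 1 if linked & ind else 0
            broad = 1 if person & ind else 0
            is_contra = 1 if person & contra else 0
            rows[i] = (narrow, broad, is_contra, broad * (1 - is_contra), 1)
        elif unknown_drug_as_offlabel:
            rows[i] = (0, 0, 0, 0, 1)

    out = rx[["rx_id", "person_id", "year", "drug_id"]].copy()
    for j, col in enumerate(INDICATOR_COLUMNS + ("in_scope",)):
        out[col] = rows[:, j].astype(int)

    in_scope = out[out["in_scope"] == 1]
    qc = {
        "n_prescriptions": int(len(out)),
        "n_in_scope": int(len(in_scope)),
        "n_excluded_unknown_drug": int((out["in_scope"] == 0).sum()),
        "prevalence_pct": {
            col: (float(100 * in_scope[col].mean()) if len(in_scope) else None)
            for col in INDICATOR_COLUMNS
        },
    }
    return out, qc


def person_exposures(
    classifications: pd.DataFrame,
    ds: SurveyDataset,
    kb: KnowledgeBase,
) -> pd.DataFrame:
    """Aggregate in-scope classifications to person-year exposures.

    Fractions are unweighted means over the person-year's in-scope
    prescriptions; ``mean_approval_year`` averages the FDA approval years of
    the prescribed drugs with repetition (one term per prescription).
    Person-years with no in-scope prescription are skipped.
    """
    cls = classifications[classifications["in_scope"] == 1].copy()
    if cls.empty:
        return pd.DataFrame(columns=["person_id", "year", "n_rx", "frac_indicated",
                                     "frac_offlabel", "frac_contraindicated",
                                     "mean_approval_year"])
    years = {d: rec.approval_year for d, rec in kb.drugs.items()}
    cls["approval_year"] = cls["drug_id"].map(years)
    grouped = cls.groupby(["person_id", "year"], sort=True).agg(
        n_rx=("rx_id", "size"),
        frac_indicated=("indic_broad", "mean"),
        frac_contraindicated=("contraindicated", "mean"),
        mean_approval_year=("approval_year", "mean"),
    ).reset_index()
    grouped["frac_offlabel"] = 1.0 - grouped["frac_indicated"]
    return grouped[["person_id", "year", "n_rx", "frac_indicated", "frac_offlabel",
                    "frac_contraindicated", "mean_approval_year"]]
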