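"""Drug indication / contraindication knowledge base.

Drug labels list the conditions a drug is approved for (indications) and the
conditions under which it should not be used (contraindications).  Public drug
information resources distribute these as (drug, clinical concept) pairs keyed
by SNOMED CT concept identifiers; survey condition records instead carry
ICD-10-CM codes.  This module translates concept pairs through a SNOMED ->
ICD-10-CM map, truncates codes to their 3-character category (the resolution
at which drug-disease matching is performed throughout the package), and
collapses the result into per-drug sets of indicated and contraindicated
disease categories.

A SNOMED concept may map to several ICD-10-CM codes; all targets are expanded
(the mapping resource is one-to-many) and duplicates collapse after
truncation.  Concepts with no map entry are dropped and counted in the QC
report rather than guessed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

__all__ = [
    "ICD10_PATTERN",
    "ICD10_CATEGORY_PATTERN",
    "RELATIONS",
    "ConceptMapEntry",
    "DrugRecord",
    "DrugConditionPair",
    "KnowledgeBase",
    "truncate_icd10",
    "normalize_ingredient",
    "build_knowledge_base",
    "lookup",
    "read_delimited",
    "read_drugs",
    "read_concept_pairs",
    "read_concept_map",
    "write_knowledge_base",
    "load_knowledge_base",
]

#: full-precision ICD-10-CM code: letter, two digits, optional 1-4 char suffix
ICD10_PATTERN = re.compile(r"^[A-Za-z]\d{2}(?:\.[A-Za-z0-9]{1,4})?$")
#: 3-character category code
ICD10_CATEGORY_PATTERN = re.compile(r"^[A-Z]\d{2}$")

RELATIONS = ("indication", "contraindication")


def truncate_icd10(code: str) -> str:
    """Truncate a full ICD-10-CM code to its upper-cased 3-character category.

    >>> truncate_icd10("E11.9")
    'E11'
    >>> truncate_icd10("k52.9")
    'K52'
    """
    if not isinstance(code, str) or not ICD10_PATTERN.match(code.strip()):
        raise ValidationError(f"malformed ICD-10-CM code: {code!r}")
    return code.strip()[:3].upper()


def normalize_ingredient(name: str) -> str:
    """Normalise an active-ingredient name: trimmed, lower-case, single spaces."""
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class ConceptMapEntry:
    """One SNOMED CT concept and its ICD-10-CM targets (one-to-many)."""

    snomed_id: str
    icd10_targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.icd10_targets:
            raise ValidationError(
                f"concept {self.snomed_id!r} has no ICD-10 targets"
            )
        for code in self.icd10_targets:
            if not ICD10_PATTERN.match(code):
                raise ValidationError(
                    f"concept {self.snomed_id!r}: malformed ICD-10-CM code {code!r}"
                )


@dataclass(frozen=True)
class DrugRecord:
    """An active ingredient with its FDA approval year."""

    drug_id: str
    ingredient_name: str
    approval_year: int

    def __post_init__(self) -> None:
        if not 1900 <= int(self.approval_year) <= 2025:
            raise ValidationError(
                f"drug {self.drug_id!r}: approval year {self.approval_year} "
                "outside [1900, 2025]"
            )


@dataclass(frozen=True)
class DrugConditionPair:
    """A (drug, 3-character disease category) pair under one relation."""

    drug_id: str
    icd10_3: str
    relation: str

    def __post_init__(self) -> None:
        if not ICD10_CATEGORY_PATTERN.match(self.icd10_3):
            raise ValidationError(
                f"pair ({self.drug_id!r}, {self.icd10_3!r}): not a 3-character "
                "ICD-10 category code"
            )
        if self.relation not in RELATIONS:
            raise ValidationError(f"unknown relation {self.relation!r}")


@dataclass
class KnowledgeBase:
    """Per-drug indicated and contraindicated ICD-10 category sets.

    ``indications`` / ``contraindications`` map drug_id -> frozenset of
    3-character codes; drugs without pairs under a relation simply have an
    empty set.  ``qc`` records ingest counts, including dropped unmappable
    concept pairs.
    """

    drugs: dict[str, DrugRecord]
    indications: dict[str, frozenset[str]]
    contraindications: dict[str, frozenset[str]]
    qc: dict = field(default_factory=dict)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.drugs

    def approval_year(self, drug_id: str) -> int:
        return self.drugs[drug_id].approval_year

    @property
    def n_indication_pairs(self) -> int:
        return sum(len(s) for s in self.indications.values())

    @property
    def n_contraindication_pairs(self) -> int:
        return sum(len(s) for s in self.contraindications.values())

    def pairs_frame(self) -> pd.DataFrame:
        """All pairs as a tidy frame (drug_id, icd10_3, relation), sorted."""
        rows = [
            (d, c, rel)
            for rel, mapping in (
                ("indication", self.indications),
                ("contraindication", self.contraindications),
            )
            for d, codes in sorted(mapping.items())
            for c in sorted(codes)
        ]
        return pd.DataFrame(rows, columns=["drug_id", "icd10_3", "relation"])


def _as_map(concept_map: Iterable[ConceptMapEntry] | Mapping[str, Iterable[str]]) -> dict[str, tuple[str, ...]]:
    if isinstance(concept_map, Mapping):
        return {k: tuple(v) for k, v in concept_map.items()}
    return {e.snomed_id: e.icd10_targets for e in concept_map}


def build_knowledge_base(
    drug_records: Iterable[DrugRecord],
    concept_pairs: Iterable[tuple[str, str, str]],
    concept_map: Iterable[ConceptMapEntry] | Mapping[str, Iterable[str]],
) -> KnowledgeBase:
    """Expand (drug, SNOMED concept, relation) rows into the knowledge base.

    Each concept expands to one pair per mapped ICD-10 target after
    3-character truncation; duplicates collapse.  Concept pairs whose
    snomed_id has no map entry are dropped and counted in ``kb.qc``.

    Raises
    ------
    IntegrityError
        if a concept pair references a drug_id absent from ``drug_records``.
    ValidationError
        for invalid relations, codes or approval years.
    """
    drugs: dict[str, DrugRecord] = {}
    for rec in drug_records:
        if rec.drug_id in drugs:
            raise ValidationError(f"duplicate drug_id {rec.drug_id!r}")
        drugs[rec.drug_id] = DrugRecord(
            rec.drug_id, normalize_ingredient(rec.ingredient_name), int(rec.approval_year)
        )
    if not drugs:
        raise ValidationError("drug_records must be non-empty")

    cmap = _as_map(concept_map)
    sets: dict[str, dict[str, set[str]]] = {r: {} for r in RELATIONS}
    n_dropped = 0
    dropped_ids: set[str] = set()
    n_input = 0
    for drug_id, snomed_id, relation in concept_pairs:
        n_input += 1
        if relation not in RELATIONS:
            raise ValidationError(f"unknown relation {relation!r}")
        if drug_id not in drugs:
            raise IntegrityError(
                f"concept pair references unknown drug_id {drug_id!r}"
            )
        targets = cmap.get(snomed_id)
        if targets is None:
            n_dropped += 1
            dropped_ids.add(snomed_id)
            continue
        bucket = sets[relation].setdefault(drug_id, set())
        for code in targets:
            bucket.add(truncate_icd10(code))

    indications = {d: frozenset(s) for d, s in sets["indication"].items() if s}
    contraindications = {
        d: frozenset(s) for d, s in sets["contraindication"].items() if s
    }
    qc = {
        "n_drugs": len(drugs),
        "n_concept_pairs_in": n_input,
        "n_concept_pairs_dropped_unmapped": n_dropped,
        "dropped_snomed_ids": sorted(dropped_ids),
        "n_indication_pairs": sum(len(s) for s in indications.values()),
        "n_contraindication_pairs": sum(len(s) for s in contraindications.values()),
        "n_drugs_with_indications": len(indications),
        "n_drugs_with_contraindications": len(contraindications),
    }
    return KnowledgeBase(drugs, indications, contraindications, qc)


def lookup(kb: KnowledgeBase, drug_id: str, relation: str) -> frozenset[str]:
    """The set of 3-character codes paired with ``drug_id`` under ``relation``."""
    if relation not in RELATIONS:
        raise ValidationError(f"unknown relation {relation!r}")
    if drug_id not in kb.drugs:
        raise KeyError(f"unknown drug_id {drug_id!r}")
    mapping = kb.indications if relation == "indication" else kb.contraindications
    return mapping.get(drug_id, frozenset())


# ---------------------------------------------------------------------------
# file I/O: tab- or comma-delimited with headers, dialect by extension

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_delimited(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_drugs(path: str | Path) -> list[DrugRecord]:
    df = read_delimited(path, ("drug_id", "ingredient_name", "approval_year"))
    return [
        DrugRecord(r.drug_id, r.ingredient_name, int(r.approval_year))
        for r in df.itertuples()
    ]


def read_concept_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    df = read_delimited(path, ("drug_id", "snomed_id", "relation"))
    return list(df[["drug_id", "snomed_id", "relation"]].itertuples(index=False, name=None))


def read_concept_map(path: str | Path) -> list[ConceptMapEntry]:
    """Read (snomed_id, icd10_code) rows, grouping targets per concept."""
    df = read_delimited(path, ("snomed_id", "icd10_code"))
    grouped = df.groupby("snomed_id", sort=True)["icd10_code"].apply(tuple)
    return [ConceptMapEntry(sid, targets) for sid, targets in grouped.items()]


def write_knowledge_base(kb: KnowledgeBase, pairs_path: str | Path,
                         qc_path: str | Path | None = None) -> None:
    """Write the canonical one-pair-per-row file and (optionally) the QC JSON."""
    kb.pairs_frame().to_csv(pairs_path, sep=_sep_for(pairs_path), index=False)
    if qc_path is not None:
        Path(qc_path).write_text(json.dumps(kb.qc, indent=2, sort_keys=True))


def load_knowledge_base(pairs_path: str | Path, drugs_path: str | Path) -> KnowledgeBase:
    """Rebuild a KnowledgeBase from the canonical pair file plus a drug table."""
    drugs = read_drugs(drugs_path)
    df = read_delimited(pairs_path, ("drug_id", "icd10_3", "relation"))
    # identity concept map: each category code maps to itself
    pairs = [
        (r.drug_id, f"_cat_{r.icd10_3}", r.relation) for r in df.itertuples()
    ]
    cmap = {f"_cat_{c}": (c,) for c in df["icd10_3"].unique()}
    return build_knowledge_base(drugs, pairs, cmap)
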