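"""Household-survey data model: persons, conditions, prescriptions, links.

Mirrors the four-file layout of MEPS-style public use data:

* a full-year consolidated **person** file (demographics, insurance, health
  status and utilisation outcomes, survey weight),
* a medical **conditions** file (one row per reported condition, ICD-10-CM
  coded; a condition is *current* when it was linked to an event during the
  survey year),
* a **prescriptions** (prescribed-medicine events) file — one row per fill
  event, carrying the drug and its therapeutic class,
* a **links** appendix joining prescription events to the condition records
  that motivated them.

Readers accept delimited text with a header row; source column names are
remapped to the canonical names below through a schema config, so real
survey exports (RXRECIDX, ICD10CDX, CONDIDX, ...) can be ingested without
code changes.  All referential integrity is validated on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, Field

from .errors import IntegrityError, SchemaError, ValidationError
from .knowledge_base import ICD10_CATEGORY_PATTERN

__all__ = [
    "BINARY_OUTCOMES",
    "COUNT_OUTCOMES",
    "EDUCATION_LEVELS",
    "RACE_LEVELS",
    "PERSON_COLUMNS",
    "CONDITION_COLUMNS",
    "PRESCRIPTION_COLUMNS",
    "LINK_COLUMNS",
    "SurveySchema",
    "SurveyDataset",
    "read_survey",
    "write_survey",
    "linked_condition_codes",
    "person_condition_codes",
]

#: 0/1 health-status outcomes carried on the person file
BINARY_OUTCOMES = (
    "ANYLMT", "ACTLIM31", "UNABLE31", "WLKLIM31", "WRKLIM31",
    "SCHLIM31", "HSELIM31", "SOCLIM31", "COGLIM31",
)
#: non-negative integer utilisation outcomes (inpatient discharges,
#: emergency-room visits, office-based visits)
COUNT_OUTCOMES = ("ipdis", "ertot", "obtotv")

EDUCATION_LEVELS = ("missing", "0-11", "12", "13+", "18+")
RACE_LEVELS = ("White", "Black", "American Indian-Alaska", "Asian", "Multiple")
SEX_LEVELS = ("male", "female")

PERSON_COLUMNS = (
    ("person_id", "year", "sex", "age", "education", "race",
     "medicare", "medicaid", "weight", "total_expenditure")
    + COUNT_OUTCOMES + BINARY_OUTCOMES
)
CONDITION_COLUMNS = ("condition_id", "person_id", "year", "icd10_3", "is_current")
PRESCRIPTION_COLUMNS = ("rx_id", "person_id", "year", "drug_id",
                        "therapeutic_class", "ndc")
LINK_COLUMNS = ("rx_id", "condition_id")


class SurveySchema(BaseModel):
    """Maps canonical field names to source column names per file.

    Only entries that differ from the canonical name need to be given, e.g.
    ``SurveySchema(conditions={"icd10_3": "ICD10CDX"})``.
    """

    persons: dict[str, str] = Field(default_factory=dict)
    conditions: dict[str, str] = Field(default_factory=dict)
    prescriptions: dict[str, str] = Field(default_factory=dict)
    links: dict[str, str] = Field(default_factory=dict)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path: str | Path, canonical: tuple[str, ...],
                rename: Mapping[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), keep_default_na=False,
                     na_values=[""], dtype={rename.get(c, c): str for c in
                                            ("person_id", "condition_id", "rx_id",
                                             "drug_id", "ndc", "therapeutic_class",
                                             "icd10_3", "sex", "education", "race")
                                            if rename.get(c, c)})
    source_to_canonical = {src: canon for canon, src in rename.items()}
    df = df.rename(columns=source_to_canonical)
    missing = [c for c in canonical if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df[list(canonical)]


def _bad_rows(msg: str, idx) -> str:
    rows = ", ".join(str(i) for i in list(idx)[:10])
    more = "" if len(idx) <= 10 else f" (+{len(idx) - 10} more)"
    return f"{msg} at rows [{rows}]{more}"


@dataclass
class SurveyDataset:
    """The four survey tables with validated referential integrity."""

    persons: pd.DataFrame
    conditions: pd.DataFrame
    prescriptions: pd.DataFrame
    links: pd.DataFrame
    _person_codes_cache: dict = field(default_factory=dict, repr=False)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "SurveyDataset":
        p, c, rx, lk = self.persons, self.conditions, self.prescriptions, self.links

        dup = p.duplicated(["person_id", "year"])
        if dup.any():
            raise ValidationError(_bad_rows("duplicate (person_id, year)", p.index[dup]))
        if (p["age"].astype(int) < 0).any():
            raise ValidationError("negative age in person file")
        if (p["weight"].astype(float) < 0).any():
            raise ValidationError("negative survey weight in person file")
        for col in BINARY_OUTCOMES + ("medicare", "medicaid"):
            bad = ~p[col].astype(int).isin([0, 1])
            if bad.any():
                raise ValidationError(_bad_rows(f"non-binary {col}", p.index[bad]))
        for col, levels in (("sex", SEX_LEVELS), ("education", EDUCATION_LEVELS),
                            ("race", RACE_LEVELS)):
            bad = ~p[col].isin(levels)
            if bad.any():
                raise ValidationError(_bad_rows(f"invalid {col} category", p.index[bad]))

        if c["condition_id"].duplicated().any():
            raise ValidationError("duplicate condition_id")
        bad = ~c["icd10_3"].str.match(ICD10_CATEGORY_PATTERN)
        if bad.any():
            raise ValidationError(_bad_rows("invalid icd10_3 code", c.index[bad]))

        if rx["rx_id"].duplicated().any():
            raise ValidationError("duplicate rx_id")

        person_keys = set(zip(p["person_id"], p["year"].astype(int)))
        for name, tbl in (("conditions", c), ("prescriptions", rx)):
            keys = list(zip(tbl["person_id"], tbl["year"].astype(int)))
            orphans = [k for k in set(keys) if k not in person_keys]
            if orphans:
                raise IntegrityError(
                    f"{name} reference unknown (person_id, year): {sorted(orphans)[:10]}"
                )

        rx_ids = set(rx["rx_id"])
        cond_ids = set(c["condition_id"])
        bad_rx = sorted(set(lk["rx_id"]) - rx_ids)
        if bad_rx:
            raise IntegrityError(f"links reference unknown rx_id: {bad_rx[:10]}")
        bad_cond = sorted(set(lk["condition_id"]) - cond_ids)
        if bad_cond:
            raise IntegrityError(f"links reference unknown condition_id: {bad_cond[:10]}")

        # link endpoints must share person-year
        merged = lk.merge(rx[["rx_id", "person_id", "year"]], on="rx_id").merge(
            c[["condition_id", "person_id", "year"]], on="condition_id",
            suffixes=("_rx", "_cond"))
        mismatch = (merged["person_id_rx"] != merged["person_id_cond"]) | (
            merged["year_rx"].astype(int) != merged["year_cond"].astype(int))
        if mismatch.any():
            bad = merged.loc[mismatch, ["rx_id", "condition_id"]].head(10)
            raise IntegrityError(
                f"link endpoints belong to different person-years: {bad.to_dict('records')}"
            )
        return self

    # -- fast lookup maps used by the classifier ----------------------------
    def person_codes_map(self, current_only: bool = True) -> dict[tuple[str, int], frozenset[str]]:
        """(person_id, year) -> set of distinct 3-character condition codes."""
        key = bool(current_only)
        if key not in self._person_codes_cache:
            c = self.conditions
            if current_only:
                c = c[c["is_current"].astype(int) == 1]
            grouped = c.groupby(["person_id", "year"])["icd10_3"].agg(frozenset)
            self._person_codes_cache[key] = {
                (pid, int(yr)): codes for (pid, yr), codes in grouped.items()
            }
        return self._person_codes_cache[key]

    def rx_linked_map(self) -> dict[str, frozenset[str]]:
        """rx_id -> set of 3-character codes of conditions linked to it."""
        merged = self.links.merge(
            self.conditions[["condition_id", "icd10_3"]], on="condition_id"
        )
        grouped = merged.groupby("rx_id")["icd10_3"].agg(frozenset)
        return dict(grouped.items())


def linked_condition_codes(ds: SurveyDataset, rx_id: str) -> frozenset[str]:
    """Codes of the conditions linked to one prescription event."""
    if rx_id not in set(ds.prescriptions["rx_id"]):
        raise KeyError(f"unknown rx_id {rx_id!r}")
    return ds.rx_linked_map().get(rx_id, frozenset())


def person_condition_codes(ds: SurveyDataset, person_id: str, year: int,
                           current_only: bool = True) -> frozenset[str]:
    """Distinct condition codes recorded for a person-year."""
    key = (person_id, int(year))
    persons = set(zip(ds.persons["person_id"], ds.persons["year"].astype(int)))
    if key not in persons:
        raise KeyError(f"unknown person-year {key!r}")
    return ds.person_codes_map(current_only).get(key, frozenset())


def read_survey(paths: Mapping[str, str | Path],
                schema: SurveySchema | None = None) -> SurveyDataset:
    """Read and validate the four survey files.

    ``paths`` must contain keys ``persons``, ``conditions``, ``prescriptions``
    and ``links``.
    """
    schema = schema or SurveySchema()
    missing = [k for k in ("persons", "conditions", "prescriptions", "links")
               if k not in paths]
    if missing:
        raise SchemaError(f"paths missing entries for {missing}")
    persons = _read_table(paths["persons"], PERSON_COLUMNS, schema.persons)
    conditions = _read_table(paths["conditions"], CONDITION_COLUMNS, schema.conditions)
    prescriptions = _read_table(paths["prescriptions"], PRESCRIPTION_COLUMNS,
                                schema.prescriptions)
    links = _read_table(paths["links"], LINK_COLUMNS, schema.links)

    # typed columns
    persons = persons.astype({"year": int, "age": int, "medicare": int,
                              "medicaid": int, "weight": float,
                              "total_expenditure": float,
                              **{c: int for c in COUNT_OUTCOMES},
                              **{c: int for c in BINARY_OUTCOMES}})
    conditions = conditions.astype({"year": int, "is_current": int})
    prescriptions = prescriptions.astype({"year": int})
    prescriptions["therapeutic_class"] = prescriptions["therapeutic_class"].fillna("")
    prescriptions["ndc"] = prescriptions["ndc"].fillna("")
    return SurveyDataset(persons, conditions, prescriptions, links).validate()


def write_survey(ds: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV; returns the path map ``read_survey`` takes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, tbl, cols in (
        ("persons", ds.persons, PERSON_COLUMNS),
        ("conditions", ds.conditions, CONDITION_COLUMNS),
        ("prescriptions", ds.prescriptions, PRESCRIPTION_COLUMNS),
        ("links", ds.links, LINK_COLUMNS),
    ):
        path = out / f"{name}.csv"
        tbl[list(cols)].to_csv(path, index=False)
        paths[name] = path
    return paths
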