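"""Registry case-listing ingest: parsing, eligibility filters, stratifiers.

Reads SEER*Stat-style case-listing CSV exports into :class:`PatientRecord`
objects, applies the eligibility rules used for registry survival work
(adults over 15, first and only primary, no autopsy/death-certificate-only
cases, complete records, no alive cases without a survival time), groups
histology codes into lymphoma subtypes, and partitions cohorts into the
analysis strata (sex, race, age group, subtype, nodal/extranodal,
rural/urban).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Iterable

import pandas as pd
import yaml

# -- domain types ---------------------------------------------------------


@dataclass
class PatientRecord:
    """One registry case."""

    id: str
    sex: str  # 'male' | 'female'
    race: str
    age_dx: int | None
    dx_year: int | None
    dx_month: int | None  # 1..12, None if unknown
    survival_months: int | None  # censoring time when alive
    vital_status: str | None  # 'dead' | 'alive'
    histology: int | None = None  # 4-digit ICD-O-3 morphology
    behavior: int | None = 3
    site: str | None = None  # ICD-O-3 topography, e.g. 'C770'
    nodal: str | None = None  # 'nodal' | 'extranodal' (may be derived)
    area: str | None = None  # 'rural' | 'urban'
    autopsy_or_dco: bool = False
    sequence: int | None = 0  # 0 = one primary only

    @property
    def dx_date(self) -> float | None:
        """Diagnosis date as a decimal year, dated mid-month."""
        if self.dx_year is None:
            return None
        if self.dx_month is None:
            return self.dx_year + 0.5
        return self.dx_year + (self.dx_month - 0.5) / 12.0


@dataclass
class RowParseError:
    row: int
    message: str


@dataclass
class ParseResult:
    records: list[PatientRecord]
    errors: list[RowParseError] = field(default_factory=list)


@dataclass
class FilterReport:
    """Accounting of eligibility filtering; reasons partition exclusions."""

    n_input: int
    n_kept: int
    exclusions: dict[str, int]
    reasons: dict[str, str]  # record id -> reason

    def to_dict(self) -> dict:
        return asdict(self)


class SchemaError(ValueError):
    pass


class ClassificationError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# -- defaults -------------------------------------------------------------

DEFAULT_CASE_SCHEMA = {
    "id": "id",
    "sex": "sex",
    "race": "race",
    "age_dx": "age_dx",
    "dx_year": "dx_year",
    "dx_month": "dx_month",
    "survival_months": "survival_months",
    "vital_status": "vital_status",
    "histology": "histology",
    "behavior": "behavior",
    "site": "site",
    "nodal": "nodal",
    "area": "area",
    "autopsy_or_dco": "autopsy_or_dco",
    "sequence": "sequence",
}

REQUIRED_LOGICAL = ["id", "sex", "race", "age_dx", "dx_year",
                    "survival_months", "vital_status"]

#: Age-group bins: label -> [low, high) on age at diagnosis.
DEFAULT_AGE_BINS = [
    ("15-44", 16, 45),
    ("45-54", 45, 55),
    ("55-64", 55, 65),
    ("65-74", 65, 75),
    ("75+", 75, 200),
]

SEX_VALUES = {"male": "male", "m": "male", "1": "male",
              "female": "female", "f": "female", "2": "female"}
VITAL_VALUES = {"dead": "dead", "0": "dead", "alive": "alive", "1": "alive"}


def _load_default_maps() -> dict:
    src = importlib.resources.files("periodsurv.data").joinpath("icdo3_maps.yaml")
    return yaml.safe_load(src.read_text())


_MAPS = _load_default_maps()


def default_subtype_map() -> dict[int, str]:
    """Shipped morphology-code -> subtype-label table (editable config)."""
    return {int(code): label
            for label, codes in _MAPS["subtype_map"].items()
            for code in codes}


def default_nodal_sites() -> set[str]:
    return set(_MAPS["nodal_sites"])


# -- parsing --------------------------------------------------------------

def _opt_int(value, what: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return None
    try:
        return int(float(s)) if float(s) == int(float(s)) else int(s)
    except ValueError:
        raise ValueError(f"unparseable {what}: {value!r}") from None


def read_case_listing(path, schema: dict[str, str] | None = None) -> ParseResult:
    """Parse a case-listing CSV into records, collecting bad rows.

    ``schema`` maps logical field names to the file's column headers.
    Rows whose values cannot be interpreted (e.g. survival time
    ``"unknown"``, a sex outside the vocabulary) are recorded as
    :class:`RowParseError`, never silently dropped.  Missing (blank)
    optional values are allowed and surface later as incompleteness in
    the filter step.
    """
    schema = {**DEFAULT_CASE_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str)
    missing = [schema[k] for k in REQUIRED_LOGICAL if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"case listing lacks required columns {missing}")

    def get(row, logical):
        col = schema.get(logical)
        if col is None or col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        v = str(v).strip()
        return v if v != "" else None

    records: list[PatientRecord] = []
    errors: list[RowParseError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            sex_raw = get(row, "sex")
            if sex_raw is not None and sex_raw.lower() not in SEX_VALUES:
                raise ValueError(f"sex outside vocabulary: {sex_raw!r}")
            vital_raw = get(row, "vital_status")
            if vital_raw is not None and vital_raw.lower() not in VITAL_VALUES:
                raise ValueError(f"vital status outside vocabulary: {vital_raw!r}")
            rec = PatientRecord(
                id=get(row, "id") or f"row{i}",
                sex=SEX_VALUES.get((sex_raw or "").lower(), None),
                race=get(row, "race"),
                age_dx=_opt_int(get(row, "age_dx"), "age"),
                dx_year=_opt_int(get(row, "dx_year"), "diagnosis year"),
                dx_month=_opt_int(get(row, "dx_month"), "diagnosis month"),
                survival_months=_opt_int(get(row, "survival_months"),
                                         "survival months"),
                vital_status=VITAL_VALUES.get((vital_raw or "").lower(), None),
                histology=_opt_int(get(row, "histology"), "histology"),
                behavior=_opt_int(get(row, "behavior"), "behavior"),
                site=get(row, "site"),
                nodal=get(row, "nodal"),
                area=get(row, "area"),
                autopsy_or_dco=(get(row, "autopsy_or_dco") or "").lower()
                in {"1", "true", "yes"},
                sequence=_opt_int(get(row, "sequence"), "sequence"),
            )
            sm = rec.survival_months
            if sm is not None and sm < 0:
                raise ValueError(f"negative survival months: {sm}")
            records.append(rec)
        except ValueError as exc:
            errors.append(RowParseError(row=i, message=str(exc)))
    return ParseResult(records=records, errors=errors)


# -- eligibility filters ---------------------------------------------------

# Exclusion reasons in precedence order: a record failing several criteria
# is counted once, under the first that fires.
EXCLUSION_PRECEDENCE = (
    "autopsy_or_dco",
    "age_le_15",
    "multiple_primary",
    "incomplete",
    "alive_no_survival",
)


def _exclusion_reason(rec: PatientRecord) -> str | None:
    if rec.autopsy_or_dco:
        return "autopsy_or_dco"
    if rec.age_dx is None or rec.age_dx <= 15:
        # missing age is also incomplete, but age cannot be verified >15
        if rec.age_dx is not None:
            return "age_le_15"
    if rec.sequence is None or rec.sequence != 0:
        return "multiple_primary"
    for fieldname in ("sex", "race", "age_dx", "dx_year", "vital_status"):
        if getattr(rec, fieldname) is None:
            return "incomplete"
    if rec.vital_status == "dead" and rec.survival_months is None:
        return "incomplete"
    if rec.vital_status == "alive" and rec.survival_months is None:
        return "alive_no_survival"
    return None


def apply_inclusion_filters(
    records: Iterable[PatientRecord], config=None
) -> tuple[list[PatientRecord], FilterReport]:
    """Apply eligibility criteria; total (never raises on a record).

    Kept records are adults over 15 at diagnosis, first-and-only primaries,
    not known from autopsy or death certificate alone, with all required
    fields present, and not alive without a recorded survival time.
    """
    records = list(records)
    kept: list[PatientRecord] = []
    exclusions: dict[str, int] = {}
    reasons: dict[str, str] = {}
    for rec in records:
        reason = _exclusion_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            exclusions[reason] = exclusions.get(reason, 0) + 1
            reasons[rec.id] = reason
    report = FilterReport(
        n_input=len(records), n_kept=len(kept),
        exclusions=exclusions, reasons=reasons,
    )
    assert report.n_input == report.n_kept + sum(exclusions.values())
    return kept, report


# -- classification and stratification ------------------------------------

def classify_subtype(
    record: PatientRecord, subtype_map: dict[int, str] | None = None
) -> str:
    """Map an ICD-O-3 morphology code to a lymphoma subtype label.

    Unmapped malignant codes return ``"other"``; a non-malignant behaviour
    digit is an error (such records should never reach survival analysis).
    """
    if record.behavior is not None and record.behavior != 3:
        raise ClassificationError(
            f"record {record.id}: behaviour /{record.behavior} is not malignant"
        )
    subtype_map = subtype_map if subtype_map is not None else default_subtype_map()
    return subtype_map.get(record.histology, "other")


def assign_age_group(age_dx: int, bins=None) -> str:
    """Label of the half-open age bin [low, high) containing ``age_dx``."""
    bins = bins if bins is not None else DEFAULT_AGE_BINS
    if age_dx < bins[0][1]:
        raise ValueError(f"age {age_dx} below first age-group bound {bins[0][1]}")
    for label, lo, hi in bins:
        if lo <= age_dx < hi:
            return label
    return bins[-1][0]  # open-ended top bin


def classify_nodal(record: PatientRecord, nodal_sites: set[str] | None = None) -> str:
    """Nodal/extranodal: precomputed column when present, else by topography."""
    if record.nodal in ("nodal", "extranodal"):
        return record.nodal
    sites = nodal_sites if nodal_sites is not None else default_nodal_sites()
    return "nodal" if (record.site or "").upper() in sites else "extranodal"


_STRATIFIERS = {
    "overall": lambda r: "overall",
    "sex": lambda r: r.sex,
    "race": lambda r: r.race,
    "age_group": lambda r: assign_age_group(r.age_dx),
    "subtype": lambda r: classify_subtype(r),
    "nodal": classify_nodal,
    "area": lambda r: r.area,
}


def stratify_cohort(
    records: Iterable[PatientRecord], by: list[str]
) -> dict[tuple[str, ...] | str, list[PatientRecord]]:
    """Partition records by the cross-classification of the stratifiers."""
    unknown = [s for s in by if s not in _STRATIFIERS]
    if unknown:
        raise ConfigError(
            f"unknown stratifier(s) {unknown}; valid: {sorted(_STRATIFIERS)}"
        )
    out: dict = {}
    for rec in records:
        key = tuple(_STRATIFIERS[s](rec) for s in by)
        if len(by) == 1:
            key = key[0]
        out.setdefault(key, []).append(rec)
    return out


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Columnar view of a cohort, the survival engine's fast path."""
    return pd.DataFrame([asdict(r) for r in records])
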