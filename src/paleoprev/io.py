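"""Readers, record types, validation, and record filters.

Two delimited-text inputs drive the analysis:

* a parasitism-occurrence table: one row per species-level host occurrence
  showing evidence of parasitism, with a certainty category (1–4), the
  number of specimens examined and infested (when reported), a best age
  estimate, and period/era context;
* a genus-occurrence table in Paleobiology Database export style
  (``genus, class, collection_no, max_ma, min_ma, reference_no``).

Both readers return typed records plus a row-level :class:`ValidationReport`;
rows violating hard invariants (infested > examined, unknown certainty
category, age outside the stated period, empty genus, unparseable ages)
are rejected and listed rather than silently dropped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .timescale import Timescale, load_timescale

log = logging.getLogger(__name__)

PARASITISM_COLUMNS = (
    "record_id",
    "host_taxon",
    "host_phylum",
    "host_class",
    "parasite_phylum",
    "certainty",
    "n_specimens",
    "n_infested",
    "best_age_ma",
    "period",
    "era",
    "reference_id",
)

OCCURRENCE_COLUMNS = ("genus", "collection_no", "max_ma", "min_ma")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class ParasitismOccurrence:
    """One species-level host occurrence attributed to parasitism.

    ``n_specimens``/``n_infested`` are ``None`` when the source did not
    report sample sizes; such records stay in occurrence counts but are
    never prevalence-eligible.
    """

    record_id: str
    host_taxon: str
    host_phylum: str
    host_class: str
    parasite_phylum: str
    certainty: int
    n_specimens: int | None
    n_infested: int | None
    best_age_ma: float
    period: str
    era: str
    reference_id: str


@dataclass(frozen=True)
class GenusOccurrence:
    """One genus-level occurrence from a PBDB-style export.

    ``period`` is filled when the [min_ma, max_ma] range lies within a
    single period; occurrences spanning a period boundary are flagged
    ``age_ambiguous`` and excluded from per-period bins by default.
    """

    genus: str
    host_class: str
    collection_id: str
    max_ma: float
    min_ma: float
    reference_id: str
    period: str | None = None
    age_ambiguous: bool = False


@dataclass
class ValidationIssue:
    row: int
    field: str
    message: str


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_accepted: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_accepted

    def add(self, row: int, field_name: str, message: str) -> None:
        self.issues.append(ValidationIssue(row, field_name, message))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.row, i.field, i.message) for i in self.issues],
            columns=["row", "field", "message"],
        )


def _opt_count(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return int(value)


def read_parasitism_table(
    path, timescale: Timescale | None = None
) -> tuple[list[ParasitismOccurrence], ValidationReport]:
    """Read and validate a parasitism-occurrence CSV/TSV.

    Returns the accepted records and a validation report.  Rejected rows
    (infested > examined, certainty outside 1–4, negative counts, best age
    outside the stated period's bounds, unknown period, era mismatch) are
    listed in the report with the offending field.
    """
    ts = timescale or load_timescale()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PARASITISM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows=len(df))
    records: list[ParasitismOccurrence] = []
    for idx, row in df.iterrows():
        try:
            certainty = int(row["certainty"])
        except (TypeError, ValueError):
            report.add(idx, "certainty", f"unparseable certainty {row['certainty']!r}")
            continue
        if certainty not in (1, 2, 3, 4):
            report.add(idx, "certainty", f"certainty {certainty} not in 1-4")
            continue
        try:
            n = _opt_count(row["n_specimens"])
            k = _opt_count(row["n_infested"])
        except (TypeError, ValueError):
            report.add(idx, "n_specimens", "unparseable specimen counts")
            continue
        if (n is not None and n < 0) or (k is not None and k < 0):
            report.add(idx, "n_specimens", "negative specimen count")
            continue
        if n is not None and k is not None and k > n:
            report.add(
                idx, "n_infested", f"n_infested={k} exceeds n_specimens={n}"
            )
            continue
        try:
            age = float(row["best_age_ma"])
        except (TypeError, ValueError):
            report.add(idx, "best_age_ma", f"unparseable age {row['best_age_ma']!r}")
            continue
        period_name = str(row["period"])
        try:
            period = ts.period(period_name)
        except KeyError:
            report.add(idx, "period", f"unknown period {period_name!r}")
            continue
        if not period.contains(age):
            report.add(
                idx,
                "best_age_ma",
                f"age {age} Ma outside {period_name} "
                f"[{period.min_ma}, {period.max_ma}]",
            )
            continue
        if str(row["era"]) != period.era:
            report.add(idx, "era", f"era {row['era']!r} does not match {period_name}")
            continue
        records.append(
            ParasitismOccurrence(
                record_id=str(row["record_id"]),
                host_taxon=str(row["host_taxon"]),
                host_phylum=str(row["host_phylum"]),
                host_class=str(row["host_class"]),
                parasite_phylum=str(row["parasite_phylum"]),
                certainty=certainty,
                n_specimens=n,
                n_infested=k,
                best_age_ma=age,
                period=period_name,
                era=period.era,
                reference_id=str(row["reference_id"]),
            )
        )
    report.n_accepted = len(records)
    if report.n_rejected:
        log.info(
            "read_parasitism_table: rejected %d of %d rows",
            report.n_rejected,
            report.n_rows,
        )
    return records, report


def _assign_period(
    ts: Timescale, max_ma: float, min_ma: float
) -> tuple[str | None, bool]:
    """Unique containing period, or (None, True) when the range spans a boundary."""
    for p in ts.periods:
        if p.max_ma >= max_ma and p.min_ma <= min_ma:
            return p.name, False
    return None, True


def read_occurrence_table(
    path, timescale: Timescale | None = None
) -> tuple[list[GenusOccurrence], ValidationReport]:
    """Read a PBDB-style genus occurrence CSV.

    Each occurrence is assigned to a period when its [min_ma, max_ma]
    range lies within one; ranges crossing a period boundary are flagged
    age-ambiguous.  Extra columns are ignored.
    """
    ts = timescale or load_timescale()
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows=len(df))
    records: list[GenusOccurrence] = []
    for idx, row in df.iterrows():
        genus = str(row["genus"]).strip()
        if not genus or genus.lower() == "nan":
            report.add(idx, "genus", "empty genus")
            continue
        max_ma = pd.to_numeric(row["max_ma"], errors="coerce")
        min_ma = pd.to_numeric(row["min_ma"], errors="coerce")
        if pd.isna(max_ma) or pd.isna(min_ma):
            report.add(idx, "max_ma", "unparseable age bounds")
            continue
        if max_ma < min_ma:
            report.add(idx, "max_ma", f"max_ma={max_ma} < min_ma={min_ma}")
            continue
        period, ambiguous = _assign_period(ts, float(max_ma), float(min_ma))
        records.append(
            GenusOccurrence(
                genus=genus,
                host_class=str(row.get("class", "")),
                collection_id=str(row["collection_no"]),
                max_ma=float(max_ma),
                min_ma=float(min_ma),
                reference_id=str(row.get("reference_no", "")),
                period=period,
                age_ambiguous=ambiguous,
            )
        )
    report.n_accepted = len(records)
    n_ambiguous = sum(r.age_ambiguous for r in records)
    if n_ambiguous:
        log.info(
            "read_occurrence_table: %d of %d occurrences span a period "
            "boundary and are excluded from per-period bins",
            n_ambiguous,
            len(records),
        )
    return records, report


def filter_analytical(
    records: list[ParasitismOccurrence],
) -> list[ParasitismOccurrence]:
    """Keep certainty categories 1–3; category 4 (ambiguous) is excluded.

    Idempotent; the number of removed records is logged.
    """
    kept = [r for r in records if r.certainty <= 3]
    removed = len(records) - len(kept)
    if removed:
        log.info("filter_analytical: removed %d category-4 records", removed)
    if not kept:
        warnings.warn("filter_analytical: no analytical records remain", stacklevel=2)
    return kept


def select_prevalence_eligible(
    records: list[ParasitismOccurrence], min_n: int = 10
) -> list[ParasitismOccurrence]:
    """Records with a reported sample of at least ``min_n`` specimens.

    ``min_n`` defaults to 10; 20 is the robustness setting.  Both the
    specimen count and the infested count must be present.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return [
        r
        for r in records
        if r.n_specimens is not None
        and r.n_infested is not None
        and r.n_specimens >= min_n
    ]


def parasitism_to_frame(records: list[ParasitismOccurrence]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=PARASITISM_COLUMNS)


def occurrences_to_frame(records: list[GenusOccurrence]) -> pd.DataFrame:
    cols = [
        "genus",
        "host_class",
        "collection_id",
        "max_ma",
        "min_ma",
        "reference_id",
        "period",
        "age_ambiguous",
    ]
    return pd.DataFrame([r.__dict__ for r in records], columns=cols)
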