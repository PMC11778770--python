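"""Domain types shared by all modules: patient records, clinic populations,
precision levels, ingestion and eligibility rules.

The unit of estimation is one person's extracted fields at their most recent
clinic visit inside a 12-month observation window. A clinic population is the
deduplicated, in-window collection of such records; eligibility restricts it
to adults (>= 18 completed years at the visit) who were not known to have died
before the window opened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger("estihiv")

DATE_FORMAT = "%Y-%m-%d"

#: Header of the patient-level CSV interchange format. Empty string = missing.
CSV_COLUMNS = [
    "patient_id",
    "date_of_birth",
    "gender",
    "country_of_origin",
    "transmission_group",
    "last_cd4",
    "last_cd4_date",
    "last_vl",
    "last_vl_date",
    "on_art",
    "art_status_date",
    "hiv_diagnosis_date",
    "first_visit_date",
    "last_visit_date",
    "death_date",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class EstihivError(Exception):
    """Base class for all package errors."""


class DomainError(EstihivError, ValueError):
    """A parameter is outside its mathematical or epidemiological domain."""


class RecordValidationError(EstihivError, ValueError):
    """One or more input rows failed validation; carries the row numbers."""

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        rows = ", ".join(str(r) for r, _ in self.problems[:10])
        suffix = " ..." if len(self.problems) > 10 else ""
        super().__init__(
            f"{len(self.problems)} invalid record(s) at row(s) {rows}{suffix}: "
            + "; ".join(f"row {r}: {msg}" for r, msg in self.problems[:5])
        )


class EmptyPopulationError(EstihivError, ValueError):
    """No eligible/in-window records remain."""


# ---------------------------------------------------------------------------
# Categories
# ---------------------------------------------------------------------------

class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"
    NON_MALE_FEMALE = "non-male/-female"
    UNKNOWN = "unknown"


class TransmissionGroup(str, Enum):
    MSM = "MSM"
    HETEROSEXUAL = "heterosexual"
    IDU = "IDU"
    OTHER = "other"
    UNKNOWN = "unknown"


class ArtStatus(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class PrecisionCategory(str, Enum):
    VERY_HIGH = "very_high"
    HIGH = "high"
    MODERATE = "moderate"


def _normalize_category(value: str, enum_cls, row: Optional[int] = None):
    """Case-insensitive match of a free-text label onto a category enum.

    Unrecognized or empty labels map to the enum's UNKNOWN member, with a log
    line so silent coercions are auditable.
    """
    text = (value or "").strip()
    if not text:
        return enum_cls.UNKNOWN
    for member in enum_cls:
        if member.value.lower() == text.lower():
            if member.value != text:
                logger.debug("normalized %r -> %r (row %s)", text, member.value, row)
            return member
    logger.warning("unrecognized %s label %r -> unknown (row %s)",
                   enum_cls.__name__, text, row)
    return enum_cls.UNKNOWN


@dataclass(frozen=True)
class PrecisionLevel:
    """A named accuracy level and its confidence-interval half-width ``e``.

    ``e`` is an absolute half-width on the 0-1 scale (0.05 = +/- 5 percentage
    points around the estimate).
    """

    level: PrecisionCategory
    e: float

    def __post_init__(self):
        if not 0.0 < self.e < 0.5:
            raise DomainError(f"precision half-width e must be in (0, 0.5), got {self.e}")


# ---------------------------------------------------------------------------
# Records and populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One person's extracted fields at their most recent clinic visit."""

    patient_id: str
    last_visit_date: date
    date_of_birth: Optional[date] = None
    gender: Gender = Gender.UNKNOWN
    country_of_origin: Optional[str] = None
    transmission_group: TransmissionGroup = TransmissionGroup.UNKNOWN
    last_cd4: Optional[int] = None
    last_cd4_date: Optional[date] = None
    last_vl: Optional[int] = None
    last_vl_date: Optional[date] = None
    on_art: ArtStatus = ArtStatus.UNKNOWN
    art_status_date: Optional[date] = None
    hiv_diagnosis_date: Optional[date] = None
    first_visit_date: Optional[date] = None
    death_date: Optional[date] = None

    def __post_init__(self):
        if self.last_visit_date is None:
            raise DomainError("last_visit_date is required")
        if self.last_cd4 is not None and self.last_cd4 < 0:
            raise DomainError(f"negative CD4 count: {self.last_cd4}")
        if self.last_vl is not None and self.last_vl < 0:
            raise DomainError(f"negative viral load: {self.last_vl}")
        if (self.death_date is not None and self.date_of_birth is not None
                and self.death_date < self.date_of_birth):
            raise DomainError("death_date precedes date_of_birth")

    def age_at(self, on: date) -> Optional[int]:
        """Completed years of age on a given date (birthday arithmetic).

        Returns None when date of birth is unknown.
        """
        dob = self.date_of_birth
        if dob is None:
            return None
        years = on.year - dob.year
        if (on.month, on.day) < (dob.month, dob.day):
            years -= 1
        return years


@dataclass(frozen=True)
class ClinicPopulation:
    """Deduplicated in-window patient records plus dataset-level settings.

    ``vs_threshold`` is the viral-load suppression cut-off in copies/ml
    (default <200; some settings use <500). ``lod`` optionally records an
    assay limit of detection at or above the threshold, under which
    "below LOD" values count as suppressed.
    """

    records: tuple[PatientRecord, ...]
    window_start: date
    window_end: date
    vs_threshold: int = 200
    lod: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        if self.window_start > self.window_end:
            raise DomainError("window_start must be <= window_end")
        if self.vs_threshold <= 0:
            raise DomainError("vs_threshold must be positive")
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise DomainError("duplicate patient_id in population")
        for r in self.records:
            if not self.window_start <= r.last_visit_date <= self.window_end:
                raise DomainError(
                    f"record {r.patient_id} visit {r.last_visit_date} outside window"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    def subset(self, ids: Iterable[str], label: str = "") -> "ClinicPopulation":
        """Population restricted to the given patient ids (order preserved
        from this population)."""
        wanted = set(ids)
        kept = tuple(r for r in self.records if r.patient_id in wanted)
        return replace(self, records=kept, label=label or self.label)


@dataclass(frozen=True)
class EligibilityResult:
    """Outcome of the eligibility filter: the kept population and per-reason
    exclusion counts (which partition the dropped records)."""

    population: ClinicPopulation
    exclusions: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def _parse_date(value, row: int, col: str, problems: list) -> Optional[date]:
    if value is None:
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    try:
        return date.fromisoformat(text)
    except ValueError:
        problems.append((row, f"malformed date in {col}: {text!r}"))
        return None


def _parse_count(value, row: int, col: str, problems: list) -> Optional[int]:
    if value is None:
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    try:
        n = int(float(text))
    except ValueError:
        problems.append((row, f"non-numeric {col}: {text!r}"))
        return None
    if n < 0:
        problems.append((row, f"negative {col}: {n}"))
        return None
    return n


RowsLike = Union[pd.DataFrame, Sequence[Mapping[str, object]]]


def ingest_records(
    rows: RowsLike,
    window: tuple[date, date],
    vs_threshold: int = 200,
    lod: Optional[int] = None,
    label: str = "",
) -> ClinicPopulation:
    """Build a :class:`ClinicPopulation` from tabular patient rows.

    Applies the most-recent-visit rule: multiple rows per patient_id collapse
    to the one with the latest last_visit_date (ties broken by later
    last_vl_date, then by input order). Rows whose visit falls outside the
    observation window are dropped with a logged count.

    Raises :class:`RecordValidationError` (collecting row numbers) on
    malformed dates or negative counts, and :class:`EmptyPopulationError`
    when nothing remains.
    """
    window_start, window_end = window
    if window_start > window_end:
        raise DomainError("window_start must be <= window_end")

    if isinstance(rows, pd.DataFrame):
        iterrows: Iterable[Mapping[str, object]] = (
            row._asdict() if hasattr(row, "_asdict") else dict(row)
            for row in rows.to_dict("records")
        )
    else:
        iterrows = rows

    problems: list[tuple[int, str]] = []
    parsed: list[PatientRecord] = []
    for i, raw in enumerate(iterrows, start=1):
        get = raw.get  # type: ignore[union-attr]
        pid = str(get("patient_id", "") or "").strip()
        if not pid:
            problems.append((i, "missing patient_id"))
            continue
        visit = _parse_date(get("last_visit_date"), i, "last_visit_date", problems)
        if visit is None:
            problems.append((i, "missing or malformed last_visit_date"))
            continue
        dob = _parse_date(get("date_of_birth"), i, "date_of_birth", problems)
        death = _parse_date(get("death_date"), i, "death_date", problems)
        if dob is not None and death is not None and death < dob:
            problems.append((i, "death_date precedes date_of_birth"))
            continue
        cd4 = _parse_count(get("last_cd4"), i, "last_cd4", problems)
        vl = _parse_count(get("last_vl"), i, "last_vl", problems)
        country = str(get("country_of_origin", "") or "").strip() or None
        record = PatientRecord(
            patient_id=pid,
            last_visit_date=visit,
            date_of_birth=dob,
            gender=_normalize_category(str(get("gender", "") or ""), Gender, i),
            country_of_origin=country,
            transmission_group=_normalize_category(
                str(get("transmission_group", "") or ""), TransmissionGroup, i),
            last_cd4=cd4,
            last_cd4_date=_parse_date(get("last_cd4_date"), i, "last_cd4_date", problems),
            last_vl=vl,
            last_vl_date=_parse_date(get("last_vl_date"), i, "last_vl_date", problems),
            on_art=_normalize_category(str(get("on_art", "") or ""), ArtStatus, i),
            art_status_date=_parse_date(get("art_status_date"), i, "art_status_date", problems),
            hiv_diagnosis_date=_parse_date(get("hiv_diagnosis_date"), i,
                                           "hiv_diagnosis_date", problems),
            first_visit_date=_parse_date(get("first_visit_date"), i,
                                         "first_visit_date", problems),
            death_date=death,
        )
        parsed.append(record)

    if problems:
        raise RecordValidationError(problems)

    # Most-recent-visit rule. Input order is the final tie-break, so iterate in
    # order and only replace on a strictly better (visit, vl_date) key.
    best: dict[str, PatientRecord] = {}
    order: list[str] = []
    far_past = date.min
    for rec in parsed:
        cur = best.get(rec.patient_id)
        if cur is None:
            best[rec.patient_id] = rec
            order.append(rec.patient_id)
            continue
        key_new = (rec.last_visit_date, rec.last_vl_date or far_past)
        key_cur = (cur.last_visit_date, cur.last_vl_date or far_past)
        if key_new > key_cur:
            best[rec.patient_id] = rec

    deduped = [best[pid] for pid in order]
    in_window = [r for r in deduped if window_start <= r.last_visit_date <= window_end]
    n_dropped = len(deduped) - len(in_window)
    if n_dropped:
        logger.info("dropped %d record(s) with last visit outside %s..%s",
                    n_dropped, window_start, window_end)
    if not in_window:
        raise EmptyPopulationError(
            f"no records with a visit inside {window_start}..{window_end}")
    # Canonical order: sorted by patient_id, so ingestion is row-order
    # independent given the deterministic tie-break.
    in_window.sort(key=lambda r: r.patient_id)
    return ClinicPopulation(
        records=tuple(in_window),
        window_start=window_start,
        window_end=window_end,
        vs_threshold=vs_threshold,
        lod=lod,
        label=label,
    )


def read_patient_csv(path) -> pd.DataFrame:
    """Read the standard patient CSV (all columns as text; '' = missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError([(0, f"missing column(s): {', '.join(missing)}")])
    return df


def write_patient_csv(pop: ClinicPopulation, path) -> None:
    """Write a population back to the standard patient CSV format."""
    rows = []
    for r in pop:
        rows.append({
            "patient_id": r.patient_id,
            "date_of_birth": r.date_of_birth.isoformat() if r.date_of_birth else "",
            "gender": r.gender.value if r.gender != Gender.UNKNOWN else "",
            "country_of_origin": r.country_of_origin or "",
            "transmission_group": (r.transmission_group.value
                                   if r.transmission_group != TransmissionGroup.UNKNOWN
                                   else ""),
            "last_cd4": "" if r.last_cd4 is None else str(r.last_cd4),
            "last_cd4_date": r.last_cd4_date.isoformat() if r.last_cd4_date else "",
            "last_vl": "" if r.last_vl is None else str(r.last_vl),
            "last_vl_date": r.last_vl_date.isoformat() if r.last_vl_date else "",
            "on_art": r.on_art.value if r.on_art != ArtStatus.UNKNOWN else "",
            "art_status_date": r.art_status_date.isoformat() if r.art_status_date else "",
            "hiv_diagnosis_date": (r.hiv_diagnosis_date.isoformat()
                                   if r.hiv_diagnosis_date else ""),
            "first_visit_date": r.first_visit_date.isoformat() if r.first_visit_date else "",
            "last_visit_date": r.last_visit_date.isoformat(),
            "death_date": r.death_date.isoformat() if r.death_date else "",
        })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def filter_eligible(pop: ClinicPopulation) -> EligibilityResult:
    """Restrict a population to eligible records.

    Eligible: age >= 18 completed years at the last visit (the 18th birthday
    on the visit date counts), and no death recorded before the window opened.
    Records with unknown date of birth are conservatively excluded and counted
    under "age unknown" — eligibility cannot be verified.

    Idempotent: filtering an already-filtered population excludes nothing.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot filter an empty population")
    kept: list[PatientRecord] = []
    exclusions = {"age unknown": 0, "under 18": 0, "died before window": 0}
    for r in pop:
        if r.death_date is not None and r.death_date < pop.window_start:
            exclusions["died before window"] += 1
            continue
        age = r.age_at(r.last_visit_date)
        if age is None:
            exclusions["age unknown"] += 1
            continue
        if age < 18:
            exclusions["under 18"] += 1
            continue
        kept.append(r)
    filtered = replace(pop, records=tuple(kept))
    exclusions = {k: v for k, v in exclusions.items() if v}
    if exclusions:
        logger.info("eligibility exclusions: %s", exclusions)
    return EligibilityResult(population=filtered, exclusions=exclusions)
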