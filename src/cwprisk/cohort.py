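"""Cohort data model for an underground coal-mining workforce.

A worker's career is a sequence of dated job spells, each spent in one of
four underground work areas:

* ``tunneling`` — rock drilling/blasting to open tunnels (highest silica),
* ``mining`` — drilling, cutting and loading coal at the coal face,
* ``combining`` — mixed rock/coal excavation (20–80 % rock),
* ``helping`` — maintenance, transport, electromechanics (no direct dust
  generation).

From the spells and a work-area × calendar-year dust-concentration table the
module derives the quantities the downstream analysis consumes: the worker's
occupational category, the cumulative dust exposure (CDE, mg/m³·years), and
the observation window from first dust exposure to diagnosis or censoring.
"""

from __future__ import annotations

import datetime
import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: Default end of follow-up.
STUDY_END = datetime.date(2011, 12, 31)


class Area(str, enum.Enum):
    """Underground work area of a job spell."""

    TUNNELING = "tunneling"
    MINING = "mining"
    COMBINING = "combining"
    HELPING = "helping"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


AREAS: tuple[Area, ...] = (Area.TUNNELING, Area.MINING, Area.COMBINING, Area.HELPING)

#: Entry-era labels by decade of first dust exposure.
ERAS: tuple[str, ...] = ("1970-", "1980-", "1990-")


class InvalidRecordError(ValueError):
    """A worker record violates a structural invariant."""


class MissingConcentrationError(KeyError):
    """A (work area, calendar year) cell cannot be resolved."""


def era_of_year(year: int) -> str:
    """Map a calendar year of first dust exposure to its entry-era label."""
    if year < 1970:
        raise ValueError(f"first exposure before 1970 not covered: {year}")
    if year < 1980:
        return "1970-"
    if year < 1990:
        return "1980-"
    return "1990-"


@dataclass(frozen=True)
class ExposureSegment:
    """One dust-exposed job spell; the interval is half-open [start, end)."""

    area: Area
    start: datetime.date
    end: datetime.date

    def __post_init__(self) -> None:
        object.__setattr__(self, "area", Area(self.area))
        if self.start >= self.end:
            raise InvalidRecordError(
                f"segment start {self.start} not before end {self.end}"
            )

    @property
    def duration(self) -> float:
        """Spell duration in years (days / 365.25)."""
        return (self.end - self.start).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class WorkerRecord:
    """One cohort member.

    ``cwp_status`` is True for workers diagnosed with coal workers'
    pneumoconiosis (CWP) during follow-up; cases carry a ``diagnosis_date``,
    non-cases a ``censor_date`` (loss to follow-up or study end).
    """

    worker_id: str
    birth_year: int
    first_exposure_date: datetime.date
    segments: tuple[ExposureSegment, ...]
    cwp_status: bool
    diagnosis_date: datetime.date | None = None
    censor_date: datetime.date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    def validate(self, min_total_duration: float = 1.0) -> "WorkerRecord":
        """Check all structural invariants, returning self for chaining."""
        wid = self.worker_id
        if not self.segments:
            raise InvalidRecordError(f"worker {wid}: no exposure segments")
        earliest = min(s.start for s in self.segments)
        if earliest != self.first_exposure_date:
            raise InvalidRecordError(
                f"worker {wid}: first_exposure_date {self.first_exposure_date} "
                f"!= earliest segment start {earliest}"
            )
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise InvalidRecordError(
                    f"worker {wid}: overlapping segments at {b.start}"
                )
        total = sum(s.duration for s in self.segments)
        if total < min_total_duration:
            raise InvalidRecordError(
                f"worker {wid}: total exposure {total:.2f} y below the "
                f"{min_total_duration:g}-year inclusion minimum"
            )
        if self.cwp_status:
            if self.diagnosis_date is None:
                raise InvalidRecordError(f"worker {wid}: case without diagnosis_date")
            if self.diagnosis_date <= self.first_exposure_date:
                raise InvalidRecordError(
                    f"worker {wid}: diagnosis {self.diagnosis_date} not after "
                    f"first exposure {self.first_exposure_date}"
                )
        elif self.censor_date is None:
            raise InvalidRecordError(f"worker {wid}: non-case without censor_date")
        return self

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def area_duration(self, area: Area) -> float:
        return sum(s.duration for s in self.segments if s.area is Area(area))


class ConcentrationTable:
    """Geometric-mean dust concentration (mg/m³) per (work area, year).

    Concentrations are stored as blocks ``[year_start, year_end]`` (both
    inclusive); a single-year block is an exact-year entry, which takes
    precedence over any wider block containing the year. Each cell may carry
    a geometric standard deviation (GSD) for lognormal sampling.
    """

    def __init__(
        self, rows: Iterable[tuple[Area | str, int, int, float, float | None]]
    ) -> None:
        self._rows: list[tuple[Area, int, int, float, float | None]] = []
        for area, y0, y1, gm, gsd in rows:
            area = Area(area)
            if y1 < y0:
                raise ValueError(f"block {y0}-{y1} reversed")
            if gm <= 0:
                raise ValueError(f"non-positive concentration {gm} for {area} {y0}")
            self._rows.append((area, int(y0), int(y1), float(gm), gsd))

    def lookup(self, area: Area | str, year: int) -> tuple[float, float | None]:
        """Return (geometric mean, gsd) for the cell, exact year first."""
        area = Area(area)
        best: tuple[float, float | None] | None = None
        best_width = None
        for a, y0, y1, gm, gsd in self._rows:
            if a is area and y0 <= year <= y1:
                width = y1 - y0
                if best is None or width < best_width:
                    best, best_width = (gm, gsd), width
        if best is None:
            raise MissingConcentrationError(
                f"no concentration for area={area.value}, year={year}"
            )
        return best

    def value(self, area: Area | str, year: int) -> float:
        return self.lookup(area, year)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (a.value, y0, y1, gm, gsd if gsd is not None else float("nan"))
                for a, y0, y1, gm, gsd in self._rows
            ],
            columns=["area", "year_start", "year_end", "geometric_mean_mg_m3", "gsd"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationTable":
        df = pd.read_csv(path)
        required = {"area", "year_start", "year_end", "geometric_mean_mg_m3"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"concentration file missing columns: {sorted(missing)}")
        rows = []
        for _, r in df.iterrows():
            gsd = r.get("gsd")
            gsd = None if gsd is None or pd.isna(gsd) else float(gsd)
            rows.append(
                (r["area"], int(r["year_start"]), int(r["year_end"]),
                 float(r["geometric_mean_mg_m3"]), gsd)
            )
        return cls(rows)


def classify_occupation(segments: Sequence[ExposureSegment]) -> Area:
    """Assign the occupational category from a worker's job spells.

    Rule cascade (first match wins):

    1. every spell in a single area → that area;
    2. tunneling duration > half of the total → ``tunneling``;
    3. tunneling < 2 years and mining > half of the total → ``mining``;
    4. tunneling ≥ 2 years (but ≤ half of the total) → ``combining``;
    5. otherwise → ``helping``.

    A duration of exactly half the total does not count as "more than half";
    a tunneling duration of exactly 2 years is combining-eligible.
    """
    if not segments:
        raise InvalidRecordError("cannot classify an empty segment list")
    durations: dict[Area, float] = {a: 0.0 for a in AREAS}
    for s in segments:
        if s.duration <= 0:
            raise InvalidRecordError(f"non-positive segment duration at {s.start}")
        durations[s.area] += s.duration
    total = sum(durations.values())
    present = [a for a in AREAS if durations[a] > 0]
    if len(present) == 1:
        return present[0]
    tun, mine = durations[Area.TUNNELING], durations[Area.MINING]
    if tun > total / 2:
        return Area.TUNNELING
    if tun < 2.0 and mine > total / 2:
        return Area.MINING
    if tun >= 2.0:
        return Area.COMBINING
    return Area.HELPING


def compute_cde(
    segments: Sequence[ExposureSegment], conc: ConcentrationTable
) -> float:
    """Cumulative dust exposure in mg/m³·years (printed as "mg-years").

    Each spell is split at calendar-year boundaries and every slice
    contributes (days / 365.25) × the area's geometric-mean concentration for
    that calendar year. Additive over any partition of a spell.
    """
    cde = 0.0
    for seg in segments:
        for year in range(seg.start.year, seg.end.year + 1):
            lo = max(seg.start, datetime.date(year, 1, 1))
            hi = min(seg.end, datetime.date(year + 1, 1, 1))
            days = (hi - lo).days
            if days <= 0:
                continue
            cde += days / DAYS_PER_YEAR * conc.value(seg.area, year)
    return cde


def observation_window(worker: WorkerRecord) -> float:
    """Observed years: first dust exposure → diagnosis (cases) or censoring.

    For cases this is the latency period (time from first exposure to
    diagnosis).
    """
    if worker.cwp_status:
        if worker.diagnosis_date is None:
            raise InvalidRecordError(
                f"worker {worker.worker_id}: case without diagnosis_date"
            )
        end = worker.diagnosis_date
    else:
        if worker.censor_date is None:
            raise InvalidRecordError(
                f"worker {worker.worker_id}: non-case without censor_date"
            )
        end = worker.censor_date
    years = (end - worker.first_exposure_date).days / DAYS_PER_YEAR
    if years <= 0:
        raise InvalidRecordError(
            f"worker {worker.worker_id}: non-positive observation window"
        )
    return years


@dataclass(frozen=True)
class DerivedExposure:
    """Per-worker analysis quantities derived from the raw record."""

    worker_id: str
    category: Area
    era: str
    total_duration: float
    tunneling_duration: float
    mining_duration: float
    combining_duration: float
    helping_duration: float
    cde: float
    observed_years: float
    latency: float | None  # equals observed_years for cases, None otherwise


def derive_exposure(worker: WorkerRecord, conc: ConcentrationTable) -> DerivedExposure:
    obs = observation_window(worker)
    return DerivedExposure(
        worker_id=worker.worker_id,
        category=classify_occupation(worker.segments),
        era=era_of_year(worker.first_exposure_date.year),
        total_duration=worker.total_duration,
        tunneling_duration=worker.area_duration(Area.TUNNELING),
        mining_duration=worker.area_duration(Area.MINING),
        combining_duration=worker.area_duration(Area.COMBINING),
        helping_duration=worker.area_duration(Area.HELPING),
        cde=compute_cde(worker.segments, conc),
        observed_years=obs,
        latency=obs if worker.cwp_status else None,
    )


def derive_exposures(
    workers: Sequence[WorkerRecord], conc: ConcentrationTable
) -> pd.DataFrame:
    """Tabulate :func:`derive_exposure` for a cohort, one row per worker."""
    rows = []
    for w in workers:
        d = derive_exposure(w, conc)
        rows.append(
            {
                "worker_id": d.worker_id,
                "birth_year": w.birth_year,
                "first_exposure_year": w.first_exposure_date.year,
                "era": d.era,
                "category": d.category.value,
                "total_duration": d.total_duration,
                "cde": d.cde,
                "observed_years": d.observed_years,
                "cwp_status": int(w.cwp_status),
                "latency": d.latency,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort file I/O: a worker table plus a segments sidecar, both CSV.
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "worker_id",
    "birth_year",
    "first_exposure_date",
    "cwp_status",
    "diagnosis_date",
    "censor_date",
]
_SEGMENT_COLUMNS = ["worker_id", "area", "start_date", "end_date"]


def _parse_date(value, *, line: int, column: str) -> datetime.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise InvalidRecordError(f"line {line}: unparseable {column} {value!r}") from exc


def read_cohort(
    cohort_path: str | Path, segments_path: str | Path, *, validate: bool = True
) -> list[WorkerRecord]:
    """Read a cohort from the worker CSV and its segments sidecar CSV."""
    cohort = pd.read_csv(cohort_path, dtype={"worker_id": str})
    segs = pd.read_csv(segments_path, dtype={"worker_id": str})
    for df, cols, path in (
        (cohort, _COHORT_COLUMNS, cohort_path),
        (segs, _SEGMENT_COLUMNS, segments_path),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise InvalidRecordError(f"{path}: missing columns {sorted(missing)}")
    dup = cohort["worker_id"][cohort["worker_id"].duplicated()]
    if not dup.empty:
        raise InvalidRecordError(f"duplicate worker_id: {dup.iloc[0]}")
    if cohort.empty:
        warnings.warn(f"{cohort_path}: header only, empty cohort", stacklevel=2)
        return []

    seg_map: dict[str, list[ExposureSegment]] = {}
    for i, row in enumerate(segs.itertuples(index=False), start=2):
        seg_map.setdefault(row.worker_id, []).append(
            ExposureSegment(
                area=Area(row.area),
                start=_parse_date(row.start_date, line=i, column="start_date"),
                end=_parse_date(row.end_date, line=i, column="end_date"),
            )
        )

    records = []
    for i, row in enumerate(cohort.itertuples(index=False), start=2):
        rec = WorkerRecord(
            worker_id=row.worker_id,
            birth_year=int(row.birth_year),
            first_exposure_date=_parse_date(
                row.first_exposure_date, line=i, column="first_exposure_date"
            ),
            segments=tuple(
                sorted(seg_map.get(row.worker_id, []), key=lambda s: s.start)
            ),
            cwp_status=bool(int(row.cwp_status)),
            diagnosis_date=_parse_date(row.diagnosis_date, line=i, column="diagnosis_date"),
            censor_date=_parse_date(row.censor_date, line=i, column="censor_date"),
        )
        if validate:
            rec.validate()
        records.append(rec)
    return records


def write_cohort(
    records: Sequence[WorkerRecord],
    cohort_path: str | Path,
    segments_path: str | Path,
) -> None:
    """Write a cohort as the worker CSV plus segments sidecar CSV."""
    rows, seg_rows = [], []
    for w in records:
        rows.append(
            {
                "worker_id": w.worker_id,
                "birth_year": w.birth_year,
                "first_exposure_date": w.first_exposure_date.isoformat(),
                "cwp_status": int(w.cwp_status),
                "diagnosis_date": w.diagnosis_date.isoformat() if w.diagnosis_date else "",
                "censor_date": w.censor_date.isoformat() if w.censor_date else "",
            }
        )
        for s in w.segments:
            seg_rows.append(
                {
                    "worker_id": w.worker_id,
                    "area": s.area.value,
                    "start_date": s.start.isoformat(),
                    "end_date": s.end.isoformat(),
                }
            )
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(cohort_path, index=False)
    pd.DataFrame(seg_rows, columns=_SEGMENT_COLUMNS).to_csv(segments_path, index=False)
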