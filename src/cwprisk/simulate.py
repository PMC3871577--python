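"""Synthetic coal-worker cohorts with known ground truth.

The generator emulates the structure the analysis assumes for a 1970–2011
colliery workforce: four occupational categories, three entry eras, age at
first dust exposure ≈ 21.4 ± 4.0 y, CWP latency ≈ 29.1 ± 5.3 y, work-area
dust concentrations declining by decade, and era × category subgroup
incidence rates on the per-mille-per-year scale. Every generated worker is a
valid :class:`~cwprisk.cohort.WorkerRecord` whose segments genuinely satisfy
the occupational-classification rule for the sampled category, so the whole
downstream pipeline is testable without any external data.

Onset models
------------
``linear`` (default)
    Constant absolute annual risk: a worker converts with probability
    ``min(1, rate × observed_years)``, so the life-table summary
    CI(T)/T recovers the configured subgroup rate without bias.
``exponential``
    Constant hazard: conversion probability ``1 − exp(−rate × observed_years)``.
``dose_response``
    Conversion probability ``min(cap, slope × CDE)`` — risk is driven by
    cumulative dust exposure, giving the risk model a learnable
    dose–response signal.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .cohort import (
    Area,
    AREAS,
    ConcentrationTable,
    DAYS_PER_YEAR,
    ExposureSegment,
    STUDY_END,
    WorkerRecord,
    compute_cde,
    era_of_year,
)

_CATEGORIES = tuple(a.value for a in AREAS)

#: Entry-date windows per era (inclusive); last entries leave >1 y follow-up.
_ENTRY_WINDOWS: dict[str, tuple[datetime.date, datetime.date]] = {
    "1970-": (datetime.date(1970, 1, 1), datetime.date(1979, 12, 31)),
    "1980-": (datetime.date(1980, 1, 1), datetime.date(1989, 12, 31)),
    "1990-": (datetime.date(1990, 1, 1), datetime.date(2010, 12, 1)),
}


def _default_rates() -> dict[tuple[str, str], float]:
    rates = dict(reference.SUBGROUP_ANNUAL_RATES)
    # 1990- entrants: no published subgroup estimate; carry the 1980- rates.
    for cat in _CATEGORIES:
        rates[("1990-", cat)] = rates[("1980-", cat)]
    return rates


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort draw."""

    n_workers: int = 17023
    category_mix: tuple[float, float, float, float] = reference.CATEGORY_MIX
    era_mix: tuple[float, float, float] = reference.ERA_MIX
    age_at_entry_mean: float = 21.4
    age_at_entry_sd: float = 4.0
    age_at_entry_bounds: tuple[float, float] = (16.0, 40.0)
    latency_mean: float = 29.1
    latency_sd: float = 5.3
    latency_min: float = 5.0
    career_mean: float = 28.0
    career_sd: float = 8.0
    career_max: float = 45.0
    mixed_career_fraction: float = 0.3
    subgroup_annual_rates: Mapping[tuple[str, str], float] = field(
        default_factory=_default_rates
    )
    entry_windows: Mapping[str, tuple[datetime.date, datetime.date]] = field(
        default_factory=lambda: dict(_ENTRY_WINDOWS)
    )
    onset_model: str = "linear"
    dose_slope: float = 2.5e-4  # per mg/m³·year, dose_response model
    dose_cap: float = 0.9
    life_expectancy: float = 74.0
    study_end: datetime.date = STUDY_END
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_workers <= 0:
            raise ValueError("n_workers must be positive")
        for name, mix in (("category_mix", self.category_mix), ("era_mix", self.era_mix)):
            if min(mix) < 0 or abs(sum(mix) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if any(r < 0 for r in self.subgroup_annual_rates.values()):
            raise ValueError("negative subgroup rate")
        if self.onset_model not in ("linear", "exponential", "dose_response"):
            raise ValueError(f"unknown onset_model {self.onset_model!r}")
        return self

    def rate_for(self, era: str, category: str) -> float:
        try:
            return self.subgroup_annual_rates[(era, category)]
        except KeyError as exc:
            raise KeyError(f"no rate configured for subgroup ({era}, {category})") from exc


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _build_segments(
    rng: np.random.Generator,
    category: str,
    entry: datetime.date,
    dur_days: int,
    mixed: bool,
) -> tuple[ExposureSegment, ...]:
    """A career of contiguous spells totalling ``dur_days`` that classifies
    to ``category`` under the rule cascade."""
    day = datetime.timedelta(days=1)

    def spans(parts: list[tuple[str, int]]) -> tuple[ExposureSegment, ...]:
        segs, cur = [], entry
        for area, nd in parts:
            if nd <= 0:
                continue
            segs.append(ExposureSegment(Area(area), cur, cur + nd * day))
            cur += nd * day
        return tuple(segs)

    if not mixed:
        return spans([(category, dur_days)])

    if category == "tunneling":
        # rule 2: tunneling strictly more than half
        tun = int(dur_days * rng.uniform(0.6, 0.9))
        return spans([("tunneling", tun), ("helping", dur_days - tun)])
    if category == "mining":
        # rule 3: tunneling < 2 y, mining more than half
        tun = int(min(365, dur_days * rng.uniform(0.02, 0.15)))
        mine = int(dur_days * rng.uniform(0.6, 0.85))
        return spans([("tunneling", tun), ("mining", mine),
                      ("helping", dur_days - tun - mine)])
    if category == "combining":
        # rule 4: tunneling >= 2 y but not more than half
        if dur_days < 1600:
            return spans([(category, dur_days)])
        tun = int(np.clip(dur_days * rng.uniform(0.25, 0.5), 731, dur_days // 2))
        return spans([("tunneling", tun), ("combining", dur_days - tun)])
    # rule 5 fall-through: no tunneling, mining at most half
    mine = int(dur_days * rng.uniform(0.1, 0.45))
    return spans([("mining", mine), ("helping", dur_days - mine)])


def generate_cohort(
    spec: CohortSpec, conc: ConcentrationTable | None = None
) -> tuple[list[WorkerRecord], pd.DataFrame]:
    """Draw a cohort; returns (records, ground-truth table).

    The ground truth has one row per worker: era, category, the subgroup
    rate in force (``true_rate``), the realized conversion probability
    (``p_convert``), and whether the worker converted.
    """
    spec.validate()
    if conc is None:
        conc = reference.default_concentration_table()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_workers
    eras = rng.choice(len(reference.ERA_MIX), size=n, p=np.asarray(spec.era_mix))
    cats = rng.choice(4, size=n, p=np.asarray(spec.category_mix))
    ages = _truncnorm(
        rng, spec.age_at_entry_mean, spec.age_at_entry_sd,
        *spec.age_at_entry_bounds, size=n,
    )
    careers_y = _truncnorm(rng, spec.career_mean, spec.career_sd, 1.1, spec.career_max, size=n)
    mixed_flags = rng.random(n) < spec.mixed_career_fraction
    u_convert = rng.random(n)

    era_labels = ("1970-", "1980-", "1990-")
    records: list[WorkerRecord] = []
    gt_rows = []
    for i in range(n):
        era = era_labels[eras[i]]
        category = _CATEGORIES[cats[i]]
        w0, w1 = spec.entry_windows[era]
        entry = w0 + datetime.timedelta(days=int(rng.integers((w1 - w0).days + 1)))
        window_days = (spec.study_end - entry).days
        dur_days = int(min(careers_y[i] * DAYS_PER_YEAR, window_days))
        dur_days = max(dur_days, 367)  # 1-year inclusion minimum
        segments = _build_segments(rng, category, entry, dur_days, bool(mixed_flags[i]))
        window_y = window_days / DAYS_PER_YEAR

        rate = spec.rate_for(era, category)
        if spec.onset_model == "linear":
            p_convert = min(1.0, rate * window_y)
        elif spec.onset_model == "exponential":
            p_convert = 1.0 - float(np.exp(-rate * window_y))
        else:  # dose_response
            p_convert = min(spec.dose_cap, spec.dose_slope * compute_cde(segments, conc))
        converted = bool(u_convert[i] < p_convert)

        if converted:
            lat_lo = min(spec.latency_min, window_y / 2.0)
            latency = float(
                _truncnorm(rng, spec.latency_mean, spec.latency_sd, lat_lo, window_y)
            )
            diag_days = int(np.clip(latency * DAYS_PER_YEAR, 1, window_days))
            diagnosis, censor = entry + datetime.timedelta(days=diag_days), None
        else:
            diagnosis, censor = None, spec.study_end

        birth_year = entry.year - int(round(ages[i]))
        rec = WorkerRecord(
            worker_id=f"W{i:06d}",
            birth_year=birth_year,
            first_exposure_date=entry,
            segments=segments,
            cwp_status=converted,
            diagnosis_date=diagnosis,
            censor_date=censor,
        ).validate()
        records.append(rec)
        gt_rows.append(
            {
                "worker_id": rec.worker_id,
                "era": era,
                "category": category,
                "true_rate": rate,
                "p_convert": p_convert,
                "converted": int(converted),
            }
        )
    return records, pd.DataFrame(gt_rows)


def sample_concentration(
    area: Area | str,
    year: int,
    *,
    conc: ConcentrationTable | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> float:
    """One dust-concentration draw (mg/m³) for a work area and year.

    Lognormal around the cell's geometric mean with its geometric SD; with
    ``noise=False`` returns the geometric mean itself.
    """
    if conc is None:
        conc = reference.default_concentration_table()
    gm, gsd = conc.lookup(area, year)
    if not noise:
        return gm
    if gsd is None:
        raise ValueError(f"no GSD available for {area}, {year}")
    if rng is None:
        rng = np.random.default_rng()
    return float(np.exp(rng.normal(np.log(gm), np.log(gsd))))


_FIXTURE_NAMES = ("tiny", "mixed-careers", "no-cases")


def make_fixture(name: str) -> tuple[list[WorkerRecord], pd.DataFrame]:
    """Small deterministic cohorts for tests and smoke runs.

    ``tiny`` — 50 workers, every category present, both outcomes;
    ``mixed-careers`` — 200 workers, every mixed-career classifier branch hit;
    ``no-cases`` — 60 workers, zero conversions.
    """
    if name == "tiny":
        spec = CohortSpec(
            n_workers=50,
            subgroup_annual_rates={
                (e, c): 20e-3 for e in ("1970-", "1980-", "1990-") for c in _CATEGORIES
            },
            seed=20,
        )
        records, gt = generate_cohort(spec)
        cats = {r["category"] for r in gt.to_dict("records")}
        assert cats == set(_CATEGORIES) and 0 < gt["converted"].sum() < len(gt)
        return records, gt
    if name == "no-cases":
        spec = CohortSpec(
            n_workers=60,
            subgroup_annual_rates={
                (e, c): 0.0 for e in ("1970-", "1980-", "1990-") for c in _CATEGORIES
            },
            seed=7,
        )
        return generate_cohort(spec)
    if name == "mixed-careers":
        spec = CohortSpec(
            n_workers=200,
            mixed_career_fraction=1.0,
            category_mix=(0.25, 0.25, 0.25, 0.25),
            seed=11,
        )
        records, gt = generate_cohort(spec)
        has_rule3 = any(
            0 < sum(s.duration for s in r.segments if s.area is Area.TUNNELING) < 2
            and sum(s.duration for s in r.segments if s.area is Area.MINING)
            > r.total_duration / 2
            for r in records
        )
        has_rule4 = any(
            2
            <= sum(s.duration for s in r.segments if s.area is Area.TUNNELING)
            <= r.total_duration / 2
            for r in records
        )
        assert has_rule3 and has_rule4
        return records, gt
    raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURE_NAMES}")
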