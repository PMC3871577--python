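import datetime

import pytest

from cwprisk.cohort import Area, ConcentrationTable, ExposureSegment, WorkerRecord
from cwprisk.reference import default_concentration_table


def seg(area, start, end):
    """Segment from ISO date strings or dates."""
    if isinstance(start, str):
        start = datetime.date.fromisoformat(start)
    if isinstance(end, str):
        end = datetime.date.fromisoformat(end)
    return ExposureSegment(Area(area), start, end)


def chain(entry, *parts):
    """Contiguous segments from (area, n_days) parts starting at ``entry``."""
    if isinstance(entry, str):
        entry = datetime.date.fromisoformat(entry)
    segs, cur = [], entry
    for area, days in parts:
        segs.append(ExposureSegment(Area(area), cur, cur + datetime.timedelta(days=days)))
        cur += datetime.timedelta(days=days)
    return tuple(segs)


def worker(
    wid="w1",
    entry="1975-01-01",
    segments=None,
    case=False,
    diagnosis=None,
    censor="2011-12-31",
    birth_year=1953,
):
    entry_d = datetime.date.fromisoformat(entry)
    if segments is None:
        segments = chain(entry_d, ("mining", 20 * 365))
    return WorkerRecord(
        worker_id=wid,
        birth_year=birth_year,
        first_exposure_date=entry_d,
        segments=tuple(segments),
        cwp_status=case,
        diagnosis_date=datetime.date.fromisoformat(diagnosis) if diagnosis else None,
        censor_date=datetime.date.fromisoformat(censor) if censor and not case else None,
    )


def exponential_cohort(rng, n, hazard, censor_years=40.0, entry=datetime.date(1970, 1, 1)):
    """Workers with exponential event times, censored at ``censor_years``."""
    times = rng.exponential(1.0 / hazard, size=n)
    out = []
    for i, t in enumerate(times):
        if t < censor_years:
            days = max(1, int(t * 365.25))
            out.append(
                WorkerRecord(
                    worker_id=f"e{i}",
                    birth_year=1950,
                    first_exposure_date=entry,
                    segments=chain(entry, ("mining", max(days, 400))),
                    cwp_status=True,
                    diagnosis_date=entry + datetime.timedelta(days=days),
                )
            )
        else:
            days = int(censor_years * 365.25)
            out.append(
                WorkerRecord(
                    worker_id=f"e{i}",
                    birth_year=1950,
                    first_exposure_date=entry,
                    segments=chain(entry, ("mining", days)),
                    cwp_status=False,
                    censor_date=entry + datetime.timedelta(days=days),
                )
            )
    return out


@pytest.fixture(scope="session")
def conc():
    return default_concentration_table()


@pytest.fixture(scope="session")
def flat_conc():
    """Constant 5 mg/m³ everywhere, 1970–2030."""
    return ConcentrationTable([(a, 1970, 2030, 5.0, 2.0) for a in Area])


@pytest.fixture(scope="session")
def tiny_cohort():
    from cwprisk.simulate import make_fixture

    return make_fixture("tiny")
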