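"""Projection of future CWP cases within life expectancy.

Each worker without CWP contributes ``rate × remaining_years`` expected
cases, where ``rate`` is the annual average incidence of the worker's entry
era × occupational category subgroup and ``remaining_years`` runs from the
current age to life expectancy. Accumulation is linear (non-compounding),
matching the constant annual-average-incidence assumption; a compounding
variant ``1 − (1 − rate)^m`` is available. Expected cases are
cross-classified by current-age band and, separately, by the future decade
window in which the person-years fall; both classifications partition the
same expected total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORY_ORDER = ("tunneling", "mining", "combining", "helping")

#: Default display age bands (lower edges; last band open-ended).
DEFAULT_AGE_BANDS = (20, 30, 40, 50, 60)

#: Default future-time windows (upper edges of the closed windows; a final
#: open window follows).
DEFAULT_WINDOWS = (10, 20, 30)

#: Era whose rates are applied to subgroups with no published estimate.
DEFAULT_RATE_MAPPING = {"1990-": "1980-"}


def _band_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"<{edges[0]}"]
    labels += [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]}-")
    return labels


def _window_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"<{edges[0]}"]
    labels += [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]}-")
    return labels


class MissingRateError(KeyError):
    """A worker's subgroup has no configured incidence rate."""


@dataclass(frozen=True)
class ProjectionTable:
    """Expected new cases by category × age band and category × window."""

    by_age: pd.DataFrame  # categories × age bands
    by_window: pd.DataFrame  # categories × future windows
    band_counts: pd.Series  # workers per age band (denominators)
    n_workers: int

    @property
    def grand_total(self) -> float:
        return float(self.by_age.to_numpy().sum())

    def check_consistency(self, rtol: float = 1e-9) -> None:
        """Both classifications must partition the same expected total."""
        a = self.by_age.sum(axis=1).to_numpy()
        w = self.by_window.sum(axis=1).to_numpy()
        if not np.allclose(a, w, rtol=rtol, atol=1e-12):
            raise AssertionError("age-band and window totals disagree")


def project_cases(
    workers: pd.DataFrame,
    rates: Mapping[tuple[str, str], float],
    *,
    life_expectancy: float | Callable[[float], float] = 74.0,
    age_bands: Sequence[int] = DEFAULT_AGE_BANDS,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    rate_mapping: Mapping[str, str] | None = None,
    compounding: bool = False,
) -> ProjectionTable:
    """Project expected new CWP cases among workers without CWP.

    ``workers`` needs columns ``era``, ``category``, and ``age`` (current
    age in years). ``life_expectancy`` is a scalar or a function of current
    age returning total life expectancy; remaining years are floored at 0.
    """
    rate_mapping = DEFAULT_RATE_MAPPING if rate_mapping is None else rate_mapping
    age_labels = _band_labels(age_bands)
    win_labels = _window_labels(windows)
    win_edges = [0, *windows]

    by_age = pd.DataFrame(0.0, index=list(CATEGORY_ORDER), columns=age_labels)
    by_window = pd.DataFrame(0.0, index=list(CATEGORY_ORDER), columns=win_labels)
    band_counts = pd.Series(0, index=age_labels, dtype=int)

    for row in workers.itertuples(index=False):
        era = rate_mapping.get(row.era, row.era)
        try:
            r = rates[(era, row.category)]
        except KeyError as exc:
            raise MissingRateError(
                f"no rate for subgroup ({era}, {row.category})"
            ) from exc
        age = float(row.age)
        le = life_expectancy(age) if callable(life_expectancy) else life_expectancy
        m = max(0.0, le - age)

        band = int(np.searchsorted(age_bands, age, side="right"))
        band_counts.iloc[band] += 1
        if compounding:
            total = 1.0 - (1.0 - r) ** m
        else:
            total = r * m
        by_age.loc[row.category, age_labels[band]] += total

        # split m linearly across future windows
        for j, lo in enumerate(win_edges):
            hi = windows[j] if j < len(windows) else np.inf
            years = max(0.0, min(m, hi) - lo)
            if years <= 0:
                continue
            if compounding:
                contrib = (1.0 - r) ** lo - (1.0 - r) ** min(m, hi)
            else:
                contrib = r * years
            by_window.loc[row.category, win_labels[j]] += contrib

    table = ProjectionTable(
        by_age=by_age,
        by_window=by_window,
        band_counts=band_counts,
        n_workers=len(workers),
    )
    table.check_consistency()
    return table


def summarize_projection(
    table: ProjectionTable, denominators: pd.Series | None = None
) -> pd.DataFrame:
    """Append totals and band percentages to the age-band table.

    Percentages are 100 × expected cases / band worker count; the grand
    total uses the whole-cohort denominator.
    """
    table.check_consistency()
    denom = table.band_counts if denominators is None else denominators
    if (np.asarray(denom, dtype=float) < 0).any():
        raise ValueError("negative denominator")
    out = table.by_age.copy()
    totals = out.sum(axis=0)
    out.loc["total"] = totals
    pct = {}
    for col in out.columns:
        d = float(denom[col]) if col in denom.index else float("nan")
        if d == 0:
            # an empty band with no expected cases has no defined percentage
            if totals[col] == 0:
                pct[col] = float("nan")
                continue
            raise ValueError(f"zero denominator for band {col}")
        pct[col] = 100.0 * totals[col] / d
    out.loc["pct_of_band"] = pd.Series(pct)
    out["total"] = out.sum(axis=1)
    n = table.n_workers if denominators is None else float(np.asarray(denom).sum())
    out.loc["pct_of_band", "total"] = 100.0 * table.grand_total / n
    return out
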