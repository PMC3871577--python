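"""Actuarial life-table incidence, Peto log-rank, and contingency tests.

The cumulative incidence of CWP is estimated with the classical actuarial
(life-table) method on fixed intervals of years since first dust exposure:
withdrawals in an interval contribute half an interval of risk, the
conditional incidence in interval ``k`` is ``q_k = d_k / (n_k - w_k/2)``,
and the cumulative incidence at time ``t`` is ``1 - prod_{k<t}(1 - q_k)``.
The "annual average incidence" summary used for projection is the cumulative
incidence divided by the follow-up time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import WorkerRecord, observation_window


@dataclass(frozen=True)
class CurveComparison:
    """A chi-square comparison result."""

    statistic: float
    df: int
    p_value: float

    def p_display(self) -> str:
        """p to 3 decimals with a '<0.001' floor."""
        return "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"


@dataclass(frozen=True)
class LifeTable:
    """Per-interval counts and the cumulative incidence curve.

    ``table`` has one row per interval ``[k*width, (k+1)*width)`` with
    columns t (interval start), n (entrants), d (events), w (withdrawals),
    n_eff, q, and ci (cumulative incidence at the interval's end).
    """

    table: pd.DataFrame
    width: float = 1.0

    def cumulative_incidence(self, t: float) -> float:
        """CI(t) at a time t that is a whole number of intervals."""
        k = int(round(t / self.width))
        if k < 0 or k > len(self.table):
            raise ValueError(f"t={t} outside the table span")
        if k == 0:
            return 0.0
        return float(self.table["ci"].iloc[k - 1])

    @property
    def span(self) -> float:
        return len(self.table) * self.width


def build_life_table(
    workers: Sequence[WorkerRecord], *, width: float = 1.0
) -> LifeTable:
    """Actuarial life table from observation windows.

    A case contributes an event in the interval containing its observed
    years; a non-case contributes a withdrawal there. Within an interval,
    events are counted before withdrawals; withdrawals are half-weighted in
    the denominator.
    """
    if not workers:
        raise ValueError("empty worker list")
    obs = np.array([observation_window(w) for w in workers])
    event = np.array([w.cwp_status for w in workers], dtype=bool)
    k = np.floor(obs / width).astype(int)
    n_int = int(k.max()) + 1
    d = np.bincount(k[event], minlength=n_int)
    w = np.bincount(k[~event], minlength=n_int)
    removed = np.concatenate([[0], np.cumsum(d + w)[:-1]])
    n = len(workers) - removed.astype(float)
    n_eff = n - w / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_eff > 0, d / n_eff, 0.0)
    q = np.clip(q, 0.0, 1.0)
    ci = 1.0 - np.cumprod(1.0 - q)
    table = pd.DataFrame(
        {
            "t": np.arange(n_int) * width,
            "n": n,
            "d": d,
            "w": w,
            "n_eff": n_eff,
            "q": q,
            "ci": ci,
        }
    )
    return LifeTable(table=table, width=width)


def cumulative_incidence_curve(lt: LifeTable) -> pd.DataFrame:
    """The step curve (t, CI(t)) at interval endpoints, starting at (0, 0)."""
    t = np.concatenate([[0.0], (np.arange(len(lt.table)) + 1) * lt.width])
    ci = np.concatenate([[0.0], lt.table["ci"].to_numpy()])
    return pd.DataFrame({"t": t, "ci": ci})


def annual_average_incidence(lt: LifeTable, follow_up: float) -> float:
    """CI(follow_up) / follow_up — the constant-rate incidence summary."""
    if follow_up <= 0:
        raise ValueError("follow_up must be positive")
    if follow_up > lt.span + 1e-9:
        raise ValueError(
            f"follow_up {follow_up} exceeds the table span {lt.span}"
        )
    return lt.cumulative_incidence(follow_up) / follow_up


def peto_logrank(
    group_a: Sequence[WorkerRecord],
    group_b: Sequence[WorkerRecord],
    *,
    weighting: str = "peto",
) -> CurveComparison:
    """Two-sample weighted log-rank comparison of CWP incidence curves.

    With ``weighting="peto"`` each distinct event time is weighted by the
    pooled actuarial survival estimate taken through that time,
    ``S(t_j) = prod_{i<=j}(1 - d_i/n_i)``; ``weighting="logrank"`` uses unit
    weights (the classic log-rank test). The statistic is
    ``(sum_j w_j (O_j - E_j))^2 / sum_j w_j^2 V_j`` on 1 df.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if weighting not in ("peto", "logrank"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t_a = np.array([observation_window(w) for w in group_a])
    e_a = np.array([w.cwp_status for w in group_a], dtype=bool)
    t_b = np.array([observation_window(w) for w in group_b])
    e_b = np.array([w.cwp_status for w in group_b], dtype=bool)
    if t_a.sum() == 0 or t_b.sum() == 0:
        raise ValueError("group with zero observation time")

    event_times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    num = 0.0
    den = 0.0
    s_pool = 1.0
    for t in event_times:
        n1 = float((t_a >= t).sum())
        n2 = float((t_b >= t).sum())
        n = n1 + n2
        d1 = float(((t_a == t) & e_a).sum())
        d2 = float(((t_b == t) & e_b).sum())
        d = d1 + d2
        if n <= 1 or d == 0:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        s_pool *= 1.0 - d / n
        wgt = s_pool if weighting == "peto" else 1.0
        num += wgt * (d1 - e1)
        den += wgt * wgt * v
    if den == 0:
        return CurveComparison(statistic=0.0, df=1, p_value=1.0)
    stat = num * num / den
    return CurveComparison(statistic=stat, df=1, p_value=float(stats.chi2.sf(stat, 1)))


def pearson_chi2(table: Sequence[Sequence[float]] | np.ndarray) -> CurveComparison:
    """Pearson chi-square for an r×c contingency table, no continuity
    correction; df = (r−1)(c−1)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return CurveComparison(statistic=float(stat), df=int(df), p_value=float(p))


@dataclass(frozen=True)
class SubgroupRate:
    """Annual average incidence for one entry-era × category subgroup."""

    era: str
    category: str
    annual_rate: float
    follow_up: float
    ci_at_followup: float
    n: int


def subgroup_rates(
    workers: Sequence[WorkerRecord],
    groups: Mapping[tuple[str, str], Sequence[WorkerRecord]] | None = None,
    *,
    follow_up: float | None = None,
) -> list[SubgroupRate]:
    """Annual average incidence per (era, category) subgroup.

    If ``groups`` is not given, workers are grouped by entry era and
    occupational category derived from their records. ``follow_up=None``
    uses each subgroup's own span (whole intervals fully observed).
    """
    from .cohort import classify_occupation, era_of_year

    if groups is None:
        groups = {}
        for w in workers:
            key = (
                era_of_year(w.first_exposure_date.year),
                classify_occupation(w.segments).value,
            )
            groups.setdefault(key, []).append(w)

    out = []
    for (era, category), members in sorted(groups.items()):
        lt = build_life_table(members)
        fu = follow_up if follow_up is not None else lt.span
        fu = min(fu, lt.span)
        rate = annual_average_incidence(lt, fu)
        out.append(
            SubgroupRate(
                era=era,
                category=category,
                annual_rate=rate,
                follow_up=fu,
                ci_at_followup=lt.cumulative_incidence(fu),
                n=len(members),
            )
        )
    return out
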