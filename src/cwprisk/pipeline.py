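"""End-to-end cohort analysis: simulate/load → derive → life tables →
projection → risk model → calibrated risk report.

Every stage writes delimited-text outputs into a run directory, and a run
re-executed from its persisted config and seed reproduces those outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .cohort import (
    Area,
    ConcentrationTable,
    STUDY_END,
    WorkerRecord,
    derive_exposures,
    read_cohort,
    write_cohort,
)
from .lifetable import (
    build_life_table,
    cumulative_incidence_curve,
    pearson_chi2,
    peto_logrank,
    subgroup_rates,
)
from .projection import ProjectionTable, project_cases, summarize_projection
from .risk import (
    calibrate_thresholds,
    classify_risk,
    confusion_metrics,
    predict_risk,
    split_data,
    train_model,
    variable_importance,
)
from .simulate import CohortSpec, generate_cohort, make_fixture

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("tunneling", "mining", "combining", "helping")
ERA_ORDER = ("1970-", "1980-", "1990-")
DURATION_BINS = (10, 20, 30)
CDE_BINS = (100, 1000)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # input: either paths to an existing cohort, or a synthetic spec
    cohort_path: str | None = None
    segments_path: str | None = None
    concentration_path: str | None = None
    fixture: str | None = None
    synthetic: dict[str, Any] = field(default_factory=dict)
    # analysis options
    lifetable_width: float = 1.0
    life_expectancy: float = 74.0
    windows: tuple[int, ...] = (10, 20, 30)
    rate_era_mapping: dict[str, str] = field(default_factory=lambda: {"1990-": "1980-"})
    hidden_units: int = 9
    split_ratio: float = 0.7
    cutoff: float = 0.2
    mlp_max_iter: int = 300
    expansion: float = 0.5
    study_end: str = STUDY_END.isoformat()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "windows" in d:
            d["windows"] = tuple(d["windows"])
        return cls(**d)


def _strata(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Stratifying factors for the characteristics table and risk report."""
    dur_labels = ["<10", "10-", "20-", "30-"]
    cde_labels = ["<100", "100-", "1000-"]
    return {
        "occupational_category": pd.Categorical(
            df["category"], categories=list(CATEGORY_ORDER)
        ),
        "era_of_first_exposure": pd.Categorical(df["era"], categories=list(ERA_ORDER)),
        "duration_of_exposure": pd.cut(
            df["total_duration"], bins=[-np.inf, *DURATION_BINS, np.inf],
            labels=dur_labels, right=False,
        ),
        "cumulative_dust_exposure": pd.cut(
            df["cde"], bins=[-np.inf, *CDE_BINS, np.inf], labels=cde_labels, right=False
        ),
    }


def report_table2(derived: pd.DataFrame) -> pd.DataFrame:
    """Cases vs non-cases per characteristic stratum with Pearson χ².

    Strata: occupational category; entry era; duration of exposure
    (<10/10-/20-/30- y); cumulative dust exposure (<100/100-/1000- mg-years).
    """
    if derived.empty:
        raise PipelineError("report_table2: empty cohort")
    is_case = derived["cwp_status"].astype(bool)
    rows = []
    for characteristic, strat in _strata(derived).items():
        counts = pd.crosstab(strat, is_case).reindex(
            strat.categories if hasattr(strat, "categories") else None
        ).fillna(0).astype(int)
        cases = counts[True] if True in counts.columns else counts.iloc[:, 0] * 0
        noncases = counts[False] if False in counts.columns else counts.iloc[:, 0] * 0
        if cases.sum() > 0 and noncases.sum() > 0:
            keep = (cases + noncases) > 0
            cmp = pearson_chi2(np.column_stack([cases[keep], noncases[keep]]).T)
            chi2, dfree, p = round(cmp.statistic, 1), cmp.df, cmp.p_display()
        else:
            chi2, dfree, p = "NA", "NA", "NA"
        for i, stratum in enumerate(counts.index):
            rows.append(
                {
                    "characteristic": characteristic,
                    "stratum": str(stratum),
                    "cases": int(cases.iloc[i]),
                    "cases_pct": round(100 * cases.iloc[i] / max(cases.sum(), 1), 1),
                    "noncases": int(noncases.iloc[i]),
                    "noncases_pct": round(
                        100 * noncases.iloc[i] / max(noncases.sum(), 1), 1
                    ),
                    "chi2": chi2 if i == 0 else "",
                    "df": dfree if i == 0 else "",
                    "p": p if i == 0 else "",
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(
    config: RunConfig,
) -> tuple[list[WorkerRecord], pd.DataFrame | None, ConcentrationTable]:
    if config.concentration_path:
        conc = ConcentrationTable.from_csv(config.concentration_path)
    else:
        conc = reference.default_concentration_table()
    if config.fixture:
        records, gt = make_fixture(config.fixture)
    elif config.cohort_path:
        if not config.segments_path:
            raise PipelineError("load: cohort_path given without segments_path")
        records, gt = read_cohort(config.cohort_path, config.segments_path), None
    else:
        spec = CohortSpec(**{"seed": config.seed, **config.synthetic})
        records, gt = generate_cohort(spec, conc)
    return records, gt, conc


def _estimate_rates(
    workers: Sequence[WorkerRecord],
) -> dict[tuple[str, str], float]:
    """Annual average incidence per observed (era, category) subgroup."""
    return {
        (r.era, r.category): r.annual_rate
        for r in subgroup_rates(workers)
        if r.n > 0
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cwprisk")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    study_end = datetime.date.fromisoformat(config.study_end)
    summary: list[str] = []

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("load_inputs")
        records, ground_truth, conc = _load_inputs(config)
        logger.info("cohort loaded: %d workers", len(records))
        write_cohort(records, out / "cohort.csv", out / "segments.csv")
        conc.to_csv(out / "concentrations.csv")
        if ground_truth is not None:
            ground_truth.to_csv(out / "ground_truth.csv", index=False)
        summary.append(f"workers: {len(records)}")

        name = stage("derive_exposures")
        derived = derive_exposures(records, conc)
        derived.to_csv(out / "derived_exposures.csv", index=False, float_format="%.6f")
        n_cases = int(derived["cwp_status"].sum())
        summary.append(f"cases: {n_cases} ({100 * n_cases / len(derived):.1f}%)")

        name = stage("characteristics_report")
        table2 = report_table2(derived)
        table2.to_csv(out / "characteristics.csv", index=False)

        name = stage("life_tables")
        by_cat = {c: [] for c in CATEGORY_ORDER}
        for rec, cat in zip(records, derived["category"]):
            by_cat[cat].append(rec)
        comparisons = []
        for cat, members in by_cat.items():
            if not members:
                continue
            lt = build_life_table(members, width=config.lifetable_width)
            lt.table.to_csv(out / f"lifetable_{cat}.csv", index=False, float_format="%.6f")
            cumulative_incidence_curve(lt).to_csv(
                out / f"curve_{cat}.csv", index=False, float_format="%.6f"
            )
            fu = min(40.0, lt.span)
            summary.append(
                f"CI({fu:.0f}y) {cat}: {100 * lt.cumulative_incidence(fu):.1f}%"
            )
        cats_present = [c for c in CATEGORY_ORDER if by_cat[c]]
        for i, a in enumerate(cats_present):
            for b in cats_present[i + 1:]:
                try:
                    cmp = peto_logrank(by_cat[a], by_cat[b])
                    comparisons.append(
                        {"groupA": a, "groupB": b, "chi2": round(cmp.statistic, 1),
                         "df": cmp.df, "p": cmp.p_display()}
                    )
                except ValueError as exc:
                    logger.warning("comparison %s vs %s skipped: %s", a, b, exc)
        pd.DataFrame(comparisons).to_csv(out / "curve_comparisons.csv", index=False)

        name = stage("subgroup_rates")
        est = subgroup_rates(records)
        rates_df = pd.DataFrame(
            [
                {"era": r.era, "category": r.category, "n": r.n,
                 "follow_up": round(r.follow_up, 1),
                 "ci_at_followup": round(r.ci_at_followup, 4),
                 "annual_rate_per_1000": round(1000 * r.annual_rate, 2)}
                for r in est
            ]
        )
        rates_df.to_csv(out / "subgroup_rates.csv", index=False)
        rates = {(r.era, r.category): r.annual_rate for r in est}
        # fill subgroups unobserved in this cohort from the published defaults
        for key, val in reference.SUBGROUP_ANNUAL_RATES.items():
            rates.setdefault(key, val)

        name = stage("projection")
        noncase = derived[derived["cwp_status"] == 0].copy()
        noncase["age"] = study_end.year - noncase["birth_year"]
        proj = project_cases(
            noncase,
            rates,
            life_expectancy=config.life_expectancy,
            windows=config.windows,
            rate_mapping=config.rate_era_mapping,
        )
        summarize_projection(proj).to_csv(out / "projection_by_age.csv", float_format="%.1f")
        bw = proj.by_window.copy()
        bw.loc["total"] = bw.sum(axis=0)
        bw["total"] = bw.sum(axis=1)
        bw.to_csv(out / "projection_by_window.csv", float_format="%.1f")
        projected_total = proj.grand_total
        summary.append(f"projected new cases within life expectancy: {projected_total:.1f}")

        name = stage("risk_model")
        features = derived[
            ["worker_id", "category", "era", "total_duration", "cde", "cwp_status"]
        ]
        train, valid = split_data(features, config.split_ratio, config.seed)
        model = train_model(
            train, hidden_units=config.hidden_units, seed=config.seed,
            max_iter=config.mlp_max_iter,
        )
        model.save(out / "model.json")
        metrics_rows = []
        for scope, frame in (("validation", valid), ("all", features)):
            m = confusion_metrics(
                model.predict_proba(frame), frame["cwp_status"].to_numpy(), config.cutoff
            )
            metrics_rows.append(
                {"scope": scope, "cutoff": config.cutoff,
                 "accuracy_pct": round(m.accuracy_pct, 1),
                 "sensitivity_pct": round(m.sensitivity_pct, 1),
                 "specificity_pct": round(m.specificity_pct, 1),
                 "tp": m.tp, "tn": m.tn, "n_pos": m.n_pos, "n_neg": m.n_neg}
            )
            if scope == "all":
                summary.append(
                    f"model accuracy at {config.cutoff}: {m.accuracy_pct:.1f}% "
                    f"({m.tp + m.tn} of {m.n})"
                )
        pd.DataFrame(metrics_rows).to_csv(out / "model_metrics.csv", index=False)
        importance = variable_importance(model, valid, seed=config.seed)
        importance.rename("importance").round(4).to_csv(out / "importance.csv")

        name = stage("risk_stratification")
        assessments = predict_risk(model, noncase)
        low_pool = int(
            ((noncase["era"] != "1970-") & (noncase["category"] == "helping")).sum()
        )
        cal = calibrate_thresholds(
            assessments["probability"].to_numpy(),
            projected_total,
            low_pool,
            expansion=config.expansion,
        )
        classified = classify_risk(assessments, cal.c_low, cal.c_high)
        classified.to_csv(out / "risk_report.csv", index=False, float_format="%.6f")
        strata_rows = []
        merged = classified.merge(noncase, on="worker_id")
        for characteristic, strat in _strata(merged).items():
            tab = pd.crosstab(strat, merged["risk_class"]).reindex(
                columns=["low", "middle", "high"], fill_value=0
            )
            for stratum, row in tab.iterrows():
                total = int(row.sum())
                strata_rows.append(
                    {"characteristic": characteristic, "stratum": str(stratum),
                     "n": total,
                     **{f"{c}_n": int(row[c]) for c in ("low", "middle", "high")},
                     **{
                         f"{c}_pct": round(100 * row[c] / total, 1) if total else 0.0
                         for c in ("low", "middle", "high")
                     }}
                )
        pd.DataFrame(strata_rows).to_csv(out / "risk_by_stratum.csv", index=False)
        counts = classified["risk_class"].value_counts()
        summary.append(
            "risk classes (low/middle/high): "
            f"{counts.get('low', 0)}/{counts.get('middle', 0)}/{counts.get('high', 0)} "
            f"at cutoffs ({cal.c_low:.2f}, {cal.c_high:.2f}), "
            f"high-risk target {cal.target_high}"
        )

        name = stage("finalize")
        config.to_yaml(out / "config_resolved.yaml")
        (out / "run_summary.txt").write_text("\n".join(summary) + "\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
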