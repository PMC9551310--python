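"""End-to-end analysis driver and table rendering.

``run_analysis`` wires the pipeline together: life table in, case listing
in, eligibility filters, stratified period (or cohort) estimates of k-year
relative survival with Greenwood errors, optional ICSS age standardization,
and the model-based projection of the next period.  ``render_tables``
formats the resulting tidy frame the way registry survival reports print
it: percentages to one decimal as ``"73.3 ± 0.3"``, with the projected
period as a final column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from .config import RunConfig
from .engine import AnalysisWindow, build_risk_sets, compute_estimate
from .lifetable import PopulationLifeTable, load_lifetable
from .projection import FittingError, build_conditional_grid, \
    fit_projection_model, predict_future_period
from .standardize import age_standardized_rs

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything a run produces, before any formatting."""

    estimates: pd.DataFrame  # tidy: one row per stratum x window (+ projections)
    counts: pd.DataFrame  # descriptive counts per stratum x diagnosis period
    filter_report: ch.FilterReport
    projection_meta: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _estimate_stratum(records, windows, lifetable):
    """Per-window estimates for one stratum; returns (rows, estimates)."""
    rows = []
    ests = []
    frame = ch.records_to_frame(records) if records else pd.DataFrame()
    for win in windows:
        if len(frame) == 0:
            rows.append({"window": win.label, "R": np.nan, "se_R": np.nan,
                         "n_contributing": 0})
            ests.append(None)
            continue
        rs = build_risk_sets(frame, win, lifetable)
        est = compute_estimate(rs)
        k = win.k
        defined = est.defined(k)
        rows.append({
            "window": win.label,
            "R": float(est.R[k - 1]) if defined else np.nan,
            "se_R": float(est.se_R[k - 1]) if defined else np.nan,
            "n_contributing": int(rs.n[0] + rs.entrants.sum()),
        })
        ests.append(est)
    return rows, ests


def _project_label(windows: list[AnalysisWindow], ahead: int) -> str:
    last = windows[-1]
    width = last.end - last.start + 1
    start = last.end + 1 + (ahead - 1) * width
    return f"{start}-{start + width - 1}"


def run_analysis(
    config: RunConfig,
    lifetable: PopulationLifeTable | None = None,
    records: list[ch.PatientRecord] | None = None,
) -> AnalysisResult:
    """Execute the configured analysis; inputs may be passed in-memory."""
    windows = config.analysis_windows()
    if lifetable is None:
        if config.lifetable is None:
            raise ch.ConfigError("no life table configured or supplied")
        lifetable = load_lifetable(config.lifetable, config.lifetable_schema)
    if records is None:
        if config.cases is None:
            raise ch.ConfigError("no case listing configured or supplied")
        parsed = ch.read_case_listing(config.cases, config.case_schema)
        if parsed.errors:
            logger.warning("%d unparseable rows in %s",
                           len(parsed.errors), config.cases)
        records = parsed.records

    kept, report = ch.apply_inclusion_filters(records)
    logger.info("kept %d of %d records (%s)", report.n_kept, report.n_input,
                report.exclusions)

    flags: list[str] = []
    rows = []
    projection_meta: dict = {}
    proj_label = _project_label(windows, config.project_ahead)
    stratifiers = ["overall"] + [s for s in config.stratifiers if s != "overall"]

    by_age_per_window: dict[str, dict] = {}
    for strat in stratifiers:
        strata = ch.stratify_cohort(kept, [strat])
        for stratum in sorted(strata, key=str):
            recs = strata[stratum]
            est_rows, ests = _estimate_stratum(recs, windows, lifetable)
            for row in est_rows:
                rows.append({"stratifier": strat, "stratum": stratum,
                             "standardized": False, **row})
            if strat == "age_group":
                for row in est_rows:
                    by_age_per_window.setdefault(row["window"], {})[stratum] = (
                        row["R"], row["se_R"])
            # projection per stratum across periods
            usable = [e for e in ests if e is not None and e.defined()]
            if len(usable) == len(windows) and len(windows) >= 2:
                try:
                    grid = build_conditional_grid(
                        ests, [w.label for w in windows])
                    model = fit_projection_model(grid, config.projection_link)
                    pred = predict_future_period(
                        model, len(windows) + config.project_ahead)
                    rows.append({
                        "stratifier": strat, "stratum": stratum,
                        "standardized": False,
                        "window": f"projected:{proj_label}",
                        "R": pred.R_hat, "se_R": np.nan,
                        "n_contributing": np.nan,
                    })
                    projection_meta[f"{strat}/{stratum}"] = {
                        "link": model.link, "gamma": model.gamma,
                        "alpha": list(model.alpha),
                        "deviance": model.deviance,
                        "clamped_cells": model.n_clamped,
                        "target": proj_label,
                    }
                except FittingError as exc:
                    flags.append(f"{strat}/{stratum}: projection failed ({exc})")
            else:
                flags.append(f"{strat}/{stratum}: projection skipped "
                             "(undefined windows)")

    if config.standardize:
        weights = config.standard_weights()
        if "age_group" not in stratifiers:
            flags.append("standardize requested without age_group stratifier")
        for window, by_age in by_age_per_window.items():
            R_std, se_std = age_standardized_rs(by_age, weights)
            rows.append({"stratifier": "overall", "stratum": "overall",
                         "standardized": True, "window": window,
                         "R": R_std, "se_R": se_std, "n_contributing": np.nan})

    counts = descriptive_counts(kept, windows, config.stratifiers)
    estimates = pd.DataFrame(rows)
    return AnalysisResult(estimates=estimates, counts=counts,
                          filter_report=report, projection_meta=projection_meta,
                          flags=flags)


def descriptive_counts(records, windows, stratifiers) -> pd.DataFrame:
    """Diagnosis counts per stratum and diagnosis-period, Table-1 shaped."""
    rows = []
    for strat in ["overall"] + [s for s in stratifiers if s != "overall"]:
        strata = ch.stratify_cohort(records, [strat])
        for stratum in sorted(strata, key=str):
            row = {"stratifier": strat, "stratum": stratum}
            for win in windows:
                n = sum(1 for r in strata[stratum]
                        if win.start <= r.dx_year <= win.end)
                row[win.label] = n
            rows.append(row)
    return pd.DataFrame(rows)


def format_pct(R: float, se: float | None = None) -> str:
    """``"73.3 ± 0.3"`` with half-even rounding; missing values render as em dash."""
    if R is None or not np.isfinite(R):
        return "—"
    r = f"{np.round(100.0 * R, 1):.1f}"
    if se is None or not np.isfinite(se):
        return r
    return f"{r} ± {np.round(100.0 * se, 1):.1f}"


def render_tables(estimates: pd.DataFrame, fmt: str = "csv") -> str:
    """Render the estimate frame as CSV or a GitHub-style markdown table.

    One row per stratum, one column per window (observed windows show
    ``mean ± se`` percent; the projected column a point estimate).  Raw
    unrounded values live in the tidy CSV written alongside.
    """
    if fmt not in ("csv", "markdown"):
        raise ValueError(f"unknown format {fmt!r}")
    df = estimates[~estimates["standardized"]].copy()
    df["cell"] = [format_pct(R, se) for R, se in zip(df["R"], df["se_R"])]
    wide = df.pivot_table(index=["stratifier", "stratum"], columns="window",
                          values="cell", aggfunc="first", sort=False)
    windows = list(dict.fromkeys(df["window"]))  # preserve configured order
    wide = wide[windows].reset_index().fillna("—")
    if fmt == "csv":
        return wide.to_csv(index=False)
    header = "| " + " | ".join(map(str, wide.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(wide.columns)) + "|"
    body = ["| " + " | ".join(map(str, row)) + " |"
            for row in wide.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"


def write_outputs(result: AnalysisResult, config: RunConfig) -> Path:
    """Write the tidy CSV, rendered tables, reports, and resolved config."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.estimates.to_csv(out / "estimates.csv", index=False)
    (out / "table_survival.csv").write_text(render_tables(result.estimates, "csv"))
    (out / "table_survival.md").write_text(
        render_tables(result.estimates, "markdown"))
    result.counts.to_csv(out / "table_counts.csv", index=False)
    (out / "filter_report.json").write_text(
        json.dumps(result.filter_report.to_dict(), indent=2))
    (out / "projection_meta.json").write_text(
        json.dumps(result.projection_meta, indent=2))
    if result.flags:
        (out / "flags.log").write_text("\n".join(result.flags) + "\n")
    config.to_yaml(out / "config.resolved.yaml")
    return out
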