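"""End-to-end surveillance pipeline.

Runs indicators -> cow-level models -> 21-day cohorts -> quartile-threshold
screening -> attributable-fraction series and writes a report bundle:

* ``descriptive.csv``   — outcome percentages and mean milk per stratum
* ``cow_models.csv``    — BCS/ΔBCS odds ratios and milk estimates per stratum
* ``cohorts.csv``       — per-cohort counts, exposure prevalence, pd
* ``thresholds.csv``    — quartile-threshold screening (OR, Se, Sp, AUC, cells)
* ``selected_thresholds.csv`` — the max-AUC threshold per stratum
* ``afp_series.csv``    — per-cohort anestrus rate, pd, aRR and AF_P
* ``manifest.json``     — config, seed, package version, row counts per stage

Re-running with the same configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .attributable import afp_series
from .cohorts import DEFAULT_MIN_COHORT, DEFAULT_WINDOW, assign_cohorts, summarize_cohorts
from .indicators import OUTCOMES, ExposureRule, add_indicators
from .io import read_cow_records, write_cow_records
from .models import cow_model_report
from .screening import screen_stratum, screening_report, select_threshold
from .synthetic import default_study_configs, generate_herd

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``input_path=None`` generates the default two-herd synthetic study with
    ``seed`` instead of reading a CSV.
    """

    input_path: str | None = None
    output_dir: str = "bcsherd_out"
    bcs_cut: float = 3.0
    loss_cut: float = 0.5
    window: int = DEFAULT_WINDOW
    min_cohort_size: int = DEFAULT_MIN_COHORT
    quantile_method: str = "linear"
    coding: str = "protective"          # threshold OR coding: protective | risk
    arr_mode: str = "standardized"      # standardized | or-as-rr
    arr_scope: str = "stratum"          # stratum | cohort
    n_boot: int = 0
    seed: int = 0
    n_cows_per_year: int | None = None  # override for synthetic input

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_cohort_size < 1:
            raise ValueError("min_cohort_size must be >= 1")
        for name, value, allowed in (
                ("coding", self.coding, ("protective", "risk")),
                ("arr_mode", self.arr_mode, ("standardized", "or-as-rr")),
                ("arr_scope", self.arr_scope, ("stratum", "cohort"))):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")

    @property
    def rule(self) -> ExposureRule:
        return ExposureRule(bcs_cut=self.bcs_cut, loss_cut=self.loss_cut)


def load_records(config: RunConfig) -> pd.DataFrame:
    """Read the input CSV, or generate the default synthetic study."""
    if config.input_path is not None:
        return read_cow_records(config.input_path)
    frames = []
    for cfg in default_study_configs(config.seed).values():
        if config.n_cows_per_year is not None:
            cfg = dataclasses.replace(cfg, n_cows_per_year=config.n_cows_per_year)
        frames.append(generate_herd(cfg))
    return pd.concat(frames, ignore_index=True)


def descriptive_report(records: pd.DataFrame) -> pd.DataFrame:
    """Outcome percentages and mean first-test milk per herd × parity stratum."""
    g = records.groupby(["herd", "parity_group"], sort=True)
    out = g[list(OUTCOMES)].mean().mul(100).round(1)
    out.columns = [f"{c}_pct" for c in OUTCOMES]
    out["milk_mean"] = g["milk_kg"].mean().round(1)
    out["n"] = g.size()
    return out.reset_index()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the tables.

    Any stage failure is re-raised annotated with the stage name; a
    machine-readable error record is written to ``error.json`` in the output
    directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }
    results: dict = {}
    stage = "load"
    try:
        records = load_records(config)
        manifest["stages"]["load"] = {"rows": len(records)}
        if config.input_path is None:
            write_cow_records(records, outdir / "records.csv")

        stage = "indicators"
        records = add_indicators(records, config.rule)
        n_missing = int(records["exposed"].isna().sum())
        manifest["stages"]["indicators"] = {"rows": len(records),
                                            "missing_exposure": n_missing}

        stage = "descriptive"
        desc = descriptive_report(records)
        results["descriptive"] = desc

        stage = "cow_models"
        cow_report = cow_model_report(records)
        results["cow_models"] = cow_report
        manifest["stages"]["cow_models"] = {"rows": len(cow_report)}

        stage = "cohorts"
        records = assign_cohorts(records, window=config.window)
        summaries = summarize_cohorts(records, config.rule,
                                      min_cohort_size=config.min_cohort_size,
                                      window=config.window)
        results["cohorts"] = summaries
        manifest["stages"]["cohorts"] = {
            "rows": len(summaries),
            "included": int(summaries["included"].sum()) if len(summaries) else 0,
            "excluded_below_min": int((~summaries["included"]).sum()) if len(summaries) else 0,
            "min_cohort_size": config.min_cohort_size,
        }

        stage = "screen"
        evals, selected = [], []
        for (_, _), strat in summaries.groupby(["herd", "parity_group"], sort=True):
            try:
                es = screen_stratum(strat, quantile_method=config.quantile_method,
                                    coding=config.coding)
            except ValueError as exc:
                logger.warning("screening skipped for a stratum: %s", exc)
                continue
            evals.extend(es)
            selected.append(select_threshold(es))
        results["thresholds"] = screening_report(evals)
        results["selected_thresholds"] = screening_report(selected)
        manifest["stages"]["screen"] = {"rows": len(results["thresholds"]),
                                        "strata_selected": len(selected)}
        if not evals:
            manifest["stages"]["screen"]["note"] = (
                f"no stratum had enough cohorts with >= {config.min_cohort_size} "
                "calvings and both median-split classes")

        stage = "afp"
        series = afp_series(records, summaries, config.rule, mode=config.arr_mode,
                            arr_scope=config.arr_scope, n_boot=config.n_boot,
                            seed=config.seed)
        results["afp_series"] = series
        manifest["stages"]["afp"] = {"rows": len(series)}
    except Exception as exc:
        record = {"stage": stage, "error": type(exc).__name__, "detail": str(exc)}
        (outdir / "error.json").write_text(json.dumps(record, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, frame in (("descriptive", desc), ("cow_models", cow_report),
                        ("cohorts", summaries), ("thresholds", results["thresholds"]),
                        ("selected_thresholds", results["selected_thresholds"]),
                        ("afp_series", series)):
        frame.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                     default=str))
    results["manifest"] = manifest
    return results


def plot_afp_series(series: pd.DataFrame, path: str | Path) -> None:
    """Plain line plot of the paired (anestrus rate, AF_P) series per stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = list(series.groupby(["herd", "parity_group"], sort=True))
    fig, axes = plt.subplots(len(strata), 1, figsize=(8, 2.6 * max(len(strata), 1)),
                             squeeze=False, sharex=True)
    for ax, ((herd, pg), s) in zip(axes.ravel(), strata):
        s = s.sort_values("cohort_index")
        ax.plot(s["cohort_index"], s["anestrus_rate"], marker="o", ms=2,
                label="anestrus rate")
        ax.plot(s["cohort_index"], s["afp"], marker="s", ms=2, label="AF_P")
        ax.set_title(f"herd {herd}, {pg}s")
        ax.set_ylabel("proportion")
        ax.legend(fontsize=8)
    axes.ravel()[-1].set_xlabel("21-day cohort index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
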