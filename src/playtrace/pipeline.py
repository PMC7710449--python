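"""End-to-end orchestration: telemetry -> sequences -> chain -> measures -> stats.

A pipeline run reads an event log and a cohort outcome table, then emits the
full report bundle: encoded sequences, the pooled transition matrix, per-child
measures with their cohort summary, the treatment-vs-control comparison, the
Kendall screening table, the normal and Poisson outcome regressions (with and
without the baseline-preference adjustment), and a run manifest with
CONSORT-style accounting of who entered and who was excluded at each stage.

Site exclusions are asymmetric by design: play-pattern outputs (sequences,
chain, measures) use all sites, while outcome analyses honor the exclusion
list — matching a trial in which one school's food choices were contaminated
by an unblinded choice setting while its telemetry remained valid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .association import (
    distribution_fit_aic,
    fit_linear_robust,
    fit_poisson_robust,
    screen_measures,
    stepwise_select,
)
from .markov_model import TransitionMatrix, estimate_transition_matrix
from .outcome_stats import GroupComparison, compare_groups
from .play_measures import MEASURE_NAMES, compute_cohort_measures, summarize_measures
from .sequence_builder import build_level_sequences, filter_first_encounters, plays_to_frame
from .telemetry_io import (
    cohort_to_frame,
    load_food_taxonomy,
    read_cohort_table,
    read_event_log,
)

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline", "render_report"]

logger = logging.getLogger("playtrace")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and options of one pipeline run."""

    events_path: Union[str, Path]
    outcomes_path: Union[str, Path]
    taxonomy_path: Optional[Union[str, Path]] = None
    events_dialect: str = "csv"
    first_encounters_only: bool = True
    smoothing_alpha: float = 0.5
    exclude_schools: tuple[str, ...] = ()
    level: Optional[int] = None            # restrict the chain to one level
    mw_mode: str = "auto"
    se_linear: str = "HC1"
    se_poisson: str = "HC0"
    out_dir: Optional[Union[str, Path]] = None
    log_level: str = "INFO"


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    sequences: pd.DataFrame
    matrix: TransitionMatrix
    measures: pd.DataFrame
    summary: pd.DataFrame
    group_comparison: pd.DataFrame
    screen: pd.DataFrame
    regressions: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "sequences": self.sequences,
            "markov_matrix": self.matrix.to_frame("probs").reset_index(names="state"),
            "measures": self.measures,
            "measures_summary": self.summary.reset_index(),
            "group_comparison": self.group_comparison,
            "kendall_screen": self.screen.reset_index(),
            "regressions": self.regressions,
        }


def _comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "outcome": c.outcome, "mean_t": c.mean_t, "sd_t": c.sd_t, "n_t": c.n_t,
        "mean_c": c.mean_c, "sd_c": c.sd_c, "n_c": c.n_c,
        "u_statistic": c.u_statistic, "p_value": c.p_value, "cohens_d": c.cohens_d,
    } for c in comparisons])


def _group_values(frame: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
    t = frame.loc[frame["group"] == "treatment", col].dropna().to_numpy(float)
    c = frame.loc[frame["group"] == "control", col].dropna().to_numpy(float)
    return t, c


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and return (and optionally write) the report bundle."""
    logging.basicConfig()
    logger.setLevel(config.log_level.upper())
    manifest: dict = {"package_version": _pkg_version,
                      "options": {
                          "first_encounters_only": config.first_encounters_only,
                          "smoothing_alpha": config.smoothing_alpha,
                          "exclude_schools": list(config.exclude_schools),
                          "level": config.level,
                          "mw_mode": config.mw_mode,
                          "se_linear": config.se_linear,
                          "se_poisson": config.se_poisson,
                      }}
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _write(name: str, df: pd.DataFrame) -> None:
        if out_dir is not None:
            df.to_csv(out_dir / f"{name}.csv", index=False)

    # ---- telemetry ingestion -------------------------------------------
    stage = "read events"
    try:
        rejects: list = []
        events = read_event_log(config.events_path, dialect=config.events_dialect,
                                rejects=rejects)
        children = read_cohort_table(config.outcomes_path)
        taxonomy = (load_food_taxonomy(config.taxonomy_path)
                    if config.taxonomy_path is not None else None)
        manifest["counts"] = {"events": len(events), "rejected_records": len(rejects)}
        logger.info("stage=%s events=%d rejects=%d", stage, len(events), len(rejects))

        # ---- sequences (all sites) -------------------------------------
        stage = "sequence building"
        plays_all = build_level_sequences(events)
        plays = filter_first_encounters(plays_all) if config.first_encounters_only else plays_all
        seq_df = plays_to_frame(plays)
        _write("sequences", seq_df)
        manifest["counts"].update({
            "sequences_total": len(plays_all),
            "replays_removed": len(plays_all) - len(plays),
            "sequences_analyzed": len(plays),
            "children_with_telemetry": seq_df["child_id"].nunique(),
        })
        logger.info("stage=%s total=%d analyzed=%d", stage, len(plays_all), len(plays))

        # ---- Markov chain ----------------------------------------------
        stage = "markov estimation"
        chain_plays = [p for p in plays if config.level is None or p.level == config.level]
        matrix = estimate_transition_matrix(chain_plays)
        if out_dir is not None:
            matrix.to_frame("probs").to_csv(out_dir / "markov_matrix.csv",
                                            index_label="state")
        manifest["counts"]["sequences_in_chain"] = matrix.n_sequences

        # ---- measures + summary (all sites) ----------------------------
        stage = "measure computation"
        fact_events = [e for e in events if e.event_class == "fact_read"]
        measures = compute_cohort_measures(plays, fact_events, taxonomy,
                                           alpha=config.smoothing_alpha)
        summary = summarize_measures(measures)
        _write("measures", measures)
        if out_dir is not None:
            summary.reset_index().to_csv(out_dir / "measures_summary.csv", index=False)

        # ---- CONSORT accounting for outcome analyses -------------------
        stage = "cohort filtering"
        cohort = cohort_to_frame(children)
        excluded_school = cohort["school"].isin(config.exclude_schools)
        incomplete = cohort["GoodChoice"].isna() & ~excluded_school
        analyzed = cohort[~excluded_school & ~incomplete]
        manifest["children"] = {
            "in": len(cohort),
            "analyzed": int(len(analyzed)),
            "excluded": {"school_excluded": int(excluded_school.sum()),
                         "incomplete_outcomes": int(incomplete.sum())},
        }
        logger.info("stage=%s in=%d analyzed=%d", stage, len(cohort), len(analyzed))

        # ---- group comparison ------------------------------------------
        stage = "group comparison"
        eligible = cohort[~excluded_school].copy()
        eligible["GoodChoiceChange"] = eligible["good_choice_day2"] - eligible["good_choice_day1"]
        eligible["GoodIDChange"] = eligible["good_id_day2"] - eligible["good_id_day1"]
        comparisons = []
        for name in ("GoodChoice", "GoodID", "GoodChoiceChange", "GoodIDChange"):
            t, c = _group_values(eligible, name)
            if len(t) >= 2 and len(c) >= 2:
                comparisons.append(compare_groups(name, t, c, mode=config.mw_mode))
        comparison_df = _comparison_frame(comparisons)
        _write("group_comparison", comparison_df)

        # ---- association screening + regressions -----------------------
        stage = "association analysis"
        data = measures.merge(eligible[["child_id", "group", "GoodChoice", "good_base"]],
                              on="child_id", how="inner")
        data = data[data["group"] == "treatment"].dropna(subset=["GoodChoice"])
        screen = screen_measures(data, "GoodChoice", MEASURE_NAMES)
        if out_dir is not None:
            screen.reset_index().to_csv(out_dir / "kendall_screen.csv", index=False)

        fit = distribution_fit_aic(data["GoodChoice"])
        manifest["distribution_fit"] = {"aic_normal": fit.aic_normal,
                                        "aic_poisson": fit.aic_poisson,
                                        "chosen": fit.chosen}
        manifest["stepwise_selected"] = stepwise_select(
            data["GoodChoice"], data[list(MEASURE_NAMES)])

        stage = "outcome regressions"
        y = data["GoodChoice"].to_numpy(float)
        X_facts = data[["AvgGFact", "AvgBFact"]]
        adj = data.dropna(subset=["good_base"])
        y_adj = adj["GoodChoice"].to_numpy(float)
        X_adj = adj[["AvgGFact", "AvgBFact", "good_base"]].rename(
            columns={"good_base": "GoodBase"})
        models = [
            ("model1", fit_linear_robust(y, X_facts, cov_type=config.se_linear)),
            ("model2", fit_linear_robust(y_adj, X_adj, cov_type=config.se_linear)),
            ("model3", fit_poisson_robust(y, X_facts, cov_type=config.se_poisson)),
            ("model4", fit_poisson_robust(y_adj, X_adj, cov_type=config.se_poisson)),
        ]
        rows = []
        for name, res in models:
            for t in res.terms:
                rows.append({"model": name, "family": res.family, "term": t.name,
                             "coefficient": t.coefficient, "robust_se": t.robust_se,
                             "p_value": t.p_value, "aic": res.aic,
                             "adj_r2": res.adj_r2, "n": res.n})
        regressions = pd.DataFrame(rows)
        _write("regressions", regressions)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return ReportBundle(sequences=seq_df, matrix=matrix, measures=measures,
                        summary=summary, group_comparison=comparison_df,
                        screen=screen, regressions=regressions, manifest=manifest)


def _df_to_markdown(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    def fmt(v) -> str:
        if isinstance(v, float):
            return "" if pd.isna(v) else floatfmt.format(v)
        return "" if v is None else str(v)

    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)


def render_report(bundle: ReportBundle, out_dir: Union[str, Path],
                  format: str = "markdown") -> list[Path]:
    """Render the bundle as human-readable tables (markdown) or CSV files."""
    if format not in ("markdown", "csv"):
        raise ValueError(f"unknown format {format!r}")
    tables = bundle.tables()
    empty = [name for name, df in tables.items() if df is None or len(df) == 0]
    if empty:
        raise ValueError(f"report bundle is incomplete; empty tables: {empty}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "csv":
        for name, df in tables.items():
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        return written
    titles = {
        "sequences": "Encoded play sequences",
        "markov_matrix": "Pooled transition matrix (probabilities)",
        "measures": "Per-child gameplay measures",
        "measures_summary": "Gameplay measure summary",
        "group_comparison": "Treatment vs control outcomes",
        "kendall_screen": "Kendall correlation screen",
        "regressions": "Outcome regressions",
    }
    parts = ["# Pipeline report", ""]
    for name, df in tables.items():
        if name == "sequences" and len(df) > 50:
            df = df.head(50)
        parts += [f"## {titles[name]}", "", _df_to_markdown(df), ""]
    path = out_dir / "report.md"
    path.write_text("\n".join(parts), encoding="utf-8")
    written.append(path)
    return written
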