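"""End-to-end orchestration: simulate -> rank -> fit -> scan -> report.

`run_pipeline` accepts a survey CSV path, an in-memory respondent table,
or a :class:`~ranknorms.cohort.CohortConfig` (in which case a synthetic
cohort is generated first), then builds reference groups, applies the
judgment-eligibility filter, assigns ranks, fits Models 1-4 for each of
the four outcomes, computes the BrAC-vs-rank collinearity diagnostics,
scans eta per outcome, and assembles everything into an
:class:`AnalysisReport` that serializes to JSON and renders as plain
text tables.  Every filtering step logs counts in and out.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    RATING_COLUMNS,
    CohortConfig,
    JudgementMechanism,
    generate_judgements,
    generate_pool,
)
from .etascan import EtaProfile, scan_eta
from .io import read_survey_csv, write_survey_csv
from .ranks import assign_ranks, build_reference_groups, mean_comparison_set_size
from .regression import (
    OUTCOME_LABELS,
    ModelFit,
    compute_vif,
    descriptives,
    fit_ladder,
    spearman_rho,
)

logger = logging.getLogger(__name__)

#: Per-outcome rank mechanisms whose intercept/slope and residual SD echo
#: the study's printed Model 2 coefficients and R2 (residual SD derived as
#: outcome SD * sqrt(1 - R2)).  Used when simulating a default cohort.
DEFAULT_MECHANISMS: Mapping[str, JudgementMechanism] = {
    "judge_drunk": JudgementMechanism("rank", intercept=2.78, slope=3.42, noise_sd=1.75),
    "judge_extreme": JudgementMechanism("rank", intercept=3.14, slope=2.77, noise_sd=2.12),
    "judge_health15y": JudgementMechanism("rank", intercept=4.76, slope=3.19, noise_sd=3.08),
    "judge_cirrhosis15y": JudgementMechanism("rank", intercept=4.49, slope=3.38, noise_sd=3.18),
}


@dataclass
class AnalysisConfig:
    """Tunables of the analysis stage (not of the data generator)."""

    eta_grid_start: float = 0.01
    eta_grid_stop: float = 5.0
    eta_grid_step: float = 0.01
    ties: str = "strict"            # or "midrank"
    group_mean_as_distance: bool = True  # regressor: BrAC - group mean (else raw group mean)
    outcomes: tuple[str, ...] = RATING_COLUMNS

    def to_dict(self) -> dict:
        return {
            "eta_grid_start": self.eta_grid_start,
            "eta_grid_stop": self.eta_grid_stop,
            "eta_grid_step": self.eta_grid_step,
            "ties": self.ties,
            "group_mean_as_distance": self.group_mean_as_distance,
            "outcomes": list(self.outcomes),
        }


class PipelineError(RuntimeError):
    """The pipeline cannot proceed (e.g. no judgment-eligible respondents)."""


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, plus provenance."""

    descriptives: dict
    group_summary: dict
    fits: dict[str, dict[int, ModelFit]]
    collinearity: dict
    eta_profiles: dict[str, EtaProfile]
    filter_log: list[dict]
    provenance: dict
    timestamp: str = ""

    def to_dict(self, include_eta_grids: bool = False) -> dict:
        d = {
            "descriptives": {
                "table1": self.descriptives["table1"].to_dict(orient="records"),
                "gender_t": self.descriptives["gender_t"],
                "location_anova": self.descriptives["location_anova"],
            },
            "group_summary": self.group_summary,
            "table2": {
                out: {str(m): fit.to_dict() for m, fit in by_model.items()}
                for out, by_model in self.fits.items()
            },
            "collinearity": self.collinearity,
            "eta_results": {
                out: prof.to_dict(include_grid=include_eta_grids)
                for out, prof in self.eta_profiles.items()
            },
            "filter_log": self.filter_log,
            "provenance": self.provenance,
        }
        return _jsonable(d)

    def to_json(self, include_timestamp: bool = True, **kw) -> str:
        d = self.to_dict(**kw)
        if include_timestamp:
            d["timestamp"] = self.timestamp
        return json.dumps(d, indent=2, sort_keys=True, allow_nan=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if (np.isnan(f) or np.isinf(f)) else f
    return obj


def build_analysis_frame(ranked: pd.DataFrame, group_mean_as_distance: bool = True) -> pd.DataFrame:
    """Map a ranked respondent table onto regression-variable names.

    Produces columns ``brac``, ``rank``, ``group_mean_distance`` (or the
    raw ``group_mean`` regressor — the two span the same column space
    alongside ``brac``, so fits are R2-identical), ``duration``,
    ``after_11pm``, ``male``, ``fast``, ``age`` and the four outcomes.
    """
    frame = pd.DataFrame(
        {
            "brac": ranked["brac_ug_per_100ml"].astype(float),
            "rank": ranked["R"].astype(float),
            "duration": ranked["session_duration_h"].astype(float),
            "after_11pm": ranked["survey_after_23h"].astype(float),
            "male": (ranked["gender"] == "M").astype(float),
            "fast": ranked["fast_score"].astype(float),
            "age": ranked["age_years"].astype(float),
        }
    )
    if group_mean_as_distance:
        frame["group_mean_distance"] = (
            ranked["brac_ug_per_100ml"] - ranked["group_mean"]
        ).astype(float)
    else:
        frame["group_mean_distance"] = ranked["group_mean"].astype(float)
    for out in RATING_COLUMNS:
        if out in ranked.columns:
            frame[out] = ranked[out].astype(float)
    for carry in ("below", "above", "n_group"):
        frame[carry] = ranked[carry].astype(float)
    return frame


def _simulate(cohort_config: CohortConfig, seed: int | None,
              mechanisms: Mapping[str, JudgementMechanism] | None) -> pd.DataFrame:
    base_seed = cohort_config.seed if seed is None else seed
    pool = generate_pool(cohort_config, seed=base_seed)
    judgements = generate_judgements(
        pool,
        mechanisms or DEFAULT_MECHANISMS,
        n_sub=cohort_config.judgement_subsample,
        seed=base_seed + 1,
    )
    # merge ratings back into the pool table (one survey table, subsample rated)
    survey = pool.set_index("id")
    rated = judgements.set_index("id")
    for col in RATING_COLUMNS:
        survey.loc[rated.index, col] = rated[col]
    return survey.reset_index()


def run_pipeline(
    source: str | Path | pd.DataFrame | CohortConfig,
    analysis_config: AnalysisConfig | None = None,
    seed: int | None = None,
    mechanisms: Mapping[str, JudgementMechanism] | None = None,
) -> AnalysisReport:
    """Execute the full analysis and return an :class:`AnalysisReport`.

    ``source`` may be a survey CSV path, an already-loaded respondent
    table, or a :class:`CohortConfig` to simulate from.  ``seed``
    overrides the cohort config's seed when simulating (it has no effect
    on the deterministic analysis of an existing table).
    """
    cfg = analysis_config or AnalysisConfig()
    filter_log: list[dict] = []

    if isinstance(source, CohortConfig):
        survey = _simulate(source, seed, mechanisms)
        source_desc = {"kind": "synthetic", "cohort_config": source.to_dict(),
                       "config_hash": source.config_hash(),
                       "seed": source.seed if seed is None else seed}
    elif isinstance(source, pd.DataFrame):
        survey = source.copy()
        source_desc = {"kind": "table", "n_rows": len(survey)}
    else:
        survey = read_survey_csv(source)
        source_desc = {"kind": "csv", "path": str(source),
                       "sha256": hashlib.sha256(Path(source).read_bytes()).hexdigest()}

    groups = build_reference_groups(survey)
    group_summary = {
        "n_groups": len(groups),
        "sizes": {f"{g}|{loc}": grp.n for (g, loc), grp in sorted(groups.items())},
        "mean_comparison_set_size": mean_comparison_set_size(groups),
    }

    has_any_rating = survey[list(RATING_COLUMNS)].notna().any(axis=1)
    drinkers = survey["brac_ug_per_100ml"] > 0
    eligible = survey[has_any_rating & drinkers]
    filter_log.append({"step": "rated respondents", "n_in": int(len(survey)),
                       "n_out": int(has_any_rating.sum())})
    filter_log.append({"step": "judgment-eligible (BrAC > 0)",
                       "n_in": int(has_any_rating.sum()), "n_out": int(len(eligible))})
    logger.info("eligibility: %d surveyed -> %d rated -> %d with BrAC > 0",
                len(survey), int(has_any_rating.sum()), len(eligible))
    if len(eligible) == 0:
        raise PipelineError("no judgment-eligible respondents (need ratings and BrAC > 0)")

    ranked = assign_ranks(eligible, survey, ties=cfg.ties)
    frame = build_analysis_frame(ranked, cfg.group_mean_as_distance)

    desc = descriptives(survey, eligible)
    fits = fit_ladder(frame, outcomes=cfg.outcomes)

    complete_m3 = frame[["brac", "rank", "group_mean_distance"]].dropna()
    collinearity = {
        "spearman_rho_brac_rank": spearman_rho(complete_m3["brac"], complete_m3["rank"]),
        "pearson_r_brac_rank": float(np.corrcoef(complete_m3["brac"], complete_m3["rank"])[0, 1]),
        "vif_model3": {k: float(v) for k, v in compute_vif(complete_m3).items()},
        "group_mean_regressor": (
            "distance (BrAC - group mean)" if cfg.group_mean_as_distance else "raw group mean"
        ),
    }

    eta_profiles = {}
    for out in cfg.outcomes:
        if out not in frame.columns or frame[out].notna().sum() < 10:
            logger.warning("eta scan skipped for %s (insufficient data)", out)
            continue
        eta_profiles[out] = scan_eta(
            frame, out, cfg.eta_grid_start, cfg.eta_grid_stop, cfg.eta_grid_step
        )

    provenance = {
        "software": f"ranknorms {__version__}",
        "source": source_desc,
        "analysis_config": cfg.to_dict(),
        "analysis_config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    }
    return AnalysisReport(
        descriptives=desc,
        group_summary=group_summary,
        fits=fits,
        collinearity=collinearity,
        eta_profiles=eta_profiles,
        filter_log=filter_log,
        provenance=provenance,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def render_report_text(report: AnalysisReport) -> str:
    """Plain-text tables for terminal / log consumption."""
    lines: list[str] = []
    lines.append("=" * 72)
    lines.append("Rank-based social-norms analysis of intoxication judgments")
    lines.append("=" * 72)

    gs = report.group_summary
    lines.append(f"\nReference groups: {gs['n_groups']} "
                 f"(mean comparison-set size {gs['mean_comparison_set_size']:.2f})")
    for key, n in gs["sizes"].items():
        lines.append(f"  {key:>6}: n = {n}")

    lines.append("\n-- Descriptives (judgment subsample) " + "-" * 34)
    t1 = report.descriptives["table1"]
    for _, row in t1.iterrows():
        sd = "" if pd.isna(row["sd"]) else f"  SD {row['sd']:.2f}"
        lines.append(f"  {row['variable']:<36} {row['value']:>7.2f}{sd}")
    gt = report.descriptives["gender_t"]
    if not np.isnan(gt.get("t", float("nan"))):
        lines.append(
            f"  BrAC by gender: male {gt['male_mean']:.1f} (SD {gt['male_sd']:.1f}, n={gt['n_male']}) "
            f"vs female {gt['female_mean']:.1f} (SD {gt['female_sd']:.1f}, n={gt['n_female']}); "
            f"t = {gt['t']:.2f}, p = {gt['p']:.2g}"
        )
    la = report.descriptives["location_anova"]
    if not np.isnan(la.get("F", float("nan"))):
        lines.append(f"  BrAC by location: F({la['df_between']}, {la['df_within']}) "
                     f"= {la['F']:.1f}, p = {la['p']:.2g}")

    lines.append("\n-- Collinearity " + "-" * 55)
    col = report.collinearity
    lines.append(f"  Spearman rho(BrAC, rank) = {col['spearman_rho_brac_rank']:.3f}")
    for name, v in col["vif_model3"].items():
        lines.append(f"  VIF {name:<22} = {v:.2f}")

    lines.append("\n-- Regression ladder (b [95% CI] beta; R2) " + "-" * 28)
    for out, by_model in report.fits.items():
        lines.append(f"\n  Outcome: {OUTCOME_LABELS.get(out, out)}")
        for mid, fit in sorted(by_model.items()):
            lines.append(f"    Model {mid} (n={fit.n_used}, R2={fit.r_squared:.3f})")
            for name, row in fit.params.iterrows():
                lines.append(
                    f"      {name:<22} b={row['b']:>8.3f} "
                    f"[{row['ci_low']:>7.3f}, {row['ci_high']:>7.3f}] "
                    f"beta={row['beta']:>6.3f} {row['stars']}"
                )

    lines.append("\n-- Comparison-bias parameter eta " + "-" * 38)
    for out, prof in report.eta_profiles.items():
        lines.append(
            f"  {OUTCOME_LABELS.get(out, out):<24} best eta = {prof.best_eta:.2f} "
            f"(R2 = {prof.best_r_squared:.3f})"
        )
    lines.append("")
    return "\n".join(lines)


def brac_histogram(survey: pd.DataFrame, path: str | Path, by_gender: bool = True):
    """Histogram of positive BrAC readings (optionally split by gender).

    Requires matplotlib; import deferred so the core pipeline has no
    plotting dependency.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    drinkers = survey[survey["brac_ug_per_100ml"] > 0]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    bins = np.arange(0, drinkers["brac_ug_per_100ml"].max() + 10, 10)
    if by_gender:
        for g, label in (("M", "Male"), ("F", "Female")):
            ax.hist(drinkers.loc[drinkers["gender"] == g, "brac_ug_per_100ml"],
                    bins=bins, alpha=0.6, label=label)
        ax.legend()
    else:
        ax.hist(drinkers["brac_ug_per_100ml"], bins=bins)
    ax.set_xlabel("BrAC (ug alcohol / 100 ml breath)")
    ax.set_ylabel("Respondents")
    ax.set_title("Breath alcohol, positive readings")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def response_rate_percent(n_accepted: int, n_invited: int) -> int:
    """Participation rate as a rounded whole percentage."""
    if n_invited <= 0:
        raise ValueError("n_invited must be positive")
    return round(100 * n_accepted / n_invited)


__all__ = [
    "AnalysisConfig", "AnalysisReport", "DEFAULT_MECHANISMS", "PipelineError",
    "build_analysis_frame", "brac_histogram", "render_report_text",
    "response_rate_percent", "run_pipeline", "write_survey_csv",
]
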