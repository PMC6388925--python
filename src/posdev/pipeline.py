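"""End-to-end orchestration of the positive-deviance workflow.

Runs, in order: indicator computation, relative-performance residuals,
Pareto ranking, deviance profiling, diverse case selection, and (when a
practice catalog is supplied) resource-homologue matching with practice
targeting. Stage outputs are written as CSV tables plus one JSON run
summary; two runs with identical inputs, config and seed produce identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .case_selection import SELECTION_CHARACTERISTICS, select_diverse_cases
from .deviance_profile import (
    assign_strata,
    compare_groups,
    deviance_correlations,
    stratum_mean_deviance,
    z_transform,
)
from .indicators import performance_matrix
from .io_config import PipelineConfig, ValidationReport, validate_and_filter
from .pareto_ranking import pareto_ranks, positive_deviants
from .relative_performance import market_access_proxy, relative_performance
from .resource_homologues import nearest_homologues, practice_menu, resource_profile

__all__ = ["PipelineError", "run_positive_deviance"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the failing stage's name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _write(df: pd.DataFrame, outdir: Path | None, name: str, index: bool = False) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, index=index)


def run_positive_deviance(
    records: pd.DataFrame,
    config: PipelineConfig | None = None,
    practice_catalog: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    visited_ids: list | None = None,
) -> dict:
    """Execute the full workflow on a raw household table.

    Parameters
    ----------
    records
        Canonical household table (see :mod:`posdev.io_config`).
    config
        Pipeline configuration; defaults used when omitted.
    practice_catalog
        Optional (practice_code, positive_deviant_id, description) table;
        when absent the homologue stage is skipped and flagged.
    outdir
        Directory for stage CSV outputs and ``run_summary.json``.
    visited_ids
        Positive deviants actually visited in follow-up; defaults to the
        diverse case selection.

    Returns the run summary dict.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"software_version": __version__, "seed": config.seed}
    summary["config"] = config.model_dump(mode="json")

    try:
        clean, report = validate_and_filter(records, config)
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc
    summary["input"] = report.summary()

    try:
        perf, pca_fit, cap_flags = performance_matrix(clean, config)
    except Exception as exc:
        raise PipelineError("indicators", str(exc)) from exc
    summary["pca_fit"] = pca_fit.to_dict()
    summary["pc1_variance_fraction"] = float(pca_fit.variance_fractions[0])
    summary["n_capped_values"] = int(cap_flags.to_numpy().sum())
    if outdir is not None:
        out = perf.copy()
        for col in cap_flags.columns:
            out[f"{col}_capped"] = cap_flags[col]
        _write(out, outdir, "indicators.csv", index=True)
        (outdir / "pca_fit.json").write_text(json.dumps(pca_fit.to_dict(), indent=2))

    try:
        residuals, models = relative_performance(perf, clean, config)
    except Exception as exc:
        raise PipelineError("residuals", str(exc)) from exc
    summary["selected_models"] = {
        col: models[col]["selected"]["covariates"] for col in residuals.columns
    }
    if outdir is not None:
        _write(residuals, outdir, "residuals.csv", index=True)
        (outdir / "models.json").write_text(json.dumps(models, indent=2))

    try:
        result = pareto_ranks(residuals.to_numpy(), config.max_front_rank, index=perf.index)
        deviant_ids = positive_deviants(result)
    except Exception as exc:
        raise PipelineError("pareto", str(exc)) from exc
    summary["rank_counts"] = result.rank_counts()
    summary["n_positive_deviants"] = len(deviant_ids)
    if outdir is not None:
        _write(result.to_frame(), outdir, "pareto.csv", index=True)

    try:
        assignment = assign_strata(
            clean["land_ha"], clean["livestock_tlu"], config.n_land_deciles
        )
        strata_frame = assignment.to_frame(index=perf.index)
        deviant_mask = result.positive_deviant
        profile = stratum_mean_deviance(residuals, assignment, deviant_mask)
        corr, pvals = deviance_correlations(residuals, deviant_mask)
        comparison = compare_groups(
            clean, perf, deviant_mask, test=config.group_test
        )
    except Exception as exc:
        raise PipelineError("profile", str(exc)) from exc
    occupied = strata_frame.loc[deviant_mask, "stratum_id"].nunique()
    summary["strata"] = {
        "n_possible": config.n_land_deciles * 2,
        "n_occupied_by_deviants": int(occupied),
        "livestock_median": assignment.livestock_median,
    }
    if outdir is not None:
        _write(strata_frame, outdir, "strata.csv", index=True)
        _write(profile, outdir, "deviance_profile.csv")
        _write(corr, outdir, "deviance_correlations.csv", index=True)
        _write(pvals, outdir, "deviance_correlation_pvalues.csv", index=True)
        _write(comparison, outdir, "group_comparison.csv")

    try:
        ma = market_access_proxy(clean)
        chars = pd.DataFrame(
            {
                "mae": clean["mae"].to_numpy(dtype=float),
                "land_ha": clean["land_ha"].to_numpy(dtype=float),
                "livestock_tlu": clean["livestock_tlu"].to_numpy(dtype=float),
                "market_access": ma.to_numpy(dtype=float),
            },
            index=perf.index,
        )[SELECTION_CHARACTERISTICS]
        rank_series = pd.Series(result.front_rank, index=perf.index)
        stratum_series = pd.Series(assignment.stratum_id, index=perf.index)
        selection = select_diverse_cases(
            deviant_ids, rank_series, stratum_series, chars
        )
    except Exception as exc:
        raise PipelineError("select-cases", str(exc)) from exc
    summary["case_selection"] = {
        "n_selected": len(selection.household_ids),
        "mean_crowding_distance": selection.mean_crowding_distance,
        "empty_strata": selection.empty_strata,
        "selected": selection.household_ids,
    }
    if outdir is not None:
        sel = selection.selected.copy()
        sel["mean_crowding_distance"] = selection.mean_crowding_distance
        _write(sel, outdir, "case_selection.csv")

    if practice_catalog is not None:
        try:
            visited = visited_ids if visited_ids is not None else selection.household_ids
            _, standardized = resource_profile(clean, config.resource_proxies)
            hom = nearest_homologues(
                standardized,
                visited,
                k=config.homologue_k,
                include_self=config.homologue_include_self,
            )
            unknown = set(practice_catalog["positive_deviant_id"]) - set(visited)
            if unknown:
                raise ValueError(
                    f"catalog holders are not visited deviants: {sorted(unknown)}"
                )
            menus, targeting = practice_menu(hom, practice_catalog)
        except Exception as exc:
            raise PipelineError("homologues", str(exc)) from exc
        summary["homologues"] = {
            "n_targets": len(hom),
            "k": config.homologue_k,
            "n_practices": int(targeting["practice_code"].nunique()),
            "practice_targeting": {
                row["practice_code"]: int(row["n_target_households"])
                for _, row in targeting.iterrows()
            },
        }
        if outdir is not None:
            _write(hom, outdir, "homologues.csv", index=True)
            _write(targeting, outdir, "practice_targeting.csv")
    else:
        summary["homologues"] = {"skipped": True, "reason": "no practice catalog supplied"}

    if outdir is not None:
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
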