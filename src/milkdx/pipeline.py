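"""End-to-end orchestration: cohort (simulated or loaded) -> descriptive
group comparison -> ROC/cutoffs -> per-cutoff diagnostic table -> two-cutoff
triage -> bootstrap validation -> delimited reports plus one JSON bundle.

All randomness in a run flows from the single configured seed; reruns with
the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import cohort as coh
from .cohort import CohortConfig, cohort_to_frame, read_cohort, write_cohort
from .errors import ConfigurationError, DegenerateRocError, EmptyAnalysisError, MilkdxError
from .model import DiagnosticCutoffModel
from .stats import compare_groups

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_PARTIAL = 2

DEFAULT_MARKERS = (
    "spt_milk_extract_mm",
    "spt_baked_milk_mm",
    "sige_cows_milk",
    "sige_boiled_milk",
    "bat_me_cd63_pct",
    "bat_bm_si_cd203c",
)


@dataclass
class AnalysisConfig:
    cohort_source: str = "simulate"  # or "file"
    cohort_path: Optional[str] = None
    generator: CohortConfig = field(default_factory=CohortConfig)
    markers: Sequence[str] = DEFAULT_MARKERS
    populations: Sequence[str] = ("all_ages", "under2")
    endpoints: Sequence[str] = ("bm_allergy", "fm_allergy")
    nonresponder_policy: str = "include"  # include | exclude | both
    bootstrap_resamples: int = 0
    seed: int = 0
    output_dir: str = "milkdx_output"

    def __post_init__(self):
        if not self.markers or not self.populations or not self.endpoints:
            raise ConfigurationError("need at least one marker, population and endpoint")
        if self.cohort_source not in ("simulate", "file"):
            raise ConfigurationError(f"unknown cohort_source {self.cohort_source!r}")
        if self.cohort_source == "file" and not self.cohort_path:
            raise ConfigurationError("cohort_source='file' requires cohort_path")
        if self.nonresponder_policy not in ("include", "exclude", "both"):
            raise ConfigurationError(
                f"unknown nonresponder_policy {self.nonresponder_policy!r}"
            )


@dataclass
class PipelineResult:
    analyses: dict          # (marker, population, endpoint, policy) -> result bundle
    skipped: list           # (key, reason)
    output_dir: Path
    exit_code: int


def _endpoint_field(endpoint: str) -> str:
    return {"bm_allergy": "bm", "fm_allergy": "fm"}[endpoint]


def _log(lines: list, msg: str) -> None:
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    lines.append(f"{stamp} {msg}")


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run the full analysis and write reports under ``config.output_dir``.

    Degenerate strata (a single outcome class, no subjects, missing marker)
    are skipped with a logged reason; the result's ``exit_code`` is 2 when
    any analysis was skipped, 0 otherwise.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    _log(log_lines, f"seed={config.seed} source={config.cohort_source}")

    if config.cohort_source == "simulate":
        gen = config.generator
        if gen.seed != config.seed:
            from dataclasses import replace

            gen = replace(gen, seed=config.seed)
        subjects = coh.generate_cohort(gen)
        write_cohort(subjects, out / "cohort.csv")
        coh.save_config(gen, out / "cohort_config.json")
        _log(log_lines, f"simulated cohort n={len(subjects)}")
    else:
        subjects = read_cohort(config.cohort_path)
        _log(log_lines, f"loaded cohort n={len(subjects)} from {config.cohort_path}")

    frame = cohort_to_frame(subjects)
    missing_markers = [m for m in config.markers if m not in frame.columns]
    if missing_markers:
        raise ConfigurationError(f"markers absent from cohort: {missing_markers}")

    # Descriptive group comparison on the baked-milk endpoint
    desc = frame[frame["bm_outcome"].isin(["allergic", "tolerant"])]
    try:
        comparisons = compare_groups(desc, "bm_outcome", list(config.markers))
        pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    "allergic": c.summary_a,
                    "tolerant": c.summary_b,
                    "test": c.test,
                    "p": c.p_formatted,
                }
                for c in comparisons
            ]
        ).to_csv(out / "group_comparison.csv", index=False)
    except MilkdxError as exc:
        _log(log_lines, f"group comparison skipped: {exc}")

    policies = (
        ("include", "exclude")
        if config.nonresponder_policy == "both"
        else (config.nonresponder_policy,)
    )

    analyses = {}
    skipped = []
    cutoff_rows = []
    triage_rows = []
    bundle = {}
    for marker in config.markers:
        for population in config.populations:
            for endpoint in config.endpoints:
                for policy in policies:
                    key = (marker, population, endpoint, policy)
                    try:
                        model = DiagnosticCutoffModel.from_cohort(
                            subjects,
                            marker,
                            endpoint=_endpoint_field(endpoint),
                            population=population,
                            nonresponder_policy=policy,
                        )
                        res = model.fit()
                    except (DegenerateRocError, EmptyAnalysisError) as exc:
                        skipped.append((key, str(exc)))
                        _log(log_lines, f"skipped {key}: {exc}")
                        continue
                    analyses[key] = res
                    tab = res.table.copy()
                    for col, val in (
                        ("marker", marker),
                        ("population", population),
                        ("endpoint", endpoint),
                        ("nonresponder_policy", policy),
                    ):
                        tab[col] = val
                    cutoff_rows.append(tab)
                    trow = res.triage_row()
                    trow.update(
                        population=population, endpoint=endpoint, nonresponder_policy=policy
                    )
                    triage_rows.append(trow)
                    entry = {
                        "n": model.n,
                        "auc": res.auc,
                        "cutoffs": {
                            "optimal": res.cutoffs.optimal,
                            "se100": res.cutoffs.se100,
                            "sp100": res.cutoffs.sp100,
                            "youden_at_optimal": float(res.cutoffs.youden_at_optimal),
                        },
                        "triage": {
                            "tolerant": res.triage.n_tolerant_zone,
                            "equivocal": res.triage.n_equivocal,
                            "allergic": res.triage.n_allergic_zone,
                            "pct_ofc": float(res.triage.pct_ofc),
                            "strategy_accuracy": float(res.triage.strategy_accuracy),
                        },
                    }
                    if config.bootstrap_resamples > 0:
                        rep = res.bootstrap(
                            "auc",
                            n_resamples=config.bootstrap_resamples,
                            seed=config.seed,
                        )
                        entry["bootstrap_auc"] = {
                            "point": rep.point_estimate,
                            "ci_low": rep.ci_low,
                            "ci_high": rep.ci_high,
                            "n_resamples": rep.n_resamples,
                        }
                    bundle["|".join(key)] = entry
                    _log(log_lines, f"analysed {key}: n={model.n} auc={res.auc:.3f}")

    if cutoff_rows:
        pd.concat(cutoff_rows, ignore_index=True).to_csv(
            out / "cutoff_table.csv", index=False
        )
    if triage_rows:
        cols = [
            "marker",
            "population",
            "endpoint",
            "nonresponder_policy",
            "tolerant",
            "equivocal",
            "allergic",
            "ofc_negative",
            "ofc_positive",
            "pct_ofc",
            "pct_ofc_positive",
        ]
        pd.DataFrame(triage_rows)[cols].to_csv(out / "triage_table.csv", index=False)
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")

    exit_code = EXIT_PARTIAL if skipped else EXIT_OK
    return PipelineResult(
        analyses=analyses, skipped=skipped, output_dir=out, exit_code=exit_code
    )
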