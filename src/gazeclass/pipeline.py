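"""One-shot orchestration: simulate -> fixations -> statistics -> classifier.

``run_pipeline`` executes every stage in order, writes all stage CSVs plus a
markdown report, and is byte-deterministic given the same configuration and
seed.  ``fixture_mode`` runs only the summary-level computations that the
published tables permit without raw data: t/d recomputation from the printed
group summaries, panel selection from the printed effect sizes, and the
count-threshold sweep from the printed combination counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .__about__ import __version__
from .battery import default_battery, load_battery
from .cohort import default_params, generate_cohort, write_cohort_csvs
from .discriminant import sweep_from_counts
from .exceptions import ConfigurationError
from .fixtures import load_fixtures
from .metrics import (
    DEFAULT_AVAILABILITY_THRESHOLD,
    compute_fixation_table,
    read_gaze_csv,
    write_fixation_csv,
)
from .model import GazeDiscriminantModel
from .stats import compare_from_summary, comparisons_frame, effect_flag

log = logging.getLogger("gazeclass")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "fixture_mode"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs of a pipeline run.

    Either ``simulate=True`` (a synthetic cohort is generated with ``seed``)
    or ``gaze_csv``/``participants_csv`` point at real-format data.
    """

    out_dir: str
    seed: int = 0
    simulate: bool = True
    gaze_csv: str | None = None
    participants_csv: str | None = None
    battery_path: str | None = None
    variant_policy: str = "levene"
    d_min: float = 0.8
    panel: str = "large_effect"
    availability_threshold: float = DEFAULT_AVAILABILITY_THRESHOLD

    def __post_init__(self) -> None:
        if not self.simulate and (self.gaze_csv is None or self.participants_csv is None):
            raise ConfigurationError("non-simulation runs need gaze_csv and participants_csv")


@dataclass
class RunReport:
    config: RunConfig
    version: str
    stage_counts: dict[str, int]
    tables: dict[str, pd.DataFrame]
    warnings: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = [
            "# gazeclass run report",
            "",
            f"- version: {self.version}",
            f"- seed: {self.config.seed}",
            f"- simulate: {self.config.simulate}",
            f"- variant policy: {self.config.variant_policy}",
            f"- availability threshold: {self.config.availability_threshold:g}%",
            f"- panel: {self.config.panel} (d_min={self.config.d_min:g})",
            "",
            "## Stage row counts",
            "",
        ]
        lines += [f"- {k}: {v}" for k, v in self.stage_counts.items()]
        for name, df in self.tables.items():
            lines += ["", f"## {name}", "", "```", df.to_string(), "```"]
        if self.warnings:
            lines += ["", "## Warnings", ""] + [f"- {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages, writing stage CSVs and ``report.md`` to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    battery = load_battery(config.battery_path) if config.battery_path else default_battery()

    if config.simulate:
        log.info("simulate: generating synthetic cohort (seed=%d)", config.seed)
        params = default_params(seed=config.seed)
        participants, gaze = generate_cohort(params, battery)
        write_cohort_csvs(participants, gaze, out)
    else:
        log.info("load: %s / %s", config.gaze_csv, config.participants_csv)
        gaze = read_gaze_csv(config.gaze_csv)
        participants = pd.read_csv(config.participants_csv, index_col="participant_id")

    table = compute_fixation_table(gaze, battery, config.availability_threshold)
    log.info(
        "fixations: %d included, %d excluded (<%g%%)",
        table.n_included,
        table.n_excluded,
        config.availability_threshold,
    )
    write_fixation_csv(table, out / "fixations.csv")
    table.excluded.round(1).to_csv(out / "excluded.csv")

    model = GazeDiscriminantModel(table, participants, battery)
    results = model.fit(
        variant_policy=config.variant_policy, d_min=config.d_min, panel=config.panel
    )
    warnings = list(results.warnings)
    for m in results.discriminant:
        if m.specificity == 1.0:
            warnings.append(f"k={m.k}: specificity 1 gives an infinite PLR")
    results.comparisons_table.to_csv(out / "comparisons.csv", float_format="%.6g")
    results.correlations_table.to_csv(out / "correlations.csv", float_format="%.6g")
    results.roc_table.to_csv(out / "roc.csv", float_format="%.6g")
    results.breakdown_table.to_csv(out / "breakdown.csv")
    results.discriminant_table.to_csv(out / "discriminant.csv", float_format="%.6g")

    report = RunReport(
        config=config,
        version=__version__,
        stage_counts={
            "participants": len(participants),
            "gaze_samples": len(gaze),
            "included": table.n_included,
            "excluded": table.n_excluded,
            "comparisons": len(results.comparisons),
            "correlations": len(results.correlations),
            "roc_items": len(results.roc),
            "panel_items": len(results.panel),
        },
        tables={
            "Group comparisons": results.comparisons_table.round(4),
            "ROC per item": results.roc_table.round(4),
            "Breakdown of items over cutoff": results.breakdown_table,
            "Discriminant parameters": results.discriminant_table,
        },
        warnings=warnings,
    )
    (out / "report.md").write_text(report.to_markdown())
    (out / "summary.txt").write_text(results.summary() + "\n")
    return report


def fixture_mode(out_dir=None) -> RunReport:
    """Summary-level reanalysis of the printed tables (no simulation).

    Recomputes t/df/p and Cohen's d from the printed group summaries, selects
    the large-effect primary-AoI panel from the recomputed d values, and
    reconstructs the discriminant parameter rows from the printed
    combination counts.
    """
    fx = load_fixtures()
    battery = default_battery()
    comps = compare_from_summary(fx.table2, battery)
    comp_df = comparisons_frame(comps)

    panel = [
        c.item_id
        for c in comps
        if c.item_id in {f"{s.stimulus_id}.{s.aoi1.aoi_id}" for s in battery}
        and effect_flag(c.cohens_d) == "large"
    ]
    sweep = sweep_from_counts(fx.panel_counts(panel))
    disc = pd.DataFrame(
        [
            {
                "k": m.k,
                "sensitivity_pct": m.sensitivity_pct,
                "specificity_pct": m.specificity_pct,
                "plr": m.plr_reported,
                "nlr": m.nlr_reported,
            }
            for m in sweep
        ]
    ).set_index("k")

    report = RunReport(
        config=RunConfig(out_dir=str(out_dir) if out_dir else ".", simulate=False,
                         gaze_csv="(fixtures)", participants_csv="(fixtures)"),
        version=__version__,
        stage_counts={
            "table2_rows": len(comps),
            "panel_items": len(panel),
            "breakdown_cells": len(fx.table5),
        },
        tables={
            "Recomputed group comparisons": comp_df.round(4),
            "Panel": pd.DataFrame({"item": panel}).set_index("item"),
            "Discriminant parameters from printed counts": disc,
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comp_df.to_csv(out / "comparisons_recomputed.csv", float_format="%.6g")
        disc.to_csv(out / "discriminant_from_counts.csv", float_format="%.6g")
        (out / "report.md").write_text(report.to_markdown())
    return report
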