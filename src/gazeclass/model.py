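"""Model/results surface tying the pipeline stages together.

``GazeDiscriminantModel`` holds the data (a fixation table after exclusion,
participant metadata, the battery); ``fit()`` runs the full analysis - group
comparisons, psychometric correlations, per-item ROC, panel selection and the
count-over-cutoff sweep - and returns a ``GazeDiscriminantResults`` carrying
the estimates with a ``summary()`` table, in the spirit of statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import __about__
from .battery import StimulusSpec, default_battery, aoi1_items
from .cohort import CohortParams, default_params, generate_cohort, simulate_fixation_table
from .discriminant import (
    CutoffRule,
    DiscriminantMetrics,
    RocResult,
    discriminant_sweep,
    roc_analysis,
    select_panel,
)
from .metrics import (
    DEFAULT_AVAILABILITY_THRESHOLD,
    FixationTable,
    compute_fixation_table,
    read_gaze_csv,
)
from .stats import (
    CorrelationResult,
    GroupComparison,
    compare_groups,
    comparisons_frame,
    correlations_frame,
    within_group_correlations,
)

__all__ = ["GazeDiscriminantModel", "GazeDiscriminantResults"]


class GazeDiscriminantModel:
    """ASD/TD discrimination from AoI percentage-fixation data.

    Parameters
    ----------
    fixation_table : FixationTable
        Post-exclusion fixation percentages (see ``compute_fixation_table``).
    participants : DataFrame indexed by participant id with a ``group`` column
        (``"ASD"``/``"TD"``) and optional ``srs_total``/``fsiq`` covariates.
    battery : list of StimulusSpec, default the standard eight-stimulus battery.
    """

    def __init__(
        self,
        fixation_table: FixationTable,
        participants: pd.DataFrame,
        battery: list[StimulusSpec] | None = None,
    ):
        self.fixation_table = fixation_table
        self.participants = participants
        self.battery = battery or fixation_table.battery or default_battery()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_simulation(
        cls,
        params: CohortParams | None = None,
        seed: int | None = None,
        threshold: float = DEFAULT_AVAILABILITY_THRESHOLD,
        battery: list[StimulusSpec] | None = None,
        streams: bool = False,
    ) -> "GazeDiscriminantModel":
        """Build from the synthetic cohort generator.

        With ``streams=True`` the full per-sample gaze streams are generated
        and recounted; otherwise the vectorised count-level shortcut is used
        (same distribution, much faster for large cohorts).
        """
        params = params or default_params()
        battery = battery or default_battery()
        if streams:
            participants, gaze = generate_cohort(params, battery, seed=seed)
            table = compute_fixation_table(gaze, battery, threshold)
        else:
            participants, table = simulate_fixation_table(params, battery, seed=seed, threshold=threshold)
        return cls(table, participants, battery)

    @classmethod
    def from_csv(
        cls,
        gaze_csv,
        participants_csv,
        battery: list[StimulusSpec] | None = None,
        threshold: float = DEFAULT_AVAILABILITY_THRESHOLD,
    ) -> "GazeDiscriminantModel":
        battery = battery or default_battery()
        gaze = read_gaze_csv(gaze_csv)
        participants = pd.read_csv(participants_csv, index_col="participant_id")
        table = compute_fixation_table(gaze, battery, threshold)
        return cls(table, participants, battery)

    # -- estimation -------------------------------------------------------
    def fit(
        self,
        variant_policy: str = "levene",
        d_min: float = 0.8,
        panel: str = "large_effect",
        correlations: bool = True,
    ) -> "GazeDiscriminantResults":
        """Run comparisons, correlations, ROC and the discriminant sweep.

        ``panel="large_effect"`` screens the primary AoIs at ``d > d_min``;
        ``panel="all_aoi1"`` uses every stimulus's primary AoI.
        """
        comps = compare_groups(self.fixation_table, self.participants, self.battery, variant_policy)
        corrs = (
            within_group_correlations(self.fixation_table, self.participants, self.battery)
            if correlations
            else []
        )
        roc = roc_analysis(self.fixation_table, self.participants, self.battery)
        if panel == "all_aoi1":
            panel_items = aoi1_items(self.battery)
        elif panel == "large_effect":
            panel_items = select_panel(comps, d_min=d_min, aoi1_only=True, battery=self.battery)
        else:
            raise ValueError(f"unknown panel {panel!r}")
        rules = [r.rule for r in roc if r.item_id in panel_items]
        breakdown, sweep = discriminant_sweep(self.fixation_table, self.participants, rules)
        return GazeDiscriminantResults(
            model=self,
            comparisons=comps,
            correlations=corrs,
            roc=roc,
            panel=panel_items,
            rules=rules,
            breakdown=breakdown,
            discriminant=sweep,
        )


@dataclass
class GazeDiscriminantResults:
    """Fitted tables: comparisons, correlations, ROC, panel and sweep."""

    model: GazeDiscriminantModel
    comparisons: list[GroupComparison]
    correlations: list[CorrelationResult]
    roc: list[RocResult]
    panel: list[str]
    rules: list[CutoffRule]
    breakdown: pd.DataFrame
    discriminant: list[DiscriminantMetrics]
    warnings: list[str] = field(default_factory=list)

    # -- tabular views ----------------------------------------------------
    @property
    def comparisons_table(self) -> pd.DataFrame:
        return comparisons_frame(self.comparisons)

    @property
    def correlations_table(self) -> pd.DataFrame:
        return correlations_frame(self.correlations)

    @property
    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item": r.item_id,
                    "auc": r.auc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "direction": r.rule.direction,
                    "cutoff": r.rule.cutoff_value,
                    "cutoff_printed": r.rule.printed,
                }
                for r in self.roc
            ]
        ).set_index("item")

    @property
    def discriminant_table(self) -> pd.DataFrame:
        rows = []
        for m in self.discriminant:
            rows.append(
                {
                    "k": m.k,
                    "tp": m.tp,
                    "fn": m.fn,
                    "tn": m.tn,
                    "fp": m.fp,
                    "sensitivity_pct": m.sensitivity_pct,
                    "specificity_pct": m.specificity_pct,
                    "plr": m.plr_reported,
                    "nlr": m.nlr_reported,
                }
            )
        return pd.DataFrame(rows).set_index("k")

    @property
    def breakdown_table(self) -> pd.DataFrame:
        df = self.breakdown.copy()
        df.index = ["none" if not s else "+".join(sorted(s)) for s in df.index]
        df.index.name = "items_met"
        return df

    def best_threshold(self) -> DiscriminantMetrics:
        """The count threshold maximising Youden's J (ties -> smaller k)."""
        return max(self.discriminant, key=lambda m: (m.sensitivity + m.specificity, -m.k))

    def summary(self) -> str:
        ft = self.model.fixation_table
        n_groups = self.model.participants.loc[
            self.model.participants.index.intersection(ft.included.index), "group"
        ].value_counts()
        sig = [c.item_id for c in self.comparisons if c.significant and c.item_id != "availability"]
        best = self.best_threshold()
        lines = [
            f"Gaze AoI discriminant analysis (gazeclass {__about__.__version__})",
            "=" * 60,
            f"Included: ASD n={n_groups.get('ASD', 0)}, TD n={n_groups.get('TD', 0)}"
            f"  (excluded below {ft.threshold:g}% availability: {ft.n_excluded})",
            f"Significant group differences: {', '.join(sig) if sig else 'none'}",
            f"Panel ({len(self.panel)} items): {', '.join(self.panel)}",
            "Cutoffs: " + ", ".join(f"{r.item_id} {r.printed}" for r in self.rules),
            "",
            "k  sens%  spec%   PLR   NLR",
        ]
        for m in self.discriminant:
            plr = "inf" if math.isinf(m.plr_reported) else f"{m.plr_reported:.1f}"
            nlr = "nan" if math.isnan(m.nlr_reported) else f"{m.nlr_reported:.1f}"
            mark = " *" if m.k == best.k else ""
            lines.append(
                f"{m.k}  {m.sensitivity_pct:5.1f}  {m.specificity_pct:5.1f}  {plr:>4}  {nlr:>4}{mark}"
            )
        lines.append("(*) best Youden threshold; classify ASD when count >= k")
        return "\n".join(lines)
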