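"""Group comparisons and psychometric correlations.

One independent two-sample t test per AoI item (plus a preliminary one for
availability), with a per-stimulus Bonferroni level of .05 divided by the
stimulus's AoI count (.025 for two-AoI stimuli, .05 for the single-AoI
small-window clip).  Cohen's d always uses the df-weighted pooled SD and is
reported as an absolute standardized difference; d > 0.5 flags a medium and
d > 0.8 a large effect.  The equal-variance decision follows the common
statistics-package convention: a center-mean Levene test at alpha = .05
chooses between the pooled and Welch variants per item ("levene" policy);
"pooled" and "welch" force one variant throughout.

Correlations are plain product-moment r of each item against SRS within each
group separately, and against FSIQ in the ASD group only, tested at an
uncorrected .05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .battery import StimulusSpec, default_battery, iter_items
from .exceptions import InsufficientDataError, UndefinedStatisticError
from .metrics import FixationTable

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "two_sample_t",
    "cohens_d",
    "bonferroni_alpha",
    "effect_flag",
    "compare_groups",
    "compare_from_summary",
    "within_group_correlations",
    "comparisons_frame",
    "correlations_frame",
]

MEDIUM_D = 0.5
LARGE_D = 0.8


@dataclass(frozen=True)
class GroupComparison:
    item_id: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    t_value: float  # signed, group1 - group2
    df: float
    p_value: float
    variant: str  # "pooled" or "welch"
    cohens_d: float  # absolute, pooled-SD
    alpha_level: float
    effect_flag: str  # "none" / "medium" / "large"
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    item_id: str
    covariate: str  # "SRS" or "FSIQ"
    group: str
    n: int
    r: float
    p_value: float
    significant: bool


def two_sample_t(mean1, sd1, n1, mean2, sd2, n2, variant="pooled"):
    """Independent t from summary statistics; returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("two_sample_t needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise UndefinedStatisticError("negative SD")
    if sd1 == 0 and sd2 == 0:
        raise UndefinedStatisticError("both SDs are zero; t is undefined")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohens_d(mean1, sd1, n1, mean2, sd2, n2):
    """Absolute standardized mean difference with the df-weighted pooled SD."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("cohens_d needs n >= 2 per group")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise UndefinedStatisticError("zero pooled SD; d is undefined")
    return abs(mean1 - mean2) / math.sqrt(pooled_var)


def bonferroni_alpha(stimulus: StimulusSpec) -> float:
    """Per-stimulus significance level: .05 divided by the AoI count."""
    return 0.05 / len(stimulus.aois)


def effect_flag(d: float) -> str:
    if d > LARGE_D:
        return "large"
    if d > MEDIUM_D:
        return "medium"
    return "none"


def _choose_variant(x: np.ndarray, y: np.ndarray, policy: str) -> str:
    if policy in ("pooled", "welch"):
        return policy
    if policy != "levene":
        raise ValueError(f"unknown variant policy {policy!r}")
    _, p = sps.levene(x, y, center="mean")
    return "pooled" if p >= 0.05 else "welch"


def compare_groups(
    fixation_table: FixationTable,
    participants: pd.DataFrame,
    battery: list[StimulusSpec] | None = None,
    variant_policy: str = "levene",
    group1: str = "ASD",
    group2: str = "TD",
) -> list[GroupComparison]:
    """One comparison per AoI item plus a preliminary one for availability.

    The availability comparison is not part of any Bonferroni family; its
    alpha is the plain .05.
    """
    battery = battery or fixation_table.battery or default_battery()
    items: list[tuple[str, float]] = [("availability", 0.05)]
    for stim, _aoi, item in iter_items(battery):
        items.append((item, bonferroni_alpha(stim)))
    out = []
    for item, alpha in items:
        x = fixation_table.values_for(item, participants, group1)
        y = fixation_table.values_for(item, participants, group2)
        if len(x) < 2 or len(y) < 2:
            raise InsufficientDataError(
                f"item {item!r}: a group has fewer than 2 included participants"
            )
        variant = _choose_variant(x, y, variant_policy)
        t, df, p = two_sample_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), variant)
        d = cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
        out.append(
            GroupComparison(
                item_id=item,
                n1=len(x),
                n2=len(y),
                mean1=float(x.mean()),
                sd1=float(x.std(ddof=1)),
                mean2=float(y.mean()),
                sd2=float(y.std(ddof=1)),
                t_value=t,
                df=df,
                p_value=p,
                variant=variant,
                cohens_d=d,
                alpha_level=alpha,
                effect_flag=effect_flag(d),
                significant=bool(p < alpha),
            )
        )
    return out


def compare_from_summary(
    table2: pd.DataFrame,
    battery: list[StimulusSpec] | None = None,
    variant_policy: str = "best_match",
) -> list[GroupComparison]:
    """Summary-level comparisons from a printed-table frame.

    ``table2`` is indexed by item with columns ``n_asd, asd_mean, asd_sd,
    n_td, td_mean, td_sd`` and optionally the printed ``t``.  Raw values are
    unavailable here, so the Levene policy cannot run; ``best_match`` picks,
    per item, the variant whose t is closest to the printed one (and records
    it), which is how the published mix of pooled and Welch rows is
    reproduced.  ``pooled``/``welch`` force a variant.
    """
    battery = battery or default_battery()
    alphas = {"availability": 0.05}
    for stim, _aoi, item in iter_items(battery):
        alphas[item] = bonferroni_alpha(stim)
    out = []
    for item, row in table2.iterrows():
        item = str(item)
        if item not in alphas:
            continue
        args = (
            float(row["asd_mean"]),
            float(row["asd_sd"]),
            int(row["n_asd"]),
            float(row["td_mean"]),
            float(row["td_sd"]),
            int(row["n_td"]),
        )
        if variant_policy == "best_match":
            if "t" not in row or pd.isna(row["t"]):
                raise UndefinedStatisticError(f"item {item!r}: best_match policy needs a printed t")
            cands = {v: two_sample_t(*args, variant=v) for v in ("pooled", "welch")}
            variant = min(cands, key=lambda v: abs(abs(cands[v][0]) - float(row["t"])))
            t, df, p = cands[variant]
        else:
            variant = variant_policy
            t, df, p = two_sample_t(*args, variant=variant)
        d = cohens_d(*args)
        out.append(
            GroupComparison(
                item_id=item,
                n1=args[2],
                n2=args[5],
                mean1=args[0],
                sd1=args[1],
                mean2=args[3],
                sd2=args[4],
                t_value=t,
                df=df,
                p_value=p,
                variant=variant,
                cohens_d=d,
                alpha_level=alphas[item],
                effect_flag=effect_flag(d),
                significant=bool(p < alphas[item]),
            )
        )
    return out


def _pearson(x: np.ndarray, y: np.ndarray):
    if len(x) < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero-variance input; correlation is undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def within_group_correlations(
    fixation_table: FixationTable,
    participants: pd.DataFrame,
    battery: list[StimulusSpec] | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Item vs SRS within each group, and item vs FSIQ in the ASD group only.

    Participants with a missing covariate are dropped pairwise.
    """
    battery = battery or fixation_table.battery or default_battery()
    items = [item for _, _, item in iter_items(battery)]
    inc = fixation_table.included
    meta = participants.loc[participants.index.intersection(inc.index)]
    out = []
    specs = [("SRS", "srs_total", "ASD"), ("SRS", "srs_total", "TD"), ("FSIQ", "fsiq", "ASD")]
    for covariate, col, group in specs:
        ids = meta.index[(meta["group"] == group) & meta[col].notna()]
        cov = meta.loc[ids, col].to_numpy(dtype=float)
        for item in items:
            vals = inc.loc[ids, item].to_numpy(dtype=float)
            r, p = _pearson(vals, cov)
            out.append(
                CorrelationResult(
                    item_id=item,
                    covariate=covariate,
                    group=group,
                    n=len(ids),
                    r=r,
                    p_value=p,
                    significant=bool(p < alpha),
                )
            )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Comparisons as a table mirroring the published layout."""
    df = pd.DataFrame([c.__dict__ for c in comparisons]).set_index("item_id")
    return df.rename(
        columns={
            "n1": "n_asd",
            "mean1": "mean_asd",
            "sd1": "sd_asd",
            "n2": "n_td",
            "mean2": "mean_td",
            "sd2": "sd_td",
            "t_value": "t",
            "p_value": "p",
            "cohens_d": "d",
            "alpha_level": "alpha",
        }
    )


def correlations_frame(correlations: list[CorrelationResult]) -> pd.DataFrame:
    df = pd.DataFrame([c.__dict__ for c in correlations])
    return df.set_index(["covariate", "group", "item_id"])
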