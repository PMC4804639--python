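"""Per-item ROC cutoffs and the count-over-cutoff panel classifier.

Each AoI item gets a direction-aware cutoff from its ROC curve: items where
the ASD group fixates less use a ``value < cutoff`` rule, items where it
fixates more use ``value > cutoff`` (strictly, in both cases - a value
exactly at the cutoff never meets the rule, matching the published "<81" /
">31" notation).  The AUC is the rank-sum statistic normalised by the number
of group pairs, i.e. the probability that a randomly drawn ASD participant
scores more ASD-like than a randomly drawn TD participant, counting ties as
half.  Cutoffs maximise Youden's J = sensitivity + specificity - 1 over the
midpoints between adjacent distinct pooled values plus the two extremes;
J-ties break toward the more specific cutoff.

The panel classifier counts, per participant, how many panel items meet
their cutoff rules and labels the participant ASD when the count reaches a
threshold k.  The panel is either every stimulus's primary AoI or only those
with a large group-difference effect (d > 0.8).  For each k the classifier
reports sensitivity, specificity, the positive likelihood ratio
PLR = sens/(1-spec) and the negative likelihood ratio NLR = (1-sens)/spec.
Reported one-decimal PLR/NLR values are computed from the one-decimal-rounded
percentages (half away from zero), which is how the published rows round;
exact fractions are kept alongside.  A perfect specificity yields an
infinite PLR sentinel rather than an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .battery import ASD_LOWER, StimulusSpec, default_battery, aoi1_items
from .exceptions import InsufficientDataError, PanelEmptyError
from .metrics import FixationTable
from .stats import GroupComparison

__all__ = [
    "CutoffRule",
    "RocResult",
    "DiscriminantMetrics",
    "auc",
    "hanley_mcneil_ci",
    "select_cutoff",
    "roc_analysis",
    "select_panel",
    "count_items_met",
    "breakdown_by_combination",
    "discriminant_sweep",
    "sweep_from_counts",
    "rules_from_table4",
    "round_half_away",
]

ASD_BELOW = "asd_below"
ASD_ABOVE = "asd_above"


@dataclass(frozen=True)
class CutoffRule:
    """Directional strict-inequality rule for one item."""

    item_id: str
    direction: str  # asd_below -> "x < cutoff" is ASD-like; asd_above -> "x > cutoff"
    cutoff_value: float

    def meets(self, x: float) -> bool:
        if self.direction == ASD_BELOW:
            return x < self.cutoff_value
        return x > self.cutoff_value

    @property
    def printed(self) -> str:
        sym = "<" if self.direction == ASD_BELOW else ">"
        return f"{sym}{round(self.cutoff_value):g}"


@dataclass(frozen=True)
class RocResult:
    item_id: str
    auc: float
    ci_low: float
    ci_high: float
    rule: CutoffRule
    sens_at_cutoff: float
    spec_at_cutoff: float


@dataclass(frozen=True)
class DiscriminantMetrics:
    """Confusion counts and derived parameters at one count threshold k."""

    k: int
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_asd(self) -> int:
        return self.tp + self.fn

    @property
    def n_td(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_asd

    @property
    def specificity(self) -> float:
        return self.tn / self.n_td

    @property
    def plr(self) -> float:
        if self.specificity == 1.0:
            return math.inf
        return self.sensitivity / (1.0 - self.specificity)

    @property
    def nlr(self) -> float:
        if self.specificity == 0.0:
            return math.nan
        return (1.0 - self.sensitivity) / self.specificity

    # Report-level values: percentages at one decimal, likelihood ratios
    # recomputed from those rounded percentages (half away from zero).
    @property
    def sensitivity_pct(self) -> float:
        return round_half_away(100.0 * self.sensitivity, 1)

    @property
    def specificity_pct(self) -> float:
        return round_half_away(100.0 * self.specificity, 1)

    @property
    def plr_reported(self) -> float:
        if self.specificity_pct == 100.0:
            return math.inf
        return round_half_away(self.sensitivity_pct / (100.0 - self.specificity_pct), 1)

    @property
    def nlr_reported(self) -> float:
        if self.specificity_pct == 0.0:
            return math.nan
        return round_half_away((100.0 - self.sensitivity_pct) / self.specificity_pct, 1)


def round_half_away(x: float, digits: int = 1) -> float:
    """Round with halves away from zero (the convention of the printed tables)."""
    scale = 10.0**digits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def _oriented(values, direction: str) -> np.ndarray:
    """Orient scores so that larger means more ASD-like."""
    v = np.asarray(values, dtype=float)
    return -v if direction == ASD_BELOW else v


def auc(values_asd, values_td, direction: str = ASD_BELOW) -> float:
    """P(oriented ASD score > oriented TD score) + 1/2 P(tie).

    Computed from midranks (the Mann-Whitney U statistic over n1*n2), which
    equals the brute-force all-pairs win/tie count.
    """
    x = _oriented(values_asd, direction)
    y = _oriented(values_td, direction)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("AUC needs both groups non-empty")
    u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u) / (len(x) * len(y))


def hanley_mcneil_ci(a: float, n1: int, n2: int, level: float = 0.95):
    """Normal-approximation CI for an AUC (Hanley & McNeil standard error)."""
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n2 - 1) * (q2 - a**2)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    zcrit = sps.norm.ppf(0.5 + level / 2)
    return max(0.0, a - zcrit * se), min(1.0, a + zcrit * se)


def _sens_spec(rule: CutoffRule, values_asd, values_td):
    sens = float(np.mean([rule.meets(v) for v in values_asd]))
    spec = float(np.mean([not rule.meets(v) for v in values_td]))
    return sens, spec


def select_cutoff(values_asd, values_td, direction: str = ASD_BELOW, item_id: str = "") -> CutoffRule:
    """Youden-optimal strict-inequality cutoff over midpoint candidates.

    Candidates are the midpoints between adjacent distinct pooled values plus
    one candidate below the minimum and one above the maximum.  Ties in J
    break toward higher specificity, then (still tied) toward the cutoff
    classifying fewer participants as ASD-like.
    """
    x = np.asarray(values_asd, dtype=float)
    y = np.asarray(values_td, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("cutoff selection needs both groups non-empty")
    pooled = np.unique(np.concatenate([x, y]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    best = None
    for c in candidates:
        rule = CutoffRule(item_id=item_id, direction=direction, cutoff_value=float(c))
        sens, spec = _sens_spec(rule, x, y)
        j = sens + spec - 1.0
        key = (j, spec, -sens)
        if best is None or key > best[0]:
            best = (key, rule, sens, spec)
    return best[1]


def roc_analysis(
    fixation_table: FixationTable,
    participants: pd.DataFrame,
    battery: list[StimulusSpec] | None = None,
) -> list[RocResult]:
    """Per-item AUC with CI plus the Youden cutoff, for every AoI item."""
    battery = battery or fixation_table.battery or default_battery()
    out = []
    for stim in battery:
        for aoi in stim.aois:
            item = f"{stim.stimulus_id}.{aoi.aoi_id}"
            direction = ASD_BELOW if aoi.direction == ASD_LOWER else ASD_ABOVE
            x = fixation_table.values_for(item, participants, "ASD")
            y = fixation_table.values_for(item, participants, "TD")
            a = auc(x, y, direction)
            lo, hi = hanley_mcneil_ci(a, len(x), len(y))
            rule = select_cutoff(x, y, direction, item_id=item)
            sens, spec = _sens_spec(rule, x, y)
            out.append(
                RocResult(
                    item_id=item,
                    auc=a,
                    ci_low=lo,
                    ci_high=hi,
                    rule=rule,
                    sens_at_cutoff=sens,
                    spec_at_cutoff=spec,
                )
            )
    return out


def select_panel(
    comparisons: list[GroupComparison],
    d_min: float = 0.8,
    aoi1_only: bool = True,
    battery: list[StimulusSpec] | None = None,
) -> list[str]:
    """Items for the classifier panel: (primary) AoIs with d above ``d_min``.

    Returned in battery presentation order; an empty screen is an error.
    """
    battery = battery or default_battery()
    eligible = aoi1_items(battery) if aoi1_only else [c.item_id for c in comparisons]
    by_item = {c.item_id: c for c in comparisons}
    panel = [
        item
        for item in eligible
        if item in by_item and by_item[item].cohens_d > d_min
    ]
    if not panel:
        raise PanelEmptyError(f"no item exceeds d > {d_min}")
    return panel


def count_items_met(record, rules: list[CutoffRule]) -> int:
    """How many panel rules a participant's record meets (strict inequalities)."""
    count = 0
    for rule in rules:
        try:
            value = record[rule.item_id]
        except KeyError as exc:
            raise InsufficientDataError(f"record lacks a value for {rule.item_id!r}") from exc
        if pd.isna(value):
            raise InsufficientDataError(f"record value for {rule.item_id!r} is missing")
        count += bool(rule.meets(float(value)))
    return count


def breakdown_by_combination(
    fixation_table: FixationTable,
    participants: pd.DataFrame,
    rules: list[CutoffRule],
) -> pd.DataFrame:
    """Per-group counts for every subset of panel items met (the 2^m cells)."""
    items = [r.item_id for r in rules]
    rows = {}
    for mask in range(2 ** len(items)):
        subset = frozenset(items[i] for i in range(len(items)) if mask >> i & 1)
        rows[subset] = {"asd_n": 0, "td_n": 0}
    inc = fixation_table.included
    meta = participants.loc[participants.index.intersection(inc.index)]
    for pid, row in inc.iterrows():
        met = frozenset(r.item_id for r in rules if r.meets(float(row[r.item_id])))
        grp = meta.loc[pid, "group"]
        rows[met]["asd_n" if grp == "ASD" else "td_n"] += 1
    order = sorted(rows, key=lambda s: (len(s), sorted(s)))
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(pd.Index(order, tupleize_cols=False))
    df.index.name = "items_met"
    return df


def _sweep(counts_by_n_met: dict[int, tuple[int, int]], m: int) -> list[DiscriminantMetrics]:
    n_asd = sum(v[0] for v in counts_by_n_met.values())
    n_td = sum(v[1] for v in counts_by_n_met.values())
    if n_asd == 0 or n_td == 0:
        raise InsufficientDataError("discriminant sweep needs both groups non-empty")
    out = []
    for k in range(1, m + 1):
        tp = sum(v[0] for n, v in counts_by_n_met.items() if n >= k)
        fp = sum(v[1] for n, v in counts_by_n_met.items() if n >= k)
        out.append(DiscriminantMetrics(k=k, tp=tp, fn=n_asd - tp, tn=n_td - fp, fp=fp))
    return out


def discriminant_sweep(
    fixation_table: FixationTable,
    participants: pd.DataFrame,
    rules: list[CutoffRule],
):
    """Classify "ASD iff count >= k" for every k = 1..m.

    Returns ``(breakdown, metrics)``: the full item-combination breakdown and
    one :class:`DiscriminantMetrics` per count threshold.
    """
    if not rules:
        raise PanelEmptyError("discriminant sweep needs a non-empty rule panel")
    breakdown = breakdown_by_combination(fixation_table, participants, rules)
    counts: dict[int, tuple[int, int]] = {}
    for subset, row in breakdown.iterrows():
        n = len(subset)
        a, t = counts.get(n, (0, 0))
        counts[n] = (a + int(row["asd_n"]), t + int(row["td_n"]))
    return breakdown, _sweep(counts, len(rules))


def sweep_from_counts(panel_counts: dict[frozenset, tuple[int, int]], m: int | None = None):
    """The same sweep driven by printed combination counts (no raw data).

    ``panel_counts`` maps each subset of items met to (n_asd, n_td); this is
    exactly the published breakdown table's shape.
    """
    if m is None:
        m = max((len(s) for s in panel_counts), default=0)
    if m == 0:
        raise PanelEmptyError("empty combination table")
    counts: dict[int, tuple[int, int]] = {}
    for subset, (a, t) in panel_counts.items():
        n = len(subset)
        pa, pt = counts.get(n, (0, 0))
        counts[n] = (pa + a, pt + t)
    return _sweep(counts, m)


def rules_from_table4(table4: pd.DataFrame, items: list[str]) -> list[CutoffRule]:
    """The published integer cutoffs as rules, for applying the paper's classifier."""
    return [
        CutoffRule(
            item_id=item,
            direction=str(table4.loc[item, "direction"]),
            cutoff_value=float(table4.loc[item, "cutoff"]),
        )
        for item in items
    ]
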