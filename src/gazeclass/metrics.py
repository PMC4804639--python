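"""From raw gaze samples to the participant x AoI percentage-fixation table.

The device metric is deliberately simple: no fixation-event detection, no
velocity filtering, no gap interpolation.  A participant's percentage fixation
for an AoI is the share of *scheduled* samples (stimulus duration times the
50 Hz sampling rate) whose recorded gaze point falls inside the AoI
rectangle.  Invalid samples (tracker lost the eyes) stay in the denominator,
which is why the published per-stimulus percentages do not sum to 100: the
remainder splits into out-of-AoI time and untracked time.

Availability is the share of scheduled samples over the whole battery that
were valid; participants under the threshold (80% in the study) are excluded
from every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import StimulusSpec, default_battery, iter_items
from .exceptions import IncompleteStreamError

__all__ = [
    "FixationTable",
    "compute_availability",
    "compute_fixation_table",
    "assemble_fixation_table",
    "read_gaze_csv",
    "write_fixation_csv",
    "read_fixation_csv",
    "item_columns",
]

GAZE_COLUMNS = ["participant_id", "stimulus_id", "t_ms", "x_px", "y_px", "valid"]

DEFAULT_AVAILABILITY_THRESHOLD = 80.0


def item_columns(battery: list[StimulusSpec]) -> list[str]:
    """AoI item columns followed by per-stimulus out-of-AoI columns."""
    cols = [item for _, _, item in iter_items(battery)]
    cols += [f"{s.stimulus_id}.out" for s in battery]
    return cols


@dataclass
class FixationTable:
    """Included fixation records plus the excluded roster.

    ``included`` is indexed by participant id with one column per AoI item
    (``"B.eyes"``-style), one ``"<stimulus>.out"`` column per stimulus, and an
    ``"availability"`` column, all in percent of the scheduled samples.
    ``excluded`` carries (participant_id index, availability).
    """

    included: pd.DataFrame
    excluded: pd.DataFrame
    threshold: float = DEFAULT_AVAILABILITY_THRESHOLD
    battery: list[StimulusSpec] = field(default_factory=default_battery)

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def values_for(self, item: str, participants: pd.DataFrame, group: str) -> np.ndarray:
        """Included values of one item for one group, aligned by participant id."""
        ids = participants.index[participants["group"] == group]
        ids = [i for i in ids if i in self.included.index]
        return self.included.loc[ids, item].to_numpy(dtype=float)


def compute_availability(stream: pd.DataFrame, battery: list[StimulusSpec] | None = None) -> float:
    """Percent of scheduled samples (whole battery) with a valid eye position."""
    battery = battery or default_battery()
    _validate_stream(stream, battery)
    total = sum(s.n_samples for s in battery)
    valid = int(stream["valid"].sum())
    return 100.0 * valid / total


def _validate_stream(stream: pd.DataFrame, battery: list[StimulusSpec]) -> None:
    counts = stream.groupby("stimulus_id").size()
    for spec in battery:
        n = int(counts.get(spec.stimulus_id, 0))
        if n == 0:
            raise IncompleteStreamError(f"stream is missing stimulus {spec.stimulus_id!r}")
        if n != spec.n_samples:
            raise IncompleteStreamError(
                f"stimulus {spec.stimulus_id!r}: expected {spec.n_samples} samples, got {n}"
            )


def compute_fixation_table(
    streams: pd.DataFrame,
    battery: list[StimulusSpec] | None = None,
    threshold: float = DEFAULT_AVAILABILITY_THRESHOLD,
) -> FixationTable:
    """Count every participant's samples into AoIs and apply the exclusion rule.

    ``streams`` is a long-format frame with the simulator's gaze columns
    (one or many participants).  Percentages use the scheduled sample count of
    each stimulus as denominator; participants whose battery-wide availability
    is strictly below ``threshold`` go to the excluded roster.
    """
    battery = battery or default_battery()
    rows = {}
    for pid, stream in streams.groupby("participant_id", sort=True):
        _validate_stream(stream, battery)
        rec: dict[str, float] = {}
        valid_total = 0
        for spec in battery:
            sub = stream[stream["stimulus_id"] == spec.stimulus_id]
            valid = sub["valid"].to_numpy(dtype=bool)
            x = sub["x_px"].to_numpy(dtype=float)
            y = sub["y_px"].to_numpy(dtype=float)
            n = spec.n_samples
            valid_total += int(valid.sum())
            in_any = np.zeros(n, dtype=bool)
            for aoi in spec.aois:
                inside = valid & aoi.contains(x, y)
                rec[f"{spec.stimulus_id}.{aoi.aoi_id}"] = 100.0 * inside.sum() / n
                in_any |= inside
            rec[f"{spec.stimulus_id}.out"] = 100.0 * (valid & ~in_any).sum() / n
        rec["availability"] = 100.0 * valid_total / sum(s.n_samples for s in battery)
        rows[pid] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=item_columns(battery) + ["availability"])
    table.index.name = "participant_id"
    return assemble_fixation_table(table, threshold, battery)


def assemble_fixation_table(
    table: pd.DataFrame,
    threshold: float = DEFAULT_AVAILABILITY_THRESHOLD,
    battery: list[StimulusSpec] | None = None,
) -> FixationTable:
    """Split a per-participant percentage table on the availability rule."""
    battery = battery or default_battery()
    low = table["availability"] < threshold
    return FixationTable(
        included=table.loc[~low].copy(),
        excluded=table.loc[low, ["availability"]].copy(),
        threshold=threshold,
        battery=battery,
    )


def read_gaze_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise IncompleteStreamError(f"gaze CSV is missing columns {missing}")
    return df


def write_fixation_csv(table: FixationTable, path) -> None:
    out = table.included.copy()
    cols = ["availability"] + [c for c in out.columns if c != "availability"]
    out[cols].round(1).to_csv(path, float_format="%.1f")


def read_fixation_csv(path, threshold: float = DEFAULT_AVAILABILITY_THRESHOLD) -> FixationTable:
    df = pd.read_csv(path, index_col="participant_id")
    return assemble_fixation_table(df, threshold)
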