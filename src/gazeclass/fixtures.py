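"""Packaged fixtures of the published summary tables.

The study this battery design comes from printed its group demographics,
per-AoI fixation summaries with t/p/d, per-item ROC results with integer
cutoffs, the per-group breakdown of which panel-item combinations exceeded
their cutoffs, and the count-threshold discriminant parameters.  Raw
per-participant data were never deposited, so these printed summaries are
the only real-data surface the package can be checked against; they are
shipped as small CSVs (``table1`` demographics through ``table6``
discriminant rows) and exposed as DataFrames here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PaperFixtures", "load_fixtures"]


@dataclass(frozen=True)
class PaperFixtures:
    table1: pd.DataFrame  # demographics: measure/group/n/mean/sd (+ printed t, p)
    table2: pd.DataFrame  # per-item group summaries, indexed by item id
    table4: pd.DataFrame  # per-item AUC/CI/direction/cutoff, indexed by item id
    table5: pd.DataFrame  # panel-combination counts, indexed by combination label
    table6: pd.DataFrame  # printed discriminant rows per panel and count threshold

    @property
    def n_asd(self) -> int:
        """Included ASD group size."""
        return int(self.table5["asd_n"].sum())

    @property
    def n_td(self) -> int:
        return int(self.table5["td_n"].sum())

    @property
    def srs_asd_n(self) -> int:
        """ASD participants with a usable SRS total (4 of 21 are missing)."""
        row = self.table1[(self.table1["measure"] == "srs") & (self.table1["group"] == "ASD")]
        return int(row["n"].iloc[0])

    def panel_counts(self, items: list[str]) -> dict[frozenset, tuple[int, int]]:
        """The combination-count table as {subset of items met: (n_asd, n_td)}."""
        out: dict[frozenset, tuple[int, int]] = {}
        for label, row in self.table5.iterrows():
            subset = frozenset(i for i in items if row.get(i, 0) == 1)
            out[subset] = (int(row["asd_n"]), int(row["td_n"]))
        return out


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("gazeclass.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def load_fixtures() -> PaperFixtures:
    """Load the packaged printed-table fixtures."""
    return PaperFixtures(
        table1=_read("table1.csv"),
        table2=_read("table2.csv", index_col="item"),
        table4=_read("table4.csv", index_col="item"),
        table5=_read("table5.csv", index_col="label"),
        table6=_read("table6.csv"),
    )
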