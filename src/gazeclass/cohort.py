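"""Synthetic two-group cohort: participant metadata and raw 50 Hz gaze streams.

The generator emulates the case-control structure of the study: ~26 autistic
(ASD) and 35 typically developing (TD) male adolescents/adults, whose derived
per-AoI percentage fixation times reproduce, in distribution, the published
group means and SDs, and whose availability distribution includes the five
low-tracking ASD participants (60, 58, 53, 52 and 31% availability) that the
80% rule excludes.

Per participant and stimulus the model is:

1. draw a latent attention profile - one normal draw per AoI, clipped to
   [0, 100] and rescaled proportionally if the within-stimulus sum exceeds
   the participant's availability (see :mod:`gazeclass.calibration` for why
   the latent parameters are fitted rather than set to the published values);
2. emit ``duration x 50`` samples, each independently invalid with
   probability ``1 - availability/100``, otherwise placed uniformly inside
   the AoI (or the out-of-AoI region) chosen with the profile's proportions.

There is deliberately no saccade or dwell-time model: every downstream
statistic consumes time-aggregated percentages, for which per-sample
independence is sufficient.  SRS and FSIQ scores are drawn from the published
group normals; by default they are independent of gaze (the study found
almost no within-group correlation), with an optional coupling knob for power
experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import calibration
from .battery import ASD_LOWER, StimulusSpec, default_battery
from .exceptions import ConfigurationError, GenerationError
from .fixtures import load_fixtures
from .metrics import (
    DEFAULT_AVAILABILITY_THRESHOLD,
    FixationTable,
    assemble_fixation_table,
    item_columns,
)

__all__ = [
    "AvailabilityModel",
    "GroupParams",
    "CohortParams",
    "default_params",
    "draw_attention_profile",
    "generate_cohort",
    "simulate_fixation_table",
    "write_cohort_csvs",
    "regenerate_latent_table",
]

ASD, TD = "ASD", "TD"

#: Availabilities (%) of the five excluded low-tracking ASD participants.
LOW_AVAILABILITY_VALUES = (60.0, 58.0, 53.0, 52.0, 31.0)


@dataclass(frozen=True)
class AvailabilityModel:
    """Mean/SD of normally tracking participants plus the low-tracking mixture."""

    mean: float
    sd: float
    low_probability: float = 0.0
    low_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.low_probability <= 1:
            raise ConfigurationError("availability.low_probability must be in [0, 1]")
        if self.low_probability > 0 and not self.low_values:
            raise ConfigurationError("availability.low_values required when low_probability > 0")


@dataclass(frozen=True)
class GroupParams:
    n: int
    availability: AvailabilityModel
    srs_mean: float
    srs_sd: float
    srs_missing: int = 0
    fsiq_mean: float | None = None
    fsiq_sd: float | None = None
    age_mean: float = 25.0
    age_sd: float = 5.0
    age_range: tuple[float, float] = (15.0, 41.0)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("each group needs n >= 2")


@dataclass(frozen=True)
class CohortParams:
    """Everything the simulator needs, including the calibrated latent model.

    ``targets`` maps ``(group, stimulus_id)`` to ``[(aoi_id, mean, sd), ...]``
    in battery AoI order; ``latents`` maps the same keys to
    ``[(aoi_id, mu, sigma), ...]`` fitted so the derived percentages hit the
    targets.  ``seed`` is the root of all randomness; every participant gets
    a named substream spawned from it.
    """

    groups: dict[str, GroupParams]
    targets: dict[tuple[str, str], list[tuple[str, float, float]]]
    latents: dict[tuple[str, str], list[tuple[str, float, float]]]
    seed: int = 0
    srs_fixation_r: float = 0.0

    def __post_init__(self) -> None:
        for (group, stim), rows in self.targets.items():
            means = [m for _, m, _ in rows]
            if any(not 0 <= m <= 100 for m in means):
                raise ConfigurationError(f"targets for {group}/{stim}: means must be in [0, 100]")
            if any(s < 0 for _, _, s in rows):
                raise ConfigurationError(f"targets for {group}/{stim}: SDs must be >= 0")
            if sum(means) > 100:
                raise ConfigurationError(f"targets for {group}/{stim}: AoI means sum above 100")

    @property
    def n_asd(self) -> int:
        return self.groups[ASD].n

    @property
    def n_td(self) -> int:
        return self.groups[TD].n

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)

    def target_mean(self, group: str, item: str) -> float:
        stim, aoi = item.split(".", 1)
        for aoi_id, mean, _ in self.targets[(group, stim)]:
            if aoi_id == aoi:
                return mean
        raise KeyError(item)


def _load_latent_table() -> dict[tuple[str, str], list[tuple[str, float, float]]]:
    with resources.files("gazeclass.data").joinpath("latent_calibration.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[tuple[str, str], list[tuple[str, float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault((row.group, row.stimulus), []).append((row.aoi, float(row.mu), float(row.sigma)))
    return out


def default_params(seed: int = 0) -> CohortParams:
    """The study conditions: published group sizes, moments and availability."""
    fx = load_fixtures()
    t2 = fx.table2
    targets: dict[tuple[str, str], list[tuple[str, float, float]]] = {}
    for item, row in t2.iterrows():
        if item == "availability":
            continue
        stim, aoi = str(item).split(".", 1)
        for group, mcol, scol in ((ASD, "asd_mean", "asd_sd"), (TD, "td_mean", "td_sd")):
            targets.setdefault((group, stim), []).append((aoi, float(row[mcol]), float(row[scol])))
    av = t2.loc["availability"]
    groups = {
        ASD: GroupParams(
            n=26,
            availability=AvailabilityModel(
                mean=float(av["asd_mean"]),
                sd=float(av["asd_sd"]),
                low_probability=5 / 26,
                low_values=LOW_AVAILABILITY_VALUES,
            ),
            srs_mean=111.8,
            srs_sd=18.5,
            srs_missing=4,
            fsiq_mean=99.8,
            fsiq_sd=13.5,
            age_mean=27.6,
            age_sd=7.7,
            age_range=(15.0, 41.0),
        ),
        TD: GroupParams(
            n=35,
            availability=AvailabilityModel(mean=float(av["td_mean"]), sd=float(av["td_sd"])),
            srs_mean=53.6,
            srs_sd=16.9,
            age_mean=25.2,
            age_sd=4.5,
            age_range=(20.0, 41.0),
        ),
    }
    return CohortParams(groups=groups, targets=targets, latents=_load_latent_table(), seed=seed)


def _latent_arrays(params: CohortParams, group: str, stim: StimulusSpec):
    key = (group, stim.stimulus_id)
    if key not in params.latents:
        raise ConfigurationError(f"no calibrated latents for group {group!r}, stimulus {stim.stimulus_id!r}")
    rows = params.latents[key]
    order = {a.aoi_id: i for i, a in enumerate(stim.aois)}
    if set(order) != {r[0] for r in rows}:
        raise ConfigurationError(
            f"latents for {group}/{stim.stimulus_id} do not match the battery AoIs"
        )
    rows = sorted(rows, key=lambda r: order[r[0]])
    mus = np.array([r[1] for r in rows])
    sigmas = np.array([r[2] for r in rows])
    return mus, sigmas


def draw_attention_profile(
    params: CohortParams,
    group: str,
    stim: StimulusSpec,
    rng: np.random.Generator,
    availability: float = 100.0,
    z: np.ndarray | None = None,
):
    """One participant's latent per-AoI percentages plus the out-of-AoI share.

    Returns ``(per_aoi, out)`` where ``per_aoi`` is an array aligned with
    ``stim.aois`` of percentages of the full stimulus duration, and
    ``out = availability - sum(per_aoi)``.
    """
    mus, sigmas = _latent_arrays(params, group, stim)
    if z is None:
        z = rng.standard_normal(len(mus))
    latent = mus + sigmas * z
    per_aoi = calibration.clip_rescale(latent[:, None], np.array([availability]))[:, 0]
    out = availability - per_aoi.sum()
    return per_aoi, max(out, 0.0)


def _draw_availability(gp: GroupParams, n: int, rng: np.random.Generator):
    """Per-participant availability (%) with a deterministic low-tracking count."""
    n_low = int(round(gp.availability.low_probability * n))
    avail = calibration.draw_normal_availability(gp.availability.mean, gp.availability.sd, n, rng)
    low_idx = np.array([], dtype=int)
    if n_low:
        vals = list(gp.availability.low_values)
        if n_low <= len(vals):
            low_vals = np.array(vals[:n_low])
        else:
            low_vals = np.concatenate([vals, rng.choice(vals, size=n_low - len(vals), replace=True)])
        low_idx = rng.choice(n, size=n_low, replace=False)
        avail[low_idx] = low_vals
    return avail, low_idx


def _direction_signs(stim: StimulusSpec) -> np.ndarray:
    # Sign with which the shared severity factor loads on each AoI: social
    # regions (ASD-lower) load negatively, competing regions positively.
    return np.array([-1.0 if a.direction == ASD_LOWER else 1.0 for a in stim.aois])


def _draw_scores(gp: GroupParams, n: int, rng: np.random.Generator, severity: np.ndarray):
    srs = np.round(gp.srs_mean + gp.srs_sd * severity).clip(0, 195).astype(int)
    age = np.round(np.clip(rng.normal(gp.age_mean, gp.age_sd, n), *gp.age_range), 1)
    if gp.fsiq_mean is not None:
        fsiq = np.round(rng.normal(gp.fsiq_mean, gp.fsiq_sd, n)).astype(float)
    else:
        fsiq = np.full(n, np.nan)
    return srs.astype(float), age, fsiq


def _participant_frame(params: CohortParams, rng: np.random.Generator):
    """Participant metadata plus per-participant availability and severity."""
    frames = []
    extras = {}
    for group in (ASD, TD):
        gp = params.groups[group]
        avail, low_idx = _draw_availability(gp, gp.n, rng)
        severity = rng.standard_normal(gp.n)
        srs, age, fsiq = _draw_scores(gp, gp.n, rng, severity)
        ids = [f"{group}-{i + 1:03d}" for i in range(gp.n)]
        if gp.srs_missing:
            candidates = np.setdiff1d(np.arange(gp.n), low_idx)
            miss = rng.choice(candidates, size=gp.srs_missing, replace=False)
            srs[miss] = np.nan
        frames.append(
            pd.DataFrame(
                {"group": group, "age_years": age, "srs_total": srs, "fsiq": fsiq},
                index=pd.Index(ids, name="participant_id"),
            )
        )
        extras[group] = {"availability": avail, "severity": severity, "ids": ids}
    return pd.concat(frames), extras


def _category_probs(per_aoi: np.ndarray, out: float, availability: float) -> np.ndarray:
    """Per-sample probabilities (invalid, aoi..., out); absorbs float round-off."""
    p = np.empty(len(per_aoi) + 2)
    p[1:-1] = per_aoi / 100.0
    p[-1] = out / 100.0
    p[0] = max(1.0 - p[1:].sum(), 0.0)
    return p / p.sum()


def _sample_positions_out(stim: StimulusSpec, count: int, rng: np.random.Generator):
    """Uniform integer pixels on the screen outside every AoI (rejection)."""
    scr = stim.screen
    free = scr.width_px * scr.height_px - sum(a.area for a in stim.aois)
    if free <= 0:
        raise GenerationError(
            f"stimulus {stim.stimulus_id!r}: AoIs tile the screen; no out-of-AoI region exists"
        )
    xs = np.empty(count, dtype=int)
    ys = np.empty(count, dtype=int)
    todo = np.arange(count)
    while todo.size:
        x = rng.integers(0, scr.width_px, todo.size)
        y = rng.integers(0, scr.height_px, todo.size)
        bad = np.zeros(todo.size, dtype=bool)
        for a in stim.aois:
            bad |= a.contains(x, y)
        xs[todo[~bad]] = x[~bad]
        ys[todo[~bad]] = y[~bad]
        todo = todo[bad]
    return xs, ys


def generate_cohort(
    params: CohortParams | None = None,
    battery: list[StimulusSpec] | None = None,
    seed: int | None = None,
):
    """Draw the full cohort: metadata frame plus long-format gaze samples.

    Deterministic given (params, seed): the root seed spawns one substream for
    the cohort-level assignments and one per participant.
    """
    params = params or default_params()
    battery = battery or default_battery()
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    n_total = sum(g.n for g in params.groups.values())
    cohort_ss, *participant_ss = root.spawn(1 + n_total)
    participants, extras = _participant_frame(params, np.random.default_rng(cohort_ss))

    r = params.srs_fixation_r
    records: list[pd.DataFrame] = []
    k_part = 0
    for group in (ASD, TD):
        ex = extras[group]
        for i, pid in enumerate(ex["ids"]):
            rng = np.random.default_rng(participant_ss[k_part])
            k_part += 1
            a = float(ex["availability"][i])
            sev = float(ex["severity"][i])
            for stim in battery:
                kaoi = len(stim.aois)
                eps = rng.standard_normal(kaoi)
                z = r * _direction_signs(stim) * sev + np.sqrt(1 - r**2) * eps
                per_aoi, out = draw_attention_profile(params, group, stim, rng, a, z=z)
                probs = _category_probs(per_aoi, out, a)
                n = stim.n_samples
                cats = rng.choice(kaoi + 2, size=n, p=probs)
                x = np.full(n, np.nan)
                y = np.full(n, np.nan)
                for j, aoi in enumerate(stim.aois, start=1):
                    m = cats == j
                    x0, y0, x1, y1 = aoi.rect
                    x[m] = rng.integers(x0, x1, m.sum())
                    y[m] = rng.integers(y0, y1, m.sum())
                m = cats == kaoi + 1
                if m.any():
                    xs, ys = _sample_positions_out(stim, int(m.sum()), rng)
                    x[m] = xs
                    y[m] = ys
                records.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "stimulus_id": stim.stimulus_id,
                            "t_ms": np.arange(n) * (1000 // stim.screen.sample_rate_hz),
                            "x_px": x,
                            "y_px": y,
                            "valid": (cats != 0).astype(int),
                        }
                    )
                )
    gaze = pd.concat(records, ignore_index=True)
    return participants, gaze


def simulate_fixation_table(
    params: CohortParams | None = None,
    battery: list[StimulusSpec] | None = None,
    seed: int | None = None,
    threshold: float = DEFAULT_AVAILABILITY_THRESHOLD,
):
    """Vectorised shortcut from parameters straight to the fixation table.

    Distributionally identical to ``generate_cohort`` followed by
    ``compute_fixation_table`` - sample counts per category are multinomial
    either way and positions inside a region do not affect the counts - but
    skips materialising per-sample streams, so cohorts of thousands per group
    take seconds.  Returns ``(participants, FixationTable)``.
    """
    params = params or default_params()
    battery = battery or default_battery()
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    cohort_ss, sim_ss = root.spawn(2)
    participants, extras = _participant_frame(params, np.random.default_rng(cohort_ss))
    rng = np.random.default_rng(sim_ss)
    r = params.srs_fixation_r

    frames = []
    for group in (ASD, TD):
        ex = extras[group]
        n = len(ex["ids"])
        avail = ex["availability"]
        sev = ex["severity"]
        data: dict[str, np.ndarray] = {}
        valid_total = np.zeros(n)
        for stim in battery:
            mus, sigmas = _latent_arrays(params, group, stim)
            kaoi = len(mus)
            eps = rng.standard_normal((kaoi, n))
            z = r * _direction_signs(stim)[:, None] * sev[None, :] + np.sqrt(1 - r**2) * eps
            per_aoi = calibration.clip_rescale(mus[:, None] + sigmas[:, None] * z, avail)
            out = np.maximum(avail - per_aoi.sum(axis=0), 0.0)
            probs = np.vstack([per_aoi / 100.0, out / 100.0]).T
            probs = np.column_stack([np.maximum(1.0 - probs.sum(axis=1), 0.0), probs])
            probs /= probs.sum(axis=1, keepdims=True)
            counts = rng.multinomial(stim.n_samples, probs)
            valid_total += stim.n_samples - counts[:, 0]
            for j, aoi in enumerate(stim.aois):
                data[f"{stim.stimulus_id}.{aoi.aoi_id}"] = 100.0 * counts[:, j + 1] / stim.n_samples
            data[f"{stim.stimulus_id}.out"] = 100.0 * counts[:, kaoi + 1] / stim.n_samples
        data["availability"] = 100.0 * valid_total / sum(s.n_samples for s in battery)
        frames.append(pd.DataFrame(data, index=pd.Index(ex["ids"], name="participant_id")))
    table = pd.concat(frames).reindex(columns=item_columns(battery) + ["availability"])
    return participants, assemble_fixation_table(table, threshold, battery)


def write_cohort_csvs(participants: pd.DataFrame, gaze: pd.DataFrame, out_dir) -> tuple[str, str]:
    """Write ``participants.csv`` and ``gaze.csv`` with stable formatting."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ppath = out / "participants.csv"
    gpath = out / "gaze.csv"
    pt = participants.copy()
    pt.to_csv(ppath, float_format="%.1f")
    g = gaze.copy()
    g["x_px"] = g["x_px"].map(lambda v: "" if pd.isna(v) else f"{int(v)}")
    g["y_px"] = g["y_px"].map(lambda v: "" if pd.isna(v) else f"{int(v)}")
    g.to_csv(gpath, index=False)
    return str(ppath), str(gpath)


def regenerate_latent_table(path=None, n_mc: int = 120_000) -> pd.DataFrame:
    """Re-run the calibration that produced the packaged latent table.

    Uses the packaged printed-table targets and the fixed calibration seed;
    writing to ``path`` reproduces ``data/latent_calibration.csv``.
    """
    fx = load_fixtures()
    t2 = fx.table2
    targets: dict[tuple[str, str], list[tuple[str, float, float]]] = {}
    for item, row in t2.iterrows():
        if item == "availability":
            continue
        stim, aoi = str(item).split(".", 1)
        for group, mcol, scol in ((ASD, "asd_mean", "asd_sd"), (TD, "td_mean", "td_sd")):
            targets.setdefault((group, stim), []).append((aoi, float(row[mcol]), float(row[scol])))
    av = t2.loc["availability"]
    availability = {ASD: (float(av["asd_mean"]), float(av["asd_sd"])), TD: (float(av["td_mean"]), float(av["td_sd"]))}
    records = calibration.calibrate_latents(targets, availability, n_mc=n_mc)
    df = pd.DataFrame(records, columns=["group", "stimulus", "aoi", "mu", "sigma"])
    if path is not None:
        df.to_csv(path, index=False, float_format="%.6f")
    return df
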