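"""Stimulus battery definition: screen constants, AoI geometry, presentation order.

The battery is the two-minute sequence of eight short movies shown on a
1280 x 1024 monitor while gaze is sampled at 50 Hz: five face clips (still
image, blinking, mouth moving, silent, talking), one biological-motion clip
(upright and inverted point-light dancers side by side), and two
people-vs-geometry clips (same size, and geometry in a small window).
Each stimulus carries one or two rectangular areas of interest (AoIs);
"AoI-1" is the socially salient region (eyes, upright motion, people) except
in the small-window clip, where the single AoI is the geometric window.

AoI rectangles are half-open pixel rectangles ``[x0, x1) x [y0, y1)`` with the
origin at the top-left corner, x rightward and y downward.  The published
battery does not document the device's exact AoI pixel geometry, so the
defaults here are documented placeholders (an eye band and a mouth band on the
face, left/right half-screens for the side-by-side clips, a window in the
lower-right quadrant for the small-window clip).  Geometry only affects how
simulated samples are placed and recounted; every downstream statistic
consumes the derived fixation percentages, which are calibrated directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .exceptions import ConfigurationError, GeometryError

__all__ = [
    "ScreenSpec",
    "AoIRegion",
    "StimulusSpec",
    "default_battery",
    "default_screen",
    "load_battery",
    "battery_to_config",
    "save_battery",
    "iter_items",
    "aoi1_items",
    "scheduled_samples",
]

#: Direction labels: which group is expected to score lower on the AoI.
ASD_LOWER = "asd_lower"
ASD_HIGHER = "asd_higher"

STANDARD_STIMULUS_IDS = list("ABCDEFGH")


@dataclass(frozen=True)
class ScreenSpec:
    """Monitor raster and gaze sampling constants."""

    width_px: int = 1280
    height_px: int = 1024
    sample_rate_hz: int = 50

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"screen.{name} must be positive")


@dataclass(frozen=True)
class AoIRegion:
    """A named half-open pixel rectangle with a role and expected direction."""

    aoi_id: str
    rect: tuple[int, int, int, int]  # (x0, y0, x1, y1)
    role: str  # "aoi1" or "aoi2"
    direction: str = ASD_LOWER

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise GeometryError(
                f"AoI {self.aoi_id!r}: rect must satisfy x0 < x1 and y0 < y1, got {self.rect}"
            )
        if self.role not in ("aoi1", "aoi2"):
            raise ConfigurationError(f"AoI {self.aoi_id!r}: role must be aoi1/aoi2, got {self.role!r}")
        if self.direction not in (ASD_LOWER, ASD_HIGHER):
            raise ConfigurationError(
                f"AoI {self.aoi_id!r}: direction must be {ASD_LOWER!r} or {ASD_HIGHER!r}"
            )

    @property
    def area(self) -> int:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)

    def contains(self, x, y):
        """Half-open point-in-rectangle test (right/bottom edges are outside)."""
        x0, y0, x1, y1 = self.rect
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)


@dataclass(frozen=True)
class StimulusSpec:
    """One movie in the battery: id, duration and its AoIs in a fixed order."""

    stimulus_id: str
    name: str
    duration_s: float
    aois: tuple[AoIRegion, ...]
    screen: ScreenSpec = field(default_factory=ScreenSpec)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError(f"stimulus {self.stimulus_id!r}: duration_s must be positive")
        if not self.aois:
            raise ConfigurationError(f"stimulus {self.stimulus_id!r}: needs at least one AoI")
        seen: set[str] = set()
        for aoi in self.aois:
            if aoi.aoi_id in seen:
                raise ConfigurationError(f"stimulus {self.stimulus_id!r}: duplicate AoI {aoi.aoi_id!r}")
            seen.add(aoi.aoi_id)
            x0, y0, x1, y1 = aoi.rect
            if x0 < 0 or y0 < 0 or x1 > self.screen.width_px or y1 > self.screen.height_px:
                raise GeometryError(
                    f"stimulus {self.stimulus_id!r}: AoI {aoi.aoi_id!r} exceeds the screen"
                )
        for i, a in enumerate(self.aois):
            for b in self.aois[i + 1 :]:
                if _rects_overlap(a.rect, b.rect):
                    raise GeometryError(
                        f"stimulus {self.stimulus_id!r}: AoIs {a.aoi_id!r} and {b.aoi_id!r} overlap"
                    )

    @property
    def n_samples(self) -> int:
        """Scheduled gaze samples for this stimulus (duration x sample rate)."""
        n = self.duration_s * self.screen.sample_rate_hz
        return int(round(n))

    @property
    def aoi1(self) -> AoIRegion:
        for aoi in self.aois:
            if aoi.role == "aoi1":
                return aoi
        raise ConfigurationError(f"stimulus {self.stimulus_id!r}: no aoi1 region")

    def item_ids(self) -> list[str]:
        return [f"{self.stimulus_id}.{a.aoi_id}" for a in self.aois]


def _rects_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def default_screen() -> ScreenSpec:
    return ScreenSpec()


# Placeholder geometry (pixels).  Face AoIs are horizontal bands over the
# central face region; the side-by-side clips use left/right panels with a
# gutter; the small-window clip uses a lower-right window.
_EYES = (440, 260, 840, 460)
_MOUTH = (480, 560, 800, 720)
_LEFT = (40, 112, 600, 912)
_RIGHT = (680, 112, 1240, 912)
_WINDOW = (880, 640, 1240, 944)

_FACE_AOIS = (
    ("eyes", _EYES, "aoi1", ASD_LOWER),
    ("mouth", _MOUTH, "aoi2", ASD_HIGHER),
)

_DEFAULT_LAYOUT: list[tuple[str, str, float, tuple]] = [
    ("A", "human face (still image)", 7.0, _FACE_AOIS),
    ("B", "human face (blinking)", 7.0, _FACE_AOIS),
    ("C", "human face (mouth moving)", 4.0, _FACE_AOIS),
    ("D", "human face (silent)", 3.0, _FACE_AOIS),
    ("E", "human face (talking)", 7.0, _FACE_AOIS),
    (
        "F",
        "biological motion (upright vs inverted)",
        20.0,
        (("upright", _LEFT, "aoi1", ASD_LOWER), ("inverted", _RIGHT, "aoi2", ASD_HIGHER)),
    ),
    (
        "G",
        "people and geometry (same size)",
        16.0,
        (("people", _LEFT, "aoi1", ASD_LOWER), ("geometry", _RIGHT, "aoi2", ASD_HIGHER)),
    ),
    (
        "H",
        "people and geometry (small window)",
        16.0,
        (("geometry", _WINDOW, "aoi1", ASD_HIGHER),),
    ),
]


def default_battery(screen: ScreenSpec | None = None) -> list[StimulusSpec]:
    """The eight-stimulus battery A..H in presentation order."""
    screen = screen or default_screen()
    specs = []
    for sid, name, dur, aois in _DEFAULT_LAYOUT:
        regions = tuple(AoIRegion(aoi_id=a, rect=r, role=role, direction=d) for a, r, role, d in aois)
        specs.append(StimulusSpec(stimulus_id=sid, name=name, duration_s=dur, aois=regions, screen=screen))
    return specs


def load_battery(config) -> list[StimulusSpec]:
    """Parse a battery from a JSON file path or an already-parsed mapping.

    The battery is extensible: stimuli beyond the standard A..H set are
    accepted; callers can detect non-standard entries by ``stimulus_id``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("battery config must be a JSON object")
    try:
        scr = config["screen"]
        screen = ScreenSpec(
            width_px=int(scr["width_px"]),
            height_px=int(scr["height_px"]),
            sample_rate_hz=int(scr["sample_rate_hz"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"battery config: missing screen field {exc.args[0]!r}") from exc
    stimuli = config.get("stimuli")
    if not isinstance(stimuli, list) or not stimuli:
        raise ConfigurationError("battery config: 'stimuli' must be a non-empty list")
    specs = []
    for entry in stimuli:
        try:
            sid = str(entry["id"])
            name = str(entry.get("name", sid))
            dur = float(entry["duration_s"])
            aois = entry["aois"]
        except KeyError as exc:
            raise ConfigurationError(f"battery config: stimulus missing field {exc.args[0]!r}") from exc
        if not isinstance(aois, list) or not aois:
            raise ConfigurationError(f"battery config: stimulus {sid!r} 'aois' must be a non-empty list")
        regions = []
        for a in aois:
            try:
                rect = tuple(int(v) for v in a["rect"])
                if len(rect) != 4:
                    raise ConfigurationError(
                        f"battery config: stimulus {sid!r} AoI {a.get('id')!r} rect must have 4 entries"
                    )
                regions.append(
                    AoIRegion(
                        aoi_id=str(a["id"]),
                        rect=rect,  # type: ignore[arg-type]
                        role=str(a.get("role", "aoi1")),
                        direction=str(a.get("direction", ASD_LOWER)),
                    )
                )
            except KeyError as exc:
                raise ConfigurationError(
                    f"battery config: stimulus {sid!r} AoI missing field {exc.args[0]!r}"
                ) from exc
        specs.append(
            StimulusSpec(stimulus_id=sid, name=name, duration_s=dur, aois=tuple(regions), screen=screen)
        )
    return specs


def battery_to_config(battery: list[StimulusSpec]) -> dict:
    """Inverse of :func:`load_battery` (round-trips the default battery)."""
    screen = battery[0].screen
    return {
        "screen": {
            "width_px": screen.width_px,
            "height_px": screen.height_px,
            "sample_rate_hz": screen.sample_rate_hz,
        },
        "stimuli": [
            {
                "id": s.stimulus_id,
                "name": s.name,
                "duration_s": s.duration_s,
                "aois": [
                    {"id": a.aoi_id, "role": a.role, "rect": list(a.rect), "direction": a.direction}
                    for a in s.aois
                ],
            }
            for s in battery
        ],
    }


def save_battery(battery: list[StimulusSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump(battery_to_config(battery), fh, indent=1)
        fh.write("\n")


def iter_items(battery: list[StimulusSpec]) -> Iterator[tuple[StimulusSpec, AoIRegion, str]]:
    """Yield (stimulus, aoi, item_id) over the battery in presentation order."""
    for stim in battery:
        for aoi in stim.aois:
            yield stim, aoi, f"{stim.stimulus_id}.{aoi.aoi_id}"


def aoi1_items(battery: list[StimulusSpec]) -> list[str]:
    """Item ids of the primary AoI of each stimulus, in battery order."""
    return [f"{s.stimulus_id}.{s.aoi1.aoi_id}" for s in battery]


def scheduled_samples(battery: list[StimulusSpec]) -> int:
    """Total scheduled samples over the whole battery."""
    return sum(s.n_samples for s in battery)
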