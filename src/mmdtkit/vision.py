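"""Board vision: HSV disc-colour states and the placing/turning event machine.

The dexterity board has 60 holes on a white table; each disc is red on one
face and black on the other. A fixed camera watches the board at 640x480 and
only the pixels around each known hole centre are inspected. Colour
classification is a threshold test in HSV (hue on the half-degree 0-180
scale, saturation/value on 0-255): white = empty hole, red = disc face-up,
black = disc flipped (or placed upside down during the placing phase).

A per-hole finite-state machine turns observed colour transitions into
timed events (placed correctly / upside down, turned correctly, removed),
with a short debounce so a transition must persist across consecutive
frames before it is committed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BoardLayout",
    "ColorThresholds",
    "DiscEvent",
    "BoardState",
    "rgb_to_hsv",
    "classify_hole_color",
    "observe_board",
    "advance_state",
    "disc_timings",
    "PLACING",
    "TURNING",
]

WHITE, RED, BLACK, UNKNOWN = "white", "red", "black", "unknown"
PLACING, TURNING = "placing", "turning"

N_HOLES = 60
IMAGE_SIZE = (640, 480)  # (width, height)


@dataclass(frozen=True)
class Hole:
    id: int
    row: int
    col: int
    x: float
    y: float


@dataclass
class BoardLayout:
    """Known hole-centre coordinates on the camera image.

    Pixel convention: 0-based pixel centres, x rightward, y downward.
    Default grid is 4 rows x 15 columns centred on the 640x480 frame.
    """

    holes: list[Hole]
    image_size: tuple[int, int] = IMAGE_SIZE
    sample_radius: int = 5

    def __post_init__(self) -> None:
        w, h = self.image_size
        if len({hole.id for hole in self.holes}) != len(self.holes):
            raise ValueError("hole ids must be unique")
        for hole in self.holes:
            if not (0 <= hole.x < w and 0 <= hole.y < h):
                raise ValueError(f"hole {hole.id} centre outside image bounds")

    @property
    def n_holes(self) -> int:
        return len(self.holes)

    @classmethod
    def default_grid(cls, rows: int = 4, cols: int = 15,
                     image_size: tuple[int, int] = IMAGE_SIZE,
                     sample_radius: int = 5) -> "BoardLayout":
        w, h = image_size
        dx = w / (cols + 1)
        dy = h / (rows + 1)
        holes = [
            Hole(id=r * cols + c, row=r, col=c,
                 x=round((c + 1) * dx), y=round((r + 1) * dy))
            for r in range(rows) for c in range(cols)
        ]
        return cls(holes, image_size, sample_radius)

    def to_json(self, path) -> None:
        doc = {
            "image_size": list(self.image_size),
            "sample_radius": self.sample_radius,
            "holes": [{"id": hl.id, "row": hl.row, "col": hl.col,
                       "x": hl.x, "y": hl.y} for hl in self.holes],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BoardLayout":
        with open(path) as fh:
            doc = json.load(fh)
        holes = [Hole(h["id"], h["row"], h["col"], h["x"], h["y"])
                 for h in doc["holes"]]
        return cls(holes, tuple(doc["image_size"]), doc["sample_radius"])


@dataclass(frozen=True)
class HsvRange:
    h: tuple[tuple[float, float], ...]
    s: tuple[float, float]
    v: tuple[float, float]

    def contains(self, h: float, s: float, v: float) -> bool:
        return (any(lo <= h <= hi for lo, hi in self.h)
                and self.s[0] <= s <= self.s[1]
                and self.v[0] <= v <= self.v[1])


@dataclass(frozen=True)
class ColorThresholds:
    """HSV membership ranges for the three board colours.

    Defaults follow the half-degree hue convention (H in 0-180). The printed
    ranges overlap (a very dark red pixel satisfies both red and black);
    classification applies precedence black -> red -> white so darkness
    dominates.
    """

    white: HsvRange = HsvRange(((0, 180),), (0, 30), (220, 255))
    red: HsvRange = HsvRange(((0, 10), (160, 180)), (100, 255), (30, 255))
    black: HsvRange = HsvRange(((0, 180),), (0, 255), (0, 30))


DEFAULT_THRESHOLDS = ColorThresholds()


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB (0-255) to HSV with H in 0-180, S and V in 0-255.

    Vectorised over any leading shape; the last axis must be the 3 channels.
    Hue uses the standard piecewise formula and is 0 for achromatic pixels.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must hold (R, G, B)")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("channels must lie in [0, 255]")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = np.maximum.reduce([r, g, b])
    mn = np.minimum.reduce([r, g, b])
    delta = v - mn
    s = np.where(v > 0, 255.0 * delta / np.where(v > 0, v, 1.0), 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(delta > 0, delta, 1.0)
        h_deg = np.select(
            [delta == 0, v == r, v == g],
            [0.0,
             60.0 * ((g - b) / safe),
             60.0 * (2.0 + (b - r) / safe)],
            default=60.0 * (4.0 + (r - g) / safe),
        )
    h_deg = np.where(h_deg < 0, h_deg + 360.0, h_deg)
    return np.stack([h_deg / 2.0, s, v], axis=-1)


def classify_hole_color(hsv, thresholds: ColorThresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify one HSV pixel as white / red / black / unknown."""
    h, s, v = float(hsv[0]), float(hsv[1]), float(hsv[2])
    if thresholds.black.contains(h, s, v):
        return BLACK
    if thresholds.red.contains(h, s, v):
        return RED
    if thresholds.white.contains(h, s, v):
        return WHITE
    return UNKNOWN


_CODE_NAMES = (WHITE, RED, BLACK, UNKNOWN)


def _range_mask(h, s, v, rng: HsvRange) -> np.ndarray:
    hm = np.zeros(h.shape, dtype=bool)
    for lo, hi in rng.h:
        hm |= (h >= lo) & (h <= hi)
    return (hm & (s >= rng.s[0]) & (s <= rng.s[1])
            & (v >= rng.v[0]) & (v <= rng.v[1]))


def _classify_hsv_array(hsv: np.ndarray,
                        thresholds: ColorThresholds) -> np.ndarray:
    """Vectorised colour coding (0 white, 1 red, 2 black, 3 unknown)."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    codes = np.full(h.shape, 3, dtype=np.int8)
    codes[_range_mask(h, s, v, thresholds.white)] = 0
    codes[_range_mask(h, s, v, thresholds.red)] = 1
    codes[_range_mask(h, s, v, thresholds.black)] = 2  # precedence: darkness last
    return codes


def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    rr = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(rr, rr, indexing="ij")
    mask = dx ** 2 + dy ** 2 <= radius ** 2
    return dx[mask], dy[mask]


def observe_board(
    image: np.ndarray,
    layout: BoardLayout,
    thresholds: ColorThresholds = DEFAULT_THRESHOLDS,
) -> list[str]:
    """Majority colour class over the sampling disc at every hole centre.

    Ties in the majority vote give ``unknown`` (fail-safe: unknown never
    drives the event machine).
    """
    image = np.asarray(image)
    h_img, w_img = image.shape[:2]
    if (w_img, h_img) != tuple(layout.image_size):
        raise ValueError(
            f"image size {(w_img, h_img)} does not match layout {layout.image_size}")
    dx, dy = _disc_offsets(layout.sample_radius)
    xs = np.array([[round(hole.x + d) for d in dx] for hole in layout.holes])
    ys = np.array([[round(hole.y + d) for d in dy] for hole in layout.holes])
    if xs.min() < 0 or ys.min() < 0 or xs.max() >= w_img or ys.max() >= h_img:
        bad = next(h.id for h, x, y in zip(layout.holes, xs, ys)
                   if x.min() < 0 or y.min() < 0
                   or x.max() >= w_img or y.max() >= h_img)
        raise ValueError(f"sampling disc of hole {bad} leaves the image")
    hsv = rgb_to_hsv(image[ys, xs, :])        # (n_holes, n_px, 3)
    codes = _classify_hsv_array(hsv, thresholds)
    out = []
    for row in codes:
        votes = np.bincount(row, minlength=4)
        best = votes.max()
        winners = np.flatnonzero(votes == best)
        out.append(_CODE_NAMES[winners[0]] if winners.size == 1 else UNKNOWN)
    return out


@dataclass(frozen=True)
class DiscEvent:
    hole_id: int
    timestamp: float
    kind: str  # placed_correct | placed_upside_down | turned_correct | removed_incorrect
    phase: str


# (phase, colour before, colour observed) -> event kind
_TRANSITIONS = {
    (PLACING, WHITE, RED): "placed_correct",
    (PLACING, WHITE, BLACK): "placed_upside_down",
    (TURNING, RED, BLACK): "turned_correct",
    (TURNING, RED, WHITE): "removed_incorrect",
}


@dataclass
class BoardState:
    """Per-hole colour state plus the committed event log and counters."""

    layout: BoardLayout
    phase: str = PLACING
    colors: list[str] = field(default_factory=list)
    events: list[DiscEvent] = field(default_factory=list)
    debounce: int = 2
    _pending: dict = field(default_factory=dict)  # hole -> (colour, count, first_t)

    def __post_init__(self) -> None:
        if not self.colors:
            # placing starts on an empty (white) board; turning starts with
            # every disc in place red-side up
            fill = WHITE if self.phase == PLACING else RED
            self.colors = [fill] * self.layout.n_holes

    @property
    def placed(self) -> int:
        return sum(1 for c in self.colors if c != WHITE)

    @property
    def empty(self) -> int:
        return sum(1 for c in self.colors if c == WHITE)

    def start_phase(self, phase: str, reset_pending: bool = True) -> None:
        if phase not in (PLACING, TURNING):
            raise ValueError(f"unknown phase {phase!r}")
        self.phase = phase
        if reset_pending:
            self._pending.clear()


def advance_state(
    state: BoardState,
    observation: list[str],
    timestamp: float,
) -> list[DiscEvent]:
    """Feed one frame's colour observation into the event machine.

    A hole's transition is committed — and its event stamped with the FIRST
    frame time at which the new colour appeared — only after the new colour
    persists for ``state.debounce`` consecutive frames. Unknown observations
    and undefined transitions leave the hole untouched. Mutates ``state``
    and returns the newly committed events.
    """
    if len(observation) != state.layout.n_holes:
        raise ValueError("observation length must match the hole count")
    new_events: list[DiscEvent] = []
    for i, obs in enumerate(observation):
        if obs == UNKNOWN or obs == state.colors[i]:
            state._pending.pop(i, None)
            continue
        color, count, first_t = state._pending.get(i, (None, 0, timestamp))
        if color != obs:
            color, count, first_t = obs, 0, timestamp
        count += 1
        if count >= state.debounce:
            kind = _TRANSITIONS.get((state.phase, state.colors[i], obs))
            if kind is not None:
                ev = DiscEvent(i, first_t, kind, state.phase)
                state.events.append(ev)
                new_events.append(ev)
                state.colors[i] = obs
            state._pending.pop(i, None)
        else:
            state._pending[i] = (color, count, first_t)
    return new_events


def disc_timings(events: list[DiscEvent], phase_start: float):
    """Per-disc durations (gaps between consecutive events) and total time.

    The first disc is timed from ``phase_start``; the total is the last
    event's timestamp minus ``phase_start``.
    """
    times = [ev.timestamp for ev in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be time-ordered")
    if not events:
        return [], 0.0
    durations = list(np.diff([phase_start] + times))
    if any(d < 0 for d in durations):
        raise ValueError("event precedes phase start")
    return durations, times[-1] - phase_start


def events_to_csv(events: list[DiscEvent], path) -> None:
    pd.DataFrame(
        [{"t": ev.timestamp, "hole_id": ev.hole_id,
          "kind": ev.kind, "phase": ev.phase} for ev in events]
    ).to_csv(path, index=False)
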