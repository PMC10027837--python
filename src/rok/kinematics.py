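"""Frame-by-frame state evolution of a kinematogram layer.

Objects translate at constant per-object speed along their movement
direction.  The random class may re-draw its direction (and/or orientation)
every frame when the ``time_varying`` type is set.  Objects that leave the
aperture re-enter on the boundary locus opposite their motion — i.e. at a
uniformly random admissible entry point whose inward normal has a positive
component along the motion — which preserves class counts and coherent
motion energy.  The clock is headless: a fixed nominal fps drives the
kinematics (dt = 1/fps), while per-frame millisecond durations are
synthesized (optionally jittered) purely for the frame-rate bookkeeping of
the trial record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assignment import RANDOM, build_layer_assignment, resolve_object_count
from .core import (
    ApertureShape,
    ApertureSpec,
    LayerSpec,
    OOBState,
    RandomType,
    Region,
    SceneSpec,
    angle_to_unit_vector,
    to_pixels,
)
from .errors import ContractViolationError, InvalidParameterError

__all__ = [
    "FrameClock",
    "LayerState",
    "sample_speed",
    "init_positions",
    "refresh_random_direction",
    "reinsert",
    "fade_alpha",
    "step",
    "realize_layer",
    "simulate_scene",
    "SceneRun",
    "write_trajectory_log",
    "read_trajectory_log",
    "LOG_COLUMNS",
]

#: Fraction of the aperture half-extent over which edge fade ramps 1 -> 0.
FADE_BAND = 0.1

LOG_COLUMNS = [
    "frame_index",
    "time_ms",
    "object_id",
    "x",
    "y",
    "movement_direction",
    "orientation",
    "movement_class",
    "orientation_class",
    "alpha",
]


@dataclass
class FrameClock:
    """Headless frame clock with synthesized per-frame durations.

    ``jitter_ms`` adds seeded Gaussian noise to the recorded frame durations
    (emulating browser timing variance) without affecting the kinematics,
    which always advance by the nominal dt.
    """

    nominal_fps: float = 60.0
    jitter_ms: float = 0.0
    frame_index: int = 0
    frame_times_ms: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nominal_fps <= 0:
            raise InvalidParameterError("nominal_fps must be positive")

    @property
    def dt(self) -> float:
        """Nominal seconds per frame."""
        return 1.0 / self.nominal_fps

    @property
    def elapsed_s(self) -> float:
        """Nominal elapsed time at the current frame."""
        return self.frame_index * self.dt

    def tick(self, rng: Optional[np.random.Generator] = None) -> float:
        """Advance one frame; returns the recorded duration in ms."""
        duration = 1000.0 / self.nominal_fps
        if self.jitter_ms > 0:
            if rng is None:
                raise InvalidParameterError("jittered clock needs an rng")
            duration = max(1.0, duration + self.jitter_ms * rng.standard_normal())
        self.frame_times_ms.append(duration)
        self.frame_index += 1
        return duration


def sample_speed(base: float, randomisation: float, rng: np.random.Generator) -> float:
    """Draw a speed uniformly from [base*(1-r), base*(1+r)]; r=0 is exact."""
    if base < 0:
        raise InvalidParameterError("base speed must be >= 0")
    if not 0 <= randomisation <= 1:
        raise InvalidParameterError("speed randomisation must lie in [0, 1]")
    if randomisation == 0:
        return float(base)
    return float(rng.uniform(base * (1 - randomisation), base * (1 + randomisation)))


def init_positions(
    n: int, aperture: ApertureSpec | Region, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points over the aperture region, shape (n, 2); elliptic
    apertures use rejection sampling inside the inscribed ellipse."""
    region = aperture if isinstance(aperture, Region) else aperture.region()
    if n == 0:
        return np.empty((0, 2))
    if region.shape is ApertureShape.elliptic:
        pts = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = 2 * (n - filled) + 8
            x = rng.uniform(region.x0, region.x1, size=m)
            y = rng.uniform(region.y0, region.y1, size=m)
            a, b = region.width / 2.0, region.height / 2.0
            keep = ((x - region.cx) / a) ** 2 + ((y - region.cy) / b) ** 2 <= 1.0
            take = min(int(keep.sum()), n - filled)
            pts[filled : filled + take, 0] = x[keep][:take]
            pts[filled : filled + take, 1] = y[keep][:take]
            filled += take
        return pts
    x = rng.uniform(region.x0, region.x1, size=n)
    y = rng.uniform(region.y0, region.y1, size=n)
    return np.column_stack([x, y])


def refresh_random_direction(
    state: OOBState, random_type: RandomType, rng: np.random.Generator
) -> OOBState:
    """Re-draw a random-class object's movement direction.

    ``fixed_random`` leaves the state untouched; ``time_varying`` draws a
    fresh uniform direction (the per-frame rule used by :func:`step`).
    """
    if state.movement_class != RANDOM:
        raise ContractViolationError("refresh_random_direction applies to random-class objects")
    if RandomType(random_type) is RandomType.fixed_random:
        return state
    return replace(state, movement_direction=float(rng.uniform(0.0, 360.0)))


def _entry_point(
    direction_deg: float, region: Region, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniform admissible boundary point for a mover with the given heading:
    the inward normal at the entry point must have a positive component along
    the motion (the locus opposite the exit side)."""
    dx, dy = angle_to_unit_vector(direction_deg)
    if region.shape is ApertureShape.elliptic:
        a, b = region.width / 2.0, region.height / 2.0
        for _ in range(1000):
            t = rng.uniform(0.0, 2.0 * math.pi)
            nx, ny = -math.cos(t) / a, -math.sin(t) / b  # inward (unnormalized)
            if dx * nx + dy * ny > 1e-12:
                return region.cx + a * math.cos(t), region.cy + b * math.sin(t)
        raise ContractViolationError("no admissible entry point found")
    w, h = region.width, region.height
    perimeter = 2 * (w + h)
    # edges with their inward normals: left(+x), right(-x), top(+y), bottom(-y)
    for _ in range(1000):
        u = rng.uniform(0.0, perimeter)
        if u < h:  # left edge
            pt, normal = (region.x0, region.y0 + u), (1.0, 0.0)
        elif u < 2 * h:
            pt, normal = (region.x1, region.y0 + (u - h)), (-1.0, 0.0)
        elif u < 2 * h + w:
            pt, normal = (region.x0 + (u - 2 * h), region.y0), (0.0, 1.0)
        else:
            pt, normal = (region.x0 + (u - 2 * h - w), region.y1), (0.0, -1.0)
        if dx * normal[0] + dy * normal[1] > 1e-12:
            return pt
    raise ContractViolationError("no admissible entry point found")


def reinsert(state: OOBState, aperture: ApertureSpec | Region, rng: np.random.Generator) -> OOBState:
    """Re-enter an object that left the aperture; direction, class, speed and
    orientation are preserved, only the position changes."""
    region = aperture if isinstance(aperture, Region) else aperture.region()
    x, y = _entry_point(state.movement_direction, region, rng)
    return replace(state, x=x, y=y)


def fade_alpha(x: float, y: float, aperture: ApertureSpec | Region, band: float = FADE_BAND) -> float:
    """Edge-fade opacity: 1 in the inner region, ramping linearly to 0 on the
    boundary across the outer ``band`` fraction of the aperture extent."""
    region = aperture if isinstance(aperture, Region) else aperture.region()
    return float(min(1.0, region.edge_fraction(x, y) / band))


# ---------------------------------------------------------------------------
# vectorized layer state


@dataclass
class LayerState:
    """Struct-of-arrays state of every object in one layer."""

    x: np.ndarray
    y: np.ndarray
    movement_direction: np.ndarray
    orientation: np.ndarray
    speed: np.ndarray  # px/s
    movement_class: np.ndarray
    orientation_class: np.ndarray
    alpha: np.ndarray
    keyframe_index: np.ndarray
    colors: np.ndarray  # (n, 3) uint8

    @property
    def n(self) -> int:
        return self.x.size

    def objects(self) -> list[OOBState]:
        """Per-object scalar views (copies)."""
        return [
            OOBState(
                x=float(self.x[i]),
                y=float(self.y[i]),
                movement_direction=float(self.movement_direction[i]),
                orientation=float(self.orientation[i]),
                speed=float(self.speed[i]),
                movement_class=str(self.movement_class[i]),
                orientation_class=str(self.orientation_class[i]),
                alpha=float(self.alpha[i]),
                keyframe_index=int(self.keyframe_index[i]),
            )
            for i in range(self.n)
        ]


def _layer_colors(layer: LayerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    color = layer.oob_color
    if isinstance(color, list) and color and isinstance(color[0], (list, tuple)):
        palette = np.asarray(color, dtype=np.uint8)
        # multi-color layers: each object draws one palette color, seeded
        return palette[rng.integers(0, len(palette), size=n)]
    return np.tile(np.asarray(color, dtype=np.uint8), (n, 1))


def _update_alpha(state: LayerState, region: Region) -> None:
    if not region.fade_out:
        state.alpha[:] = 1.0
        return
    for i in range(state.n):
        state.alpha[i] = fade_alpha(state.x[i], state.y[i], region)


def realize_layer(
    aperture: ApertureSpec,
    layer: LayerSpec,
    rng: np.random.Generator,
    canvas_width: float = 800,
    canvas_height: float = 600,
) -> LayerState:
    """Instantiate a layer: counts, class assignment, positions, speeds."""
    region = aperture.region(canvas_width, canvas_height)
    n = resolve_object_count(layer.number_of_oobs, layer.density_unit_area, aperture)
    assignment = build_layer_assignment(layer, n, rng)
    pos = init_positions(n, region, rng)
    base = to_pixels(layer.movement_speed, region, layer.units)
    r = layer.movement_speed_randomisation
    speeds = (
        np.full(n, base)
        if r == 0
        else rng.uniform(base * (1 - r), base * (1 + r), size=n)
    )
    state = LayerState(
        x=pos[:, 0].copy(),
        y=pos[:, 1].copy(),
        movement_direction=np.asarray(assignment.movement_direction, dtype=float).copy(),
        orientation=np.asarray(assignment.orientation, dtype=float).copy(),
        speed=speeds,
        movement_class=np.asarray(assignment.movement_class, dtype=object),
        orientation_class=np.asarray(assignment.orientation_class, dtype=object),
        alpha=np.ones(n),
        keyframe_index=np.zeros(n, dtype=int),
        colors=_layer_colors(layer, n, rng),
    )
    _update_alpha(state, region)
    return state


def step(
    states: LayerState,
    layer: LayerSpec,
    aperture: ApertureSpec | Region,
    clock: FrameClock,
    rng: np.random.Generator,
) -> LayerState:
    """Advance one frame in place: refresh time-varying random features, move
    by speed*dt, reinsert leavers, recompute edge fade and keyframe index."""
    region = aperture if isinstance(aperture, Region) else aperture.region()
    dt = clock.dt

    if layer.random_movement_type is RandomType.time_varying:
        idx = np.flatnonzero(states.movement_class == RANDOM)
        states.movement_direction[idx] = rng.uniform(0.0, 360.0, size=idx.size)
    if layer.random_orientation_type is RandomType.time_varying:
        idx = np.flatnonzero(states.orientation_class == RANDOM)
        states.orientation[idx] = rng.uniform(0.0, 360.0, size=idx.size)

    rad = np.radians(states.movement_direction)
    states.x += states.speed * dt * np.cos(rad)
    states.y -= states.speed * dt * np.sin(rad)

    for i in range(states.n):
        if not region.contains(states.x[i], states.y[i]):
            states.x[i], states.y[i] = _entry_point(
                float(states.movement_direction[i]), region, rng
            )

    _update_alpha(states, region)
    if layer.stimulus_image_keyframes > 1:
        k = int(clock.elapsed_s // layer.stimulus_keyframe_time) % layer.stimulus_image_keyframes
        states.keyframe_index[:] = k
    return states


# ---------------------------------------------------------------------------
# scene simulation and trajectory logs


@dataclass
class SceneRun:
    """Result of a headless scene animation."""

    scene: SceneSpec
    states: list[LayerState]
    clock: FrameClock
    log: Optional[pd.DataFrame]
    layer_offsets: list[int]


def simulate_scene(
    scene: SceneSpec,
    n_frames: int,
    rng: np.random.Generator,
    fps: float = 60.0,
    jitter_ms: float = 0.0,
    record: bool = True,
    on_frame=None,
) -> SceneRun:
    """Realize and animate every layer of a scene for ``n_frames`` frames.

    Object ids in the trajectory log are global: layer i occupies the
    contiguous id block starting at the i-th layer offset.  ``on_frame``
    (states, clock) is invoked at every displayed frame, e.g. to rasterize.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    clock = FrameClock(nominal_fps=fps, jitter_ms=jitter_ms)
    states, offsets, regions, layers = [], [], [], []
    offset = 0
    for aperture, layer in scene.apertures:
        st = realize_layer(aperture, layer, rng, scene.canvas_width, scene.canvas_height)
        states.append(st)
        offsets.append(offset)
        offset += st.n
        regions.append(aperture.region(scene.canvas_width, scene.canvas_height))
        layers.append(layer)

    rows: list[pd.DataFrame] = []

    def snapshot() -> None:
        t_ms = clock.elapsed_s * 1000.0
        for st, off in zip(states, offsets):
            rows.append(
                pd.DataFrame(
                    {
                        "frame_index": clock.frame_index,
                        "time_ms": t_ms,
                        "object_id": np.arange(off, off + st.n),
                        "x": st.x.copy(),
                        "y": st.y.copy(),
                        "movement_direction": st.movement_direction.copy(),
                        "orientation": st.orientation.copy(),
                        "movement_class": st.movement_class.copy(),
                        "orientation_class": st.orientation_class.copy(),
                        "alpha": st.alpha.copy(),
                    }
                )
            )

    if record:
        snapshot()
    if on_frame is not None:
        on_frame(states, clock)
    for _ in range(n_frames - 1):
        clock.tick(rng)
        for st, layer, region in zip(states, layers, regions):
            step(st, layer, region, clock, rng)
        if record:
            snapshot()
        if on_frame is not None:
            on_frame(states, clock)

    log = pd.concat(rows, ignore_index=True)[LOG_COLUMNS] if record else None
    return SceneRun(scene=scene, states=states, clock=clock, log=log, layer_offsets=offsets)


def write_trajectory_log(log: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write a per-frame per-object log as CSV or JSON-lines."""
    if fmt == "csv":
        log.to_csv(path, index=False)
    elif fmt == "jsonl":
        log.to_json(path, orient="records", lines=True)
    else:
        raise InvalidParameterError(f"unknown log format {fmt!r}")


def read_trajectory_log(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".jsonl") or path.endswith(".json"):
        return pd.read_json(path, orient="records", lines=True)
    return pd.read_csv(path)
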