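"""Domain types, units, and coordinate conventions for the ROK engine.

A random-object kinematogram (ROK) is a field of "oriented objects" (oobs)
drawn inside an aperture; each object carries both a movement direction and
an orientation, so motion coherence and orientation coherence can be varied
independently and played against each other (stimulus congruency).

Coordinate conventions
----------------------
Canvas coordinates follow the browser canvas: origin at the top-left,
x rightward, y downward, all lengths in float pixels.  Angles are measured
counter-clockwise *on screen*, so 0 deg points right and 90 deg points
visually up (which is -y in canvas coordinates).  Aperture-relative
quantities (the default unit system) are percentages of the aperture width
and are converted to pixels once, at scene realization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import InvalidParameterError, UnknownParameterError

__all__ = [
    "Units",
    "ApertureShape",
    "StimulusType",
    "MirrorAxis",
    "RandomType",
    "CongruencyMode",
    "CongruencyScope",
    "MainTask",
    "LayerOrder",
    "ApertureSpec",
    "Region",
    "LayerSpec",
    "SceneSpec",
    "OOBState",
    "angle_to_unit_vector",
    "wrap_angle",
    "to_pixels",
    "point_in_aperture",
    "scene_from_config",
    "TABLE1_KEYS",
]


class Units(str, Enum):
    """Unit system for object size and speed (``null``/``px`` in configs)."""

    aperture_relative = "aperture_relative"  # percentage of aperture width
    pixels = "pixels"


class ApertureShape(str, Enum):
    rectangular = "rectangular"
    elliptic = "elliptic"


class StimulusType(str, Enum):
    triangle = "triangle"
    circle = "circle"
    square = "square"
    bird = "bird"
    image = "image"


class MirrorAxis(str, Enum):
    none = "none"
    x_axis = "x_axis"
    y_axis = "y_axis"


class RandomType(str, Enum):
    """Whether the random class re-draws its feature every frame."""

    fixed_random = "fixed_random"
    time_varying = "time_varying"


class CongruencyMode(str, Enum):
    off = "off"
    random_rest = "random_rest"  # out-of-scope objects: secondary feature random
    yoked_rest = "yoked_rest"  # out-of-scope objects: secondary copies main feature


class CongruencyScope(str, Enum):
    """Which objects the congruency split is applied over.

    ``coherent_only`` is the plugin's documented behavior (congruency applies
    only to coherent objects of the main task); ``all_objects`` reproduces the
    experiments' arithmetic, where e.g. a 75% congruency level means 450 of
    all 600 objects carry the target direction on their secondary feature.
    """

    coherent_only = "coherent_only"
    all_objects = "all_objects"


class MainTask(str, Enum):
    movement = "movement"
    orientation = "orientation"


class LayerOrder(str, Enum):
    as_given = "as_given"
    randomized = "randomized"


# ---------------------------------------------------------------------------
# angles and units

def wrap_angle(theta: float) -> float:
    """Normalize an angle in degrees to [0, 360)."""
    return float(theta) % 360.0


def angle_to_unit_vector(theta: float) -> tuple[float, float]:
    """Unit displacement in canvas coordinates for a screen angle in degrees.

    0 deg -> (+1, 0) (rightward); 90 deg -> (0, -1) (visually up, since the
    canvas y axis grows downward).  Periodic with period 360.
    """
    rad = math.radians(theta)
    return (math.cos(rad), -math.sin(rad))


# ---------------------------------------------------------------------------
# aperture geometry


class ApertureSpec(BaseModel):
    """Geometry of one stimulus aperture.

    ``width``/``height`` are in pixels; ``center_x``/``center_y`` place the
    aperture midpoint as a percentage of the canvas width/height (50 = center).
    """

    model_config = ConfigDict(extra="forbid")

    width: float = Field(gt=0)
    height: float = Field(gt=0)
    center_x: float = Field(default=50.0, ge=0, le=100)
    center_y: float = Field(default=50.0, ge=0, le=100)
    shape: ApertureShape = ApertureShape.rectangular
    fade_out: bool = False

    def region(self, canvas_width: float = 800, canvas_height: float = 600) -> "Region":
        cx = self.center_x / 100.0 * canvas_width
        cy = self.center_y / 100.0 * canvas_height
        return Region(
            x0=cx - self.width / 2.0,
            y0=cy - self.height / 2.0,
            x1=cx + self.width / 2.0,
            y1=cy + self.height / 2.0,
            shape=self.shape,
            fade_out=self.fade_out,
        )


@dataclass(frozen=True)
class Region:
    """An aperture resolved to absolute canvas pixels."""

    x0: float
    y0: float
    x1: float
    y1: float
    shape: ApertureShape = ApertureShape.rectangular
    fade_out: bool = False

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def cx(self) -> float:
        return (self.x0 + self.x1) / 2.0

    @property
    def cy(self) -> float:
        return (self.y0 + self.y1) / 2.0

    def contains(self, x: float, y: float) -> bool:
        if self.shape is ApertureShape.elliptic:
            a, b = self.width / 2.0, self.height / 2.0
            return ((x - self.cx) / a) ** 2 + ((y - self.cy) / b) ** 2 <= 1.0 + 1e-12
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def edge_fraction(self, x: float, y: float) -> float:
        """Normalized distance to the boundary: 0 on the boundary, 1 at the
        center (rectangles: per-axis half-extent scaling; ellipses: radial)."""
        if self.shape is ApertureShape.elliptic:
            a, b = self.width / 2.0, self.height / 2.0
            r = math.hypot((x - self.cx) / a, (y - self.cy) / b)
            return max(0.0, 1.0 - r)
        tx = min(x - self.x0, self.x1 - x) / (self.width / 2.0)
        ty = min(y - self.y0, self.y1 - y) / (self.height / 2.0)
        return max(0.0, min(tx, ty))


def to_pixels(value: float, aperture: ApertureSpec | Region, units: Units = Units.aperture_relative) -> float:
    """Convert a size/speed quantity to pixels.

    ``aperture_relative`` values are percentages of the aperture width
    (1% of an 800 px aperture -> 8 px); ``pixels`` is the identity.
    """
    if value < 0:
        raise InvalidParameterError(f"quantity must be non-negative, got {value}")
    if Units(units) is Units.pixels:
        return float(value)
    return value / 100.0 * aperture.width


def point_in_aperture(
    x: float,
    y: float,
    aperture: ApertureSpec | Region,
    canvas_width: float = 800,
    canvas_height: float = 600,
) -> bool:
    """Whether a canvas point lies inside the aperture region (boundary
    inclusive).  Elliptic apertures use the ellipse inscribed in the box."""
    region = aperture if isinstance(aperture, Region) else aperture.region(canvas_width, canvas_height)
    return region.contains(x, y)


# ---------------------------------------------------------------------------
# layer and scene specifications

RGB = tuple[int, int, int]


class LayerSpec(BaseModel):
    """Per-layer stimulus parameters of one kinematogram layer.

    Coherence parameters are proportions in [0, 1]; for each feature the
    coherent and opposite proportions may sum to at most 1, the remainder
    being the random class.  Sizes and speeds are interpreted through
    ``units`` (default: percent of aperture width, speed per second).
    """

    model_config = ConfigDict(extra="forbid")

    number_of_oobs: int = Field(default=300, ge=0)
    density_unit_area: Optional[float] = None
    coherent_movement_direction: float = 0.0
    coherent_orientation: float = 0.0
    coherence_movement: float = Field(default=0.5, ge=0, le=1)
    coherence_movement_opposite: float = Field(default=0.0, ge=0, le=1)
    coherence_orientation: float = Field(default=0.5, ge=0, le=1)
    coherence_orientation_opposite: float = Field(default=0.0, ge=0, le=1)
    movement_speed: float = Field(default=10.0, ge=0)
    movement_speed_randomisation: float = Field(default=0.0, ge=0, le=1)
    random_movement_type: RandomType = RandomType.fixed_random
    random_orientation_type: RandomType = RandomType.fixed_random
    oob_size: float = Field(default=2.0, gt=0)
    oob_color: Union[RGB, list[RGB]] = (255, 255, 255)
    stimulus_type: StimulusType = StimulusType.triangle
    stimulus_images: list[str] = Field(default_factory=list)
    stimulus_image_keyframes: int = Field(default=1, ge=1)
    stimulus_keyframe_time: float = Field(default=0.1, gt=0)
    stimulus_mirror: MirrorAxis = MirrorAxis.none
    experiment_congruency_mode: CongruencyMode = CongruencyMode.off
    experiment_main_task: MainTask = MainTask.movement
    congruency_scope: CongruencyScope = CongruencyScope.coherent_only
    units: Units = Units.aperture_relative

    @field_validator("coherent_movement_direction", "coherent_orientation")
    @classmethod
    def _wrap(cls, v: float) -> float:
        return wrap_angle(v)

    @field_validator("density_unit_area")
    @classmethod
    def _density(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("density_unit_area must be positive when given")
        return v

    @model_validator(mode="after")
    def _coherence_budget(self) -> "LayerSpec":
        if self.coherence_movement + self.coherence_movement_opposite > 1 + 1e-9:
            raise ValueError("coherence_movement + coherence_movement_opposite exceeds 1")
        if self.coherence_orientation + self.coherence_orientation_opposite > 1 + 1e-9:
            raise ValueError("coherence_orientation + coherence_orientation_opposite exceeds 1")
        return self

    def congruency_level(self) -> float:
        """In congruency mode the coherence parameter of the non-task feature
        doubles as the congruency level (fraction of in-scope objects whose
        secondary feature carries the target direction)."""
        if self.experiment_main_task is MainTask.movement:
            return self.coherence_orientation
        return self.coherence_movement


class SceneSpec(BaseModel):
    """A full stimulus scene: an ordered stack of (aperture, layer) pairs on
    a canvas with a plain color or image background."""

    model_config = ConfigDict(extra="forbid")

    apertures: list[tuple[ApertureSpec, LayerSpec]]
    canvas_width: int = Field(default=800, gt=0)
    canvas_height: int = Field(default=600, gt=0)
    background_color: RGB = (0, 0, 0)
    background_image: Optional[str] = None
    layer_order: LayerOrder = LayerOrder.as_given

    @model_validator(mode="after")
    def _nonempty(self) -> "SceneSpec":
        if not self.apertures:
            raise ValueError("a scene needs at least one (aperture, layer) pair")
        return self


@dataclass
class OOBState:
    """One oriented object's realized state at a frame."""

    x: float
    y: float
    movement_direction: float
    orientation: float
    speed: float  # px/s
    movement_class: str  # coherent | opposite | random
    orientation_class: str
    alpha: float = 1.0
    keyframe_index: int = 0


# ---------------------------------------------------------------------------
# configuration documents (Table-1 style flat JSON)

_SHAPE_CODES = {0: ApertureShape.rectangular, 1: ApertureShape.elliptic}
_STIM_CODES = {
    0: StimulusType.triangle,
    1: StimulusType.circle,
    2: StimulusType.square,
    3: StimulusType.bird,
    4: StimulusType.image,
}
_MIRROR_CODES = {0: MirrorAxis.none, 1: MirrorAxis.x_axis, 2: MirrorAxis.y_axis}
_RANDOM_CODES = {0: RandomType.fixed_random, 1: RandomType.time_varying}
_CONGRUENCY_CODES = {0: CongruencyMode.off, 1: CongruencyMode.random_rest, 2: CongruencyMode.yoked_rest}
_TASK_CODES = {0: MainTask.movement, 1: MainTask.orientation}

#: Keys accepted in a flat scene/trial configuration document.  These are the
#: plugin's parameter names plus canvas_width/canvas_height (recorded per
#: trial, needed here to size the raster).
TABLE1_KEYS = frozenset(
    {
        "choices",
        "correct_choice",
        "trial_duration",
        "response_ends_trial",
        "number_of_apertures",
        "density_unit_area",
        "number_of_oobs",
        "coherence",
        "opposite_coherence",
        "coherent_movement_direction",
        "coherent_orientation",
        "coherence_movement",
        "coherence_orientation",
        "coherence_movement_opposite",
        "coherence_orientation_opposite",
        "movement_speed",
        "movement_speed_randomisation",
        "random_movement_type",
        "random_orientation_type",
        "oob_size",
        "oob_color",
        "background_color",
        "background_image",
        "aperture_width",
        "aperture_height",
        "aperture_position_left",
        "aperture_position_top",
        "aperture_shape",
        "stimulus_type",
        "stimulus_image",
        "stimulus_image_keyframes",
        "stimulus_keyframe_time",
        "stimulus_mirror",
        "prompt",
        "fade_out",
        "experiment_congruency_mode",
        "experiment_main_task",
        "units",
        "canvas_width",
        "canvas_height",
    }
)

_TRIAL_ONLY_KEYS = {"choices", "correct_choice", "trial_duration", "response_ends_trial", "prompt"}


def _coerce_enum(value, enum_cls, codes):
    if isinstance(value, enum_cls):
        return value
    if isinstance(value, bool):
        raise InvalidParameterError(f"cannot interpret {value!r} as {enum_cls.__name__}")
    if isinstance(value, int):
        try:
            return codes[value]
        except KeyError:
            raise InvalidParameterError(f"unknown {enum_cls.__name__} code {value}") from None
    try:
        return enum_cls(value)
    except ValueError:
        raise InvalidParameterError(f"unknown {enum_cls.__name__} value {value!r}") from None


def _coerce_color(value):
    if isinstance(value, str):
        from PIL import ImageColor

        return tuple(ImageColor.getrgb(value)[:3])
    if isinstance(value, Sequence) and len(value) == 3:
        return tuple(int(c) for c in value)
    if (
        isinstance(value, Sequence)
        and value
        and all(isinstance(v, (str, list, tuple)) for v in value)
    ):
        return [_coerce_color(v) for v in value]
    raise InvalidParameterError(f"cannot interpret color {value!r}")


def _per_aperture(value, index: int, n: int):
    """Resolve a possibly per-aperture config value: with several apertures a
    list of length n is indexed, a scalar broadcasts."""
    if n > 1 and isinstance(value, list) and len(value) == n:
        return value[index]
    return value


def scene_from_config(config: dict) -> SceneSpec:
    """Build a :class:`SceneSpec` from a flat configuration document.

    Keys are the plugin parameter names; with ``number_of_apertures`` > 1,
    other parameters may be arrays with one entry per aperture.  Unknown keys
    raise :class:`UnknownParameterError`; trial-level keys (choices, timing)
    are tolerated here and consumed by the trial engine.
    """
    unknown = set(config) - TABLE1_KEYS
    if unknown:
        raise UnknownParameterError(f"unknown configuration keys: {sorted(unknown)}")

    n_ap = int(config.get("number_of_apertures", 1))
    if n_ap < 1:
        raise InvalidParameterError("number_of_apertures must be >= 1")

    pairs = []
    for i in range(n_ap):
        def get(key, default=None):
            if key not in config:
                return default
            return _per_aperture(config[key], i, n_ap)

        units = get("units")
        units = Units.pixels if units in ("px", "pixels") else Units.aperture_relative

        aperture = ApertureSpec(
            width=get("aperture_width", 600),
            height=get("aperture_height", 400),
            center_x=get("aperture_position_left", 50),
            center_y=get("aperture_position_top", 50),
            shape=_coerce_enum(get("aperture_shape", 0), ApertureShape, _SHAPE_CODES),
            fade_out=bool(get("fade_out", False)),
        )

        layer_kwargs: dict = {
            "number_of_oobs": get("number_of_oobs", 300),
            "density_unit_area": get("density_unit_area"),
            "coherent_movement_direction": get("coherent_movement_direction", 0),
            "coherent_orientation": get("coherent_orientation", 0),
            "movement_speed": get("movement_speed", 10),
            "movement_speed_randomisation": get("movement_speed_randomisation", 0),
            "random_movement_type": _coerce_enum(
                get("random_movement_type", 0), RandomType, _RANDOM_CODES
            ),
            "random_orientation_type": _coerce_enum(
                get("random_orientation_type", 0), RandomType, _RANDOM_CODES
            ),
            "oob_size": get("oob_size", 2),
            "stimulus_type": _coerce_enum(get("stimulus_type", 0), StimulusType, _STIM_CODES),
            "stimulus_image_keyframes": get("stimulus_image_keyframes", 1),
            "stimulus_keyframe_time": get("stimulus_keyframe_time", 0.1),
            "stimulus_mirror": _coerce_enum(get("stimulus_mirror", 0), MirrorAxis, _MIRROR_CODES),
            "experiment_congruency_mode": _coerce_enum(
                get("experiment_congruency_mode", 0), CongruencyMode, _CONGRUENCY_CODES
            ),
            "experiment_main_task": _coerce_enum(
                get("experiment_main_task", 0), MainTask, _TASK_CODES
            ),
            "units": units,
        }
        # generic coherence applies to both features; feature-specific keys win
        coh = get("coherence")
        opp = get("opposite_coherence")
        for feature in ("movement", "orientation"):
            value = get(f"coherence_{feature}", coh if coh is not None else 0.5)
            value_opp = get(f"coherence_{feature}_opposite", opp if opp is not None else 0.0)
            layer_kwargs[f"coherence_{feature}"] = value
            layer_kwargs[f"coherence_{feature}_opposite"] = value_opp
        if "oob_color" in config:
            layer_kwargs["oob_color"] = _coerce_color(get("oob_color"))
        if "stimulus_image" in config:
            img = get("stimulus_image")
            layer_kwargs["stimulus_images"] = [img] if isinstance(img, str) else list(img)

        pairs.append((aperture, LayerSpec(**layer_kwargs)))

    scene_kwargs: dict = {"apertures": pairs}
    if "canvas_width" in config:
        scene_kwargs["canvas_width"] = config["canvas_width"]
    if "canvas_height" in config:
        scene_kwargs["canvas_height"] = config["canvas_height"]
    if "background_color" in config:
        scene_kwargs["background_color"] = _coerce_color(config["background_color"])
    if "background_image" in config:
        scene_kwargs["background_image"] = config["background_image"]
    return SceneSpec(**scene_kwargs)
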