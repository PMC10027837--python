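"""Partition objects into movement/orientation classes.

Coherence parameters are nominal proportions; displayed objects are integers,
so proportions are apportioned to exact counts with the largest-remainder
method (quotas ``n*p``, floor, then distribute the remaining units to the
largest fractional remainders).  Ties are broken in a fixed priority order —
coherent > opposite > random, and congruent > incongruent — which makes every
partition reproducible and keeps realized fractions within 1/n of nominal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ApertureShape,
    ApertureSpec,
    CongruencyMode,
    CongruencyScope,
    LayerSpec,
    MainTask,
    Region,
    wrap_angle,
)
from .errors import ContractViolationError, InvalidParameterError

__all__ = [
    "COHERENT",
    "OPPOSITE",
    "RANDOM",
    "ClassCounts",
    "FeatureAssignment",
    "largest_remainder",
    "resolve_object_count",
    "partition_counts",
    "assign_movement",
    "assign_orientation",
    "apply_congruency",
    "build_layer_assignment",
    "assignment_to_frame",
]

COHERENT = "coherent"
OPPOSITE = "opposite"
RANDOM = "random"


def largest_remainder(n: int, proportions: list[float]) -> list[int]:
    """Apportion ``n`` units to ``proportions`` (summing to ~1); ties on the
    fractional remainder go to the earlier entry."""
    quotas = [n * p for p in proportions]
    counts = [math.floor(q) for q in quotas]
    remaining = n - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remaining]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class ClassCounts:
    """Integer partition of N objects into coherent/opposite/random."""

    n_coherent: int
    n_opposite: int
    n_random: int

    @property
    def total(self) -> int:
        return self.n_coherent + self.n_opposite + self.n_random


def resolve_object_count(
    number_of_oobs: int,
    density_unit_area: Optional[float],
    aperture: ApertureSpec | Region,
) -> int:
    """Object count for a layer; with a density unit area set, the count is
    per that area and scales with the aperture area (rounded half away from
    zero)."""
    if number_of_oobs < 0:
        raise InvalidParameterError("number_of_oobs must be >= 0")
    if density_unit_area is None:
        return int(number_of_oobs)
    if density_unit_area <= 0:
        raise InvalidParameterError("density_unit_area must be positive")
    area = aperture.width * aperture.height
    if aperture.shape is ApertureShape.elliptic:
        area = math.pi * (aperture.width / 2.0) * (aperture.height / 2.0)
    return int(math.floor(number_of_oobs * area / density_unit_area + 0.5))


def partition_counts(n: int, p_coherent: float, p_opposite: float) -> ClassCounts:
    """Split ``n`` objects into coherent/opposite/random counts by
    largest-remainder apportionment (ties: coherent > opposite > random)."""
    if not (0 <= p_coherent <= 1 and 0 <= p_opposite <= 1):
        raise InvalidParameterError("proportions must lie in [0, 1]")
    if p_coherent + p_opposite > 1 + 1e-9:
        raise InvalidParameterError("coherent + opposite proportions exceed 1")
    p_random = max(0.0, 1.0 - p_coherent - p_opposite)
    c, o, r = largest_remainder(n, [p_coherent, p_opposite, p_random])
    return ClassCounts(c, o, r)


@dataclass
class FeatureAssignment:
    """Per-object class labels and feature angles (degrees).

    Either feature may be absent (None) when only one has been assigned yet.
    """

    n: int
    movement_class: Optional[np.ndarray] = None
    movement_direction: Optional[np.ndarray] = None
    orientation_class: Optional[np.ndarray] = None
    orientation: Optional[np.ndarray] = None


def _assign_feature(
    n: int, p_coherent: float, p_opposite: float, coherent_angle: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    counts = partition_counts(n, p_coherent, p_opposite)
    classes = np.array(
        [COHERENT] * counts.n_coherent + [OPPOSITE] * counts.n_opposite + [RANDOM] * counts.n_random,
        dtype=object,
    )
    rng.shuffle(classes)  # class membership is a seeded permutation of indices
    angles = np.full(n, wrap_angle(coherent_angle))
    angles[classes == OPPOSITE] = wrap_angle(coherent_angle + 180.0)
    n_random = int(np.sum(classes == RANDOM))
    angles[classes == RANDOM] = rng.uniform(0.0, 360.0, size=n_random)
    return classes, angles


def assign_movement(
    n: int, layer: LayerSpec, rng: np.random.Generator, into: Optional[FeatureAssignment] = None
) -> FeatureAssignment:
    """Assign movement classes and directions for ``n`` objects."""
    a = into if into is not None else FeatureAssignment(n=n)
    a.movement_class, a.movement_direction = _assign_feature(
        n,
        layer.coherence_movement,
        layer.coherence_movement_opposite,
        layer.coherent_movement_direction,
        rng,
    )
    return a


def assign_orientation(
    n: int, layer: LayerSpec, rng: np.random.Generator, into: Optional[FeatureAssignment] = None
) -> FeatureAssignment:
    """Assign orientation classes and angles for ``n`` objects."""
    a = into if into is not None else FeatureAssignment(n=n)
    a.orientation_class, a.orientation = _assign_feature(
        n,
        layer.coherence_orientation,
        layer.coherence_orientation_opposite,
        layer.coherent_orientation,
        rng,
    )
    return a


def _classify_angle(angle: float, target: float) -> str:
    d = wrap_angle(angle - target)
    if min(d, 360 - d) < 1e-9:
        return COHERENT
    if abs(d - 180.0) < 1e-9:
        return OPPOSITE
    return RANDOM


def apply_congruency(
    assignment: FeatureAssignment,
    mode: CongruencyMode,
    main_task: MainTask,
    congruency_level: float,
    scope: CongruencyScope,
    rng: np.random.Generator,
    target_direction: Optional[float] = None,
) -> FeatureAssignment:
    """Set the secondary (non-task) feature from the congruency level.

    Over the scoped object set (coherent main-task objects, or all objects) a
    largest-remainder fraction ``congruency_level`` receives the coherent
    main-task (target) direction on its secondary feature and the rest its
    180-degree opposite — this reproduces the experiments' arithmetic where a
    75% level puts the target direction on 450 of 600 objects.  Out-of-scope
    objects get a uniform random secondary feature (``random_rest``) or copy
    their own main-task direction (``yoked_rest``).
    """
    if mode is CongruencyMode.off:
        raise ContractViolationError("apply_congruency requires a congruency mode")
    if not 0 <= congruency_level <= 1:
        raise InvalidParameterError("congruency_level must lie in [0, 1]")

    if main_task is MainTask.movement:
        main_class, main_angle = assignment.movement_class, assignment.movement_direction
    else:
        main_class, main_angle = assignment.orientation_class, assignment.orientation
    if main_class is None:
        raise ContractViolationError("main-task feature must be assigned before congruency")

    n = assignment.n
    if target_direction is None:
        coherent_idx = np.flatnonzero(main_class == COHERENT)
        if coherent_idx.size == 0:
            raise InvalidParameterError(
                "target_direction required when the main task has no coherent objects"
            )
        target_direction = float(main_angle[coherent_idx[0]])
    target_direction = wrap_angle(target_direction)

    if scope is CongruencyScope.all_objects:
        in_scope = np.arange(n)
    else:
        in_scope = np.flatnonzero(main_class == COHERENT)

    sec_angle = np.zeros(n)
    sec_class = np.empty(n, dtype=object)

    n_congruent, _ = largest_remainder(in_scope.size, [congruency_level, 1 - congruency_level])
    scoped = in_scope.copy()
    rng.shuffle(scoped)
    congruent, incongruent = scoped[:n_congruent], scoped[n_congruent:]
    sec_angle[congruent] = target_direction
    sec_class[congruent] = COHERENT
    sec_angle[incongruent] = wrap_angle(target_direction + 180.0)
    sec_class[incongruent] = OPPOSITE

    mask = np.ones(n, dtype=bool)
    mask[in_scope] = False
    rest = np.flatnonzero(mask)
    if rest.size:
        if mode is CongruencyMode.random_rest:
            sec_angle[rest] = rng.uniform(0.0, 360.0, size=rest.size)
            sec_class[rest] = RANDOM
        else:  # yoked_rest: secondary feature copies the object's main feature
            sec_angle[rest] = main_angle[rest]
            for i in rest:
                sec_class[i] = _classify_angle(main_angle[i], target_direction)

    if main_task is MainTask.movement:
        assignment.orientation, assignment.orientation_class = sec_angle, sec_class
    else:
        assignment.movement_direction, assignment.movement_class = sec_angle, sec_class
    return assignment


def build_layer_assignment(
    layer: LayerSpec,
    n: int,
    rng: np.random.Generator,
    target_direction: Optional[float] = None,
) -> FeatureAssignment:
    """Full per-object assignment for one layer.

    With congruency mode off, movement and orientation are assigned
    independently from their own coherence parameters; in congruency mode the
    main-task feature is assigned from its coherence parameters and the
    secondary feature from the layer's congruency level.
    """
    a = FeatureAssignment(n=n)
    if layer.experiment_congruency_mode is CongruencyMode.off:
        assign_movement(n, layer, rng, into=a)
        assign_orientation(n, layer, rng, into=a)
        return a
    if layer.experiment_main_task is MainTask.movement:
        assign_movement(n, layer, rng, into=a)
        if target_direction is None:
            target_direction = layer.coherent_movement_direction
    else:
        assign_orientation(n, layer, rng, into=a)
        if target_direction is None:
            target_direction = layer.coherent_orientation
    apply_congruency(
        a,
        layer.experiment_congruency_mode,
        layer.experiment_main_task,
        layer.congruency_level(),
        layer.congruency_scope,
        rng,
        target_direction=target_direction,
    )
    return a


def assignment_to_frame(assignment: FeatureAssignment) -> pd.DataFrame:
    """One row per object: index, classes, and feature angles."""
    return pd.DataFrame(
        {
            "index": np.arange(assignment.n),
            "movement_class": assignment.movement_class,
            "movement_direction": assignment.movement_direction,
            "orientation_class": assignment.orientation_class,
            "orientation": assignment.orientation,
        }
    )
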