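"""Factorial experiment builders, a synthetic observer, and trial filters.

Both experiments share one structure: 16 training trials, then ten 72-trial
blocks.  Blocks 2-5 and 7-10 cross three coherence levels (90/75/60%) with
four congruency levels (100/75/25/0%), six repetitions per cell, in seeded
shuffled order; the task (motion vs orientation judgment) switches between
the two halves, with task order and key mapping counterbalanced across
simulated participants.  Blocks 1 and 6 fix coherence at 65% and congruency
at 50% and add a 70-object distractor layer (squares, points, or randomly
oriented triangles in turquoise/yellow) on a random 10% of trials.  Displays
are two-directional: the opposite-coherence proportion is the complement of
the coherence, so every object moves either up or down.

Experiment 1 uses 600 purple isosceles triangles on black; experiment 2 the
same design with leaf sprites on a naturalistic background (both assets are
procedural stand-ins).  The synthetic observer is a logistic/log-normal
agent for end-to-end testing — its parameters are illustrative defaults
shaped like the experiments' qualitative psychometrics, not fitted claims.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    ApertureShape,
    ApertureSpec,
    CongruencyMode,
    CongruencyScope,
    LayerSpec,
    MainTask,
    SceneSpec,
    StimulusType,
)
from .errors import InvalidParameterError
from .trial_engine import ResponseEvent, TrialResult, TrialSpec, results_to_frame, run_trial

__all__ = [
    "COHERENCE_LEVELS",
    "CONGRUENCY_LEVELS",
    "BlockSpec",
    "DesignSpec",
    "SyntheticObserverParams",
    "build_experiment",
    "build_distractor_layer",
    "synthetic_observer",
    "make_responder",
    "simulate_experiment",
    "filter_trials",
]

COHERENCE_LEVELS = (0.90, 0.75, 0.60)
CONGRUENCY_LEVELS = (1.00, 0.75, 0.25, 0.00)
REPETITIONS = 6
N_BLOCKS = 10
TRIALS_PER_BLOCK = 72
TRAINING_TRIALS = 16
DISTRACTOR_BLOCKS = (0, 5)  # blocks 1 and 6, zero-based
DISTRACTOR_COHERENCE = 0.65
DISTRACTOR_CONGRUENCY = 0.50
DISTRACTOR_PROBABILITY = 0.10
N_OBJECTS = 600
N_DISTRACTOR_OBJECTS = 70
OBJECT_SIZE = 1.0  # % of aperture width
MOVEMENT_SPEED = 3.0  # % of aperture width per second
UP, DOWN = 90.0, 270.0
PURPLE = (128, 0, 128)
TURQUOISE = (64, 224, 208)
YELLOW = (255, 255, 0)

#: Default fixture geometry (the experiments never print aperture sizes).
APERTURE_WIDTH = 600.0
APERTURE_HEIGHT = 600.0
CANVAS = (800, 600)


class BlockSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    task: MainTask
    block_type: Literal["factorial", "distractor"]
    trials: list[TrialSpec]


class DesignSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    experiment: Literal["exp1", "exp2"]
    task_order: Literal["motion_first", "orientation_first"]
    key_mapping: Literal["up_F", "up_J"]
    training: list[TrialSpec]
    blocks: list[BlockSpec]

    @property
    def training_trials(self) -> int:
        return len(self.training)


def _target_layer(
    experiment: str, task: MainTask, coherence: float, congruency: float, direction: float
) -> LayerSpec:
    kwargs: dict = {
        "number_of_oobs": N_OBJECTS,
        "coherent_movement_direction": direction,
        "coherent_orientation": direction,
        "movement_speed": MOVEMENT_SPEED,
        "oob_size": OBJECT_SIZE,
        "experiment_congruency_mode": CongruencyMode.random_rest,
        "experiment_main_task": task,
        "congruency_scope": CongruencyScope.all_objects,
    }
    if task is MainTask.movement:
        kwargs.update(
            coherence_movement=coherence,
            coherence_movement_opposite=1 - coherence,
            coherence_orientation=congruency,  # doubles as the congruency level
            coherence_orientation_opposite=0.0,
        )
    else:
        kwargs.update(
            coherence_orientation=coherence,
            coherence_orientation_opposite=1 - coherence,
            coherence_movement=congruency,
            coherence_movement_opposite=0.0,
        )
    if experiment == "exp1":
        kwargs.update(stimulus_type=StimulusType.triangle, oob_color=PURPLE)
    else:
        kwargs.update(
            stimulus_type=StimulusType.image,
            stimulus_images=["builtin:leaf"],
        )
    return LayerSpec(**kwargs)


def _aperture() -> ApertureSpec:
    return ApertureSpec(
        width=APERTURE_WIDTH,
        height=APERTURE_HEIGHT,
        shape=ApertureShape.rectangular,
    )


def build_distractor_layer(rng: np.random.Generator) -> tuple[ApertureSpec, LayerSpec]:
    """The 70-object distractor layer: shape drawn per trial from squares,
    points, or randomly oriented triangles; each object turquoise or yellow
    with equal probability; fully random motion at the target layer's size
    and speed."""
    shapes = [StimulusType.square, StimulusType.circle, StimulusType.triangle]
    shape = shapes[int(rng.integers(len(shapes)))]
    layer = LayerSpec(
        number_of_oobs=N_DISTRACTOR_OBJECTS,
        coherence_movement=0.0,
        coherence_movement_opposite=0.0,
        coherence_orientation=0.0,
        coherence_orientation_opposite=0.0,
        movement_speed=MOVEMENT_SPEED,
        oob_size=OBJECT_SIZE,
        oob_color=[TURQUOISE, YELLOW],
        stimulus_type=StimulusType(shape),
    )
    return _aperture(), layer


def _make_trial(
    experiment: str,
    task: MainTask,
    coherence: float,
    congruency: float,
    key_mapping: str,
    rng: np.random.Generator,
    block_index: Optional[int],
    block_type: str,
    with_distractor: bool = False,
    context: str = "experimental",
) -> TrialSpec:
    direction = UP if rng.random() < 0.5 else DOWN
    up_key, down_key = ("F", "J") if key_mapping == "up_F" else ("J", "F")
    correct = up_key if direction == UP else down_key
    apertures = [(_aperture(), _target_layer(experiment, task, coherence, congruency, direction))]
    if with_distractor:
        apertures.append(build_distractor_layer(rng))
    scene_kwargs: dict = {
        "apertures": apertures,
        "canvas_width": CANVAS[0],
        "canvas_height": CANVAS[1],
        "background_color": (0, 0, 0),
    }
    if experiment == "exp2":
        scene_kwargs["background_image"] = "builtin:nature"
    return TrialSpec(
        scene=SceneSpec(**scene_kwargs),
        choices=["F", "J"],
        correct_choice=[correct],
        trial_duration=2000.0,
        response_ends_trial=True,
        fixation_duration=500.0,
        context=context,
        meta={
            "experiment": experiment,
            "block": block_index,
            "block_type": block_type,
            "task": task.value,
            "coherence": coherence,
            "congruency": congruency,
            "direction": direction,
            "distractor": with_distractor,
        },
    )


def build_experiment(
    exp: Literal["exp1", "exp2"],
    task_order: Literal["motion_first", "orientation_first"] = "motion_first",
    key_mapping: Literal["up_F", "up_J"] = "up_F",
    rng: Optional[np.random.Generator] = None,
    distractor_quota: bool = False,
) -> DesignSpec:
    """Build the full ten-block design of one experiment.

    ``distractor_quota`` switches the distractor blocks from a per-trial
    Bernoulli(0.10) draw (the default) to a fixed quota of
    round(0.10 x 72) = 7 distractor trials per block, shuffled.
    """
    if rng is None:
        raise InvalidParameterError("build_experiment needs a seeded rng")
    first = MainTask.movement if task_order == "motion_first" else MainTask.orientation
    second = MainTask.orientation if first is MainTask.movement else MainTask.movement

    blocks: list[BlockSpec] = []
    for b in range(N_BLOCKS):
        task = first if b < 5 else second
        if b in DISTRACTOR_BLOCKS:
            if distractor_quota:
                n_dist = round(DISTRACTOR_PROBABILITY * TRIALS_PER_BLOCK)
                flags = np.array([True] * n_dist + [False] * (TRIALS_PER_BLOCK - n_dist))
                rng.shuffle(flags)
            else:
                flags = rng.random(TRIALS_PER_BLOCK) < DISTRACTOR_PROBABILITY
            trials = [
                _make_trial(
                    exp,
                    task,
                    DISTRACTOR_COHERENCE,
                    DISTRACTOR_CONGRUENCY,
                    key_mapping,
                    rng,
                    b,
                    "distractor",
                    with_distractor=bool(flag),
                )
                for flag in flags
            ]
            blocks.append(BlockSpec(task=task, block_type="distractor", trials=trials))
        else:
            cells = [
                (coh, con)
                for coh in COHERENCE_LEVELS
                for con in CONGRUENCY_LEVELS
                for _ in range(REPETITIONS)
            ]
            order = rng.permutation(len(cells))
            trials = [
                _make_trial(exp, task, *cells[i], key_mapping, rng, b, "factorial")
                for i in order
            ]
            blocks.append(BlockSpec(task=task, block_type="factorial", trials=trials))

    training = [
        _make_trial(
            exp,
            first,
            COHERENCE_LEVELS[int(rng.integers(len(COHERENCE_LEVELS)))],
            CONGRUENCY_LEVELS[int(rng.integers(len(CONGRUENCY_LEVELS)))],
            key_mapping,
            rng,
            None,
            "training",
            context="training",
        )
        for _ in range(TRAINING_TRIALS)
    ]
    return DesignSpec(
        experiment=exp,
        task_order=task_order,
        key_mapping=key_mapping,
        training=training,
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# synthetic observer


class SyntheticObserverParams(BaseModel):
    """Logistic accuracy / shifted-log-normal RT agent.

    Accuracy: P(correct) = (1-lapse) * logistic(a + b_coh*coherence +
    b_con*congruency) + lapse/2.  RT: shift + LogNormal(mu + s_coh*coherence
    + s_con*congruency, sigma) ms, decreasing in coherence.  Defaults give
    error rates of roughly 3% at 90% coherence / full congruency up to ~35%
    at 60% coherence / full incongruency, and RTs falling by ~430 ms per
    unit coherence — the experiments' qualitative regime.
    """

    model_config = ConfigDict(extra="forbid")

    accuracy_intercept: float = -2.95
    accuracy_coherence_slope: float = 5.95
    accuracy_congruency_slope: float = 1.11
    lapse: float = Field(default=0.02, ge=0, le=1)
    rt_shift_ms: float = Field(default=300.0, ge=0)
    rt_log_mu: float = 7.0
    rt_coherence_slope: float = -0.72
    rt_congruency_slope: float = -0.10
    rt_log_sigma: float = Field(default=0.25, gt=0)


def synthetic_observer(
    trial: TrialSpec,
    params: SyntheticObserverParams,
    rng: np.random.Generator,
) -> ResponseEvent:
    """Respond to one trial from its (coherence, congruency) ground truth."""
    coherence = float(trial.meta.get("coherence", 0.5))
    congruency = float(trial.meta.get("congruency", 0.5))
    logit = (
        params.accuracy_intercept
        + params.accuracy_coherence_slope * coherence
        + params.accuracy_congruency_slope * congruency
    )
    p_correct = (1 - params.lapse) / (1 + math.exp(-logit)) + params.lapse / 2.0
    correct = rng.random() < p_correct
    correct_key = trial.correct_choice[0]
    if correct:
        key = correct_key
    else:
        others = [k for k in trial.choices if k != correct_key]
        key = others[int(rng.integers(len(others)))] if others else correct_key
    mu = (
        params.rt_log_mu
        + params.rt_coherence_slope * coherence
        + params.rt_congruency_slope * congruency
    )
    rt = params.rt_shift_ms + float(rng.lognormal(mu, params.rt_log_sigma))
    return ResponseEvent(key=key, time=rt)


def make_responder(params: Optional[SyntheticObserverParams] = None):
    """Bind observer parameters into a responder callback for run_trial."""
    params = params or SyntheticObserverParams()

    def responder(trial: TrialSpec, rng: np.random.Generator) -> ResponseEvent:
        return synthetic_observer(trial, params, rng)

    return responder


def simulate_experiment(
    design: DesignSpec,
    params: Optional[SyntheticObserverParams],
    rng: np.random.Generator,
    participant: str = "p0",
    include_training: bool = True,
    fps: float = 60.0,
    jitter_ms: float = 0.0,
) -> pd.DataFrame:
    """Run every trial of a design against the synthetic observer and return
    the analysis-ready trial table (one row per trial, in presented order)."""
    responder = make_responder(params)
    results: list[TrialResult] = []
    trials = (list(design.training) if include_training else []) + [
        t for block in design.blocks for t in block.trials
    ]
    for i, trial in enumerate(trials):
        r = run_trial(trial, responder, rng, fps=fps, jitter_ms=jitter_ms)
        r.meta["participant"] = participant
        r.meta["trial_index"] = i
        results.append(r)
    return results_to_frame(results)


# ---------------------------------------------------------------------------
# exclusion filters


def filter_trials(
    trials: pd.DataFrame,
    fast_rt_ms: float = 200.0,
    min_accuracy: float = 0.60,
) -> pd.DataFrame:
    """Annotate a trial table with the exclusion flags used in the analyses.

    Flags: ``fast`` (RT below 200 ms), ``timeout`` (no response within the
    deadline), ``error`` (responded incorrectly), ``post_error`` (trial
    immediately following an error, dropped from RT analyses) and
    ``excluded_participant`` (experimental accuracy at or below 60%).
    Training trials never feed the participant-accuracy criterion.
    """
    df = trials.copy()
    if "rt" not in df or "correct" not in df:
        raise InvalidParameterError("trial table needs rt and correct columns")
    if "timeout" not in df:
        df["timeout"] = df["rt"].isna()
    df["fast"] = df["rt"].notna() & (df["rt"] < fast_rt_ms)
    df["error"] = ~df["timeout"] & ~df["correct"].astype(bool)

    group = df.groupby("participant", sort=False) if "participant" in df else [(None, df)]
    post_error = pd.Series(False, index=df.index)
    excluded = pd.Series(False, index=df.index)
    for _, g in group:
        prev_error = g["error"].shift(1, fill_value=False)
        post_error.loc[g.index] = prev_error.values
        mask = g["context"] != "training" if "context" in g else pd.Series(True, index=g.index)
        responded = ~g["timeout"] & mask
        acc = g.loc[responded, "correct"].astype(bool).mean() if responded.any() else 0.0
        excluded.loc[g.index] = acc <= min_accuracy
    df["post_error"] = post_error
    df["excluded_participant"] = excluded
    return df
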