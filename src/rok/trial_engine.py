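"""Run simulated trials and emit the per-trial data record.

A trial is a fixation interval followed by the kinematogram, presented for
up to ``trial_duration`` ms (0 = endless) or until a valid response when
``response_ends_trial`` is set.  The responder is an injected callback — a
scripted agent, a synthetic observer, or anything else producing a
:class:`ResponseEvent` — so the engine never blocks on real input.  Response
times are continuous milliseconds from stimulus onset; frames merely bound
what was displayed.  Key presses are serialized as uppercase character codes
(F -> 70, J -> 74).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import SceneSpec
from .errors import ContractViolationError, InvalidDataError, InvalidParameterError
from .kinematics import FrameClock, SceneRun, simulate_scene

__all__ = [
    "TrialSpec",
    "ResponseEvent",
    "TrialResult",
    "Responder",
    "key_code",
    "run_trial",
    "feedback_label",
    "frame_stats",
    "results_to_frame",
    "write_trial_records",
]


def key_code(key: str) -> int:
    """Uppercase character code of a key identifier ('F' -> 70, 'J' -> 74)."""
    if len(key) != 1:
        raise InvalidParameterError(f"single-character key expected, got {key!r}")
    return ord(key.upper())


class TrialSpec(BaseModel):
    """Response mapping, timing limits, and the scene of one trial."""

    model_config = ConfigDict(extra="forbid")

    scene: SceneSpec
    choices: list[str] = Field(default_factory=lambda: ["F", "J"])
    correct_choice: list[str] = Field(default_factory=lambda: ["F"])
    trial_duration: float = Field(default=2000.0, ge=0)  # ms; 0 = endless
    response_ends_trial: bool = True
    fixation_duration: float = Field(default=500.0, ge=0)
    prompt: Optional[str] = None
    context: Literal["training", "experimental"] = "experimental"
    meta: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _correct_subset(self) -> "TrialSpec":
        if not set(self.correct_choice) <= set(self.choices):
            raise ValueError("correct_choice must be a subset of choices")
        return self


@dataclass(frozen=True)
class ResponseEvent:
    """A key press at ``time`` ms after stimulus onset."""

    key: str
    time: float


Responder = Callable[[TrialSpec, np.random.Generator], Optional[ResponseEvent]]


@dataclass
class TrialResult:
    """The per-trial data record (plus an echo of the trial parameters)."""

    rt: Optional[float]
    key_press: Optional[int]
    correct: bool
    timeout: bool
    frame_rate: float
    number_of_frames: int
    frame_rate_array: list[float]
    canvas_width: int
    canvas_height: int
    context: str
    parameters: dict
    meta: dict = field(default_factory=dict)
    trajectory: Optional[SceneRun] = None


def frame_stats(frame_times_ms: list[float]) -> tuple[float, int]:
    """Average implied frame rate (Hz) and frame count of a trial.

    An empty or single-entry list yields 0 Hz — the response preceded the
    second frame, so no rate is defined.
    """
    n = len(frame_times_ms)
    if any(t <= 0 for t in frame_times_ms):
        raise InvalidDataError("frame times must be positive milliseconds")
    if n < 2:
        return 0.0, n
    return 1000.0 / (sum(frame_times_ms) / n), n


def run_trial(
    spec: TrialSpec,
    responder: Responder,
    rng: np.random.Generator,
    fps: float = 60.0,
    jitter_ms: float = 0.0,
    log_trajectory: bool = False,
) -> TrialResult:
    """Run one trial against a responder and build its data record.

    Invalid keys (not in ``choices``) are ignored.  No valid response within
    a finite ``trial_duration`` sets the timeout flag with an absent RT.
    Object kinematics are seed-deterministic and independent of the response
    channel, so the layer states are only evolved when a trajectory log is
    requested; the frame clock always runs.
    """
    event = responder(spec, rng)
    if event is not None and event.time < 0:
        raise ContractViolationError("response before stimulus onset")
    if event is not None and event.key not in spec.choices:
        event = None  # invalid keys are ignored

    endless = spec.trial_duration == 0
    responded = event is not None and (endless or event.time <= spec.trial_duration)
    if endless and not responded:
        raise ContractViolationError("endless trial needs a response to terminate")

    if responded and spec.response_ends_trial:
        shown_ms = event.time
    else:
        shown_ms = spec.trial_duration

    n_frames = max(1, int(math.floor(shown_ms * fps / 1000.0 + 1e-9)))
    clock = FrameClock(nominal_fps=fps, jitter_ms=jitter_ms)
    for _ in range(n_frames):
        clock.tick(rng)
    frame_rate, _ = frame_stats(clock.frame_times_ms)

    trajectory = None
    if log_trajectory:
        trajectory = simulate_scene(spec.scene, n_frames, rng, fps=fps, record=True)

    correct = bool(responded and event.key in spec.correct_choice)
    return TrialResult(
        rt=float(event.time) if responded else None,
        key_press=key_code(event.key) if responded else None,
        correct=correct,
        timeout=not responded,
        frame_rate=frame_rate,
        number_of_frames=n_frames,
        frame_rate_array=list(clock.frame_times_ms),
        canvas_width=spec.scene.canvas_width,
        canvas_height=spec.scene.canvas_height,
        context=spec.context,
        parameters=spec.model_dump(mode="json"),
        meta=dict(spec.meta),
        trajectory=trajectory,
    )


def feedback_label(result: TrialResult) -> str:
    """Post-trial feedback: TOO SLOW on timeouts, FALSE on errors, CORRECT
    after accurate training responses, and none after accurate experimental
    responses."""
    if result.timeout:
        return "TOO SLOW"
    if not result.correct:
        return "FALSE"
    if result.context == "training":
        return "CORRECT"
    return "none"


_RECORD_FIELDS = [
    "rt",
    "key_press",
    "correct",
    "frame_rate",
    "number_of_frames",
    "frame_rate_array",
    "canvas_width",
    "canvas_height",
]


def results_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Analysis-ready table: the data-record fields, the timeout flag, the
    trial context, and any per-trial metadata columns."""
    rows = []
    for r in results:
        row = {f: getattr(r, f) for f in _RECORD_FIELDS}
        row["timeout"] = r.timeout
        row["context"] = r.context
        row.update(r.meta)
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_records(results: list[TrialResult], path, fmt: str = "csv") -> None:
    """Write trial records as CSV or JSON-lines (frame_rate_array serialized
    as JSON within the CSV cell)."""
    df = results_to_frame(results)
    if fmt == "csv":
        df = df.copy()
        df["frame_rate_array"] = df["frame_rate_array"].map(json.dumps)
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        raise InvalidParameterError(f"unknown record format {fmt!r}")
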