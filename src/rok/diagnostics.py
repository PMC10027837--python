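"""Independent audits that recover nominal stimulus parameters from logs.

The trajectory log is ground truth for what was animated; the audit ignores
the logged class labels and re-derives movement classes purely from
finite-difference displacements, so it cross-checks the assignment and
kinematics pipeline end to end.  Boundary reinsertions appear as single
outsized jumps; steps larger than 3x an object's median per-frame
displacement are excluded from direction and speed estimates.  Each object
is then classified by the majority direction of its kept steps, which makes
coherence/opposite/congruency counts exact for exact-angle classes; the
1-degree default angular tolerance only absorbs float error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .assignment import resolve_object_count
from .core import LayerSpec, MainTask, SceneSpec, wrap_angle
from .errors import InvalidDataError

__all__ = ["CoherenceReport", "audit_log", "frame_rate_histogram"]


@dataclass(frozen=True)
class CoherenceReport:
    """Realized stimulus statistics of one layer, recovered from its log."""

    realized_movement_coherence: float
    realized_opposite: float
    realized_orientation_coherence: float
    realized_congruency: float
    realized_mean_speed: float  # % of aperture width per second
    n_objects: int


def _angular_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(np.mod(a - b, 360.0))
    return np.minimum(d, 360.0 - d)


def _majority_label(dirs: np.ndarray, coherent: float, tol: float) -> str:
    if dirs.size == 0:
        return "other"
    n_coh = int(np.sum(_angular_distance(dirs, coherent) <= tol))
    n_opp = int(np.sum(_angular_distance(dirs, wrap_angle(coherent + 180.0)) <= tol))
    n_other = dirs.size - n_coh - n_opp
    best = max((n_coh, "coherent"), (n_opp, "opposite"), (n_other, "other"))
    return best[1]


def audit_log(
    log: pd.DataFrame,
    scene: SceneSpec,
    angular_tol: float = 1.0,
    layer: int = 0,
) -> CoherenceReport:
    """Recover realized coherence, congruency, and speed of one scene layer.

    Movement directions come from displacement finite differences (never the
    logged direction column); object ids are mapped to layers through the
    scene's per-layer counts.  Realized congruency is the fraction of
    objects whose secondary (non-task) feature carries the coherent target
    direction of the main task.
    """
    if log is None or len(log) == 0:
        raise InvalidDataError("empty trajectory log")
    required = {"frame_index", "time_ms", "object_id", "x", "y", "orientation"}
    if not required <= set(log.columns):
        raise InvalidDataError(f"log lacks columns {sorted(required - set(log.columns))}")
    if not 0 <= layer < len(scene.apertures):
        raise InvalidDataError(f"scene has no layer {layer}")

    counts = [
        resolve_object_count(ls.number_of_oobs, ls.density_unit_area, ap)
        for ap, ls in scene.apertures
    ]
    if log["object_id"].max() >= sum(counts):
        raise InvalidDataError("log object ids exceed the scene's object count")
    offset = sum(counts[:layer])
    n = counts[layer]
    aperture, layer_spec = scene.apertures[layer]
    sub = log[(log["object_id"] >= offset) & (log["object_id"] < offset + n)]
    if len(sub) == 0:
        raise InvalidDataError("log holds no rows for the requested layer")

    coh_dir = layer_spec.coherent_movement_direction
    coh_ori = layer_spec.coherent_orientation

    move_labels: dict[int, str] = {}
    ori_labels: dict[int, str] = {}
    speeds: list[float] = []
    for oid, g in sub.sort_values(["object_id", "frame_index"]).groupby("object_id"):
        dx = np.diff(g["x"].to_numpy())
        dy = np.diff(g["y"].to_numpy())
        dt = np.diff(g["time_ms"].to_numpy()) / 1000.0
        norm = np.hypot(dx, dy)
        med = np.median(norm) if norm.size else 0.0
        kept = norm <= 3.0 * med + 1e-12  # reinsertion jumps excluded
        moving = kept & (norm > 1e-12)
        dirs = np.degrees(np.arctan2(-dy[moving], dx[moving])) % 360.0
        move_labels[oid] = _majority_label(dirs, coh_dir, angular_tol)
        if np.any(kept & (dt > 0)):
            speeds.append(float(np.mean(norm[kept & (dt > 0)] / dt[kept & (dt > 0)])))
        ori = g["orientation"].to_numpy()
        ori_labels[oid] = _majority_label(ori, coh_ori, angular_tol)

    move = pd.Series(move_labels)
    ori = pd.Series(ori_labels)
    realized_coh = float((move == "coherent").mean())
    realized_opp = float((move == "opposite").mean())
    realized_ori = float((ori == "coherent").mean())

    # congruency: secondary feature vs the main task's coherent target direction
    if layer_spec.experiment_main_task is MainTask.movement:
        target = coh_dir
        sec_dirs = {oid: g["orientation"].to_numpy() for oid, g in sub.groupby("object_id")}
        congruent = [
            _majority_label(v, target, angular_tol) == "coherent" for v in sec_dirs.values()
        ]
    else:
        target = coh_ori
        congruent = [
            move_labels[oid] == "coherent" if abs(target - coh_dir) < 1e-9 else False
            for oid in move_labels
        ]
        if abs(target - coh_dir) >= 1e-9:
            # re-classify displacements against the orientation target
            congruent = []
            for oid, g in sub.sort_values(["object_id", "frame_index"]).groupby("object_id"):
                dx = np.diff(g["x"].to_numpy())
                dy = np.diff(g["y"].to_numpy())
                norm = np.hypot(dx, dy)
                med = np.median(norm) if norm.size else 0.0
                moving = (norm <= 3.0 * med + 1e-12) & (norm > 1e-12)
                dirs = np.degrees(np.arctan2(-dy[moving], dx[moving])) % 360.0
                congruent.append(_majority_label(dirs, target, angular_tol) == "coherent")
    realized_congruency = float(np.mean(congruent)) if congruent else 0.0

    region = aperture.region(scene.canvas_width, scene.canvas_height)
    mean_speed_px = float(np.mean(speeds)) if speeds else 0.0
    mean_speed = mean_speed_px / region.width * 100.0

    return CoherenceReport(
        realized_movement_coherence=realized_coh,
        realized_opposite=realized_opp,
        realized_orientation_coherence=realized_ori,
        realized_congruency=realized_congruency,
        realized_mean_speed=mean_speed,
        n_objects=n,
    )


def frame_rate_histogram(
    results: Union[pd.DataFrame, Sequence],
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-participant mean frame rates (Hz).

    Zero-Hz trials (responses before the second frame) are excluded.  Input
    is a trial table with ``frame_rate`` (and optionally ``participant``)
    columns, or a sequence of trial results.  Returns (counts, bin_edges).
    """
    if not isinstance(results, pd.DataFrame):
        rows = [
            {
                "frame_rate": r.frame_rate,
                "participant": getattr(r, "meta", {}).get("participant", "p0"),
            }
            for r in results
        ]
        results = pd.DataFrame(rows)
    if len(results) == 0:
        return np.array([], dtype=int), np.array([])
    df = results[results["frame_rate"] > 0]
    if len(df) == 0:
        return np.array([], dtype=int), np.array([])
    if "participant" not in df:
        df = df.assign(participant="p0")
    means = df.groupby("participant")["frame_rate"].mean().to_numpy()
    lo = math.floor(means.min() / bin_width) * bin_width
    hi = math.ceil(means.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(means, bins=edges)
    return counts, edges
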