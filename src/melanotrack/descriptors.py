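"""Per-trajectory kinematic descriptors.

All descriptors operate on the coordinates as provided; apply
:func:`melanotrack.simulate.quantize_to_pixels` first to reproduce the output
of a pixel-resolution tracking tool. Gap-tolerant trajectories are supported:
steps that span a frame gap are excluded from the step census.

Conventions worth noting:

* ``average_distance`` divides the total distance by the *frame count* (the
  tracking tool's literal definition), not the step count; pass
  ``divisor="steps"`` for the per-step mean.
* a pause is a step whose pixel-quantized displacement is exactly zero —
  movement below one pixel (0.16 μm by default) is unresolvable and recorded
  as static.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import DescriptorError, InvalidParameterError


def _require_steps(traj: Trajectory):
    if traj.n_frames < 2:
        raise DescriptorError(f"track {traj.track_id}: needs >= 2 frames")


def _valid_steps(traj: Trajectory) -> np.ndarray:
    """Step vectors excluding any step that spans a frame gap."""
    steps = traj.step_vectors()
    return steps[traj.step_frame_gaps() == 1]


def total_distance(traj: Trajectory) -> float:
    """Sum of consecutive-frame step lengths over the whole recording, μm."""
    _require_steps(traj)
    steps = _valid_steps(traj)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def euclidean_distance(traj: Trajectory) -> float:
    """Straight-line distance between first and last recorded position, μm."""
    _require_steps(traj)
    d = traj.positions[-1] - traj.positions[0]
    return float(np.hypot(d[0], d[1]))


def average_distance_and_velocity(
    traj: Trajectory, divisor: str = "frames"
) -> Tuple[float, float]:
    """Mean distance per frame (μm) and mean velocity (μm/s).

    ``divisor="frames"`` divides the total distance by the number of frames
    (601 for a full recording); ``"steps"`` divides by the number of steps.
    Velocity is the average distance divided by the frame interval.
    """
    _require_steps(traj)
    total = total_distance(traj)
    if divisor == "frames":
        n = traj.n_frames
    elif divisor == "steps":
        n = int(np.sum(traj.step_frame_gaps() == 1))
    else:
        raise InvalidParameterError("divisor must be 'frames' or 'steps'")
    avg = total / n
    return avg, avg / traj.settings.frame_interval


def pause_fraction(
    traj: Trajectory, mode: str = "quantized", threshold: Optional[float] = None
) -> float:
    """Fraction of steps recorded as static, in [0, 1].

    ``mode="quantized"`` (default) rounds coordinates to the pixel grid and
    counts steps with exactly zero displacement; ``mode="threshold"`` counts
    raw displacements below ``threshold`` (default: one pixel).
    """
    _require_steps(traj)
    from .simulate import quantize_to_pixels

    if mode == "quantized":
        steps = _valid_steps(quantize_to_pixels(traj))
        paused = np.all(steps == 0.0, axis=1)
    elif mode == "threshold":
        thr = traj.settings.pixel_size if threshold is None else threshold
        steps = _valid_steps(traj)
        paused = np.hypot(steps[:, 0], steps[:, 1]) < thr
    else:
        raise InvalidParameterError("mode must be 'quantized' or 'threshold'")
    if len(paused) == 0:
        raise DescriptorError(f"track {traj.track_id}: no gap-free steps")
    return float(np.mean(paused))


def radial_direction(
    traj: Trajectory,
    nucleus_center: Tuple[float, float],
    tie_tolerance: Optional[float] = None,
    mode: str = "net",
) -> str:
    """Classify a track as 'centrifugal', 'centripetal' or 'indeterminate'.

    ``mode="net"`` compares the first and last distances to the nucleus
    centre; a change smaller than ``tie_tolerance`` (default: one pixel) is
    indeterminate. ``mode="per_step"`` votes by the majority sign of
    per-step radial changes instead.
    """
    _require_steps(traj)
    c = np.asarray(nucleus_center, dtype=float)
    if not np.all(np.isfinite(c)):
        raise InvalidParameterError("nucleus_center must be finite")
    tol = traj.settings.pixel_size if tie_tolerance is None else tie_tolerance
    r = np.hypot(traj.positions[:, 0] - c[0], traj.positions[:, 1] - c[1])
    if mode == "net":
        change = r[-1] - r[0]
    elif mode == "per_step":
        dr = np.diff(r)
        change = float(np.sum(dr > 0) - np.sum(dr < 0)) * tol  # majority, in tol units
    else:
        raise InvalidParameterError("mode must be 'net' or 'per_step'")
    if change > tol:
        return "centrifugal"
    if change < -tol:
        return "centripetal"
    return "indeterminate"


def summarize_trajectory(
    traj: Trajectory,
    nucleus_center: Optional[Tuple[float, float]] = None,
    divisor: str = "frames",
    pause_mode: str = "quantized",
) -> dict:
    avg, vel = average_distance_and_velocity(traj, divisor=divisor)
    rec = {
        "track_id": traj.track_id,
        "total_distance_um": total_distance(traj),
        "euclidean_distance_um": euclidean_distance(traj),
        "average_distance_um_per_frame": avg,
        "average_velocity_um_per_s": vel,
        "pause_fraction": pause_fraction(traj, mode=pause_mode),
    }
    if nucleus_center is not None:
        rec["radial_direction"] = radial_direction(traj, nucleus_center)
    return rec


def summarize_population(
    trajs: Sequence[Trajectory],
    nucleus_center: Optional[Tuple[float, float]] = None,
    divisor: str = "frames",
    pause_mode: str = "quantized",
) -> pd.DataFrame:
    """One descriptor row per trajectory (see :func:`summarize_trajectory`)."""
    if not len(trajs):
        raise DescriptorError("empty population")
    return pd.DataFrame(
        [summarize_trajectory(t, nucleus_center, divisor, pause_mode) for t in trajs]
    )


def aggregate_descriptors(table: pd.DataFrame) -> dict:
    """Population aggregates: mean/SD of each descriptor, pause %, direction %.

    Direction percentages are computed among non-indeterminate tracks only.
    """
    numeric = table.select_dtypes("number")
    agg = {
        "n": int(len(table)),
        "mean": numeric.mean().to_dict(),
        "sd": numeric.std(ddof=1).to_dict() if len(table) > 1 else {c: 0.0 for c in numeric},
        "pause_percent_mean": float(table["pause_fraction"].mean() * 100.0),
    }
    if "radial_direction" in table:
        decided = table[table["radial_direction"] != "indeterminate"]
        n = len(decided)
        agg["percent_centrifugal"] = (
            float((decided["radial_direction"] == "centrifugal").mean() * 100.0) if n else float("nan")
        )
        agg["percent_centripetal"] = (
            float((decided["radial_direction"] == "centripetal").mean() * 100.0) if n else float("nan")
        )
    return agg
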