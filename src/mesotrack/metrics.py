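"""Per-cell migration statistics.

Four descriptors of a centroid track, mirroring standard time-lapse
migration analysis:

net displacement
    Euclidean distance between the first and last tracked positions.
travel displacement
    Summed length of all consecutive steps (the path length).
straightness
    Net over travel displacement; 1 for a linear path, near 0 for
    tortuous motion.  Undefined (NaN) for a stationary cell.
mean speed
    Duration-weighted mean of the instantaneous speeds of the
    piecewise-linear cumulative path-length curve.  Under this
    interpolation it collapses to travel displacement over total
    duration; the identity is deliberate (the observed path-length
    curves are closely linear) and asserted in the tests rather than
    hidden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import TrackDataset, Trajectory, ValidationError

__all__ = [
    "net_displacement",
    "travel_displacement",
    "straightness",
    "mean_speed",
    "summarize_tracks",
]

SUMMARY_COLUMNS = [
    "embryo_id", "cell_id", "region", "n_points", "duration_min",
    "net_displacement_um", "travel_displacement_um", "straightness",
    "mean_speed_um_min", "note",
]


def _require_points(traj: Trajectory, n: int = 2) -> None:
    if traj.n_points < n:
        raise ValidationError(
            f"cell {traj.cell_id!r}: need at least {n} points, has {traj.n_points}"
        )


def step_lengths(traj: Trajectory) -> np.ndarray:
    """Euclidean lengths (µm) of consecutive track segments."""
    _require_points(traj)
    return np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)


def net_displacement(traj: Trajectory) -> float:
    """Straight-line distance (µm) between first and last positions."""
    _require_points(traj)
    return float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))


def travel_displacement(traj: Trajectory) -> float:
    """Total path length (µm): sum of consecutive segment lengths."""
    return float(step_lengths(traj).sum())


def straightness(traj: Trajectory) -> float:
    """Net over travel displacement in [0, 1]; NaN for a stationary cell."""
    travel = travel_displacement(traj)
    if travel == 0.0:
        return float("nan")
    return net_displacement(traj) / travel


def mean_speed(traj: Trajectory) -> float:
    """Mean migration speed (µm/min).

    Instantaneous speeds are the slopes of the piecewise-linear
    cumulative path-length curve; each is weighted by the duration of
    its segment, so sampling gaps contribute in proportion to the time
    they span.
    """
    _require_points(traj)
    dt = np.diff(traj.times)
    if traj.duration <= 0:
        raise ValidationError(f"cell {traj.cell_id!r}: zero tracked duration")
    speeds = step_lengths(traj) / dt
    return float(np.sum(speeds * dt) / np.sum(dt))


def summarize_tracks(dataset: TrackDataset) -> pd.DataFrame:
    """One row of migration metrics per trajectory, in deterministic order.

    Tracks that cannot be measured (fewer than 2 points) are kept with
    NaN metrics and the reason in the ``note`` column, so no cell is
    silently dropped.
    """
    rows = []
    for tr in sorted(dataset.trajectories, key=lambda t: (t.embryo_id, t.cell_id)):
        if tr.n_points < 2:
            rows.append((
                tr.embryo_id, tr.cell_id, tr.region.value, tr.n_points,
                np.nan, np.nan, np.nan, np.nan, np.nan,
                "fewer than 2 points",
            ))
            continue
        net = net_displacement(tr)
        travel = travel_displacement(tr)
        rows.append((
            tr.embryo_id, tr.cell_id, tr.region.value, tr.n_points,
            tr.duration, net, travel,
            net / travel if travel > 0 else np.nan,
            mean_speed(tr),
            "" if travel > 0 else "stationary cell: straightness undefined",
        ))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
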