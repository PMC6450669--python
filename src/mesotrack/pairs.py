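"""Coupling statistics for annotated cell pairs.

Daughter cells after mitosis, unrelated cells starting in immediate
proximity, and colliding cells are compared through one angle and four
scalar couplings per pair, all computed over the pair's annotated
tracking window:

* angle between the two whole-window net-displacement vectors (degrees);
* net and travel displacement ratios, min/max so they are symmetric and
  lie in (0, 1];
* mean and final inter-centroid distance over common timepoints (µm).

Common timepoints are matched by exact time equality — both cells of a
pair come from the same image stack grid — with no temporal
interpolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import net_displacement, travel_displacement
from .model import CellPairRecord, TrackDataset, Trajectory, ValidationError

__all__ = [
    "pair_angle",
    "displacement_ratio",
    "pair_distance_stats",
    "summarize_pairs",
    "pair_class_aggregates",
]

PAIR_SUMMARY_COLUMNS = [
    "pair_id", "pair_class", "angle_deg", "net_ratio", "travel_ratio",
    "mean_distance_um", "final_distance_um", "n_common_timepoints",
]

Window = tuple[float, float] | None


def _windowed(traj: Trajectory, window: Window) -> Trajectory:
    if window is None:
        return traj
    return traj.crop(window[0], window[1])


def pair_angle(a: Trajectory, b: Trajectory, window: Window = None) -> float:
    """Angle (degrees, [0, 180]) between the two net-displacement vectors."""
    va = _net_vector(_windowed(a, window))
    vb = _net_vector(_windowed(b, window))
    cosang = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _net_vector(traj: Trajectory) -> np.ndarray:
    if traj.n_points < 2:
        raise ValidationError(f"cell {traj.cell_id!r}: need >= 2 points in window")
    v = traj.positions[-1] - traj.positions[0]
    if np.linalg.norm(v) == 0.0:
        raise ValidationError(
            f"cell {traj.cell_id!r}: zero net displacement, pair angle undefined"
        )
    return v


def displacement_ratio(
    a: Trajectory, b: Trajectory, mode: str = "net", window: Window = None,
) -> float:
    """min/max ratio of the two displacements (symmetric, in (0, 1])."""
    if mode not in ("net", "travel"):
        raise ValueError(f"mode must be 'net' or 'travel', got {mode!r}")
    fn = net_displacement if mode == "net" else travel_displacement
    da = fn(_windowed(a, window))
    db = fn(_windowed(b, window))
    if da == 0.0 or db == 0.0:
        raise ValidationError(
            f"pair ({a.cell_id!r}, {b.cell_id!r}): zero {mode} displacement"
        )
    return float(min(da, db) / max(da, db))


def _common_times(a: Trajectory, b: Trajectory, window: Window) -> np.ndarray:
    common = np.intersect1d(a.times, b.times)
    if window is not None:
        lo, hi = window
        common = common[(common >= lo) & (common <= hi)]
    return common


def pair_distance_stats(
    a: Trajectory, b: Trajectory, window: Window = None,
) -> tuple[float, float]:
    """(mean, final) inter-centroid distance (µm) over common timepoints."""
    common = _common_times(a, b, window)
    if common.size == 0:
        raise ValidationError(
            f"pair ({a.cell_id!r}, {b.cell_id!r}): no common timepoints in window"
        )
    pa = a.positions[np.searchsorted(a.times, common)]
    pb = b.positions[np.searchsorted(b.times, common)]
    d = np.linalg.norm(pa - pb, axis=1)
    return float(d.mean()), float(d[-1])


def summarize_pairs(
    dataset: TrackDataset, pairs: list[CellPairRecord],
) -> pd.DataFrame:
    """One row of coupling metrics per pair, ordered by pair_id.

    ``dataset`` is consulted only to verify each record's cells are
    present (records built by :func:`mesotrack.io.read_pair_table` are
    already resolved).
    """
    for rec in pairs:
        try:
            dataset.get(rec.a.embryo_id, rec.a.cell_id)
            dataset.get(rec.b.embryo_id, rec.b.cell_id)
        except KeyError as exc:
            raise ValidationError(f"pair {rec.pair_id!r}: {exc}") from exc
    rows = []
    for rec in sorted(pairs, key=lambda r: r.pair_id):
        mean_d, final_d = pair_distance_stats(rec.a, rec.b, rec.window)
        rows.append((
            rec.pair_id, rec.pair_class.value,
            pair_angle(rec.a, rec.b, rec.window),
            displacement_ratio(rec.a, rec.b, "net", rec.window),
            displacement_ratio(rec.a, rec.b, "travel", rec.window),
            mean_d, final_d,
            int(_common_times(rec.a, rec.b, rec.window).size),
        ))
    return pd.DataFrame(rows, columns=PAIR_SUMMARY_COLUMNS)


def pair_class_aggregates(pair_summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean ± SEM of each pair metric (SEM = sd/√n, ddof=1)."""
    metrics = ["angle_deg", "net_ratio", "travel_ratio",
               "mean_distance_um", "final_distance_um"]
    rows = []
    for cls, g in pair_summaries.groupby("pair_class", sort=True):
        n = len(g)
        for m in metrics:
            vals = g[m].to_numpy(dtype=float)
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append((cls, m, n, float(vals.mean()), sem))
    return pd.DataFrame(rows, columns=["pair_class", "metric", "n", "mean", "sem"])
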