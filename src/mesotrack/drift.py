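"""Whole-embryo drift removal from cell tracks.

Cultured embryos translate slowly in their wells during acquisition.
The correction subtracts, at every timepoint, the displacement of a
reference trajectory (the manually segmented embryo-contour centroid)
relative to the first frame, so residual cell motion is expressed in the
embryo frame.  Rotation is not estimated; per-frame rotation matrices
may be supplied when the embryo was re-oriented manually.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import TrackDataset, Trajectory, ValidationError

__all__ = ["DriftModel", "estimate_drift", "apply_correction"]


@dataclasses.dataclass
class DriftModel:
    """Per-frame translation offsets (µm), zero at the first frame.

    ``rotations``, when given, holds one 3×3 matrix per timepoint that is
    applied about the reference start point after translation removal.
    """

    times: np.ndarray
    offsets: np.ndarray
    rotations: np.ndarray | None = None
    anchor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != (self.times.size, 3):
            raise ValidationError("offsets must be (n_timepoints, 3)")
        if self.times.size == 0:
            raise ValidationError("drift model needs at least one timepoint")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("drift model timepoints must be strictly increasing")
        if not np.allclose(self.offsets[0], 0.0, atol=0.0):
            raise ValidationError("offset at the first frame must be exactly zero")
        if self.rotations is not None:
            self.rotations = np.asarray(self.rotations, dtype=float)
            if self.rotations.shape != (self.times.size, 3, 3):
                raise ValidationError("rotations must be (n_timepoints, 3, 3)")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)

    def offset_at(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise ValidationError(f"drift model has no offset for t={t:g} min")
        return self.offsets[idx[0]]

    def covers(self, times: np.ndarray) -> np.ndarray:
        """Timepoints in ``times`` missing from the model (empty if covered)."""
        return np.setdiff1d(np.asarray(times, dtype=float), self.times)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (repr(float(t)), repr(float(dx)), repr(float(dy)), repr(float(dz)))
            for t, (dx, dy, dz) in zip(self.times, self.offsets)
        ]
        pd.DataFrame(rows, columns=["t_min", "dx_um", "dy_um", "dz_um"]).to_csv(
            path, index=False, lineterminator="\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DriftModel":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=df["t_min"].to_numpy(dtype=float),
            offsets=df[["dx_um", "dy_um", "dz_um"]].to_numpy(dtype=float),
        )


def estimate_drift(reference: Trajectory) -> DriftModel:
    """Translation drift of the reference track relative to its first frame."""
    offsets = reference.positions - reference.positions[0]
    return DriftModel(
        times=reference.times.copy(),
        offsets=offsets,
        anchor=reference.positions[0].copy(),
    )


def _correct_one(traj: Trajectory, model: DriftModel) -> Trajectory:
    missing = model.covers(traj.times)
    if missing.size:
        raise ValidationError(
            f"cell {traj.cell_id!r}: drift model missing timepoint(s) "
            f"{[float(t) for t in missing]}"
        )
    idx = np.searchsorted(model.times, traj.times)
    corrected = traj.positions - model.offsets[idx]
    if model.rotations is not None:
        anchor = model.anchor if model.anchor is not None else np.zeros(3)
        rel = corrected - anchor
        corrected = anchor + np.einsum("nij,nj->ni", model.rotations[idx], rel)
    return Trajectory(traj.embryo_id, traj.cell_id, traj.region,
                      traj.times.copy(), corrected)


def apply_correction(dataset: TrackDataset, model: DriftModel) -> TrackDataset:
    """Return a new dataset with drift removed from every trajectory.

    The input dataset is left unmodified.  The reference track, if
    present, is corrected too (it becomes stationary when the model was
    estimated from it).
    """
    corrected = [_correct_one(tr, model) for tr in dataset.trajectories]
    reference = (
        _correct_one(dataset.reference, model)
        if dataset.reference is not None else None
    )
    return TrackDataset(
        trajectories=corrected,
        reference=reference,
        frame_interval=dataset.frame_interval,
        voxel_size=dataset.voxel_size,
    )
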