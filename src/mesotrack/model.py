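"""Core data model for mesoderm migration analysis.

All coordinates are physical micrometres, all times are minutes from the
first acquired frame.  Voxel grids are ordered (Z, Y, X), matching the
page order of multi-page TIFF stacks; their voxel size is given in the
same (z, y, x) order.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Region",
    "PairClass",
    "FilopodiumTarget",
    "FormatError",
    "ValidationError",
    "TrackPoint",
    "Trajectory",
    "TrackDataset",
    "CellPairRecord",
    "LabeledCellMask",
    "FilopodiumTrace",
]


class FormatError(ValueError):
    """A file or table does not match the expected schema."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class Region(str, enum.Enum):
    """Embryo compartment a mesoderm cell migrates into."""

    EMBRYONIC = "embryonic"
    EXTRA_EMBRYONIC = "extra_embryonic"
    UNASSIGNED = "unassigned"


class PairClass(str, enum.Enum):
    """How a pair of cells came to be compared (manual annotation)."""

    DAUGHTER = "daughter"
    PROXIMITY = "proximity"
    COLLISION = "collision"


class FilopodiumTarget(str, enum.Enum):
    """Germ layer a filopodium points toward on the Z-projection."""

    EPIBLAST = "epiblast"
    VISCERAL_ENDODERM = "visceral_endoderm"
    OTHER = "other"


@dataclasses.dataclass(frozen=True)
class TrackPoint:
    """A single centroid observation: time (min) and position (µm)."""

    t: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"TrackPoint.{name} must be finite, got {v!r}")


@dataclasses.dataclass
class Trajectory:
    """Ordered centroid track of one segmented cell.

    ``times`` is a strictly increasing 1-D array (minutes); ``positions``
    is the matching (n, 3) array of (x, y, z) centroids in µm.  A single
    observation is tolerated so readers can represent cells that left the
    field immediately; every metric requires at least two points and
    downstream summaries flag shorter tracks as missing.
    """

    embryo_id: str
    cell_id: str
    region: Region
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float)
        self.region = Region(self.region)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"positions must be (n, 3), got shape {self.positions.shape}"
            )
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValidationError("times and positions length mismatch")
        if self.times.size == 0:
            raise ValidationError(f"trajectory {self.cell_id!r} has no points")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.positions)
        ):
            raise ValidationError(
                f"trajectory {self.cell_id!r} contains non-finite coordinates"
            )
        dt = np.diff(self.times)
        if np.any(dt == 0):
            t_dup = self.times[:-1][dt == 0][0]
            raise ValidationError(
                f"duplicated timepoint t={t_dup:g} min in cell {self.cell_id!r}"
            )
        if np.any(dt < 0):
            raise ValidationError(
                f"timepoints of cell {self.cell_id!r} are not strictly increasing"
            )

    @classmethod
    def from_points(
        cls,
        embryo_id: str,
        cell_id: str,
        region: Region | str,
        points: Iterable[TrackPoint],
    ) -> "Trajectory":
        pts = list(points)
        return cls(
            embryo_id=embryo_id,
            cell_id=cell_id,
            region=Region(region),
            times=np.array([p.t for p in pts], dtype=float),
            positions=np.array([[p.x, p.y, p.z] for p in pts], dtype=float),
        )

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Tracked duration in minutes (last minus first timepoint)."""
        return float(self.times[-1] - self.times[0])

    def points(self) -> Iterator[TrackPoint]:
        for t, (x, y, z) in zip(self.times, self.positions):
            yield TrackPoint(float(t), float(x), float(y), float(z))

    def crop(self, t_start: float | None = None, t_end: float | None = None) -> "Trajectory":
        """Restrict the track to timepoints within [t_start, t_end]."""
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        keep = (self.times >= lo) & (self.times <= hi)
        if not keep.any():
            raise ValidationError(
                f"cell {self.cell_id!r} has no points in window [{lo:g}, {hi:g}] min"
            )
        return Trajectory(
            self.embryo_id, self.cell_id, self.region,
            self.times[keep].copy(), self.positions[keep].copy(),
        )

    def translated(self, offset: Sequence[float]) -> "Trajectory":
        return Trajectory(
            self.embryo_id, self.cell_id, self.region,
            self.times.copy(), self.positions + np.asarray(offset, dtype=float),
        )


@dataclasses.dataclass
class TrackDataset:
    """All trajectories from one imaging session plus acquisition metadata.

    ``reference`` is the optional embryo-contour centroid track used for
    drift correction.  ``frame_interval`` is the acquisition cadence in
    minutes; ``voxel_size`` the (z, y, x) voxel edge lengths in µm.
    """

    trajectories: list[Trajectory]
    reference: Trajectory | None = None
    frame_interval: float = 20.0
    voxel_size: tuple[float, float, float] = (3.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size components must be positive")
        seen: set[tuple[str, str]] = set()
        for tr in self.trajectories:
            key = (tr.embryo_id, tr.cell_id)
            if key in seen:
                raise ValidationError(f"duplicate trajectory for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def get(self, embryo_id: str, cell_id: str) -> Trajectory:
        for tr in self.trajectories:
            if tr.embryo_id == embryo_id and tr.cell_id == cell_id:
                return tr
        raise KeyError(f"no trajectory for embryo {embryo_id!r}, cell {cell_id!r}")

    def timepoints(self) -> np.ndarray:
        """Sorted union of all timepoints across trajectories and reference."""
        ts: list[np.ndarray] = [tr.times for tr in self.trajectories]
        if self.reference is not None:
            ts.append(self.reference.times)
        if not ts:
            return np.array([], dtype=float)
        return np.unique(np.concatenate(ts))


@dataclasses.dataclass
class CellPairRecord:
    """Two trajectories compared as a pair, with its annotated class.

    The pair class (daughter / proximity / collision) is always supplied
    by manual annotation, never inferred from the tracks.
    """

    pair_id: str
    a: Trajectory
    b: Trajectory
    pair_class: PairClass
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pair_class = PairClass(self.pair_class)
        if self.window is not None:
            lo, hi = self.window
            if not (hi > lo):
                raise ValidationError(
                    f"pair {self.pair_id!r}: window end must exceed start"
                )
        common = np.intersect1d(self.a.times, self.b.times)
        if self.window is not None:
            lo, hi = self.window
            common = common[(common >= lo) & (common <= hi)]
        if common.size < 2:
            raise ValidationError(
                f"pair {self.pair_id!r}: fewer than 2 common timepoints in window"
            )


@dataclasses.dataclass
class LabeledCellMask:
    """Binary voxel occupancy of one segmented cell, (Z, Y, X) order."""

    occupancy: np.ndarray
    voxel_size: tuple[float, float, float]
    cell_id: str
    embryo_id: str = ""
    t: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValidationError("occupancy must be a 3-D array (Z, Y, X)")
        if not self.occupancy.any():
            raise ValidationError(f"mask for cell {self.cell_id!r} is empty")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size components must be positive")

    @property
    def voxel_volume(self) -> float:
        vz, vy, vx = self.voxel_size
        return float(vz * vy * vx)

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())


@dataclasses.dataclass
class FilopodiumTrace:
    """Manually traced filopodium: a 2-D polyline (µm) on a Z-projection."""

    cell_id: str
    t: float
    vertices: np.ndarray
    target: FilopodiumTarget | None = None
    filopodium_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.target is not None:
            self.target = FilopodiumTarget(self.target)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be (n, 2)")
        if self.vertices.shape[0] < 2:
            raise ValidationError(
                f"filopodium {self.filopodium_id!r} needs at least 2 vertices"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("vertices must be finite")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValidationError(
                f"filopodium {self.filopodium_id!r} has consecutive duplicate vertices"
            )
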