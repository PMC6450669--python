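"""Readers and writers for track tables, mask volumes and annotations.

All tabular formats are plain CSV with a header row, decimal-point
numbers (scientific notation accepted) and one observation per row, so
exports from commercial tracking tools can be remapped via a column
*dialect* — a mapping from the canonical column names used here to the
names present in the file.

Canonical schemas
-----------------
tracks      : embryo_id, cell_id, region, t_min, x_um, y_um, z_um
filopodia   : cell_id, t_min, filopodium_id, vertex_index, x_um, y_um, target
pairs       : pair_id, embryo_id, cell_id_a, cell_id_b, pair_class,
              t_start_min, t_end_min
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .model import (
    CellPairRecord,
    FilopodiumTrace,
    FormatError,
    LabeledCellMask,
    Region,
    TrackDataset,
    Trajectory,
    ValidationError,
)

TRACK_COLUMNS = ("embryo_id", "cell_id", "region", "t_min", "x_um", "y_um", "z_um")
FILOPODIA_COLUMNS = (
    "cell_id", "t_min", "filopodium_id", "vertex_index", "x_um", "y_um", "target",
)
PAIR_COLUMNS = (
    "pair_id", "embryo_id", "cell_id_a", "cell_id_b", "pair_class",
    "t_start_min", "t_end_min",
)

#: cell_id under which the embryo-contour reference track is stored in a
#: track CSV (its region column is ignored).
REFERENCE_CELL_ID = "__reference__"


def _remap(df: pd.DataFrame, required: Sequence[str],
           dialect: Mapping[str, str] | None, path: Path) -> pd.DataFrame:
    dialect = dict(dialect or {})
    rename = {dialect.get(c, c): c for c in required}
    missing = [dialect.get(c, c) for c in required if dialect.get(c, c) not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing!r}; "
            f"present: {list(df.columns)!r}"
        )
    return df.rename(columns=rename)


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path: Path) -> pd.DataFrame:
    """Coerce columns to float; enumerate every rejected row instead of dropping."""
    bad_rows: list[int] = []
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() | df[c].isna()
        bad_rows.extend(df.index[bad].tolist())
        df[c] = coerced
    if bad_rows:
        rows = sorted(set(bad_rows))
        raise FormatError(
            f"{path}: {len(rows)} row(s) with non-numeric or missing coordinates "
            f"(0-based data rows {rows[:20]}{'...' if len(rows) > 20 else ''})"
        )
    return df


def read_track_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    frame_interval: float = 20.0,
    voxel_size: tuple[float, float, float] = (3.0, 1.0, 1.0),
    reference_cell_id: str = REFERENCE_CELL_ID,
) -> TrackDataset:
    """Read a centroid track CSV into a validated :class:`TrackDataset`.

    Rows are grouped by (embryo_id, cell_id) and sorted by time; a row
    whose cell_id equals ``reference_cell_id`` is taken as the
    embryo-contour reference track used for drift correction.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"embryo_id": str, "cell_id": str, "region": str},
                     float_precision="round_trip")
    df = _remap(df, TRACK_COLUMNS, dialect, path)
    df = _check_numeric(df, ["t_min", "x_um", "y_um", "z_um"], path)
    df["embryo_id"] = df["embryo_id"].astype(str)
    df["cell_id"] = df["cell_id"].astype(str)
    df = df.sort_values(["embryo_id", "cell_id", "t_min"], kind="mergesort")

    trajectories: list[Trajectory] = []
    reference: Trajectory | None = None
    for (embryo, cell), g in df.groupby(["embryo_id", "cell_id"], sort=True):
        region_values = g["region"].astype(str).unique()
        try:
            region = Region(region_values[0]) if cell != reference_cell_id else Region.UNASSIGNED
        except ValueError as exc:
            raise FormatError(
                f"{path}: unknown region {region_values[0]!r} for cell {cell!r}"
            ) from exc
        traj = Trajectory(
            embryo_id=embryo,
            cell_id=cell,
            region=region,
            times=g["t_min"].to_numpy(),
            positions=g[["x_um", "y_um", "z_um"]].to_numpy(),
        )
        if cell == reference_cell_id:
            reference = traj
        else:
            trajectories.append(traj)
    return TrackDataset(
        trajectories=trajectories,
        reference=reference,
        frame_interval=frame_interval,
        voxel_size=voxel_size,
    )


def write_track_table(dataset: TrackDataset, path: str | Path) -> None:
    """Write a track CSV (one row per point, ordered by embryo, cell, t).

    Floats are written with Python's shortest round-trip representation,
    so ``read_track_table(write_track_table(D))`` reproduces every
    coordinate bit-exactly and two writes of the same dataset are
    byte-identical.
    """
    rows = []
    trajs = list(dataset.trajectories)
    if dataset.reference is not None:
        ref = dataset.reference
        trajs = trajs + [
            Trajectory(ref.embryo_id, REFERENCE_CELL_ID, Region.UNASSIGNED,
                       ref.times, ref.positions)
        ]
    for tr in sorted(trajs, key=lambda tr: (tr.embryo_id, tr.cell_id)):
        for t, (x, y, z) in zip(tr.times, tr.positions):
            rows.append((tr.embryo_id, tr.cell_id, tr.region.value,
                         repr(float(t)), repr(float(x)), repr(float(y)), repr(float(z))))
    out = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    out.to_csv(path, index=False, lineterminator="\n")


def read_label_volume(
    path: str | Path, voxel_size: tuple[float, float, float],
    embryo_id: str = "", t: float = 0.0,
) -> list[LabeledCellMask]:
    """Read a multi-page TIFF label volume into one mask per nonzero label."""
    path = Path(path)
    vol = tifffile.imread(path)
    return masks_from_label_array(vol, voxel_size, embryo_id=embryo_id, t=t,
                                  source=str(path))


def masks_from_label_array(
    vol: np.ndarray, voxel_size: tuple[float, float, float],
    embryo_id: str = "", t: float = 0.0, source: str = "<array>",
) -> list[LabeledCellMask]:
    vol = np.asarray(vol)
    if vol.ndim == 2:
        vol = vol[None, :, :]
    if vol.ndim != 3:
        raise FormatError(f"{source}: expected a 2-D or 3-D volume, got {vol.ndim}-D")
    if not np.issubdtype(vol.dtype, np.integer) and not vol.dtype == bool:
        raise FormatError(
            f"{source}: label volume must hold integer labels, got dtype {vol.dtype}"
        )
    labels = np.unique(vol)
    labels = labels[labels != 0]
    if labels.size == 0:
        warnings.warn(f"{source}: label volume contains no nonzero labels")
        return []
    return [
        LabeledCellMask(
            occupancy=vol == lab, voxel_size=voxel_size,
            cell_id=str(int(lab)), embryo_id=embryo_id, t=t,
        )
        for lab in labels
    ]


def write_label_volume(masks: Sequence[LabeledCellMask], path: str | Path) -> None:
    """Write masks as a single multi-page TIFF with integer labels.

    ``cell_id`` values must be integer-like; overlapping masks are
    rejected.
    """
    if not masks:
        raise ValidationError("cannot write an empty mask collection")
    shape = masks[0].occupancy.shape
    vol = np.zeros(shape, dtype=np.uint16)
    for m in masks:
        if m.occupancy.shape != shape:
            raise ValidationError("all masks must share one voxel grid")
        lab = int(m.cell_id)
        if lab <= 0:
            raise ValidationError("label cell_id values must be positive integers")
        if np.any(vol[m.occupancy] != 0):
            raise ValidationError("overlapping masks cannot share a label volume")
        vol[m.occupancy] = lab
    tifffile.imwrite(path, vol, photometric="minisblack")


def read_filopodia_table(
    path: str | Path, dialect: Mapping[str, str] | None = None,
) -> list[FilopodiumTrace]:
    """Read a filopodia polyline annotation CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "filopodium_id": str, "target": str},
                     float_precision="round_trip")
    df = _remap(df, FILOPODIA_COLUMNS, dialect, path)
    df = _check_numeric(df, ["t_min", "x_um", "y_um"], path)
    traces: list[FilopodiumTrace] = []
    keys = ["cell_id", "t_min", "filopodium_id"]
    for (cell, t, fid), g in df.groupby(keys, sort=True):
        g = g.sort_values("vertex_index", kind="mergesort")
        target = g["target"].iloc[0]
        target = None if pd.isna(target) or target == "" else target
        traces.append(
            FilopodiumTrace(
                cell_id=str(cell), t=float(t),
                vertices=g[["x_um", "y_um"]].to_numpy(),
                target=target, filopodium_id=str(fid),
            )
        )
    return traces


def write_filopodia_table(traces: Sequence[FilopodiumTrace], path: str | Path) -> None:
    rows = []
    for tr in sorted(traces, key=lambda tr: (tr.cell_id, tr.t, tr.filopodium_id)):
        for i, (x, y) in enumerate(tr.vertices):
            rows.append((
                tr.cell_id, repr(float(tr.t)), tr.filopodium_id, i,
                repr(float(x)), repr(float(y)),
                "" if tr.target is None else tr.target.value,
            ))
    pd.DataFrame(rows, columns=FILOPODIA_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_pair_table(
    path: str | Path, dataset: TrackDataset,
    dialect: Mapping[str, str] | None = None,
) -> list[CellPairRecord]:
    """Read a pair annotation CSV and resolve cells against ``dataset``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"pair_id": str, "embryo_id": str,
                                  "cell_id_a": str, "cell_id_b": str,
                                  "pair_class": str},
                     float_precision="round_trip")
    df = _remap(df, PAIR_COLUMNS, dialect, path)
    df = _check_numeric(df, ["t_start_min", "t_end_min"], path)
    records: list[CellPairRecord] = []
    for row in df.itertuples(index=False):
        try:
            a = dataset.get(str(row.embryo_id), str(row.cell_id_a))
            b = dataset.get(str(row.embryo_id), str(row.cell_id_b))
        except KeyError as exc:
            raise ValidationError(
                f"{path}: pair {row.pair_id!r} references an unknown cell: {exc}"
            ) from exc
        records.append(
            CellPairRecord(
                pair_id=str(row.pair_id), a=a, b=b,
                pair_class=row.pair_class,
                window=(float(row.t_start_min), float(row.t_end_min)),
            )
        )
    return records


def write_pair_table(records: Sequence[CellPairRecord], path: str | Path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.pair_id):
        lo, hi = r.window if r.window is not None else (
            max(r.a.times[0], r.b.times[0]), min(r.a.times[-1], r.b.times[-1]))
        rows.append((r.pair_id, r.a.embryo_id, r.a.cell_id, r.b.cell_id,
                     r.pair_class.value, repr(float(lo)), repr(float(hi))))
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )
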