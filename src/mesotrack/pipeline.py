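"""End-to-end report assembly from input files.

A run consumes whichever inputs the configuration names — a track CSV
(with optional embryo-contour reference for drift correction), a pair
annotation CSV, a label-volume TIFF and a filopodia CSV — and writes a
deterministic TSV report bundle plus a plain-text log recording every
decision (test chosen per metric, cells flagged and why).  Any stage
error aborts the run with a stage-tagged message and removes partial
outputs.
"""

from __future__ import annotations

import dataclasses
import shutil
import tempfile
from pathlib import Path

import pandas as pd

from . import drift, io, metrics, morphometry, pairs as pairmod, report
from .model import ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

TRACK_METRICS = [
    "net_displacement_um", "travel_displacement_um", "straightness",
    "mean_speed_um_min",
]
SHAPE_METRICS = ["volume_um3", "surface_um2", "axis_ratio"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass
class PipelineConfig:
    """File inputs and options for one pipeline run."""

    tracks: str | None = None
    pairs: str | None = None
    masks: str | None = None
    filopodia: str | None = None
    output_dir: str = "mesotrack_report"
    drift_correction: bool = True
    voxel_size: tuple[float, float, float] = (3.0, 1.0, 1.0)
    frame_interval: float = 20.0
    alpha: float = 0.05
    group_col: str = "region"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.alpha <= 0 or self.alpha >= 1:
            raise ValidationError("frame_interval and alpha must be positive (alpha < 1)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size components must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "voxel_size" in d:
            d = dict(d)
            d["voxel_size"] = tuple(float(v) for v in d["voxel_size"])
        return cls(**d)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage with an input and write the report bundle.

    Returns the output directory.  Outputs are assembled in a temporary
    directory and moved into place only on success, so a failed run
    leaves no partial report.
    """
    for name in ("tracks", "pairs", "masks", "filopodia"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise PipelineError("config", f"input file not found: {p}")
    out_dir = Path(config.output_dir)
    log: list[str] = [f"config: {dataclasses.asdict(config)}"]
    tmp = Path(tempfile.mkdtemp(prefix="mesotrack_"))
    try:
        dataset = None
        if config.tracks is not None:
            try:
                dataset = io.read_track_table(
                    config.tracks, frame_interval=config.frame_interval,
                    voxel_size=config.voxel_size,
                )
            except (ValidationError, OSError) as exc:
                raise PipelineError("tracks", str(exc)) from exc
            log.append(f"tracks: read {len(dataset)} trajectories from {config.tracks}")
            if config.drift_correction:
                if dataset.reference is None:
                    log.append("drift: no reference track; correction skipped")
                else:
                    model = drift.estimate_drift(dataset.reference)
                    try:
                        dataset = drift.apply_correction(dataset, model)
                    except ValidationError as exc:
                        raise PipelineError("drift", str(exc)) from exc
                    model.to_csv(tmp / "drift_model.csv")
                    log.append("drift: translation correction applied from reference track")
            else:
                log.append("drift: correction disabled by config")

            summaries = metrics.summarize_tracks(dataset)
            for row in summaries.itertuples(index=False):
                if row.note:
                    log.append(f"tracks: cell {row.cell_id!r} flagged: {row.note}")
            _write_tsv(summaries, tmp / "track_summaries.tsv")

            groups = summaries[config.group_col].dropna().unique()
            if len(groups) == 2:
                try:
                    cmp = report.compare_table(
                        summaries, TRACK_METRICS,
                        group_col=config.group_col, alpha=config.alpha,
                    )
                except ValidationError as exc:
                    raise PipelineError("compare", str(exc)) from exc
                for row in cmp.itertuples(index=False):
                    log.append(
                        f"compare: {row.metric}: {row.test_used} "
                        f"p={row.p_value:.3e}"
                    )
                _write_tsv(cmp, tmp / "track_group_comparisons.tsv")
            else:
                log.append(
                    f"compare: {len(groups)} group(s) present; comparison skipped"
                )

        if config.pairs is not None:
            if dataset is None:
                raise PipelineError("pairs", "pair analysis requires a track table")
            try:
                records = io.read_pair_table(config.pairs, dataset)
                psum = pairmod.summarize_pairs(dataset, records)
            except ValidationError as exc:
                raise PipelineError("pairs", str(exc)) from exc
            log.append(f"pairs: {len(records)} pair(s) from {config.pairs}")
            _write_tsv(psum, tmp / "pair_summaries.tsv")
            _write_tsv(pairmod.pair_class_aggregates(psum),
                       tmp / "pair_class_aggregates.tsv")

        if config.masks is not None:
            try:
                masks = io.read_label_volume(config.masks, config.voxel_size)
                shapes = morphometry.summarize_shapes(masks)
            except (ValidationError, OSError) as exc:
                raise PipelineError("shape", str(exc)) from exc
            log.append(f"shape: {len(masks)} mask(s) from {config.masks}")
            _write_tsv(shapes, tmp / "shape_summaries.tsv")

        if config.filopodia is not None:
            try:
                traces = io.read_filopodia_table(config.filopodia)
                counts = morphometry.filopodia_per_cell(traces)
                lengths = morphometry.filopodia_lengths(traces)
            except (ValidationError, OSError) as exc:
                raise PipelineError("filopodia", str(exc)) from exc
            log.append(f"filopodia: {len(traces)} trace(s) from {config.filopodia}")
            _write_tsv(counts, tmp / "filopodia_counts.tsv")
            _write_tsv(lengths, tmp / "filopodia_lengths.tsv")

        (tmp / "run_log.txt").write_text("\n".join(log) + "\n")
        out_dir.mkdir(parents=True, exist_ok=True)
        for f in sorted(tmp.iterdir()):
            shutil.copy2(f, out_dir / f.name)
        return out_dir
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
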