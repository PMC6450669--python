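"""Data model invariants and file round-trips."""

import numpy as np
import pytest

from mesotrack import io
from mesotrack.model import (
    FilopodiumTrace,
    FormatError,
    LabeledCellMask,
    Region,
    TrackDataset,
    TrackPoint,
    Trajectory,
    ValidationError,
)

from conftest import make_traj, random_dataset

TRACK_CSV = """embryo_id,cell_id,region,t_min,x_um,y_um,z_um
E1,A,embryonic,0,0.0,0.0,0.0
E1,A,embryonic,20,1.5,0.0,0.0
E1,A,embryonic,40,3.0,0.5,0.0
E1,A,embryonic,60,4.5,0.5,0.0
E1,A,embryonic,80,6.0,1.0,0.0
E1,A,embryonic,100,7.5,1.0,0.0
E1,A,embryonic,120,9.0,1.5,0.0
E1,A,embryonic,140,10.5,1.5,0.0
E1,B,extra_embryonic,0,0.0,0.0,5.0
E1,B,extra_embryonic,20,0.5,0.5,5.0
E1,B,extra_embryonic,40,1.0,0.0,5.0
E1,B,extra_embryonic,60,0.5,0.5,5.0
E1,B,extra_embryonic,80,0.0,0.0,5.0
E1,B,extra_embryonic,100,0.5,0.5,5.0
E1,B,extra_embryonic,120,1.0,0.0,5.0
E1,B,extra_embryonic,140,0.5,0.5,5.0
"""


class TestModelInvariants:
    def test_track_point_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            TrackPoint(t=0.0, x=np.nan, y=0.0, z=0.0)

    def test_trajectory_rejects_duplicate_timepoint(self):
        with pytest.raises(ValidationError, match="cell_x"):
            make_traj([[0, 0, 0], [1, 0, 0]], times=[0.0, 0.0], cell_id="cell_x")

    def test_trajectory_rejects_decreasing_time(self):
        with pytest.raises(ValidationError):
            make_traj([[0, 0, 0], [1, 0, 0]], times=[20.0, 0.0])

    def test_dataset_rejects_duplicate_cell(self):
        tr = make_traj([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValidationError):
            TrackDataset(trajectories=[tr, tr])

    def test_dataset_rejects_nonpositive_interval(self):
        with pytest.raises(ValidationError):
            TrackDataset(trajectories=[], frame_interval=0.0)

    def test_mask_rejects_empty(self):
        with pytest.raises(ValidationError):
            LabeledCellMask(np.zeros((3, 3, 3), bool), (1, 1, 1), "c")

    def test_filopodium_rejects_duplicate_vertices(self):
        with pytest.raises(ValidationError):
            FilopodiumTrace("c", 0.0, [[0, 0], [0, 0], [1, 1]])


class TestTrackTable:
    def test_parses_two_cells_of_eight_points(self, tmp_path):
        p = tmp_path / "tracks.csv"
        p.write_text(TRACK_CSV)
        ds = io.read_track_table(p)
        assert len(ds) == 2
        assert all(tr.n_points == 8 for tr in ds)
        a = ds.get("E1", "A")
        assert a.region is Region.EMBRYONIC
        assert a.times[0] == 0.0 and a.times[-1] == 140.0

    def test_duplicate_timepoint_names_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "embryo_id,cell_id,region,t_min,x_um,y_um,z_um\n"
            "E1,A,embryonic,0,0,0,0\nE1,A,embryonic,0,1,0,0\n"
        )
        with pytest.raises(ValidationError, match="'A'"):
            io.read_track_table(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("embryo_id,cell_id,region,t_min,x_um,y_um\nE1,A,embryonic,0,0,0\n")
        with pytest.raises(FormatError, match="z_um"):
            io.read_track_table(p)

    def test_non_numeric_rows_enumerated_not_dropped(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "embryo_id,cell_id,region,t_min,x_um,y_um,z_um\n"
            "E1,A,embryonic,0,0,0,0\nE1,A,embryonic,20,oops,0,0\n"
        )
        with pytest.raises(FormatError, match=r"1 row\(s\)"):
            io.read_track_table(p)

    def test_scientific_notation_accepted(self, tmp_path):
        p = tmp_path / "sci.csv"
        p.write_text(
            "embryo_id,cell_id,region,t_min,x_um,y_um,z_um\n"
            "E1,A,embryonic,0,1e1,0,0\nE1,A,embryonic,2e1,1.5E1,0,0\n"
        )
        ds = io.read_track_table(p)
        assert ds.get("E1", "A").positions[1, 0] == 15.0

    def test_dialect_remaps_foreign_columns(self, tmp_path):
        p = tmp_path / "foreign.csv"
        p.write_text(
            "Embryo,Track,Compartment,Time,PosX,PosY,PosZ\n"
            "E1,A,embryonic,0,0,0,0\nE1,A,embryonic,20,1,0,0\n"
        )
        dialect = {"embryo_id": "Embryo", "cell_id": "Track",
                   "region": "Compartment", "t_min": "Time",
                   "x_um": "PosX", "y_um": "PosY", "z_um": "PosZ"}
        ds = io.read_track_table(p, dialect=dialect)
        assert len(ds) == 1

    def test_round_trip_is_bit_exact_and_deterministic(self, tmp_path, rng):
        ds = random_dataset(rng, n_cells=3, n_points=8)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_track_table(ds, p1)
        back = io.read_track_table(p1)
        for tr in ds:
            tr2 = back.get(tr.embryo_id, tr.cell_id)
            np.testing.assert_array_equal(tr.times, tr2.times)
            np.testing.assert_array_equal(tr.positions, tr2.positions)
        io.write_track_table(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_dataset_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        io.write_track_table(TrackDataset(trajectories=[]), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == list(io.TRACK_COLUMNS)

    def test_row_count_equals_point_count(self, tmp_path, rng):
        ds = random_dataset(rng, n_cells=3, n_points=5)
        p = tmp_path / "t.csv"
        io.write_track_table(ds, p)
        assert len(p.read_text().strip().splitlines()) == 1 + 3 * 5

    def test_reference_track_round_trips(self, tmp_path, rng):
        ds = random_dataset(rng, n_cells=2)
        ds.reference = make_traj(np.zeros((6, 3)), cell_id=io.REFERENCE_CELL_ID)
        p = tmp_path / "r.csv"
        io.write_track_table(ds, p)
        back = io.read_track_table(p)
        assert back.reference is not None
        assert len(back) == 2


class TestLabelVolume:
    def test_two_labels_two_masks(self, tmp_path):
        vol = np.zeros((4, 8, 8), dtype=np.uint16)
        vol[1:3, 1:4, 1:4] = 1
        vol[1:3, 5:7, 5:7] = 2
        import tifffile
        p = tmp_path / "labels.tif"
        tifffile.imwrite(p, vol, photometric="minisblack")
        masks = io.read_label_volume(p, (3.0, 1.0, 1.0))
        assert [m.cell_id for m in masks] == ["1", "2"]
        assert masks[0].n_voxels == 2 * 3 * 3

    def test_all_zero_volume_warns_and_returns_empty(self, tmp_path):
        import tifffile
        p = tmp_path / "zero.tif"
        tifffile.imwrite(p, np.zeros((2, 4, 4), dtype=np.uint8), photometric="minisblack")
        with pytest.warns(UserWarning):
            masks = io.read_label_volume(p, (1, 1, 1))
        assert masks == []

    def test_non_integer_volume_rejected(self):
        with pytest.raises(FormatError, match="integer"):
            io.masks_from_label_array(np.ones((2, 2, 2), dtype=float), (1, 1, 1))

    def test_ellipsoid_round_trip_preserves_voxel_count(self, tmp_path):
        from mesotrack.synthetic import rasterize_ellipsoid
        m = rasterize_ellipsoid((6, 4, 4), voxel_size=(1, 1, 1))
        p = tmp_path / "e.tif"
        io.write_label_volume([m], p)
        back = io.read_label_volume(p, (1, 1, 1))
        assert len(back) == 1
        assert back[0].n_voxels == m.n_voxels


class TestFilopodiaTable:
    def test_round_trip(self, tmp_path):
        traces = [
            FilopodiumTrace("c1", 0.0, [[0, 0], [3, 4]], target="epiblast",
                            filopodium_id="f000"),
            FilopodiumTrace("c1", 20.0, [[1, 1], [2, 2], [3, 1]],
                            target="visceral_endoderm", filopodium_id="f001"),
            FilopodiumTrace("c2", 0.0, [[0, 0], [0, 5]], filopodium_id="f000"),
        ]
        p = tmp_path / "filo.csv"
        io.write_filopodia_table(traces, p)
        back = io.read_filopodia_table(p)
        assert len(back) == 3
        got = {(t.cell_id, t.t, t.filopodium_id): t for t in back}
        orig = {(t.cell_id, t.t, t.filopodium_id): t for t in traces}
        assert got.keys() == orig.keys()
        for k in orig:
            np.testing.assert_array_equal(got[k].vertices, orig[k].vertices)
            assert got[k].target == orig[k].target
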