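"""STAR I/O, filament grouping, co-occurrence, and trace-plot export."""

import numpy as np
import pandas as pd
import pytest

from fibrilstab import (
    ClassMixture,
    SyntheticStarSpec,
    cooccurrence_summary,
    export_trace_plot,
    group_filaments,
    make_star_fixture,
    read_star,
    write_star,
)
from fibrilstab.tracing import StarFormatError, StarSchemaError, TracedFilament

HAND_STAR = """\
data_particles

loop_
_rlnMicrographName
_rlnCoordinateX
_rlnCoordinateY
mic_a.mrc 100.5 200.25
mic_a.mrc 150.0 210.0
mic_b.mrc 50.0 60.0
"""

TWO_BLOCK_STAR = """\
data_optics

loop_
_rlnOpticsGroup
_rlnImagePixelSize
1 1.05

data_particles

loop_
_rlnMicrographName
_rlnCoordinateX
_rlnCoordinateY
_rlnHelicalTubeID
_rlnClassNumber
mic_a.mrc 10.0 20.0 1 1
mic_a.mrc 40.0 20.0 1 2
mic_a.mrc 10.0 90.0 2 1
"""


class TestReadStar:
    def test_hand_written_rows_echoed(self, tmp_path):
        p = tmp_path / "hand.star"
        p.write_text(HAND_STAR)
        df = read_star(p)
        assert len(df) == 3
        assert df.loc[0, "micrograph"] == "mic_a.mrc"
        assert df.loc[0, "x"] == pytest.approx(100.5)
        assert df.loc[0, "y"] == pytest.approx(200.25)
        assert "tube" not in df.columns  # absent column tolerated

    def test_particles_block_selected_among_two_blocks(self, tmp_path):
        p = tmp_path / "two.star"
        p.write_text(TWO_BLOCK_STAR)
        df = read_star(p)
        assert len(df) == 3
        assert set(df["tube"].astype(int)) == {1, 2}
        assert set(df["class_label"].astype(int)) == {1, 2}

    def test_round_trip_of_synthetic_fixture(self, tmp_path):
        particles, _ = make_star_fixture(SyntheticStarSpec(n_micrographs=2, seed=4))
        p = tmp_path / "synthetic.star"
        write_star(particles, p)
        back = read_star(p)
        assert len(back) == len(particles)
        np.testing.assert_allclose(back["x"], particles["x"], atol=1e-6)
        assert (back["class_label"].astype(int) == particles["class_label"]).all()

    def test_missing_coordinates_named(self, tmp_path):
        p = tmp_path / "bad.star"
        p.write_text(
            "data_particles\nloop_\n_rlnMicrographName\n_rlnCoordinateX\nm.mrc 1.0\n"
        )
        with pytest.raises(StarSchemaError, match="rlnCoordinateY"):
            read_star(p)

    def test_no_particles_loop_raises(self, tmp_path):
        p = tmp_path / "empty.star"
        p.write_text("data_something\n_oneValue 3\n")
        with pytest.raises(StarFormatError):
            read_star(p)


class TestGroupFilaments:
    def test_single_tube_single_filament(self):
        df = pd.DataFrame(
            {
                "micrograph": ["m"] * 4,
                "x": [0.0, 10.0, 20.0, 30.0],
                "y": [0.0] * 4,
                "tube": [1] * 4,
                "class_label": [1, 1, 2, 1],
            }
        )
        fil = group_filaments(df, "TUBE_ID")
        assert len(fil) == 1
        assert fil[0].n_segments == 4
        assert fil[0].class_counts == {1: 3, 2: 1}

    def test_known_filament_count_recovered(self):
        spec = SyntheticStarSpec(n_micrographs=4, filaments_per_micrograph=7, seed=2)
        particles, truth = make_star_fixture(spec)
        fil = group_filaments(particles, "TUBE_ID")
        assert len(fil) == len(truth) == 28

    def test_conservation_of_segments(self):
        particles, _ = make_star_fixture(SyntheticStarSpec(n_micrographs=3, seed=8))
        fil = group_filaments(particles, "TUBE_ID")
        assert sum(f.n_segments for f in fil) == len(particles)

    def test_proximity_mode_does_not_merge_distant_filaments(self):
        # two parallel filaments 5x the threshold apart
        t = np.arange(10) * 20.0
        df = pd.DataFrame(
            {
                "micrograph": ["m"] * 20,
                "x": np.concatenate([t, t]),
                "y": np.concatenate([np.zeros(10), np.full(10, 150.0)]),
                "class_label": [1] * 10 + [2] * 10,
            }
        )
        fil = group_filaments(df, "PROXIMITY", threshold=30.0)
        assert len(fil) == 2
        assert all(len(f.class_counts) == 1 for f in fil)

    def test_proximity_requires_threshold(self):
        df = pd.DataFrame({"micrograph": ["m"], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="threshold"):
            group_filaments(df, "PROXIMITY")

    def test_segments_ordered_along_path(self):
        rng = np.random.default_rng(0)
        t = np.arange(12) * 15.0
        perm = rng.permutation(12)
        df = pd.DataFrame(
            {
                "micrograph": ["m"] * 12,
                "x": t[perm],
                "y": 0.3 * t[perm],
                "tube": [1] * 12,
            }
        )
        fil = group_filaments(df, "TUBE_ID")
        x = fil[0].segments["x"].to_numpy()
        assert (np.diff(x) > 0).all() or (np.diff(x) < 0).all()

    def test_grouping_idempotent(self):
        particles, _ = make_star_fixture(SyntheticStarSpec(n_micrographs=2, seed=3))
        fil = group_filaments(particles, "TUBE_ID")
        regrouped = group_filaments(
            pd.concat([f.segments for f in fil], ignore_index=True), "TUBE_ID"
        )
        assert len(regrouped) == len(fil)
        assert sorted(f.n_segments for f in regrouped) == sorted(
            f.n_segments for f in fil
        )


class TestCooccurrence:
    def test_single_class_zero_mixed(self):
        spec = SyntheticStarSpec(
            n_micrographs=2,
            class_mixture=ClassMixture(p_pure_a=1.0, p_pure_b=0.0, p_mixed=0.0),
            seed=6,
        )
        particles, _ = make_star_fixture(spec)
        summary = cooccurrence_summary(group_filaments(particles, "TUBE_ID"))
        assert summary.n_mixed == 0
        assert summary.mixed_fraction == 0.0

    def test_full_coverage_mixed_fraction_exact(self):
        spec = SyntheticStarSpec(
            n_micrographs=10, filaments_per_micrograph=10,
            unassigned_fraction=0.0, seed=13,
        )
        particles, truth = make_star_fixture(spec)
        summary = cooccurrence_summary(group_filaments(particles, "TUBE_ID"))
        assert summary.n_mixed == int(truth["true_mixed"].sum())
        assert summary.mixed_fraction == pytest.approx(truth["true_mixed"].mean())

    def test_partial_coverage_is_lower_bound(self):
        spec = SyntheticStarSpec(
            n_micrographs=10, filaments_per_micrograph=10,
            unassigned_fraction=0.5, seed=21,
        )
        particles, truth = make_star_fixture(spec)
        summary = cooccurrence_summary(group_filaments(particles, "TUBE_ID"))
        assert summary.n_mixed <= int(truth["true_mixed"].sum())
        assert "lower bound" in summary.caveat

    def test_no_labels_anywhere_rejected(self):
        df = pd.DataFrame(
            {"micrograph": ["m"] * 2, "x": [0.0, 10.0], "y": [0.0, 0.0],
             "tube": [1, 1]}
        )
        with pytest.raises(ValueError):
            cooccurrence_summary(group_filaments(df, "TUBE_ID"))


class TestExportTracePlot:
    def test_two_class_series(self, tmp_path):
        particles, _ = make_star_fixture(SyntheticStarSpec(n_micrographs=1, seed=1))
        fil = group_filaments(particles, "TUBE_ID")
        mic = fil[0].micrograph
        table = export_trace_plot(fil, mic, out_png=tmp_path / "trace.png")
        assert set(table["class_label"].dropna()) <= {1, 2}
        assert len(table) == sum(f.n_segments for f in fil)
        assert (tmp_path / "trace.png").exists()

    def test_unknown_micrograph_raises(self):
        particles, _ = make_star_fixture(SyntheticStarSpec(n_micrographs=1, seed=1))
        fil = group_filaments(particles, "TUBE_ID")
        with pytest.raises(KeyError):
            export_trace_plot(fil, "nope.mrc")

    def test_empty_filament_gives_empty_series(self):
        empty = TracedFilament(
            "m.mrc", 1,
            pd.DataFrame(columns=["micrograph", "x", "y", "class_label"]),
        )
        table = export_trace_plot([empty], "m.mrc")
        assert table.empty

    def test_fifteen_micrographs_all_exportable(self):
        particles, _ = make_star_fixture(
            SyntheticStarSpec(n_micrographs=15, filaments_per_micrograph=3, seed=2)
        )
        fil = group_filaments(particles, "TUBE_ID")
        mics = sorted({f.micrograph for f in fil})
        assert len(mics) == 15
        for mic in mics:
            assert not export_trace_plot(fil, mic).empty
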