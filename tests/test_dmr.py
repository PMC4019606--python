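"""Probability tracks: kernel smoothing, window averaging, region means, I/O."""

import numpy as np
import pytest

from betadiff.dmr import (
    GenomicInterval,
    PositionTrack,
    read_bed3,
    region_mean,
    smooth_track,
    window_average,
    write_bedgraph,
)


def make_track(values, spacing=100, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    return PositionTrack(chrom, 1 + spacing * np.arange(values.size), values)


class TestTrackValidation:
    def test_rejects_bad_tracks(self):
        with pytest.raises(ValueError):
            PositionTrack("chr1", np.array([1, 1]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            PositionTrack("chr1", np.array([1, 2]), np.array([0.5, 1.5]))
        with pytest.raises(ValueError):
            PositionTrack("chr1", np.array([], dtype=int), np.array([]))
        with pytest.raises(ValueError):
            PositionTrack("chr1", np.array([0]), np.array([0.5]))

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)


class TestSmoothing:
    def test_constant_track_fixed_point(self):
        track = make_track([0.3] * 50)
        for bandwidth in (1.0, 100.0, 1e5):
            assert np.allclose(smooth_track(track, bandwidth).values, 0.3)

    def test_sub_gap_bandwidth_is_identity(self):
        rng = np.random.default_rng(4)
        track = make_track(rng.random(100), spacing=100)
        # min gap 100: bandwidth 10 puts every neighbour beyond 4 bandwidths
        out = smooth_track(track, 10.0)
        assert np.array_equal(out.values, track.values)

    def test_two_point_equal_weight_limit(self):
        track = PositionTrack("chr1", np.array([100, 200]), np.array([0.0, 1.0]))
        out = smooth_track(track, 1e6)
        assert np.allclose(out.values, [0.5, 0.5], atol=1e-6)

    def test_values_stay_in_unit_interval(self):
        rng = np.random.default_rng(77)
        track = make_track(rng.random(500), spacing=10)
        out = smooth_track(track, 35.0)
        assert ((out.values >= 0) & (out.values <= 1)).all()

    def test_commutes_with_coordinate_reversal(self):
        rng = np.random.default_rng(13)
        values = rng.random(80)
        track = make_track(values, spacing=50)
        flipped_positions = track.positions.max() + 1 - track.positions[::-1]
        flipped = PositionTrack("chr1", flipped_positions, values[::-1])
        assert np.allclose(
            smooth_track(flipped, 120.0).values,
            smooth_track(track, 120.0).values[::-1],
            atol=1e-12,
        )

    def test_rejects_non_positive_bandwidth(self):
        with pytest.raises(ValueError):
            smooth_track(make_track([0.5]), 0.0)


class TestWindowAverage:
    def test_window_one_is_identity(self):
        track = make_track([0.1, 0.9, 0.4])
        assert window_average(track, 1) is track

    def test_full_block_mean(self):
        out = window_average(make_track([0.2, 0.4, 0.9]), 3)
        assert len(out) == 1
        assert out.values[0] == pytest.approx(0.5)
        assert out.positions[0] == 1

    def test_trailing_partial_block(self):
        out = window_average(make_track([0.2, 0.4, 0.9, 0.1]), 3)
        assert np.allclose(out.values, [0.5, 0.1])
        assert list(out.positions) == [1, 301]

    def test_conserves_total_mass(self):
        rng = np.random.default_rng(31)
        track = make_track(rng.random(1000))
        for window in (1, 3, 7, 64):
            out = window_average(track, window)
            sizes = np.minimum(window, len(track) - np.arange(0, len(track), window))
            assert np.dot(out.values, sizes) == pytest.approx(
                track.values.sum(), abs=1e-12
            )

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError):
            window_average(make_track([0.5]), 0)


class TestRegionMean:
    def test_whole_track_region_gives_global_mean(self):
        track = make_track([0.2, 0.4, 0.9])
        region = GenomicInterval("chr1", 1, int(track.positions[-1]) + 1)
        assert region_mean(track, [region])[0] == pytest.approx(track.values.mean())

    def test_uncovered_region_reports_no_data(self):
        track = make_track([0.2, 0.4])
        assert np.isnan(region_mean(track, [GenomicInterval("chr1", 5000, 6000)])[0])

    def test_partition_recombines_to_global_mean(self):
        rng = np.random.default_rng(55)
        track = make_track(rng.random(200))
        cut = int(track.positions[120])
        left = GenomicInterval("chr1", 1, cut)
        right = GenomicInterval("chr1", cut, int(track.positions[-1]) + 1)
        means = region_mean(track, [left, right])
        n_left = (track.positions < cut).sum()
        combined = (means[0] * n_left + means[1] * (len(track) - n_left)) / len(track)
        assert combined == pytest.approx(track.values.mean(), abs=1e-12)

    def test_half_open_boundary(self):
        track = make_track([0.1, 0.9], spacing=100)  # positions 1, 101
        assert region_mean(track, [GenomicInterval("chr1", 1, 101)])[0] == pytest.approx(0.1)

    def test_chromosome_mismatch(self):
        with pytest.raises(ValueError):
            region_mean(make_track([0.5]), [GenomicInterval("chr2", 1, 10)])


class TestGenomicIO:
    def test_bedgraph_is_zero_based_half_open(self, tmp_path):
        track = PositionTrack("chr9", np.array([1, 50]), np.array([0.25, 1.0]))
        path = tmp_path / "track.bedgraph"
        write_bedgraph(track, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "chr9\t0\t1\t0.25"
        assert lines[1] == "chr9\t49\t50\t1"

    def test_bed3_roundtrip_against_track_coordinates(self, tmp_path):
        path = tmp_path / "regions.bed"
        path.write_text("# comment\nchr1\t0\t100\nchr1\t100\t250\n")
        regions = read_bed3(path)
        # BED [0,100) covers 1-based positions 1..100
        assert (regions[0].start, regions[0].end) == (1, 101)
        assert (regions[1].start, regions[1].end) == (101, 251)
        track = make_track([0.2, 0.8], spacing=100)  # positions 1, 101
        means = region_mean(track, regions)
        assert means[0] == pytest.approx(0.2)
        assert means[1] == pytest.approx(0.8)

    def test_bed3_malformed(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t5\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed3(path)
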