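import numpy as np
import pytest

import regulomap as rm
from regulomap.tracks import track_table


def make_track(counts, bin_size=25, genome_length=None):
    counts = np.asarray(counts, dtype=float)
    if genome_length is None:
        genome_length = counts.size * bin_size
    return rm.BinnedTrack(counts, genome_length, bin_size)


class TestBinnedTrack:
    def test_bin_grid_and_centers(self):
        t = make_track([0, 0, 0], genome_length=60)  # final partial bin kept
        assert t.n_bins == 3
        assert list(t.bin_ends) == [25, 50, 60]
        assert list(t.bin_centers) == [13, 38, 55]

    def test_wrong_bin_count_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            rm.BinnedTrack(np.zeros(3), genome_length=100, bin_size=25)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_track([1, -1])


class TestReadBedgraph:
    def test_empty_file_gives_zero_track(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        t = rm.read_bedgraph(p, genome_length=100, bin_size=25)
        assert t.n_bins == 4
        assert np.all(t.counts == 0)

    @pytest.mark.parametrize(
        "record,expected",
        [
            ("chr\t0\t25\t7", [7, 0, 0, 0]),  # exactly bin 1
            ("chr\t13\t63\t10", [2.4, 5.0, 2.6, 0]),  # overlap apportionment
            ("chr\t25\t75\t10", [0, 5, 5, 0]),  # two bins equally
        ],
    )
    def test_overlap_apportionment(self, tmp_path, record, expected):
        p = tmp_path / "t.bedgraph"
        p.write_text(record + "\n")
        t = rm.read_bedgraph(p, genome_length=100, bin_size=25)
        np.testing.assert_allclose(t.counts, expected, atol=1e-12)

    def test_interval_beyond_genome_names_line(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr\t0\t25\t1\nchr\t90\t120\t1\n")
        with pytest.raises(ValueError, match=":2"):
            rm.read_bedgraph(p, genome_length=100)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "neg.bedgraph"
        p.write_text("chr\t0\t25\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            rm.read_bedgraph(p, genome_length=100)

    def test_binning_conserves_total_count(self, tmp_path, rng):
        # random intervals: sum of binned counts equals sum of record values
        L = 2000
        lines, total = [], 0.0
        for _ in range(50):
            a = int(rng.integers(0, L - 1))
            b = int(rng.integers(a + 1, min(a + 120, L) + 1))
            v = float(rng.integers(0, 40))
            lines.append(f"chr\t{a}\t{b}\t{v}")
            total += v
        p = tmp_path / "r.bedgraph"
        p.write_text("\n".join(lines) + "\n")
        t = rm.read_bedgraph(p, genome_length=L)
        assert t.total() == pytest.approx(total, rel=1e-12)

    def test_roundtrip_with_writer(self, tmp_path, rng):
        t = make_track(rng.integers(0, 50, size=40))
        path = tmp_path / "rt.bedgraph"
        rm.write_bedgraph(t, path)
        back = rm.read_bedgraph(path, t.genome_length, t.bin_size)
        np.testing.assert_allclose(back.counts, t.counts)


class TestLibraryScale:
    def test_ratio_of_totals(self):
        ip = make_track([1, 1, 1])
        inp = make_track([2, 2, 2])
        assert rm.library_scale(ip, inp) == pytest.approx(0.5)
        assert rm.library_scale(ip, ip) == pytest.approx(1.0)
        assert rm.library_scale(make_track([3]), make_track([4])) == pytest.approx(0.75)

    def test_zero_input_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rm.library_scale(make_track([1, 2]), make_track([0, 0]))


class TestLocalNormalize:
    def test_constant_track_normalizes_to_one(self):
        t = make_track(np.full(50, 8.0))
        n = rm.local_normalize(t, window_bins=11)
        np.testing.assert_allclose(n.values, 1.0)

    def test_all_zero_track_stays_zero(self):
        n = rm.local_normalize(make_track(np.zeros(20)), window_bins=5)
        np.testing.assert_allclose(n.values, 0.0)

    def test_hand_computed_median_window(self):
        t = make_track([10, 10, 10, 100, 10, 10, 10])
        n = rm.local_normalize(t, window_bins=7)
        assert n.values[3] == pytest.approx(10.0)

    def test_window_validation(self):
        t = make_track([1, 2, 3])
        with pytest.raises(ValueError):
            rm.local_normalize(t, window_bins=4)
        with pytest.raises(ValueError):
            rm.local_normalize(t, window_bins=1)

    def test_depth_equivariance(self, rng):
        # doubling all counts leaves values unchanged while median >= epsilon
        counts = rng.integers(5, 50, size=300).astype(float)
        a = rm.local_normalize(make_track(counts), window_bins=41)
        b = rm.local_normalize(make_track(2 * counts), window_bins=41)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_removes_simulated_shear_field(self, sim_bundle):
        # normalization removes nearly all shear-driven variance: only the
        # Poisson counting noise survives (raw bins carry both)
        inp = sim_bundle["tracks"]["input"]
        norm = rm.local_normalize(inp, window_bins=401)
        assert norm.values.var() < 0.25 * inp.counts.var()
        # the surviving relative variance is close to the counting-noise
        # floor 1/mean_depth, far below the raw relative variance
        norm_cv2 = norm.values.var() / norm.values.mean() ** 2
        raw_cv2 = inp.counts.var() / inp.counts.mean() ** 2
        assert norm_cv2 < 3.0 / sim_bundle["config"].mean_depth
        assert norm_cv2 < raw_cv2


class TestDiffTrack:
    def test_identical_tracks_give_zero(self):
        n = rm.local_normalize(make_track([5, 6, 7, 8, 9]), window_bins=5)
        np.testing.assert_allclose(rm.diff_track(n, n), 0.0)

    def test_elementwise_difference_may_be_negative(self):
        a = rm.NormalizedTrack(np.array([10.0, 0.5]), 3, 50)
        b = rm.NormalizedTrack(np.array([1.0, 1.0]), 3, 50)
        np.testing.assert_allclose(rm.diff_track(a, b), [9.0, -0.5])

    def test_grid_mismatch_rejected(self):
        a = rm.NormalizedTrack(np.ones(2), 3, 50)
        b = rm.NormalizedTrack(np.ones(3), 3, 75)
        with pytest.raises(ValueError, match="grid"):
            rm.diff_track(a, b)


def test_track_table_columns(rng):
    t = make_track(rng.integers(0, 9, size=5))
    n = rm.local_normalize(t, window_bins=3)
    df = track_table(t, n, rm.diff_track(n, n))
    assert list(df.columns) == ["bin", "start", "end", "count", "lnorm", "diff"]
    assert len(df) == 5
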