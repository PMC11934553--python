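"""Contact-matrix I/O and balancing."""

import numpy as np
import pytest

from hictad.hic_io import (ContactMatrix, ConvergenceError, MatrixFormatError,
                           kr_normalize, normalize, read_bed_intervals,
                           read_boundaries, read_dense_matrix,
                           read_sparse_triplets, vc_normalize,
                           write_boundaries_bed, write_dense_matrix,
                           write_domains_bed)
from hictad.assembly import TADNode
from hictad.synth import SimConfig, simulate_hic


class TestDenseIO:
    def test_zero_matrix(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 0 0\n0 0 0\n0 0 0\n")
        m = read_dense_matrix(p)
        assert m.n_bins == 3
        assert np.all(m.values == 0)

    def test_symmetrized_by_averaging(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 4\n2 0\n")
        m = read_dense_matrix(p)
        assert m.values[0, 1] == m.values[1, 0] == 3.0

    def test_nan_becomes_zero(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 nan\nnan 1\n")
        assert np.all(read_dense_matrix(p).values == np.eye(2))

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2 3\n4 5 6\n")
        with pytest.raises(MatrixFormatError):
            read_dense_matrix(p)

    def test_negative_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 -2\n-2 1\n")
        with pytest.raises(ValueError):
            read_dense_matrix(p)

    def test_round_trip_planted_simulation(self, tmp_path):
        m, _ = simulate_hic(SimConfig(n_bins=10, tad_size_range=(3, 4), seed=5))
        p = tmp_path / "m.txt"
        write_dense_matrix(m, p)
        back = read_dense_matrix(p, resolution=m.resolution)
        np.testing.assert_array_equal(back.values, m.values)


class TestSparseIO:
    def test_single_entry_mirrored(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0 1 5\n")
        m = read_sparse_triplets(p, 25_000, "chr1", 3)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 5
        np.testing.assert_array_equal(m.values, expected)

    def test_basepair_autodetect_matches_bin_indexing(self, tmp_path):
        pa, pb = tmp_path / "bins.txt", tmp_path / "bp.txt"
        pa.write_text("0 1 5\n")
        pb.write_text("0 25000 5\n")
        a = read_sparse_triplets(pa, 25_000, "chr1", 3)
        b = read_sparse_triplets(pb, 25_000, "chr1", 3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_file_gives_zero_matrix(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("")
        assert np.all(read_sparse_triplets(p, 25_000, "chr1", 4).values == 0)

    def test_duplicates_summed(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0 1 2\n0 1 3\n")
        m = read_sparse_triplets(p, 25_000, "chr1", 2)
        assert m.values[0, 1] == 5

    def test_out_of_range_index(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0 7 1\n")
        with pytest.raises(ValueError):
            # 7 >= n_bins triggers bp auto-detect, but 7 % 25000 != 0
            read_sparse_triplets(p, 25_000, "chr1", 4)


class TestVC:
    def test_constant_matrix_is_fixed_point(self):
        m = ContactMatrix(np.full((4, 4), 3.0))
        out = vc_normalize(m)
        np.testing.assert_allclose(out.values, m.values)
        assert out.normalization == "VC"

    def test_hand_computed_2x2(self):
        # r = (6, 3); unscaled entries all 1/9; rescaled to total 9 -> 2.25
        m = ContactMatrix(np.array([[4.0, 2.0], [2.0, 1.0]]))
        out = vc_normalize(m)
        np.testing.assert_allclose(out.values, np.full((2, 2), 2.25))

    def test_zero_row_left_zero(self):
        v = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        out = vc_normalize(ContactMatrix(v))
        assert np.all(out.values[2] == 0) and np.all(out.values[:, 2] == 0)
        assert out.values[:2, :2].sum() > 0

    def test_mass_preserved_and_symmetric(self, rng):
        v = rng.random((20, 20))
        m = ContactMatrix(0.5 * (v + v.T))
        out = vc_normalize(m)
        assert abs(out.values.sum() - m.values.sum()) <= 1e-9 * m.values.sum()
        np.testing.assert_allclose(out.values, out.values.T)
        assert np.all(out.values >= 0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            vc_normalize(ContactMatrix(np.zeros((3, 3))))


def _ipf_oracle(values: np.ndarray, target: float, iters: int = 20000) -> np.ndarray:
    """Independent iterative proportional fitting, run to 1e-10."""
    d = np.ones(len(values))
    for _ in range(iters):
        rs = d * (values @ d)
        if np.max(np.abs(rs - target)) / target < 1e-10:
            break
        d = d * target / rs  # full (non-square-root) update, unlike the impl
        rs = d * (values @ d)
        d = d * np.sqrt(target / rs)
    return d[:, None] * values * d[None, :]


class TestKR:
    def test_constant_matrix_unchanged(self):
        m = ContactMatrix(np.full((5, 5), 2.0))
        np.testing.assert_allclose(kr_normalize(m).values, m.values, rtol=1e-6)

    def test_matches_independent_ipf_oracle(self):
        values = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        m = ContactMatrix(values)
        out = kr_normalize(m, tol=1e-9)
        target = values.sum(axis=1).mean()
        expected = _ipf_oracle(values, target)
        np.testing.assert_allclose(out.values, expected, rtol=1e-6)
        rs = out.values.sum(axis=1)
        assert np.max(np.abs(rs - rs.mean())) / rs.mean() < 1e-6

    def test_zero_row_excluded_then_restored(self):
        v = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        out = kr_normalize(ContactMatrix(v))
        assert np.all(out.values[2] == 0) and np.all(out.values[:, 2] == 0)
        rs = out.values[:2].sum(axis=1)
        assert np.max(np.abs(rs - rs.mean())) / rs.mean() < 1e-5

    def test_symmetry_and_nonnegativity(self, rng):
        v = rng.random((30, 30)) + 0.1
        out = kr_normalize(ContactMatrix(0.5 * (v + v.T)))
        np.testing.assert_allclose(out.values, out.values.T)
        assert np.all(out.values >= 0)

    def test_nonconvergence_raises(self):
        m = ContactMatrix(np.array([[100.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ConvergenceError):
            kr_normalize(m, tol=1e-14, max_iter=1)

    def test_normalize_dispatch(self):
        m = ContactMatrix(np.full((3, 3), 1.0))
        assert normalize(m, "raw") is m
        assert normalize(m, "KR").normalization == "KR"
        with pytest.raises(ValueError):
            normalize(m, "ICE")


class TestBed:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr20\t100\t200\n")
        track = read_bed_intervals(p)
        (iv,) = track.intervals
        assert (iv.chrom, iv.start, iv.end) == ("chr20", 100, 200)

    def test_sorted_and_overlaps_preserved(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t50\t60\nchr1\t500\t600\nchr1\t100\t300\nchr1\t200\t400\n")
        track = read_bed_intervals(p)
        assert len(track) == 4  # overlapping records not merged
        starts = [(iv.chrom, iv.start) for iv in track]
        assert starts == sorted(starts)

    def test_bad_interval_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t200\n")
        with pytest.raises(MatrixFormatError):
            read_bed_intervals(p)


class TestDomainsBed:
    def test_single_tad_coordinates(self, tmp_path):
        p = tmp_path / "d.bed"
        write_domains_bed([TADNode(4, 10)], 25_000, "chr20", p)
        assert p.read_text() == "chr20\t100000\t275000\t0\n"

    def test_empty_hierarchy(self, tmp_path):
        p = tmp_path / "d.bed"
        write_domains_bed([], 25_000, "chr20", p)
        assert p.read_text() == ""

    def test_parent_precedes_child_at_same_start(self, tmp_path):
        child_a, child_b = TADNode(0, 5, level=1), TADNode(5, 9, level=1)
        parent = TADNode(0, 9, children=[child_a, child_b], level=0)
        p = tmp_path / "d.bed"
        write_domains_bed([parent], 10, "chr1", p)
        lines = p.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0].split("\t") == ["chr1", "0", "100", "0"]
        assert lines[1].split("\t") == ["chr1", "0", "60", "1"]

    def test_boundaries_round_trip(self, tmp_path):
        p = tmp_path / "b.bed"
        write_boundaries_bed([3, 10, 25], 25_000, "chr7", p)
        assert read_boundaries(p, 25_000, "chr7") == [3, 10, 25]

    def test_bin_index_column_format(self, tmp_path):
        p = tmp_path / "b.txt"
        p.write_text("25\n3\n10\n10\n")
        assert read_boundaries(p, 25_000) == [3, 10, 25]
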