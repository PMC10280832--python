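"""Genome tiling, annotation schemes, fragment counting and bin merging."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schptm_bench import (
    FragmentSet,
    GenomeLayout,
    count_fragments,
    load_annotation_bins,
    make_fixed_bins,
    merge_bins,
)
from schptm_bench.binning import DEFAULT_BIN_SIZES_BP

from conftest import dense_to_cm


@pytest.mark.parametrize(
    "length,bin_size,expected",
    [
        (10_000, 5_000, [(0, 5_000), (5_000, 10_000)]),
        (12_000, 5_000, [(0, 5_000), (5_000, 10_000), (10_000, 12_000)]),
        (4_999, 5_000, [(0, 4_999)]),
    ],
)
def test_fixed_bins_tile_each_chromosome(length, bin_size, expected):
    scheme = make_fixed_bins(GenomeLayout(("chr1",), (length,)), bin_size)
    assert list(zip(scheme.starts, scheme.ends)) == expected
    assert scheme.kind == "fixed"
    assert scheme.region_ids[0] == f"chr1:0-{min(bin_size, length)}"


def test_fixed_bins_input_validation():
    with pytest.raises(ValueError):
        GenomeLayout((), ())
    with pytest.raises(ValueError):
        make_fixed_bins(GenomeLayout(("chr1",), (100,)), 0)
    # the default sweep grid spans the 5 kbp .. 1 Mbp logarithmic range
    assert 5_000 in DEFAULT_BIN_SIZES_BP and 1_000_000 in DEFAULT_BIN_SIZES_BP


class TestAnnotationBins:
    layout = GenomeLayout(("chr1", "chr2"), (10_000, 8_000))

    def test_disjoint_intervals_in_coordinate_order(self):
        bed = io.StringIO("chr1\t100\t200\nchr1\t500\t900\nchr2\t0\t50\n")
        scheme = load_annotation_bins(bed, self.layout)
        assert scheme.n_regions == 3
        assert scheme.kind == "annotation"
        assert list(scheme.starts) == [100, 500, 0]

    def test_unsorted_input_gives_identical_scheme(self):
        sorted_bed = "chr1\t100\t200\nchr1\t500\t900\nchr2\t0\t50\n"
        shuffled_bed = "chr2\t0\t50\nchr1\t500\t900\nchr1\t100\t200\n"
        a = load_annotation_bins(io.StringIO(sorted_bed), self.layout)
        b = load_annotation_bins(io.StringIO(shuffled_bed), self.layout)
        assert np.array_equal(a.starts, b.starts)
        assert np.array_equal(a.region_ids, b.region_ids)

    def test_empty_bed_is_an_error(self):
        with pytest.raises((ValueError, Exception), match="[nN]o (regions|columns)"):
            load_annotation_bins(io.StringIO(""), self.layout)

    def test_interval_beyond_chromosome_end_names_the_record(self):
        bed = io.StringIO("chr1\t100\t200\nchr2\t7000\t9000\n")
        with pytest.raises(ValueError, match="chr2:7000-9000"):
            load_annotation_bins(bed, self.layout)

    def test_overlapping_intervals_are_preserved(self):
        bed = io.StringIO("chr1\t100\t500\nchr1\t300\t700\n")
        scheme = load_annotation_bins(bed, self.layout)
        assert scheme.n_regions == 2


class TestCountFragments:
    layout = GenomeLayout(("chr1",), (10_000,))

    def test_empty_fragment_set_gives_zero_rows(self):
        scheme = make_fixed_bins(self.layout, 5_000)
        frags = FragmentSet(np.array([]), np.array([]), np.array([]), np.array([]), np.array([]))
        cm = count_fragments(frags, scheme)
        assert cm.n_cells == 0 and cm.n_regions == 2

    def test_midpoint_rule_on_boundary_spanning_fragment(self):
        # fragment [4990, 5010) has midpoint 5000, which lies in the second bin
        scheme = make_fixed_bins(self.layout, 5_000)
        frags = FragmentSet(["chr1"], [4990], [5010], ["A"], [1])
        cm = count_fragments(frags, scheme)
        assert cm.counts.toarray().tolist() == [[0, 1]]

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        layout = GenomeLayout(("chr1", "chr2"), (10_000, 6_000))
        scheme = make_fixed_bins(layout, 1_000)
        n = 500
        chroms = rng.choice(["chr1", "chr2"], n)
        lengths = {"chr1": 10_000, "chr2": 6_000}
        starts = np.array([rng.integers(0, lengths[c] - 300) for c in chroms])
        ends = starts + rng.integers(50, 300, n)
        barcodes = rng.choice(["A", "B", "C"], n)
        counts = rng.integers(1, 4, n)
        frags = FragmentSet(chroms, starts, ends, barcodes, counts)
        cm = count_fragments(frags, scheme)

        # independent per-fragment loop oracle
        expected = np.zeros((3, scheme.n_regions), dtype=int)
        bc_row = {"A": 0, "B": 1, "C": 2}
        for c, s, e, bc, ct in zip(chroms, starts, ends, barcodes, counts):
            mid = (s + e) // 2
            for j in range(scheme.n_regions):
                if scheme.chroms[j] == c and scheme.starts[j] <= mid < scheme.ends[j]:
                    expected[bc_row[bc], j] += ct
                    break
        assert np.array_equal(cm.counts.toarray(), expected)
        assert cm.counts.sum() == counts.sum()

    def test_explicit_barcode_order_and_zero_fragment_cells(self):
        scheme = make_fixed_bins(self.layout, 5_000)
        frags = FragmentSet(["chr1"], [0], [100], ["B"], [2])
        cm = count_fragments(frags, scheme, barcodes=["B", "A"])
        assert list(cm.barcodes) == ["B", "A"]
        assert cm.row_sums().tolist() == [2, 0]


class TestMergeBins:
    def test_pairwise_column_sums_against_dense_oracle(self):
        rng = np.random.default_rng(1)
        dense = rng.integers(0, 5, size=(4, 6))
        fine = dense_to_cm(dense, bin_size=5_000)
        target = make_fixed_bins(fine.scheme.layout, 10_000)
        coarse = merge_bins(fine, target)
        expected = dense.reshape(4, 3, 2).sum(axis=2)
        assert np.array_equal(coarse.counts.toarray(), expected)

    def test_identity_when_target_equals_source(self):
        fine = dense_to_cm(np.arange(12).reshape(3, 4), bin_size=100)
        coarse = merge_bins(fine, fine.scheme)
        assert np.array_equal(coarse.counts.toarray(), fine.counts.toarray())

    def test_error_when_target_is_finer(self):
        fine = dense_to_cm(np.ones((2, 4)), bin_size=1_000)
        with pytest.raises(ValueError, match="finer"):
            merge_bins(fine, make_fixed_bins(fine.scheme.layout, 500))

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(st.integers(0, 9), min_size=24, max_size=24),
        multiple=st.sampled_from([2, 3, 4]),
    )
    def test_total_count_conserved_for_multiple_merges(self, data, multiple):
        dense = np.array(data).reshape(2, 12)
        fine = dense_to_cm(dense, bin_size=500)
        coarse = merge_bins(fine, make_fixed_bins(fine.scheme.layout, 500 * multiple))
        assert coarse.counts.sum() == fine.counts.sum()

    def test_direct_rebinning_equals_merge_of_fine_matrix(self):
        # counting fragments at 2 kbp equals merging the 1 kbp matrix to 2 kbp
        rng = np.random.default_rng(2)
        layout = GenomeLayout(("chr1",), (20_000,))
        n = 400
        starts = rng.integers(0, 19_500, n)
        ends = starts + rng.integers(50, 400, n)  # shorter than the fine bin
        frags = FragmentSet(
            np.repeat("chr1", n), starts, np.minimum(ends, 20_000),
            rng.choice(["A", "B"], n), np.ones(n, dtype=int),
        )
        fine = count_fragments(frags, make_fixed_bins(layout, 1_000))
        direct = count_fragments(frags, make_fixed_bins(layout, 2_000))
        merged = merge_bins(fine, make_fixed_bins(layout, 2_000))
        assert np.array_equal(direct.counts.toarray(), merged.counts.toarray())
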