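"""Canonical unit inference, copy partition, cascading layout, signatures."""

import pytest

from horscan import (
    ArraySpec,
    CanonicalUnit,
    Monomer,
    VariantEvent,
    build_array,
    build_chromosome,
    infer_canonical_unit,
    partition_copies,
    render_scheme,
    segment_arrays,
    summarize_array,
)
from horscan.synthetic import WILLARD_10MER_UNIT

from conftest import U10, U17, U36


def sigs(labels, unit):
    return [
        (c.status, c.n_monomers, c.signature)
        for c in partition_copies(labels, unit)
    ]


class TestCanonicalUnit:
    def test_tau_counts_distinct_types(self, unit17, unit10, unit36):
        assert (unit17.n, unit17.tau, unit17.is_cascading) == (17, 16, True)
        assert (unit10.n, unit10.tau, unit10.is_cascading) == (10, 10, False)
        assert (unit36.n, unit36.tau) == (36, 18)

    def test_inference_pure_tandem(self, unit17):
        got = infer_canonical_unit(U17 * 4, 17)
        assert got.type_sequence == unit17.type_sequence
        assert (got.n, got.tau) == (17, 16)

    def test_inference_willard(self, unit10):
        got = infer_canonical_unit(U10 * 3, 10)
        assert got.type_sequence == unit10.type_sequence
        assert got.tau == got.n == 10

    def test_inference_survives_variant_copies(self, unit17):
        dup = U17[:15] + U17  # duplicated first row
        labels = U17 * 3 + dup + U17 * 3
        assert infer_canonical_unit(labels, 17).type_sequence == unit17.type_sequence

    def test_inference_anchors_at_enumeration_start_when_trimmed(self):
        # an array trimmed mid-copy has no label-level record of the original
        # phase; the unit is anchored at the first monomer of the array, the
        # same convention family renumbering itself uses
        labels = U17[5:] + U17 * 4
        got = infer_canonical_unit(labels, 17)
        assert got.type_sequence == tuple(U17[5:] + U17[:5])
        assert got.tau == 16

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            infer_canonical_unit(U17, 17)


class TestPartition:
    def test_pure_canonical_tandem(self, unit17):
        got = sigs(U17 * 10, unit17)
        assert got == [("canonical", 17, "15 + 2")] * 10

    def test_duplicated_first_row_variants(self, unit17):
        # copies 7-8 carry a duplicated first row: 15 + 15 + 2 = 32 monomers
        dup = U17[:15] + U17
        got = sigs(U17 * 6 + dup + dup + U17 * 2, unit17)
        assert got[:6] == [("canonical", 17, "15 + 2")] * 6
        assert got[6] == got[7] == ("variant", 32, "15 + 15 + 2")
        assert got[8:] == [("canonical", 17, "15 + 2")] * 2

    def test_sixfold_first_row_extended_copy(self, unit17):
        # 6 x 15 + 2 = 92-monomer extended copy
        ext6 = U17[:15] * 6 + U17[15:]
        got = sigs(U17 + ext6 + U17, unit17)
        assert got[1] == ("variant", 92, "15 + 15 + 15 + 15 + 15 + 15 + 2")

    def test_trailing_doublets_and_interior_deletion(self, unit17):
        # the period-2 contributing region: 15+2+2 and (6+4)+2 variants
        v1522 = U17 + [0, 15]
        v64 = list(range(6)) + list(range(11, 15)) + [0, 15]
        got = sigs(v1522 + v64 + v1522 + U17 + v1522 + U17, unit17)
        assert got == [
            ("variant", 19, "15 + 2 + 2"),
            ("variant", 12, "(6 + 4)+2"),
            ("variant", 19, "15 + 2 + 2"),
            ("canonical", 17, "15 + 2"),
            ("variant", 19, "15 + 2 + 2"),
            ("canonical", 17, "15 + 2"),
        ]

    def test_canonical_36mer_four_rows(self, unit36):
        copies = partition_copies(U36 * 3, unit36)
        for c in copies:
            assert c.status == "canonical"
            assert [len(r) for r in c.rows] == [6, 17, 8, 5]
            assert c.signature == "6 + 17 + 8 + 5"

    def test_partition_completeness(self, unit17):
        labels = U17 * 3 + U17[:15] + U17 + [0, 15] + U17 * 2
        copies = partition_copies(labels, unit17)
        covered = [i for c in copies for i in range(c.start_index, c.end_index)]
        assert covered == list(range(len(labels)))
        rebuilt = [labels[i] for c in copies
                   for row in c.rows for i, _ in row]
        # rows concatenate back to the copy's monomer sequence
        assert rebuilt == labels

    def test_willard_layout_single_row(self, unit10):
        copies = partition_copies(U10 * 5, unit10)
        assert all(len(c.rows) == 1 and c.signature == "10" for c in copies)

    def test_layout_rows_have_distinct_types_increasing_columns(self, unit17):
        labels = U17 * 2 + U17[:15] + U17
        for c in partition_copies(labels, unit17):
            for row in c.rows:
                cols = [col for _, col in row]
                assert cols == sorted(set(cols))
                types = [labels[i] for i, _ in row]
                assert len(types) == len(set(types))

    def test_layout_is_deterministic(self, unit17):
        labels = U17 * 3 + U17[:15] + U17
        a = partition_copies(labels, unit17)
        b = partition_copies(labels, unit17)
        assert [(c.rows, c.signature) for c in a] == [
            (c.rows, c.signature) for c in b
        ]


class TestSegmentArrays:
    @staticmethod
    def _monomers_from_truth(truth):
        return [
            Monomer("chr", m["start"], m["end"], m["strand"], "", i)
            for i, m in enumerate(truth["monomers"])
        ]

    def test_single_array_single_segment(self):
        seq, truth = build_array(ArraySpec(n_copies=6, seed=3))
        segs = segment_arrays(self._monomers_from_truth(truth), truth["labels"])
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index) == (0, 102)

    def test_two_arrays_split_by_insert(self):
        seq, truth = build_chromosome(
            [
                ArraySpec(n_copies=12, seed=3),
                ArraySpec(unit=WILLARD_10MER_UNIT, n_copies=12, seed=4),
            ],
            seed=5,
            spacer_len=10_000,
        )
        segs = segment_arrays(self._monomers_from_truth(truth), truth["labels"])
        assert len(segs) == 2
        assert segs[0].hor_period == 17
        assert segs[1].hor_period == 10
        assert segs[0].subfragment_periods == (2, 15)

    def test_gap_below_threshold_keeps_one_segment(self):
        monomers = [Monomer("c", i * 171, i * 171 + 171, "+", "", i)
                    for i in range(40)]
        # introduce a 1.5 kb internal gap, below the 2 kb default
        for m in monomers[20:]:
            m.start += 1500
            m.end += 1500
        segs = segment_arrays(monomers, U10 * 4)
        assert len(segs) == 1


class TestSummary:
    def test_percent_canonical_rounding(self, unit10):
        d1 = U10[:5] + U10[6:]
        d2 = U10[:9]
        labels = U10 * 94 + (d1 + d2) * 3
        copies = partition_copies(labels, unit10)
        seg = type("S", (), {"hor_period": 10, "subfragment_periods": ()})()
        s = summarize_array(seg, copies)
        assert s["n_copies"] == 100
        assert s["pct_canonical"] == 94
        assert s["n_variant"] == 6

    def test_all_canonical(self, unit17):
        copies = partition_copies(U17 * 5, unit17)
        seg = type("S", (), {"hor_period": 17, "subfragment_periods": (15, 2)})()
        assert summarize_array(seg, copies)["pct_canonical"] == 100

    def test_variant_cluster_run_lengths(self, unit10):
        d1 = U10[:9]                 # t10 deleted
        d2 = U10[:4] + U10[5:]       # t5 deleted
        labels = U10 * 10 + (d1 + d2) * 2 + d1
        copies = partition_copies(labels, unit10)
        seg = type("S", (), {"hor_period": 10, "subfragment_periods": ()})()
        assert 5 in summarize_array(seg, copies)["variant_runs"]


class TestRenderScheme:
    def test_scheme_alignment_and_positions(self, unit17):
        labels = U17 * 2
        monomers = [Monomer("c", 100 + i * 171, 100 + (i + 1) * 171, "+", "", i)
                    for i in range(len(labels))]
        copies = partition_copies(labels, unit17)
        text = render_scheme(copies, labels, monomers)
        lines = [l for l in text.splitlines() if l.strip()]
        assert lines[0].lstrip().startswith("101")  # 1-based start of copy 1
        assert "t16" in lines[1]
        # t1 of row 2 is vertically aligned with t1 of row 1
        assert lines[0].index("t1 ") == lines[1].index("t1 ")
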