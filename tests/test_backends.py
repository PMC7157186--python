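"""Storage backends: block compression, lookups, element accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import negstore as ns
from negstore import GenomicLocus, PositionState
from negstore.backends import MISS, REF, VAR

from conftest import brute_force_runs

R, V, M = PositionState.REFERENCE, PositionState.VARIANT, PositionState.MISSING


class TestCompressRuns:
    def test_examples_against_brute_force_scanner(self):
        cases = [
            [R, R, R, V, M, M],
            [R] * 100,
            [R, V, R, V],
            [M],
        ]
        for states in cases:
            blocks = ns.compress_runs(states, GenomicLocus("chr1", 0))
            expected = brute_force_runs([int(s) for s in states])
            assert [(b.start, b.end, int(b.state)) for b in blocks] == expected

    def test_mixed_example_block_shapes(self):
        blocks = ns.compress_runs([R, R, R, V, M, M], GenomicLocus("chr1", 10))
        assert [(b.state, b.end - b.start) for b in blocks] == [(R, 3), (V, 1), (M, 2)]
        assert blocks[0].start == 10

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=60),
           st.integers(0, 1000))
    def test_compress_expand_identity(self, states, origin):
        blocks = ns.compress_runs(states, GenomicLocus("chr1", origin))
        assert ns.expand_blocks(blocks).tolist() == states
        # maximality: adjacent blocks always differ in state
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.state is not b2.state
            assert b1.end == b2.start
        assert sum(b.end - b.start for b in blocks) == len(states)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ns.compress_runs([], GenomicLocus("chr1", 0))


def _single_kit_backend(kind, roi_len=100, **kwargs):
    be = ns.open_backend(kind, **kwargs)
    kit = ns.TargetRegionSet.from_records("kit1", [("chr1", 0, roi_len)])
    be.register_kit(kit)
    return be, kit


class TestPutSample:
    def test_all_reference_sample_element_counts(self):
        """100 bp all-reference sample: NSM 0 records, FSM 100, BLSM 1 block."""
        for kind, expected in [("nsm", 0), ("fsm", 100), ("blsm", 1)]:
            be, _ = _single_kit_backend(kind)
            be.put_sample("s1", "kit1", [], [])
            assert be.count_elements().n_elements == expected

    def test_nsm_rejects_out_of_target_records(self):
        be, _ = _single_kit_backend("nsm")
        v = ns.VariantCall("s1", GenomicLocus("chr1", 150), "A", "T")
        with pytest.raises(ns.ContractViolationError):
            be.put_sample("s1", "kit1", [v], [])
        with pytest.raises(ns.ContractViolationError):
            be.put_sample("s1", "kit1", [], [("chr1", 90, 110)])

    def test_conflicting_records_are_corruption(self):
        be, _ = _single_kit_backend("nsm")
        v = ns.VariantCall("s1", GenomicLocus("chr1", 10), "A", "T")
        with pytest.raises(ns.DataCorruptionError):
            be.put_sample("s1", "kit1", [v], [("chr1", 8, 12)])
        v2 = ns.VariantCall("s1", GenomicLocus("chr1", 10), "C", "G")
        with pytest.raises(ns.DataCorruptionError):
            be.put_sample("s1", "kit1", [v, v2], [])

    def test_reput_replaces(self):
        be, _ = _single_kit_backend("nsm")
        v = ns.VariantCall("s1", GenomicLocus("chr1", 10), "A", "T")
        be.put_sample("s1", "kit1", [v], [("chr1", 20, 25)])
        be.put_sample("s1", "kit1", [], [])
        assert be.count_elements().n_elements == 0


class TestLookups:
    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_unknown_sample_raises_not_missing(self, kind, fig1_backends):
        with pytest.raises(ns.UnknownSampleError):
            fig1_backends[kind].lookup_point("nobody", GenomicLocus("chr1", 0))

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_outside_cohort_universe_resolves_missing(self, kind, fig1_backends):
        be = fig1_backends[kind]
        assert be.resolve_point("S1", GenomicLocus("chr1", 10_000)) is M
        assert be.resolve_point("S1", GenomicLocus("chr9", 0)) is M

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_worked_example_positions(self, kind, fig1_backends):
        """Position 1: Sample 5 variant, 4/6 missing; Position 9: S1-3 variant,
        S4 inferred reference, S5-7 untargeted hence missing."""
        be = fig1_backends[kind]
        lookup = be.lookup_point("S5", GenomicLocus("chr1", 0))
        assert lookup.in_target and lookup.has_variant
        assert lookup.variant.annotation.aa_change == "G12D"
        assert be.resolve_point("S4", GenomicLocus("chr1", 8)) is R
        assert be.resolve_point("S5", GenomicLocus("chr1", 8)) is M
        assert be.resolve_point("S1", GenomicLocus("chr1", 8)) is V

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_range_tiles_and_matches_point_lookups(self, kind, fig1_backends):
        be = fig1_backends[kind]
        for sid in ("S1", "S5"):
            runs = be.lookup_range(sid, "chr1", 0, 11)
            dense = ns.runs_to_dense(runs, 0, 11)
            expected = [int(be.resolve_point(sid, GenomicLocus("chr1", p))) for p in range(11)]
            assert dense.tolist() == expected
            for r1, r2 in zip(runs, runs[1:]):
                assert r1.state is not r2.state  # maximal runs

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_range_outside_target_is_single_missing_run(self, kind, fig1_backends):
        runs = fig1_backends[kind].lookup_range("S5", "chr1", 100, 200)
        assert len(runs) == 1 and runs[0].state is M
        assert (runs[0].start, runs[0].end) == (100, 200)

    def test_full_roi_range_on_all_reference_sample(self):
        for kind in ("nsm", "fsm", "blsm"):
            be, _ = _single_kit_backend(kind)
            be.put_sample("s1", "kit1", [], [])
            runs = be.lookup_range("s1", "chr1", 0, 100)
            assert len(runs) == 1 and runs[0].state is R

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_inverted_range_rejected(self, kind, fig1_backends):
        with pytest.raises(ValueError):
            fig1_backends[kind].lookup_range("S1", "chr1", 5, 5)

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_multibase_variant_spans_its_ref_allele(self, kind):
        be, _ = _single_kit_backend(kind)
        v = ns.VariantCall("s1", GenomicLocus("chr1", 10), "ACG", "A")
        be.put_sample("s1", "kit1", [v], [])
        for p in (10, 11, 12):
            assert be.resolve_point("s1", GenomicLocus("chr1", p)) is V
        assert be.resolve_point("s1", GenomicLocus("chr1", 13)) is R
        got = be.iter_variants("s1")
        assert len(got) == 1 and got[0].ref_allele == "ACG"


class TestElementCounts:
    def test_fsm_analytic_count_at_cohort_scale(self):
        """367 samples x 43,022,725 ROI bases is 15.8 billion elements."""
        total = ns.fsm_element_count(367, 43_022_725)
        assert total == 15_789_340_075
        assert round(total / 1e9, 1) == 15.8

    def test_nsm_count_is_variants_plus_missing(self, small_cohort):
        data, backends = small_cohort
        count = backends["nsm"].count_elements()
        assert count.n_elements == data.n_variants_total + data.n_missing_total
        assert count.n_reference == 0

    def test_fsm_count_matches_formula(self, small_cohort):
        data, backends = small_cohort
        count = backends["fsm"].count_elements()
        assert count.n_elements == ns.fsm_element_count(
            len(data.sample_ids), data.roi.total_bases
        )

    def test_blsm_blocks_tile_the_universe(self, small_cohort):
        data, backends = small_cohort
        be = backends["blsm"]
        n = len(data.sample_ids)
        total_span = be._conn.execute(
            "SELECT SUM(end - start) FROM blocks"
        ).fetchone()[0]
        assert total_span == n * data.roi.total_bases

    def test_compression_ordering(self, small_cohort):
        _, backends = small_cohort
        nsm = backends["nsm"].count_elements().n_elements
        blsm = backends["blsm"].count_elements().n_elements
        fsm = backends["fsm"].count_elements().n_elements
        assert nsm <= blsm <= fsm

    def test_single_full_kit_reference_sample_is_one_block(self):
        be, _ = _single_kit_backend("blsm", roi_len=5000)
        be.put_sample("s1", "kit1", [], [])
        count = be.count_elements()
        assert count.n_blocks == 1 == count.n_elements

    def test_vosm_analytic_reduction(self):
        assert ns.vosm_reduction_percent(0.0016) > 99.0
        assert ns.vosm_reduction_percent(0.0) == 100.0
        assert ns.vosm_element_count(42) == 42


class TestFsmBudget:
    def test_materialization_refused_beyond_cell_budget(self):
        be = ns.open_backend("fsm", cell_budget=50)
        kit = ns.TargetRegionSet.from_records("kit1", [("chr1", 0, 100)])
        be.register_kit(kit)
        with pytest.raises(ns.FsmBudgetError):
            be.put_sample("s1", "kit1", [], [])


class TestIndexEquivalence:
    def test_indexed_and_unindexed_lookups_agree(self, fig1_data):
        """Index creation changes query plans, never results."""
        plain = {k: ns.open_backend(k) for k in ("nsm", "fsm", "blsm")}
        ns.load_cohort_into(fig1_data, plain.values())
        indexed = {k: ns.open_backend(k) for k in ("nsm", "fsm", "blsm")}
        ns.load_cohort_into(fig1_data, indexed.values())
        for be in indexed.values():
            be.create_indexes()
        for kind in plain:
            for sid in fig1_data.sample_ids:
                a = ns.runs_to_dense(plain[kind].lookup_range(sid, "chr1", 0, 11), 0, 11)
                b = ns.runs_to_dense(indexed[kind].lookup_range(sid, "chr1", 0, 11), 0, 11)
                assert np.array_equal(a, b)
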