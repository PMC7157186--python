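"""Loading pipeline: missing derivation, classification, conservation."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import negstore as ns
from negstore import CoverageProfile, GenomicLocus, PositionState, TargetRegionSet
from negstore.ingest import SUFFICIENT, IngestConfig, derive_missing


def make_coverage(sid, rows):
    by_chrom = {}
    for chrom, s, e, d in rows:
        by_chrom.setdefault(chrom, []).append((s, e, d))
    return CoverageProfile(sid, by_chrom)


def brute_force_missing(coverage, target, min_depth):
    """Per-position oracle: depth lookup for every targeted base."""
    missing = []
    for chrom, s, e in target.iter_records():
        for p in range(s, e):
            depth = None
            found = False
            for cs, ce, d in coverage.intervals.get(chrom, []):
                if cs <= p < ce:
                    depth, found = d, True
                    break
            ok = found and (depth is SUFFICIENT or depth >= min_depth)
            if not ok:
                missing.append((chrom, p))
    return missing


class TestDeriveMissing:
    def test_fully_covered_target_has_no_missing(self):
        target = TargetRegionSet.from_records("k", [("chr1", 0, 10)])
        cov = make_coverage("s", [("chr1", 0, 10, 20)])
        assert derive_missing(cov, target, 10) == []

    def test_partially_covered_target(self):
        target = TargetRegionSet.from_records("k", [("chr1", 0, 10)])
        cov = make_coverage("s", [("chr1", 0, 4, 20)])
        assert derive_missing(cov, target, 10) == [("chr1", 4, 10)]

    def test_depth_equal_to_threshold_is_sufficient(self):
        target = TargetRegionSet.from_records("k", [("chr1", 0, 10)])
        cov = make_coverage("s", [("chr1", 0, 10, 10)])
        assert derive_missing(cov, target, 10) == []

    def test_overlapping_coverage_is_malformed(self):
        with pytest.raises(ns.NegstoreError):
            make_coverage("s", [("chr1", 0, 5, 10), ("chr1", 3, 8, 12)])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 10), st.integers(0, 30)),
            max_size=6,
        ),
        st.lists(st.tuples(st.integers(0, 50), st.integers(1, 10)), min_size=1, max_size=4),
        st.integers(1, 25),
    )
    def test_matches_per_position_oracle(self, cov_rows, target_rows, min_depth):
        # build non-overlapping coverage intervals by laying them end to end
        rows, cursor = [], 0
        for gap, length, depth in cov_rows:
            start = cursor + gap
            rows.append(("chr1", start, start + length, depth))
            cursor = start + length
        cov = make_coverage("s", rows)
        target = TargetRegionSet.from_records(
            "k", [("chr1", s, s + l) for s, l in target_rows]
        )
        got = {
            (chrom, p)
            for chrom, s, e in derive_missing(cov, target, min_depth)
            for p in range(s, e)
        }
        assert got == set(brute_force_missing(cov, target, min_depth))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 20), st.integers(0, 10))
    def test_monotone_in_min_depth(self, min_depth, bump):
        target = TargetRegionSet.from_records("k", [("chr1", 0, 40)])
        cov = make_coverage(
            "s", [("chr1", 0, 10, 5), ("chr1", 10, 25, 12), ("chr1", 30, 40, 25)]
        )
        lo = sum(e - s for _, s, e in derive_missing(cov, target, min_depth))
        hi = sum(e - s for _, s, e in derive_missing(cov, target, min_depth + bump))
        assert hi >= lo


def fig1_sample(data, sid):
    kit = data.kits[data.sample_kits[sid]]
    cov_rows = {
        c: [(s, e, SUFFICIENT) for s, e in ns.intervals.subtract(
            ivs,
            [(ms, me) for mc, ms, me in data.missing[sid] if mc == c],
        )]
        for c, ivs in kit.intervals.items()
    }
    return kit, data.variants[sid], CoverageProfile(sid, cov_rows)


class TestLoadSample:
    def test_conservation_invariant(self, fig1_data):
        be = ns.open_backend("nsm")
        for sid in fig1_data.sample_ids:
            kit, variants, cov = fig1_sample(fig1_data, sid)
            stats = ns.load_sample([be], sid, kit, variants, cov)
            assert (
                stats.n_variant_span_bases
                + stats.n_missing_stored
                + stats.n_reference_inferred
                == stats.n_target_bases
            )

    def test_worked_example_sample_stores_its_variant(self, fig1_data):
        be = ns.open_backend("nsm")
        kit, variants, cov = fig1_sample(fig1_data, "S5")
        stats = ns.load_sample([be], "S5", kit, variants, cov)
        assert stats.n_variants_stored >= 1
        assert be.resolve_point("S5", GenomicLocus("chr1", 0)) is PositionState.VARIANT

    def test_empty_kit_sample_stores_nothing(self):
        be = ns.open_backend("nsm")
        kit = TargetRegionSet("empty", {})
        stats = ns.load_sample([be], "s1", kit, [], CoverageProfile("s1"))
        assert stats.n_target_bases == 0
        assert stats.n_reference_inferred == 0
        assert be.count_elements().n_elements == 0

    def test_full_depth_no_variant_kit_infers_all_reference(self):
        be = ns.open_backend("nsm")
        kit = TargetRegionSet.from_records("k", [("chr1", 0, 1000)])
        cov = make_coverage("s1", [("chr1", 0, 1000, 50)])
        stats = ns.load_sample([be], "s1", kit, [], cov)
        assert stats.n_reference_inferred == 1000
        assert be.count_elements().n_elements == 0

    def test_out_of_kit_variant_dropped_with_warning(self, caplog):
        be = ns.open_backend("nsm")
        kit = TargetRegionSet.from_records("k", [("chr1", 0, 100)])
        cov = make_coverage("s1", [("chr1", 0, 100, 50)])
        v = ns.VariantCall("s1", GenomicLocus("chr1", 500), "A", "T")
        with caplog.at_level(logging.WARNING, logger="negstore.ingest"):
            stats = ns.load_sample([be], "s1", kit, [v], cov)
        assert stats.n_out_of_target_variants_dropped == 1
        assert any("outside kit" in r.message for r in caplog.records)

    def test_failed_filter_variant_becomes_missing(self):
        be = ns.open_backend("nsm")
        kit = TargetRegionSet.from_records("k", [("chr1", 0, 100)])
        cov = make_coverage("s1", [("chr1", 0, 100, 50)])
        v = ns.VariantCall("s1", GenomicLocus("chr1", 10), "A", "T", passed_filter=False)
        stats = ns.load_sample([be], "s1", kit, [v], cov)
        assert stats.n_variants_stored == 0
        assert stats.n_missing_stored == 1
        assert be.resolve_point("s1", GenomicLocus("chr1", 10)) is PositionState.MISSING

    def test_variant_wins_over_low_coverage(self, caplog):
        """A confident call implies sufficient data: missing marker suppressed."""
        be = ns.open_backend("nsm")
        kit = TargetRegionSet.from_records("k", [("chr1", 0, 100)])
        cov = make_coverage("s1", [("chr1", 0, 50, 50)])  # 50-100 uncovered
        v = ns.VariantCall("s1", GenomicLocus("chr1", 60), "A", "T")
        with caplog.at_level(logging.WARNING, logger="negstore.ingest"):
            stats = ns.load_sample([be], "s1", kit, [v], cov)
        assert be.resolve_point("s1", GenomicLocus("chr1", 60)) is PositionState.VARIANT
        assert stats.n_missing_stored == 49
        assert any("variant wins" in r.message for r in caplog.records)

    def test_duplicate_sample_requires_replace(self):
        be = ns.open_backend("nsm")
        kit = TargetRegionSet.from_records("k", [("chr1", 0, 10)])
        cov = make_coverage("s1", [("chr1", 0, 10, 50)])
        ns.load_sample([be], "s1", kit, [], cov)
        with pytest.raises(ns.NegstoreError):
            ns.load_sample([be], "s1", kit, [], cov)
        ns.load_sample([be], "s1", kit, [], cov, IngestConfig(replace=True))

    def test_order_independence_of_variant_list(self):
        kit = TargetRegionSet.from_records("k", [("chr1", 0, 100)])
        cov = make_coverage("s1", [("chr1", 0, 100, 50)])
        calls = [
            ns.VariantCall("s1", GenomicLocus("chr1", p), "A", "T") for p in (50, 10, 30)
        ]
        dumps = []
        for order in (calls, calls[::-1]):
            be = ns.open_backend("nsm")
            ns.load_sample([be], "s1", kit, list(order), cov)
            dumps.append(be._conn.execute("SELECT * FROM variants ORDER BY rowid").fetchall())
        assert dumps[0] == dumps[1]


class TestLoadCohort:
    def test_fig1_cohort_counts_are_additive(self, fig1_data, fig1_backends):
        count = fig1_backends["nsm"].count_elements()
        assert count.n_elements == fig1_data.n_variants_total + fig1_data.n_missing_total

    def test_missing_input_file_is_reported(self, tmp_path):
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("s1\tkitX\t/nonexistent.vcf\t/nonexistent.bed\n")
        with pytest.raises(FileNotFoundError):
            ns.load_cohort(str(manifest), [ns.open_backend("nsm")])

    def test_deterministic_reload(self, fig1_data):
        counts = []
        for _ in range(2):
            be = ns.open_backend("nsm")
            ns.load_cohort(fig1_data.manifest_path, [be])
            counts.append(be.count_elements())
        assert counts[0] == counts[1]
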