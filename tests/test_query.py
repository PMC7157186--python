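"""The four cohort use cases, checked on the worked fixture and for
backend agnosticism."""

import pytest

import negstore as ns
from negstore import CohortQuery, GeneModel, GeneModelSet, GenomicLocus, PositionState

R, V, M = PositionState.REFERENCE, PositionState.VARIANT, PositionState.MISSING


@pytest.fixture(scope="module")
def fig1_queries(fig1_data, fig1_backends):
    genes = GeneModelSet.from_tsv(fig1_data.genes_path)
    return {k: CohortQuery(be, genes) for k, be in fig1_backends.items()}


class TestStatusAtPosition:
    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_position_one_tallies(self, kind, fig1_queries):
        """Five of seven samples informative at Position 1; one of five variant."""
        rep = fig1_queries[kind].status_at_position("chr1", 0)
        assert len(rep.states) == 7
        assert rep.n_informative == 5
        assert rep.n_variant == 1
        assert rep.states["S5"] is V

    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_position_nine_tallies(self, kind, fig1_queries):
        """S1-3 variant, S4 inferred reference, S5-7 untargeted at Position 9."""
        rep = fig1_queries[kind].status_at_position("chr1", 8)
        assert {s: rep.states[s] for s in rep.states} == {
            "S1": V, "S2": V, "S3": V, "S4": R, "S5": M, "S6": M, "S7": M,
        }
        assert rep.n_informative == 4 and rep.n_variant == 3

    def test_position_outside_every_kit_is_all_missing(self, fig1_queries):
        rep = fig1_queries["nsm"].status_at_position("chr1", 5000)
        assert all(s is M for s in rep.states.values())

    def test_variant_entries_carry_annotation_others_do_not(self, fig1_queries):
        rep = fig1_queries["nsm"].status_at_position("chr1", 0)
        assert set(rep.annotations) == {"S5"}
        assert rep.annotations["S5"].gene_symbol == "GENEA"


class TestStatusForMutation:
    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_single_locus_mutation(self, kind, fig1_queries):
        rep = fig1_queries[kind].status_for_mutation("GENEA", "G12D")
        assert rep.states["S5"] is V
        assert rep.states["S4"] is M and rep.states["S6"] is M
        assert all(rep.states[s] is R for s in ("S1", "S2", "S3", "S7"))

    def test_gene_symbol_is_case_insensitive(self, fig1_queries):
        rep = fig1_queries["nsm"].status_for_mutation("genea", "G12D")
        assert rep.states["S5"] is V

    def test_unmatched_mutation_signals_empty_match(self, fig1_queries):
        with pytest.raises(ns.EmptyMatchError):
            fig1_queries["nsm"].status_for_mutation("GENEA", "Q999*")

    def test_multi_locus_precedence(self):
        """Same protein change at two loci: carrier at either locus is VARIANT,
        any missing locus beats reference (VARIANT > MISSING > REFERENCE)."""
        be = ns.open_backend("nsm")
        kit = ns.TargetRegionSet.from_records("k", [("chr1", 0, 100)])
        be.register_kit(kit)
        ann = ns.AnnotationBundle("G1", "R10W")
        mk = lambda sid, pos: ns.VariantCall(sid, GenomicLocus("chr1", pos), "A", "T", True, ann)
        be.put_sample("carrierA", "k", [mk("carrierA", 10)], [])
        be.put_sample("carrierB", "k", [mk("carrierB", 50)], [])
        be.put_sample("lowcov", "k", [], [("chr1", 10, 11)])
        be.put_sample("clean", "k", [], [])
        rep = CohortQuery(be).status_for_mutation("G1", "R10W")
        assert rep.states == {
            "carrierA": V, "carrierB": V, "lowcov": M, "clean": R,
        }


class TestGeneMutations:
    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_map_matches_repeated_position_queries(self, kind, fig1_queries):
        q = fig1_queries[kind]
        out = q.statuses_for_gene_mutations("GENEB")
        assert {l.pos for l in out} == {7, 8, 10}
        for locus, rep in out.items():
            direct = q.status_at_position(locus.chrom, locus.pos)
            assert rep.states == direct.states

    def test_gene_without_stored_variants_is_empty_map(self, fig1_backends):
        genes = GeneModelSet([GeneModel("EMPTY1", "chr1", [(3, 4)])])
        out = CohortQuery(fig1_backends["nsm"], genes).statuses_for_gene_mutations("EMPTY1")
        assert out == {}

    def test_unknown_gene_raises(self, fig1_queries):
        with pytest.raises(KeyError):
            fig1_queries["nsm"].statuses_for_gene_mutations("NOPE")


class TestCoverageAcrossGene:
    @pytest.mark.parametrize("kind", ["nsm", "fsm", "blsm"])
    def test_matches_per_position_brute_force(self, kind, fig1_queries, fig1_backends):
        q = fig1_queries[kind]
        be = fig1_backends[kind]
        for gene in ("GENEA", "GENEB"):
            rep = q.coverage_across_gene(gene)
            model = q.genes[gene]
            for sid, frac in rep.fractions.items():
                usable = sum(
                    1
                    for s, e in model.intervals
                    for p in range(s, e)
                    if be.resolve_point(sid, GenomicLocus("chr1", p)) is not M
                )
                assert frac == pytest.approx(usable / model.total_bases)

    def test_kit_excluding_gene_gives_zero(self, fig1_queries):
        """GENEB spans positions the short kit misses entirely beyond pos 8."""
        genes = GeneModelSet([GeneModel("TAIL", "chr1", [(8, 11)])])
        q = CohortQuery(fig1_queries["nsm"].backend, genes)
        rep = q.coverage_across_gene("TAIL")
        assert rep.fractions["S5"] == 0.0
        assert rep.fractions["S1"] == 1.0

    def test_fraction_with_in_kit_missing(self):
        """10 bp gene, 3 in-kit missing positions, rest covered: 0.7."""
        be = ns.open_backend("nsm")
        kit = ns.TargetRegionSet.from_records("k", [("chr1", 0, 10)])
        be.register_kit(kit)
        be.put_sample("s1", "k", [], [("chr1", 2, 5)])
        genes = GeneModelSet([GeneModel("G", "chr1", [(0, 10)])])
        rep = CohortQuery(be, genes).coverage_across_gene("G")
        assert rep.fractions["s1"] == pytest.approx(0.7)


class TestBackendAgnosticism:
    def test_all_use_case_outputs_identical_across_backends(self, fig1_queries):
        tsvs = {}
        for kind, q in fig1_queries.items():
            pos = q.status_at_position("chr1", 8).to_tsv()
            mut = q.status_for_mutation("GENEB", "V600E").to_tsv()
            cov = q.coverage_across_gene("GENEA").to_tsv()
            tsvs[kind] = pos + mut + cov
        assert len(set(tsvs.values())) == 1


class TestGeneModels:
    def test_duplicate_symbol_raises(self):
        with pytest.raises(ns.NegstoreError):
            GeneModelSet([
                GeneModel("G", "chr1", [(0, 5)]),
                GeneModel("g", "chr1", [(5, 10)]),
            ])

    def test_bed12_exon_blocks(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t100\t500\tMYGENE\t0\t+\t100\t500\t0\t2\t50,100,\t0,300,\n"
        )
        genes = GeneModelSet.from_bed12(str(p))
        g = genes["MYGENE"]
        assert g.intervals == [(100, 150), (400, 500)]
        assert g.strand == "+"
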