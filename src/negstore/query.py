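"""Cohort-level use-case queries over any backend.

Four canonical cohort questions, all answered purely through the
point/range lookup contract so that every backend gives bit-identical
output:

1. sample status (ref / alt / missing) at a genomic position;
2. sample status for a named mutation (gene + protein change);
3. sample status at every stored mutation within a gene;
4. per-sample fraction of a gene's bases with usable (non-missing) data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .backends import Backend
from .state import (
    AnnotationBundle,
    EmptyMatchError,
    GenomicLocus,
    NegstoreError,
    PositionState,
)


@dataclass
class GeneModel:
    """One gene's merged (exon + padding) intervals."""

    gene_symbol: str
    chrom: str
    intervals: List[Tuple[int, int]]
    strand: str = "unknown"

    def __post_init__(self) -> None:
        from .intervals import merge_intervals

        if not self.intervals:
            raise NegstoreError(f"gene {self.gene_symbol}: empty model")
        self.intervals = merge_intervals(self.intervals)
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def total_bases(self) -> int:
        return sum(e - s for s, e in self.intervals)


class GeneModelSet:
    """Case-insensitive gene symbol -> model registry; duplicates raise."""

    def __init__(self, genes: Optional[List[GeneModel]] = None) -> None:
        self._genes: Dict[str, GeneModel] = {}
        for g in genes or []:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        key = gene.gene_symbol.upper()
        if key in self._genes:
            raise NegstoreError(f"duplicate gene symbol {gene.gene_symbol!r}")
        self._genes[key] = gene

    def __getitem__(self, symbol: str) -> GeneModel:
        try:
            return self._genes[symbol.upper()]
        except KeyError:
            raise KeyError(f"unknown gene {symbol!r}")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._genes

    def __iter__(self):
        return iter(self._genes.values())

    @classmethod
    def from_tsv(cls, path: str) -> "GeneModelSet":
        """4-column TSV: gene, chrom, start, end — one row per exon."""
        from .state import ParseError

        rows: Dict[str, Tuple[str, List[Tuple[int, int]]]] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError("expected gene, chrom, start, end", path, i)
                gene, chrom = parts[0], parts[1]
                try:
                    s, e = int(parts[2]), int(parts[3])
                except ValueError:
                    raise ParseError("non-integer exon coordinates", path, i)
                if gene in rows and rows[gene][0] != chrom:
                    raise ParseError(f"gene {gene} spans multiple chromosomes", path, i)
                rows.setdefault(gene, (chrom, []))[1].append((s, e))
        return cls([GeneModel(g, chrom, ivs) for g, (chrom, ivs) in rows.items()])

    @classmethod
    def from_bed12(cls, path: str) -> "GeneModelSet":
        """BED12: one line per gene; block fields give the exon structure."""
        from .state import ParseError

        genes: List[GeneModel] = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 12:
                    raise ParseError("BED12 needs 12 columns", path, i)
                chrom, start = parts[0], int(parts[1])
                name, strand = parts[3], parts[5] if parts[5] in "+-" else "unknown"
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                ivs = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
                genes.append(GeneModel(name, chrom, ivs, strand))
        return cls(genes)


@dataclass
class StatusReport:
    """Per-sample resolved state (with annotation for VARIANT entries)."""

    states: Dict[str, PositionState] = field(default_factory=dict)
    annotations: Dict[str, AnnotationBundle] = field(default_factory=dict)

    def counts(self) -> Dict[str, int]:
        out = {s.short: 0 for s in PositionState}
        for st in self.states.values():
            out[st.short] += 1
        return out

    @property
    def n_informative(self) -> int:
        """Samples whose state is known (REFERENCE or VARIANT)."""
        return sum(1 for s in self.states.values() if s is not PositionState.MISSING)

    @property
    def n_variant(self) -> int:
        return sum(1 for s in self.states.values() if s is PositionState.VARIANT)

    def to_rows(self) -> List[Tuple[str, str, str]]:
        rows = []
        for sid in self.states:
            ann = self.annotations.get(sid)
            detail = ""
            if ann is not None and ann.gene_symbol:
                detail = ann.gene_symbol + (f":{ann.aa_change}" if ann.aa_change else "")
            rows.append((sid, self.states[sid].short, detail))
        return rows

    def to_tsv(self) -> str:
        lines = ["sample_id\tstatus\tannotation"]
        lines += ["\t".join(r) for r in self.to_rows()]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {sid: {"status": st.short,
                   "annotation": (self.annotations[sid].__dict__
                                  if sid in self.annotations else None)}
             for sid, st in self.states.items()},
            indent=2, sort_keys=True, default=str,
        )


@dataclass
class CoverageReport:
    """Per-sample fraction of a region's bases with usable data."""

    fractions: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {sid} outside [0, 1]: {f}")

    def to_tsv(self) -> str:
        lines = ["sample_id\tfraction_covered"]
        lines += [f"{sid}\t{frac:.6f}" for sid, frac in self.fractions.items()]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.fractions, indent=2, sort_keys=True)


class CohortQuery:
    """The use-case surface bound to one backend (and optional gene models)."""

    def __init__(self, backend: Backend, genes: Optional[GeneModelSet] = None) -> None:
        self.backend = backend
        self.genes = genes or GeneModelSet()

    # -- use case 1 ----------------------------------------------------
    def status_at_position(self, chrom: str, pos: int) -> StatusReport:
        """Resolve every cohort sample's state at one position."""
        report = StatusReport()
        locus = GenomicLocus(chrom, pos)
        for sid in self.backend.samples():
            lookup = self.backend.lookup_point(sid, locus)
            from .state import resolve_state

            st = resolve_state(lookup)
            report.states[sid] = st
            if st is PositionState.VARIANT and lookup.variant is not None:
                report.annotations[sid] = lookup.variant.annotation
        return report

    # -- use case 2 ----------------------------------------------------
    def status_for_mutation(self, gene_symbol: str, aa_change: str) -> StatusReport:
        """Per-sample status for a named mutation (gene + protein change).

        The mutation may be realized at several loci; a sample is VARIANT
        if it carries a matching call at any of them, REFERENCE only if
        every matching locus resolves reference, MISSING otherwise
        (precedence VARIANT > MISSING > REFERENCE across loci).
        """
        loci = self.backend.variant_loci(gene_symbol=gene_symbol, aa_change=aa_change)
        if not loci:
            raise EmptyMatchError(
                f"no stored variant matches {gene_symbol} {aa_change}"
            )
        carriers = {
            v.sample_id
            for v in self.backend.iter_variants(
                gene_symbol=gene_symbol, aa_change=aa_change
            )
        }
        per_locus = [self.status_at_position(l.chrom, l.pos) for l in loci]
        report = StatusReport()
        for sid in self.backend.samples():
            if sid in carriers:
                report.states[sid] = PositionState.VARIANT
                for rep in per_locus:
                    if rep.states[sid] is PositionState.VARIANT and sid in rep.annotations:
                        report.annotations[sid] = rep.annotations[sid]
                        break
            elif any(r.states[sid] is PositionState.MISSING for r in per_locus):
                report.states[sid] = PositionState.MISSING
            else:
                report.states[sid] = PositionState.REFERENCE
        return report

    # -- use case 3 ----------------------------------------------------
    def statuses_for_gene_mutations(
        self, gene_symbol: str
    ) -> Dict[GenomicLocus, StatusReport]:
        """One status report per distinct stored mutation locus in a gene."""
        gene = self.genes[gene_symbol]
        out: Dict[GenomicLocus, StatusReport] = {}
        for locus in self.backend.variant_loci():
            if locus.chrom != gene.chrom:
                continue
            from .intervals import contains

            if contains(gene.intervals, locus.pos):
                out[locus] = self.status_at_position(locus.chrom, locus.pos)
        return out

    # -- use case 4 ----------------------------------------------------
    def coverage_across_gene(self, gene_symbol: str) -> CoverageReport:
        """Fraction of gene bases with usable data, per sample.

        "Usable" means the resolved state is not MISSING.  The denominator
        is the gene model's length (not the sample's kit intersection) so
        fractions are comparable across samples with different kits.
        """
        gene = self.genes[gene_symbol]
        denom = gene.total_bases
        if denom == 0:
            raise NegstoreError(f"gene {gene_symbol}: zero-length model")
        report = CoverageReport()
        for sid in self.backend.samples():
            usable = 0
            for s, e in gene.intervals:
                for run in self.backend.lookup_range(sid, gene.chrom, s, e):
                    if run.state is not PositionState.MISSING:
                        usable += run.length
            report.fractions[sid] = usable / denom
        return report
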