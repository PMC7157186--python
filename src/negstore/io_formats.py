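"""Readers and writers for the standard formats the store touches.

Coordinate policy: everything inside the package is 0-based half-open;
conversion to and from 1-based happens only here (VCF/gVCF, MAF, per-base
depth TSV are 1-based on disk; BED already matches the internal
convention).

The gVCF export is the "precise" dialect of this store: it writes variant
records, reference blocks and — because standard gVCF has no first-class
*untested* state — missing blocks marked by a dedicated ``MISSING``
FILTER.  The dialect is self-describing (the FILTER is declared in the
header) and round-trips: importing an export reproduces the resolved
state of every universe position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import pysam

from .backends import Backend
from .ingest import SUFFICIENT, CoverageProfile
from .intervals import TargetRegionSet
from .state import (
    AnnotationBundle,
    GenomicLocus,
    ParseError,
    PositionState,
    VariantCall,
)

# ---------------------------------------------------------------- BED

def read_bed(
    path: str,
    kit_id: Optional[str] = None,
    pad: int = 0,
    chrom_lengths: Optional[Dict[str, int]] = None,
    aliases: Optional[Dict[str, str]] = None,
) -> TargetRegionSet:
    """Read a BED (3+ columns) into a merged target-region set.

    ``pad`` applies symmetric padding per interval (clamped at 0 and, when
    ``chrom_lengths`` is given, at the chromosome end) before re-merging.
    """
    kit_id = kit_id or os.path.splitext(os.path.basename(path))[0]
    aliases = aliases or {}
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line needs >= 3 columns", path, i)
            chrom = aliases.get(parts[0], parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"non-integer coordinates {parts[1]!r}/{parts[2]!r}", path, i)
            if start >= end:
                raise ParseError(f"start {start} >= end {end}", path, i)
            if start < 0:
                raise ParseError(f"negative start {start}", path, i)
            records.append((chrom, start, end))
    trs = TargetRegionSet.from_records(kit_id, records)
    if pad:
        trs = trs.padded(pad, chrom_lengths)
    return trs


def write_bed(trs: TargetRegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in trs.iter_records():
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------- variants

@dataclass
class MafColumnMap:
    """Column names for MAF-like tab-delimited mutation tables."""

    sample: str = "Tumor_Sample_Barcode"
    chrom: str = "Chromosome"
    pos: str = "Start_Position"  # 1-based
    ref: str = "Reference_Allele"
    alt: str = "Tumor_Seq_Allele2"
    gene: str = "Hugo_Symbol"
    aa_change: str = "HGVSp_Short"
    filter: str = "FILTER"  # optional column; absent means all pass


def _strip_hgvsp(value: str) -> Optional[str]:
    """'p.V600E' -> 'V600E'; empty/'.' -> None."""
    value = value.strip()
    if not value or value == ".":
        return None
    return value[2:] if value.startswith("p.") else value


def read_variants(
    path: str,
    dialect: Optional[str] = None,
    sample_id: Optional[str] = None,
    aliases: Optional[Dict[str, str]] = None,
    maf_columns: Optional[MafColumnMap] = None,
    info_gene: str = "GENE",
    info_aa: str = "AACHANGE",
) -> List[VariantCall]:
    """Read variant calls from VCF (``vcf``) or MAF-like TSV (``maf_tsv``).

    The dialect is inferred from the extension when not given.  1-based
    file coordinates become 0-based loci; the FILTER column maps to
    ``passed_filter``; gene and protein change come from the configured
    INFO keys (VCF) or columns (MAF).
    """
    if dialect is None:
        dialect = "vcf" if path.endswith((".vcf", ".vcf.gz", ".vcf.bgz", ".gvcf")) else "maf_tsv"
    if dialect == "vcf":
        return _read_vcf(path, sample_id, aliases or {}, info_gene, info_aa)
    if dialect == "maf_tsv":
        return _read_maf(path, sample_id, aliases or {}, maf_columns or MafColumnMap())
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_vcf(path, sample_id, aliases, info_gene, info_aa) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with pysam.VariantFile(path) as vf:
        header_samples = list(vf.header.samples)
        sid = sample_id or (header_samples[0] if header_samples else None)
        if sid is None:
            raise ValueError(f"{path}: no sample column and no sample_id given")
        for rec in vf:
            if rec.alts is None:
                continue
            filters = list(rec.filter.keys())
            passed = not filters or filters == ["PASS"]
            gene = rec.info.get(info_gene)
            aa = rec.info.get(info_aa)
            if isinstance(gene, tuple):
                gene = gene[0]
            if isinstance(aa, tuple):
                aa = aa[0]
            for alt in rec.alts:
                if alt in ("<NON_REF>", "*") or alt is None:
                    continue
                calls.append(
                    VariantCall(
                        sample_id=sid,
                        locus=GenomicLocus(aliases.get(rec.chrom, rec.chrom), rec.start),
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        passed_filter=passed,
                        annotation=AnnotationBundle(
                            gene_symbol=gene, aa_change=aa if gene else None
                        ),
                    )
                )
    return calls


def _read_maf(path, sample_id, aliases, cols: MafColumnMap) -> List[VariantCall]:
    import csv

    calls: List[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        required = [cols.sample, cols.chrom, cols.pos, cols.ref, cols.alt]
        for c in required:
            if c not in reader.fieldnames:
                raise ParseError(f"missing column {c!r}", path, 1)
        for i, row in enumerate(reader, 2):
            sid = row[cols.sample]
            if sample_id is not None and sid != sample_id:
                continue
            try:
                pos = int(row[cols.pos]) - 1
            except ValueError:
                raise ParseError(f"non-integer position {row[cols.pos]!r}", path, i)
            gene = (row.get(cols.gene) or "").strip() or None
            aa = _strip_hgvsp(row.get(cols.aa_change) or "") if gene else None
            filt = (row.get(cols.filter) or "PASS").strip()
            try:
                calls.append(
                    VariantCall(
                        sample_id=sid,
                        locus=GenomicLocus(
                            aliases.get(row[cols.chrom], row[cols.chrom]), pos
                        ),
                        ref_allele=row[cols.ref].strip(),
                        alt_allele=row[cols.alt].strip(),
                        passed_filter=filt in ("PASS", "", "."),
                        annotation=AnnotationBundle(gene_symbol=gene, aa_change=aa),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, i)
    return calls


def write_vcf(
    variants: Sequence[VariantCall],
    path: str,
    sample_id: str,
    contigs: Sequence[str],
    info_gene: str = "GENE",
    info_aa: str = "AACHANGE",
) -> None:
    """Write a minimal deterministic single-sample VCF 4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=negstore",
        f'##INFO=<ID={info_gene},Number=1,Type=String,Description="Gene symbol">',
        f'##INFO=<ID={info_aa},Number=1,Type=String,Description="Protein change">',
        '##FILTER=<ID=lowqual,Description="Call failed quality filters">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for v in sorted(variants, key=lambda v: (v.locus.chrom, v.locus.pos, v.alt_allele)):
        info = []
        if v.annotation.gene_symbol:
            info.append(f"{info_gene}={v.annotation.gene_symbol}")
        if v.annotation.aa_change:
            info.append(f"{info_aa}={v.annotation.aa_change}")
        lines.append(
            "\t".join(
                [
                    v.locus.chrom, str(v.locus.pos + 1), ".",
                    v.ref_allele, v.alt_allele, ".",
                    "PASS" if v.passed_filter else "lowqual",
                    ";".join(info) or ".", "GT", "0/1",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------- coverage

def read_coverage(
    path: str,
    dialect: Optional[str] = None,
    sample_id: Optional[str] = None,
    aliases: Optional[Dict[str, str]] = None,
) -> CoverageProfile:
    """Read coverage as per-base depth TSV or callable-interval BED.

    ``perbase_tsv`` rows are ``chrom, pos(1-based), depth``; consecutive
    equal-depth rows coalesce into one interval.  ``callable_bed``
    intervals carry the sentinel "sufficient" depth.
    """
    aliases = aliases or {}
    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    if dialect is None:
        dialect = "callable_bed" if path.endswith(".bed") else "perbase_tsv"
    intervals: Dict[str, List[Tuple[int, int, Optional[int]]]] = {}
    if dialect == "callable_bed":
        trs = read_bed(path, kit_id=sid, aliases=aliases)
        for chrom, s, e in trs.iter_records():
            intervals.setdefault(chrom, []).append((s, e, SUFFICIENT))
    elif dialect == "perbase_tsv":
        last: Dict[str, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError("depth row needs chrom, pos, depth", path, i)
                chrom = aliases.get(parts[0], parts[0])
                try:
                    pos0 = int(parts[1]) - 1
                    depth = int(parts[2])
                except ValueError:
                    raise ParseError(f"non-integer field in {parts[:3]}", path, i)
                if chrom in last and pos0 <= last[chrom]:
                    raise ParseError(
                        f"non-monotonic position {pos0 + 1} on {chrom}", path, i
                    )
                last[chrom] = pos0
                ivs = intervals.setdefault(chrom, [])
                if ivs and ivs[-1][1] == pos0 and ivs[-1][2] == depth:
                    ivs[-1] = (ivs[-1][0], pos0 + 1, depth)
                else:
                    ivs.append((pos0, pos0 + 1, depth))
    else:
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    return CoverageProfile(sample_id=sid, intervals=intervals)


def write_callable_bed(coverage: CoverageProfile, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in coverage.intervals.items():
            for s, e, _d in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------- gVCF

_GVCF_MISSING_FILTER = "MISSING"


@dataclass
class GvcfSample:
    """Parsed content of one precise gVCF: full state over its universe."""

    sample_id: str
    variants: List[VariantCall] = field(default_factory=list)
    missing: List[Tuple[str, int, int]] = field(default_factory=list)
    reference: List[Tuple[str, int, int]] = field(default_factory=list)
    contigs: List[str] = field(default_factory=list)

    def tested_intervals(self, kit_id: str) -> TargetRegionSet:
        """Every interval the file makes a statement about (the universe)."""
        recs = list(self.reference) + list(self.missing) + [
            (v.locus.chrom, v.locus.pos, v.end) for v in self.variants
        ]
        by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in self.contigs}
        for chrom, s, e in recs:
            by_chrom.setdefault(chrom, []).append((s, e))
        return TargetRegionSet(kit_id, by_chrom)


def _gvcf_header(sample_id: str, contigs: Sequence[str]) -> List[str]:
    return [
        "##fileformat=VCFv4.2",
        "##source=negstore",
        '##ALT=<ID=NON_REF,Description="Non-variant block">',
        '##FILTER=<ID=MISSING,Description="Tested region with insufficient data '
        'or untested region of the cohort universe">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of block (1-based inclusive)">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AACHANGE,Number=1,Type=String,Description="Protein change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *[f"##contig=<ID={c}>" for c in contigs],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]


def export_gvcf(
    backend: Backend,
    sample_id: str,
    out: str | TextIO,
    reference=None,
) -> None:
    """Export one sample as a precise gVCF over the cohort universe.

    Emits a variant record per stored call, reference blocks (``0/0`` with
    an ``END``) over inferred-reference runs and missing blocks (``./.``,
    FILTER ``MISSING``) over both low-quality and out-of-kit runs.  Block
    REF alleles are ``N`` placeholders unless a ``reference`` object with
    a ``fetch(chrom, start, end)`` method supplies real bases.  Output is
    byte-deterministic for a given store.
    """
    roi = backend.roi()
    by_anchor = {
        (v.locus.chrom, v.locus.pos): v for v in backend.iter_variants(sample_id)
    }

    def base(chrom: str, pos: int) -> str:
        if reference is None:
            return "N"
        return str(reference.fetch(chrom, pos, pos + 1)).upper() or "N"

    lines = _gvcf_header(sample_id, list(roi.intervals.keys()))
    for chrom, s, e in roi.iter_records():
        for run in backend.lookup_range(sample_id, chrom, s, e):
            if run.state is PositionState.VARIANT:
                p = run.start
                while p < run.end:
                    v = by_anchor[(chrom, p)]
                    info = []
                    if v.annotation.gene_symbol:
                        info.append(f"GENE={v.annotation.gene_symbol}")
                    if v.annotation.aa_change:
                        info.append(f"AACHANGE={v.annotation.aa_change}")
                    lines.append(
                        "\t".join(
                            [chrom, str(p + 1), ".", v.ref_allele, v.alt_allele,
                             ".", "PASS", ";".join(info) or ".", "GT", "0/1"]
                        )
                    )
                    p = v.end
            else:
                is_miss = run.state is PositionState.MISSING
                lines.append(
                    "\t".join(
                        [chrom, str(run.start + 1), ".", base(chrom, run.start),
                         "<NON_REF>", ".",
                         _GVCF_MISSING_FILTER if is_miss else "PASS",
                         f"END={run.end}", "GT", "./." if is_miss else "0/0"]
                    )
                )
    text = "\n".join(lines) + "\n"
    if isinstance(out, str):
        with open(out, "w") as fh:
            fh.write(text)
    else:
        out.write(text)


def read_gvcf(path: str) -> GvcfSample:
    """Parse a precise gVCF back into variants / missing / reference intervals."""
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ParseError(f"expected exactly one sample, got {samples}", path)
        out = GvcfSample(sample_id=samples[0], contigs=list(vf.header.contigs))
        for rec in vf:
            alts = rec.alts or ()
            filters = list(rec.filter.keys())
            if alts and alts[0] == "<NON_REF>":
                interval = (rec.chrom, rec.start, rec.stop)
                if _GVCF_MISSING_FILTER in filters:
                    out.missing.append(interval)
                else:
                    out.reference.append(interval)
            else:
                gene = rec.info.get("GENE")
                aa = rec.info.get("AACHANGE")
                if isinstance(gene, tuple):
                    gene = gene[0]
                if isinstance(aa, tuple):
                    aa = aa[0]
                passed = not filters or filters == ["PASS"]
                out.variants.append(
                    VariantCall(
                        sample_id=out.sample_id,
                        locus=GenomicLocus(rec.chrom, rec.start),
                        ref_allele=rec.ref,
                        alt_allele=alts[0],
                        passed_filter=passed,
                        annotation=AnnotationBundle(
                            gene_symbol=gene, aa_change=aa if gene else None
                        ),
                    )
                )
    return out


def import_gvcf(
    backend: Backend,
    path: str,
    sample_id: Optional[str] = None,
    kit_id: Optional[str] = None,
) -> str:
    """Load a precise gVCF as a sample; its universe becomes the kit.

    Missing blocks (low-quality *and* formerly out-of-kit regions alike)
    become stored missing records inside the new kit, which resolves to
    the identical state at every position as the exporting store.
    Returns the sample id used.
    """
    gv = read_gvcf(path)
    sid = sample_id or gv.sample_id
    kid = kit_id or f"gvcf-{sid}"
    kit = gv.tested_intervals(kid)
    backend.register_kit(kit)
    variants = [
        VariantCall(sid, v.locus, v.ref_allele, v.alt_allele, v.passed_filter, v.annotation)
        for v in gv.variants
    ]
    backend.put_sample(sid, kid, variants, gv.missing)
    return sid
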