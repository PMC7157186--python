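"""Synthetic multi-kit cohorts with a dense ground-truth oracle.

The generator emulates the study conditions of a targeted-capture cohort
stored in a variant warehouse: samples are assigned to one of several
capture kits with differing target interval sets; within a sample's kit,
sparse somatic-scale variants (default 0.15% of targeted bases, the middle
of the 0.13–0.16% per-genome variation range) and sparse low-coverage
positions (default 1%) are drawn disjointly; everything outside the kit is
untested.  The dense ``StateMatrix`` records the resolved-state truth for
every (sample, position) of the universe and exists only for testing and
benchmarking — backends never see it.

A hand-set 7-sample x 11-position worked fixture (:func:`fig1_fixture`)
encodes the two canonical worked positions: Position 1 (all samples
targeted; one variant, two missing, four reference) and Position 9 (three
variants, one inferred reference, three samples untargeted).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io_formats
from .backends import MISS, REF, VAR
from .ingest import SUFFICIENT, CoverageProfile
from .intervals import TargetRegionSet, merge_intervals, positions_to_intervals, subtract
from .state import AnnotationBundle, GenomicLocus, PositionState, VariantCall

_AA = "ARNDCQEGHILKMFPSTWYV"
_BASES = "ACGT"


@dataclass
class KitSpec:
    kit_id: str
    fraction: float  # of the universe targeted
    granularity: int = 150  # target interval size, bp (exon-like)


@dataclass
class CohortSpec:
    """Conditions of one synthetic cohort; same seed -> identical cohort."""

    n_samples: int = 50
    chrom: str = "chr1"
    universe_bp: int = 1_000_000
    kits: Tuple[KitSpec, ...] = (
        KitSpec("kitA", 0.015),
        KitSpec("kitB", 0.020),
        KitSpec("kitC", 0.025),
    )
    variant_rate: float = 0.0015  # per in-kit base
    missing_rate: float = 0.01  # per in-kit base
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.variant_rate <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.variant_rate + self.missing_rate > 1:
            raise ValueError("variant_rate + missing_rate must not exceed 1")
        if self.n_samples < 1 or self.universe_bp < 1 or not self.kits:
            raise ValueError("need >= 1 sample, >= 1 bp universe and >= 1 kit")

    @classmethod
    def from_file(cls, path: str) -> "CohortSpec":
        """Parse a ``key = value`` cohort config (``kit = id:fraction:granularity``)."""
        kwargs: dict = {}
        kits: List[KitSpec] = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "kit":
                    kit_id, frac, gran = value.split(":")
                    kits.append(KitSpec(kit_id, float(frac), int(gran)))
                elif key in ("n_samples", "universe_bp", "seed"):
                    kwargs[key] = int(value)
                elif key in ("variant_rate", "missing_rate"):
                    kwargs[key] = float(value)
                elif key == "chrom":
                    kwargs[key] = value
                else:
                    raise ValueError(f"unknown cohort spec key {key!r}")
        if kits:
            kwargs["kits"] = tuple(kits)
        return cls(**kwargs)


@dataclass
class StateMatrix:
    """Dense samples x positions truth oracle (never read by backends)."""

    sample_ids: List[str]
    chrom: str
    data: np.ndarray  # int8, shape (n_samples, universe_bp)

    def row(self, sample_id: str) -> np.ndarray:
        return self.data[self.sample_ids.index(sample_id)]

    def state(self, sample_id: str, pos: int) -> PositionState:
        return PositionState(int(self.row(sample_id)[pos]))

    @property
    def n_variant_cells(self) -> int:
        return int((self.data == VAR).sum())


@dataclass
class CohortData:
    """A generated cohort: truth, per-sample records and on-disk manifest."""

    spec: Optional[CohortSpec]
    matrix: StateMatrix
    kits: Dict[str, TargetRegionSet]
    sample_kits: Dict[str, str]
    variants: Dict[str, List[VariantCall]]
    missing: Dict[str, List[Tuple[str, int, int]]]
    roi: TargetRegionSet
    out_dir: Optional[str] = None
    manifest_path: Optional[str] = None
    genes_path: Optional[str] = None

    @property
    def sample_ids(self) -> List[str]:
        return self.matrix.sample_ids

    @property
    def n_variants_total(self) -> int:
        return sum(len(v) for v in self.variants.values())

    @property
    def n_missing_total(self) -> int:
        return sum(e - s for ivs in self.missing.values() for _, s, e in ivs)


def _make_kit(spec: KitSpec, chrom: str, universe_bp: int, rng: np.random.Generator) -> TargetRegionSet:
    slots = universe_bp // spec.granularity
    n_iv = max(1, round(spec.fraction * universe_bp / spec.granularity))
    if n_iv > slots:
        raise ValueError(f"kit {spec.kit_id}: fraction too high for granularity")
    starts = np.sort(rng.choice(slots, size=n_iv, replace=False)) * spec.granularity
    return TargetRegionSet.from_records(
        spec.kit_id,
        [(chrom, int(s), min(int(s) + spec.granularity, universe_bp)) for s in starts],
    )


def _make_gene_model(roi: TargetRegionSet, exons_per_gene: int = 10) -> List[Tuple[str, str, int, int]]:
    """Partition ROI intervals into consecutive pseudo-genes; rows (gene, chrom, s, e)."""
    rows = []
    idx = 0
    for chrom, ivs in roi.intervals.items():
        for i in range(0, len(ivs), exons_per_gene):
            idx += 1
            gene = f"GENE{idx:04d}"
            for s, e in ivs[i : i + exons_per_gene]:
                rows.append((gene, chrom, s, e))
    return rows


def generate_cohort(spec: CohortSpec, out_dir: Optional[str] = None) -> CohortData:
    """Draw one cohort; optionally write its files and manifest to ``out_dir``.

    Per sample, a single uniform draw per in-kit base is stratified into
    missing (first ``missing_rate``) and variant (next ``variant_rate``)
    so the two sets are disjoint by construction and count additivity is
    exact.  Alleles and annotations are assigned once per locus, so calls
    at a shared locus agree across samples.
    """
    rng = np.random.default_rng(spec.seed)
    kits = {k.kit_id: _make_kit(k, spec.chrom, spec.universe_bp, rng) for k in spec.kits}
    roi = TargetRegionSet.from_records(
        "roi", [r for kit in kits.values() for r in kit.iter_records()]
    )
    gene_rows = _make_gene_model(roi)

    def gene_at(pos: int) -> Tuple[str, int]:
        # gene_rows sorted by construction within chrom
        for gene, _chrom, s, e in gene_rows:
            if s <= pos < e:
                return gene, s
        return "INTERGENIC", 0

    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    sample_kits = {
        sid: spec.kits[i % len(spec.kits)].kit_id for i, sid in enumerate(sample_ids)
    }

    matrix = np.full((spec.n_samples, spec.universe_bp), MISS, dtype=np.int8)
    locus_registry: Dict[int, Tuple[str, str, AnnotationBundle]] = {}
    variants: Dict[str, List[VariantCall]] = {}
    missing: Dict[str, List[Tuple[str, int, int]]] = {}

    for si, sid in enumerate(sample_ids):
        kit = kits[sample_kits[sid]]
        in_kit = np.concatenate(
            [np.arange(s, e) for _c, s, e in kit.iter_records()]
        ) if kit.total_bases else np.empty(0, dtype=int)
        matrix[si, in_kit] = REF
        u = rng.random(in_kit.size)
        miss_pos = in_kit[u < spec.missing_rate]
        var_pos = in_kit[(u >= spec.missing_rate) & (u < spec.missing_rate + spec.variant_rate)]
        matrix[si, miss_pos] = MISS
        matrix[si, var_pos] = VAR
        missing[sid] = [
            (spec.chrom, s, e) for s, e in positions_to_intervals(miss_pos.tolist())
        ]
        calls = []
        for p in var_pos.tolist():
            if p not in locus_registry:
                ref = _BASES[rng.integers(4)]
                alt = _BASES[(rng.integers(3) + _BASES.index(ref) + 1) % 4]
                gene, gstart = gene_at(p)
                aa = (
                    f"{_AA[rng.integers(20)]}{(p - gstart) // 3 + 1}{_AA[rng.integers(20)]}"
                )
                locus_registry[p] = (ref, alt, AnnotationBundle(gene, aa))
            ref, alt, ann = locus_registry[p]
            calls.append(
                VariantCall(sid, GenomicLocus(spec.chrom, p), ref, alt, True, ann)
            )
        variants[sid] = calls

    data = CohortData(
        spec=spec,
        matrix=StateMatrix(sample_ids, spec.chrom, matrix),
        kits=kits,
        sample_kits=sample_kits,
        variants=variants,
        missing=missing,
        roi=roi,
    )
    if out_dir is not None:
        _write_cohort_files(data, gene_rows, out_dir)
    return data


def _write_cohort_files(
    data: CohortData, gene_rows: Sequence[Tuple[str, str, int, int]], out_dir: str
) -> None:
    os.makedirs(os.path.join(out_dir, "kits"), exist_ok=True)
    for kit in data.kits.values():
        io_formats.write_bed(kit, os.path.join(out_dir, "kits", kit.kit_id + ".bed"))

    genes_path = os.path.join(out_dir, "genes.tsv")
    with open(genes_path, "w") as fh:
        for gene, chrom, s, e in gene_rows:
            fh.write(f"{gene}\t{chrom}\t{s}\t{e}\n")

    manifest_path = os.path.join(out_dir, "manifest.tsv")
    chrom = data.matrix.chrom
    with open(manifest_path, "w") as fh:
        for sid in data.sample_ids:
            kit = data.kits[data.sample_kits[sid]]
            vcf_name, cov_name = sid + ".vcf", sid + ".cov.bed"
            vcf_path = os.path.join(out_dir, vcf_name)
            cov_path = os.path.join(out_dir, cov_name)
            io_formats.write_vcf(data.variants[sid], vcf_path, sid, [chrom])
            miss_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for mc, ms, me in data.missing[sid]:
                miss_by_chrom.setdefault(mc, []).append((ms, me))
            callable_ivs = {
                c: [
                    (s, e, SUFFICIENT)
                    for s, e in subtract(ivs, merge_intervals(miss_by_chrom.get(c, [])))
                ]
                for c, ivs in kit.intervals.items()
            }
            io_formats.write_callable_bed(CoverageProfile(sid, callable_ivs), cov_path)
            # relative paths keep the cohort directory relocatable and
            # byte-identical across working directories
            fh.write(f"{sid}\t{kit.kit_id}\t{vcf_name}\t{cov_name}\n")
    data.out_dir = out_dir
    data.manifest_path = manifest_path
    data.genes_path = genes_path


# ------------------------------------------------------------ worked fixture

# Hand-set 7 x 11 state table.  Only positions 0 and 8 (1-based Positions 1
# and 9) are normative worked examples; every other cell is declared filler
# chosen to exercise runs, variants and missing markers.  "." marks cells
# outside the sample's kit.
_FIG1_ROWS = {
    #        pos: 0    1    2    3    4    5    6    7    8    9    10
    "S1": list("R    R    R    R    M    R    R    R    V    R    R".split()),
    "S2": list("R    M    R    R    R    R    R    R    V    R    V".split()),
    "S3": list("R    R    R    R    R    R    M    R    V    R    R".split()),
    "S4": list("M    R    R    R    V    R    R    R    R    R    R".split()),
    "S5": list("V    R    R    R    R    R    R    R    .    .    .".split()),
    "S6": list("M    R    V    R    R    R    R    R    .    .    .".split()),
    "S7": list("R    R    R    R    R    R    R    V    .    .    .".split()),
}

_FIG1_KITS = {"kitFull": [(0, 11)], "kitShort": [(0, 8)]}
_FIG1_SAMPLE_KITS = {
    "S1": "kitFull", "S2": "kitFull", "S3": "kitFull", "S4": "kitFull",
    "S5": "kitShort", "S6": "kitShort", "S7": "kitShort",
}

# Per-locus alleles and annotations (consistent across carriers).
_FIG1_LOCI = {
    0: ("A", "T", "GENEA", "G12D"),
    2: ("C", "G", "GENEA", "R50Q"),
    4: ("G", "A", "GENEA", "L30F"),
    7: ("T", "C", "GENEB", "P10T"),
    8: ("A", "T", "GENEB", "V600E"),
    10: ("G", "T", "GENEB", "K90N"),
}

_FIG1_GENES = [("GENEA", "chr1", 0, 6), ("GENEB", "chr1", 6, 11)]

FIG1_CHROM = "chr1"
FIG1_UNIVERSE_BP = 11


def fig1_fixture(out_dir: Optional[str] = None) -> CohortData:
    """The 7-sample x 11-position worked cohort (see module docstring)."""
    chrom = FIG1_CHROM
    sample_ids = sorted(_FIG1_ROWS)
    kits = {
        kid: TargetRegionSet.from_records(kid, [(chrom, s, e) for s, e in ivs])
        for kid, ivs in _FIG1_KITS.items()
    }
    roi = TargetRegionSet.from_records(
        "roi", [r for k in kits.values() for r in k.iter_records()]
    )
    matrix = np.full((len(sample_ids), FIG1_UNIVERSE_BP), MISS, dtype=np.int8)
    variants: Dict[str, List[VariantCall]] = {}
    missing: Dict[str, List[Tuple[str, int, int]]] = {}
    code = {"R": REF, "V": VAR, "M": MISS}
    for si, sid in enumerate(sample_ids):
        calls: List[VariantCall] = []
        miss_pos: List[int] = []
        for pos, cell in enumerate(_FIG1_ROWS[sid]):
            if cell == ".":
                continue  # outside kit: inferred missing, never stored
            matrix[si, pos] = code[cell]
            if cell == "V":
                ref, alt, gene, aa = _FIG1_LOCI[pos]
                calls.append(
                    VariantCall(
                        sid, GenomicLocus(chrom, pos), ref, alt, True,
                        AnnotationBundle(gene, aa),
                    )
                )
            elif cell == "M":
                miss_pos.append(pos)
        variants[sid] = calls
        missing[sid] = [(chrom, s, e) for s, e in positions_to_intervals(miss_pos)]

    data = CohortData(
        spec=None,
        matrix=StateMatrix(sample_ids, chrom, matrix),
        kits=kits,
        sample_kits=dict(_FIG1_SAMPLE_KITS),
        variants=variants,
        missing=missing,
        roi=roi,
    )
    if out_dir is not None:
        _write_cohort_files(data, _FIG1_GENES, out_dir)
    return data


def load_cohort_into(data: CohortData, backends) -> None:
    """Write a cohort's truth records directly into backends (no file I/O)."""
    backends = list(backends)
    for be in backends:
        for kit in data.kits.values():
            be.register_kit(kit)
        for sid in data.sample_ids:
            be.put_sample(
                sid, data.sample_kits[sid], data.variants[sid], data.missing[sid]
            )
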