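"""End-to-end loading: classify every targeted position, write backends.

The loading pipeline mirrors the storage decision procedure position by
position but works on intervals: from a sample's capture-kit targets, its
variant calls and its coverage profile it derives (a) the in-target
intervals with insufficient depth (stored as missing), (b) the passing
in-target variant calls (stored), and implicitly (c) everything else
in-target (inferred reference, never stored).  Variants falling outside
the sample's kit are dropped with a warning — they cannot be represented
faithfully, since out-of-target positions are by definition untested.

"Sufficient quality" is a declared, configurable rule, not a value from
any upstream pipeline: a position is sufficient when its depth is at least
``min_depth`` (default 10) and no failing variant filter touches it.  A
call that failed its filters is demoted to MISSING over its span (a
low-confidence call is evidence of insufficient data, not of variation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .backends import Backend
from .intervals import (
    Interval,
    TargetRegionSet,
    intersect,
    merge_intervals,
    subtract,
    total_length,
)
from .state import NegstoreError, VariantCall

logger = logging.getLogger("negstore.ingest")

#: Sentinel depth for callable-interval coverage (depth known to suffice).
SUFFICIENT = None


@dataclass
class CoverageProfile:
    """Observed sequencing depth for one sample.

    ``intervals`` maps chromosome to sorted, non-overlapping
    ``(start, end, depth)`` tuples; ``depth`` of :data:`SUFFICIENT` (None)
    marks a callable interval whose exact depth is unknown but adequate.
    """

    sample_id: str
    intervals: Dict[str, List[Tuple[int, int, Optional[int]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            ivs.sort(key=lambda t: t[0])
            prev_end = -1
            for s, e, d in ivs:
                if s >= e:
                    raise ValueError(f"empty coverage interval {chrom}:{s}-{e}")
                if d is not None and d < 0:
                    raise ValueError("depth must be >= 0")
                if s < prev_end:
                    raise NegstoreError(
                        f"overlapping coverage intervals on {chrom} at {s}"
                    )
                prev_end = e

    def sufficient_intervals(self, min_depth: int) -> Dict[str, List[Interval]]:
        """Maximal merged intervals where depth >= min_depth (or callable)."""
        out: Dict[str, List[Interval]] = {}
        for chrom, ivs in self.intervals.items():
            keep = [(s, e) for s, e, d in ivs if d is None or d >= min_depth]
            if keep:
                out[chrom] = merge_intervals(keep)
        return out


@dataclass
class LoadStats:
    """Per-sample accounting of the load classification outcomes.

    Base conservation holds exactly: ``n_variant_span_bases +
    n_missing_stored + n_reference_inferred == n_target_bases`` (a
    multi-base call is one stored record, ``n_variants_stored``, but its
    whole reference span counts as VARIANT bases).
    """

    sample_id: str
    n_target_bases: int = 0
    n_variants_stored: int = 0
    n_variant_span_bases: int = 0
    n_missing_stored: int = 0
    n_reference_inferred: int = 0
    n_out_of_target_variants_dropped: int = 0

    def __add__(self, other: "LoadStats") -> "LoadStats":
        return LoadStats(
            sample_id="cohort",
            n_target_bases=self.n_target_bases + other.n_target_bases,
            n_variants_stored=self.n_variants_stored + other.n_variants_stored,
            n_variant_span_bases=self.n_variant_span_bases + other.n_variant_span_bases,
            n_missing_stored=self.n_missing_stored + other.n_missing_stored,
            n_reference_inferred=self.n_reference_inferred + other.n_reference_inferred,
            n_out_of_target_variants_dropped=(
                self.n_out_of_target_variants_dropped
                + other.n_out_of_target_variants_dropped
            ),
        )

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class IngestConfig:
    min_depth: int = 10
    replace: bool = False
    pad_bp: int = 0
    chrom_aliases: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")


def normalize_chrom(name: str, aliases: Dict[str, str]) -> str:
    """Map chromosome-name dialects ("1" vs "chr1") through an alias table."""
    return aliases.get(name, name)


def derive_missing(
    coverage: CoverageProfile, target: TargetRegionSet, min_depth: int
) -> List[Tuple[str, int, int]]:
    """Target intervals whose depth is below ``min_depth`` (or uncovered).

    Depth exactly equal to ``min_depth`` is sufficient.  The result is a
    sorted, disjoint, maximally merged subset of the target.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    sufficient = coverage.sufficient_intervals(min_depth)
    out: List[Tuple[str, int, int]] = []
    for chrom, target_ivs in target.intervals.items():
        ok = intersect(target_ivs, sufficient.get(chrom, []))
        for s, e in subtract(target_ivs, ok):
            out.append((chrom, s, e))
    return out


def _prepare_sample(
    sample_id: str,
    kit: TargetRegionSet,
    variants: Sequence[VariantCall],
    coverage: CoverageProfile,
    config: IngestConfig,
) -> Tuple[List[VariantCall], List[Tuple[str, int, int]], LoadStats]:
    """Classify one sample's inputs into storable variants + missing intervals."""
    stats = LoadStats(sample_id=sample_id, n_target_bases=kit.total_bases)

    in_kit: List[VariantCall] = []
    for v in variants:
        if kit.covers_interval(v.locus.chrom, v.locus.pos, v.end):
            in_kit.append(v)
        else:
            stats.n_out_of_target_variants_dropped += 1
            logger.warning(
                "%s: variant at %s:%d outside kit %s dropped",
                sample_id, v.locus.chrom, v.locus.pos, kit.kit_id,
            )

    missing_by_chrom: Dict[str, List[Interval]] = {}
    for chrom, s, e in derive_missing(coverage, kit, config.min_depth):
        missing_by_chrom.setdefault(chrom, []).append((s, e))

    # A failed-filter call is insufficient data over its span, not a variant.
    passing: List[VariantCall] = []
    for v in in_kit:
        if v.passed_filter:
            passing.append(v)
        else:
            missing_by_chrom.setdefault(v.locus.chrom, []).append((v.locus.pos, v.end))
    missing_by_chrom = {c: merge_intervals(ivs) for c, ivs in missing_by_chrom.items()}

    # Conflict rule: a confident call implies the data sufficed, so the
    # variant wins and any overlapping missing marker is suppressed.
    deduped: Dict[Tuple[str, int, str], VariantCall] = {}
    for v in passing:
        key = (v.locus.chrom, v.locus.pos, v.alt_allele)
        if key in deduped:
            if deduped[key].ref_allele != v.ref_allele:
                raise NegstoreError(
                    f"{sample_id}: conflicting ref alleles at {key[0]}:{key[1]}"
                )
            continue
        deduped[key] = v
    passing = sorted(deduped.values(), key=lambda v: (v.locus.chrom, v.locus.pos, v.alt_allele))
    spans_by_chrom: Dict[str, List[Interval]] = {}
    for v in passing:
        spans_by_chrom.setdefault(v.locus.chrom, []).append((v.locus.pos, v.end))
    for chrom, spans in spans_by_chrom.items():
        spans = merge_intervals(spans)
        if chrom in missing_by_chrom:
            before = total_length(missing_by_chrom[chrom])
            missing_by_chrom[chrom] = subtract(missing_by_chrom[chrom], spans)
            if total_length(missing_by_chrom[chrom]) != before:
                logger.warning(
                    "%s: variant overlapped a low-coverage interval on %s; "
                    "variant wins, missing marker suppressed", sample_id, chrom,
                )

    missing = [
        (chrom, s, e)
        for chrom in sorted(missing_by_chrom)
        for s, e in missing_by_chrom[chrom]
    ]
    stats.n_variants_stored = len(passing)
    stats.n_variant_span_bases = sum(v.end - v.locus.pos for v in passing)
    stats.n_missing_stored = sum(e - s for _, s, e in missing)
    stats.n_reference_inferred = (
        stats.n_target_bases - stats.n_variant_span_bases - stats.n_missing_stored
    )
    return passing, missing, stats


def load_sample(
    backends: Iterable[Backend],
    sample_id: str,
    kit: TargetRegionSet,
    variants: Sequence[VariantCall],
    coverage: CoverageProfile,
    config: IngestConfig | None = None,
) -> LoadStats:
    """Classify one sample and write it to every requested backend."""
    config = config or IngestConfig()
    backends = list(backends)
    for be in backends:
        if be.has_sample(sample_id) and not config.replace:
            raise NegstoreError(
                f"sample {sample_id!r} already loaded in {be.kind.value}; "
                "pass replace=True to overwrite"
            )
    passing, missing, stats = _prepare_sample(sample_id, kit, variants, coverage, config)
    for be in backends:
        be.register_kit(kit)
        be.put_sample(sample_id, kit.kit_id, passing, missing)
    return stats


@dataclass
class ManifestEntry:
    sample_id: str
    kit_id: str
    variants_path: str
    coverage_path: str


def read_manifest(path: str) -> List[ManifestEntry]:
    """Tab-delimited manifest: sample_id, kit_id, variants_path, coverage_path."""
    from .state import ParseError

    entries = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"expected 4 tab-separated fields, got {len(parts)}", path, i)
            entries.append(ManifestEntry(*parts))
    return entries


def load_cohort(
    manifest_path: str,
    backends: Iterable[Backend],
    config: IngestConfig | None = None,
    kits_dir: str | None = None,
) -> Tuple[LoadStats, List[LoadStats]]:
    """Load every manifest sample; returns (cohort summary, per-sample stats).

    Kit BED files are resolved as ``<kits_dir>/<kit_id>.bed`` (default:
    a ``kits`` directory next to the manifest).  Input dialects are chosen
    by extension: ``.vcf``/``.vcf.gz`` vs MAF-like TSV for variants,
    ``.bed`` (callable intervals) vs per-base depth TSV for coverage.
    All kit targets are registered on every backend *before* any sample is
    written, so the backends' default ROI (the union of kit targets) is
    identical no matter how many samples have loaded.
    """
    import os

    from . import io_formats

    config = config or IngestConfig()
    backends = list(backends)
    entries = read_manifest(manifest_path)
    if kits_dir is None:
        kits_dir = os.path.join(os.path.dirname(os.path.abspath(manifest_path)), "kits")

    kits: Dict[str, TargetRegionSet] = {}
    for entry in entries:
        if entry.kit_id not in kits:
            bed = os.path.join(kits_dir, entry.kit_id + ".bed")
            if not os.path.exists(bed):
                raise FileNotFoundError(f"kit file not found: {bed}")
            kit = io_formats.read_bed(bed, kit_id=entry.kit_id, pad=config.pad_bp)
            kits[entry.kit_id] = kit
    for be in backends:
        for kit in kits.values():
            be.register_kit(kit)

    manifest_dir = os.path.dirname(os.path.abspath(manifest_path))
    per_sample: List[LoadStats] = []
    for entry in entries:
        # relative manifest paths resolve against the manifest's directory
        vpath = os.path.join(manifest_dir, entry.variants_path)
        cpath = os.path.join(manifest_dir, entry.coverage_path)
        for p in (vpath, cpath):
            if not os.path.exists(p):
                raise FileNotFoundError(f"sample {entry.sample_id}: input not found: {p}")
        variants = io_formats.read_variants(
            vpath, sample_id=entry.sample_id, aliases=config.chrom_aliases
        )
        coverage = io_formats.read_coverage(
            cpath, sample_id=entry.sample_id, aliases=config.chrom_aliases
        )
        stats = load_sample(
            backends, entry.sample_id, kits[entry.kit_id], variants, coverage, config
        )
        logger.info("loaded %s: %s", entry.sample_id, stats.as_dict())
        per_sample.append(stats)

    total = LoadStats(sample_id="cohort")
    for s in per_sample:
        total = total + s
    return total, per_sample
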