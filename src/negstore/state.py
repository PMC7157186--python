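"""Core three-state model and the two decision procedures of the store.

A tested genomic position in one sample is in exactly one of three states:
REFERENCE (matches the reference genome), VARIANT (a confident call differs
from reference) or MISSING (insufficient data to decide).  The negative
storage model persists only VARIANT and in-target MISSING records;
REFERENCE is *inferred* at query time from target-region membership plus
the absence of any stored record, and everything outside a sample's target
region resolves to MISSING.

Two pure functions define the whole model:

* :func:`classify_for_storage` — given target membership, data quality and
  variant status of a position, decide what (if anything) to persist.
* :func:`resolve_state` — given what the store holds for a queried
  position, reconstruct its precise state.  The check order is fixed:
  target membership, then variant, then missing, then inferred reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Optional

_ALLELE_ALPHABET = frozenset("ACGTN")


class NegstoreError(Exception):
    """Base class for package errors."""


class DataCorruptionError(NegstoreError):
    """The store holds mutually contradictory records for one position."""


class ContractViolationError(NegstoreError):
    """A write violates a storage-model precondition (e.g. out-of-target record)."""


class UnknownSampleError(KeyError, NegstoreError):
    """Lookup for a sample the store has never seen (distinct from MISSING)."""


class EmptyMatchError(NegstoreError):
    """A mutation query matched no stored variant."""


class ParseError(NegstoreError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:" + (str(line) if line is not None else "?") + ": "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class PositionState(enum.IntEnum):
    """The three possible resolved states of a (sample, position) pair."""

    REFERENCE = 0
    VARIANT = 1
    MISSING = 2

    @property
    def short(self) -> str:
        return {"REFERENCE": "ref", "VARIANT": "alt", "MISSING": "missing"}[self.name]


class StorageAction(enum.Enum):
    """Outcome of the ingest-time classification of one position."""

    STORE_NOTHING_OUT_OF_TARGET = "out_of_target"
    STORE_MISSING = "store_missing"
    STORE_VARIANT = "store_variant"
    STORE_NOTHING_INFER_REFERENCE = "infer_reference"


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A single genomic position, 0-based."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


@dataclass
class AnnotationBundle:
    """Contextual annotation carried by a variant (gene, protein change, ...)."""

    gene_symbol: Optional[str] = None
    aa_change: Optional[str] = None
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aa_change is not None and self.gene_symbol is None:
            raise ValueError("aa_change requires gene_symbol")


def _validate_allele(allele: str, label: str) -> None:
    if not allele:
        raise ValueError(f"{label} allele must be non-empty")
    bad = set(allele.upper()) - _ALLELE_ALPHABET
    if bad:
        raise ValueError(f"{label} allele {allele!r} contains non-ACGTN characters {sorted(bad)}")


@dataclass
class VariantCall:
    """One sample's difference from the reference genome at one locus.

    ``ref_allele`` spans ``[locus.pos, locus.pos + len(ref_allele))``; for
    range queries and block construction a multi-base call occupies that
    whole span, while for element counting it is a single stored record.
    """

    sample_id: str
    locus: GenomicLocus
    ref_allele: str
    alt_allele: str
    passed_filter: bool = True
    annotation: AnnotationBundle = field(default_factory=AnnotationBundle)

    def __post_init__(self) -> None:
        _validate_allele(self.ref_allele, "ref")
        _validate_allele(self.alt_allele, "alt")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")

    @property
    def end(self) -> int:
        """Exclusive end of the reference-allele span."""
        return self.locus.pos + len(self.ref_allele)


@dataclass(frozen=True)
class MissingRecord:
    """A stored in-target interval of insufficient data for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("missing interval must be non-empty")


@dataclass
class StoredLookup:
    """What the store knows about one (sample, locus) — input to resolution."""

    in_target: bool
    has_variant: bool = False
    has_missing: bool = False
    variant: Optional[VariantCall] = None


def classify_for_storage(
    in_target: bool, sufficient_quality: bool, is_variant: bool
) -> StorageAction:
    """Decide what to persist for one classified position.

    Out-of-target positions store nothing (their missing-ness is inferred
    from kit membership at query time).  In-target positions with
    insufficient data store an explicit missing marker.  Confident variants
    are stored; confident reference genotypes are *never* stored — that is
    the negative-storage idea.
    """
    if not in_target:
        return StorageAction.STORE_NOTHING_OUT_OF_TARGET
    if not sufficient_quality:
        return StorageAction.STORE_MISSING
    if is_variant:
        return StorageAction.STORE_VARIANT
    return StorageAction.STORE_NOTHING_INFER_REFERENCE


def resolve_state(lookup: StoredLookup) -> PositionState:
    """Reconstruct the precise state of a queried position.

    Check order is fixed: target membership first (outside the target
    region nothing was tested, so the state is MISSING no matter what),
    then stored variant, then stored missing marker, and finally inferred
    REFERENCE when nothing at all is stored for an in-target position.
    """
    if lookup.has_variant and lookup.has_missing:
        raise DataCorruptionError(
            "position flagged both variant and missing for one sample"
        )
    if not lookup.in_target:
        return PositionState.MISSING
    if lookup.has_variant:
        return PositionState.VARIANT
    if lookup.has_missing:
        return PositionState.MISSING
    return PositionState.REFERENCE


def classify_then_resolve_roundtrip(
    state_truth: PositionState, in_target: bool
) -> PositionState:
    """Compose classification and resolution for one position of known truth.

    The core correctness property of the model: for in-target positions the
    composition is the identity; out-of-target positions always come back
    MISSING because nothing about them is ever stored.
    """
    action = classify_for_storage(
        in_target=in_target,
        sufficient_quality=state_truth is not PositionState.MISSING,
        is_variant=state_truth is PositionState.VARIANT,
    )
    lookup = StoredLookup(
        in_target=in_target,
        has_variant=action is StorageAction.STORE_VARIANT,
        has_missing=action is StorageAction.STORE_MISSING,
    )
    return resolve_state(lookup)
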