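"""Three interchangeable persistence engines over embedded SQLite.

All three storage models answer the same point/range lookup contract and,
passed through :func:`negstore.state.resolve_state`, give identical answers
for every (sample, position); they differ only in *what* they persist:

* **NSM** (negative storage model) — persists only variant records and
  explicit in-target missing positions.  Reference is inferred from kit
  membership plus absence of records.
* **FSM** (full storage model) — one explicit state record per (sample,
  position) of the cohort region of interest (ROI).  Positions of the ROI
  outside a sample's kit are stored as MISSING.
* **BLSM** (block storage model) — maximal runs of identical state stored
  as single block records, analogous to gVCF reference blocks; variant
  blocks span their reference allele and carry the call.

Each backend is a single SQLite file (or ``:memory:``).  Composite
``(sample, chrom, pos)`` and ``(chrom, pos)`` indexes are created after
bulk load, which is much faster than maintaining them during inserts.
"""

from __future__ import annotations

import enum
import json
import os
import sqlite3
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import (
    Interval,
    TargetRegionSet,
    merge_intervals,
    positions_to_intervals,
    subtract,
)
from .state import (
    AnnotationBundle,
    ContractViolationError,
    DataCorruptionError,
    GenomicLocus,
    NegstoreError,
    PositionState,
    StoredLookup,
    UnknownSampleError,
    VariantCall,
)

REF = int(PositionState.REFERENCE)
VAR = int(PositionState.VARIANT)
MISS = int(PositionState.MISSING)


class BackendKind(enum.Enum):
    NSM = "nsm"
    FSM = "fsm"
    BLSM = "blsm"


class FsmBudgetError(NegstoreError):
    """FSM materialization would exceed the configured cell budget."""


@dataclass
class StateRun:
    """One maximal run of a single resolved state, half-open."""

    chrom: str
    start: int
    end: int
    state: PositionState

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StateBlock:
    """A BLSM storage unit: a contiguous run of one state for one sample.

    VARIANT blocks span the call's reference allele and carry it; blocks of
    other states never carry a variant.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    state: PositionState
    variant: Optional[VariantCall] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("block must be non-empty")
        if self.variant is not None and self.state is not PositionState.VARIANT:
            raise ValueError("only VARIANT blocks carry a variant call")


@dataclass
class ElementCount:
    """Stored-element accounting for one backend (the 'DB rows' view)."""

    backend: BackendKind
    n_elements: int
    n_variant: int = 0
    n_missing: int = 0
    n_reference: int = 0
    n_blocks: int = 0


def fsm_element_count(n_samples: int, roi_bases: int) -> int:
    """Analytic FSM size: one element per (sample, ROI position).

    Used instead of materialization for cohorts whose cell count would be
    impractical to hold (e.g. hundreds of samples over tens of megabases).
    """
    if n_samples < 0 or roi_bases < 0:
        raise ValueError("counts must be non-negative")
    return n_samples * roi_bases


def vosm_element_count(n_variants: int) -> int:
    """Analytic element count of a variant-only store (not queryable here).

    Variant-only storage is excluded as a backend because it cannot
    distinguish reference from missing; it exists only as this counter for
    storage-reduction arithmetic.
    """
    return int(n_variants)


def vosm_reduction_percent(variant_rate: float) -> float:
    """Percent element reduction of variant-only storage vs the FSM.

    At a per-base variation rate ``r`` the variant-only store keeps a
    fraction ``r`` of the FSM's elements, a ``(1 - r) * 100`` percent
    reduction — above 99% for rates below 1%.
    """
    if not 0.0 <= variant_rate <= 1.0:
        raise ValueError("variant_rate must be in [0, 1]")
    return (1.0 - variant_rate) * 100.0


def compress_runs(
    dense_states: Sequence[int] | np.ndarray,
    origin: GenomicLocus,
    sample_id: str = "",
) -> List[StateBlock]:
    """Run-length encode a dense per-position state vector into blocks.

    Output blocks are maximal equal-state runs; their lengths sum to the
    input length and expansion inverts compression exactly.
    """
    arr = np.asarray([int(s) for s in dense_states] if not isinstance(dense_states, np.ndarray) else dense_states)
    if arr.size == 0:
        raise ValueError("dense_states must be non-empty")
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return [
        StateBlock(
            sample_id=sample_id,
            chrom=origin.chrom,
            start=origin.pos + int(s),
            end=origin.pos + int(e),
            state=PositionState(int(arr[s])),
        )
        for s, e in zip(starts, ends)
    ]


def expand_blocks(blocks: Sequence[StateBlock]) -> np.ndarray:
    """Inverse of :func:`compress_runs` for contiguous block lists."""
    if not blocks:
        return np.zeros(0, dtype=np.int8)
    return np.repeat(
        np.asarray([int(b.state) for b in blocks], dtype=np.int8),
        np.asarray([b.end - b.start for b in blocks]),
    )


def runs_to_dense(runs: Sequence[StateRun], start: int, end: int) -> np.ndarray:
    """Expand a tiling run list over [start, end) to a dense int8 vector."""
    out = np.empty(end - start, dtype=np.int8)
    cursor = start
    for r in runs:
        if r.start != cursor:
            raise ValueError("runs do not tile the requested window")
        out[r.start - start : r.end - start] = int(r.state)
        cursor = r.end
    if cursor != end:
        raise ValueError("runs do not tile the requested window")
    return out


def dense_states(
    kit: TargetRegionSet,
    variants: Sequence[VariantCall],
    missing: Dict[str, List[Interval]],
    chrom: str,
    s: int,
    e: int,
) -> np.ndarray:
    """Dense resolved states over one ROI window for one sample.

    Out-of-kit positions are MISSING, in-kit default REFERENCE, then stored
    missing intervals and variant spans are painted on top.
    """
    arr = np.full(e - s, MISS, dtype=np.int8)
    for ks, ke in kit.clip(chrom, s, e):
        arr[ks - s : ke - s] = REF
    for ms, me in missing.get(chrom, []):
        lo, hi = max(ms, s), min(me, e)
        if lo < hi:
            arr[lo - s : hi - s] = MISS
    for v in variants:
        if v.locus.chrom != chrom:
            continue
        lo, hi = max(v.locus.pos, s), min(v.end, e)
        if lo < hi:
            arr[lo - s : hi - s] = VAR
    return arr


def _merge_adjacent(runs: List[StateRun]) -> List[StateRun]:
    out: List[StateRun] = []
    for r in runs:
        if out and out[-1].state is r.state and out[-1].end == r.start and out[-1].chrom == r.chrom:
            out[-1] = StateRun(r.chrom, out[-1].start, r.end, r.state)
        else:
            out.append(r)
    return out


_COMMON_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS kits (kit_id TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS kit_intervals (
    kit_id TEXT NOT NULL, chrom TEXT NOT NULL,
    start INTEGER NOT NULL, end INTEGER NOT NULL);
CREATE TABLE IF NOT EXISTS roi_intervals (
    chrom TEXT NOT NULL, start INTEGER NOT NULL, end INTEGER NOT NULL);
CREATE TABLE IF NOT EXISTS samples (
    sample_id TEXT PRIMARY KEY, kit_id TEXT NOT NULL REFERENCES kits(kit_id));
"""


class Backend:
    """Shared cohort bookkeeping: kits, samples, region of interest.

    Subclasses add their model-specific tables and implement the storage
    and lookup contract.  ``path`` may be ``":memory:"`` for tests.
    """

    kind: BackendKind

    def __init__(self, path: str = ":memory:") -> None:
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.executescript(_COMMON_SCHEMA + self._schema())
        self._conn.execute("PRAGMA synchronous=OFF")
        self._kit_cache: Dict[str, TargetRegionSet] = {}
        self._roi_cache: Optional[TargetRegionSet] = None
        self._indexed = False

    # -- schema hooks -------------------------------------------------
    def _schema(self) -> str:
        return ""

    def _index_sql(self) -> List[str]:
        return []

    # -- cohort bookkeeping -------------------------------------------
    def register_kit(self, kit: TargetRegionSet) -> None:
        cur = self._conn.cursor()
        row = cur.execute("SELECT 1 FROM kits WHERE kit_id=?", (kit.kit_id,)).fetchone()
        if row:
            return
        cur.execute("INSERT INTO kits VALUES (?)", (kit.kit_id,))
        cur.executemany(
            "INSERT INTO kit_intervals VALUES (?,?,?,?)",
            [(kit.kit_id, c, s, e) for c, s, e in kit.iter_records()],
        )
        self._conn.commit()
        self._kit_cache[kit.kit_id] = kit
        if self._explicit_roi() is None:
            self._roi_cache = None  # ROI defaults to union of kits

    def set_roi(self, roi: TargetRegionSet) -> None:
        """Declare the cohort region of interest explicitly (else: kit union)."""
        cur = self._conn.cursor()
        cur.execute("DELETE FROM roi_intervals")
        cur.executemany(
            "INSERT INTO roi_intervals VALUES (?,?,?)",
            [(c, s, e) for c, s, e in roi.iter_records()],
        )
        cur.execute("INSERT OR REPLACE INTO meta VALUES ('roi_explicit', '1')")
        self._conn.commit()
        self._roi_cache = TargetRegionSet.from_records("roi", roi.iter_records())

    def _explicit_roi(self) -> Optional[TargetRegionSet]:
        row = self._conn.execute("SELECT value FROM meta WHERE key='roi_explicit'").fetchone()
        if not row:
            return None
        recs = self._conn.execute(
            "SELECT chrom, start, end FROM roi_intervals ORDER BY rowid"
        ).fetchall()
        return TargetRegionSet.from_records("roi", recs)

    def roi(self) -> TargetRegionSet:
        if self._roi_cache is None:
            explicit = self._explicit_roi()
            if explicit is not None:
                self._roi_cache = explicit
            else:
                recs = self._conn.execute(
                    "SELECT chrom, start, end FROM kit_intervals ORDER BY rowid"
                ).fetchall()
                self._roi_cache = TargetRegionSet.from_records("roi", recs)
        return self._roi_cache

    def kit(self, kit_id: str) -> TargetRegionSet:
        if kit_id not in self._kit_cache:
            recs = self._conn.execute(
                "SELECT chrom, start, end FROM kit_intervals WHERE kit_id=?", (kit_id,)
            ).fetchall()
            if not recs:
                exists = self._conn.execute(
                    "SELECT 1 FROM kits WHERE kit_id=?", (kit_id,)
                ).fetchone()
                if not exists:
                    raise KeyError(f"unknown kit {kit_id!r}")
            self._kit_cache[kit_id] = TargetRegionSet.from_records(kit_id, recs)
        return self._kit_cache[kit_id]

    def kit_of(self, sample_id: str) -> TargetRegionSet:
        row = self._conn.execute(
            "SELECT kit_id FROM samples WHERE sample_id=?", (sample_id,)
        ).fetchone()
        if row is None:
            raise UnknownSampleError(sample_id)
        return self.kit(row[0])

    def samples(self) -> List[str]:
        return [r[0] for r in self._conn.execute("SELECT sample_id FROM samples ORDER BY rowid")]

    def has_sample(self, sample_id: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM samples WHERE sample_id=?", (sample_id,)
        ).fetchone() is not None

    def _register_sample(self, sample_id: str, kit_id: str) -> None:
        self.kit(kit_id)  # raises on unknown kit
        self._conn.execute(
            "INSERT OR REPLACE INTO samples VALUES (?,?)", (sample_id, kit_id)
        )

    # -- storage contract ---------------------------------------------
    def put_sample(
        self,
        sample_id: str,
        kit_id: str,
        variants: Sequence[VariantCall],
        missing: Sequence[Tuple[str, int, int]],
    ) -> None:
        """Persist one sample's records; idempotent (re-put replaces).

        ``variants`` and ``missing`` must already lie inside the sample's
        kit targets; overlap between a variant span and a missing interval
        is corruption (resolved upstream by ingest).
        """
        kit = self.kit(kit_id)
        self._validate_records(kit, variants, missing)
        self._register_sample(sample_id, kit_id)
        canon = sorted(variants, key=lambda v: (v.locus.chrom, v.locus.pos, v.alt_allele))
        self._delete_sample_rows(sample_id)
        self._write_sample(sample_id, kit, canon, self._canon_missing(missing))
        self._conn.commit()

    @staticmethod
    def _canon_missing(missing: Sequence[Tuple[str, int, int]]) -> Dict[str, List[Interval]]:
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, s, e in missing:
            by_chrom.setdefault(chrom, []).append((s, e))
        return {c: merge_intervals(v) for c, v in by_chrom.items()}

    def _validate_records(
        self,
        kit: TargetRegionSet,
        variants: Sequence[VariantCall],
        missing: Sequence[Tuple[str, int, int]],
    ) -> None:
        seen: Dict[Tuple[str, int], str] = {}
        for v in variants:
            if not kit.covers_interval(v.locus.chrom, v.locus.pos, v.end):
                raise ContractViolationError(
                    f"variant at {v.locus.chrom}:{v.locus.pos} outside kit {kit.kit_id!r}"
                )
            key = (v.locus.chrom, v.locus.pos)
            if key in seen and seen[key] != v.ref_allele:
                raise DataCorruptionError(
                    f"conflicting ref alleles at {key[0]}:{key[1]}"
                )
            seen[key] = v.ref_allele
        miss = self._canon_missing(missing)
        for chrom, ivs in miss.items():
            for s, e in ivs:
                if not kit.covers_interval(chrom, s, e):
                    raise ContractViolationError(
                        f"missing interval {chrom}:{s}-{e} outside kit {kit.kit_id!r}"
                    )
        for v in variants:
            for s, e in miss.get(v.locus.chrom, []):
                if s < v.end and v.locus.pos < e:
                    raise DataCorruptionError(
                        f"variant and missing overlap at {v.locus.chrom}:{v.locus.pos}"
                    )

    # -- subclass storage hooks ---------------------------------------
    def _delete_sample_rows(self, sample_id: str) -> None:
        raise NotImplementedError

    def _write_sample(
        self,
        sample_id: str,
        kit: TargetRegionSet,
        variants: List[VariantCall],
        missing: Dict[str, List[Interval]],
    ) -> None:
        raise NotImplementedError

    # -- lookup contract ----------------------------------------------
    def lookup_point(self, sample_id: str, locus: GenomicLocus) -> StoredLookup:
        raise NotImplementedError

    def lookup_range(
        self, sample_id: str, chrom: str, start: int, end: int
    ) -> List[StateRun]:
        raise NotImplementedError

    def resolve_point(self, sample_id: str, locus: GenomicLocus) -> PositionState:
        from .state import resolve_state

        return resolve_state(self.lookup_point(sample_id, locus))

    def _check_range(self, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"inverted or empty range [{start}, {end})")

    def iter_variants(
        self,
        sample_id: Optional[str] = None,
        gene_symbol: Optional[str] = None,
        aa_change: Optional[str] = None,
    ) -> List[VariantCall]:
        raise NotImplementedError

    def variant_loci(
        self, gene_symbol: Optional[str] = None, aa_change: Optional[str] = None
    ) -> List[GenomicLocus]:
        """Distinct loci of stored variants matching the annotation filter."""
        loci = {
            (v.locus.chrom, v.locus.pos)
            for v in self.iter_variants(gene_symbol=gene_symbol, aa_change=aa_change)
        }
        return [GenomicLocus(c, p) for c, p in sorted(loci)]

    def count_elements(self) -> ElementCount:
        raise NotImplementedError

    # -- maintenance ---------------------------------------------------
    def create_indexes(self) -> None:
        """Create composite lookup indexes; fastest after bulk load."""
        for sql in self._index_sql():
            self._conn.execute(sql)
        self._conn.commit()
        self._indexed = True

    def flush_cache(self) -> None:
        """Benchmark hook: drop connection-level caches by reconnecting."""
        if self.path == ":memory:":
            return
        self._conn.commit()
        self._conn.close()
        self._conn = sqlite3.connect(self.path)

    def db_size_bytes(self) -> int:
        if self.path == ":memory:":
            page = self._conn.execute("PRAGMA page_size").fetchone()[0]
            count = self._conn.execute("PRAGMA page_count").fetchone()[0]
            return page * count
        self._conn.commit()
        return os.path.getsize(self.path)

    def close(self) -> None:
        self._conn.commit()
        self._conn.close()


def _variant_row(sample_id: str, v: VariantCall) -> tuple:
    a = v.annotation
    extra = json.dumps(a.extra, sort_keys=True) if a.extra else None
    return (
        sample_id, v.locus.chrom, v.locus.pos, v.end,
        v.ref_allele, v.alt_allele, a.gene_symbol, a.aa_change, extra,
    )


def _row_to_variant(row: tuple) -> VariantCall:
    sample_id, chrom, pos, _end, ref, alt, gene, aa, extra = row
    ann = AnnotationBundle(
        gene_symbol=gene, aa_change=aa, extra=json.loads(extra) if extra else {}
    )
    return VariantCall(sample_id, GenomicLocus(chrom, pos), ref, alt, True, ann)


_VCOLS = "sample_id, chrom, pos, end, ref, alt, gene, aa_change, extra"


def _variant_filter_sql(
    sample_id: Optional[str], gene_symbol: Optional[str], aa_change: Optional[str]
) -> Tuple[str, list]:
    clauses, params = [], []
    if sample_id is not None:
        clauses.append("sample_id=?")
        params.append(sample_id)
    if gene_symbol is not None:
        clauses.append("gene=? COLLATE NOCASE")
        params.append(gene_symbol)
    if aa_change is not None:
        clauses.append("aa_change=?")
        params.append(aa_change)
    where = (" WHERE " + " AND ".join(clauses)) if clauses else ""
    return where, params


class NsmBackend(Backend):
    """Negative storage model: variants + explicit in-target missing only."""

    kind = BackendKind.NSM

    def _schema(self) -> str:
        return """
        CREATE TABLE IF NOT EXISTS variants (
            sample_id TEXT NOT NULL, chrom TEXT NOT NULL,
            pos INTEGER NOT NULL, end INTEGER NOT NULL,
            ref TEXT NOT NULL, alt TEXT NOT NULL,
            gene TEXT, aa_change TEXT, extra TEXT);
        CREATE TABLE IF NOT EXISTS missing (
            sample_id TEXT NOT NULL, chrom TEXT NOT NULL, pos INTEGER NOT NULL);
        """

    def _index_sql(self) -> List[str]:
        return [
            "CREATE INDEX IF NOT EXISTS ix_var_scp ON variants(sample_id, chrom, pos)",
            "CREATE INDEX IF NOT EXISTS ix_var_cp ON variants(chrom, pos)",
            "CREATE INDEX IF NOT EXISTS ix_var_gene ON variants(gene, aa_change)",
            "CREATE INDEX IF NOT EXISTS ix_miss_scp ON missing(sample_id, chrom, pos)",
            "CREATE INDEX IF NOT EXISTS ix_miss_cp ON missing(chrom, pos)",
        ]

    def _delete_sample_rows(self, sample_id: str) -> None:
        self._conn.execute("DELETE FROM variants WHERE sample_id=?", (sample_id,))
        self._conn.execute("DELETE FROM missing WHERE sample_id=?", (sample_id,))

    def _write_sample(self, sample_id, kit, variants, missing) -> None:
        cur = self._conn.cursor()
        cur.executemany(
            f"INSERT INTO variants ({_VCOLS}) VALUES (?,?,?,?,?,?,?,?,?)",
            [_variant_row(sample_id, v) for v in variants],
        )
        for chrom, ivs in missing.items():
            for s, e in ivs:
                cur.executemany(
                    "INSERT INTO missing VALUES (?,?,?)",
                    ((sample_id, chrom, p) for p in range(s, e)),
                )

    def lookup_point(self, sample_id: str, locus: GenomicLocus) -> StoredLookup:
        kit = self.kit_of(sample_id)
        if not kit.contains(locus.chrom, locus.pos):
            return StoredLookup(in_target=False)
        row = self._conn.execute(
            f"SELECT {_VCOLS} FROM variants"
            " WHERE sample_id=? AND chrom=? AND pos<=? AND end>?",
            (sample_id, locus.chrom, locus.pos, locus.pos),
        ).fetchone()
        if row:
            return StoredLookup(True, has_variant=True, variant=_row_to_variant(row))
        miss = self._conn.execute(
            "SELECT 1 FROM missing WHERE sample_id=? AND chrom=? AND pos=?",
            (sample_id, locus.chrom, locus.pos),
        ).fetchone()
        return StoredLookup(True, has_missing=miss is not None)

    def lookup_range(self, sample_id, chrom, start, end) -> List[StateRun]:
        self._check_range(start, end)
        kit = self.kit_of(sample_id)
        tested = kit.clip(chrom, start, end)
        untested = subtract([(start, end)], tested)
        miss_pos = [
            r[0]
            for r in self._conn.execute(
                "SELECT pos FROM missing WHERE sample_id=? AND chrom=?"
                " AND pos>=? AND pos<? ORDER BY pos",
                (sample_id, chrom, start, end),
            )
        ]
        miss_iv = positions_to_intervals(miss_pos)
        var_iv = merge_intervals(
            (max(r[0], start), min(r[1], end))
            for r in self._conn.execute(
                "SELECT pos, end FROM variants WHERE sample_id=? AND chrom=?"
                " AND end>? AND pos<?",
                (sample_id, chrom, start, end),
            )
        )
        ref_iv = subtract(subtract(tested, miss_iv), var_iv)
        runs = (
            [StateRun(chrom, s, e, PositionState.MISSING) for s, e in untested]
            + [StateRun(chrom, s, e, PositionState.MISSING) for s, e in miss_iv]
            + [StateRun(chrom, s, e, PositionState.VARIANT) for s, e in var_iv]
            + [StateRun(chrom, s, e, PositionState.REFERENCE) for s, e in ref_iv]
        )
        runs.sort(key=lambda r: r.start)
        return _merge_adjacent(runs)

    def iter_variants(self, sample_id=None, gene_symbol=None, aa_change=None):
        where, params = _variant_filter_sql(sample_id, gene_symbol, aa_change)
        rows = self._conn.execute(
            f"SELECT {_VCOLS} FROM variants{where} ORDER BY chrom, pos, sample_id", params
        ).fetchall()
        return [_row_to_variant(r) for r in rows]

    def count_elements(self) -> ElementCount:
        n_var = self._conn.execute("SELECT COUNT(*) FROM variants").fetchone()[0]
        n_miss = self._conn.execute("SELECT COUNT(*) FROM missing").fetchone()[0]
        return ElementCount(self.kind, n_var + n_miss, n_var, n_miss, 0, 0)


class FsmBackend(Backend):
    """Full storage model: an explicit state for every (sample, ROI position).

    Refuses to materialize cohorts beyond ``cell_budget`` cells; counts at
    that scale are available analytically via :func:`fsm_element_count`.
    """

    def __init__(self, path: str = ":memory:", cell_budget: int = 10**8) -> None:
        super().__init__(path)
        self.cell_budget = cell_budget

    kind = BackendKind.FSM

    def _schema(self) -> str:
        return """
        CREATE TABLE IF NOT EXISTS fsm_states (
            sample_id TEXT NOT NULL, chrom TEXT NOT NULL, pos INTEGER NOT NULL,
            state INTEGER NOT NULL, anchor_pos INTEGER,
            ref TEXT, alt TEXT, gene TEXT, aa_change TEXT, extra TEXT);
        """

    def _index_sql(self) -> List[str]:
        return [
            "CREATE INDEX IF NOT EXISTS ix_fsm_scp ON fsm_states(sample_id, chrom, pos)",
            "CREATE INDEX IF NOT EXISTS ix_fsm_cp ON fsm_states(chrom, pos)",
        ]

    def _delete_sample_rows(self, sample_id: str) -> None:
        self._conn.execute("DELETE FROM fsm_states WHERE sample_id=?", (sample_id,))

    def _write_sample(self, sample_id, kit, variants, missing) -> None:
        roi = self.roi()
        n_after = len(self.samples())
        if n_after * roi.total_bases > self.cell_budget:
            raise FsmBudgetError(
                f"{n_after} samples x {roi.total_bases} ROI bases exceeds the "
                f"cell budget of {self.cell_budget}; use fsm_element_count() "
                "for analytic accounting instead of materializing"
            )
        cur = self._conn.cursor()
        # Bulk path: every non-variant cell is a bare (sample, chrom, pos,
        # state) row; the sparse variant cells carry alleles and anchors.
        from itertools import repeat

        for chrom, s, e in roi.iter_records():
            arr = dense_states(kit, variants, missing, chrom, s, e)
            nonvar = np.flatnonzero(arr != VAR)
            cur.executemany(
                "INSERT INTO fsm_states (sample_id, chrom, pos, state)"
                " VALUES (?,?,?,?)",
                zip(repeat(sample_id), repeat(chrom),
                    (nonvar + s).tolist(), arr[nonvar].tolist()),
            )
        var_rows = []
        for v in variants:
            a = v.annotation
            extra = json.dumps(a.extra, sort_keys=True) if a.extra else None
            chrom, anchor = v.locus.chrom, v.locus.pos
            var_rows.append((sample_id, chrom, anchor, VAR, anchor,
                             v.ref_allele, v.alt_allele, a.gene_symbol,
                             a.aa_change, extra))
            for p in range(anchor + 1, v.end):
                var_rows.append((sample_id, chrom, p, VAR, anchor,
                                 None, None, None, None, None))
        cur.executemany("INSERT INTO fsm_states VALUES (?,?,?,?,?,?,?,?,?,?)", var_rows)

    def _anchor_variant(self, sample_id: str, chrom: str, anchor_pos: int) -> VariantCall:
        row = self._conn.execute(
            "SELECT sample_id, chrom, pos, pos, ref, alt, gene, aa_change, extra"
            " FROM fsm_states WHERE sample_id=? AND chrom=? AND pos=? AND ref IS NOT NULL",
            (sample_id, chrom, anchor_pos),
        ).fetchone()
        if row is None:
            raise DataCorruptionError(f"missing variant anchor at {chrom}:{anchor_pos}")
        return _row_to_variant(row)

    def lookup_point(self, sample_id: str, locus: GenomicLocus) -> StoredLookup:
        self.kit_of(sample_id)  # raises on unknown sample
        row = self._conn.execute(
            "SELECT state, anchor_pos FROM fsm_states"
            " WHERE sample_id=? AND chrom=? AND pos=?",
            (sample_id, locus.chrom, locus.pos),
        ).fetchone()
        if row is None:
            return StoredLookup(in_target=False)
        state, anchor_pos = row
        if state == VAR:
            v = self._anchor_variant(sample_id, locus.chrom, anchor_pos)
            return StoredLookup(True, has_variant=True, variant=v)
        return StoredLookup(True, has_missing=(state == MISS))

    def lookup_range(self, sample_id, chrom, start, end) -> List[StateRun]:
        self._check_range(start, end)
        self.kit_of(sample_id)
        rows = self._conn.execute(
            "SELECT pos, state FROM fsm_states"
            " WHERE sample_id=? AND chrom=? AND pos>=? AND pos<? ORDER BY pos",
            (sample_id, chrom, start, end),
        ).fetchall()
        if not rows:
            return [StateRun(chrom, start, end, PositionState.MISSING)]
        pos = np.asarray([r[0] for r in rows])
        state = np.asarray([r[1] for r in rows], dtype=np.int8)
        brk = np.flatnonzero((np.diff(pos) != 1) | (np.diff(state) != 0)) + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [pos.size]))
        runs = []
        cursor = start
        for i, j in zip(starts, ends):
            s, e = int(pos[i]), int(pos[j - 1]) + 1
            if s > cursor:  # ROI gap: nothing stored, outside the universe
                runs.append(StateRun(chrom, cursor, s, PositionState.MISSING))
            runs.append(StateRun(chrom, s, e, PositionState(int(state[i]))))
            cursor = e
        if cursor < end:
            runs.append(StateRun(chrom, cursor, end, PositionState.MISSING))
        return _merge_adjacent(runs)

    def iter_variants(self, sample_id=None, gene_symbol=None, aa_change=None):
        where, params = _variant_filter_sql(sample_id, gene_symbol, aa_change)
        where = (where + " AND " if where else " WHERE ") + "ref IS NOT NULL"
        rows = self._conn.execute(
            "SELECT sample_id, chrom, pos, pos, ref, alt, gene, aa_change, extra"
            f" FROM fsm_states{where} ORDER BY chrom, pos, sample_id",
            params,
        ).fetchall()
        return [_row_to_variant(r) for r in rows]

    def count_elements(self) -> ElementCount:
        by_state = dict(
            self._conn.execute("SELECT state, COUNT(*) FROM fsm_states GROUP BY state")
        )
        n_var_cells = by_state.get(VAR, 0)
        n_miss = by_state.get(MISS, 0)
        n_ref = by_state.get(REF, 0)
        total = n_var_cells + n_miss + n_ref
        return ElementCount(self.kind, total, n_var_cells, n_miss, n_ref, 0)

    def analytic_count(self) -> int:
        return fsm_element_count(len(self.samples()), self.roi().total_bases)


class BlsmBackend(Backend):
    """Block storage model: maximal same-state runs stored as block records.

    The per-sample block tiling covers the whole cohort ROI; ROI positions
    outside the sample's kit become MISSING blocks (the model, like gVCF,
    still spends records on untested regions).
    """

    kind = BackendKind.BLSM

    def _schema(self) -> str:
        return """
        CREATE TABLE IF NOT EXISTS blocks (
            sample_id TEXT NOT NULL, chrom TEXT NOT NULL,
            start INTEGER NOT NULL, end INTEGER NOT NULL, state INTEGER NOT NULL,
            ref TEXT, alt TEXT, gene TEXT, aa_change TEXT, extra TEXT);
        """

    def _index_sql(self) -> List[str]:
        return [
            "CREATE INDEX IF NOT EXISTS ix_blk_scs ON blocks(sample_id, chrom, start)",
            "CREATE INDEX IF NOT EXISTS ix_blk_cs ON blocks(chrom, start)",
        ]

    def _delete_sample_rows(self, sample_id: str) -> None:
        self._conn.execute("DELETE FROM blocks WHERE sample_id=?", (sample_id,))

    def sample_blocks(self, sample_id: str, kit, variants, missing) -> List[StateBlock]:
        """Single linear scan per ROI interval: RLE then per-call variant split."""
        blocks: List[StateBlock] = []
        by_locus = {(v.locus.chrom, v.locus.pos): v for v in variants}
        for chrom, s, e in self.roi().iter_records():
            arr = dense_states(kit, variants, missing, chrom, s, e)
            for blk in compress_runs(arr, GenomicLocus(chrom, s), sample_id):
                if blk.state is PositionState.VARIANT:
                    p = blk.start
                    while p < blk.end:
                        v = by_locus.get((chrom, p))
                        if v is None:
                            raise DataCorruptionError(
                                f"variant run without anchored call at {chrom}:{p}"
                            )
                        blocks.append(
                            StateBlock(sample_id, chrom, p, min(v.end, blk.end),
                                       PositionState.VARIANT, v)
                        )
                        p = v.end
                else:
                    blocks.append(blk)
        return blocks

    def _write_sample(self, sample_id, kit, variants, missing) -> None:
        rows = []
        for b in self.sample_blocks(sample_id, kit, variants, missing):
            if b.variant is not None:
                v = b.variant
                a = v.annotation
                extra = json.dumps(a.extra, sort_keys=True) if a.extra else None
                rows.append((sample_id, b.chrom, b.start, b.end, int(b.state),
                             v.ref_allele, v.alt_allele, a.gene_symbol, a.aa_change, extra))
            else:
                rows.append((sample_id, b.chrom, b.start, b.end, int(b.state),
                             None, None, None, None, None))
        self._conn.executemany("INSERT INTO blocks VALUES (?,?,?,?,?,?,?,?,?,?)", rows)

    def _block_variant(self, row: tuple) -> VariantCall:
        sample_id, chrom, start, _end, _state, ref, alt, gene, aa, extra = row
        return _row_to_variant((sample_id, chrom, start, None, ref, alt, gene, aa, extra))

    def lookup_point(self, sample_id: str, locus: GenomicLocus) -> StoredLookup:
        self.kit_of(sample_id)
        row = self._conn.execute(
            "SELECT sample_id, chrom, start, end, state, ref, alt, gene, aa_change, extra"
            " FROM blocks WHERE sample_id=? AND chrom=? AND start<=?"
            " ORDER BY start DESC LIMIT 1",
            (sample_id, locus.chrom, locus.pos),
        ).fetchone()
        if row is None or row[3] <= locus.pos:
            return StoredLookup(in_target=False)
        state = row[4]
        if state == VAR:
            return StoredLookup(True, has_variant=True, variant=self._block_variant(row))
        return StoredLookup(True, has_missing=(state == MISS))

    def lookup_range(self, sample_id, chrom, start, end) -> List[StateRun]:
        self._check_range(start, end)
        self.kit_of(sample_id)
        rows = self._conn.execute(
            "SELECT start, end, state FROM blocks"
            " WHERE sample_id=? AND chrom=? AND end>? AND start<? ORDER BY start",
            (sample_id, chrom, start, end),
        ).fetchall()
        runs: List[StateRun] = []
        cursor = start
        for s, e, st in rows:
            s, e = max(s, start), min(e, end)
            if s > cursor:
                runs.append(StateRun(chrom, cursor, s, PositionState.MISSING))
            runs.append(StateRun(chrom, s, e, PositionState(st)))
            cursor = e
        if cursor < end:
            runs.append(StateRun(chrom, cursor, end, PositionState.MISSING))
        return _merge_adjacent(runs)

    def iter_variants(self, sample_id=None, gene_symbol=None, aa_change=None):
        where, params = _variant_filter_sql(sample_id, gene_symbol, aa_change)
        where = (where + " AND " if where else " WHERE ") + f"state={VAR}"
        rows = self._conn.execute(
            "SELECT sample_id, chrom, start, end, state, ref, alt, gene, aa_change, extra"
            f" FROM blocks{where} ORDER BY chrom, start, sample_id",
            params,
        ).fetchall()
        return [self._block_variant(r) for r in rows]

    def count_elements(self) -> ElementCount:
        by_state = dict(
            self._conn.execute("SELECT state, COUNT(*) FROM blocks GROUP BY state")
        )
        n_blocks = sum(by_state.values())
        return ElementCount(
            self.kind, n_blocks,
            by_state.get(VAR, 0), by_state.get(MISS, 0), by_state.get(REF, 0),
            n_blocks,
        )


_BACKENDS = {
    BackendKind.NSM: NsmBackend,
    BackendKind.FSM: FsmBackend,
    BackendKind.BLSM: BlsmBackend,
}


def open_backend(kind: BackendKind | str, path: str = ":memory:", **kwargs) -> Backend:
    if isinstance(kind, str):
        kind = BackendKind(kind.lower())
    return _BACKENDS[kind](path, **kwargs)
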