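"""Benchmark harness: load one synthetic cohort into every backend,
count stored elements, time loads and the four use-case queries, and
verify that all backends answer identically.

Counts and output-equality are deterministic and meaningful; wall times
are informational only (they depend on hardware and filesystem cache, so
the harness flushes each backend's connection cache before every query
but never asserts on timings).
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .backends import BackendKind, fsm_element_count, open_backend
from .ingest import IngestConfig, load_cohort
from .query import CohortQuery, GeneModelSet
from .synth import CohortSpec, generate_cohort

USE_CASES = ("position", "mutation", "gene_mutations", "gene_coverage")


@dataclass
class BackendBenchmark:
    kind: str
    n_elements: int
    n_variant: int
    n_missing: int
    n_reference: int
    n_blocks: int
    db_bytes: int
    load_seconds: float
    query_seconds: Dict[str, float] = field(default_factory=dict)
    materialized: bool = True


@dataclass
class BenchmarkReport:
    n_samples: int
    roi_bases: int
    universe_bp: int
    seed: int
    backends: Dict[str, BackendBenchmark]
    outputs_identical: bool
    truth_n_variants: int
    truth_n_missing: int

    def to_json(self) -> str:
        payload = {
            "n_samples": self.n_samples,
            "roi_bases": self.roi_bases,
            "universe_bp": self.universe_bp,
            "seed": self.seed,
            "outputs_identical": self.outputs_identical,
            "truth_n_variants": self.truth_n_variants,
            "truth_n_missing": self.truth_n_missing,
            "backends": {k: vars(v) for k, v in self.backends.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_table(self) -> str:
        header = f"{'model':<6} {'elements':>12} {'variant':>10} {'missing':>10} {'reference':>10} {'blocks':>8} {'bytes':>12} {'load_s':>8}"
        lines = [header, "-" * len(header)]
        for k, b in self.backends.items():
            lines.append(
                f"{k:<6} {b.n_elements:>12} {b.n_variant:>10} {b.n_missing:>10}"
                f" {b.n_reference:>10} {b.n_blocks:>8} {b.db_bytes:>12} {b.load_seconds:>8.2f}"
            )
        lines.append(f"outputs identical across backends: {self.outputs_identical}")
        return "\n".join(lines)


def _run_case(query: CohortQuery, probes: dict, case: str) -> str:
    """Run one use case and serialize its output for equality comparison."""
    if case == "position":
        return query.status_at_position(*probes["position"]).to_tsv()
    if case == "mutation":
        return query.status_for_mutation(*probes["mutation"]).to_tsv()
    if case == "gene_mutations":
        gm = query.statuses_for_gene_mutations(probes["gene"])
        return json.dumps(
            {f"{l.chrom}:{l.pos}": r.to_rows() for l, r in sorted(gm.items())},
            sort_keys=True,
        )
    if case == "gene_coverage":
        return query.coverage_across_gene(probes["gene"]).to_tsv()
    raise ValueError(f"unknown use case {case!r}")


def run_benchmark(
    spec: CohortSpec,
    workdir: str,
    backends: Sequence[str] = ("nsm", "blsm", "fsm"),
    count_only_fsm: bool = False,
    config: Optional[IngestConfig] = None,
) -> BenchmarkReport:
    """Generate a cohort, load every backend from its manifest, and measure.

    With ``count_only_fsm`` the full storage model is not materialized;
    its element count is computed analytically (n_samples x ROI bases) —
    the only honest option for cohorts beyond the cell budget.
    """
    os.makedirs(workdir, exist_ok=True)
    cohort_dir = os.path.join(workdir, "cohort")
    data = generate_cohort(spec, out_dir=cohort_dir)
    genes = GeneModelSet.from_tsv(data.genes_path)
    config = config or IngestConfig()

    results: Dict[str, BackendBenchmark] = {}
    fingerprints: Dict[str, Dict[str, str]] = {}
    probes = None
    for name in backends:
        kind = BackendKind(name)
        if kind is BackendKind.FSM and count_only_fsm:
            results[name] = BackendBenchmark(
                kind=name,
                n_elements=fsm_element_count(spec.n_samples, data.roi.total_bases),
                n_variant=0, n_missing=0, n_reference=0, n_blocks=0,
                db_bytes=0, load_seconds=0.0, materialized=False,
            )
            continue
        db_path = os.path.join(workdir, f"{name}.db")
        if os.path.exists(db_path):
            os.remove(db_path)
        be = open_backend(kind, db_path)
        t0 = time.perf_counter()
        load_cohort(data.manifest_path, [be], config)
        be.create_indexes()
        load_s = time.perf_counter() - t0

        if probes is None and be.iter_variants():
            # Deterministic probe inputs shared by every backend: the first
            # stored variant locus and its gene annotation.
            first = be.iter_variants()[0]
            probes = {
                "position": (first.locus.chrom, first.locus.pos),
                "mutation": (first.annotation.gene_symbol, first.annotation.aa_change),
                "gene": first.annotation.gene_symbol,
            }

        times: Dict[str, float] = {}
        fp: Dict[str, str] = {}
        if probes is not None:
            query = CohortQuery(be, genes)
            for case in USE_CASES:
                be.flush_cache()
                t0 = time.perf_counter()
                fp[case] = _run_case(query, probes, case)
                times[case] = time.perf_counter() - t0
        fingerprints[name] = fp
        ec = be.count_elements()
        results[name] = BackendBenchmark(
            kind=name,
            n_elements=ec.n_elements,
            n_variant=ec.n_variant,
            n_missing=ec.n_missing,
            n_reference=ec.n_reference,
            n_blocks=ec.n_blocks,
            db_bytes=be.db_size_bytes(),
            load_seconds=load_s,
            query_seconds=times,
        )
        be.close()

    identical = len({json.dumps(fp, sort_keys=True) for fp in fingerprints.values()}) <= 1
    return BenchmarkReport(
        n_samples=spec.n_samples,
        roi_bases=data.roi.total_bases,
        universe_bp=spec.universe_bp,
        seed=spec.seed,
        backends=results,
        outputs_identical=identical,
        truth_n_variants=data.n_variants_total,
        truth_n_missing=data.n_missing_total,
    )
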