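# negstore

Precise, compact warehousing of per-sample genomic position states for
targeted-sequencing cohorts.

## The problem

A cohort variant warehouse must answer, for any sample and any genomic
position, one of three things: the sample matches the **reference** genome
there, it carries a **variant**, or the data were insufficient to tell
(**missing**).  Storing that three-state matrix explicitly — one element
per sample per position of the region of interest — scales terribly: 367
exomes over a 43-Mb padded-exon region already need ~15.8 billion
elements.  Storing only variants is compact but unsafe, because it cannot
distinguish "reference" from "untested or low-coverage": every position
outside a sample's capture kit, and every low-depth position inside it,
would silently masquerade as reference.

## The negative storage model

`negstore` implements the *negative storage model* (NSM): persist only

1. variant calls (with their contextual annotation: gene, protein change, …), and
2. explicit *missing* markers for in-target positions with insufficient data,

and resolve any queried position `(s, p)` with a fixed decision order:

```
p ∉ target(kit(s))        → MISSING      (never tested, nothing stored)
variant stored at (s, p)  → VARIANT      (annotation attached)
missing stored at (s, p)  → MISSING
otherwise                 → REFERENCE    (inferred, never stored)
```

Because the capture-kit target regions are part of the store, the
inference is exact: the model is as precise as the full matrix at a tiny
fraction of its elements.  Two baselines are provided behind the same
lookup contract for accounting and cross-validation: the **full storage
model** (FSM, one explicit state per sample × ROI position) and the
**block storage model** (BLSM, maximal same-state runs stored as single
blocks, as in gVCF reference blocks).  A variant-only model exists only as
an analytic counter — at a per-base variation rate *r* it would store a
fraction *r* of the FSM, a `(1 − r)·100 %` reduction (> 99 % for
*r* ≤ 1.6 × 10⁻³) — but is deliberately not queryable.

All three backends are single-file SQLite databases sharing one
point/range lookup API, an ingest pipeline (BED kit targets, VCF or
MAF-like variant tables, per-base depth or callable-interval coverage), a
cohort query layer (status at a position, status for a gene/protein-change
mutation, all mutations in a gene, per-sample gene coverage), a precise
gVCF exporter/importer, a seeded synthetic-cohort generator with a dense
truth oracle, and a benchmark harness.

## Worked example

```python
import tempfile
import negstore as ns

with tempfile.TemporaryDirectory() as tmp:
    data = ns.fig1_fixture(out_dir=tmp)          # 7 samples x 11 positions
    backends = {k: ns.open_backend(k) for k in ("nsm", "fsm", "blsm")}
    ns.load_cohort(data.manifest_path, backends.values())
    for kind, be in backends.items():
        q = ns.CohortQuery(be)
        p1 = q.status_at_position("chr1", 0)     # "Position 1", 0-based
        print(kind, p1.counts(), be.count_elements().n_elements)
```

prints

```
nsm {'ref': 4, 'alt': 1, 'missing': 2} 13
fsm {'ref': 4, 'alt': 1, 'missing': 2} 77
blsm {'ref': 4, 'alt': 1, 'missing': 2} 31
```

Five of the seven samples are informative at Position 1 (four inferred
reference, one stored variant) and two are missing — identically in every
model — while the element counts differ by model: the NSM stores 13
records for the cohort that the full model spells out in 77.  The
`examples/` directory has one narrative script per capability
(worked example, storage accounting, gVCF round trip, benchmark); each
prints what it computes and what the numbers mean.  The same machinery is
scriptable from a shell via the `negstore` command
(`load`, `query`, `export-gvcf`, `benchmark`, `make-fixture`).

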