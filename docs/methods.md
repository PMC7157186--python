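# Methods

## The model

Every (sample, position) pair has exactly one resolved state: REFERENCE,
VARIANT or MISSING.  The store never records REFERENCE.  Ingest classifies
each targeted position with a pure decision function — out-of-target
stores nothing; in-target with insufficient data stores a missing marker;
a passing variant stores a variant record; a confident reference genotype
stores nothing — and query-time resolution inverts it with a fixed check
order: target membership, stored variant, stored missing marker, inferred
reference.  The composition of the two procedures is the identity on
in-target truth and constant-MISSING outside the target, which the test
suite asserts exhaustively over all state/flag combinations.

All coordinates are 0-based half-open internally; 1-based conventions
(VCF/gVCF, MAF, per-base depth tables) are converted only at the format
boundary.

## Backends

Three storage models implement one lookup contract over single-file
SQLite stores:

- **NSM** — tables `variants` (one row per call, reference-allele span kept
  for multi-base calls) and `missing` (one row per position).  Missing
  markers are persisted per position rather than as intervals so the row
  count *is* the element count, matching how stored elements are compared
  across models.
- **FSM** — table `fsm_states`, one row per (sample, ROI position).  ROI
  positions outside a sample's kit are stored MISSING.  Materialization
  refuses cohorts above a configurable cell budget (default 10⁸ cells);
  beyond it the count `n_samples × |ROI|` is computed analytically, which
  is also how the published-scale figure (367 × 43,022,725 ≈ 15.8 × 10⁹)
  is reproduced without a multi-day load.
- **BLSM** — table `blocks`: maximal same-state runs per sample tiling the
  cohort ROI, built in a single linear scan per ROI interval.  VARIANT
  blocks are one per call (they carry alleles and annotation and span the
  reference allele), so maximality applies to REFERENCE/MISSING blocks;
  two adjacent variant calls remain two blocks.

The cohort **region of interest** defaults to the union of all registered
kit targets and can be declared explicitly.  FSM and BLSM materialize over
the ROI for every sample; the NSM's universe is each sample's own kit.
Composite `(sample, chrom, pos)` and `(chrom, pos)` indexes are created
after bulk load (faster than index maintenance during inserts); index
presence changes query plans only, never results, which is tested.

A variant-only model is exposed purely as arithmetic
(`vosm_element_count`, `vosm_reduction_percent`): it is excluded as a
backend because absence of a record is ambiguous between reference and
missing, exactly the imprecision the negative model removes.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 10× | depth at or above which a position counts as sufficiently covered; strictly below is missing.  "Sufficient quality" has no canonical numeric definition, so this is a declared, configurable rule |
| `pad_bp` | 0 | symmetric kit-target padding applied explicitly at BED read time (e.g. 25 bp around exons), clamped at 0 and at the chromosome end when lengths are known |
| `cell_budget` | 10⁸ | FSM materialization ceiling (cells = samples × ROI bases) |
| `variant_rate` | 0.0015 | generator: per in-kit-base variant probability, the middle of the 0.13–0.16 % per-genome variation range |
| `missing_rate` | 0.01 | generator: per in-kit-base insufficient-coverage probability; a round WES-plausible choice, fixed once |
| kit fractions | 1.5 / 2.0 / 2.5 % | generator: per-kit targeted fraction of the universe, exome-like (targeted capture covers ~1–2 % of a genome), in 150 bp exon-sized intervals |

A call that failed its variant filters is stored as MISSING over its span:
a low-confidence call is evidence of insufficient data, not of variation.
Conversely, when a passing call overlaps a low-coverage interval the
variant wins and the missing marker is suppressed (a confident call
implies the data sufficed); the suppression is logged.

## Synthetic cohorts and what they do not show

`generate_cohort` draws, per sample, one uniform variate per in-kit base
and stratifies it into missing (first `missing_rate`) then variant (next
`variant_rate`), so the two sets are disjoint by construction and element
counts are exactly additive.  Alleles and annotations are assigned once
per locus, so recurrent variants agree across samples.  Kits are drawn as
non-overlapping exon-sized intervals on a single synthetic chromosome;
samples are assigned to kits round-robin; pseudo-genes partition the ROI
into consecutive ten-exon groups.  Everything is reproducible
byte-for-byte from the seed, and manifests use relative paths so a cohort
directory is relocatable.

The generator emulates the *structure* of a multi-kit cohort (kit
heterogeneity, sparse variants, sparse in-target dropout), not the
*content* of real data: no mutation hotspots or signatures, no
depth-correlated dropout, SNVs only by default (multi-base calls are
supported and unit-tested through the ingest and storage paths), a single
chromosome, and uniformly placed targets.  Passing tests therefore
demonstrate storage-model correctness and accounting — state equivalence,
count formulas, ordering — not calling accuracy or biological realism.

## Numerical and design choices

- Point/range lookups return resolved runs; range answers are checked
  against per-position point lookups and, on random cohorts, against the
  dense truth matrix at every one of the 50 × 10⁶ (sample, position)
  pairs per cohort.
- Multi-locus mutation queries (one protein change realized at several
  loci) use the precedence VARIANT > MISSING > REFERENCE across loci —
  a sample is only called reference for a mutation when every matching
  locus affirmatively resolved reference.
- Gene coverage uses the gene model's length as denominator (not the
  kit∩gene intersection) so fractions are comparable across samples with
  different kits; gene symbols match case-insensitively and duplicate
  symbols raise rather than merge.
- The gVCF dialect writes reference blocks (`0/0`, `END=`), missing
  blocks (`./.` with a dedicated `MISSING` FILTER declared in the header)
  and per-call variant records.  Standard gVCF has no first-class
  "untested" state, so out-of-kit ROI regions export as missing blocks;
  on re-import the file's full record span becomes the new sample's kit,
  which provably reproduces the identical resolved state everywhere.
  Block REF alleles are `N` placeholders unless a reference sequence
  source is supplied, since the store does not retain reference bases.
  Headers are timestamp-free, making export → import → export
  byte-identical.
- Benchmark wall times are informational only (the harness flushes
  connection caches between queries but asserts nothing about speed);
  counts, sizes and the cross-backend output-equality flag are the
  meaningful outputs.

## Problem sizes

The acceptance checks run at desk scale by choice: the worked 7 × 11
fixture; twenty seeded cohorts of 50 samples over a 1-Mb universe with
three kits (ROI ≈ 59 kb, so each FSM materialization is ≈ 3 × 10⁶ rows);
and the published 367-sample × 43-Mb full-model count reproduced
analytically rather than by materialization.  Absolute load/query times
and on-disk sizes of any particular database engine are out of scope.

## Known limitations

- One writer at a time; no client/server deployment, replication or
  concurrent ingest.
- Overlapping variant spans within one sample (e.g. two overlapping
  deletions) are not modeled; ingest stores them but base-conservation
  accounting assumes disjoint spans.
- Annotation `extra` key/value pairs round-trip through the backends but
  are not exported to gVCF.
- Chromosome name dialects are normalized via an explicit alias map, not
  inferred.
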