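# Methods

## Coordinate model

All in-memory intervals are 1-based and fully closed; an interval's width is
`end − start + 1`. This makes `minoverlap = k` mean "at least k shared
bases" with no off-by-one caveats. Formats keep their native conventions on
disk: BED (0-based half-open) is shifted at the I/O boundary, GFF3 (1-based
closed) passes through. Strand is carried on intervals but ignored by
overlap queries unless the strict-strand switch is set; identifier
namespaces routinely mix stranded and unstranded annotations, so requiring
strand agreement is opt-in.

## The qualification predicate

A subject interval *s* qualifies against query *q* under parameters
(`type`, `maxgap`, `minoverlap`) as follows, with `ow` the signed
intersection width and `gap = max(0, −ow)`:

| type     | rule                                                                 |
|----------|----------------------------------------------------------------------|
| `any`    | `ow ≥ minoverlap` **or** (`maxgap > 0` and `gap ≤ maxgap`)            |
| `start`  | `|q.start − s.start| ≤ maxgap` **and** `ow ≥ minoverlap`              |
| `end`    | `|q.end − s.end| ≤ maxgap` **and** `ow ≥ minoverlap`                  |
| `equal`  | both the `start` and `end` conditions                                 |
| `within` | `q.start ≥ s.start − maxgap` and `q.end ≤ s.end + maxgap` and `ow ≥ minoverlap` |

The composition of `maxgap` with `minoverlap` for disjoint pairs is a
genuine design choice: we let a positive `maxgap` admit disjoint pairs
regardless of `minoverlap` (the flanking-region use case — finding genes
near, not on, a query — would otherwise be impossible), while `minoverlap`
governs whenever bases are actually shared. The choice is validated by a
designed tripwire: the canonical 10-bp worked example (below) is *searched
for*, not asserted, and the search has solutions only if the semantics are
consistent with all of its published outcome statements.

`select` reduces the canonical hit order (chrom, start, end, identifier):
`first`/`last` are the extremes; `arbitrary` is defined here as the middle
element of the canonical order — any qualifying subject is admissible, but
the choice must be reproducible, so it is a pure function of the hit list.

## The worked 10-bp example

The reference example that pins down the overlap semantics states only hit
sets (four subjects, four queries, three parameter settings), never
coordinates. Rather than inventing coordinates, `solve_reference_example()`
enumerates all 55 closed intervals on the 10-base axis and searches the
full subject/query configuration space (feasibility is decomposed per query
slot and evaluated with boolean tensors, so the 55⁴ subject combinations
are tractable). The search finds 850 solutions; the lexicographically
smallest is frozen as the canonical fixture and the test suite asserts the
search still recovers it. Queries not mentioned in a statement are required
to have empty hit sets under that statement's parameters.

## Interval trees

One red-black tree per (namespace, chromosome), keyed on
(start, end, payload string) so traversal is deterministic under duplicate
coordinates; exact duplicates are allowed and individually deletable.
Each node is augmented with `max_end`, the maximum interval end in its
subtree, maintained through rotations and repaired upward after every
structural edit. Overlap search prunes any subtree whose `max_end` falls
short of `q.start − (maxgap + 1)` and stops descending right past
`q.end + (maxgap + 1)`; the window is conservative for every overlap type
(qualifying subjects either share a base or lie within `maxgap`). Bulk
construction is simply repeated insertion — `O(n log n)`, adequate at the
scales this package targets — and a registry serializes to a flat sorted
TSV from which the trees are rebuilt on load.

A brute-force linear-scan backend with identical semantics (including hit
order and `select` reduction) serves two roles: the correctness oracle in
randomized equivalence tests, and the baseline in the benchmark. The
benchmark reports visited-element counts rather than wall time: counts are
deterministic under a seed, hardware-independent, and directly exhibit the
`O(log n)` vs `O(n)` separation.

## Representations of multi-exon entities

Both transcript representations are supported, and their interaction with
the predicate required decisions:

- An exon-union record inserts each exon as a tree node (payload
  `(id, ordinal)`) **plus** one span node (`ordinal 0`). Exon nodes carry
  base-level accounting; the span node guarantees that a containment query
  landing mid-intron — possibly tens of kilobases from the nearest exon,
  hence outside any exon-node search window — still surfaces the record as
  a candidate.
- Under `type=any`, an exon-union record's shared bases are summed across
  exons and compared to `minoverlap`; intron-only overlap therefore counts
  zero and does not qualify (the behavior that distinguishes the two
  representations). Positional types (`start`/`end`/`equal`/`within`) are
  evaluated against the record span, since exon boundaries are not
  meaningful anchors for those relations.
- When an exon-union identifier is itself the conversion *query*, its span
  is used as the query interval. This keeps self-conversion under
  `type=equal` reflexive for every representation; the cost — intronic
  bases count on the query side under `type=any` — is documented rather
  than hidden.
- Span-mode records may carry several intervals (independent genomic
  placements, e.g. a multi-mapped EST); each placement is queried or
  qualified independently and per-identifier hits are deduplicated, keeping
  the best-overlapping placement.

## Sequence mapping

The mapper performs gapless alignment with 0–3 substitutions. Candidates
come from pigeonhole seeding: a read with ≤ *k* mismatches must contain one
of *k*+1 contiguous segments matching exactly, so exact occurrences of each
segment (string search) propose offsets which are verified by early-exit
Hamming count. `N` matches nothing, in read or genome, and the seeding
remains complete under that rule. Reverse-complement alignments are
reported on the `−` strand in forward coordinates; canonical hit order is
(chrom, start, `+` before `−`).

Report modes: `all`; `all_best` (the minimum-mismatch stratum; default);
`k` (first *k* in canonical order); `k_best` (first *k* of the best
stratum). The suppression threshold is compared against the *total*
alignment count before mode filtering and uses a strictly-greater-than
comparator — a read with exactly the threshold's number of placements is
kept; one more and all of its alignments are discarded. The two plausible
comparators (`>` vs `≥`) differ only on exact equality; we fixed `>` from
the parameter's primary description ("more than the specified value") and
test the boundary on both sides.

Fragmentation tiles a sequence into `window`-length pieces every `step`
bases (defaults 50/25) with ordinal name suffixes `_1, _2, …`; only
full-length windows are emitted, so a 100-base input yields exactly three
fragments and a 49-base input none. The best-score filter keeps alignments
with `score ≥ (1 − fraction)·max(score)` (default fraction 0.05).

## Evaluation framework

Given truth sets *Z(x)* and predicted sets *Y(x)*: TP iff *Z* ≠ ∅ and
*Z* ⊆ *Y*; FN iff *Z* ≠ ∅ and *Y* = ∅; TN iff *Z* = *Y* = ∅; FP otherwise
(a wrong conversion, or a prediction where the authority annotates
nothing). These four labels provably partition all cases (property-tested
over random sets). Metrics: ACC = 100·(TP+TN)/n, TPR = 100·TP/(TP+FN),
FPR = 100·FP/(FP+TN), FDR = 100·FP/(TP+FP), F1 = 100·2TP/(2TP+FP+FN);
computed in full precision, reported at 2 decimals with half-up rounding
(matching conventional table formatting); a zero-denominator metric is
reported as undefined, never as zero. An accession-class prefix filter
(keep `NM_`/`NR_`, drop `X*` by default) can be applied to predictions
before classification, for comparisons across converters that segregate
curated and predicted accessions differently. The suite verifies that the
framework reproduces every metric cell of two published ten-tool benchmark
tables from their printed contingency counts.

`corrupt_truth` adds an unsatisfiable required target to a seeded fraction
*f* of truth entries; each corrupted entry demotes one query (TP→FP or
TN→FN), so accuracy must fall by exactly 100·*f* points — a linearity check
on the evaluation scale.

## Synthetic data

`generate_genome` draws i.i.d. nucleotides at a requested GC fraction
(default 0.5), seeded and byte-reproducible. `generate_layers` emulates the
granularity ladder: coarse features (transcript-scale, default 0.8–2.5 kb
in the pipeline studies) placed uniformly and allowed to overlap, fine
features (25 bp, probe-scale) placed inside a random coarse feature with
probability `p_inside` (0.9 in the pipeline studies, leaving some
background probes) and uniformly otherwise. The emitted truth maps each
fine feature to every coarse feature whose span contains it, computed with
the same containment predicate the converter uses — so generated truth is
consistent by construction, and the containment pipeline recovers 100%
accuracy on it. This by design: the studies validate the *machinery*
(coordinate resolution, tree search, accounting, scoring), not biological
annotation quality. The generator does not model splicing realism, sequence
homology between paralogous features, GC structure along the chromosome, or
expression; conclusions about real annotation databases require real
annotations.

## Problem sizes and numerical choices

Randomized studies use sizes chosen to exercise the structures well past
their small-case regimes while keeping the whole suite quick on a single
CPU: 10,000 (database, query, parameter) cases for tree/oracle equivalence;
a 10,000-operation insert/delete torture test with full structural
validation after every step (tree size held in the 300–700 range so
validation stays cheap); mapper verification on 4 kb of genome across all
mismatch allowances and report modes; pipeline studies with 80 transcripts
and 500 probes over 100 kb; benchmark databases up to 10⁵ intervals.
Degenerate inputs are defined, not accidental: empty trees return empty hit
lists, empty identifier lists produce empty reports with empty unconverted
lists, deleting an absent element raises a not-found error, and a read
longer than every chromosome maps nowhere.

## Known limitations

- The mapper is substitution-only; spliced or gapped alignment (long-read aligner style)
  is out of scope, so sequences spanning exon junctions map only if one
  exon-side fragment is used as the query.
- Registry construction is in-memory; no external-memory or concurrent
  trees.
- Identifier lookup is exact-string; aliases must be registered explicitly.
- `convert-ids` of an exon-union source queries by span (see above).
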