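"""Multi-namespace identifier store backed by per-chromosome interval trees.

A *namespace* is one identifier domain (Entrez genes, RefSeq, Ensembl
transcripts, an array's probe sets, or anything user-defined) registered as a
set of genomic intervals.  Identifier conversion then never consults
annotation cross-reference tables: a query is resolved to coordinates and the
trees of the target namespace are asked which identifiers' intervals qualify
as overlapping.

Two structural representations are supported for multi-exon entities:

``span``
    One interval from first to last base (introns included).  Records may
    carry several intervals, one per independent genomic placement (a
    multi-mapped EST, for example).
``exon_union``
    The entity is the union of its exon intervals; intronic overlap does not
    count.  All exons share one chromosome and strand.

For ``exon_union`` records both the exon sub-intervals (payload ordinal 1..n)
and the overall span (ordinal 0) are inserted as tree nodes: exon nodes carry
the base-level overlap accounting, while the span node guarantees that
containment-style queries landing deep inside a long intron still find the
record as a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .core import (
    GenomicInterval,
    OverlapParams,
    gap,
    overlap_width,
    qualifies,
)
from .rbtree import IntervalTree, NotFoundError

MODES = ("span", "exon_union")


@dataclass(frozen=True)
class IdentifierRecord:
    """One identifier in one namespace, mapped to genomic intervals."""

    id: str
    namespace: str
    intervals: tuple[GenomicInterval, ...]
    mode: str = "span"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"{self.id}: intervals must be non-empty")
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "exon_union":
            chroms = {iv.chrom for iv in self.intervals}
            strands = {iv.strand for iv in self.intervals}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(
                    f"{self.id}: exon_union intervals must share chrom and strand"
                )

    def span(self, chrom: str | None = None) -> GenomicInterval:
        """Enclosing interval [min start, max end] (restricted to ``chrom``)."""
        ivs = self.intervals
        if chrom is not None:
            ivs = tuple(iv for iv in ivs if iv.chrom == chrom)
            if not ivs:
                raise ValueError(f"{self.id} has no interval on {chrom!r}")
        return GenomicInterval(
            ivs[0].chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            ivs[0].strand,
        )


@dataclass
class RegistryHit:
    """One qualifying (query, record) match with overlap statistics."""

    record: IdentifierRecord
    subject_interval: GenomicInterval
    overlap_bases: int
    gap_bases: int


class DuplicateIdentifierError(ValueError):
    pass


@dataclass
class Registry:
    """Identifier records, their trees, and the batch type-lookup index."""

    namespaces: dict[str, dict[str, IdentifierRecord]] = field(default_factory=dict)
    trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    id_index: dict[str, set[str]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def register(self, rec: IdentifierRecord) -> None:
        """Add a record; its intervals are inserted into the namespace trees.

        Exon-union records insert each exon with payload ``(id, ordinal)``
        (1-based) plus one span node with ordinal 0; span-mode records insert
        one node per placement interval with ordinal 0, 1, ... in input order.
        """
        ns = self.namespaces.setdefault(rec.namespace, {})
        if rec.id in ns:
            raise DuplicateIdentifierError(f"{rec.id!r} already in {rec.namespace!r}")
        ns[rec.id] = rec
        if rec.mode == "exon_union":
            nodes = [(rec.span(), (rec.id, 0))]
            nodes += [(iv, (rec.id, k + 1)) for k, iv in enumerate(rec.intervals)]
        else:
            nodes = [(iv, (rec.id, k)) for k, iv in enumerate(rec.intervals)]
        for iv, payload in nodes:
            tree = self.trees.get((rec.namespace, iv.chrom))
            if tree is None:
                tree = IntervalTree(iv.chrom)
                self.trees[(rec.namespace, iv.chrom)] = tree
            tree.insert(iv, payload)
        self.id_index.setdefault(rec.id, set()).add(rec.namespace)

    def register_all(self, records: Iterable[IdentifierRecord]) -> None:
        for rec in records:
            self.register(rec)

    # -- lookups -----------------------------------------------------------

    def lookup_identifier_types(self, ids: Iterable[str]) -> dict[str, set[str]]:
        """Classify a mixed identifier list: id -> set of namespaces (maybe empty).

        Input order is preserved in the returned mapping.
        """
        return {i: set(self.id_index.get(i, set())) for i in ids}

    def get_record(self, id: str, namespace: str) -> IdentifierRecord:
        try:
            return self.namespaces[namespace][id]
        except KeyError:
            raise NotFoundError(f"{id!r} not registered in {namespace!r}") from None

    def intervals_for_id(self, id: str, namespace: str) -> list[GenomicInterval]:
        """The genomic intervals registered for one identifier."""
        return list(self.get_record(id, namespace).intervals)

    # -- overlap queries ---------------------------------------------------

    def query(
        self,
        namespace: str,
        query: GenomicInterval,
        p: OverlapParams | None = None,
        *,
        strict_strand: bool = False,
        counter: list | None = None,
    ) -> list[RegistryHit]:
        """All records of ``namespace`` qualifying against ``query`` under ``p``.

        Candidate records come from the chromosome's tree (queried with a
        permissive ``any``-type window so no qualifying record is missed);
        each candidate is then qualified per its representation:

        - span mode: the pairwise predicate per placement interval; a record
          qualifies if any placement does, and the best-overlapping placement
          is reported.
        - exon_union with ``type='any'``: shared bases are summed across
          exons and compared against ``minoverlap``; a disjoint record can
          still qualify when ``maxgap > 0`` and the nearest exon is within
          ``maxgap``.  Intron-only overlap contributes zero shared bases.
        - exon_union with any other type: the predicate is evaluated against
          the record's span.

        Hits are deduplicated per identifier, ordered by
        (chrom, span start, span end, id), then reduced by ``p.select``.
        """
        if p is None:
            p = OverlapParams()
        if namespace not in self.namespaces:
            raise NotFoundError(f"unknown namespace {namespace!r}")
        tree = self.trees.get((namespace, query.chrom))
        if tree is None:
            return []
        window = OverlapParams("any", p.maxgap, 1, "all")
        raw = tree.search_overlaps(
            query, window, strict_strand=strict_strand, counter=counter
        )
        candidate_ids: list[str] = []
        seen: set[str] = set()
        for _, (rid, _ordinal) in raw:
            if rid not in seen:
                seen.add(rid)
                candidate_ids.append(rid)

        hits: list[RegistryHit] = []
        for rid in candidate_ids:
            rec = self.namespaces[namespace][rid]
            hit = self._qualify_record(query, rec, p, strict_strand)
            if hit is not None:
                hits.append(hit)
        hits.sort(
            key=lambda h: (
                h.subject_interval.chrom,
                h.subject_interval.start,
                h.subject_interval.end,
                h.record.id,
            )
        )
        if p.select == "all" or not hits:
            return hits
        if p.select == "first":
            return [hits[0]]
        if p.select == "last":
            return [hits[-1]]
        return [hits[len(hits) // 2]]

    def _qualify_record(
        self,
        query: GenomicInterval,
        rec: IdentifierRecord,
        p: OverlapParams,
        strict_strand: bool,
    ) -> RegistryHit | None:
        if rec.mode == "exon_union":
            span = rec.span()
            if span.chrom != query.chrom:
                return None
            if strict_strand and span.strand != query.strand:
                return None
            if p.type == "any":
                total_ow = sum(
                    max(0, overlap_width(query, ex)) for ex in rec.intervals
                )
                min_gap = min(gap(query, ex) for ex in rec.intervals)
                ok = total_ow >= p.minoverlap or (p.maxgap > 0 and min_gap <= p.maxgap)
                if not ok:
                    return None
                return RegistryHit(
                    rec, span, total_ow, 0 if total_ow > 0 else min_gap
                )
            if not qualifies(query, span, p, strict_strand=strict_strand):
                return None
            ow = max(0, overlap_width(query, span))
            return RegistryHit(rec, span, ow, gap(query, span))
        # span mode: any placement may qualify; report the best one
        best: RegistryHit | None = None
        for iv in rec.intervals:
            if iv.chrom != query.chrom:
                continue
            if not qualifies(query, iv, p, strict_strand=strict_strand):
                continue
            ow = max(0, overlap_width(query, iv))
            cand = RegistryHit(rec, iv, ow, gap(query, iv))
            if (
                best is None
                or cand.overlap_bases > best.overlap_bases
                or (
                    cand.overlap_bases == best.overlap_bases
                    and (iv.start, iv.end) < (best.subject_interval.start, best.subject_interval.end)
                )
            ):
                best = cand
        return best

    # -- consistency -------------------------------------------------------

    def stored_multiset(self, namespace: str) -> dict[tuple, int]:
        """Multiset of (chrom, start, end, payload) tree nodes of a namespace."""
        out: dict[tuple, int] = {}
        for (ns, chrom), tree in self.trees.items():
            if ns != namespace:
                continue
            for iv, payload in tree.items():
                key = (chrom, iv.start, iv.end, payload)
                out[key] = out.get(key, 0) + 1
        return out

    def expected_multiset(self, namespace: str) -> dict[tuple, int]:
        """The tree-node multiset implied by the namespace's records."""
        out: dict[tuple, int] = {}
        for rec in self.namespaces.get(namespace, {}).values():
            if rec.mode == "exon_union":
                nodes = [(rec.span(), (rec.id, 0))]
                nodes += [(iv, (rec.id, k + 1)) for k, iv in enumerate(rec.intervals)]
            else:
                nodes = [(iv, (rec.id, k)) for k, iv in enumerate(rec.intervals)]
            for iv, payload in nodes:
                key = (iv.chrom, iv.start, iv.end, payload)
                out[key] = out.get(key, 0) + 1
        return out
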