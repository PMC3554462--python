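"""The three conversion entry points: identifier lists, interval lists, and
sequences.

Every conversion is the same two-step procedure: resolve the query to
genomic coordinates (step 1 — trivial for interval input, a registry lookup
for identifiers, a genome alignment for sequences), then ask the target
namespaces which identifiers' intervals qualify as overlapping (step 2).
Each report accounts for every input query exactly once, either among the
hits or among the unconverted queries with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import GenomicInterval, OverlapParams
from .mapping import MappingResult, map_sequence
from .registry import Registry
from .rbtree import NotFoundError

UNCONVERTED_REASONS = ("no_coordinates", "no_overlap", "suppressed_multimap")


@dataclass(frozen=True)
class ConversionHit:
    """One (query, subject identifier) match with its overlap statistics."""

    query_id: str
    query_interval: GenomicInterval
    subject_id: str
    subject_namespace: str
    subject_interval: GenomicInterval
    overlap_bases: int
    gap_bases: int
    source_namespace: str = ""

    def __post_init__(self) -> None:
        if self.overlap_bases < 0 or self.gap_bases < 0:
            raise ValueError("overlap_bases and gap_bases must be >= 0")
        if self.overlap_bases > 0 and self.gap_bases > 0:
            raise ValueError("overlap_bases and gap_bases cannot both be positive")


@dataclass
class ConversionReport:
    hits: list[ConversionHit] = field(default_factory=list)
    unconverted: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def converted_ids(self) -> list[str]:
        seen, out = set(), []
        for h in self.hits:
            if h.query_id not in seen:
                seen.add(h.query_id)
                out.append(h.query_id)
        return out

    def predicted_sets(self) -> dict[str, set[str]]:
        """Query id -> set of converted subject ids (empty for unconverted)."""
        out: dict[str, set[str]] = {}
        for h in self.hits:
            out.setdefault(h.query_id, set()).add(h.subject_id)
        for qid, _reason in self.unconverted:
            out.setdefault(qid, set())
        return out


def _check_targets(reg: Registry, target_ns: Sequence[str]) -> None:
    unknown = [t for t in target_ns if t not in reg.namespaces]
    if unknown:
        raise NotFoundError(f"unknown target namespace(s): {unknown}")


def _query_targets(
    reg: Registry,
    query_id: str,
    query_ivs: list[GenomicInterval],
    target_ns: Sequence[str],
    p: OverlapParams,
    strict_strand: bool,
    source_ns: str = "",
) -> list[ConversionHit]:
    """Step 2 for one query: overlap-query every target namespace.

    With several query intervals (multi-placement queries) the same subject
    can qualify more than once; one hit per (target namespace, subject id) is
    kept — the one with most shared bases.
    """
    best: dict[tuple[str, str], ConversionHit] = {}
    for ns in target_ns:
        for iv in query_ivs:
            for rhit in reg.query(ns, iv, p, strict_strand=strict_strand):
                key = (ns, rhit.record.id)
                cand = ConversionHit(
                    query_id=query_id,
                    query_interval=iv,
                    subject_id=rhit.record.id,
                    subject_namespace=ns,
                    subject_interval=rhit.subject_interval,
                    overlap_bases=rhit.overlap_bases,
                    gap_bases=rhit.gap_bases,
                    source_namespace=source_ns,
                )
                prev = best.get(key)
                if prev is None or cand.overlap_bases > prev.overlap_bases:
                    best[key] = cand
    return sorted(
        best.values(),
        key=lambda h: (
            h.subject_namespace,
            h.subject_interval.chrom,
            h.subject_interval.start,
            h.subject_interval.end,
            h.subject_id,
        ),
    )


def convert_intervals(
    reg: Registry,
    intervals: Sequence[tuple[str, GenomicInterval]],
    target_ns: Sequence[str],
    p: OverlapParams | None = None,
    *,
    strict_strand: bool = False,
) -> ConversionReport:
    """Convert labelled query intervals into target-namespace identifiers."""
    if p is None:
        p = OverlapParams()
    _check_targets(reg, target_ns)
    report = ConversionReport()
    for label, iv in intervals:
        hits = _query_targets(reg, label, [iv], target_ns, p, strict_strand)
        if hits:
            report.hits.extend(hits)
        else:
            report.unconverted.append((label, "no_overlap"))
    return report


def convert_ids(
    reg: Registry,
    ids: Sequence[str],
    source_ns: str | None,
    target_ns: Sequence[str],
    p: OverlapParams | None = None,
    *,
    strict_strand: bool = False,
) -> ConversionReport:
    """Batch identifier conversion.

    ``source_ns=None`` auto-detects each identifier's namespace(s) via the
    type-lookup index; an identifier living in several namespaces is queried
    from all of them and its hits are tagged with the source namespace.
    Exon-union source records are resolved to their span; span-mode records
    contribute one query interval per genomic placement.
    """
    if p is None:
        p = OverlapParams()
    _check_targets(reg, target_ns)
    report = ConversionReport()
    for qid in ids:
        if source_ns is None:
            sources = sorted(reg.id_index.get(qid, set()))
        else:
            sources = [source_ns] if qid in reg.namespaces.get(source_ns, {}) else []
        if not sources:
            report.unconverted.append((qid, "no_coordinates"))
            continue
        hits: list[ConversionHit] = []
        for sns in sources:
            rec = reg.get_record(qid, sns)
            if rec.mode == "exon_union":
                qivs = [rec.span()]
            else:
                qivs = list(rec.intervals)
            hits.extend(
                _query_targets(reg, qid, qivs, target_ns, p, strict_strand, sns)
            )
        if hits:
            report.hits.extend(hits)
        else:
            report.unconverted.append((qid, "no_overlap"))
    return report


def convert_sequences(
    reg: Registry,
    genome: Mapping[str, str],
    reads: Mapping[str, str],
    target_ns: Sequence[str],
    p: OverlapParams | None = None,
    *,
    max_mismatch: int = 0,
    report_mode: str = "all_best",
    k: int = 1,
    suppress_more_than: int = -1,
    strict_strand: bool = False,
) -> ConversionReport:
    """Map each read onto the genome, then convert the aligned intervals.

    Reads whose alignments were discarded by the suppression threshold are
    reported as ``suppressed_multimap``; unalignable reads as
    ``no_coordinates``; aligned reads without a qualifying target identifier
    as ``no_overlap``.
    """
    if p is None:
        p = OverlapParams()
    _check_targets(reg, target_ns)
    report = ConversionReport()
    for name in reads:
        mres: MappingResult = map_sequence(
            genome,
            reads[name],
            max_mismatch=max_mismatch,
            report_mode=report_mode,
            k=k,
            suppress_more_than=suppress_more_than,
        )
        if mres.suppressed:
            report.unconverted.append((name, "suppressed_multimap"))
            continue
        if not mres.hits:
            report.unconverted.append((name, "no_coordinates"))
            continue
        hits = _query_targets(
            reg, name, mres.intervals, target_ns, p, strict_strand
        )
        if hits:
            report.hits.extend(hits)
        else:
            report.unconverted.append((name, "no_overlap"))
    return report
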