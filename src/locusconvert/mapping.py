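"""Mismatch-tolerant short-sequence mapping onto a reference genome.

Gapless (substitution-only) alignment of short reads, the coordinate-
resolution step for sequence queries.  Candidate placements are generated by
a pigeonhole seed-and-extend scheme: a read aligned with at most *k*
mismatches must contain at least one of *k*+1 contiguous segments matching
the genome exactly, so exact occurrences of each segment seed the candidate
offsets, which are then verified by Hamming count.  ``N`` never matches
anything (in read or genome) and always counts as a mismatch.

Report modes mirror the usual short-read-aligner vocabulary:

- ``all``       every alignment with <= ``max_mismatch`` mismatches;
- ``all_best``  every alignment in the best (fewest-mismatch) stratum (default);
- ``k``         up to *k* alignments in canonical order;
- ``k_best``    up to *k* alignments from the best stratum.

Independently, a repeat-masking suppression threshold discards *all* of a
read's alignments when their total count exceeds it (strictly greater than;
``-1`` disables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import GenomicInterval

REPORT_MODES = ("all", "all_best", "k", "k_best")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceHit:
    """One gapless alignment of a read."""

    interval: GenomicInterval  # strand carries the alignment orientation
    mismatches: int


@dataclass
class MappingResult:
    """Alignments of one read after report-mode filtering.

    ``total_found`` is the pre-filter alignment count (what the suppression
    threshold is compared against); ``suppressed`` is True when that count
    exceeded the threshold, in which case ``hits`` is empty.
    """

    hits: list[SequenceHit]
    total_found: int
    suppressed: bool = False

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [h.interval for h in self.hits]


def _mismatches(genome: str, offset: int, pattern: str, limit: int) -> int:
    """Hamming count of ``pattern`` vs genome[offset:], early-exit past limit."""
    n = 0
    for i, c in enumerate(pattern):
        g = genome[offset + i]
        if g != c or c == "N" or g == "N":
            n += 1
            if n > limit:
                return n
    return n


def _candidate_offsets(chrom_seq: str, pattern: str, k: int) -> set[int]:
    """Pigeonhole seeding: offsets where some exact segment occurrence lands."""
    m = len(pattern)
    if k == 0:
        segments = [(0, pattern)]
    else:
        n_seg = k + 1
        bounds = [round(j * m / n_seg) for j in range(n_seg + 1)]
        segments = [
            (bounds[j], pattern[bounds[j] : bounds[j + 1]])
            for j in range(n_seg)
            if bounds[j + 1] > bounds[j]
        ]
    out: set[int] = set()
    last_valid = len(chrom_seq) - m
    for seg_off, seg in segments:
        pos = chrom_seq.find(seg)
        while pos != -1:
            start = pos - seg_off
            if 0 <= start <= last_valid:
                out.add(start)
            pos = chrom_seq.find(seg, pos + 1)
    return out


def map_sequence(
    genome: Mapping[str, str],
    read: str,
    max_mismatch: int = 0,
    report_mode: str = "all_best",
    k: int = 1,
    suppress_more_than: int = -1,
) -> MappingResult:
    """Map one read onto both strands of a genome.

    Parameters
    ----------
    genome : mapping of chromosome name -> sequence (A/C/G/T/N).
    read : str
        The query sequence (A/C/G/T/N); case-insensitive.
    max_mismatch : int
        0..3 substitutions tolerated (no indels).
    report_mode : str
        One of ``all``, ``all_best``, ``k``, ``k_best``.
    k : int
        Alignment cap for the ``k``/``k_best`` modes.
    suppress_more_than : int
        If >= 0 and the total alignment count is strictly greater, all of the
        read's alignments are discarded (``suppressed=True``); -1 disables.

    Returns
    -------
    MappingResult
        Hits in canonical order: (chrom, start, '+' before '-').  Reverse-
        complement matches are reported on the '-' strand with forward
        (reference) coordinates.
    """
    read = read.upper()
    if not read:
        raise ValueError("empty read")
    bad = set(read) - _VALID
    if bad:
        raise ValueError(f"invalid characters in read: {sorted(bad)}")
    if not 0 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 0..3")
    if report_mode not in REPORT_MODES:
        raise ValueError(f"report_mode must be one of {REPORT_MODES}")
    if report_mode in ("k", "k_best") and k < 1:
        raise ValueError("k must be >= 1")

    m = len(read)
    found: list[SequenceHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        if m > len(seq):
            continue
        for strand, pattern in (("+", read), ("-", reverse_complement(read))):
            for off in _candidate_offsets(seq, pattern, max_mismatch):
                mm = _mismatches(seq, off, pattern, max_mismatch)
                if mm <= max_mismatch:
                    found.append(
                        SequenceHit(
                            GenomicInterval(chrom, off + 1, off + m, strand), mm
                        )
                    )
    found.sort(
        key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand != "+")
    )
    total = len(found)
    if suppress_more_than >= 0 and total > suppress_more_than:
        return MappingResult([], total, suppressed=True)
    if report_mode == "all":
        hits = found
    elif report_mode == "all_best":
        best = min((h.mismatches for h in found), default=0)
        hits = [h for h in found if h.mismatches == best]
    elif report_mode == "k":
        hits = found[:k]
    else:  # k_best
        best = min((h.mismatches for h in found), default=0)
        hits = [h for h in found if h.mismatches == best][:k]
    return MappingResult(hits, total)


def fragment_sequence(
    name: str, seq: str, window: int = 50, step: int = 25
) -> list[tuple[str, str]]:
    """Tile a sequence into overlapping windows with ordinal-suffixed names.

    Windows start at positions 1, 1+step, 1+2*step, ...; only full-length
    windows are emitted (a sequence shorter than ``window`` yields nothing).
    Names are ``{name}_1``, ``{name}_2``, ... in order of appearance.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    out = []
    i = 0
    while i + window <= len(seq):
        out.append((f"{name}_{len(out) + 1}", seq[i : i + window]))
        i += step
    return out


def filter_best_fraction(alignments: list, scores: list[float], fraction: float = 0.05):
    """Keep alignments scoring within ``fraction`` of the maximum score.

    An alignment is kept iff ``score >= (1 - fraction) * max(scores)``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if len(alignments) != len(scores):
        raise ValueError("alignments and scores must have equal length")
    if not alignments:
        return []
    if any(s < 0 for s in scores):
        raise ValueError("scores must be non-negative")
    cutoff = (1.0 - fraction) * max(scores)
    return [a for a, s in zip(alignments, scores) if s >= cutoff]
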