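"""Coordinate conventions and the pairwise overlap predicate.

All intervals are 1-based and fully closed: ``GenomicInterval("chr1", 1, 10)``
covers ten bases.  BED input (0-based, half-open) is converted at the I/O
boundary, never here.  With closed coordinates ``minoverlap=1`` literally
means "at least one shared base".
"""

from __future__ import annotations

from dataclasses import dataclass, field

OVERLAP_TYPES = ("any", "start", "end", "equal", "within")
SELECT_MODES = ("all", "first", "last", "arbitrary")

STRANDS = ("+", "-", ".")


class ChromosomeMismatchError(ValueError):
    """Raised when two intervals on different chromosomes are compared."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located span on a named sequence.

    Parameters
    ----------
    chrom : str
        Chromosome (or contig) name.
    start, end : int
        1-based inclusive coordinates, ``1 <= start <= end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unspecified, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == "." else f"{s}({self.strand})"


@dataclass(frozen=True)
class OverlapParams:
    """The overlap-query contract: ``type``, ``maxgap``, ``minoverlap``, ``select``.

    ``type``
        ``any``     -- any shared base (or a gap of at most ``maxgap``);
        ``start``   -- query start must match the subject start (within ``maxgap``);
        ``end``     -- symmetric on ends;
        ``equal``   -- both coordinates match;
        ``within``  -- the query lies wholly inside the subject.
    ``maxgap``
        Maximum tolerated distance, in bases, between query and subject
        (0 = none).  For ``start``/``end``/``equal`` it relaxes the coordinate
        match; for ``within`` it relaxes the containment bounds.
    ``minoverlap``
        Minimum number of shared bases (>= 1).
    ``select``
        Hit-list reduction: ``all``, ``first``, ``last`` or ``arbitrary``.
    """

    type: str = "any"
    maxgap: int = 0
    minoverlap: int = 1
    select: str = "all"

    def __post_init__(self) -> None:
        if self.type not in OVERLAP_TYPES:
            raise ValueError(f"type must be one of {OVERLAP_TYPES}, got {self.type!r}")
        if self.maxgap < 0:
            raise ValueError("maxgap must be >= 0")
        if self.minoverlap < 1:
            raise ValueError("minoverlap must be >= 1")
        if self.select not in SELECT_MODES:
            raise ValueError(
                f"select must be one of {SELECT_MODES}, got {self.select!r}"
            )


def _check_same_chrom(a: GenomicInterval, b: GenomicInterval) -> None:
    if a.chrom != b.chrom:
        raise ChromosomeMismatchError(
            f"intervals on different chromosomes: {a.chrom!r} vs {b.chrom!r}"
        )


def overlap_width(a: GenomicInterval, b: GenomicInterval) -> int:
    """Signed intersection width of two closed intervals on one chromosome.

    Positive iff the intervals share at least one base, 0 iff they are
    adjacent, and ``-g`` when separated by a gap of ``g`` bases.
    """
    _check_same_chrom(a, b)
    return min(a.end, b.end) - max(a.start, b.start) + 1


def gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases strictly between two intervals; 0 when they touch."""
    return max(0, -overlap_width(a, b))


def qualifies(
    query: GenomicInterval,
    subject: GenomicInterval,
    p: OverlapParams | None = None,
    *,
    strict_strand: bool = False,
) -> bool:
    """Does ``subject`` satisfy the overlap query ``(query, p)``?

    The combined positional/proximity rule, per overlap type (``ow`` is
    :func:`overlap_width`, ``g`` is :func:`gap`):

    - ``any``:    ``ow >= minoverlap`` or (``maxgap > 0`` and ``g <= maxgap``)
    - ``start``:  ``|query.start - subject.start| <= maxgap`` and ``ow >= minoverlap``
    - ``end``:    ``|query.end - subject.end| <= maxgap`` and ``ow >= minoverlap``
    - ``equal``:  both of the ``start`` and ``end`` conditions
    - ``within``: ``query.start >= subject.start - maxgap`` and
      ``query.end <= subject.end + maxgap`` and ``ow >= minoverlap``

    Strand is ignored unless ``strict_strand`` is set, in which case both
    intervals must carry the same explicit strand.
    """
    if p is None:
        p = OverlapParams()
    _check_same_chrom(query, subject)
    if strict_strand and query.strand != subject.strand:
        return False

    ow = overlap_width(query, subject)
    t = p.type
    if t == "any":
        return ow >= p.minoverlap or (p.maxgap > 0 and -ow <= p.maxgap)
    if t == "start":
        return abs(query.start - subject.start) <= p.maxgap and ow >= p.minoverlap
    if t == "end":
        return abs(query.end - subject.end) <= p.maxgap and ow >= p.minoverlap
    if t == "equal":
        return (
            abs(query.start - subject.start) <= p.maxgap
            and abs(query.end - subject.end) <= p.maxgap
            and ow >= p.minoverlap
        )
    # within
    return (
        query.start >= subject.start - p.maxgap
        and query.end <= subject.end + p.maxgap
        and ow >= p.minoverlap
    )
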