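"""Augmented red-black interval tree.

A balanced binary search tree keyed on ``(start, end, payload)`` in which
every node additionally carries ``max_end``, the maximum interval end over
its subtree.  The augmentation lets an overlap search prune any subtree whose
``max_end`` falls short of the query window, giving O(log n + k) stabbing
queries while insert and delete stay O(log n) — the data structure that makes
interval-based identifier conversion fast enough for whole-genome annotation
sets, and dynamic enough to absorb the daily churn of annotation databases.

Payloads are arbitrary identifier references; ties on coordinates are broken
by ``str(payload)`` so traversal order is deterministic.  Exact duplicates
(same interval, same payload) may be stored more than once and each copy is
independently retrievable and deletable.
"""

from __future__ import annotations

from typing import Any, Callable, Iterator

from .core import ChromosomeMismatchError, GenomicInterval, OverlapParams, qualifies

RED = 0
BLACK = 1


class NotFoundError(KeyError):
    """Deleting or fetching an (interval, payload) pair that is not stored."""


class _Node:
    __slots__ = ("interval", "payload", "pkey", "max_end", "color", "left", "right", "parent")

    def __init__(self, interval: GenomicInterval | None, payload: Any = None):
        self.interval = interval
        self.payload = payload
        self.pkey = "" if payload is None else str(payload)
        self.max_end = interval.end if interval is not None else 0
        self.color = BLACK
        self.left: "_Node" = self  # overwritten; sentinel points to itself
        self.right: "_Node" = self
        self.parent: "_Node" = self

    def key(self) -> tuple:
        return (self.interval.start, self.interval.end, self.pkey)


class IntervalTree:
    """Red-black interval tree over one chromosome.

    Parameters
    ----------
    chrom : str
        The chromosome this tree indexes; every inserted interval must match.
    """

    def __init__(self, chrom: str):
        self.chrom = chrom
        self.nil = _Node(None)
        self.nil.color = BLACK
        self.root = self.nil
        self.size = 0

    # -- basic helpers -----------------------------------------------------

    def _check_chrom(self, iv: GenomicInterval) -> None:
        if iv.chrom != self.chrom:
            raise ChromosomeMismatchError(
                f"tree indexes {self.chrom!r}, interval is on {iv.chrom!r}"
            )

    def _update_max_end(self, x: _Node) -> None:
        m = x.interval.end
        if x.left is not self.nil and x.left.max_end > m:
            m = x.left.max_end
        if x.right is not self.nil and x.right.max_end > m:
            m = x.right.max_end
        x.max_end = m

    def _update_upward(self, x: _Node) -> None:
        while x is not self.nil:
            self._update_max_end(x)
            x = x.parent

    def _left_rotate(self, x: _Node) -> None:
        y = x.right
        x.right = y.left
        if y.left is not self.nil:
            y.left.parent = x
        y.parent = x.parent
        if x.parent is self.nil:
            self.root = y
        elif x is x.parent.left:
            x.parent.left = y
        else:
            x.parent.right = y
        y.left = x
        x.parent = y
        self._update_max_end(x)
        self._update_max_end(y)

    def _right_rotate(self, x: _Node) -> None:
        y = x.left
        x.left = y.right
        if y.right is not self.nil:
            y.right.parent = x
        y.parent = x.parent
        if x.parent is self.nil:
            self.root = y
        elif x is x.parent.right:
            x.parent.right = y
        else:
            x.parent.left = y
        y.right = x
        x.parent = y
        self._update_max_end(x)
        self._update_max_end(y)

    # -- insert ------------------------------------------------------------

    def insert(self, iv: GenomicInterval, payload: Any) -> None:
        """Insert one (interval, payload) element; duplicates are kept."""
        self._check_chrom(iv)
        z = _Node(iv, payload)
        z.left = z.right = z.parent = self.nil
        y = self.nil
        x = self.root
        zkey = z.key()
        while x is not self.nil:
            y = x
            x = x.left if zkey < x.key() else x.right
        z.parent = y
        if y is self.nil:
            self.root = z
        elif zkey < y.key():
            y.left = z
        else:
            y.right = z
        z.color = RED
        self._update_upward(z.parent)
        self._insert_fixup(z)
        self.size += 1

    def _insert_fixup(self, z: _Node) -> None:
        while z.parent.color == RED:
            gp = z.parent.parent
            if z.parent is gp.left:
                u = gp.right
                if u.color == RED:
                    z.parent.color = BLACK
                    u.color = BLACK
                    gp.color = RED
                    z = gp
                else:
                    if z is z.parent.right:
                        z = z.parent
                        self._left_rotate(z)
                    z.parent.color = BLACK
                    z.parent.parent.color = RED
                    self._right_rotate(z.parent.parent)
            else:
                u = gp.left
                if u.color == RED:
                    z.parent.color = BLACK
                    u.color = BLACK
                    gp.color = RED
                    z = gp
                else:
                    if z is z.parent.left:
                        z = z.parent
                        self._right_rotate(z)
                    z.parent.color = BLACK
                    z.parent.parent.color = RED
                    self._left_rotate(z.parent.parent)
        self.root.color = BLACK

    # -- delete ------------------------------------------------------------

    def _find_node(self, iv: GenomicInterval, payload: Any) -> _Node:
        key = (iv.start, iv.end, str(payload))
        x = self.root
        while x is not self.nil:
            xkey = x.key()
            if key == xkey and x.payload == payload and x.interval == iv:
                return x
            x = x.left if key < xkey else x.right
        raise NotFoundError(f"({iv}, {payload!r}) not in tree")

    def _transplant(self, u: _Node, v: _Node) -> None:
        if u.parent is self.nil:
            self.root = v
        elif u is u.parent.left:
            u.parent.left = v
        else:
            u.parent.right = v
        v.parent = u.parent

    def _minimum(self, x: _Node) -> _Node:
        while x.left is not self.nil:
            x = x.left
        return x

    def delete(self, iv: GenomicInterval, payload: Any) -> None:
        """Remove one stored copy of (interval, payload).

        Raises
        ------
        NotFoundError
            If the pair is not present.
        """
        self._check_chrom(iv)
        z = self._find_node(iv, payload)
        y = z
        y_orig_color = y.color
        if z.left is self.nil:
            x = z.right
            fix_from = z.parent
            self._transplant(z, z.right)
        elif z.right is self.nil:
            x = z.left
            fix_from = z.parent
            self._transplant(z, z.left)
        else:
            y = self._minimum(z.right)
            y_orig_color = y.color
            x = y.right
            if y.parent is z:
                x.parent = y
                fix_from = y
            else:
                fix_from = y.parent
                self._transplant(y, y.right)
                y.right = z.right
                y.right.parent = y
            self._transplant(z, y)
            y.left = z.left
            y.left.parent = y
            y.color = z.color
        self._update_upward(fix_from)
        if y_orig_color == BLACK:
            self._delete_fixup(x)
        self.size -= 1

    def _delete_fixup(self, x: _Node) -> None:
        while x is not self.root and x.color == BLACK:
            if x is x.parent.left:
                w = x.parent.right
                if w.color == RED:
                    w.color = BLACK
                    x.parent.color = RED
                    self._left_rotate(x.parent)
                    w = x.parent.right
                if w.left.color == BLACK and w.right.color == BLACK:
                    w.color = RED
                    x = x.parent
                else:
                    if w.right.color == BLACK:
                        w.left.color = BLACK
                        w.color = RED
                        self._right_rotate(w)
                        w = x.parent.right
                    w.color = x.parent.color
                    x.parent.color = BLACK
                    w.right.color = BLACK
                    self._left_rotate(x.parent)
                    x = self.root
            else:
                w = x.parent.left
                if w.color == RED:
                    w.color = BLACK
                    x.parent.color = RED
                    self._right_rotate(x.parent)
                    w = x.parent.left
                if w.right.color == BLACK and w.left.color == BLACK:
                    w.color = RED
                    x = x.parent
                else:
                    if w.left.color == BLACK:
                        w.right.color = BLACK
                        w.color = RED
                        self._left_rotate(w)
                        w = x.parent.left
                    w.color = x.parent.color
                    x.parent.color = BLACK
                    w.left.color = BLACK
                    self._right_rotate(x.parent)
                    x = self.root
        x.color = BLACK

    # -- queries -----------------------------------------------------------

    def search_overlaps(
        self,
        query: GenomicInterval,
        p: OverlapParams | None = None,
        *,
        strict_strand: bool = False,
        counter: list | None = None,
    ) -> list[tuple[GenomicInterval, Any]]:
        """All stored (interval, payload) pairs qualifying against ``query``.

        Results come back in canonical ``(start, end, str(payload))`` order.
        ``select=first/last`` keep the first/last element of that order;
        ``select=arbitrary`` keeps a single deterministic element (the middle
        of the canonical order).  If ``counter`` is given, its first
        element is incremented once per visited node (used by the benchmark).

        The ``max_end`` pruning window is ``maxgap + 1`` bases on each side,
        which is conservative for every overlap type: any qualifying subject
        either shares a base with the query or lies within ``maxgap`` of it.
        """
        if p is None:
            p = OverlapParams()
        self._check_chrom(query)
        w = p.maxgap + 1
        lo = query.start - w
        hi = query.end + w
        out: list[tuple[GenomicInterval, Any]] = []
        self._collect(self.root, query, p, strict_strand, lo, hi, out, counter)
        if p.select == "all" or not out:
            return out
        if p.select == "first":
            return [out[0]]
        if p.select == "last":
            return [out[-1]]
        # arbitrary: deterministic — middle element of the canonical order
        return [out[len(out) // 2]]

    def _collect(self, node, query, p, strict_strand, lo, hi, out, counter) -> None:
        if node is self.nil:
            return
        if counter is not None:
            counter[0] += 1
        if node.max_end < lo:
            return
        self._collect(node.left, query, p, strict_strand, lo, hi, out, counter)
        if node.interval.start <= hi:
            if node.interval.end >= lo and qualifies(
                query, node.interval, p, strict_strand=strict_strand
            ):
                out.append((node.interval, node.payload))
            self._collect(node.right, query, p, strict_strand, lo, hi, out, counter)

    def items(self) -> Iterator[tuple[GenomicInterval, Any]]:
        """All stored pairs in canonical order (in-order traversal)."""
        stack: list[_Node] = []
        x = self.root
        while stack or x is not self.nil:
            while x is not self.nil:
                stack.append(x)
                x = x.left
            x = stack.pop()
            yield (x.interval, x.payload)
            x = x.right

    def __len__(self) -> int:
        return self.size

    # -- structural validation --------------------------------------------

    def height(self) -> int:
        def h(n: _Node) -> int:
            if n is self.nil:
                return 0
            return 1 + max(h(n.left), h(n.right))

        return h(self.root)

    def check_invariants(self) -> None:
        """Assert every structural invariant; raises AssertionError on breach.

        Checks: BST order on (start, end, payload key), ``max_end``
        correctness, root blackness, no red node with a red child, and equal
        black height on every root-to-leaf path.
        """
        assert self.root.color == BLACK, "root must be black"
        count = [0]

        def walk(n: _Node, lo_key, hi_key) -> tuple[int, int]:
            # returns (black_height, max_end)
            if n is self.nil:
                return (1, 0)
            count[0] += 1
            k = n.key()
            assert lo_key is None or k >= lo_key, "BST order violated (left bound)"
            assert hi_key is None or k <= hi_key, "BST order violated (right bound)"
            if n.color == RED:
                assert n.left.color == BLACK and n.right.color == BLACK, "red-red"
            bh_l, me_l = walk(n.left, lo_key, k)
            bh_r, me_r = walk(n.right, k, hi_key)
            assert bh_l == bh_r, "black-height mismatch"
            expect = max(n.interval.end, me_l, me_r)
            assert n.max_end == expect, f"max_end stale: {n.max_end} != {expect}"
            return (bh_l + (1 if n.color == BLACK else 0), n.max_end)

        walk(self.root, None, None)
        assert count[0] == self.size, f"size {self.size} != reachable {count[0]}"


def linear_search_overlaps(
    stored: list[tuple[GenomicInterval, Any]],
    query: GenomicInterval,
    p: OverlapParams | None = None,
    *,
    strict_strand: bool = False,
    counter: list | None = None,
) -> list[tuple[GenomicInterval, Any]]:
    """Reference backend: brute-force scan applying the pairwise predicate.

    Semantically identical to :meth:`IntervalTree.search_overlaps` (including
    ordering and select reduction) but O(n) per query.  Serves as the
    correctness oracle and the baseline for the benchmark.
    """
    if p is None:
        p = OverlapParams()
    hits = []
    for iv, payload in stored:
        if counter is not None:
            counter[0] += 1
        if iv.chrom == query.chrom and qualifies(query, iv, p, strict_strand=strict_strand):
            hits.append((iv, payload))
    hits.sort(key=lambda t: (t[0].start, t[0].end, str(t[1])))
    if p.select == "all" or not hits:
        return hits
    if p.select == "first":
        return [hits[0]]
    if p.select == "last":
        return [hits[-1]]
    return [hits[len(hits) // 2]]
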