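"""Strand-aware genomic intervals, overlap tests, set operations and an
overlap-query index.

All coordinates are 0-based half-open ``[start, end)`` — format readers
convert at the boundary, so every internal consumer sees one convention.
``start == end`` denotes an empty interval.  Strand is ``'+'``, ``'-'`` or
``'.'``; an unstranded ``'.'`` interval matches either strand even when
strand agreement is required (unstranded features such as CpG islands must
still annotate stranded queries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from intervaltree import IntervalTree

from .errors import ContractError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Contig name + 0-based half-open span + optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ContractError("chrom must be non-empty")
        if not 0 <= self.start <= self.end:
            raise ContractError(
                f"need 0 <= start <= end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ContractError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.start == self.end


def strands_compatible(a: str, b: str) -> bool:
    """'.' matches any strand; otherwise strands must be equal."""
    return a == "." or b == "." or a == b


def overlaps(a: GenomicInterval, b: GenomicInterval, require_strand: bool = False) -> bool:
    """True iff same contig and the half-open spans share at least one base
    (abutting intervals do not overlap), with optional strand agreement."""
    if a.chrom != b.chrom:
        return False
    if require_strand and not strands_compatible(a.strand, b.strand):
        return False
    return max(a.start, b.start) < min(a.end, b.end)


# ---------------------------------------------------------------------------
# Set operations (strand-agnostic by contract)
# ---------------------------------------------------------------------------


def _merge(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of spans on one contig: sorted, disjoint, minimal."""
    out: List[Tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(xs: List[Tuple[int, int]], ys: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        s = max(xs[i][0], ys[j][0])
        e = min(xs[i][1], ys[j][1])
        if s < e:
            out.append((s, e))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(xs: List[Tuple[int, int]], ys: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out = []
    j = 0
    for s, e in xs:
        cur = s
        while j < len(ys) and ys[j][1] <= cur:
            j += 1
        k = j
        while k < len(ys) and ys[k][0] < e:
            if ys[k][0] > cur:
                out.append((cur, ys[k][0]))
            cur = max(cur, ys[k][1])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def interval_set_op(
    xs: Iterable[GenomicInterval],
    ys: Iterable[GenomicInterval],
    op: str,
) -> List[GenomicInterval]:
    """Per-chromosome union / intersection / subtraction of covered bases.

    Strand is ignored (output strand is '.').  The result is the minimal
    sorted list of disjoint intervals covering exactly the set-theoretic
    result; empty input intervals contribute nothing.
    """
    if op not in ("union", "intersection", "subtraction"):
        raise ContractError(f"unknown set op {op!r}")
    by_chrom_x: Dict[str, List[Tuple[int, int]]] = {}
    by_chrom_y: Dict[str, List[Tuple[int, int]]] = {}
    for iv in xs:
        by_chrom_x.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for iv in ys:
        by_chrom_y.setdefault(iv.chrom, []).append((iv.start, iv.end))
    chroms = sorted(set(by_chrom_x) | set(by_chrom_y))
    result: List[GenomicInterval] = []
    for chrom in chroms:
        mx = _merge(by_chrom_x.get(chrom, []))
        my = _merge(by_chrom_y.get(chrom, []))
        if op == "union":
            spans = _merge(mx + my)
        elif op == "intersection":
            spans = _intersect(mx, my)
        else:
            spans = _subtract(mx, my)
        result.extend(GenomicInterval(chrom, s, e) for s, e in spans)
    return result


# ---------------------------------------------------------------------------
# Overlap-query index
# ---------------------------------------------------------------------------


class IntervalIndex:
    """Per-chromosome interval tree mapping intervals to payloads.

    Query results are returned in deterministic (start, end, payload) order
    regardless of insertion order.  Strand filtering happens at query time so
    one index serves both stranded and unstranded lookups.
    """

    def __init__(self, entries: Iterable[Tuple[GenomicInterval, object]] = ()):
        self._trees: Dict[str, IntervalTree] = {}
        self._n = 0
        for iv, payload in entries:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        if iv.is_empty:
            return  # empty intervals overlap nothing
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, (iv.strand, payload)
        )
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query_overlapping(
        self, q: GenomicInterval, require_strand: bool = False
    ) -> List[object]:
        """Payloads of all stored intervals overlapping ``q``; unknown
        chromosome yields an empty result."""
        tree = self._trees.get(q.chrom)
        if tree is None or q.is_empty:
            return []
        hits = []
        for node in tree.overlap(q.start, q.end):
            strand, payload = node.data
            if require_strand and not strands_compatible(strand, q.strand):
                continue
            hits.append((node.begin, node.end, payload))
        hits.sort()
        return [p for _, _, p in hits]


def query_overlapping(
    index: IntervalIndex, q: GenomicInterval, require_strand: bool = False
) -> List[object]:
    """Functional wrapper over :meth:`IntervalIndex.query_overlapping`."""
    return index.query_overlapping(q, require_strand)
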