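"""Strand-specific per-base coverage and mismatch counting from alignments.

Each mapped record that passes the active filters increments the depth of
every reference base its M/=/X CIGAR blocks cover (deletion/skip gaps are not
covered), on the strand given by the reverse flag.  Options mirror the
coverage application's switches: midpoint-only counting, uniquely-aligning
reads only, a maximum alignment error (NM), region restriction, and
per-million normalization.  Mismatch positions are recovered from MD tags
walked jointly with the CIGAR so insertions do not shift reference
coordinates.

Tracks are sparse: per contig, four position→value maps (forward, reverse,
total, mismatch) with default 0 — appropriate for the mostly-empty tracks
deep sequencing produces over large genomes.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

from .errors import ContractError, ParseError
from .format_io import AlignmentRecord
from .interval_algebra import GenomicInterval, interval_set_op

log = logging.getLogger("genomekit.coverage")

ARRAYS = ("forward", "reverse", "total", "mismatch")


class SparseVector:
    """Position → value map with default 0 and ordered nonzero iteration."""

    __slots__ = ("data",)

    def __init__(self, data: Optional[Dict[int, float]] = None):
        self.data: Dict[int, float] = dict(data) if data else {}

    def __getitem__(self, pos: int) -> float:
        return self.data.get(pos, 0)

    def __setitem__(self, pos: int, value: float) -> None:
        if value == 0:
            self.data.pop(pos, None)
        else:
            self.data[pos] = value

    def add(self, pos: int, value: float = 1) -> None:
        self.data[pos] = self.data.get(pos, 0) + value

    def items(self) -> Iterator[Tuple[int, float]]:
        """Nonzero entries in position order."""
        for pos in sorted(self.data):
            v = self.data[pos]
            if v != 0:
                yield pos, v

    def scale(self, factor: float) -> None:
        if factor == 0:
            self.data.clear()
        else:
            for pos in self.data:
                self.data[pos] *= factor

    def total(self) -> float:
        return sum(self.data.values())

    def copy(self) -> "SparseVector":
        return SparseVector(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SparseVector):
            return NotImplemented
        return {p: v for p, v in self.items()} == {p: v for p, v in other.items()}


@dataclass
class CoverageTrack:
    """Per-contig forward/reverse/total depth and mismatch counts."""

    contigs: Dict[str, Dict[str, SparseVector]] = field(default_factory=dict)
    contig_lengths: Dict[str, int] = field(default_factory=dict)
    reads_counted: int = 0
    md_missing: int = 0
    md_errors: int = 0

    def _contig(self, name: str) -> Dict[str, SparseVector]:
        if name not in self.contigs:
            self.contigs[name] = {a: SparseVector() for a in ARRAYS}
        return self.contigs[name]

    def array(self, contig: str, which: str = "total") -> SparseVector:
        if which not in ARRAYS:
            raise ContractError(f"unknown array {which!r}; expected one of {ARRAYS}")
        return self._contig(contig)[which]

    def length_of(self, contig: str) -> int:
        if contig in self.contig_lengths:
            return self.contig_lengths[contig]
        arrays = self.contigs.get(contig)
        if not arrays:
            return 0
        return max((max(v.data) + 1 for v in arrays.values() if v.data), default=0)

    def total_mass(self, which: str = "total") -> float:
        return sum(arr[which].total() for arr in self.contigs.values())

    def copy(self) -> "CoverageTrack":
        t = CoverageTrack(
            contig_lengths=dict(self.contig_lengths),
            reads_counted=self.reads_counted,
            md_missing=self.md_missing,
            md_errors=self.md_errors,
        )
        for name, arrays in self.contigs.items():
            t.contigs[name] = {a: v.copy() for a, v in arrays.items()}
        return t


# ---------------------------------------------------------------------------
# Region restriction helper
# ---------------------------------------------------------------------------


class _RegionMask:
    """Per-contig union of allowed spans with O(log n) point membership."""

    def __init__(self, regions: Iterable[GenomicInterval]):
        merged = interval_set_op(regions, [], "union")
        self.starts: Dict[str, List[int]] = {}
        self.ends: Dict[str, List[int]] = {}
        for iv in merged:
            self.starts.setdefault(iv.chrom, []).append(iv.start)
            self.ends.setdefault(iv.chrom, []).append(iv.end)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self.starts.get(chrom)
        if not starts:
            return False
        k = bisect_right(starts, pos) - 1
        return k >= 0 and pos < self.ends[chrom][k]


def _passes_filters(
    rec: AlignmentRecord,
    unique_only: bool,
    max_errors: Optional[int],
    exclude_duplicates: bool,
) -> bool:
    if rec.is_unmapped:
        return False
    if exclude_duplicates and rec.is_duplicate:
        return False
    if unique_only:
        nh = rec.tags.get("NH")
        if nh is not None:
            if nh != 1:
                return False
        elif rec.mapq <= 0:
            return False
    if max_errors is not None:
        nm = rec.tags.get("NM")
        if nm is not None and nm > max_errors:
            return False
    return True


def compute_coverage(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Optional[Dict[str, int]] = None,
    midpoint: bool = False,
    unique_only: bool = False,
    regions: Optional[Iterable[GenomicInterval]] = None,
    normalize_per_million: bool = False,
    max_errors: Optional[int] = None,
    exclude_duplicates: bool = False,
) -> CoverageTrack:
    """Accumulate a strand-specific coverage track from alignment records.

    ``midpoint`` counts only floor((start+end)/2) of the outer reference
    span; ``unique_only`` keeps records with NH==1 (or, lacking NH, mapq>0);
    ``max_errors`` bounds the NM tag; ``regions`` restrict counted bases;
    ``normalize_per_million`` rescales depth by 1e6 / reads_counted, where
    reads_counted is the number of records passing the read-level filters.
    """
    track = CoverageTrack(contig_lengths=dict(contig_lengths or {}))
    declared = frozenset(track.contig_lengths)
    mask = _RegionMask(regions) if regions is not None else None
    for rec in alignments:
        if not _passes_filters(rec, unique_only, max_errors, exclude_duplicates):
            continue
        track.reads_counted += 1
        arrays = track._contig(rec.chrom)
        strand_arr = arrays["reverse" if rec.is_reverse else "forward"]
        total_arr = arrays["total"]
        if midpoint:
            s, e = rec.reference_span()
            mid = (s + e) // 2
            if mask is None or mask.contains(rec.chrom, mid):
                strand_arr.add(mid)
                total_arr.add(mid)
        else:
            for bs, be in rec.reference_blocks():
                for pos in range(bs, be):
                    if mask is None or mask.contains(rec.chrom, pos):
                        strand_arr.add(pos)
                        total_arr.add(pos)
        if rec.chrom not in declared:
            # infer length as max end seen when no @SQ was available
            end = rec.reference_span()[1]
            if end > track.contig_lengths.get(rec.chrom, 0):
                track.contig_lengths[rec.chrom] = end
    if normalize_per_million:
        if track.reads_counted == 0:
            raise ContractError("cannot normalize: zero reads passed the filters")
        factor = 1e6 / track.reads_counted
        for arrays in track.contigs.values():
            for which in ("forward", "reverse", "total"):
                arrays[which].scale(factor)
    return track


# ---------------------------------------------------------------------------
# Mismatch counting (MD tag)
# ---------------------------------------------------------------------------

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def md_mismatch_positions(rec: AlignmentRecord) -> List[int]:
    """Reference positions of the mismatches encoded in the record's MD tag.

    The MD string is walked jointly with the CIGAR: match/mismatch tokens
    advance through the reference positions covered by M/=/X bases (so
    insertions never shift the frame), and ``^``-prefixed deletion runs are
    skipped (no read base exists there).
    """
    md = rec.tags.get("MD")
    if md is None:
        raise KeyError("MD")
    aligned_positions: List[int] = []
    for bs, be in rec.reference_blocks():
        aligned_positions.extend(range(bs, be))
    cursor = 0
    deleted = 0
    mismatches: List[int] = []
    consumed = 0
    for m in _MD_TOKEN.finditer(str(md)):
        consumed = m.end()
        num, deletion, letter = m.group(1), m.group(2), m.group(3)
        if num is not None:
            cursor += int(num)
        elif deletion is not None:
            deleted += len(deletion) - 1
        else:
            if cursor >= len(aligned_positions):
                raise ParseError(
                    f"{rec.qname}: MD tag {md!r} longer than aligned bases"
                )
            mismatches.append(aligned_positions[cursor])
            cursor += 1
    if consumed != len(str(md)):
        raise ParseError(f"{rec.qname}: malformed MD tag {md!r}")
    if cursor != len(aligned_positions):
        raise ParseError(
            f"{rec.qname}: MD tag {md!r} covers {cursor} aligned bases, "
            f"CIGAR has {len(aligned_positions)}"
        )
    cig_deleted = sum(l for l, op in rec.cigar if op == "D")
    if deleted != cig_deleted:
        raise ParseError(
            f"{rec.qname}: MD deletions ({deleted}) disagree with CIGAR "
            f"({cig_deleted})"
        )
    return mismatches


def count_mismatches(
    alignments: Iterable[AlignmentRecord],
    track: CoverageTrack,
    unique_only: bool = False,
    max_errors: Optional[int] = None,
    exclude_duplicates: bool = False,
) -> CoverageTrack:
    """Increment per-base mismatch counts from MD tags into ``track``.

    Records without an MD tag are skipped and tallied in ``md_missing``;
    records whose MD disagrees with their CIGAR are skipped and tallied in
    ``md_errors``.  Mismatch counts stay integer — they are never normalized.
    """
    for rec in alignments:
        if not _passes_filters(rec, unique_only, max_errors, exclude_duplicates):
            continue
        if "MD" not in rec.tags:
            track.md_missing += 1
            continue
        try:
            positions = md_mismatch_positions(rec)
        except ParseError as exc:
            log.warning("skipping record: %s", exc)
            track.md_errors += 1
            continue
        arr = track.array(rec.chrom, "mismatch")
        for pos in positions:
            arr.add(pos)
    return track


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def window_track(track: CoverageTrack, window: int, stat: str = "sum") -> CoverageTrack:
    """Reduce non-overlapping windows [k*w, (k+1)*w); positions become
    window indices.  ``mean`` divides by the window's in-contig width."""
    if window < 1:
        raise ContractError(f"window must be >= 1, got {window}")
    if stat not in ("mean", "sum"):
        raise ContractError(f"stat must be 'mean' or 'sum', got {stat!r}")
    out = CoverageTrack(
        contig_lengths=dict(track.contig_lengths),
        reads_counted=track.reads_counted,
    )
    for contig, arrays in track.contigs.items():
        length = track.length_of(contig)
        for which, vec in arrays.items():
            out_vec = out.array(contig, which)
            for pos, value in vec.items():
                out_vec.add(pos // window, value)
            if stat == "mean":
                nwin = -(-length // window) if length else 0
                for widx in list(out_vec.data):
                    width = window
                    if length and widx == nwin - 1:
                        width = length - widx * window
                    out_vec.data[widx] /= width
    return out


def scale_track(
    track: CoverageTrack, factor: Union[float, Dict[str, float]]
) -> CoverageTrack:
    """Multiply every stored value by a scalar or per-contig factor."""
    out = track.copy()
    for contig, arrays in out.contigs.items():
        f = factor.get(contig, 1.0) if isinstance(factor, dict) else factor
        if not (f == f and abs(f) != float("inf")):
            raise ContractError(f"non-finite factor for {contig}: {f}")
        for vec in arrays.values():
            vec.scale(f)
    return out


def write_coverage_tsv(
    track: CoverageTrack,
    path,
    comment_lines: Optional[List[str]] = None,
) -> None:
    """TSV dump: contig, 1-based position, forward, reverse, total, mismatch."""
    with open(path, "w") as fh:
        if comment_lines:
            for c in comment_lines:
                fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    fh.write("\n")
        fh.write("contig\tposition\tforward\treverse\ttotal\tmismatches\n")
        for contig in sorted(track.contigs):
            arrays = track.contigs[contig]
            positions = set()
            for vec in arrays.values():
                positions.update(vec.data)
            for pos in sorted(positions):
                fwd, rev = arrays["forward"][pos], arrays["reverse"][pos]
                tot, mm = arrays["total"][pos], arrays["mismatch"][pos]
                fh.write(
                    f"{contig}\t{pos + 1}\t{_fmt(fwd)}\t{_fmt(rev)}\t"
                    f"{_fmt(tot)}\t{_fmt(mm)}\n"
                )


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))
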