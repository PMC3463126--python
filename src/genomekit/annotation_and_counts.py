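"""Interval annotation of TSV rows and per-feature alignment counting.

Two applications live here:

* :func:`annotate_tsv` — take any TSV whose rows carry a genomic interval,
  find all features intersecting each row's interval (optionally requiring
  strand agreement) and append the matching annotations to the row.
* :func:`count_hits_per_feature` — count alignments overlapping each feature,
  with optional 5'-aware feature shifting (e.g. to probe upstream promoter
  windows instead of gene bodies), read-name whitelisting, a maximum
  alignment error, uniquely-aligning-only mode and RPKM normalization
  (reads per kilobase of feature per million counted reads,
  1e9 * C / (N * L)).

A read overlapping N features increments all N; no fractional assignment is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .errors import ContractError, ParseError
from .format_io import AlignmentRecord, Feature
from .interval_algebra import GenomicInterval, IntervalIndex

log = logging.getLogger("genomekit.annotation")

PathLike = Union[str, Path]

#: Marker written into annotation columns of rows with no matching feature.
EMPTY_MARKER = "."


@dataclass
class AnnotationResult:
    """One input row with its matched features and rendered annotation."""

    input_row: List[str]
    matched_features: List[Feature]
    appended_columns: List[str]


@dataclass
class IntervalColumns:
    """Where in a TSV row the genomic interval lives (0-based column indices).

    ``one_based`` declares 1-based inclusive start coordinates (converted on
    read); ``strand`` column is optional.
    """

    chrom: int
    start: int
    end: int
    strand: Optional[int] = None
    one_based: bool = False

    def parse(self, fields: Sequence[str], row_no: int) -> GenomicInterval:
        try:
            chrom = fields[self.chrom]
            start = int(fields[self.start]) - (1 if self.one_based else 0)
            end = int(fields[self.end])
            strand = "."
            if self.strand is not None:
                s = fields[self.strand]
                strand = s if s in "+-" else "."
            return GenomicInterval(chrom, start, end, strand)
        except (IndexError, ValueError, ContractError) as exc:
            raise ParseError(f"row {row_no}: cannot parse interval: {exc}") from exc


def _feature_index(features: Sequence[Feature]) -> IntervalIndex:
    return IntervalIndex(
        (f.interval, i) for i, f in enumerate(features)
    )


def _ordered_matches(
    features: Sequence[Feature], hit_indices: List[int]
) -> List[Feature]:
    hits = [features[i] for i in hit_indices]
    hits.sort(key=lambda f: (f.interval.start, f.interval.end, f.id))
    return hits


def annotate_rows(
    rows: Iterable[List[str]],
    interval_columns: IntervalColumns,
    features: Sequence[Feature],
    require_strand: bool = False,
    mode: str = "all_matches_one_row",
    _index: Optional[IntervalIndex] = None,
    row_offset: int = 0,
) -> List[AnnotationResult]:
    """Annotate parsed rows; the file-level wrapper is :func:`annotate_tsv`.

    ``all_matches_one_row`` keeps one output row per input row, joining
    matched feature ids/names with ';'; ``one_match_per_row`` emits one row
    per match (and unmatched rows once, with the empty marker).  Matched
    features appear in deterministic (start, end, id) order.  Rows on unknown
    chromosomes are annotated empty, never dropped.
    """
    if mode not in ("all_matches_one_row", "one_match_per_row"):
        raise ContractError(f"unknown mode {mode!r}")
    index = _index if _index is not None else _feature_index(features)
    results: List[AnnotationResult] = []
    for row_no, fields in enumerate(rows, start=1 + row_offset):
        iv = interval_columns.parse(fields, row_no)
        matches = _ordered_matches(
            features, index.query_overlapping(iv, require_strand)
        )
        if mode == "all_matches_one_row":
            if matches:
                ids = ";".join(f.id for f in matches)
                names = ";".join(f.name for f in matches)
            else:
                ids = names = EMPTY_MARKER
            results.append(AnnotationResult(list(fields), matches, [ids, names]))
        else:
            if matches:
                for f in matches:
                    results.append(
                        AnnotationResult(list(fields), [f], [f.id, f.name])
                    )
            else:
                results.append(
                    AnnotationResult(
                        list(fields), [], [EMPTY_MARKER, EMPTY_MARKER]
                    )
                )
    return results


def annotate_tsv(
    input_path: PathLike,
    output_path: PathLike,
    interval_columns: IntervalColumns,
    features: Sequence[Feature],
    require_strand: bool = False,
    mode: str = "all_matches_one_row",
    comment_lines: Optional[Sequence[str]] = None,
) -> int:
    """Annotate a TSV file row by row; returns the number of output rows.

    '#'-prefixed input lines are passed through untouched; input column
    order is preserved, with annotation columns appended.
    """
    index = _feature_index(features)
    n_out = 0
    row_no = 0
    with open(input_path) as in_fh, open(output_path, "w") as out_fh:
        if comment_lines:
            for c in comment_lines:
                out_fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    out_fh.write("\n")
        for raw in in_fh:
            line = raw.rstrip("\n").rstrip("\r")
            if line.startswith("#"):
                out_fh.write(line + "\n")
                continue
            row_no += 1
            fields = line.split("\t")
            for res in annotate_rows(
                [fields], interval_columns, features, require_strand, mode,
                _index=index, row_offset=row_no - 1,
            ):
                out_fh.write(
                    "\t".join(res.input_row + res.appended_columns) + "\n"
                )
                n_out += 1
    return n_out


# ---------------------------------------------------------------------------
# Feature hit counting
# ---------------------------------------------------------------------------


@dataclass
class FeatureCount:
    feature: Feature
    raw_count: int
    rpkm: Optional[float] = None


def shift_feature_interval(iv: GenomicInterval, shift: int) -> GenomicInterval:
    """Move a feature window by ``shift`` bases toward its 5' end.

    Positive shift moves '+' (and unstranded) features toward lower
    coordinates and '-' features toward higher coordinates — the "probe the
    upstream window" convention.  Coordinates are clamped at zero.
    """
    if shift == 0:
        return iv
    delta = shift if iv.strand == "-" else -shift
    start, end = iv.start + delta, iv.end + delta
    if start < 0:
        start, end = 0, max(0, end)
    return GenomicInterval(iv.chrom, start, max(start, end), iv.strand)


def count_hits_per_feature(
    alignments: Iterable[AlignmentRecord],
    features: Sequence[Feature],
    shift: int = 0,
    read_whitelist: Optional[Set[str]] = None,
    max_errors: Optional[int] = None,
    unique_only: bool = False,
    rpkm: bool = False,
    use_blocks: bool = True,
) -> List[FeatureCount]:
    """Count alignments overlapping each (optionally shifted) feature.

    Output preserves the input feature order.  ``use_blocks`` overlaps
    against the read's M/=/X blocks (a read spanning a feature only via a
    skipped-intron gap does not count); otherwise the outer reference span is
    used.  RPKM uses feature_length = summed sub-block length when sub-blocks
    exist, else span length, and N = reads passing the filters.
    """
    if not features:
        raise ContractError("count_hits_per_feature requires a non-empty feature list")
    from .coverage_engine import _passes_filters  # shared read-level filters

    shifted = [shift_feature_interval(f.interval, shift) for f in features]
    index = IntervalIndex((iv, i) for i, iv in enumerate(shifted))
    counts = [0] * len(features)
    reads_counted = 0
    for rec in alignments:
        if not _passes_filters(rec, unique_only, max_errors, False):
            continue
        if read_whitelist is not None and rec.qname not in read_whitelist:
            continue
        reads_counted += 1
        spans = (
            rec.reference_blocks()
            if use_blocks
            else [rec.reference_span()]
        )
        hit: Set[int] = set()
        for s, e in spans:
            q = GenomicInterval(rec.chrom, s, e, rec.strand)
            hit.update(index.query_overlapping(q, require_strand=False))
        for i in hit:
            counts[i] += 1
    out: List[FeatureCount] = []
    zero_length_warned = 0
    if rpkm and reads_counted == 0:
        raise ContractError("RPKM requested but zero reads passed the filters")
    for f, c in zip(features, counts):
        value = None
        if rpkm:
            length = f.length
            if length == 0:
                value = 0.0
                zero_length_warned += 1
            else:
                value = 1e9 * c / (reads_counted * length)
        out.append(FeatureCount(f, c, value))
    if zero_length_warned:
        log.warning("%d zero-length features given RPKM 0", zero_length_warned)
    return out


def write_feature_counts(
    counts: Sequence[FeatureCount],
    path: PathLike,
    comment_lines: Optional[Sequence[str]] = None,
) -> None:
    """TSV: feature id/name/locus/strand/length, raw count, optional RPKM."""
    with_rpkm = any(fc.rpkm is not None for fc in counts)
    with open(path, "w") as fh:
        if comment_lines:
            for c in comment_lines:
                fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    fh.write("\n")
        header = ["id", "name", "chrom", "start", "end", "strand", "length", "count"]
        if with_rpkm:
            header.append("rpkm")
        fh.write("\t".join(header) + "\n")
        for fc in counts:
            iv = fc.feature.interval
            row = [
                fc.feature.id,
                fc.feature.name,
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.strand,
                str(fc.feature.length),
                str(fc.raw_count),
            ]
            if with_rpkm:
                row.append(repr(fc.rpkm) if fc.rpkm is not None else "")
            fh.write("\t".join(row) + "\n")
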