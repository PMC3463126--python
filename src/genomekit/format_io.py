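"""Readers and writers for the text formats the applications touch.

* SAM (text dialect): parsed into :class:`AlignmentRecord` with reference
  coordinates converted to the internal 0-based half-open convention and
  reference-space blocks derived from the CIGAR (M/=/X consume both query
  and reference, D/N reference only, I/S query only, H neither).
* Feature tables: BED, GFF (v2/v3 tolerated), UCSC refGene.txt, Ensembl
  Biomart TSV and generic TSV with a column map — all normalized to
  :class:`Feature` objects with 0-based half-open intervals.
* wiggle fixedStep output for coverage tracks (1-based block starts).

Only the text dialects are handled; binary BAM/CRAM are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

from .errors import ContractError, ParseError
from .interval_algebra import GenomicInterval

PathLike = Union[str, Path]

CIGAR_OPS = "MIDNSHP=X"
_CIGAR_RE = re.compile(r"(\d+)([A-Za-z=])")

#: CIGAR ops consuming the reference / the query.
REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")
ALIGNED_OPS = frozenset("M=X")  # consume both → covered reference bases

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400


@dataclass
class AlignmentRecord:
    """One parsed SAM line, reduced to reference-space geometry.

    ``pos`` is the 0-based leftmost mapped position (converted from SAM's
    1-based field on ingest).
    """

    qname: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: List[Tuple[int, str]]
    seq: str = "*"
    qual: str = "*"
    tags: Dict[str, object] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED) or self.chrom == "*"

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def reference_blocks(self) -> List[Tuple[int, int]]:
        """Covered reference spans (M/=/X only); D/N gaps split blocks."""
        if self.is_unmapped:
            return []
        blocks: List[Tuple[int, int]] = []
        ref = self.pos
        for length, op in self.cigar:
            if op in ALIGNED_OPS:
                if blocks and blocks[-1][1] == ref:
                    blocks[-1] = (blocks[-1][0], ref + length)
                else:
                    blocks.append((ref, ref + length))
                ref += length
            elif op in ("D", "N"):
                ref += length
        return blocks

    def reference_span(self) -> Tuple[int, int]:
        """Outer reference span [pos, end) including D/N gaps."""
        if self.is_unmapped:
            return (self.pos, self.pos)
        end = self.pos + sum(l for l, op in self.cigar if op in REF_CONSUMING)
        return (self.pos, end)

    def aligned_base_count(self) -> int:
        return sum(l for l, op in self.cigar if op in ALIGNED_OPS)

    def interval(self) -> GenomicInterval:
        s, e = self.reference_span()
        return GenomicInterval(self.chrom, s, e, self.strand)


def parse_cigar(text: str) -> List[Tuple[int, str]]:
    if text == "*":
        return []
    ops: List[Tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ParseError(f"malformed CIGAR {text!r}")
        length, op = int(m.group(1)), m.group(2)
        if op not in CIGAR_OPS:
            raise ParseError(f"unknown CIGAR operation {op!r} in {text!r}")
        ops.append((length, op))
        pos = m.end()
    if pos != len(text):
        raise ParseError(f"malformed CIGAR {text!r}")
    return ops


def _parse_tag(field_: str):
    try:
        name, typ, value = field_.split(":", 2)
    except ValueError:
        raise ParseError(f"malformed tag field {field_!r}")
    if typ == "i":
        return name, int(value)
    if typ == "f":
        return name, float(value)
    return name, value


def read_sam_header(path: PathLike) -> Dict[str, int]:
    """Contig lengths from @SQ header lines (SN/LN)."""
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                break
            if line.startswith("@SQ"):
                sn, ln = None, None
                for f in line.rstrip("\n").split("\t")[1:]:
                    if f.startswith("SN:"):
                        sn = f[3:]
                    elif f.startswith("LN:"):
                        ln = int(f[3:])
                if sn is not None and ln is not None:
                    lengths[sn] = ln
    return lengths


def parse_sam(path: PathLike) -> Iterator[AlignmentRecord]:
    """Yield every record of a text SAM file, mapped or not.

    Secondary/duplicate records are yielded with their flags intact;
    filtering is the consumer's decision.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(
                    f"{path}:{lineno}: SAM record has {len(fields)} fields (< 11)"
                )
            try:
                flag = int(fields[1])
                pos1 = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric mandatory field: {exc}"
                ) from exc
            try:
                cigar = parse_cigar(fields[5])
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            tags = {}
            for f in fields[11:]:
                name, value = _parse_tag(f)
                tags[name] = value
            yield AlignmentRecord(
                qname=fields[0],
                flag=flag,
                chrom=fields[2],
                pos=pos1 - 1,
                mapq=mapq,
                cigar=cigar,
                seq=fields[9],
                qual=fields[10],
                tags=tags,
            )


def write_sam(
    records: Sequence[AlignmentRecord],
    path: PathLike,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write records as text SAM with @HD/@SQ headers."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in (contig_lengths or {}).items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            cigar = (
                "".join(f"{l}{op}" for l, op in r.cigar) if r.cigar else "*"
            )
            tag_fields = []
            for name, value in r.tags.items():
                typ = "i" if isinstance(value, int) else (
                    "f" if isinstance(value, float) else "Z"
                )
                tag_fields.append(f"{name}:{typ}:{value}")
            fields = [
                r.qname,
                str(r.flag),
                r.chrom,
                str(r.pos + 1),
                str(r.mapq),
                cigar,
                "*",
                "0",
                "0",
                r.seq,
                r.qual,
            ] + tag_fields
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """A named genomic feature; ``sub_blocks`` hold exon-like sub-intervals."""

    id: str
    name: str
    interval: GenomicInterval
    sub_blocks: Optional[List[GenomicInterval]] = None
    attributes: Dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        """Summed sub-block length when sub-blocks exist, else span length."""
        if self.sub_blocks:
            return sum(len(b) for b in self.sub_blocks)
        return len(self.interval)


DIALECTS = ("refgene", "bed", "gff", "biomart_tsv", "generic_tsv")


def _data_lines(path: PathLike) -> Iterator[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_gff_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in re.split(r";\s*", text.strip()):
        if not part:
            continue
        if "=" in part:  # GFF3
            k, _, v = part.partition("=")
            attrs[k.strip()] = v.strip()
        else:  # GFF2/GTF: key "value"
            bits = part.strip().split(None, 1)
            if len(bits) == 2:
                attrs[bits[0]] = bits[1].strip('"')
            else:
                attrs[bits[0]] = ""
    return attrs


def read_features(
    path: PathLike,
    dialect: str,
    column_map: Optional[Dict[str, str]] = None,
    one_based: bool = False,
) -> List[Feature]:
    """Read a feature table, normalizing coordinates to 0-based half-open.

    BED and refGene txStart/txEnd are native half-open; GFF start/end are
    1-based inclusive (start-1 .. end); Biomart/generic TSV columns are
    located by ``column_map`` (keys: chrom, start, end; optional strand, id,
    name) against the header row, with ``one_based`` declaring 1-based
    inclusive coordinates.
    """
    if dialect not in DIALECTS:
        raise ContractError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "bed":
        return _read_bed(path)
    if dialect == "gff":
        return _read_gff(path)
    if dialect == "refgene":
        return _read_refgene(path)
    if column_map is None:
        raise ContractError(f"dialect {dialect!r} requires a column_map")
    if dialect == "biomart_tsv":
        one_based = True  # Biomart exports are 1-based inclusive
    return _read_mapped_tsv(path, column_map, one_based)


def _read_bed(path: PathLike) -> List[Feature]:
    feats = []
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ContractError(
                f"{path}:{lineno}: BED needs >= 3 columns (chrom, start, end)"
            )
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name = f[3] if len(f) > 3 else f"bed_{lineno}"
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
        feats.append(
            Feature(name, name, GenomicInterval(chrom, start, end, strand))
        )
    return feats


def _read_gff(path: PathLike) -> List[Feature]:
    feats = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 8:
            raise ContractError(f"{path}:{lineno}: GFF needs >= 8 columns")
        chrom, start, end = f[0], int(f[3]) - 1, int(f[4])
        strand = f[6] if f[6] in "+-" else "."
        attrs = _parse_gff_attributes(f[8]) if len(f) > 8 else {}
        fid = attrs.get("ID") or attrs.get("gene_id") or f"gff_{lineno}"
        name = attrs.get("Name") or attrs.get("gene_name") or fid
        feats.append(
            Feature(fid, name, GenomicInterval(chrom, start, end, strand), None, attrs)
        )
    return feats


#: UCSC refGene.txt column order (no header line in the real file).
REFGENE_COLUMNS = (
    "bin name chrom strand txStart txEnd cdsStart cdsEnd exonCount "
    "exonStarts exonEnds score name2"
).split()


def _read_refgene(path: PathLike) -> List[Feature]:
    feats = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 11:
            raise ContractError(
                f"{path}:{lineno}: refGene needs >= 11 columns "
                f"({', '.join(REFGENE_COLUMNS[:11])})"
            )
        name, chrom, strand = f[1], f[2], f[3]
        tx_start, tx_end = int(f[4]), int(f[5])
        exon_starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
        exon_ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
        if len(exon_starts) != len(exon_ends):
            raise ParseError(
                f"{path}:{lineno}: exonStarts/exonEnds arity mismatch"
            )
        strand = strand if strand in "+-" else "."
        blocks = [
            GenomicInterval(chrom, s, e, strand)
            for s, e in zip(exon_starts, exon_ends)
        ]
        name2 = f[12] if len(f) > 12 else name
        feats.append(
            Feature(
                name,
                name2,
                GenomicInterval(chrom, tx_start, tx_end, strand),
                blocks or None,
            )
        )
    return feats


def _read_mapped_tsv(
    path: PathLike, column_map: Dict[str, str], one_based: bool
) -> List[Feature]:
    for key in ("chrom", "start", "end"):
        if key not in column_map:
            raise ContractError(f"column_map must map {key!r}")
    lines = _data_lines(path)
    try:
        _, header_line = next(lines)
    except StopIteration:
        return []
    header = header_line.split("\t")
    col_idx: Dict[str, int] = {}
    for key, col_name in column_map.items():
        if col_name not in header:
            raise ContractError(
                f"{path}: mapped column {col_name!r} ({key}) not in header {header}"
            )
        col_idx[key] = header.index(col_name)
    feats = []
    off = 1 if one_based else 0
    for lineno, line in lines:
        f = line.split("\t")
        chrom = f[col_idx["chrom"]]
        start = int(f[col_idx["start"]]) - off
        end = int(f[col_idx["end"]])
        strand = f[col_idx["strand"]] if "strand" in col_idx else "."
        if strand in ("1", "+1"):
            strand = "+"
        elif strand == "-1":
            strand = "-"
        elif strand not in "+-":
            strand = "."
        fid = f[col_idx["id"]] if "id" in col_idx else f"row_{lineno}"
        name = f[col_idx["name"]] if "name" in col_idx else fid
        feats.append(Feature(fid, name, GenomicInterval(chrom, start, end, strand)))
    return feats


def write_features_bed(features: Sequence[Feature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.id}\t0\t{iv.strand}\n"
            )


def write_features_gff(features: Sequence[Feature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.chrom}\tgenomekit\tfeature\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={f.id};Name={f.name}\n"
            )


def write_features_refgene(features: Sequence[Feature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            blocks = f.sub_blocks or [iv]
            starts = ",".join(str(b.start) for b in blocks) + ","
            ends = ",".join(str(b.end) for b in blocks) + ","
            fh.write(
                "\t".join(
                    [
                        "0",
                        f.id,
                        iv.chrom,
                        iv.strand if iv.strand in "+-" else ".",
                        str(iv.start),
                        str(iv.end),
                        str(iv.start),
                        str(iv.end),
                        str(len(blocks)),
                        starts,
                        ends,
                        "0",
                        f.name,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# wiggle
# ---------------------------------------------------------------------------


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_wiggle(
    track,
    path: PathLike,
    span: int = 1,
    array: str = "total",
    comment_lines: Optional[Sequence[str]] = None,
) -> None:
    """Write a coverage track as wiggle fixedStep (1-based starts).

    Zero runs are omitted by opening a new fixedStep block at each gap.
    ``array`` selects which per-contig array to export (total/forward/
    reverse/mismatch).
    """
    with open(path, "w") as fh:
        if comment_lines:
            for c in comment_lines:
                fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    fh.write("\n")
        fh.write('track type=wiggle_0 name="genomekit"\n')
        for contig in sorted(track.contigs):
            vec = track.array(contig, array)
            prev_pos = None
            for pos, value in vec.items():
                if value == 0:
                    continue
                if prev_pos is None or pos != prev_pos + 1:
                    fh.write(
                        f"fixedStep chrom={contig} start={pos + 1} step=1 span={span}\n"
                    )
                fh.write(_fmt_value(value) + "\n")
                prev_pos = pos


def read_wiggle(path: PathLike) -> Dict[str, Dict[int, float]]:
    """Parse fixedStep wiggle back into {contig: {0-based pos: value}}."""
    out: Dict[str, Dict[int, float]] = {}
    contig, pos, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(
                    part.split("=", 1) for part in line.split()[1:] if "=" in part
                )
                contig = kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                out.setdefault(contig, {})
                continue
            if contig is None:
                raise ParseError(f"{path}: data line before any fixedStep header")
            out[contig][pos] = float(line)
            pos += step
    return out
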