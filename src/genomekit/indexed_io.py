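"""Random access by line number to large text, TSV, FASTA and FASTQ files.

A one-pass scan records the byte offset of every line start into a sidecar
index file (``<source>.idx``).  The index itself has a fixed number of bytes
per entry (zero-padded decimal offsets), so entry *k* can be located at a
constant byte position without reading the whole index; after that, a single
seek into the source file retrieves the line.  The net effect is that an
arbitrarily large text file can be used like a string array.

The index header records the source file's size and mtime; an index whose
header no longer matches the source is considered stale and rebuilt.  Purely
sequential traversal (:func:`stream_lines`) never creates an index.

Conventions
-----------
* ``'\n'`` separates lines; a ``'\r'`` immediately before it is stripped on
  return, so CRLF files index identically to LF files.
* A final line without a trailing newline still counts as a line.
* FASTQ records are strictly 4 lines (no wrapped sequences); FASTA sequences
  may wrap over any number of lines.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Union

from .errors import ContractError, ParseError

log = logging.getLogger("genomekit.indexed_io")

#: Digits reserved per serialized offset; 19 covers any signed 64-bit offset.
OFFSET_WIDTH = 19

PathLike = Union[str, Path]


@dataclass
class LineIndex:
    """Byte-offset index of the lines of a text file."""

    source_path: Path
    source_size: int
    source_mtime_ns: int
    offsets: List[int]
    width: int = OFFSET_WIDTH

    _handle: Optional[io.BufferedReader] = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.offsets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineIndex):
            return NotImplemented
        return (
            Path(self.source_path) == Path(other.source_path)
            and self.source_size == other.source_size
            and self.source_mtime_ns == other.source_mtime_ns
            and self.offsets == other.offsets
            and self.width == other.width
        )

    # -- persistence -------------------------------------------------------

    def serialize(self) -> str:
        head = f"{self.source_size}\t{self.source_mtime_ns}\t{self.width}\n"
        body = "".join(f"{off:0{self.width}d}\n" for off in self.offsets)
        return head + body

    @classmethod
    def deserialize(cls, text: str, source_path: PathLike) -> "LineIndex":
        lines = text.split("\n")
        try:
            size_s, mtime_s, width_s = lines[0].split("\t")
            size, mtime_ns, width = int(size_s), int(mtime_s), int(width_s)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"corrupt line index header: {lines[0]!r}") from exc
        offsets = [int(ln) for ln in lines[1:] if ln]
        return cls(Path(source_path), size, mtime_ns, offsets, width)

    def _file(self) -> io.BufferedReader:
        if self._handle is None or self._handle.closed:
            self._handle = open(self.source_path, "rb")
        return self._handle

    def close(self) -> None:
        if self._handle is not None and not self._handle.closed:
            self._handle.close()


def index_path_for(text_path: PathLike) -> Path:
    return Path(str(text_path) + ".idx")


def _scan_offsets(text_path: PathLike) -> List[int]:
    """One sequential pass noting the starting byte position of each line."""
    offsets: List[int] = []
    pos = 0
    at_line_start = True
    with open(text_path, "rb") as fh:
        while True:
            chunk = fh.read(1 << 20)
            if not chunk:
                break
            start = 0
            while True:
                if at_line_start:
                    offsets.append(pos + start)
                    at_line_start = False
                nl = chunk.find(b"\n", start)
                if nl == -1:
                    break
                start = nl + 1
                if start == len(chunk):
                    at_line_start = True
                    break
                at_line_start = True
            pos += len(chunk)
    return offsets


def build_line_index(text_path: PathLike) -> LineIndex:
    """Build (or reuse) the persistent line index for ``text_path``.

    An up-to-date sidecar index is loaded without rescanning the source; a
    stale one (source size or mtime changed) is rebuilt.  If the sidecar
    cannot be written, the index is kept in memory and a warning is logged.
    """
    text_path = Path(text_path)
    st = text_path.stat()  # raises OSError for unreadable/missing files
    idx_path = index_path_for(text_path)
    if idx_path.exists():
        try:
            idx = LineIndex.deserialize(idx_path.read_text(), text_path)
        except ParseError:
            idx = None
        if (
            idx is not None
            and idx.source_size == st.st_size
            and idx.source_mtime_ns == st.st_mtime_ns
        ):
            return idx
    offsets = _scan_offsets(text_path)
    idx = LineIndex(text_path, st.st_size, st.st_mtime_ns, offsets)
    try:
        idx_path.write_text(idx.serialize())
    except OSError as exc:
        log.warning("cannot write index %s (%s); keeping it in memory", idx_path, exc)
    return idx


def read_line(index: LineIndex, line_no: int) -> str:
    """Return line ``line_no`` (0-based) without its trailing newline."""
    n = len(index.offsets)
    if not 0 <= line_no < n:
        raise IndexError(f"line {line_no} out of range [0, {n})")
    fh = index._file()
    fh.seek(index.offsets[line_no])
    if line_no + 1 < n:
        raw = fh.read(index.offsets[line_no + 1] - index.offsets[line_no])
    else:
        raw = fh.read(index.source_size - index.offsets[line_no])
    return _chomp(raw.decode())


def _chomp(s: str) -> str:
    """Strip one trailing newline and one carriage return before it."""
    if s.endswith("\n"):
        s = s[:-1]
    if s.endswith("\r"):
        s = s[:-1]
    return s


def read_tsv_row(index: LineIndex, line_no: int) -> List[str]:
    """Line ``line_no`` split on single tabs; empty fields preserved."""
    return read_line(index, line_no).split("\t")


def stream_lines(text_path: PathLike) -> Iterator[str]:
    """Yield lines sequentially; creates no index artifact."""
    with open(text_path, "rb") as fh:
        for raw in fh:
            yield _chomp(raw.decode())


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """One FASTA or FASTQ record; ``quality`` is present only for FASTQ."""

    name: str
    sequence: str
    quality: Optional[str] = None


class SequencesFile:
    """Random-access or sequential FASTA/FASTQ reader built on the line index.

    FASTA records may wrap their sequence over multiple lines; FASTQ records
    are strictly 4 lines.  Format is sniffed from the first non-empty line.
    """

    def __init__(self, path: PathLike):
        self.path = Path(path)
        self.index = build_line_index(path)
        self.format = self._sniff()
        self._record_starts: List[int] = self._locate_records()

    def _sniff(self) -> str:
        for k in range(len(self.index)):
            line = read_line(self.index, k)
            if line:
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ParseError(
                    f"{self.path}: first non-empty line is neither '>' nor '@'"
                )
        return "fasta"  # empty file: zero records either way

    def _locate_records(self) -> List[int]:
        starts: List[int] = []
        if self.format == "fasta":
            for k in range(len(self.index)):
                if read_line(self.index, k).startswith(">"):
                    starts.append(k)
        else:
            nlines = len(self.index)
            if nlines % 4 != 0:
                raise ParseError(
                    f"{self.path}: FASTQ line count {nlines} is not a multiple of 4"
                )
            starts = list(range(0, nlines, 4))
        return starts

    def __len__(self) -> int:
        return len(self._record_starts)

    def __getitem__(self, record_no: int) -> SequenceRecord:
        n = len(self._record_starts)
        if not 0 <= record_no < n:
            raise IndexError(f"record {record_no} out of range [0, {n})")
        start = self._record_starts[record_no]
        if self.format == "fasta":
            name = read_line(self.index, start)[1:]
            stop = (
                self._record_starts[record_no + 1]
                if record_no + 1 < n
                else len(self.index)
            )
            seq = "".join(read_line(self.index, k) for k in range(start + 1, stop))
            return SequenceRecord(name, seq)
        header = read_line(self.index, start)
        seq = read_line(self.index, start + 1)
        plus = read_line(self.index, start + 2)
        qual = read_line(self.index, start + 3)
        if not header.startswith("@"):
            raise ParseError(f"record {record_no}: FASTQ header missing '@'")
        if not plus.startswith("+"):
            raise ParseError(f"record {record_no}: FASTQ '+' line missing")
        if len(qual) != len(seq):
            raise ParseError(
                f"record {record_no}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        return SequenceRecord(header[1:], seq, qual)

    def __iter__(self) -> Iterator[SequenceRecord]:
        for k in range(len(self)):
            yield self[k]

    def close(self) -> None:
        self.index.close()


def read_sequence_record(path: PathLike, record_no: int) -> SequenceRecord:
    """Random access to record ``record_no`` of a FASTA/FASTQ file."""
    sf = SequencesFile(path)
    try:
        return sf[record_no]
    finally:
        sf.close()


def write_sequences(records, path: PathLike, fastq: Optional[bool] = None) -> None:
    """Write records as FASTA, or FASTQ when qualities are present."""
    records = list(records)
    if fastq is None:
        fastq = bool(records) and records[0].quality is not None
    with open(path, "w") as fh:
        for rec in records:
            if fastq:
                if rec.quality is None:
                    raise ContractError(f"record {rec.name!r} has no quality string")
                fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")
            else:
                fh.write(f">{rec.name}\n{rec.sequence}\n")
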