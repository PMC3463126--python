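"""Small-application layer: list statistics, histograms, text-file set
operations, FASTA/FASTQ subset/trim/dedupe, and a seeded RNG with
permutations."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .errors import ContractError
from .indexed_io import SequenceRecord, SequencesFile, write_sequences

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    n: int
    mean: float
    median: float
    sample_variance: float
    sd: float
    min: float
    max: float
    q1: float
    q3: float
    sum: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Descriptive statistics of a non-empty number list.

    Sample variance uses the n-1 denominator (0 for n == 1); quartiles use
    linear interpolation.
    """
    if len(values) == 0:
        raise ContractError("summarize requires at least one value")
    arr = np.asarray(values, dtype=float)
    var = float(arr.var(ddof=1)) if len(arr) > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return SummaryStats(
        n=len(arr),
        mean=float(arr.mean()),
        median=med,
        sample_variance=var,
        sd=math.sqrt(var),
        min=float(arr.min()),
        max=float(arr.max()),
        q1=q1,
        q3=q3,
        sum=float(arr.sum()),
    )


def histogram(
    values: Sequence,
    bin_width: Optional[float] = None,
    n_bins: Optional[int] = None,
    lo: Optional[float] = None,
) -> List[Tuple[str, int]]:
    """Histogram of numbers (binned) or strings (exact counts).

    Numeric bins are half-open [a, a+w) with the final bin closed so counts
    always sum to n.  String mode sorts by descending count, then label.
    """
    values = list(values)
    if values and all(isinstance(v, str) for v in values):
        counts = Counter(values)
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if not values:
        return []
    arr = np.asarray(values, dtype=float)
    vmin = float(arr.min()) if lo is None else float(lo)
    vmax = float(arr.max())
    if bin_width is None:
        if n_bins is None:
            raise ContractError("numeric histogram needs bin_width or n_bins")
        if n_bins < 1:
            raise ContractError(f"n_bins must be >= 1, got {n_bins}")
        bin_width = (vmax - vmin) / n_bins or 1.0
        nb = int(n_bins)
    else:
        if bin_width <= 0:
            raise ContractError(f"bin width must be positive, got {bin_width}")
        # successive [a, a+w) bins; a value on the top edge opens one more
        nb = int((vmax - vmin) // bin_width) + 1 if vmax >= vmin else 1
    counts = [0] * nb
    for v in arr:
        k = int((v - vmin) // bin_width)
        if k >= nb:  # v == right edge of the final bin
            k = nb - 1
        counts[k] += 1
    out = []
    for k in range(nb):
        a = vmin + k * bin_width
        b = a + bin_width
        closer = "]" if k == nb - 1 else ")"
        out.append((f"[{a:g},{b:g}{closer}", counts[k]))
    return out


# ---------------------------------------------------------------------------
# Text-file set operations
# ---------------------------------------------------------------------------


def _unique_lines(path: PathLike) -> List[str]:
    seen: Set[str] = set()
    out: List[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.endswith("\r"):
                line = line[:-1]
            if line not in seen:
                seen.add(line)
                out.append(line)
    return out


def text_set_op(a: PathLike, b: PathLike, op: str) -> List[str]:
    """Set algebra on the lines of two files (exact-match, raw lines).

    Duplicates within a file collapse to the first occurrence; results keep
    first-occurrence order from ``a`` (union appends ``b``'s novel lines).
    """
    if op not in ("intersection", "subtraction", "union"):
        raise ContractError(f"unknown set op {op!r}")
    ua, ub = _unique_lines(a), _unique_lines(b)
    sb = set(ub)
    if op == "intersection":
        return [ln for ln in ua if ln in sb]
    if op == "subtraction":
        return [ln for ln in ua if ln not in sb]
    sa = set(ua)
    return ua + [ln for ln in ub if ln not in sa]


# ---------------------------------------------------------------------------
# Seeded RNG
# ---------------------------------------------------------------------------


class SeededRng:
    """Deterministic RNG: identical seeds yield identical draw sequences and
    permutations (uniform, Fisher-Yates contract)."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._gen = np.random.default_rng(self.seed)

    def random(self) -> float:
        return float(self._gen.random())

    def integers(self, low: int, high: int) -> int:
        return int(self._gen.integers(low, high))

    def permutation(self, n: int) -> List[int]:
        if n < 0:
            raise ContractError(f"permutation length must be >= 0, got {n}")
        return [int(x) for x in self._gen.permutation(n)]


def permutation(rng: SeededRng, n: int) -> List[int]:
    """Uniform random permutation of 0..n-1."""
    return rng.permutation(n)


# ---------------------------------------------------------------------------
# FASTA/FASTQ operations
# ---------------------------------------------------------------------------


def subset_records(
    path: PathLike,
    out_path: PathLike,
    names: Optional[Iterable[str]] = None,
    fraction: Optional[float] = None,
    seed: int = 0,
) -> int:
    """Keep records by name (order preserved) or by a seeded random fraction.

    Exactly one of ``names`` / ``fraction`` must be given.  Returns the
    number of records written.
    """
    if (names is None) == (fraction is None):
        raise ContractError("subset needs exactly one of names or fraction")
    sf = SequencesFile(path)
    kept: List[SequenceRecord] = []
    if names is not None:
        wanted = set(names)
        kept = [rec for rec in sf if rec.name in wanted]
    else:
        if not 0 <= fraction <= 1:
            raise ContractError(f"fraction must be in [0, 1], got {fraction}")
        rng = SeededRng(seed)
        kept = [rec for rec in sf if rng.random() < fraction]
    write_sequences(kept, out_path, fastq=sf.format == "fastq")
    sf.close()
    return len(kept)


def trim_records(
    path: PathLike, out_path: PathLike, start: int, length: int
) -> int:
    """Slice every record to [start, start+length); quality trimmed in
    lockstep.  Records shorter than requested are emitted at the available
    length; the count of such records is returned."""
    if start < 0 or length < 0:
        raise ContractError("trim start and length must be non-negative")
    sf = SequencesFile(path)
    short = 0
    out: List[SequenceRecord] = []
    for rec in sf:
        if len(rec.sequence) < start + length:
            short += 1
        seq = rec.sequence[start : start + length]
        qual = rec.quality[start : start + length] if rec.quality else None
        out.append(SequenceRecord(rec.name, seq, qual))
    write_sequences(out, out_path, fastq=sf.format == "fastq")
    sf.close()
    return short


def dedupe_records(path: PathLike, out_path: PathLike) -> int:
    """Keep the first record per exact sequence; returns records written."""
    sf = SequencesFile(path)
    seen: Set[str] = set()
    out: List[SequenceRecord] = []
    for rec in sf:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    write_sequences(out, out_path, fastq=sf.format == "fastq")
    sf.close()
    return len(out)
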