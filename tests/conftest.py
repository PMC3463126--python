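"""Shared fixtures and independent oracles used across the test suite.

The oracles here are deliberately naive re-computations (nested loops,
bit vectors, dense pileups) kept independent of the library code paths
they check.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from genomekit.format_io import AlignmentRecord
from genomekit.interval_algebra import GenomicInterval
from genomekit.table_core import Table, TableSchema


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def cigar_walk_oracle(pos: int, cigar: List[Tuple[int, str]]) -> List[int]:
    """Reference positions covered by aligned (M/=/X) bases — naive walk."""
    covered = []
    ref = pos
    for length, op in cigar:
        if op in ("M", "=", "X"):
            covered.extend(range(ref, ref + length))
            ref += length
        elif op in ("D", "N"):
            ref += length
        # I, S, H, P: no reference movement
    return covered


def pileup_oracle(
    records: Sequence[AlignmentRecord],
) -> Dict[str, Dict[str, Counter]]:
    """Dense per-base pileup by walking every CIGAR base by base."""
    out: Dict[str, Dict[str, Counter]] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        tracks = out.setdefault(
            rec.chrom, {"forward": Counter(), "reverse": Counter(), "total": Counter()}
        )
        strand = "reverse" if rec.is_reverse else "forward"
        for p in cigar_walk_oracle(rec.pos, rec.cigar):
            tracks[strand][p] += 1
            tracks["total"][p] += 1
    return out


def bitvector_set_op(
    xs: Sequence[GenomicInterval],
    ys: Sequence[GenomicInterval],
    op: str,
    universe: int = 1000,
) -> Dict[str, set]:
    """Set algebra over explicit per-base sets on a small universe."""
    chroms = {iv.chrom for iv in xs} | {iv.chrom for iv in ys}
    out = {}
    for chrom in chroms:
        a = set()
        for iv in xs:
            if iv.chrom == chrom:
                a.update(range(iv.start, min(iv.end, universe)))
        b = set()
        for iv in ys:
            if iv.chrom == chrom:
                b.update(range(iv.start, min(iv.end, universe)))
        if op == "union":
            out[chrom] = a | b
        elif op == "intersection":
            out[chrom] = a & b
        else:
            out[chrom] = a - b
    return out


def nested_loop_join(
    a_rows: List[tuple],
    b_rows: List[tuple],
    a_key: List[int],
    b_key: List[int],
    how: str,
    a_arity: int,
    b_extra: List[int],
    nulls_a: List[object],
    nulls_b: List[object],
) -> List[tuple]:
    """O(n*m) reference join returning rows as tuples (multiset compare)."""
    out = []
    matched_b = set()
    for ra in a_rows:
        ka = tuple(ra[i] for i in a_key)
        hits = [
            (j, rb) for j, rb in enumerate(b_rows)
            if tuple(rb[i] for i in b_key) == ka
        ]
        if hits:
            for j, rb in hits:
                out.append(tuple(ra) + tuple(rb[i] for i in b_extra))
                matched_b.add(j)
        elif how in ("left", "full"):
            out.append(tuple(ra) + tuple(nulls_b))
    if how in ("right", "full"):
        for j, rb in enumerate(b_rows):
            if j not in matched_b:
                key_vals = {bi: rb[bi] for bi in b_key}
                row_a = list(nulls_a)
                for ai, bi in zip(a_key, b_key):
                    row_a[ai] = rb[bi]
                out.append(tuple(row_a) + tuple(rb[i] for i in b_extra))
    return out


def random_table(rng: np.random.Generator, nrows: int, key_space: int = 8) -> Table:
    """Small random table with duplicate-rich keys for join/sort tests."""
    schema = TableSchema([("k", int), ("x", float), ("s", str), ("b", bool)])
    return Table(
        schema,
        {
            "k": [int(v) for v in rng.integers(0, key_space, nrows)],
            "x": [float(v) for v in rng.normal(size=nrows)],
            "s": ["s" + str(int(v)) for v in rng.integers(0, 5, nrows)],
            "b": [bool(v) for v in rng.integers(0, 2, nrows)],
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
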