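"""A relational-database-like Table: schema-typed columns with row semantics.

The Table is the universal tabular currency of the package: annotation files,
coverage dumps, count matrices and peak lists all travel through it.  Data are
stored column-wise (one Python list per column) under a schema that fixes each
column's name and type (``int``, ``float``, ``str`` or ``bool``); row *i* is
the tuple of column values at position *i*.

Provided operations mirror a small relational algebra: filtering,
concatenation, stable multi-key sorting, binary-search bounds on a sorted
column, inner/left/right/full joins (via a key→rows map built on the smaller
operand), plus numeric column smoothing and TSV round-tripping.

Outer joins pad the missing side with per-type null sentinels rather than an
option type: ``INT_MISSING`` for int, NaN for float, ``""`` for str and
``False`` for bool.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import ContractError, ParseError

ColumnType = type
Row = Tuple[object, ...]

#: Null sentinel used for int columns padded by outer joins.
INT_MISSING = -(2**63)

_NULLS: Dict[type, object] = {int: INT_MISSING, float: float("nan"), str: "", bool: False}

_TYPE_NAMES = {int: "int", float: "float", str: "string", bool: "bool"}


def _coerce(text: str, typ: type):
    if typ is str:
        return text
    if typ is int:
        return int(text)
    if typ is float:
        return float(text)
    if typ is bool:
        low = text.strip().lower()
        if low in ("true", "1", "t", "yes"):
            return True
        if low in ("false", "0", "f", "no"):
            return False
        raise ValueError(f"not a bool: {text!r}")
    raise ContractError(f"unsupported column type {typ!r}")


def _render(value: object, typ: type) -> str:
    if typ is bool:
        return "true" if value else "false"
    if typ is float:
        return repr(float(value))
    return str(value)


@dataclass(frozen=True)
class TableSchema:
    """Ordered (name, type) column declarations; names unique and non-empty."""

    columns: Tuple[Tuple[str, type], ...]

    def __init__(self, columns: Iterable[Tuple[str, type]]):
        cols = tuple((str(n), t) for n, t in columns)
        names = [n for n, _ in cols]
        if any(not n for n in names):
            raise ContractError("column names must be non-empty")
        if len(set(names)) != len(names):
            raise ContractError(f"duplicate column names in schema: {names}")
        for n, t in cols:
            if t not in (int, float, str, bool):
                raise ContractError(f"column {n!r}: unsupported type {t!r}")
        object.__setattr__(self, "columns", cols)

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.columns]

    def type_of(self, name: str) -> type:
        for n, t in self.columns:
            if n == name:
                return t
        raise ContractError(f"unknown column {name!r}; have {self.names}")

    def index_of(self, name: str) -> int:
        for i, (n, _) in enumerate(self.columns):
            if n == name:
                return i
        raise ContractError(f"unknown column {name!r}; have {self.names}")


class Table:
    """Schema-typed columnar container with row semantics."""

    def __init__(self, schema: TableSchema, columns: Optional[Dict[str, list]] = None):
        self.schema = schema
        if columns is None:
            self.columns: Dict[str, list] = {n: [] for n in schema.names}
        else:
            if set(columns) != set(schema.names):
                raise ContractError(
                    f"column dict {sorted(columns)} does not match schema "
                    f"{schema.names}"
                )
            lengths = {len(v) for v in columns.values()}
            if len(lengths) > 1:
                raise ContractError(f"ragged columns: lengths {sorted(lengths)}")
            self.columns = {n: list(columns[n]) for n in schema.names}

    # -- basics ------------------------------------------------------------

    @property
    def nrows(self) -> int:
        return len(self.columns[self.schema.names[0]]) if self.schema.columns else 0

    def __len__(self) -> int:
        return self.nrows

    def row(self, i: int) -> Row:
        return tuple(self.columns[n][i] for n in self.schema.names)

    def rows(self) -> Iterable[Row]:
        names = self.schema.names
        cols = [self.columns[n] for n in names]
        return zip(*cols) if cols else iter(())

    def append_row(self, values: Sequence[object]) -> None:
        names = self.schema.names
        if len(values) != len(names):
            raise ContractError(
                f"row arity {len(values)} != schema arity {len(names)}"
            )
        for n, v in zip(names, values):
            self.columns[n].append(v)

    def column(self, name: str) -> list:
        if name not in self.columns:
            raise ContractError(f"unknown column {name!r}; have {self.schema.names}")
        return self.columns[name]

    def copy(self) -> "Table":
        return Table(self.schema, {n: list(c) for n, c in self.columns.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Table):
            return NotImplemented
        return self.schema == other.schema and self.columns == other.columns

    def __repr__(self) -> str:
        return f"Table({self.schema.names}, nrows={self.nrows})"

    @classmethod
    def from_rows(cls, schema: TableSchema, rows: Iterable[Sequence[object]]) -> "Table":
        t = cls(schema)
        for r in rows:
            t.append_row(r)
        return t


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_tsv_table(
    path: Union[str, Path], schema: TableSchema, has_header: bool = False
) -> Table:
    """Read a TSV file into a Table, skipping '#'-prefixed comment lines.

    When ``has_header`` is set, the first non-comment line must repeat the
    schema's column names.  Arity or coercion failures report the offending
    1-based line number and column name.
    """
    t = Table(schema)
    names = schema.names
    header_seen = not has_header
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line.startswith("#"):
                continue
            if not header_seen:
                got = line.split("\t")
                if got != names:
                    raise ParseError(
                        f"{path}:{lineno}: header {got} does not match schema {names}"
                    )
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != len(names):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(names)} fields, got {len(fields)}"
                )
            values = []
            for (name, typ), text in zip(schema.columns, fields):
                try:
                    values.append(_coerce(text, typ))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: column {name!r}: cannot coerce "
                        f"{text!r} to {_TYPE_NAMES[typ]}"
                    ) from exc
            t.append_row(values)
    return t


def write_tsv_table(
    table: Table,
    path: Union[str, Path],
    with_header: bool = True,
    comment_lines: Optional[Sequence[str]] = None,
) -> None:
    """Write a Table as TSV; optional '#'-prefixed comment lines go first."""
    with open(path, "w") as fh:
        if comment_lines:
            for c in comment_lines:
                fh.write(c if c.startswith("#") else "#" + c)
                if not c.endswith("\n"):
                    fh.write("\n")
        if with_header:
            fh.write("\t".join(table.schema.names) + "\n")
        types = [t for _, t in table.schema.columns]
        for row in table.rows():
            fh.write("\t".join(_render(v, t) for v, t in zip(row, types)) + "\n")


# ---------------------------------------------------------------------------
# Relational operations
# ---------------------------------------------------------------------------


def filter_rows(t: Table, predicate: Callable[[Row], bool]) -> Table:
    """Rows satisfying ``predicate``, order preserved, schema unchanged."""
    out = Table(t.schema)
    for i, row in enumerate(t.rows()):
        try:
            keep = predicate(row)
        except Exception as exc:
            raise ContractError(f"predicate raised on row {i}: {exc}") from exc
        if keep:
            out.append_row(row)
    return out


def concat_tables(a: Table, b: Table) -> Table:
    """Rows of ``a`` followed by rows of ``b``; schemas must be identical."""
    if a.schema != b.schema:
        diff = set(a.schema.columns) ^ set(b.schema.columns)
        raise ContractError(f"schema mismatch; differing columns: {sorted(diff)}")
    out = a.copy()
    for n in out.schema.names:
        out.columns[n].extend(b.columns[n])
    return out


def sort_table(
    t: Table, by: Sequence[str], ascending: Union[bool, Sequence[bool]] = True
) -> Table:
    """Stable lexicographic sort on the named columns."""
    if isinstance(ascending, bool):
        ascending = [ascending] * len(by)
    if len(ascending) != len(by):
        raise ContractError("ascending flags must match the sort key count")
    for name in by:
        t.schema.index_of(name)  # raises on unknown column
    order = list(range(t.nrows))
    # Stable sorts composed from the least-significant key outward realize the
    # lexicographic order while honoring per-key direction.
    for name, asc in list(zip(by, ascending))[::-1]:
        col = t.columns[name]
        order.sort(key=lambda i: col[i], reverse=not asc)
    return Table(
        t.schema, {n: [c[i] for i in order] for n, c in t.columns.items()}
    )


def lower_bound(t: Table, column: str, value) -> int:
    """Smallest i with t[i][column] >= value (column sorted ascending).

    An unsorted column is *not* detected; that precondition is the caller's.
    """
    return bisect_left(t.column(column), value)


def upper_bound(t: Table, column: str, value) -> int:
    """Smallest i with t[i][column] > value (column sorted ascending)."""
    return bisect_right(t.column(column), value)


@dataclass
class KeyMap:
    """Map from key tuples to the ordered row indices holding that key."""

    key_columns: Tuple[str, ...]
    mapping: Dict[Tuple, List[int]] = field(default_factory=dict)

    @classmethod
    def build(cls, t: Table, key_columns: Sequence[str]) -> "KeyMap":
        cols = [t.column(n) for n in key_columns]
        km = cls(tuple(key_columns))
        for i in range(t.nrows):
            km.mapping.setdefault(tuple(c[i] for c in cols), []).append(i)
        return km


def join_tables(
    a: Table, b: Table, on: Sequence[str], how: str = "inner"
) -> Table:
    """Relational join on the named key columns.

    Result schema: all of ``a``'s columns, then ``b``'s non-key columns
    (name clashes suffixed ``_right``).  Duplicate keys produce the full
    Cartesian pairing; outer variants pad the missing side with null
    sentinels.  The key→rows map is built on the smaller operand.
    """
    if how not in ("inner", "left", "right", "full"):
        raise ContractError(f"unknown join mode {how!r}")
    on = list(on)
    for name in on:
        ta, tb = a.schema.type_of(name), b.schema.type_of(name)
        if ta is not tb:
            raise ContractError(
                f"key column {name!r}: type mismatch "
                f"({_TYPE_NAMES[ta]} vs {_TYPE_NAMES[tb]})"
            )

    b_extra = [(n, t) for n, t in b.schema.columns if n not in on]
    out_names_b = [
        (n + "_right") if n in a.schema.names else n for n, _ in b_extra
    ]
    out_schema = TableSchema(
        list(a.schema.columns)
        + [(on_, t) for on_, (_, t) in zip(out_names_b, b_extra)]
    )
    a_nulls = [_NULLS[t] for _, t in a.schema.columns]
    b_nulls = [_NULLS[t] for _, t in b_extra]
    a_keypos = [a.schema.index_of(n) for n in on]
    b_cols_extra = [b.column(n) for n, _ in b_extra]
    a_cols = [a.column(n) for n in a.schema.names]

    def b_extra_row(j: int) -> list:
        return [c[j] for c in b_cols_extra]

    def a_row(i: int) -> list:
        return [c[i] for c in a_cols]

    # KeyMap on the smaller table; iteration stays a-major either way.
    out = Table(out_schema)
    if b.nrows <= a.nrows:
        km_b = KeyMap.build(b, on)
        matched_b: set = set()
        for i in range(a.nrows):
            key = tuple(a_cols[p][i] for p in a_keypos)
            hits = km_b.mapping.get(key, [])
            if hits:
                for j in hits:
                    out.append_row(a_row(i) + b_extra_row(j))
                matched_b.update(hits)
            elif how in ("left", "full"):
                out.append_row(a_row(i) + b_nulls)
        if how in ("right", "full"):
            for j in range(b.nrows):
                if j not in matched_b:
                    key_vals = {n: b.column(n)[j] for n in on}
                    row = [
                        key_vals[n] if n in on else null
                        for (n, _), null in zip(a.schema.columns, a_nulls)
                    ]
                    out.append_row(row + b_extra_row(j))
    else:
        km_a = KeyMap.build(a, on)
        matched_a: set = set()
        b_key_cols = [b.column(n) for n in on]
        pair_rows: List[Tuple[int, int]] = []
        for j in range(b.nrows):
            key = tuple(c[j] for c in b_key_cols)
            hits = km_a.mapping.get(key, [])
            for i in hits:
                pair_rows.append((i, j))
            matched_a.update(hits)
        pair_rows.sort(key=lambda ij: ij[0])  # a-major order
        matched_b2 = {j for _, j in pair_rows}
        ai = 0
        for i in range(a.nrows):
            pairs_i = []
            while ai < len(pair_rows) and pair_rows[ai][0] == i:
                pairs_i.append(pair_rows[ai][1])
                ai += 1
            if pairs_i:
                for j in pairs_i:
                    out.append_row(a_row(i) + b_extra_row(j))
            elif how in ("left", "full"):
                out.append_row(a_row(i) + b_nulls)
        if how in ("right", "full"):
            for j in range(b.nrows):
                if j not in matched_b2:
                    key_vals = {n: b.column(n)[j] for n in on}
                    row = [
                        key_vals[n] if n in on else null
                        for (n, _), null in zip(a.schema.columns, a_nulls)
                    ]
                    out.append_row(row + b_extra_row(j))
    return out


def smooth_column(t: Table, column: str, window: int) -> Table:
    """Replace a numeric column by its centered moving average.

    The window shrinks at the table edges (mean over the in-range slice).
    The smoothed column's type becomes float.  ``window`` must be odd, >= 1.
    """
    typ = t.schema.type_of(column)
    if typ not in (int, float):
        raise ContractError(f"column {column!r} is {_TYPE_NAMES[typ]}, not numeric")
    if window < 1 or window % 2 == 0:
        raise ContractError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    col = t.column(column)
    n = len(col)
    smoothed = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = col[lo:hi]
        smoothed.append(sum(seg) / len(seg))
    new_schema = TableSchema(
        [(nm, float if nm == column else ty) for nm, ty in t.schema.columns]
    )
    cols = {nm: (smoothed if nm == column else list(c)) for nm, c in t.columns.items()}
    return Table(new_schema, cols)
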