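"""Intensity tables: accumulation, CSV I/O, merging, reshaping, filtering.

Every analyzed line yields one :class:`IntensityRecord` carrying its full
provenance (file, strip, line, threshold method and parameters) next to the
mean/median signal, so a table alone documents how its numbers were made.
Tables are plain pandas DataFrames with a fixed column schema and round-trip
losslessly through CSV in the default dialect.

Row filtering uses a small, injection-safe predicate grammar instead of a
general expression evaluator: clauses ``column OP constant`` with
``OP in {==, !=, <, <=, >, >=, in}``, combined with ``and`` / ``or`` /
``not`` and parentheses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("lfaquant")

#: canonical column order of an intensity table
INTENSITY_COLUMNS = [
    "file", "strip", "line", "method", "offset", "quantile_prob",
    "mode", "inverted", "mean_signal", "median_signal",
]
#: columns identifying one measurement (settings included): duplicates on
#: these keys are replacements, not new rows
KEY_COLUMNS = ["file", "strip", "line", "method", "offset", "quantile_prob",
               "mode", "inverted"]


class SchemaError(ValueError):
    """A required column is missing or a join key is ambiguous."""


class PredicateError(ValueError):
    """Malformed subset predicate; message carries the offending position."""


@dataclass(frozen=True)
class IntensityRecord:
    """One line's measurement with the settings that produced it."""

    file: str
    strip: int
    line: int
    method: str
    offset: float
    quantile_prob: float | None
    mode: str
    inverted: bool
    mean_signal: float
    median_signal: float

    def __post_init__(self) -> None:
        for name in ("mean_signal", "median_signal", "offset"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"field {name!r} must be finite, got {v!r}")
        if self.mean_signal < 0 or self.median_signal < 0:
            raise ValueError("signal statistics must be >= 0")


def new_table() -> pd.DataFrame:
    """An empty intensity table with the canonical schema."""
    return pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(
        INTENSITY_COLUMNS,
        ["object", "int64", "int64", "object", "float64", "float64",
         "object", "bool", "float64", "float64"],
    )})


def records_from_analysis(file: str, threshold_result, line_intensities) -> list[IntensityRecord]:
    """Turn one strip's analysis output into table records."""
    spec = threshold_result.spec
    qp = spec.quantile_prob if spec.method == "quantile" else None
    return [
        IntensityRecord(
            file=file, strip=li.strip, line=li.line, method=spec.method,
            offset=spec.offset, quantile_prob=qp, mode=spec.mode,
            inverted=spec.inverted, mean_signal=li.mean_signal,
            median_signal=li.median_signal,
        )
        for li in line_intensities
    ]


def append_record(table: pd.DataFrame, record: IntensityRecord) -> pd.DataFrame:
    """Append one record; an identical-keyed row is replaced with a warning."""
    row = {f.name: getattr(record, f.name) for f in dc_fields(record)}
    if len(table):
        qp = row["quantile_prob"]
        mask = np.ones(len(table), dtype=bool)
        for k in KEY_COLUMNS:
            if k == "quantile_prob":
                col = table[k]
                mask &= col.isna().to_numpy() if qp is None else (col == qp).to_numpy()
            else:
                mask &= (table[k] == row[k]).to_numpy()
        if mask.any():
            logger.warning("replacing %d existing record(s) with identical keys",
                           int(mask.sum()))
            table = table[~mask]
    new_row = pd.DataFrame([row])
    out = pd.concat([table, new_row], ignore_index=True) if len(table) else new_row
    return out.reindex(columns=INTENSITY_COLUMNS).reset_index(drop=True)


def append_records(table: pd.DataFrame, records) -> pd.DataFrame:
    for r in records:
        table = append_record(table, r)
    return table


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dialect:
    """CSV flavour: field separator, decimal mark, preamble rows to skip."""

    separator: str = ","
    decimal: str = "."
    skip_rows: int = 0

    def __post_init__(self) -> None:
        if self.separator not in (",", ";", "\t"):
            raise ValueError("separator must be ',', ';' or tab")
        if self.decimal not in (".", ","):
            raise ValueError("decimal mark must be '.' or ','")


def read_table(path: str | Path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Read a CSV (any supported dialect) into a DataFrame."""
    try:
        return pd.read_csv(path, sep=dialect.separator, decimal=dialect.decimal,
                           skiprows=dialect.skip_rows)
    except pd.errors.ParserError as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc


def write_table(table: pd.DataFrame, path: str | Path,
                dialect: Dialect = Dialect()) -> None:
    table.to_csv(path, index=False, sep=dialect.separator, decimal=dialect.decimal)


# ---------------------------------------------------------------------------
# Merging, averaging, reshaping
# ---------------------------------------------------------------------------

def merge_experiment(intensity: pd.DataFrame, experiment: pd.DataFrame,
                     key_intensity: str, key_experiment: str) -> pd.DataFrame:
    """Inner-join experiment metadata onto intensity rows by the named keys."""
    if key_intensity not in intensity.columns:
        raise SchemaError(f"intensity table has no column {key_intensity!r}")
    if key_experiment not in experiment.columns:
        raise SchemaError(f"experiment table has no column {key_experiment!r}")
    dup = experiment[key_experiment].duplicated()
    if dup.any():
        raise SchemaError(
            f"experiment key {key_experiment!r} is not unique: "
            f"{sorted(experiment.loc[dup, key_experiment].unique().tolist())}"
        )
    merged = intensity.merge(experiment, left_on=key_intensity,
                             right_on=key_experiment, how="inner")
    unmatched = len(intensity) - len(merged)
    if unmatched:
        logger.warning("merge_experiment: %d intensity row(s) had no matching "
                       "experiment entry and were dropped", unmatched)
    return merged.reset_index(drop=True)


def average_replicates(table: pd.DataFrame, group_cols: list[str]) -> pd.DataFrame:
    """Collapse technical replicates: group means of numeric columns plus
    an ``n_replicates`` count column."""
    missing = [c for c in group_cols if c not in table.columns]
    if missing:
        raise SchemaError(f"grouping column(s) not in table: {missing}")
    num_cols = [c for c in table.columns
                if c not in group_cols and pd.api.types.is_numeric_dtype(table[c])]
    grouped = table.groupby(group_cols, as_index=False, sort=True, dropna=False)
    out = grouped[num_cols].mean()
    out["n_replicates"] = grouped.size()["size"].to_numpy()
    return out


def reshape_wide(table: pd.DataFrame, line_labels: list[str]) -> pd.DataFrame:
    """Long (one row per line) to wide (one row per file/strip).

    ``line_labels`` names the lines top to bottom (e.g. ``["tl", "cl"]``)
    and must match the number of distinct line indices; the wide table
    gains ``<label>_mean`` and ``<label>_median`` columns.
    """
    for c in ("file", "strip", "line", "mean_signal", "median_signal"):
        if c not in table.columns:
            raise SchemaError(f"long table has no column {c!r}")
    lines = sorted(table["line"].unique())
    if len(line_labels) != len(lines):
        raise SchemaError(
            f"{len(line_labels)} label(s) given for {len(lines)} distinct line(s)"
        )
    label_of = dict(zip(lines, line_labels))
    id_cols = ["file", "strip"]
    other = [c for c in table.columns
             if c not in ("line", "mean_signal", "median_signal") + tuple(id_cols)]
    wide = table[id_cols].drop_duplicates().reset_index(drop=True)
    # per-group constants (settings, merged metadata) carried over from the
    # first row of each group
    if other:
        firsts = table.groupby(id_cols, as_index=False, sort=False)[other].first()
        wide = wide.merge(firsts, on=id_cols, how="left")
    for line, label in label_of.items():
        sub = table[table["line"] == line]
        part = sub[id_cols + ["mean_signal", "median_signal"]].rename(
            columns={"mean_signal": f"{label}_mean", "median_signal": f"{label}_median"}
        )
        wide = wide.merge(part, on=id_cols, how="left")
    return wide


def reshape_long(wide: pd.DataFrame, line_labels: list[str]) -> pd.DataFrame:
    """Inverse of :func:`reshape_wide` for tables it produced."""
    id_cols = ["file", "strip"]
    rows = []
    value_cols = [f"{lbl}_{stat}" for lbl in line_labels for stat in ("mean", "median")]
    other = [c for c in wide.columns if c not in id_cols + value_cols]
    for _, r in wide.iterrows():
        for line, lbl in enumerate(line_labels):
            rows.append({
                **{c: r[c] for c in id_cols},
                **{c: r[c] for c in other},
                "line": line,
                "mean_signal": r[f"{lbl}_mean"],
                "median_signal": r[f"{lbl}_median"],
            })
    long = pd.DataFrame(rows)
    ordered = [c for c in INTENSITY_COLUMNS if c in long.columns]
    rest = [c for c in long.columns if c not in ordered]
    return long[ordered + rest]


# ---------------------------------------------------------------------------
# Safe subset predicates
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<lpar>\() | (?P<rpar>\)) | (?P<comma>,) |
      (?P<op>==|!=|<=|>=|<|>) |
      (?P<number>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?) |
      (?P<string>'[^']*'|"[^"]*") |
      (?P<word>[A-Za-z_][A-Za-z0-9_.]*)
    )""", re.VERBOSE)

_KEYWORDS = {"and", "or", "not", "in", "true", "false"}


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise PredicateError(f"unexpected character at position {pos}: "
                                 f"{text[pos:pos + 10]!r}")
        pos = m.end()
        kind = m.lastgroup
        value = m.group(kind)
        if kind == "number":
            value = float(value) if any(c in value for c in ".eE") else int(value)
            tokens.append(("literal", value, m.start()))
        elif kind == "string":
            tokens.append(("literal", value[1:-1], m.start()))
        elif kind == "word":
            w = value.lower()
            if w in ("true", "false"):
                tokens.append(("literal", w == "true", m.start()))
            elif w in _KEYWORDS:
                tokens.append((w, w, m.start()))
            else:
                tokens.append(("ident", value, m.start()))
        else:
            tokens.append((kind, value, m.start()))
    tokens.append(("end", None, len(text)))
    return tokens


class _PredicateParser:
    """Recursive descent over: or_expr > and_expr > not_expr > clause."""

    def __init__(self, text: str, table: pd.DataFrame):
        self.text = text
        self.table = table
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.next()
        if tok[0] != kind:
            raise PredicateError(
                f"expected {kind} at position {tok[2]}, got {tok[1]!r}")
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        tok = self.peek()
        if tok[0] != "end":
            raise PredicateError(f"unexpected token {tok[1]!r} at position {tok[2]}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok[0] == "not":
            self.next()
            return ~self.not_expr()
        if tok[0] == "lpar":
            self.next()
            mask = self.or_expr()
            self.expect("rpar")
            return mask
        return self.clause()

    def clause(self) -> np.ndarray:
        tok = self.next()
        if tok[0] != "ident":
            raise PredicateError(
                f"expected a column name at position {tok[2]}, got {tok[1]!r}")
        col = tok[1]
        if col not in self.table.columns:
            raise PredicateError(
                f"unknown column {col!r} at position {tok[2]}")
        series = self.table[col]
        op_tok = self.next()
        if op_tok[0] == "in":
            self.expect("lpar")
            values = [self.expect("literal")[1]]
            while self.peek()[0] == "comma":
                self.next()
                values.append(self.expect("literal")[1])
            self.expect("rpar")
            return series.isin(values).to_numpy()
        if op_tok[0] != "op":
            raise PredicateError(
                f"expected a comparator at position {op_tok[2]}, got {op_tok[1]!r}")
        value = self.expect("literal")[1]
        op = op_tok[1]
        with np.errstate(invalid="ignore"):
            if op == "==":
                return (series == value).to_numpy()
            if op == "!=":
                return (series != value).to_numpy()
            if op == "<":
                return (series < value).to_numpy()
            if op == "<=":
                return (series <= value).to_numpy()
            if op == ">":
                return (series > value).to_numpy()
            return (series >= value).to_numpy()


def subset(table: pd.DataFrame, predicate: str) -> pd.DataFrame:
    """Rows satisfying a predicate in the restricted filter grammar.

    Example: ``"(strip == 1) and (line == 0) or concentration >= 2.5"``.
    """
    mask = _PredicateParser(predicate, table).parse()
    return table[mask].reset_index(drop=True)
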