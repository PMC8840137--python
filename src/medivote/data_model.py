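"""Tabular data model: labeled tables, CSV/ARFF I/O, discretization.

A :class:`LabeledTable` is the package's in-memory container for a
classification dataset: an ordered set of named attributes, one of which
is the designated target, and an ordered list of instances.  Columns are
either numeric (floats, missing as NaN) or categorical (string tokens,
missing as the reserved token ``"?"``).  Row order is stable under every
operation that subsets rows.

Continuous features must be discretized before rule induction, because
the rule learner branches on exact value equality.  The discretizer uses
per-column equal-frequency binning fitted on training data only.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError, SchemaError

logger = logging.getLogger(__name__)

#: Reserved token representing a missing categorical value.
MISSING = "?"


def _is_float_token(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


@dataclass
class LabeledTable:
    """A labeled instance table with one designated target attribute.

    Parameters
    ----------
    df
        Column order defines attribute order; dtypes are ``float64`` for
        numeric columns and ``object`` (str) for categorical ones.
    target
        Name of the target attribute; must be a column of ``df``.
    provenance
        Free-text tag describing where the table came from.
    """

    df: pd.DataFrame
    target: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.target not in self.df.columns:
            raise ConfigurationError(
                f"target attribute {self.target!r} not among columns "
                f"{list(self.df.columns)}"
            )
        self.df = self.df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def attributes(self) -> list[str]:
        return list(self.df.columns)

    @property
    def other_attributes(self) -> list[str]:
        """All attributes except the target, in column order."""
        return [a for a in self.df.columns if a != self.target]

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def column(self, name: str) -> list:
        if name not in self.df.columns:
            raise KeyError(name)
        return self.df[name].tolist()

    def is_numeric(self, name: str) -> bool:
        return pd.api.types.is_numeric_dtype(self.df[name])

    @property
    def target_values(self) -> list[str]:
        """Distinct target values in first-encounter order."""
        seen: dict = {}
        for v in self.df[self.target]:
            if v not in seen:
                seen[v] = None
        return list(seen)

    def rows(self):
        """Iterate instances as attribute-name -> value mappings."""
        cols = list(self.df.columns)
        for tup in self.df.itertuples(index=False, name=None):
            yield dict(zip(cols, tup))

    # -- structural operations -------------------------------------------
    def subset(self, index) -> "LabeledTable":
        """Rows at positional ``index`` (order-preserving)."""
        return LabeledTable(self.df.iloc[list(index)], self.target, self.provenance)

    def drop_attributes(self, names) -> "LabeledTable":
        names = [n for n in names if n != self.target]
        return LabeledTable(self.df.drop(columns=list(names)), self.target, self.provenance)

    def equals(self, other: "LabeledTable", atol: float = 1e-9) -> bool:
        if self.attributes != other.attributes or self.target != other.target:
            return False
        if self.n_rows != other.n_rows:
            return False
        for col in self.attributes:
            a, b = self.df[col], other.df[col]
            if self.is_numeric(col) != other.is_numeric(col):
                return False
            if self.is_numeric(col):
                av, bv = a.to_numpy(float), b.to_numpy(float)
                ok = np.isclose(av, bv, atol=atol, rtol=0.0) | (np.isnan(av) & np.isnan(bv))
                if not ok.all():
                    return False
            elif not (a.astype(str) == b.astype(str)).all():
                return False
        return True


# ---------------------------------------------------------------------------
# CSV / ARFF readers and writers
# ---------------------------------------------------------------------------

def _finalize_columns(header: list[str], rows: list[list[str]],
                      target: str, provenance: str,
                      numeric_hint: dict[str, bool] | None = None) -> LabeledTable:
    """Build a LabeledTable from string cells, auto-detecting numeric columns."""
    if target == "last":
        target = header[-1]
    if target not in header:
        raise ConfigurationError(f"target column {target!r} not in header {header}")
    data: dict[str, list] = {h: [] for h in header}
    for r in rows:
        for h, v in zip(header, r):
            data[h].append(v)
    df_cols = {}
    for h in header:
        vals = data[h]
        non_missing = [v for v in vals if v != MISSING and v != ""]
        if numeric_hint is not None:
            numeric = numeric_hint.get(h, False)
        else:
            numeric = bool(non_missing) and all(_is_float_token(v) for v in non_missing)
        if numeric and h != target:
            df_cols[h] = [float(v) if v not in (MISSING, "") else math.nan for v in vals]
        else:
            df_cols[h] = [MISSING if v == "" else v for v in vals]
    df = pd.DataFrame(df_cols, columns=header)
    # rows with a missing target carry no supervision signal
    mask = df[target].astype(str) != MISSING
    if not mask.all():
        n_drop = int((~mask).sum())
        logger.warning("dropping %d row(s) with missing target %r", n_drop, target)
        df = df[mask]
    return LabeledTable(df, target, provenance)


def _read_csv(path: str, target: str) -> LabeledTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataFormatError(f"{path}: empty file") from None
        rows = []
        for i, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != len(header):
                raise DataFormatError(
                    f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
                )
            rows.append(row)
    return _finalize_columns(header, rows, target, provenance=str(path))


_ARFF_ATTR = re.compile(r"@attribute\s+(?:'([^']+)'|(\S+))\s+(.+)$", re.IGNORECASE)


def _split_arff_row(line: str) -> list[str]:
    return next(csv.reader([line], quotechar="'", skipinitialspace=True))


def _read_arff(path: str, target: str) -> LabeledTable:
    """Minimal reader for the Weka ARFF dialect.

    Supports @relation, @attribute with numeric/real/integer, nominal
    ``{a,b,c}`` and string types, ``%`` comments and ``?`` missing values.
    Sparse rows and date attributes are not supported.
    """
    header: list[str] = []
    numeric_hint: dict[str, bool] = {}
    nominal_domains: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            if in_data:
                row = [c.strip() for c in _split_arff_row(line)]
                if len(row) != len(header):
                    raise DataFormatError(
                        f"{path}: data row at line {lineno} has {len(row)} "
                        f"fields, expected {len(header)}"
                    )
                rows.append(row)
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                m = _ARFF_ATTR.match(line)
                if not m:
                    raise DataFormatError(f"{path}: bad @attribute at line {lineno}")
                name = m.group(1) or m.group(2)
                typ = m.group(3).strip()
                header.append(name)
                if typ.startswith("{"):
                    numeric_hint[name] = False
                    inner = typ.strip().lstrip("{").rstrip("}").strip()
                    nominal_domains[name] = [
                        t.strip() for t in _split_arff_row(inner)
                    ]
                elif typ.lower() in ("numeric", "real", "integer"):
                    numeric_hint[name] = True
                elif typ.lower() == "string":
                    numeric_hint[name] = False
                else:
                    raise DataFormatError(
                        f"{path}: unsupported attribute type {typ!r} at line {lineno}"
                    )
            elif low.startswith("@data"):
                if not header:
                    raise DataFormatError(f"{path}: @data before any @attribute")
                in_data = True
            else:
                raise DataFormatError(f"{path}: unrecognized line {lineno}: {line!r}")
    if not in_data:
        raise DataFormatError(f"{path}: no @data section")
    table = _finalize_columns(header, rows, target, provenance=str(path),
                              numeric_hint=numeric_hint)
    # validate nominal tokens against their declared domains
    for name, domain in nominal_domains.items():
        if name == table.target or not table.is_numeric(name):
            bad = set(table.df[name].astype(str)) - set(domain) - {MISSING}
            if bad:
                raise DataFormatError(
                    f"{path}: value(s) {sorted(bad)} outside declared domain of {name!r}"
                )
    return table


def read_table(path: str, format: str = "infer", target: str = "last") -> LabeledTable:
    """Read a labeled table from CSV (RFC 4180, header row) or ARFF.

    ``target`` names the target column, or ``"last"`` for the final
    column.  Numeric columns are detected by successful numeric parse of
    every non-missing entry (CSV) or by the declared type (ARFF).
    """
    if format == "infer":
        format = "arff" if str(path).lower().endswith(".arff") else "csv"
    if format == "csv":
        return _read_csv(path, target)
    if format == "arff":
        return _read_arff(path, target)
    raise ConfigurationError(f"unknown format {format!r}")


def _fmt_cell(v, numeric: bool) -> str:
    if numeric:
        if isinstance(v, float) and math.isnan(v):
            return MISSING
        return repr(float(v))
    return str(v)


def _arff_quote(tok: str) -> str:
    if tok == MISSING:
        return tok
    if re.search(r"[\s,{}%']", tok) or tok == "":
        return "'" + tok.replace("'", "\\'") + "'"
    return tok


def write_table(table: LabeledTable, path: str, format: str = "infer") -> None:
    """Write a table as CSV or ARFF; round-trips through :func:`read_table`."""
    if table.n_rows == 0:
        raise ConfigurationError("refusing to write an empty table")
    if format == "infer":
        format = "arff" if str(path).lower().endswith(".arff") else "csv"
    numeric = {c: table.is_numeric(c) for c in table.attributes}
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(table.attributes)
            for row in table.rows():
                w.writerow([_fmt_cell(row[c], numeric[c]) for c in table.attributes])
        return
    if format != "arff":
        raise ConfigurationError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("@relation " + _arff_quote(table.provenance or "medivote") + "\n\n")
        for c in table.attributes:
            if numeric[c]:
                fh.write(f"@attribute {_arff_quote(c)} numeric\n")
            else:
                seen: dict = {}
                for v in table.df[c].astype(str):
                    if v != MISSING:
                        seen[v] = None
                domain = ",".join(_arff_quote(v) for v in seen)
                fh.write(f"@attribute {_arff_quote(c)} {{{domain}}}\n")
        fh.write("\n@data\n")
        for row in table.rows():
            fh.write(",".join(
                _arff_quote(_fmt_cell(row[c], numeric[c])) for c in table.attributes
            ) + "\n")


# ---------------------------------------------------------------------------
# Equal-frequency discretization
# ---------------------------------------------------------------------------

def _bin_labels(edges: np.ndarray) -> list[str]:
    """Human-readable interval labels for interior cut points ``edges``."""
    if len(edges) == 0:
        return ["(-inf,inf)"]
    labels = [f"(-inf,{edges[0]:.6g}]"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"({lo:.6g},{hi:.6g}]")
    labels.append(f"({edges[-1]:.6g},inf)")
    return labels


@dataclass
class DiscretizationMap:
    """Per-attribute equal-frequency bin edges and labels.

    ``cuts[col]`` holds the strictly ascending interior cut points; a
    value ``v`` falls in bin ``i`` iff ``cuts[i-1] < v <= cuts[i]``, with
    the outer bins open (out-of-range values clamp to the first/last
    bin).  Columns absent from ``cuts`` pass through untouched, which
    makes application idempotent on already-categorical tables.
    """

    cuts: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, list[str]] = field(default_factory=dict)
    bin_count: int = 5

    def to_dict(self) -> dict:
        return {
            "bin_count": self.bin_count,
            "cuts": {c: [float(x) for x in v] for c, v in self.cuts.items()},
            "labels": dict(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationMap":
        return cls(
            cuts={c: np.asarray(v, dtype=float) for c, v in d["cuts"].items()},
            labels={c: list(v) for c, v in d["labels"].items()},
            bin_count=int(d["bin_count"]),
        )


def fit_discretizer(table: LabeledTable, bin_count: int = 5) -> DiscretizationMap:
    """Fit equal-frequency bins to every numeric non-target column.

    Quantile boundaries that coincide (low-cardinality columns) are
    merged, so a column may end up with fewer than ``bin_count`` bins; a
    constant column collapses to a single bin.
    """
    if bin_count < 1:
        raise ConfigurationError(f"bin_count must be >= 1, got {bin_count}")
    m = DiscretizationMap(bin_count=bin_count)
    for col in table.other_attributes:
        if not table.is_numeric(col):
            continue
        vals = table.df[col].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            cuts = np.empty(0)
        else:
            qs = np.quantile(vals, np.linspace(0, 1, bin_count + 1))
            cuts = np.unique(qs[1:-1])
            # drop cut points equal to the global min/max: they would
            # create empty outer bins
            cuts = cuts[(cuts > vals.min()) & (cuts < vals.max())]
        m.cuts[col] = cuts
        m.labels[col] = _bin_labels(cuts)
    return m


def apply_discretizer(m: DiscretizationMap, table: LabeledTable) -> LabeledTable:
    """Replace numeric columns by their bin labels; target left untouched."""
    missing_cols = set(m.cuts) - set(table.attributes)
    if missing_cols:
        raise SchemaError(f"table lacks fitted column(s) {sorted(missing_cols)}")
    out = {}
    for col in table.attributes:
        if col in m.cuts and col != table.target and table.is_numeric(col):
            vals = table.df[col].to_numpy(float)
            idx = np.searchsorted(m.cuts[col], vals, side="left")
            labels = m.labels[col]
            col_out = [
                MISSING if math.isnan(v) else labels[i] for v, i in zip(vals, idx)
            ]
            out[col] = col_out
        else:
            out[col] = table.df[col].tolist()
    return LabeledTable(pd.DataFrame(out, columns=table.attributes),
                        table.target, table.provenance)
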