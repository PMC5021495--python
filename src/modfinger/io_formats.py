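"""Readers and writers for every external artifact.

Expression matrices are accepted as plain TSV (first column gene id,
header row of sample ids) or GCT 1.2; gene sets as GMT; sample metadata
as a two-column TSV.  All loaders validate aggressively and raise
:class:`LoadError` with the offending row/column named — downstream code
may assume a loaded object satisfies its invariants.

Numeric result tables (differential-expression tables, fingerprints) are
written as TSV with a stable column order; floats are serialized with
shortest round-trip ``repr`` so that write∘read is the identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "ExpressionMatrix",
    "SampleMetadata",
    "Module",
    "ModuleSet",
    "DGE_COLUMNS",
    "FINGERPRINT_COLUMNS",
    "ENRICHMENT_COLUMNS",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
    "read_dge",
    "write_dge",
    "read_fingerprint",
    "write_fingerprint",
    "write_fingerprint_json",
    "read_series_matrix",
]


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of normalized log2 intensities.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (genes or probes), in row order.
    sample_ids
        Unique column identifiers, in column order.
    values
        ``(len(gene_ids), len(sample_ids))`` float array; all entries
        must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise LoadError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise LoadError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise LoadError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise LoadError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise LoadError(
                f"non-finite value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order); unknown ids error."""
        idx = self.gene_index()
        try:
            rows = [idx[g] for g in genes]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        try:
            cols = [idx[s] for s in samples]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.sample_ids),
        )


@dataclass
class SampleMetadata:
    """Sample-to-group assignment with a declared finite label set."""

    sample_ids: list[str]
    groups: list[str]
    allowed_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        if len(self.sample_ids) != len(self.groups):
            raise LoadError("sample_ids and groups differ in length")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise LoadError(f"duplicate sample id {dup!r} in metadata")
        if not self.allowed_groups:
            seen: list[str] = []
            for g in self.groups:
                if g not in seen:
                    seen.append(g)
            self.allowed_groups = tuple(seen)
        bad = [g for g in self.groups if g not in self.allowed_groups]
        if bad:
            raise LoadError(
                f"group label {bad[0]!r} not in declared set {self.allowed_groups}"
            )

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.groups))

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def subset(self, samples: Sequence[str]) -> "SampleMetadata":
        mapping = self.group_of()
        return SampleMetadata(
            list(samples),
            [mapping[s] for s in samples],
            allowed_groups=self.allowed_groups,
        )


@dataclass(frozen=True)
class Module:
    """One named gene set, e.g. ``M3.1`` / ``Interferon``."""

    module_id: str
    label: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise LoadError(f"module {self.module_id!r} has an empty gene list")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleSet:
    """Ordered collection of modules; gene sets need not be disjoint."""

    modules: list[Module]

    def __post_init__(self) -> None:
        dup = _first_duplicate([m.module_id for m in self.modules])
        if dup is not None:
            raise LoadError(f"duplicate module id {dup!r}")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.gene_set
        return frozenset(out)


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

_COLLAPSE_RULES = ("max-mean", "mean", "none")


def read_expression(
    path: str | Path,
    format: str = "tsv",
    collapse: str = "max-mean",
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    Parameters
    ----------
    path
        Input file. TSV layout: header row ``gene_id<TAB>s1<TAB>s2...``,
        one gene per row. GCT layout: ``#1.2`` version line, dimension
        line, then ``Name``/``Description`` columns before the samples.
    format
        ``"tsv"`` or ``"gct"``.
    collapse
        Rule applied when several rows share a gene id (multiple probes
        per gene): ``"max-mean"`` keeps the row with the highest mean
        intensity, ``"mean"`` averages the rows, ``"none"`` treats
        duplicates as a load error.

    Raises
    ------
    LoadError
        Malformed header, non-numeric cell, duplicate sample id, NaN.
    """
    path = Path(path)
    if collapse not in _COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {collapse!r}; choose from {_COLLAPSE_RULES}")
    if not path.exists():
        raise LoadError(f"expression file not found: {path}")
    if format == "tsv":
        lines = path.read_text().splitlines()
        if not lines:
            raise LoadError(f"{path}: empty file")
        header = lines[0].rstrip("\n").split("\t")
        body = lines[1:]
    elif format == "gct":
        lines = path.read_text().splitlines()
        if len(lines) < 3:
            raise LoadError(f"{path}: truncated GCT file")
        if lines[0].strip() != "#1.2":
            raise LoadError(
                f"{path}: GCT version line is {lines[0].strip()!r}, expected '#1.2'"
            )
        dims = lines[1].split("\t")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except (IndexError, ValueError):
            raise LoadError(f"{path}: malformed GCT dimension line {lines[1]!r}") from None
        header_fields = lines[2].rstrip("\n").split("\t")
        if len(header_fields) < 3 or header_fields[0] != "Name":
            raise LoadError(f"{path}: malformed GCT header (expected Name/Description)")
        header = ["gene_id"] + header_fields[2:]
        # drop the Description column from each body row
        body = []
        for raw in lines[3:]:
            if not raw.strip():
                continue
            fields = raw.split("\t")
            body.append("\t".join([fields[0]] + fields[2:]))
        if len(body) != n_rows or len(header) - 1 != n_cols:
            raise LoadError(
                f"{path}: GCT dimension line says {n_rows}x{n_cols}, "
                f"found {len(body)}x{len(header) - 1}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")

    sample_ids = header[1:]
    if not sample_ids:
        raise LoadError(f"{path}: header row has no sample columns")
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise LoadError(f"{path}: duplicate sample id {dup!r} in header")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(body, start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise LoadError(
                f"{path}: row {lineno} has {len(fields) - 1} values, "
                f"expected {len(sample_ids)}"
            )
        vals: list[float] = []
        for s, cell in zip(sample_ids, fields[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise LoadError(
                    f"{path}: non-numeric cell {cell!r} at gene {fields[0]!r}, "
                    f"sample {s!r}"
                ) from None
            if not math.isfinite(v):
                raise LoadError(
                    f"{path}: non-finite value at gene {fields[0]!r}, sample {s!r}"
                )
            vals.append(v)
        gene_ids.append(fields[0])
        rows.append(vals)
    if not rows:
        raise LoadError(f"{path}: no data rows")
    values = np.asarray(rows, dtype=float)
    gene_ids, values = _collapse_duplicates(gene_ids, values, collapse, path)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _collapse_duplicates(
    gene_ids: list[str], values: np.ndarray, rule: str, path: Path
) -> tuple[list[str], np.ndarray]:
    if len(set(gene_ids)) == len(gene_ids):
        return gene_ids, values
    if rule == "none":
        raise LoadError(
            f"{path}: duplicate gene id {_first_duplicate(gene_ids)!r} "
            "(collapse rule 'none' forbids duplicates)"
        )
    # group row indices by id, preserving first-occurrence order
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(gene_ids):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    out = np.empty((len(order), values.shape[1]), dtype=float)
    for k, g in enumerate(order):
        idx = groups[g]
        if len(idx) == 1:
            out[k] = values[idx[0]]
        elif rule == "max-mean":
            means = values[idx].mean(axis=1)
            out[k] = values[idx[int(np.argmax(means))]]
        else:  # mean
            out[k] = values[idx].mean(axis=0)
    return order, out


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV or GCT 1.2."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
            for g, row in zip(expr.gene_ids, expr.values):
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{len(expr.gene_ids)}\t{len(expr.sample_ids)}\n")
            fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
            for g, row in zip(expr.gene_ids, expr.values):
                fh.write(
                    g + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> ModuleSet:
    """Read a GMT gene-set file: ``id<TAB>description<TAB>gene1<TAB>...``.

    File order is preserved; duplicate gene entries within a line are
    de-duplicated keeping first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"GMT file not found: {path}")
    modules: list[Module] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise LoadError(
                f"{path}: line {lineno} has {len(fields)} fields; GMT needs "
                "id, description and at least one gene"
            )
        module_id, label = fields[0], fields[1]
        genes: list[str] = []
        for g in fields[2:]:
            g = g.strip()
            if g and g not in genes:
                genes.append(g)
        if not genes:
            raise LoadError(f"{path}: module {module_id!r} (line {lineno}) has no genes")
        modules.append(Module(module_id, label, tuple(genes)))
    if not modules:
        raise LoadError(f"{path}: no modules found")
    try:
        return ModuleSet(modules)
    except LoadError as exc:
        raise LoadError(f"{path}: {exc}") from None


def write_gmt(modules: ModuleSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in modules:
            fh.write("\t".join([m.module_id, m.label, *m.gene_ids]) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def read_metadata(
    path: str | Path, allowed_groups: Sequence[str] | None = None
) -> SampleMetadata:
    """Read a two-column TSV ``sample_id<TAB>group`` with a header row."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"metadata file not found: {path}")
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise LoadError(f"{path}: empty metadata file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "sample_id" or header[1] != "group":
        raise LoadError(
            f"{path}: metadata header must be 'sample_id<TAB>group', got {lines[0]!r}"
        )
    sample_ids: list[str] = []
    groups: list[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        fields = raw.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise LoadError(f"{path}: malformed metadata row {lineno}: {raw!r}")
        sample_ids.append(fields[0])
        groups.append(fields[1])
    try:
        return SampleMetadata(
            sample_ids, groups,
            allowed_groups=tuple(allowed_groups) if allowed_groups else (),
        )
    except LoadError as exc:
        raise LoadError(f"{path}: {exc}") from None


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in zip(meta.sample_ids, meta.groups):
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

DGE_COLUMNS = ["gene_id", "log_fc", "s2", "t_mod", "df_total", "p_raw", "q_bh"]
FINGERPRINT_COLUMNS = [
    "module_id", "label", "n_total", "n_measured", "n_up", "n_down",
    "pct_up", "pct_down",
]
ENRICHMENT_COLUMNS = [
    "set_id", "set_name", "p_value", "q_bonferroni", "q_bh",
    "hit_count_query", "hit_count_genome",
]


def _write_table(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    """TSV writer with shortest round-trip float repr (bit-exact read-back)."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in df[columns].itertuples(index=False):
            cells = []
            for v in row:
                if isinstance(v, float):
                    cells.append("NA" if math.isnan(v) else repr(v))
                elif isinstance(v, (np.floating,)):
                    fv = float(v)
                    cells.append("NA" if math.isnan(fv) else repr(fv))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def write_dge(table: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-expression table; columns in ``DGE_COLUMNS`` order."""
    missing = [c for c in DGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DGE table missing columns {missing}")
    _write_table(table, DGE_COLUMNS, path)


def read_dge(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"DGE table not found: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str}, na_values=["NA"],
        float_precision="round_trip",
    )
    missing = [c for c in DGE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: DGE table missing columns {missing}")
    return df[DGE_COLUMNS]


def write_fingerprint(fp: "pd.DataFrame | object", path: str | Path) -> None:
    """Write a fingerprint table (or a Fingerprint object) as TSV."""
    table = getattr(fp, "table", fp)
    missing = [c for c in FINGERPRINT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fingerprint table missing columns {missing}")
    _write_table(table, FINGERPRINT_COLUMNS, path)


def read_fingerprint(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"fingerprint table not found: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype={"module_id": str, "label": str}, na_values=["NA"],
        keep_default_na=False, float_precision="round_trip",
    )
    missing = [c for c in FINGERPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: fingerprint table missing columns {missing}")
    for c in ("n_total", "n_measured", "n_up", "n_down"):
        df[c] = df[c].astype(int)
    for c in ("pct_up", "pct_down"):
        df[c] = df[c].astype(float)
    return df[FINGERPRINT_COLUMNS]


def write_fingerprint_json(fp, path: str | Path) -> None:
    """Structured-JSON form of a fingerprint (contrast id + per-module rows)."""
    table = getattr(fp, "table", fp)
    payload = {
        "contrast_id": getattr(fp, "contrast_id", ""),
        "alpha": getattr(fp, "alpha", None),
        "denominator": getattr(fp, "denominator", None),
        "modules": [
            {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in rec.items()}
            for rec in table[FINGERPRINT_COLUMNS].to_dict(orient="records")
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GEO series-matrix reader (for the documented GSE11909 recipe)
# ---------------------------------------------------------------------------


def read_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse an (uncompressed) GEO series-matrix text file.

    Returns the probe-by-sample :class:`ExpressionMatrix` plus a sample
    annotation frame built from the ``!Sample_*`` header lines (one row
    per sample, one column per annotation key; repeated keys such as
    ``characteristics_ch1`` are suffixed ``.1``, ``.2``...).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"series-matrix file not found: {path}")
    sample_meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    for raw in path.read_text().splitlines():
        if raw.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if raw.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(raw)
        elif raw.startswith("!Sample_"):
            fields = [f.strip('"') for f in raw.split("\t")]
            key = fields[0][len("!Sample_"):]
            base, n = key, 0
            while key in sample_meta:
                n += 1
                key = f"{base}.{n}"
            sample_meta[key] = fields[1:]
    if not table_lines:
        raise LoadError(f"{path}: no series_matrix_table_begin/end block found")
    header = [f.strip('"') for f in table_lines[0].split("\t")]
    sample_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for raw in table_lines[1:]:
        if not raw.strip():
            continue
        fields = raw.split("\t")
        gene_ids.append(fields[0].strip('"'))
        vals = []
        for cell in fields[1:]:
            cell = cell.strip('"')
            vals.append(float("nan") if cell in ("", "null", "NA") else float(cell))
        rows.append(vals)
    values = np.asarray(rows, dtype=float)
    # drop probes with any missing value rather than impute
    keep = np.all(np.isfinite(values), axis=1)
    gene_ids = [g for g, k in zip(gene_ids, keep) if k]
    values = values[keep]
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    ann = pd.DataFrame(sample_meta)
    if "geo_accession" in ann.columns:
        ann.index = ann["geo_accession"]
    return expr, ann
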