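"""Comparison harness for the public pediatric-lupus reproduction (GSE11909).

No stage here touches the network: the user supplies locally obtained
expression data (plain TSV/GCT or an uncompressed GEO series-matrix
file), a sample annotation TSV assigning each array to a contrast group,
an optional probe-to-gene map, the module GMT, and a reference TSV of
published per-module percentages.  The harness runs the standard
moderated-DGE + fingerprint pipeline on the local data and writes a
side-by-side comparison against the reference values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from modfinger import io_formats as iof
from modfinger.dge import moderated_t
from modfinger.fingerprint import Fingerprint, module_fingerprint

__all__ = ["repro_fingerprint_comparison", "load_local_expression"]

_ACCESSION_HINT = (
    "obtain the GSE11909 series matrix (or a derived TSV) locally and point "
    "the config at it; this harness never downloads"
)


def load_local_expression(
    path: str | Path,
    gene_map: str | Path | None = None,
    collapse: str = "max-mean",
) -> iof.ExpressionMatrix:
    """Load a locally obtained expression matrix for the reproduction.

    ``path`` may be a plain TSV, a GCT 1.2 file, or an uncompressed GEO
    series-matrix text file (sniffed from content).  ``gene_map`` is an
    optional two-column TSV (``probe_id<TAB>gene_id``) applied before
    probe collapse; probes without a mapping are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise iof.LoadError(f"expression file not found: {path} — {_ACCESSION_HINT}")
    head = path.open().readline()
    if head.startswith("!Series") or head.startswith("!Sample") or head.startswith("^"):
        expr, _ = iof.read_series_matrix(path)
    elif head.startswith("#1.2"):
        expr = iof.read_expression(path, format="gct", collapse="none")
    else:
        expr = iof.read_expression(path, format="tsv", collapse="none")
    if gene_map is not None:
        gene_map = Path(gene_map)
        if not gene_map.exists():
            raise iof.LoadError(f"gene map not found: {gene_map}")
        mapping: dict[str, str] = {}
        for lineno, raw in enumerate(gene_map.read_text().splitlines(), start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.split("\t")
            if len(fields) < 2:
                raise iof.LoadError(f"{gene_map}: malformed row {lineno}: {raw!r}")
            if fields[0] == "probe_id":  # optional header
                continue
            mapping[fields[0]] = fields[1]
        keep = [i for i, g in enumerate(expr.gene_ids) if g in mapping]
        if not keep:
            raise iof.LoadError(f"{gene_map}: no probe of the matrix is mapped")
        gene_ids = [mapping[expr.gene_ids[i]] for i in keep]
        values = expr.values[keep, :]
        gene_ids, values = iof._collapse_duplicates(gene_ids, values, collapse, gene_map)
        expr = iof.ExpressionMatrix(gene_ids, expr.sample_ids, values)
    return expr


def read_reference(path: str | Path) -> pd.DataFrame:
    """Reference TSV of published percentages: module_id, pct_up, pct_down."""
    path = Path(path)
    if not path.exists():
        raise iof.LoadError(f"reference table not found: {path}")
    ref = pd.read_csv(path, sep="\t", dtype={"module_id": str})
    for col in ("module_id", "pct_up", "pct_down"):
        if col not in ref.columns:
            raise iof.LoadError(f"{path}: reference table missing column {col!r}")
    return ref


def repro_fingerprint_comparison(
    expr_path: str | Path,
    meta_path: str | Path,
    gmt_path: str | Path,
    reference_path: str | Path,
    contrast: tuple[str, str],
    out_path: str | Path,
    gene_map: str | Path | None = None,
    alpha: float = 0.05,
    collapse: str = "max-mean",
    denominator: str = "measured",
    tolerance: float = 10.0,
) -> pd.DataFrame:
    """Compute a fingerprint on local data and compare to published values.

    Writes (and returns) a per-module table with computed and reference
    up/down percentages, their differences, and a ``within_tol`` flag at
    ``tolerance`` percentage points.  This is a reproduction *report*;
    agreement is not asserted.
    """
    expr = load_local_expression(expr_path, gene_map=gene_map, collapse=collapse)
    meta = iof.read_metadata(meta_path)
    missing_group = [g for g in contrast if g not in meta.allowed_groups]
    if missing_group:
        raise iof.LoadError(
            f"sample annotations lack contrast group {missing_group[0]!r} "
            f"(declared: {meta.allowed_groups}); check the treatment-status "
            "annotation of the local GSE11909 metadata"
        )
    modules = iof.read_gmt(gmt_path)
    reference = read_reference(reference_path)

    table = moderated_t(expr, meta, contrast)
    fp: Fingerprint = module_fingerprint(
        table, modules, alpha=alpha, denominator=denominator,
        contrast_id=f"{contrast[0]}_vs_{contrast[1]}",
    )
    comp = fp.table.merge(
        reference.rename(columns={"pct_up": "ref_pct_up", "pct_down": "ref_pct_down"}),
        on="module_id",
        how="inner",
    )
    if comp.empty:
        raise iof.LoadError(
            "no module id of the GMT matches the reference table; "
            "check that both use the same module naming"
        )
    comp["diff_up"] = comp["pct_up"] - comp["ref_pct_up"]
    comp["diff_down"] = comp["pct_down"] - comp["ref_pct_down"]
    comp["within_tol"] = (
        comp["diff_up"].abs().le(tolerance) & comp["diff_down"].abs().le(tolerance)
    )
    cols = [
        "module_id", "label", "n_total", "n_measured",
        "pct_up", "ref_pct_up", "diff_up",
        "pct_down", "ref_pct_down", "diff_down", "within_tol",
    ]
    comp = comp[cols]
    comp.to_csv(out_path, sep="\t", index=False, na_rep="NA")
    return comp
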