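"""Directional module fingerprints.

For one contrast, a fingerprint reports per module the percentage of
member genes that are significantly differentially expressed, split into
up- and down-regulated fractions.  Percentages use either the genes
actually measured in the matrix (default) or the full module size as
denominator; a module with no measured genes gets NaN percentages rather
than a 0/0 division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from modfinger.dge import significant_genes
from modfinger.io_formats import FINGERPRINT_COLUMNS, ModuleSet

__all__ = ["Fingerprint", "FingerprintGrid", "module_fingerprint", "fingerprint_grid", "render_grid"]


@dataclass
class Fingerprint:
    """Per-module directional significance proportions for one contrast."""

    contrast_id: str
    table: pd.DataFrame  # FINGERPRINT_COLUMNS, one row per module in file order
    alpha: float
    denominator: str  # "measured" or "total"

    def row(self, module_id: str) -> pd.Series:
        hit = self.table[self.table["module_id"] == module_id]
        if hit.empty:
            raise KeyError(module_id)
        return hit.iloc[0]


@dataclass
class FingerprintGrid:
    """Ordered contrasts x ordered modules of (pct_up, pct_down)."""

    contrast_ids: list[str]
    fingerprints: dict[str, Fingerprint] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: module rows, two columns (up/down) per contrast."""
        first = self.fingerprints[self.contrast_ids[0]].table
        out = first[["module_id", "label"]].copy()
        for cid in self.contrast_ids:
            t = self.fingerprints[cid].table
            out[f"{cid}:up"] = t["pct_up"].to_numpy()
            out[f"{cid}:down"] = t["pct_down"].to_numpy()
        return out


def module_fingerprint(
    dge: pd.DataFrame,
    modules: ModuleSet,
    alpha: float = 0.05,
    denominator: str = "measured",
    contrast_id: str = "",
) -> Fingerprint:
    """Score every module of ``modules`` against one DGE table.

    Parameters
    ----------
    dge
        DGE table with ``q_bh`` filled (one row per measured gene).
    modules
        Gene-set collection; members absent from ``dge`` count toward
        ``n_total`` only.
    alpha
        Significance threshold on ``q_bh``.
    denominator
        ``"measured"`` divides counts by the number of module genes
        present in the DGE table; ``"total"`` by the full module size.

    Returns
    -------
    Fingerprint
        One row per module, in module-file order.
    """
    if denominator not in ("measured", "total"):
        raise ValueError(f"denominator must be 'measured' or 'total', got {denominator!r}")
    if dge["q_bh"].isna().any():
        raise ValueError("DGE table has missing q_bh values")
    up, down = significant_genes(dge, alpha)
    measured = set(dge["gene_id"])
    rows = []
    for m in modules:
        members = m.gene_set
        meas = members & measured
        n_up = len(meas & up)
        n_down = len(meas & down)
        denom = len(meas) if denominator == "measured" else len(members)
        if not meas:  # unavailable regardless of denominator choice
            pct_up = pct_down = float("nan")
        else:
            pct_up = 100.0 * n_up / denom
            pct_down = 100.0 * n_down / denom
        rows.append(
            {
                "module_id": m.module_id,
                "label": m.label,
                "n_total": len(members),
                "n_measured": len(meas),
                "n_up": n_up,
                "n_down": n_down,
                "pct_up": pct_up,
                "pct_down": pct_down,
            }
        )
    table = pd.DataFrame(rows, columns=FINGERPRINT_COLUMNS)
    return Fingerprint(contrast_id=contrast_id, table=table, alpha=alpha, denominator=denominator)


def fingerprint_grid(
    dge_tables: list[tuple[str, pd.DataFrame]],
    modules: ModuleSet,
    alpha: float = 0.05,
    denominator: str = "measured",
) -> FingerprintGrid:
    """Fingerprint several contrasts against one module collection."""
    if not dge_tables:
        raise ValueError("need at least one contrast")
    ids = [cid for cid, _ in dge_tables]
    if len(set(ids)) != len(ids):
        dup = next(c for i, c in enumerate(ids) if c in ids[:i])
        raise ValueError(f"duplicate contrast_id {dup!r}")
    fps = {
        cid: module_fingerprint(dge, modules, alpha=alpha, denominator=denominator, contrast_id=cid)
        for cid, dge in dge_tables
    }
    return FingerprintGrid(contrast_ids=ids, fingerprints=fps)


def render_grid(grid: FingerprintGrid, path, image_path=None) -> pd.DataFrame:
    """Write the wide grid TSV (always) and optionally a heat-grid image.

    The image shows, per module row and contrast, the up-percentage in
    red and the down-percentage in blue; cells without measured genes
    render as ``NA`` in the TSV and grey in the image.
    """
    wide = grid.to_frame()
    if wide.empty:
        raise ValueError("cannot render an empty grid")
    with open(path, "w") as fh:
        fh.write("\t".join(wide.columns) + "\n")
        for row in wide.itertuples(index=False):
            cells = []
            for v in row:
                if isinstance(v, float) or isinstance(v, np.floating):
                    fv = float(v)
                    cells.append("NA" if math.isnan(fv) else repr(fv))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
    if image_path is not None:
        _render_grid_image(grid, wide, image_path)
    return wide


def _render_grid_image(grid: FingerprintGrid, wide: pd.DataFrame, image_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_mod = len(wide)
    n_con = len(grid.contrast_ids)
    # signed score: +pct_up dominates red, -pct_down dominates blue
    img = np.zeros((n_mod, 2 * n_con))
    for j, cid in enumerate(grid.contrast_ids):
        img[:, 2 * j] = wide[f"{cid}:up"].to_numpy()
        img[:, 2 * j + 1] = -wide[f"{cid}:down"].to_numpy()
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.9 * n_con, 1.0 + 0.25 * n_mod), constrained_layout=True
    )
    masked = np.ma.masked_invalid(img)
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad("0.8")
    ax.imshow(masked, cmap=cmap, vmin=-100, vmax=100, aspect="auto")
    ax.set_yticks(range(n_mod))
    ax.set_yticklabels(wide["module_id"])
    ax.set_xticks(np.arange(0.5, 2 * n_con, 2))
    ax.set_xticklabels(grid.contrast_ids)
    fig.savefig(image_path, metadata={"Software": None})
    plt.close(fig)
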