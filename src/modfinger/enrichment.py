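"""Over-representation analysis against user-supplied gene-set collections.

For a query list drawn from a declared gene universe, each set is tested
with the hypergeometric upper tail ``P(X >= k)`` where ``X`` counts the
overlap expected by chance; the family is controlled by Bonferroni
(matching the classic enrichment-report layout) with Benjamini–Hochberg
q-values reported alongside.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from modfinger.dge import bh_adjust
from modfinger.io_formats import ENRICHMENT_COLUMNS, ModuleSet

__all__ = ["hypergeometric_enrichment"]


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: ModuleSet,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test every set for over-representation of ``query`` genes.

    Parameters
    ----------
    query
        Gene ids of interest (e.g. significantly differentially
        expressed genes); must be a subset of ``universe``.
    sets
        Gene-set collection; each set is intersected with the universe
        before testing.
    universe
        All genes that could have entered the query (e.g. every gene
        measured on the array after probe collapse).

    Returns
    -------
    pandas.DataFrame
        Columns ``set_id, set_name, p_value, q_bonferroni, q_bh,
        hit_count_query, hit_count_genome``; rows sorted by p ascending,
        ties by set_id.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not query:
        raise ValueError("query is empty")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query gene {sorted(stray)[0]!r} is not in the universe "
            f"({len(stray)} such genes)"
        )
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for m in sets:
        members = m.gene_set & universe
        k_set = len(members)
        k_hit = len(members & query)
        # upper tail P(X >= k_hit) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k_hit - 1, n_universe, k_set, n_query))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "set_id": m.module_id,
                "set_name": m.label,
                "p_value": p,
                "hit_count_query": k_hit,
                "hit_count_genome": k_set,
            }
        )
    out = pd.DataFrame(rows)
    m_tests = len(out)
    out["q_bonferroni"] = np.minimum(1.0, m_tests * out["p_value"].to_numpy())
    out["q_bh"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(
        ["p_value", "set_id"], kind="mergesort", ignore_index=True
    )
    return out[ENRICHMENT_COLUMNS]
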