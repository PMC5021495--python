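"""Two-group differential expression with empirical-Bayes variance moderation.

Per gene, the pooled within-group variance ``s_g^2`` (on ``d_g = nA+nB-2``
degrees of freedom) is shrunk toward a prior ``s0^2`` estimated across all
genes, giving the posterior variance

    s_tilde^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)

and a moderated statistic ``t = log_fc / (s_tilde * sqrt(1/nA + 1/nB))``
referred to a t distribution on ``d0 + d_g`` degrees of freedom.  The
prior ``(d0, s0^2)`` is estimated by method of moments on the log sample
variances; ``d0 = inf`` (one shared variance) is returned when the
observed spread of ``log s^2`` does not exceed the sampling spread of a
scaled chi-square on ``d_g`` degrees of freedom.

Multiplicity is controlled by the Benjamini–Hochberg step-up procedure
(:func:`bh_adjust`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from modfinger.io_formats import DGE_COLUMNS, ExpressionMatrix, SampleMetadata

__all__ = [
    "ModerationPrior",
    "fit_moderation_prior",
    "moderated_t",
    "bh_adjust",
    "significant_genes",
]


@dataclass(frozen=True)
class ModerationPrior:
    """Variance prior: ``d0`` prior degrees of freedom, ``s0_sq`` prior variance.

    ``d0 = inf`` means every gene shares the single variance ``s0_sq``;
    ``d0 = 0`` is the documented escape hatch meaning *no moderation*
    (ordinary pooled-variance t-test).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or math.isnan(self.d0):
            raise ValueError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not (self.s0_sq > 0) and not (self.d0 == 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_moderation_prior(s2: np.ndarray, df_resid: float) -> ModerationPrior:
    """Method-of-moments estimate of the variance prior from per-gene variances.

    Works on ``z = log(s2)``: after removing the known mean/variance
    contribution of a chi-square on ``df_resid`` degrees of freedom, the
    residual spread of ``z`` identifies ``d0`` through the trigamma
    function and its location identifies ``s0_sq``.  When the residual
    spread is non-positive the prior is degenerate: ``d0 = inf`` with
    ``s0_sq`` the geometric mean of the observed variances.

    Parameters
    ----------
    s2
        Per-gene sample variances, all ``>= 0``, at least two genes.
    df_resid
        Residual degrees of freedom each variance was computed on (``>= 1``).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.ndim != 1 or s2.size < 2:
        raise ValueError("need a 1-D array of at least 2 variances")
    if np.any(s2 < 0) or not np.all(np.isfinite(s2)):
        raise ValueError("variances must be finite and non-negative")
    if df_resid < 1:
        raise ValueError(f"df_resid must be >= 1, got {df_resid}")
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all variances are zero; prior is undefined")
    if pos.size < 2:
        # one informative variance: no spread to estimate from
        return ModerationPrior(d0=math.inf, s0_sq=float(pos[0]))
    d = float(df_resid)
    z = np.log(pos)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        # observed spread within chi-square sampling spread -> shared variance
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(np.mean(z))))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(
        np.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    )
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    contrast: tuple[str, str],
    prior: ModerationPrior | None = None,
) -> pd.DataFrame:
    """Moderated two-group test for every gene; returns the DGE table.

    Parameters
    ----------
    expr
        Log2 expression matrix.
    meta
        Sample-to-group assignment; every sample of the two contrast
        groups must be a column of ``expr``.
    contrast
        ``(groupA, groupB)``; ``log_fc = mean(A) - mean(B)``.
    prior
        Variance prior. ``None`` (default) estimates it from the data
        with :func:`fit_moderation_prior`; ``ModerationPrior(0, ...)``
        gives the ordinary pooled t-test.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_id, log_fc, s2, t_mod, df_total, p_raw, q_bh``,
        one row per gene in matrix order.
    """
    group_a, group_b = contrast
    for g in (group_a, group_b):
        if g not in meta.allowed_groups:
            raise ValueError(f"unknown group label {g!r}; declared: {meta.allowed_groups}")
    in_matrix = set(expr.sample_ids)
    samples_a = [s for s in meta.samples_in(group_a) if s in in_matrix]
    samples_b = [s for s in meta.samples_in(group_b) if s in in_matrix]
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"each contrast group needs >= 2 samples in the matrix; "
            f"got {group_a}={n_a}, {group_b}={n_b}"
        )
    idx = expr.sample_index()
    xa = expr.values[:, [idx[s] for s in samples_a]]
    xb = expr.values[:, [idx[s] for s in samples_b]]

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    log_fc = mean_a - mean_b
    d_g = n_a + n_b - 2
    # pooled within-group variance
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g

    if prior is None:
        prior = fit_moderation_prior(s2, d_g)

    if prior.d0 == 0:  # ordinary t
        s2_post = s2.copy()
        df_total = float(d_g)
    elif math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g

    scale = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(
            scale > 0,
            log_fc / np.where(scale > 0, scale, 1.0),
            np.where(log_fc == 0, 0.0, np.sign(log_fc) * np.inf),
        )
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    # keep p in (0, 1] so downstream log/threshold logic never sees 0
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    q_bh = bh_adjust(p_raw)

    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log_fc": log_fc,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": float(df_total),
            "p_raw": p_raw,
            "q_bh": q_bh,
        },
        columns=DGE_COLUMNS,
    )


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} ( m * p_(j) / j )`` over the ascending order
    statistics, capped at 1, reported in the original input order.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be 1-D")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def significant_genes(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split genes with ``q_bh <= alpha`` by fold-change sign.

    Returns ``(up, down)``: disjoint sets of gene ids with positive and
    negative ``log_fc`` respectively.  A significant gene with
    ``log_fc == 0`` cannot occur (it would have ``t = 0``, ``p = 1``).
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    hit = table["q_bh"] <= alpha
    up = set(table.loc[hit & (table["log_fc"] > 0), "gene_id"])
    down = set(table.loc[hit & (table["log_fc"] < 0), "gene_id"])
    return up, down
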