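"""Minimal discriminating gene lists by nearest shrunken centroids.

Class centroids are standardized against the overall centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n),

soft-thresholded by ``delta`` and the shrunken centroids reconstructed;
genes whose standardized difference survives shrinkage in at least one
class form the signature.  The threshold is chosen by stratified
cross-validation: the smallest misclassification count wins and, among
ties, the largest ``delta`` (fewest genes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from modfinger.io_formats import ExpressionMatrix, SampleMetadata

__all__ = ["ShrunkenCentroidModel", "CVResult", "nsc_train", "nsc_predict", "nsc_cv"]


@dataclass(frozen=True)
class ShrunkenCentroidModel:
    """Fitted nearest-shrunken-centroid classifier."""

    classes: tuple[str, ...]
    gene_ids: tuple[str, ...]
    overall_centroid: np.ndarray  # (G,)
    d_ik: np.ndarray              # (K, G) raw standardized centroid differences
    s_i: np.ndarray               # (G,) pooled within-class sd
    s0: float                     # fuzzing constant, median of s_i
    m_k: np.ndarray               # (K,) sqrt(1/n_k - 1/n)
    delta: float
    class_priors: np.ndarray      # (K,), sums to 1

    @property
    def d_shrunk(self) -> np.ndarray:
        return _soft_threshold(self.d_ik, self.delta)

    @property
    def class_centroids_shrunken(self) -> np.ndarray:
        """(K, G) centroids reconstructed from the soft-thresholded differences."""
        denom = self.m_k[:, None] * (self.s_i + self.s0)[None, :]
        return self.overall_centroid[None, :] + denom * self.d_shrunk

    @property
    def surviving_genes(self) -> list[str]:
        keep = np.any(self.d_shrunk != 0.0, axis=0)
        return [g for g, k in zip(self.gene_ids, keep) if k]

    def at_delta(self, delta: float) -> "ShrunkenCentroidModel":
        """Same fit re-thresholded at a different ``delta`` (no refit needed)."""
        if delta < 0:
            raise ValueError(f"delta must be >= 0, got {delta}")
        return replace(self, delta=float(delta))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "gene_ids": list(self.gene_ids),
            "overall_centroid": self.overall_centroid.tolist(),
            "d_ik": self.d_ik.tolist(),
            "s_i": self.s_i.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "delta": self.delta,
            "class_priors": self.class_priors.tolist(),
            "class_centroids_shrunken": self.class_centroids_shrunken.tolist(),
            "surviving_genes": self.surviving_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ShrunkenCentroidModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            classes=tuple(p["classes"]),
            gene_ids=tuple(p["gene_ids"]),
            overall_centroid=np.asarray(p["overall_centroid"], dtype=float),
            d_ik=np.asarray(p["d_ik"], dtype=float),
            s_i=np.asarray(p["s_i"], dtype=float),
            s0=float(p["s0"]),
            m_k=np.asarray(p["m_k"], dtype=float),
            delta=float(p["delta"]),
            class_priors=np.asarray(p["class_priors"], dtype=float),
        )


@dataclass
class CVResult:
    """Cross-validated threshold search."""

    deltas: np.ndarray          # grid, ascending
    errors: np.ndarray          # (n_folds, n_deltas) misclassification counts
    genes_surviving: np.ndarray # per delta, on the full-data fit
    chosen_delta: float
    model: ShrunkenCentroidModel = field(repr=False)

    @property
    def total_errors(self) -> np.ndarray:
        return self.errors.sum(axis=0)


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _class_layout(
    expr: ExpressionMatrix, meta: SampleMetadata
) -> tuple[list[str], list[np.ndarray]]:
    """Classes in declared-group order with column indices per class."""
    idx = expr.sample_index()
    classes, cols = [], []
    for g in meta.allowed_groups:
        members = [idx[s] for s in meta.samples_in(g) if s in idx]
        if members:
            classes.append(g)
            cols.append(np.asarray(members, dtype=int))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes with samples, found {classes}")
    for g, c in zip(classes, cols):
        if c.size < 2:
            raise ValueError(f"class {g!r} has {c.size} sample(s); need >= 2")
    return classes, cols


def nsc_train(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    delta: float = 0.0,
    priors: str = "frequency",
) -> ShrunkenCentroidModel:
    """Fit a shrunken-centroid model at threshold ``delta``.

    ``priors`` is ``"frequency"`` (observed class frequencies, default)
    or ``"uniform"``.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    classes, cols = _class_layout(expr, meta)
    x = expr.values
    n = sum(c.size for c in cols)
    k = len(classes)
    used = np.concatenate(cols)
    overall = x[:, used].mean(axis=1)
    centroids = np.stack([x[:, c].mean(axis=1) for c in cols])  # (K, G)
    ss = np.zeros(x.shape[0])
    for c, cent in zip(cols, centroids):
        ss += ((x[:, c] - cent[:, None]) ** 2).sum(axis=1)
    s_i = np.sqrt(ss / (n - k))  # pooled within-class sd on n-K df
    s0 = float(np.median(s_i))
    m_k = np.array([math.sqrt(1.0 / c.size - 1.0 / n) for c in cols])
    d_ik = (centroids - overall[None, :]) / (m_k[:, None] * (s_i + s0)[None, :])
    if priors == "frequency":
        pr = np.array([c.size / n for c in cols])
    elif priors == "uniform":
        pr = np.full(k, 1.0 / k)
    else:
        raise ValueError(f"priors must be 'frequency' or 'uniform', got {priors!r}")
    return ShrunkenCentroidModel(
        classes=tuple(classes),
        gene_ids=tuple(expr.gene_ids),
        overall_centroid=overall,
        d_ik=d_ik,
        s_i=s_i,
        s0=s0,
        m_k=m_k,
        delta=float(delta),
        class_priors=pr,
    )


def nsc_predict(model: ShrunkenCentroidModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Classify samples by the discriminant score.

    ``score_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log prior_k``;
    the predicted label minimizes the score, ties broken by class order.

    Returns a frame with ``sample_id``, ``label`` and one ``score:<class>``
    column per class.
    """
    have = set(expr.gene_ids)
    missing = [g for g in model.gene_ids if g not in have]
    if missing:
        raise ValueError(f"expression matrix lacks model gene {missing[0]!r}")
    sub = expr.subset_genes(list(model.gene_ids))
    x = sub.values  # (G, S)
    w = (model.s_i + model.s0) ** 2
    cents = model.class_centroids_shrunken
    scores = np.empty((len(model.classes), x.shape[1]))
    for ki in range(len(model.classes)):
        diff = x - cents[ki][:, None]
        scores[ki] = (diff**2 / w[:, None]).sum(axis=0)
    scores -= 2.0 * np.log(model.class_priors)[:, None]
    labels = [model.classes[int(np.argmin(scores[:, j]))] for j in range(x.shape[1])]
    out = pd.DataFrame({"sample_id": sub.sample_ids, "label": labels})
    for ki, cls in enumerate(model.classes):
        out[f"score:{cls}"] = scores[ki]
    return out


def _stratified_folds(
    meta: SampleMetadata, n_folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Deterministic stratified folds: shuffle within class, deal round-robin."""
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for g in meta.allowed_groups:
        members = meta.samples_in(g)
        if not members:
            continue
        if len(members) < n_folds:
            raise ValueError(
                f"n_folds={n_folds} exceeds size of class {g!r} ({len(members)})"
            )
        perm = rng.permutation(len(members))
        for pos, mi in enumerate(perm):
            folds[pos % n_folds].append(members[int(mi)])
    return folds


def nsc_cv(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    n_folds: int = 10,
    delta_grid: np.ndarray | None = None,
    seed: int = 0,
    priors: str = "frequency",
    n_deltas: int = 30,
) -> CVResult:
    """Stratified cross-validation over a shrinkage-threshold grid.

    The default grid is ``n_deltas`` evenly spaced values from 0 to the
    full-data ``max|d_ik|``.  ``chosen_delta`` attains the minimal total
    CV error; among ties the largest delta (fewest surviving genes)
    wins.  The returned model is the full-data fit at ``chosen_delta``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    meta = meta.subset([s for s in meta.sample_ids if s in set(expr.sample_ids)])
    full = nsc_train(expr, meta, delta=0.0, priors=priors)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.max(np.abs(full.d_ik))), n_deltas)
    delta_grid = np.sort(np.asarray(delta_grid, dtype=float))
    if delta_grid.size == 0 or delta_grid[0] < 0:
        raise ValueError("delta_grid must be non-empty and non-negative")

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(meta, n_folds, rng)
    truth = meta.group_of()
    errors = np.zeros((n_folds, delta_grid.size), dtype=int)
    for fi, test_samples in enumerate(folds):
        test_set = set(test_samples)
        train_samples = [s for s in meta.sample_ids if s not in test_set]
        fold_fit = nsc_train(
            expr.subset_samples(train_samples), meta.subset(train_samples),
            delta=0.0, priors=priors,
        )
        test_expr = expr.subset_samples(test_samples)
        for di, delta in enumerate(delta_grid):
            pred = nsc_predict(fold_fit.at_delta(float(delta)), test_expr)
            errors[fi, di] = sum(
                1 for s, lab in zip(pred["sample_id"], pred["label"]) if truth[s] != lab
            )

    genes_surviving = np.array(
        [len(full.at_delta(float(d)).surviving_genes) for d in delta_grid]
    )
    total = errors.sum(axis=0)
    chosen_delta = float(delta_grid[np.where(total == total.min())[0].max()])
    return CVResult(
        deltas=delta_grid,
        errors=errors,
        genes_surviving=genes_surviving,
        chosen_delta=chosen_delta,
        model=full.at_delta(chosen_delta),
    )
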