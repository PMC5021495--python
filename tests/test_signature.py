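import math

import numpy as np
import pytest

from conftest import random_expression
from modfinger.io_formats import ExpressionMatrix, SampleMetadata
from modfinger.signature import ShrunkenCentroidModel, nsc_cv, nsc_predict, nsc_train
from modfinger.synthetic_data import ModuleSpec, SimulationConfig, simulate_cohorts


def _planted(seed=7, n_genes=400, shift=1.5, n_sig=20, n_per=15):
    conf = SimulationConfig(
        n_genes=n_genes,
        modules=(ModuleSpec("SIG", n_sig, shift, "up", 1.0, group_weights={"case": 1.0}),),
        groups=(("case", n_per), ("ctrl", n_per)),
        gene_sd_prior=(math.inf, 0.09),
        seed=seed,
    )
    return simulate_cohorts(conf)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_delta_zero_reconstruction_identity():
    rng = np.random.default_rng(0)
    expr, meta = random_expression(rng, 25, {"a": 4, "b": 6})
    model = nsc_train(expr, meta, delta=0.0)
    raw = np.stack(
        [
            expr.values[:, :4].mean(axis=1),
            expr.values[:, 4:].mean(axis=1),
        ]
    )
    np.testing.assert_allclose(model.class_centroids_shrunken, raw, atol=1e-12)


def test_d_ik_matches_hand_computation_on_fixture():
    # 2 classes, 4 genes, 3 vs 3 — recompute every quantity from scratch
    values = np.array(
        [
            [2.0, 2.2, 2.4, 1.0, 1.1, 1.2],
            [0.0, 0.1, -0.1, 0.0, 0.2, -0.2],
            [5.0, 5.5, 4.5, 6.0, 6.5, 5.5],
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.1],
        ]
    )
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    expr = ExpressionMatrix(["g1", "g2", "g3", "g4"], samples, values)
    meta = SampleMetadata(samples, ["a"] * 3 + ["b"] * 3)
    model = nsc_train(expr, meta, delta=0.0)

    xa, xb = values[:, :3], values[:, 3:]
    overall = values.mean(axis=1)
    cents = np.stack([xa.mean(axis=1), xb.mean(axis=1)])
    ss = ((xa - cents[0][:, None]) ** 2).sum(axis=1) + ((xb - cents[1][:, None]) ** 2).sum(axis=1)
    s_i = np.sqrt(ss / (6 - 2))
    s0 = np.median(s_i)
    m_k = np.array([math.sqrt(1 / 3 - 1 / 6)] * 2)
    d_ref = (cents - overall[None, :]) / (m_k[:, None] * (s_i + s0)[None, :])
    np.testing.assert_allclose(model.d_ik, d_ref, atol=1e-10)
    assert model.s0 == pytest.approx(s0, abs=1e-12)


def test_full_shrinkage_classifies_to_max_prior():
    rng = np.random.default_rng(1)
    expr, meta = random_expression(rng, 30, {"a": 3, "b": 7})
    model = nsc_train(expr, meta, delta=float(np.abs(nsc_train(expr, meta).d_ik).max()) + 1.0)
    assert model.surviving_genes == []
    pred = nsc_predict(model, expr)
    assert (pred["label"] == "b").all()  # larger class wins via frequency prior


def test_full_shrinkage_equal_priors_tie_breaks_to_first_class():
    rng = np.random.default_rng(2)
    expr, meta = random_expression(rng, 30, {"a": 5, "b": 5})
    big = float(np.abs(nsc_train(expr, meta).d_ik).max()) + 1.0
    model = nsc_train(expr, meta, delta=big, priors="uniform")
    pred = nsc_predict(model, expr)
    assert (pred["label"] == "a").all()


def test_training_errors():
    rng = np.random.default_rng(3)
    expr, meta = random_expression(rng, 10, {"a": 4, "b": 4})
    one_class = SampleMetadata(expr.sample_ids, ["a"] * 8)
    with pytest.raises(ValueError, match=">= 2 classes"):
        nsc_train(expr, one_class)
    tiny = SampleMetadata(expr.sample_ids, ["a"] * 7 + ["b"])
    with pytest.raises(ValueError, match="need >= 2"):
        nsc_train(expr, tiny)
    with pytest.raises(ValueError, match="delta"):
        nsc_train(expr, meta, delta=-0.1)


def test_survivor_count_monotone_in_delta():
    rng = np.random.default_rng(4)
    expr, meta = random_expression(rng, 80, {"a": 6, "b": 6}, shift_genes=10, shift=1.0)
    model = nsc_train(expr, meta)
    grid = np.linspace(0, np.abs(model.d_ik).max() * 1.05, 25)
    counts = [len(model.at_delta(float(d)).surviving_genes) for d in grid]
    assert counts == sorted(counts, reverse=True)
    assert counts[0] == 80 and counts[-1] == 0


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def test_separable_training_data_zero_errors_at_delta0():
    expr, meta, _, _ = _planted(seed=5)
    model = nsc_train(expr, meta, delta=0.0)
    pred = nsc_predict(model, expr)
    truth = meta.group_of()
    assert all(truth[s] == l for s, l in zip(pred["sample_id"], pred["label"]))


def test_heldout_batch_error_low():
    expr, meta, _, _ = _planted(seed=6)
    model = nsc_train(expr, meta, delta=0.0)
    # held-out batch from the same generative process, different seed
    expr2, meta2, _, _ = _planted(seed=61)
    pred = nsc_predict(model, expr2)
    truth = meta2.group_of()
    err = np.mean([truth[s] != l for s, l in zip(pred["sample_id"], pred["label"])])
    assert err <= 0.10


def test_predict_missing_gene_errors():
    rng = np.random.default_rng(7)
    expr, meta = random_expression(rng, 10, {"a": 3, "b": 3})
    model = nsc_train(expr, meta)
    sub = expr.subset_genes(expr.gene_ids[:5])
    with pytest.raises(ValueError, match="lacks model gene"):
        nsc_predict(model, sub)


def _naive_nearest_centroid(expr, meta, test_expr):
    """Independent diagonal-covariance nearest-centroid oracle (delta = 0)."""
    labels = []
    classes = list(meta.allowed_groups)
    cols = {g: [i for i, s in enumerate(expr.sample_ids) if meta.group_of()[s] == g]
            for g in classes}
    cents = {g: expr.values[:, c].mean(axis=1) for g, c in cols.items()}
    n = len(expr.sample_ids)
    resid = np.zeros(len(expr.gene_ids))
    for g, c in cols.items():
        resid += ((expr.values[:, c] - cents[g][:, None]) ** 2).sum(axis=1)
    s_i = np.sqrt(resid / (n - len(classes)))
    s0 = np.median(s_i)
    w = (s_i + s0) ** 2
    priors = {g: len(c) / n for g, c in cols.items()}
    for j in range(len(test_expr.sample_ids)):
        x = test_expr.values[:, j]
        best, best_score = None, None
        for g in classes:
            score = float((((x - cents[g]) ** 2) / w).sum() - 2 * math.log(priors[g]))
            if best_score is None or score < best_score - 1e-12:
                best, best_score = g, score
        labels.append(best)
    return labels


@pytest.mark.parametrize("seed", range(5))
def test_delta0_matches_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = int(rng.integers(3, 7)), int(rng.integers(3, 7))
    expr, meta = random_expression(rng, 40, {"a": n_a, "b": n_b}, shift_genes=5, shift=0.8)
    test_expr, _ = random_expression(rng, 40, {"a": 4, "b": 4}, shift_genes=5, shift=0.8)
    model = nsc_train(expr, meta, delta=0.0)
    pred = nsc_predict(model, test_expr)
    oracle = _naive_nearest_centroid(expr, meta, test_expr)
    assert list(pred["label"]) == oracle


def test_class_permutation_equivariance():
    rng = np.random.default_rng(8)
    expr, meta = random_expression(rng, 50, {"a": 5, "b": 5}, shift_genes=8, shift=1.0)
    swapped = SampleMetadata(
        meta.sample_ids, meta.groups, allowed_groups=("b", "a")
    )
    m1 = nsc_train(expr, meta, delta=0.5)
    m2 = nsc_train(expr, swapped, delta=0.5)
    assert m1.classes == ("a", "b") and m2.classes == ("b", "a")
    np.testing.assert_allclose(m1.d_ik, m2.d_ik[::-1], atol=1e-12)
    p1 = nsc_predict(m1, expr)["label"]
    p2 = nsc_predict(m2, expr)["label"]
    assert list(p1) == list(p2)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_cv_deterministic_under_seed():
    expr, meta, _, _ = _planted(seed=9, n_genes=200)
    cv1 = nsc_cv(expr, meta, n_folds=5, seed=17)
    cv2 = nsc_cv(expr, meta, n_folds=5, seed=17)
    np.testing.assert_array_equal(cv1.errors, cv2.errors)
    assert cv1.chosen_delta == cv2.chosen_delta
    assert cv1.model.surviving_genes == cv2.model.surviving_genes


def test_cv_null_data_keeps_few_genes():
    rng = np.random.default_rng(10)
    expr, meta = random_expression(rng, 300, {"a": 12, "b": 12})
    cv = nsc_cv(expr, meta, n_folds=4, seed=3)
    assert len(cv.model.surviving_genes) <= 0.05 * 300


def test_cv_chooses_largest_delta_among_ties():
    expr, meta, _, _ = _planted(seed=11, n_genes=200)
    cv = nsc_cv(expr, meta, n_folds=5, seed=1)
    total = cv.total_errors
    ties = np.where(total == total.min())[0]
    assert cv.chosen_delta == cv.deltas[ties.max()]


def test_cv_survivors_mostly_planted_on_strong_signal():
    # strong per-gene signal: CV error hits zero far into the shrinkage path,
    # so the minimal list is a (pure) subset of the planted signature
    expr, meta, _, truth = _planted(seed=12)
    cv = nsc_cv(expr, meta, n_folds=10, seed=5)
    surv = set(cv.model.surviving_genes)
    planted = set(truth[truth.carries_effect].gene_id)
    assert surv, "some genes must survive at the chosen delta"
    assert len(surv & planted) / len(surv) >= 0.9  # precision
    assert cv.total_errors.min() == 0


def test_cv_fold_infeasible_errors():
    rng = np.random.default_rng(13)
    expr, meta = random_expression(rng, 20, {"a": 3, "b": 8})
    with pytest.raises(ValueError, match="n_folds"):
        nsc_cv(expr, meta, n_folds=4, seed=0)
    with pytest.raises(ValueError, match="n_folds"):
        nsc_cv(expr, meta, n_folds=1, seed=0)


def test_model_json_round_trip(tmp_path):
    expr, meta, _, _ = _planted(seed=14, n_genes=100)
    model = nsc_train(expr, meta, delta=1.0)
    p = tmp_path / "model.json"
    model.to_json(p)
    back = ShrunkenCentroidModel.from_json(p)
    assert back.classes == model.classes
    assert back.surviving_genes == model.surviving_genes
    np.testing.assert_allclose(back.d_ik, model.d_ik, atol=0)
    np.testing.assert_allclose(
        back.class_centroids_shrunken, model.class_centroids_shrunken, atol=0
    )
    assert np.isclose(back.class_priors.sum(), 1.0)
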