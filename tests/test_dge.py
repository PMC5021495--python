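import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import random_expression
from modfinger.dge import (
    ModerationPrior,
    bh_adjust,
    fit_moderation_prior,
    moderated_t,
    significant_genes,
)
from modfinger.io_formats import ExpressionMatrix, SampleMetadata

ORDINARY = ModerationPrior(d0=0.0, s0_sq=1.0)


# ---------------------------------------------------------------------------
# fit_moderation_prior
# ---------------------------------------------------------------------------


def test_identical_variances_give_degenerate_prior():
    prior = fit_moderation_prior(np.full(100, 0.37), df_resid=10)
    assert math.isinf(prior.d0)
    assert prior.s0_sq == pytest.approx(0.37, rel=1e-12)


def test_prior_recovery_from_scaled_inv_chisq():
    # variances drawn exactly from the prior (no chi-square sampling layer),
    # so the matching residual df is large
    rng = np.random.default_rng(1)
    s2 = 0.05 * 4.0 / rng.chisquare(4.0, size=5000)
    prior = fit_moderation_prior(s2, df_resid=200)
    assert prior.d0 == pytest.approx(4.0, rel=0.25)
    assert prior.s0_sq == pytest.approx(0.05, rel=0.10)


def test_two_wild_variances_give_finite_positive_d0():
    prior = fit_moderation_prior(np.array([1e-4, 10.0]), df_resid=5)
    assert 0 < prior.d0 < math.inf


def test_all_zero_variances_rejected():
    with pytest.raises(ValueError, match="zero"):
        fit_moderation_prior(np.zeros(10), df_resid=4)


def test_prior_validation():
    with pytest.raises(ValueError):
        ModerationPrior(d0=-1.0, s0_sq=0.1)
    with pytest.raises(ValueError):
        ModerationPrior(d0=4.0, s0_sq=0.0)
    ModerationPrior(d0=math.inf, s0_sq=0.1)  # allowed


# ---------------------------------------------------------------------------
# moderated_t
# ---------------------------------------------------------------------------


def test_identical_group_means_give_t0_p1():
    values = np.array([[1.0, 2.0, 1.0, 2.0], [3.0, 3.0, 3.0, 3.0]])
    expr = ExpressionMatrix(["g1", "g2"], ["a1", "a2", "b1", "b2"], values)
    meta = SampleMetadata(["a1", "a2", "b1", "b2"], ["a", "a", "b", "b"])
    table = moderated_t(expr, meta, ("a", "b"))
    assert table.loc[0, "t_mod"] == 0.0
    assert table.loc[0, "p_raw"] == 1.0
    # g2: zero variance everywhere and zero log_fc -> t = 0, p = 1, not NaN
    assert table.loc[1, "t_mod"] == 0.0
    assert table.loc[1, "p_raw"] == 1.0


def test_ordinary_t_matches_pooled_t_on_3v3_fixture():
    # hand fixture: 2 genes, 3 vs 3
    values = np.array(
        [
            [5.1, 5.3, 5.2, 4.0, 4.2, 4.1],
            [1.0, 1.5, 0.5, 1.1, 1.2, 1.6],
        ]
    )
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    expr = ExpressionMatrix(["g1", "g2"], samples, values)
    meta = SampleMetadata(samples, ["a"] * 3 + ["b"] * 3)
    table = moderated_t(expr, meta, ("a", "b"), prior=ORDINARY)
    for i in range(2):
        t_ref, p_ref = stats.ttest_ind(values[i, :3], values[i, 3:], equal_var=True)
        assert table.loc[i, "t_mod"] == pytest.approx(t_ref, abs=1e-10)
        assert table.loc[i, "p_raw"] == pytest.approx(p_ref, abs=1e-10)
    assert table.loc[0, "log_fc"] == pytest.approx(5.2 - 4.1, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ordinary_t_equivalence_oracle_random(seed):
    rng = np.random.default_rng(seed)
    expr, meta = random_expression(rng, 30, {"a": 4, "b": 5})
    table = moderated_t(expr, meta, ("a", "b"), prior=ORDINARY)
    ref_t, ref_p = stats.ttest_ind(
        expr.values[:, :4], expr.values[:, 4:], axis=1, equal_var=True
    )
    np.testing.assert_allclose(table["t_mod"], ref_t, atol=1e-10)
    np.testing.assert_allclose(table["p_raw"], ref_p, atol=1e-10)


def test_infinite_prior_orders_by_log_fc():
    rng = np.random.default_rng(3)
    expr, meta = random_expression(rng, 50, {"a": 5, "b": 5})
    prior = ModerationPrior(d0=math.inf, s0_sq=0.09)
    table = moderated_t(expr, meta, ("a", "b"), prior=prior)
    by_t = table.reindex(table["t_mod"].abs().sort_values().index)["gene_id"]
    by_fc = table.reindex(table["log_fc"].abs().sort_values().index)["gene_id"]
    assert list(by_t) == list(by_fc)
    assert math.isinf(table["df_total"].iloc[0])


def test_contrast_swap_negates_effect_keeps_p():
    rng = np.random.default_rng(4)
    expr, meta = random_expression(rng, 40, {"a": 3, "b": 4}, shift_genes=10, shift=1.0)
    fwd = moderated_t(expr, meta, ("a", "b"))
    rev = moderated_t(expr, meta, ("b", "a"))
    np.testing.assert_allclose(fwd["log_fc"], -rev["log_fc"], atol=1e-12)
    np.testing.assert_allclose(fwd["t_mod"], -rev["t_mod"], atol=1e-12)
    np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)


def test_group_errors():
    rng = np.random.default_rng(5)
    expr, meta = random_expression(rng, 5, {"a": 2, "b": 2})
    with pytest.raises(ValueError, match="unknown group"):
        moderated_t(expr, meta, ("a", "zzz"))
    small_meta = SampleMetadata(expr.sample_ids, ["a", "a", "a", "b"])
    with pytest.raises(ValueError, match=">= 2 samples"):
        moderated_t(expr, small_meta, ("a", "b"))


def test_t_ordering_matches_p_ordering():
    rng = np.random.default_rng(6)
    expr, meta = random_expression(rng, 60, {"a": 5, "b": 5}, shift_genes=15, shift=0.6)
    table = moderated_t(expr, meta, ("a", "b"))
    order_p = np.argsort(table["p_raw"].to_numpy(), kind="mergesort")
    order_t = np.argsort(-table["t_mod"].abs().to_numpy(), kind="mergesort")
    assert (table["p_raw"].to_numpy()[order_p] == table["p_raw"].to_numpy()[order_t]).all()


def test_null_type_one_calibration():
    rng = np.random.default_rng(42)
    sd = np.sqrt(0.05 * 4 / rng.chisquare(4, size=5000))
    x = 8 + rng.standard_normal((5000, 20)) * sd[:, None]
    samples = [f"s{j}" for j in range(20)]
    expr = ExpressionMatrix([f"g{i}" for i in range(5000)], samples, x)
    meta = SampleMetadata(samples, ["a"] * 10 + ["b"] * 10)
    table = moderated_t(expr, meta, ("a", "b"))
    frac = (table["p_raw"] < 0.05).mean()
    assert 0.035 <= frac <= 0.065


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------


def test_bh_single_p():
    np.testing.assert_array_equal(bh_adjust(np.array([0.03])), [0.03])


def test_bh_step_up_hand_case():
    # hand computation: q_(j) = min_{k>=j} 4*p_(k)/k = 0.04 for every j
    q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-15)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.2]))
    with pytest.raises(ValueError):
        bh_adjust(np.array([-0.1]))


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(1, 200))
def test_bh_matches_statsmodels_and_inflates(seed, n):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, size=n)
    q = bh_adjust(p)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, q_ref, atol=1e-12)
    assert (q >= p - 1e-15).all()
    assert (q <= 1.0).all()


def test_bh_permutation_equivariance():
    rng = np.random.default_rng(7)
    p = rng.uniform(0, 1, size=100)
    perm = rng.permutation(100)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-15)


# ---------------------------------------------------------------------------
# significant_genes
# ---------------------------------------------------------------------------


def _fixture_table():
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "log_fc": [1, -1, 2, -2, 0.5, -0.5, 3, -3, 1, -1],
            "s2": [0.1] * 10,
            "t_mod": [2, -2, 4, -4, 1, -1, 6, -6, 2, -2],
            "df_total": [8.0] * 10,
            "p_raw": [0.01, 0.02, 0.001, 0.002, 0.2, 0.3, 1e-4, 1e-4, 0.04, 0.06],
            "q_bh": [0.03, 0.04, 0.005, 0.008, 0.3, 0.4, 5e-4, 5e-4, 0.05, 0.08],
        }
    )


def test_significant_genes_hand_partition():
    up, down = significant_genes(_fixture_table(), alpha=0.05)
    assert up == {"g0", "g2", "g6", "g8"}
    assert down == {"g1", "g3", "g7"}
    assert up.isdisjoint(down)


def test_significant_genes_none_and_alpha_one():
    table = _fixture_table()
    up, down = significant_genes(table, alpha=1e-5)
    assert up == set() and down == set()
    up, down = significant_genes(table, alpha=1.0)
    assert up | down == set(table.loc[table["log_fc"] != 0, "gene_id"])


def test_significant_genes_alpha_validation():
    with pytest.raises(ValueError):
        significant_genes(_fixture_table(), alpha=0.0)
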