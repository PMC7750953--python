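"""Message-passing engine: normalization, similarity kernel, update step."""
from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

import pumanet as pn
from pumanet.core import PumaState, _replace_diagonal, message_passing_step


# --- independent loop oracles -------------------------------------------------

def oracle_normalize(M: np.ndarray) -> np.ndarray:
    """Per-cell definition of the z-score normalization, two explicit loops."""
    M = np.asarray(M, float)
    out = np.empty_like(M)
    mu, sd = M.mean(), M.std(ddof=1)
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            row, col = M[i, :], M[:, j]
            zr = (M[i, j] - row.mean()) / row.std(ddof=1) if row.std(ddof=1) > 0 else np.nan
            zc = (M[i, j] - col.mean()) / col.std(ddof=1) if col.std(ddof=1) > 0 else np.nan
            v = (zr + zc) / math.sqrt(2)
            out[i, j] = v if np.isfinite(v) else (M[i, j] - mu) / sd
    return out


def oracle_tanimoto(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    out = np.empty((X.shape[0], Y.shape[0]))
    for i, x in enumerate(X):
        for j, y in enumerate(Y):
            dot = float(np.dot(x, y))
            denom = x @ x + y @ y - abs(dot)
            out[i, j] = 0.0 if denom <= 0 else dot / math.sqrt(denom)
    return out


def oracle_pearson(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x**2).sum() - sx**2) * math.sqrt(n * (y**2).sum() - sy**2)
    return num / den


# --- normalize_network --------------------------------------------------------

def test_normalize_two_by_two_hand_computed():
    out = pn.normalize_network(np.array([[0.0, 1.0], [1.0, 0.0]]))
    np.testing.assert_allclose(out, [[-1.0, 1.0], [1.0, -1.0]], atol=1e-12)


def test_normalize_matches_loop_oracle(rng):
    M = rng.normal(size=(5, 7))
    np.testing.assert_allclose(pn.normalize_network(M), oracle_normalize(M), atol=1e-12)


def test_normalize_output_mean_is_zero(rng):
    out = pn.normalize_network(rng.normal(size=(6, 9)))
    assert abs(out.mean()) < 1e-10


def test_normalize_constant_matrix_raises():
    with pytest.raises(ValueError, match="constant"):
        pn.normalize_network(np.full((3, 3), 2.0))


def test_normalize_degenerate_row_falls_back_to_global_zscore(rng):
    M = rng.normal(size=(4, 5))
    M[2, :] = 3.0  # constant row: row z-score undefined
    out = pn.normalize_network(M)
    assert np.all(np.isfinite(out))
    np.testing.assert_allclose(out, oracle_normalize(M), atol=1e-12)


# --- tanimoto -----------------------------------------------------------------

def test_tanimoto_identical_unit_vectors_is_one():
    e = np.array([[1.0, 0.0, 0.0]])
    assert pn.tanimoto(e, e)[0, 0] == pytest.approx(1.0, abs=1e-15)


def test_tanimoto_orthogonal_vectors_is_zero():
    x = np.array([[1.0, 0.0]])
    y = np.array([[0.0, 1.0]])
    assert pn.tanimoto(x, y)[0, 0] == 0.0


def test_tanimoto_both_zero_defined_as_zero():
    z = np.zeros((1, 4))
    assert pn.tanimoto(z, z)[0, 0] == 0.0


def test_tanimoto_matches_loop_oracle(rng):
    X, Y = rng.normal(size=(4, 6)), rng.normal(size=(3, 6))
    np.testing.assert_allclose(pn.tanimoto(X, Y), oracle_tanimoto(X, Y), atol=1e-12)


def test_tanimoto_dimension_mismatch_raises(rng):
    with pytest.raises(ValueError, match="inner dimensions"):
        pn.tanimoto(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))


# --- compute_coexpression -----------------------------------------------------

def test_coexpression_duplicated_and_negated_genes(rng):
    base = rng.normal(size=10)
    expr = pn.ExpressionMatrix(
        ["a", "b", "c"], [f"s{k}" for k in range(10)],
        np.vstack([base, base, -base]),
    )
    C = pn.compute_coexpression(expr).values
    assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert C[0, 2] == pytest.approx(-1.0, abs=1e-12)


def test_coexpression_matches_sum_formula_oracle(rng):
    V = rng.normal(size=(5, 10))
    expr = pn.ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"s{k}" for k in range(10)], V
    )
    C = pn.compute_coexpression(expr).values
    for i in range(5):
        for j in range(5):
            expected = 1.0 if i == j else oracle_pearson(V[i], V[j])
            assert C[i, j] == pytest.approx(expected, abs=1e-12)


def test_coexpression_constant_gene_gets_zero(rng):
    V = rng.normal(size=(3, 6))
    V[1] = 5.0
    expr = pn.ExpressionMatrix(["a", "b", "c"], [f"s{k}" for k in range(6)], V)
    C = pn.compute_coexpression(expr).values
    assert C[1, 1] == 1.0
    assert np.all(C[1, [0, 2]] == 0.0) and np.all(C[[0, 2], 1] == 0.0)


def test_coexpression_too_few_samples_raises():
    expr = pn.ExpressionMatrix(["a", "b"], ["s0", "s1"], np.ones((2, 2)))
    with pytest.raises(ValueError, match="samples"):
        pn.compute_coexpression(expr)


# --- align_inputs -------------------------------------------------------------

def test_align_intersects_genes_in_prior_order(rng):
    prior = pn.RegulatoryNetwork(["r1"], ["g1", "g2", "g3"], np.ones((1, 3)))
    expr = pn.ExpressionMatrix(
        ["g2", "g3", "g4"], [f"s{k}" for k in range(4)], rng.normal(size=(3, 4))
    )
    pa, ea, ca = pn.align_inputs(prior, expr)
    assert pa.genes == ea.genes == ["g2", "g3"]
    np.testing.assert_array_equal(ca.values, np.eye(1))


def test_align_missing_coop_defaults_to_identity(small_prior, small_expression):
    _, _, coop = pn.align_inputs(small_prior, small_expression, None)
    np.testing.assert_array_equal(coop.values, np.eye(4))


def test_align_disjoint_gene_sets_raise(small_prior, rng):
    expr = pn.ExpressionMatrix(
        ["x1", "x2", "x3"], ["s0", "s1", "s2"], rng.normal(size=(3, 3))
    )
    with pytest.raises(ValueError, match="disjoint"):
        pn.align_inputs(small_prior, expr)


# --- message_passing_step -----------------------------------------------------

def _make_state(rng, m=4, n=6, alpha=0.1, mask=None):
    W = pn.normalize_network(rng.normal(size=(m, n)))
    P = pn.normalize_network(np.eye(m) + 0.01 * rng.normal(size=(m, m)))
    C = pn.normalize_network(rng.normal(size=(n, n)))
    mask = np.zeros(m, bool) if mask is None else mask
    return PumaState(W=W, P=P, C=C, P0=P.copy(), mirna_mask=mask, alpha=alpha)


def test_step_all_mirna_pins_cooperativity_exactly(rng):
    state = _make_state(rng, mask=np.ones(4, bool))
    for _ in range(5):
        message_passing_step(state)
        np.testing.assert_array_equal(state.P, state.P0)


def test_step_alpha_zero_leaves_network_unchanged(rng):
    state = _make_state(rng)
    state.alpha = 0.0
    W_before = state.W.copy()
    h = message_passing_step(state)
    np.testing.assert_array_equal(state.W, W_before)
    assert np.isfinite(h) and h > 0


def test_step_matches_straight_line_oracle(rng):
    """One iteration replicated with loop tanimoto and explicit arithmetic."""
    state = _make_state(rng)
    W, P, C, a = state.W.copy(), state.P.copy(), state.C.copy(), state.alpha

    R = oracle_tanimoto(P, W.T)
    A = oracle_tanimoto(W, C)
    W_hat = (R + A) / 2.0
    h_expected = np.abs(W - W_hat).mean()
    W_next = (1 - a) * W + a * W_hat

    h = message_passing_step(state)
    assert h == pytest.approx(h_expected, abs=1e-10)
    np.testing.assert_allclose(state.W, W_next, atol=1e-10)

    # P update: self-similarity of the UPDATED W with annealed diagonal
    P_hat = oracle_tanimoto(W_next, W_next)
    for i in range(4):
        off = np.delete(P_hat[i], i)
        P_hat[i, i] = off.std(ddof=1) * 4 * math.exp(0.0)  # step 0
    np.testing.assert_allclose(state.P, (1 - a) * P + a * P_hat, atol=1e-10)


def test_step_empty_mask_reset_is_noop(rng):
    """With no miRNA flags the cooperativity reset must change nothing."""
    s1 = _make_state(rng)
    s2 = _make_state(np.random.default_rng(12345))
    message_passing_step(s1)
    # force the reset assignment on the empty mask: provably a no-op
    P_before = s2.P.copy()
    s2.P[s2.mirna_mask, :] = s2.P0[s2.mirna_mask, :]
    s2.P[:, s2.mirna_mask] = s2.P0[:, s2.mirna_mask]
    np.testing.assert_array_equal(s2.P, P_before)


def test_replace_diagonal_keeps_offdiagonal(rng):
    S = rng.normal(size=(5, 5))
    out = _replace_diagonal(S, 0.1, 3)
    off = ~np.eye(5, dtype=bool)
    np.testing.assert_array_equal(out[off], S[off])


# --- run_puma -----------------------------------------------------------------

def test_run_puma_zero_iterations_returns_normalized_prior(small_prior, small_expression):
    out = pn.run_puma(small_prior, small_expression, params=pn.PumaParams(max_iter=0))
    np.testing.assert_array_equal(out.weights, pn.normalize_network(small_prior.weights))
    assert out.meta["iterations"] == 0


def test_run_puma_empty_mirna_set_equals_panda_mode(small_prior, small_expression):
    params = pn.PumaParams(max_iter=30, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        puma_empty = pn.run_puma(
            small_prior, small_expression, mirna_ids=[], params=params
        )
        prior_unflagged = pn.RegulatoryNetwork(
            list(small_prior.regulators), list(small_prior.genes),
            small_prior.weights.copy(),
        )
        panda = pn.run_puma(prior_unflagged, small_expression, params=params)
    assert puma_empty.weights.tobytes() == panda.weights.tobytes()


def test_run_puma_is_deterministic(small_prior, small_expression):
    params = pn.PumaParams(max_iter=25, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = pn.run_puma(small_prior, small_expression, params=params)
        b = pn.run_puma(small_prior, small_expression, params=params)
    assert a.weights.tobytes() == b.weights.tobytes()
    assert a.meta == b.meta


def test_run_puma_gene_permutation_equivariance(small_prior, small_expression, rng):
    """Relabeling genes by a permutation permutes output columns identically."""
    perm = rng.permutation(len(small_prior.genes))
    prior_p = pn.RegulatoryNetwork(
        list(small_prior.regulators),
        [small_prior.genes[j] for j in perm],
        small_prior.weights[:, perm],
        small_prior.mirna_mask.copy(),
    )
    expr_p = pn.ExpressionMatrix(
        [small_expression.genes[j] for j in perm],
        list(small_expression.samples),
        small_expression.values[perm],
    )
    params = pn.PumaParams(max_iter=15, tol=1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = pn.run_puma(small_prior, small_expression, params=params)
        permuted = pn.run_puma(prior_p, expr_p, params=params)
    np.testing.assert_allclose(permuted.weights, base.weights[:, perm], atol=1e-12)


def test_run_puma_nonconvergence_warns(small_prior, small_expression):
    with pytest.warns(RuntimeWarning, match="did not converge"):
        out = pn.run_puma(
            small_prior, small_expression, params=pn.PumaParams(max_iter=2, tol=1e-9)
        )
    assert out.meta["converged"] is False


def test_planted_edges_outrank_background(refined_study):
    """Median refined weight of planted edges exceeds the background median,
    including for planted edges withheld from the prior (edge learning)."""
    data, coll = refined_study
    rec = pn.evaluate_recovery(coll, data["truth"])
    assert rec["median_planted"] > rec["median_background"]
    assert rec["median_prior_absent"] > rec["median_background"]
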