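"""Detection regression, randomized null, and empirical q-values."""

import numpy as np
import pytest

from uorfseqr.candidates import CandidateUORF
from uorfseqr.features import N_FEATURES, feature_matrix
from uorfseqr.regression import (
    GeneData,
    UORFCall,
    build_null_scores,
    call_significant,
    call_uorfs,
    empirical_qvalues,
    fit_detection_regression,
    score_candidates,
)


def _features(n, rng):
    return rng.normal(0, 1, (n, N_FEATURES))


def test_fit_recovers_single_informative_feature():
    rng = np.random.default_rng(0)
    X = _features(400, rng)
    y = 0.5 + 0.1 * X[:, 3]
    model = fit_detection_regression(X, y, n_replicates=3)
    # closed-form OLS on the informative standardized column
    z3 = (X[:, 3] - X[:, 3].mean()) / X[:, 3].std()
    beta = z3 @ y / (z3 @ z3)
    assert model.weights[3] == pytest.approx(beta, rel=1e-2)
    assert np.abs(np.delete(model.weights, 3)).max() < 0.01
    assert model.r_squared > 0.999


def test_fit_refuses_degenerate_target():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError, match="constant"):
        fit_detection_regression(_features(50, rng), np.zeros(50), 3)


def test_fit_refuses_too_few_replicates():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError, match="replicates"):
        fit_detection_regression(_features(50, rng), rng.random(50), 2)


def test_duplicated_feature_columns_keep_predictions():
    rng = np.random.default_rng(2)
    X = _features(200, rng)
    X[:, 5] = X[:, 4]  # exact collinearity
    y = 0.3 + 0.2 * X[:, 4] + rng.normal(0, 0.01, 200)
    model = fit_detection_regression(X, y, 3)
    assert np.isfinite(model.weights).all()
    X_single = X.copy()
    X_single[:, 5] = rng.normal(0, 1, 200)  # replace duplicate with pure noise
    model_single = fit_detection_regression(X_single, y, 3)
    pred_dup = score_candidates(model, X)
    pred_single = score_candidates(model_single, X_single)
    assert np.allclose(pred_dup, pred_single, atol=0.02)


def test_score_linearity_and_intercept():
    rng = np.random.default_rng(3)
    X = _features(100, rng)
    y = 0.5 + 0.3 * X[:, 0] - 0.2 * X[:, 7]
    model = fit_detection_regression(X, y, 3)
    base = score_candidates(model, model.feature_means[None, :])
    assert base[0] == pytest.approx(model.intercept)
    bumped = model.feature_means + model.feature_sds * (np.arange(N_FEATURES) == 2)
    assert score_candidates(model, bumped[None, :])[0] - base[0] == pytest.approx(
        model.weights[2]
    )
    # dot-product check on three rows
    Z = (X[:3] - model.feature_means) / model.feature_sds
    assert score_candidates(model, X[:3]) == pytest.approx(
        model.intercept + Z @ model.weights
    )


def test_scores_invariant_to_affine_feature_rescaling():
    rng = np.random.default_rng(4)
    X = _features(150, rng)
    y = 0.4 + 0.2 * X[:, 1] + rng.normal(0, 0.05, 150)
    m1 = fit_detection_regression(X, y, 3)
    X2 = X.copy()
    X2[:, 1] = 7.0 * X[:, 1] - 3.0  # affine rescale of a raw feature
    m2 = fit_detection_regression(X2, y, 3)
    assert np.allclose(score_candidates(m1, X), score_candidates(m2, X2), atol=1e-6)


# ---------------------------------------------------------------------------
# Randomized null
# ---------------------------------------------------------------------------

def _gene(rng, gene_id="g", L=45, T=105, n_cand=2, signal=False):
    cands = []
    for k in range(n_cand):
        start = 3 + 12 * k
        cands.append(CandidateUORF(gene_id, start, start + 11, "ATG", 12))
    tracks = {}
    for rep in ("rep1", "rep2", "rep3"):
        arr = rng.poisson(0.5, T)
        arr[L:] = rng.poisson(5.0, T - L)
        if signal:
            arr[3:15:3] += rng.poisson(8.0, 4)
        tracks[rep] = arr
    return GeneData(gene_id, L, cands, tracks, rng.poisson(3.0, T))


def test_null_preserves_leader_totals_and_zero_leader_fixed_point():
    rng = np.random.default_rng(5)
    genes = {f"g{i}": _gene(rng, f"g{i}") for i in range(4)}
    # zero out one gene's leaders: its null features must equal real ones
    for arr in genes["g0"].psite_tracks.values():
        arr[: genes["g0"].leader_len] = 0
    X = np.vstack(
        [feature_matrix(g.candidates, g.pooled(), g.rna, g.leader_len)
         for g in genes.values()]
    )
    y = np.linspace(0, 1, X.shape[0])
    model = fit_detection_regression(X, y, 3)
    real = score_candidates(model, X)
    null = build_null_scores(genes, model, n_permutations=1, rng=0)
    assert null.shape == real.shape
    assert np.allclose(null[:2], real[:2])  # g0's two candidates unchanged

    # conservation: permutation preserves per-leader per-replicate totals
    from uorfseqr.regression import _permuted_pooled

    g = genes["g2"]
    pooled = _permuted_pooled(g, np.random.default_rng(1))
    assert pooled[: g.leader_len].sum() == g.pooled()[: g.leader_len].sum()
    assert np.array_equal(pooled[g.leader_len:], g.pooled()[g.leader_len:])


def test_planted_signal_beats_null_top_decile():
    rng = np.random.default_rng(6)
    genes = {}
    for i in range(20):
        genes[f"g{i}"] = _gene(rng, f"g{i}", signal=(i < 10))
    res = call_uorfs(genes, n_permutations=10, seed=7)
    real_top = np.quantile([c.score for c in res.all_calls], 0.9)
    null_top = np.quantile(res.null_scores, 0.9)
    assert real_top > null_top


# ---------------------------------------------------------------------------
# Empirical q-values
# ---------------------------------------------------------------------------

def brute_force_qvalues(real, null):
    real = np.asarray(real, float)
    null = np.asarray(null, float)
    fdr = {}
    for s in real:
        n_null = (null >= s).sum()
        n_real = max(1, (real >= s).sum())
        fdr[s] = ((1 + n_null) / null.size) / (n_real / real.size)
    return np.array([min(min(f for t, f in fdr.items() if t <= s), 1.0) for s in real])


def test_qvalues_match_brute_force():
    rng = np.random.default_rng(8)
    real = rng.normal(0.5, 1.0, 50)
    null = rng.normal(0.0, 1.0, 500)
    assert np.allclose(empirical_qvalues(real, null), brute_force_qvalues(real, null))


def test_qvalue_top_candidate_formula():
    rng = np.random.default_rng(9)
    null = rng.normal(0, 1, 1000)
    real = np.concatenate([rng.normal(0, 1, 99), [null.max() + 10.0]])
    q = empirical_qvalues(real, null)
    top = q[np.argmax(real)]
    # (1+0)/1000 over 1/100 -> 0.1
    assert top == pytest.approx((1 / 1000) / (1 / 100))


def test_qvalues_null_distributed_scores():
    rng = np.random.default_rng(10)
    real = rng.normal(0, 1, 200)
    null = rng.normal(0, 1, 2000)
    q = empirical_qvalues(real, null)
    assert np.median(q) > 0.5  # near 1 after monotonization
    assert (np.diff(q[np.argsort(real)]) <= 1e-12).all()  # monotone in score


def test_qvalues_all_real_below_null():
    q = empirical_qvalues(np.array([-5.0, -6.0]), np.linspace(0, 1, 100))
    assert (q == 1.0).all()


def test_qvalues_empty_null_errors():
    with pytest.raises(ValueError):
        empirical_qvalues(np.ones(3), np.empty(0))


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------

def _call(gene, start, stop, score, q):
    return UORFCall(CandidateUORF(gene, start, stop, "ATG", stop - start + 1), score, q)


def test_call_significant_threshold():
    calls = [_call("g", 0, 8, 3.0, 0.01), _call("g", 20, 28, 2.0, 0.049),
             _call("g2", 0, 8, 1.0, 0.051)]
    final = call_significant(calls, beta=0.05)
    assert len(final) == 2
    assert all(c.significant for c in final)
    assert call_significant(calls, beta=0.0) == []


def test_call_significant_resolves_nested():
    calls = [_call("g", 0, 14, 3.0, 0.01), _call("g", 3, 14, 5.0, 0.001)]
    final = call_significant(calls, beta=0.05)
    assert len(final) == 1 and final[0].candidate.start_pos == 3
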