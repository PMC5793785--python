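"""Detection regression, randomized null, and empirical FDR control.

The scoring model is a ridge-regularised linear regression of the
replicate detection fraction (how many of >= 3 biological replicates a
candidate was heuristically detected in) on the 18 standardized
features. Scores of real candidates are compared against scores of the
SAME trained model applied to features recomputed after randomly
re-positioning P-site counts within each transcript leader (per
replicate, totals preserved; the mORF is untouched). Empirical
q-values follow the (1 + #null >= s) / #real >= s ratio with step-up
monotonization, and calls are made at q <= beta (default 0.05), with
overlapping significant calls resolved greedily by score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from .candidates import CandidateUORF, resolve_overlaps
from .features import (DEFAULT_DETECT_PARAMS, FEATURE_NAMES, N_FEATURES,
                       detect_in_replicate, feature_matrix)

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.05
DEFAULT_PERMUTATIONS = 10
RIDGE_ALPHA = 1e-3
MIN_REPLICATES = 3


@dataclass
class RegressionModel:
    """Weights and standardization of one experiment's detection fit."""

    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    r_squared: float
    n_obs: int
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_means) / self.feature_sds


@dataclass
class UORFCall:
    candidate: CandidateUORF
    score: float
    q_value: float = float("nan")
    significant: bool = False
    no_signal: bool = False


@dataclass
class GeneData:
    """Everything the caller needs about one gene in one experiment."""

    gene_id: str
    leader_len: int
    candidates: list[CandidateUORF]
    psite_tracks: dict[str, np.ndarray]  # replicate_id -> transcript counts
    rna: np.ndarray

    def pooled(self) -> np.ndarray:
        return np.sum([np.asarray(t) for t in self.psite_tracks.values()], axis=0)


# ---------------------------------------------------------------------------
# Fitting and scoring
# ---------------------------------------------------------------------------

def fit_detection_regression(features: np.ndarray, detection_fractions: np.ndarray,
                             n_replicates: int, alpha: float = RIDGE_ALPHA) -> RegressionModel:
    """Ridge fit of detection fraction on standardized features.

    The target is y = (replicates detected) / n_replicates per
    candidate, in {0, 1/n, ..., 1}. Refuses to fit with fewer than
    three replicates or a constant target.
    """
    if n_replicates < MIN_REPLICATES:
        raise ValueError(
            f"uORF calling requires >= {MIN_REPLICATES} biological replicates "
            f"(got {n_replicates})"
        )
    X = np.asarray(features, dtype=float)
    y = np.asarray(detection_fractions, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES or X.shape[0] != y.size:
        raise ValueError("feature matrix must be (n_candidates, 18)")
    if np.ptp(y) == 0:
        raise ValueError("detection fractions are constant; regression is degenerate")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds
    ridge = Ridge(alpha=alpha, fit_intercept=True)
    ridge.fit(Z, y)
    r2 = float(ridge.score(Z, y))
    return RegressionModel(
        weights=np.asarray(ridge.coef_, dtype=float),
        intercept=float(ridge.intercept_),
        feature_means=means,
        feature_sds=sds,
        r_squared=r2,
        n_obs=int(y.size),
    )


def score_candidates(model: RegressionModel, features: np.ndarray) -> np.ndarray:
    """score = intercept + sum_j w_j * standardized feature_j."""
    Z = model.standardize(np.asarray(features, dtype=float))
    return model.intercept + Z @ model.weights


# ---------------------------------------------------------------------------
# Randomized null
# ---------------------------------------------------------------------------

def _permuted_pooled(gene: GeneData, rng: np.random.Generator) -> np.ndarray:
    """Pooled track with each replicate's leader counts re-positioned."""
    L = gene.leader_len
    pooled = None
    for track in gene.psite_tracks.values():
        arr = np.asarray(track).copy()
        arr[:L] = rng.permutation(arr[:L])
        pooled = arr if pooled is None else pooled + arr
    return pooled


def build_null_scores(genes: dict[str, GeneData], model: RegressionModel,
                      n_permutations: int = DEFAULT_PERMUTATIONS,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Pooled scores of all candidates under leader-permuted tracks.

    For each permutation, P-site counts within every transcript leader
    are randomly re-positioned per replicate (preserving per-leader,
    per-replicate totals), features are recomputed, and the
    already-trained model is applied. RNA coverage and mORF occupancy
    are left untouched so expression-level features keep their real
    distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng)
    scores = []
    for _ in range(n_permutations):
        for gene in genes.values():
            if not gene.candidates:
                continue
            pooled = _permuted_pooled(gene, rng)
            X = feature_matrix(gene.candidates, pooled, gene.rna, gene.leader_len)
            scores.append(score_candidates(model, X))
    if not scores:
        return np.empty(0)
    return np.concatenate(scores)


# ---------------------------------------------------------------------------
# Empirical q-values
# ---------------------------------------------------------------------------

def empirical_qvalues(real_scores: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Empirical-null q-values.

    For a threshold s:
        FDR(s) = [(1 + #null >= s) / N_null] / [max(1, #real >= s) / N_real]
    and q(candidate) = min over thresholds <= its score of FDR
    (step-up monotonization), clipped to [0, 1]. Thresholds range over
    the observed real scores. The +1 pseudocount keeps q > 0.
    """
    real = np.asarray(real_scores, dtype=float)
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("null score sample is empty")
    if real.size == 0:
        return np.empty(0)
    order = np.argsort(real)  # ascending
    sorted_real = real[order]
    n_real = real.size
    n_null = null.size
    sorted_null = np.sort(null)
    # counts >= s for each threshold s in sorted_real
    n_null_ge = n_null - np.searchsorted(sorted_null, sorted_real, side="left")
    n_real_ge = n_real - np.searchsorted(sorted_real, sorted_real, side="left")
    fdr = ((1.0 + n_null_ge) / n_null) / (np.maximum(1, n_real_ge) / n_real)
    # q at threshold s_i = min over thresholds t <= s_i of FDR(t):
    # every candidate belongs to all lists {score >= t} with t <= its score
    q_sorted = np.minimum.accumulate(fdr)
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(n_real)
    out[order] = q_sorted
    return out


def call_significant(calls: list[UORFCall], beta: float = DEFAULT_BETA) -> list[UORFCall]:
    """Flag q <= beta, resolve overlapping significant calls, sort output.

    The returned list contains ONLY the final significant calls, sorted
    by (gene, start position); the greedy overlap resolution of
    :func:`uorfseqr.candidates.resolve_overlaps` is applied to the
    significant set.
    """
    significant = [c for c in calls if c.q_value <= beta]
    retained = resolve_overlaps([(c.candidate, c.score) for c in significant])
    kept_ids = {cand.uid for cand, _ in retained}
    final = [c for c in significant if c.candidate.uid in kept_ids]
    for c in final:
        c.significant = True
    return sorted(final, key=lambda c: (c.candidate.gene_id, c.candidate.start_pos))


# ---------------------------------------------------------------------------
# Experiment-level convenience
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    calls: list[UORFCall]            # final significant calls
    all_calls: list[UORFCall]        # every scored candidate with its q
    model: RegressionModel
    null_scores: np.ndarray
    n_candidates: int = 0
    beta: float = DEFAULT_BETA


def call_uorfs(genes: dict[str, GeneData], beta: float = DEFAULT_BETA,
               n_permutations: int = DEFAULT_PERMUTATIONS,
               seed: int | None = 0,
               detect_params=DEFAULT_DETECT_PARAMS,
               include_morf_overlaps: bool = False) -> CallResult:
    """Run the full scoring pipeline on one experiment.

    Features come from pooled (replicate-summed) tracks; detection
    labels from individual replicates; the model is trained once per
    experiment, then applied to real and leader-permuted features.
    """
    n_replicates = {len(g.psite_tracks) for g in genes.values()}
    if len(n_replicates) > 1:
        raise ValueError("all genes must carry the same replicate set")
    n_rep = n_replicates.pop() if n_replicates else 0

    work: dict[str, GeneData] = {}
    rows = []
    fractions = []
    cand_objs = []
    for gid in sorted(genes):
        gene = genes[gid]
        cands = [c for c in gene.candidates if include_morf_overlaps or not c.overlaps_morf]
        if not cands:
            continue
        work[gid] = GeneData(gid, gene.leader_len, cands, gene.psite_tracks, gene.rna)
        pooled = work[gid].pooled()
        X = feature_matrix(cands, pooled, gene.rna, gene.leader_len)
        rows.append(X)
        for cand in cands:
            hits = sum(
                detect_in_replicate(cand, trk, detect_params, rep).detected
                for rep, trk in sorted(gene.psite_tracks.items())
            )
            fractions.append(hits / n_rep)
            cand_objs.append((cand, pooled[cand.start_pos : cand.stop_pos + 1].sum()))
    if not rows:
        return CallResult([], [], None, np.empty(0), 0, beta)
    X_all = np.vstack(rows)
    y = np.array(fractions)

    model = fit_detection_regression(X_all, y, n_rep)
    real_scores = score_candidates(model, X_all)
    null_scores = build_null_scores(work, model, n_permutations, rng=seed)
    qvals = empirical_qvalues(real_scores, null_scores)

    all_calls = [
        UORFCall(cand, float(s), float(q), no_signal=(tot == 0))
        for (cand, tot), s, q in zip(cand_objs, real_scores, qvals)
    ]
    final = call_significant(all_calls, beta)
    return CallResult(final, all_calls, model, null_scores, len(all_calls), beta)
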