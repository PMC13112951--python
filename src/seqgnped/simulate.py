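"""Forward simulators for sequential diagnostic response data.

Two generating schemes are provided, both built on a two-stage mechanism:
a *category walk* that produces the examinee's model-implied score, and an
item-level slip that perturbs it.  In the walk, the examinee attempts the
item's sequential steps in order and the implied score is the last step
passed; a step is passed with probability 1 when every attribute it
requires is mastered and 0 when none is.  The slip then keeps the implied
score with probability 1 - s and otherwise replaces it by a uniformly
chosen different score (total slip mass s) — the item-quality parameter
acts on the whole item score, not on each step, so a fully mastering
examinee obtains the item's implied score with probability exactly 1 - s
regardless of how many steps the item has.

The sequential DINA scheme is purely conjunctive: partial mastery of a
step's attributes fails the step, so the walk is deterministic.  The
sequential G-DINA scheme draws, per item, either a DINA or a saturated
(G-DINA) link with equal probability; under the saturated link a step
whose required attributes are only partially mastered is passed with a
probability drawn once per replication from U(0.3, 0.7) for that
(category, reduced pattern) combination.

Profile generators cover the i.i.d.-uniform pattern distribution and a
higher-order logistic model in which a single latent trait drives all
attribute masteries.  Design manipulations from the robustness studies —
random Q-matrix misspecification and reduction of the polytomous item
proportion by full-credit dichotomization — round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qc import PatternSpace, QcMatrix

__all__ = [
    "HigherOrderParams",
    "sample_profiles_uniform",
    "sample_profiles_higher_order",
    "sequential_response_probability",
    "generate_seq_dina",
    "generate_seq_gdina",
    "misspecify_q",
    "reduce_polytomous_qc",
    "reduce_polytomous_proportion",
]


@dataclass(frozen=True)
class HigherOrderParams:
    """Parameters of the higher-order attribute model.

    Attribute k is mastered with logistic probability
    ``expit(lambda1[k] * (theta_i - lambda0[k]))`` given the examinee's
    latent trait ``theta_i ~ N(0, 1)``; ``lambda0`` is the equidistant
    difficulty grid on [-1.5, 1.5] and ``lambda1 ~ U(1, 2)`` the
    discriminations.
    """

    lambda0: np.ndarray
    lambda1: np.ndarray
    theta: np.ndarray


def sample_profiles_uniform(N: int, K: int, seed) -> np.ndarray:
    """Draw N profiles i.i.d. uniform over the 2^K patterns."""
    if N < 1 or K < 1:
        raise ValueError("N and K must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 2 ** K, size=N)
    return PatternSpace(K).patterns[idx]


def sample_profiles_higher_order(
    N: int, K: int, seed
) -> tuple[np.ndarray, HigherOrderParams]:
    """Draw N profiles from the higher-order logistic model."""
    if K < 2:
        raise ValueError("the difficulty grid needs K >= 2")
    rng = np.random.default_rng(seed)
    lambda0 = np.linspace(-1.5, 1.5, K)
    lambda1 = rng.uniform(1.0, 2.0, size=K)
    theta = rng.standard_normal(N)
    logit = lambda1[None, :] * (theta[:, None] - lambda0[None, :])
    p = 1.0 / (1.0 + np.exp(-logit))
    alpha = (rng.random((N, K)) < p).astype(np.int8)
    return alpha, HigherOrderParams(lambda0, lambda1, theta)


def sequential_response_probability(S_values) -> np.ndarray:
    """Score distribution of one item given per-category success probabilities.

    With success probabilities ``S_1..S_H`` for the sequential steps (and
    the conventions ``S_0 = 1``, ``S_{H+1} = 0``), the probability of
    scoring h is ``(1 - S_{h+1}) * prod_{x<=h} S_x``.  The returned vector
    over scores 0..H sums to 1 (telescoping).
    """
    S = np.asarray(S_values, dtype=float)
    if np.any(S < 0) or np.any(S > 1):
        raise ValueError("category success probabilities must lie in [0, 1]")
    ext = np.concatenate(([1.0], S, [0.0]))
    cum = np.cumprod(ext[:-1])  # prod_{x<=h} S_x for h = 0..H
    return (1.0 - ext[1:]) * cum


def _conjunctive_depth(alpha: np.ndarray, qc: QcMatrix) -> np.ndarray:
    """(N, J) deepest category h whose steps 1..h are all conjunctively met."""
    # per-category conjunctive satisfaction, (N, C)
    sat = (alpha[:, None, :] >= qc.q[None, :, :]).all(axis=2)
    N = alpha.shape[0]
    depth = np.zeros((N, qc.n_items), dtype=np.int64)
    for j in range(qc.n_items):
        rows = qc.item_rows(j)
        depth[:, j] = np.cumprod(sat[:, rows], axis=1).sum(axis=1)
    return depth


def generate_seq_dina(alpha: np.ndarray, qc: QcMatrix, s: float, seed) -> np.ndarray:
    """Sequential-DINA scores: model-implied score with prob 1 - s, else slip.

    The model-implied score of examinee i on item j is the deepest category
    h* whose steps 1..h* are all conjunctively mastered (0 if none).  With
    probability 1 - s the examinee scores h*; with total probability s a
    different score is drawn uniformly from the remaining S_j scores.
    """
    if not 0 <= s < 0.5:
        raise ValueError("slip must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, dtype=np.int8)
    depth = _conjunctive_depth(alpha, qc)
    return _apply_item_slip(depth, qc, s, rng)


def _walk_probabilities(
    alpha: np.ndarray, qc: QcMatrix, rng, link: np.ndarray
) -> np.ndarray:
    """(N, C) step-passing probabilities of the category walk.

    Full within-step mastery passes with probability 1, zero mastery with
    0; partial mastery passes with 0 under a DINA link and with a
    per-(category, reduced pattern) draw from U(0.3, 0.7) under a G-DINA
    link.
    """
    N = alpha.shape[0]
    C = qc.n_categories
    P = np.empty((N, C))
    for c in range(C):
        req = np.flatnonzero(qc.q[c])
        j = qc.item_of_row[c]
        if req.size == 0:
            P[:, c] = 1.0  # non-diagnostic step: everyone passes
            continue
        n_req = (alpha[:, req] == 1).sum(axis=1)
        p = (n_req == req.size).astype(float)
        if link[j] == 1 and req.size > 1:  # saturated link with partial patterns
            weights = 1 << np.arange(req.size - 1, -1, -1)
            codes = alpha[:, req] @ weights
            draws = rng.uniform(0.3, 0.7, size=2 ** req.size)
            partial = (n_req > 0) & (n_req < req.size)
            p = np.where(partial, draws[codes], p)
        P[:, c] = p
    return P


def _apply_item_slip(X: np.ndarray, qc: QcMatrix, s: float, rng) -> np.ndarray:
    """Keep each item score with probability 1 - s, else a uniform other score."""
    N, J = X.shape
    smax = qc.max_scores
    out = X.copy()
    slip = rng.random((N, J)) < s
    for j in range(J):
        rows = np.flatnonzero(slip[:, j])
        if rows.size:
            draw = rng.integers(0, smax[j], size=rows.size)
            draw = np.where(draw >= X[rows, j], draw + 1, draw)
            out[rows, j] = draw
    return out


def generate_seq_gdina(
    alpha: np.ndarray, qc: QcMatrix, s: float, seed, return_params: bool = False
):
    """Sequential G-DINA scores with a 50/50 DINA / saturated link mix.

    Per item a link type is drawn (DINA or saturated, probability 1/2
    each).  The examinee walks the item's steps — passing with probability
    1 under full within-step mastery, 0 under none, and a U(0.3, 0.7) draw
    for partially mastered steps of saturated-link items — and the implied
    score (the last step passed) is kept with probability 1 - s or slipped
    uniformly to another score.  With an all-DINA link draw this
    coincides with :func:`generate_seq_dina`.
    """
    if not 0 <= s < 0.5:
        raise ValueError("slip must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, dtype=np.int8)
    link = rng.integers(0, 2, size=qc.n_items)  # 1 = saturated (G-DINA)
    P = _walk_probabilities(alpha, qc, rng, link)
    N = alpha.shape[0]
    X = np.zeros((N, qc.n_items), dtype=np.int64)
    for j in range(qc.n_items):
        # sequential walk: pass steps until the first failure
        passed = np.ones(N, dtype=bool)
        for c in qc.item_rows(j):
            passed &= rng.random(N) < P[:, c]
            X[:, j] += passed
    X = _apply_item_slip(X, qc, s, rng)
    if return_params:
        return X, {"link": link}
    return X


def misspecify_q(qc: QcMatrix, rate: float, seed) -> QcMatrix:
    """Randomly corrupt a fraction of the Q_c category rows.

    ``ceil(rate * n_categories)`` rows are chosen without replacement; each
    chosen row's q-vector is replaced by a uniformly drawn different
    nonzero vector that differs from the original in at most three
    positions.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    q = qc.q.copy()
    n_alter = int(np.ceil(rate * qc.n_categories))
    if n_alter == 0:
        return QcMatrix(q, qc.item_of_row, qc.cat_of_row)
    chosen = rng.choice(qc.n_categories, size=n_alter, replace=False)
    K = qc.n_attributes
    all_vecs = PatternSpace(K).patterns
    for c in chosen:
        orig = q[c]
        dist = np.abs(all_vecs - orig[None, :]).sum(axis=1)
        candidates = all_vecs[(dist >= 1) & (dist <= 3) & (all_vecs.sum(axis=1) > 0)]
        q[c] = candidates[rng.integers(0, len(candidates))]
    return QcMatrix(q, qc.item_of_row, qc.cat_of_row)


def _conversion_count(qc: QcMatrix, target: int) -> tuple[int, np.ndarray]:
    n_convert = {75: 0, 50: 5, 25: 10}.get(target)
    if n_convert is None:
        raise ValueError("target must be one of 75, 50, 25")
    poly = np.flatnonzero(qc.max_scores >= 2)
    if n_convert > poly.size:
        raise ValueError(f"cannot convert {n_convert} of {poly.size} polytomous items")
    return n_convert, poly


def _convert_items(qc: QcMatrix, chosen: set) -> QcMatrix:
    """Replace each chosen item's categories by a single union-q category."""
    new_cats = []
    for j in range(qc.n_items):
        rows = qc.item_rows(j)
        if j in chosen:
            new_cats.append([qc.q[rows].max(axis=0)])
        else:
            new_cats.append(list(qc.q[rows]))
    return QcMatrix.from_arrays(new_cats)


def reduce_polytomous_qc(qc: QcMatrix, target: int, seed) -> QcMatrix:
    """Dichotomize randomly chosen polytomous items in the Q_c matrix itself.

    `target` is the retained polytomous percentage relative to the 21-item
    design with 16 polytomous items: 75 keeps the matrix unchanged, 50
    converts 5 random polytomous items, 25 converts 10.  A converted item
    becomes single-category with q-vector the element-wise OR of its
    original category q-vectors (completing the whole item requires every
    step's attributes).  Data for a reduced design are then generated
    directly under the returned matrix; scoring 1 on a converted item means
    what scoring the old maximum did.
    """
    n_convert, poly = _conversion_count(qc, target)
    if n_convert == 0:
        return qc
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(poly, size=n_convert, replace=False).tolist())
    return _convert_items(qc, chosen)


def reduce_polytomous_proportion(
    qc: QcMatrix, X: np.ndarray, target: int, seed
) -> tuple[QcMatrix, np.ndarray]:
    """Dichotomize already-generated scores to hit a target proportion.

    Post-hoc counterpart of :func:`reduce_polytomous_qc` for observed data:
    the chosen items' scores are recoded 1 iff they equalled the item
    maximum, and the returned Q_c carries the union q-vectors.
    """
    n_convert, poly = _conversion_count(qc, target)
    X = np.asarray(X, dtype=np.int64)
    if n_convert == 0:
        return qc, X
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(poly, size=n_convert, replace=False).tolist())
    smax = qc.max_scores
    new_X = X.copy()
    for j in chosen:
        new_X[:, j] = (X[:, j] == smax[j]).astype(np.int64)
    return _convert_items(qc, chosen), new_X
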