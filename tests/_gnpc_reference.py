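"""Independent reference implementation of the dichotomous GNPC method.

Deliberately written in plain dict/loop style from the standard
description of the generalized nonparametric classifier for 0/1 data:
weighted ideal responses eta_lj^w = w_lj * eta_lj^c + (1 - w_lj) * eta_lj^d
with least-squares weights per (reduced pattern class, item), squared
Euclidean distance classification over all 2^K patterns, conjunctive
initialization, and iteration until the classification change rate drops
below eps.  Shares no code with the seqgnped package; used as an oracle
for the all-dichotomous special case.
"""

from itertools import product


def _patterns(K):
    # binary counting, attribute 1 as the most significant bit
    return [tuple(p) for p in product((0, 1), repeat=K)]


def _eta_c(alpha, qrow):
    for a, q in zip(alpha, qrow):
        if q == 1 and a == 0:
            return 0
    return 1


def _eta_d(alpha, qrow):
    for a, q in zip(alpha, qrow):
        if q == 1 and a == 1:
            return 1
    return 0


def _classify_one(y, eta_w_rows):
    best_m, best_d = 0, None
    for m, row in enumerate(eta_w_rows):
        d = 0.0
        for yj, ej in zip(y, row):
            d += (yj - ej) ** 2
        if best_d is None or d < best_d:
            best_m, best_d = m, d
    return best_m


def gnpc_classify(Y, Q, eps=0.001, max_iter=100):
    """Classify binary responses Y (list of N rows) under item Q-matrix Q.

    Returns (pattern index per examinee, number of iterations).
    """
    K = len(Q[0])
    J = len(Q)
    pats = _patterns(K)
    eta_c = [[_eta_c(alpha, Q[j]) for j in range(J)] for alpha in pats]
    eta_d = [[_eta_d(alpha, Q[j]) for j in range(J)] for alpha in pats]
    # reduced pattern (class) of each full pattern at each item
    req = [[k for k in range(K) if Q[j][k] == 1] for j in range(J)]
    class_of = [
        [tuple(alpha[k] for k in req[j]) for j in range(J)] for alpha in pats
    ]

    assign = [_classify_one(y, eta_c) for y in Y]
    weights = {}  # (j, class tuple) -> w
    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        new_weights = {}
        for j in range(J):
            members = {}
            for i, y in enumerate(Y):
                cl = class_of[assign[i]][j]
                members.setdefault(cl, []).append(y[j])
            for cl in set(class_of[m][j] for m in range(len(pats))):
                m_repr = next(m for m in range(len(pats)) if class_of[m][j] == cl)
                ec, ed = eta_c[m_repr][j], eta_d[m_repr][j]
                if ec == ed:
                    new_weights[(j, cl)] = 1.0
                elif cl in members:
                    ys = members[cl]
                    w = sum(v - ed for v in ys) / (len(ys) * (ec - ed))
                    new_weights[(j, cl)] = min(1.0, max(0.0, w))
                else:
                    new_weights[(j, cl)] = weights.get((j, cl), 0.5)
        weights = new_weights
        eta_w = [
            [
                weights[(j, class_of[m][j])] * eta_c[m][j]
                + (1.0 - weights[(j, class_of[m][j])]) * eta_d[m][j]
                for j in range(J)
            ]
            for m in range(len(pats))
        ]
        new_assign = [_classify_one(y, eta_w) for y in Y]
        changed = sum(1 for a, b in zip(assign, new_assign) if a != b) / len(Y)
        assign = new_assign
        if changed < eps:
            break
    return assign, n_iter
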