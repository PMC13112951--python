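"""Conjunctive, disjunctive, and weighted ideal category responses.

For an attribute pattern alpha and the q-vector of one category, the
conjunctive ideal response is 1 only when every required attribute is
mastered (DINA-type, non-compensatory); the disjunctive ideal response is 1
when at least one required attribute is mastered (DINO-type, compensatory).
Scoring category h of a sequential item means completing steps 1..h, so the
cumulative ideal response at h is the product of the per-step values over
b = 1..h.  The weighted ideal response is the convex combination
``w * eta_c + (1 - w) * eta_d`` with a per-collapsed-class weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import CollapsedClassIndex, PatternSpace, QcMatrix, build_collapsed_classes

__all__ = [
    "conjunctive_category",
    "disjunctive_category",
    "cumulative_ideal",
    "weighted_ideal",
    "IdealResponseTable",
    "build_ideal_table",
]


def _check_lengths(alpha, qvec):
    alpha = np.asarray(alpha)
    qvec = np.asarray(qvec)
    if alpha.shape != qvec.shape:
        raise ValueError("profile and q-vector lengths differ")
    return alpha, qvec


def conjunctive_category(alpha, qvec) -> int:
    """1 iff `alpha` masters every attribute the category requires.

    An all-zero q-vector yields 1 (empty product).
    """
    alpha, qvec = _check_lengths(alpha, qvec)
    return int(np.all(alpha >= qvec))


def disjunctive_category(alpha, qvec) -> int:
    """1 iff `alpha` masters at least one required attribute (0 if none required)."""
    alpha, qvec = _check_lengths(alpha, qvec)
    return int(np.any(alpha * qvec))


def cumulative_ideal(alpha, categories, h: int, mode: str = "conjunctive") -> int:
    """Cumulative ideal response at step h: product over steps 1..h.

    Parameters
    ----------
    categories : sequence of q-vectors for steps 1..S_j of one item.
    h : 1-based step index.
    mode : 'conjunctive' or 'disjunctive'.
    """
    if not 1 <= h <= len(categories):
        raise ValueError(f"h={h} out of range 1..{len(categories)}")
    step = {"conjunctive": conjunctive_category, "disjunctive": disjunctive_category}
    try:
        f = step[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}") from None
    out = 1
    for b in range(h):
        out *= f(alpha, categories[b])
    return out


def weighted_ideal(eta_c, eta_d, w):
    """Convex combination ``w * eta_c + (1 - w) * eta_d``."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weight must lie in [0, 1]")
    return w * np.asarray(eta_c, float) + (1.0 - w) * np.asarray(eta_d, float)


@dataclass(frozen=True)
class IdealResponseTable:
    """Dense (2^K patterns) x (category rows) table of ideal responses.

    ``eta_c`` and ``eta_d`` hold the cumulative conjunctive/disjunctive
    values; ``eta_w`` the weighted combination actually used for distance
    classification.  Weights live on collapsed classes, so per-pattern
    values are produced through the pattern -> class indirection and a
    weight update costs O(#classes), not O(2^K).
    """

    eta_c: np.ndarray
    eta_d: np.ndarray
    eta_w: np.ndarray
    patterns: PatternSpace
    classes: CollapsedClassIndex

    def to_frame(self, qc: QcMatrix) -> pd.DataFrame:
        """Debug dump: one row per (pattern, item, cat) cell."""
        M, C = self.eta_c.shape
        m, c = np.meshgrid(np.arange(M), np.arange(C), indexing="ij")
        return pd.DataFrame(
            {
                "pattern": m.ravel(),
                "item": qc.item_of_row[c.ravel()] + 1,
                "cat": qc.cat_of_row[c.ravel()],
                "eta_c": self.eta_c.ravel(),
                "eta_d": self.eta_d.ravel(),
                "eta_w": self.eta_w.ravel(),
            }
        )


def _cumulative_tables(qc: QcMatrix, patterns: PatternSpace):
    """(M, C) cumulative conjunctive and disjunctive tables."""
    pats = patterns.patterns  # (M, K)
    q = qc.q  # (C, K)
    # per-step values for every pattern x category row
    step_c = (pats[:, None, :] >= q[None, :, :]).all(axis=2).astype(np.int8)
    step_d = ((pats[:, None, :] * q[None, :, :]).any(axis=2)).astype(np.int8)
    eta_c = np.empty_like(step_c)
    eta_d = np.empty_like(step_d)
    for j in range(qc.n_items):
        rows = qc.item_rows(j)
        eta_c[:, rows] = np.cumprod(step_c[:, rows], axis=1)
        eta_d[:, rows] = np.cumprod(step_d[:, rows], axis=1)
    return eta_c, eta_d


def build_ideal_table(
    qc: QcMatrix,
    patterns: PatternSpace,
    weights: np.ndarray | None = None,
    classes: CollapsedClassIndex | None = None,
) -> IdealResponseTable:
    """Materialize the full ideal-response table.

    Parameters
    ----------
    weights : optional (n_categories, max_classes) array of class weights.
        When None, ``eta_w`` is set to the conjunctive table (the
        initialization used by the fitting loop).
    """
    if classes is None:
        classes = build_collapsed_classes(qc, patterns)
    eta_c, eta_d = _cumulative_tables(qc, patterns)
    if weights is None:
        eta_w = eta_c.astype(float)
    else:
        C = qc.n_categories
        if weights.shape[0] != C or weights.shape[1] < classes.n_classes.max():
            raise ValueError("weight table does not cover every (class, j, h)")
        if np.any(weights < 0) or np.any(weights > 1) or not np.isfinite(weights).all():
            raise ValueError("weights must be finite and in [0, 1]")
        # per-pattern weight at each cell via the class indirection: (C, M)
        w_pat = np.take_along_axis(weights, classes.class_of_pattern, axis=1)
        eta_w = w_pat.T * eta_c + (1.0 - w_pat.T) * eta_d
    return IdealResponseTable(eta_c, eta_d, eta_w, patterns, classes)
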