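"""The seq-GNPED classifier: model and results objects.

seq-GNPED assigns each examinee a binary attribute-mastery pattern by
minimizing the squared Euclidean distance between the examinee's observed
category responses and the weighted ideal category responses of every
candidate pattern.  The weights — one per collapsed attribute class and
category — interpolate between a conjunctive (DINA-type) and a disjunctive
(DINO-type) response mechanism and are re-estimated from the current
classification, so fitting alternates weight estimation and distance
reclassification until the fraction of examinees changing pattern drops
below a threshold.

The entry point is :class:`SeqGNPED`; ``SeqGNPED(X, qc).fit()`` returns a
:class:`SeqGNPEDResults` with the estimated profiles, the final weight
table, and the iteration trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ideal import IdealResponseTable, _cumulative_tables, build_ideal_table
from .qc import (
    CollapsedClassIndex,
    PatternSpace,
    QcMatrix,
    build_collapsed_classes,
    dichotomize_scores,
    read_qc_matrix,
    read_scores,
)

__all__ = [
    "WeightTable",
    "SeqGNPED",
    "SeqGNPEDResults",
    "estimate_weight",
    "classify",
]

# provenance codes for weight entries
ESTIMATED, DEFAULTED, DEGENERATE = 0, 1, 2
_PROVENANCE_NAMES = {ESTIMATED: "estimated", DEFAULTED: "defaulted", DEGENERATE: "degenerate"}


@dataclass(frozen=True)
class WeightTable:
    """Per (category row, collapsed class) mixing weights in [0, 1].

    ``w[c, l]`` is the weight of class l at category row c; ``provenance``
    records whether each entry was estimated from data, defaulted (empty
    class), or degenerate (conjunctive and disjunctive ideals coincide, so
    the weight is immaterial).  Rows are padded to the largest class count;
    entries beyond ``n_classes[c]`` are unused.
    """

    w: np.ndarray
    provenance: np.ndarray
    n_classes: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in [0, 1]")

    def provenance_name(self, c: int, l: int) -> str:
        return _PROVENANCE_NAMES[int(self.provenance[c, l])]


def estimate_weight(responses, eta_c: int, eta_d: int) -> tuple[float, str]:
    """Least-squares weight for one collapsed class at one category.

    Minimizing ``sum_i (y_i - w*eta_c - (1-w)*eta_d)^2`` over w gives
    ``w = sum_i (y_i - eta_d) / (n * (eta_c - eta_d))``.  Because the
    conjunctive ideal never exceeds the disjunctive one, the only
    non-degenerate case is (eta_c, eta_d) = (0, 1), where this reduces to
    ``1 - mean(y)``.  When the two ideals coincide the weight does not
    enter the weighted ideal response; 1 is returned with provenance
    ``'degenerate'``.  Results are clamped to [0, 1].
    """
    if eta_c == eta_d:
        return 1.0, "degenerate"
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0:
        return 0.5, "defaulted"
    if (eta_c, eta_d) == (0, 1):
        # the only non-degenerate case under eta_c <= eta_d; closed form
        w = 1.0 - responses.mean()
    else:
        w = np.sum(responses - eta_d) / (responses.size * (eta_c - eta_d))
    return float(np.clip(w, 0.0, 1.0)), "estimated"


def classify(Y: np.ndarray, table: IdealResponseTable) -> np.ndarray:
    """Assign each response row the pattern index minimizing squared distance.

    Distances are summed over every (item, category) cell; ties go to the
    lowest pattern index in the canonical enumeration.
    """
    Y = np.asarray(Y, dtype=float)
    eta_w = table.eta_w
    out = np.empty(Y.shape[0], dtype=np.int64)
    # chunked exact evaluation keeps memory at chunk x M x C
    step = max(1, 2_000_000 // max(1, eta_w.size))
    for start in range(0, Y.shape[0], step):
        block = Y[start : start + step]
        d = ((block[:, None, :] - eta_w[None, :, :]) ** 2).sum(axis=2)
        out[start : start + step] = np.argmin(d, axis=1)
    return out


class SeqGNPED:
    """Sequential generalized nonparametric classifier for polytomous scores.

    Parameters
    ----------
    X : (N, J) integer array
        Polytomous scores, ``0 <= X_ij <= S_j``.
    qc : QcMatrix
        Category-level Q-matrix defining the J items, their step counts
        ``S_j``, and the K attributes.

    Examples
    --------
    >>> from seqgnped.datasets import sim_qc
    >>> from seqgnped.simulate import sample_profiles_uniform, generate_seq_dina
    >>> qc = sim_qc()
    >>> alpha = sample_profiles_uniform(50, qc.n_attributes, seed=7)
    >>> X = generate_seq_dina(alpha, qc, s=0.05, seed=8)
    >>> res = SeqGNPED(X, qc).fit()
    >>> res.alpha_hat.shape
    (50, 5)
    """

    def __init__(self, X, qc: QcMatrix):
        self.qc = qc
        self.patterns = PatternSpace(qc.n_attributes)
        X = np.asarray(X)
        if not np.issubdtype(X.dtype, np.number) or not np.isfinite(
            np.asarray(X, dtype=float)
        ).all():
            raise ValueError("scores must be finite")
        self.X = np.asarray(X, dtype=np.int64)
        self.Y = dichotomize_scores(self.X, qc)
        self.classes: CollapsedClassIndex = build_collapsed_classes(qc, self.patterns)
        self._eta_c, self._eta_d = _cumulative_tables(qc, self.patterns)
        # class-level ideal responses (constant within class by construction)
        C, L = qc.n_categories, int(self.classes.n_classes.max())
        self._eta_c_class = np.zeros((C, L), dtype=np.int8)
        self._eta_d_class = np.zeros((C, L), dtype=np.int8)
        rows = np.arange(C)[:, None]
        self._eta_c_class[rows, self.classes.class_of_pattern] = self._eta_c.T
        self._eta_d_class[rows, self.classes.class_of_pattern] = self._eta_d.T

    @classmethod
    def from_csv(cls, scores_path, qc_path) -> "SeqGNPED":
        qc = read_qc_matrix(qc_path)
        return cls(read_scores(scores_path, qc), qc)

    @property
    def n_examinees(self) -> int:
        return self.X.shape[0]

    def _estimate_weights(self, alpha_idx, prev: WeightTable | None) -> WeightTable:
        C, L = self._eta_c_class.shape
        w = np.full((C, L), 0.5)
        prov = np.full((C, L), DEFAULTED, dtype=np.int8)
        degenerate = self._eta_c_class == self._eta_d_class
        w[degenerate] = 1.0
        prov[degenerate] = DEGENERATE
        if prev is not None:
            keep = (~degenerate) & (prev.provenance != DEGENERATE)
            w[keep] = prev.w[keep]
        for c in range(C):
            lab = self.classes.class_of_pattern[c, alpha_idx]
            counts = np.bincount(lab, minlength=L)
            sums = np.bincount(lab, weights=self.Y[:, c], minlength=L)
            active = (counts > 0) & ~degenerate[c]
            if active.any():
                # non-degenerate cells always have (eta_c, eta_d) = (0, 1):
                # the least-squares weight is the closed form 1 - class mean
                est = 1.0 - sums[active] / counts[active]
                w[c, active] = np.clip(est, 0.0, 1.0)
                prov[c, active] = ESTIMATED
        return WeightTable(w, prov, self.classes.n_classes)

    def fit(self, eps: float = 0.001, max_iter: int = 100) -> "SeqGNPEDResults":
        """Run the iterative weight-estimation / reclassification loop.

        Parameters
        ----------
        eps : float
            Convergence threshold on the fraction of examinees whose
            assigned pattern changed between consecutive passes (strict
            ``<`` comparison).
        max_iter : int
            Cap on the number of weight-update passes.
        """
        if self.n_examinees < 1:
            raise ValueError("need at least one examinee")
        # (1) initialize by conjunctive ideal responses
        table = build_ideal_table(self.qc, self.patterns, classes=self.classes)
        alpha_idx = classify(self.Y, table)
        weights = None
        trajectory: list[float] = []
        converged = False
        n_iter = 0
        for _ in range(max_iter):
            n_iter += 1
            # (2) per-class weights from the current classification
            weights = self._estimate_weights(alpha_idx, weights)
            # (3)-(4) weighted ideal responses and reclassification
            table = build_ideal_table(
                self.qc, self.patterns, weights=weights.w, classes=self.classes
            )
            new_idx = classify(self.Y, table)
            changed = float(np.mean(new_idx != alpha_idx))
            trajectory.append(changed)
            alpha_idx = new_idx
            # (5) convergence on classification change rate
            if changed < eps:
                converged = True
                break
        return SeqGNPEDResults(
            model=self,
            pattern_index=alpha_idx,
            n_iterations=n_iter,
            converged=converged,
            change_trajectory=np.asarray(trajectory),
            weights=weights,
            ideal_table=table,
        )


@dataclass
class SeqGNPEDResults:
    """Fitted seq-GNPED classification.

    Attributes
    ----------
    pattern_index : (N,) int array
        Index of each examinee's assigned pattern in the canonical
        enumeration.
    alpha_hat : (N, K) binary array
        The assigned mastery profiles.
    weights : WeightTable
        Final per-class mixing weights.
    change_trajectory : (n_iterations,) array
        Fraction of examinees changing pattern at each pass.
    """

    model: SeqGNPED
    pattern_index: np.ndarray
    n_iterations: int
    converged: bool
    change_trajectory: np.ndarray
    weights: WeightTable
    ideal_table: IdealResponseTable

    @property
    def alpha_hat(self) -> np.ndarray:
        return self.model.patterns.patterns[self.pattern_index]

    @property
    def attribute_mastery_rate(self) -> np.ndarray:
        """Fraction of examinees classified as mastering each attribute."""
        return self.alpha_hat.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        K = self.model.qc.n_attributes
        df = pd.DataFrame(
            self.alpha_hat, columns=[f"A{k + 1}" for k in range(K)]
        )
        df.insert(0, "examinee", np.arange(1, len(df) + 1))
        return df

    def summary(self) -> str:
        m = self.model
        amr = self.attribute_mastery_rate
        lines = [
            "seq-GNPED classification results",
            "=" * 40,
            f"Examinees:            {m.n_examinees}",
            f"Items:                {m.qc.n_items}",
            f"Category cells:       {m.qc.n_categories}",
            f"Attributes (K):       {m.qc.n_attributes}",
            f"Candidate patterns:   {m.patterns.n_patterns}",
            f"Iterations:           {self.n_iterations}",
            f"Converged:            {self.converged}",
            f"Final change rate:    {self.change_trajectory[-1]:.4f}",
            "-" * 40,
            "Attribute mastery rates:",
        ]
        for k, v in enumerate(amr, start=1):
            lines.append(f"  A{k}: {v:.3f}")
        n_est = int((self.weights.provenance == ESTIMATED).sum())
        n_deg = int((self.weights.provenance == DEGENERATE).sum())
        lines += [
            "-" * 40,
            f"Weight entries estimated: {n_est}, degenerate: {n_deg}",
        ]
        return "\n".join(lines)
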