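"""Classification accuracy metrics: PAR, AAR, AMR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "pattern_accuracy",
    "attribute_accuracy",
    "attribute_mastery_rate",
    "EvaluationReport",
    "evaluate",
]


def _check_shapes(alpha_hat, alpha_true):
    a, b = np.asarray(alpha_hat), np.asarray(alpha_true)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"profile matrices must share an (N, K) shape; got {a.shape} vs {b.shape}")
    return a, b


def pattern_accuracy(alpha_hat, alpha_true) -> float:
    """PAR: fraction of examinees whose full K-vector matches exactly."""
    a, b = _check_shapes(alpha_hat, alpha_true)
    return float((a == b).all(axis=1).mean())


def attribute_accuracy(alpha_hat, alpha_true) -> float:
    """AAR: fraction of matching (examinee, attribute) cells."""
    a, b = _check_shapes(alpha_hat, alpha_true)
    return float((a == b).mean())


def attribute_mastery_rate(alpha_hat) -> np.ndarray:
    """AMR: per-attribute fraction of examinees classified as masters."""
    a = np.asarray(alpha_hat)
    if a.ndim != 2 or a.shape[0] < 1:
        raise ValueError("need an (N, K) profile matrix with N >= 1")
    return a.mean(axis=0)


@dataclass(frozen=True)
class EvaluationReport:
    par: float
    aar: float
    amr: np.ndarray
    n: int
    k: int

    def to_dict(self) -> dict:
        return {
            "par": self.par,
            "aar": self.aar,
            "amr": [float(v) for v in self.amr],
            "n": self.n,
            "k": self.k,
        }


def evaluate(alpha_hat, alpha_true) -> EvaluationReport:
    """Bundle PAR, AAR and AMR for an estimate/truth pair."""
    a, b = _check_shapes(alpha_hat, alpha_true)
    return EvaluationReport(
        par=pattern_accuracy(a, b),
        aar=attribute_accuracy(a, b),
        amr=attribute_mastery_rate(a),
        n=a.shape[0],
        k=a.shape[1],
    )
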