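"""Category-level Q-matrices, attribute patterns, and score matrices.

A polytomous item with maximum score ``S_j`` is treated as a sequence of
``S_j`` dichotomous steps ("categories"): scoring ``h`` means the examinee
completed categories ``1..h``.  The category-level Q-matrix (``Q_c``) lists,
for every (item, category) pair, which of the ``K`` binary attributes that
step requires.  This module holds the containers for that structure, the
score-to-category dichotomization, and the collapsed-class partition of the
``2^K`` attribute patterns used when estimating category weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QcMatrix",
    "PatternSpace",
    "CollapsedClassIndex",
    "read_qc_matrix",
    "write_qc_matrix",
    "read_scores",
    "write_scores",
    "dichotomize_scores",
    "undichotomize_scores",
    "build_collapsed_classes",
]

# Dense enumeration of 2^K patterns; beyond this the pattern scan is hopeless.
MAX_ATTRIBUTES = 15


@dataclass(frozen=True)
class QcMatrix:
    """Category-level attribute-requirement structure for a test.

    Parameters
    ----------
    q : ndarray of shape (n_categories, K)
        Binary requirement vectors, one row per (item, category), ordered by
        item then by category within item.
    item_of_row : ndarray of shape (n_categories,)
        0-based item index of each category row.
    cat_of_row : ndarray of shape (n_categories,)
        1-based category (step) number of each row within its item.

    Attributes
    ----------
    n_items : int
        Number of items ``J``.
    n_attributes : int
        Number of attributes ``K``.
    max_scores : ndarray of shape (J,)
        Per-item maximum score ``S_j`` (= number of categories of item j).
    """

    q: np.ndarray
    item_of_row: np.ndarray
    cat_of_row: np.ndarray
    complete: bool = field(default=True, compare=False)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=np.int8)
        if q.ndim != 2:
            raise ValueError("q must be 2-D (category rows x attributes)")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q_c entries must be 0 or 1")
        item = np.asarray(self.item_of_row, dtype=np.int64)
        cat = np.asarray(self.cat_of_row, dtype=np.int64)
        if not (len(item) == len(cat) == q.shape[0]):
            raise ValueError("row index arrays must match q's row count")
        # categories of each item must run 1..S_j in order
        for j in np.unique(item):
            cats = cat[item == j]
            if not np.array_equal(cats, np.arange(1, len(cats) + 1)):
                raise ValueError(f"item {j + 1}: categories must be 1..S_j with no gaps")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "item_of_row", item)
        object.__setattr__(self, "cat_of_row", cat)
        if (q.sum(axis=1) == 0).any():
            warnings.warn(
                "Q_c contains an all-zero category row (non-diagnostic step)",
                stacklevel=2,
            )
        covered = q.any(axis=0)
        object.__setattr__(self, "complete", bool(covered.all()))
        if not self.complete:
            missing = [k + 1 for k in np.flatnonzero(~covered)]
            warnings.warn(
                f"attributes {missing} are required by no category (incomplete Q_c)",
                stacklevel=2,
            )

    @property
    def n_items(self) -> int:
        return int(self.item_of_row.max()) + 1 if len(self.item_of_row) else 0

    @property
    def n_attributes(self) -> int:
        return self.q.shape[1]

    @property
    def n_categories(self) -> int:
        """Total number of category rows (sum of S_j)."""
        return self.q.shape[0]

    @property
    def max_scores(self) -> np.ndarray:
        return np.bincount(self.item_of_row, minlength=self.n_items)

    def item_rows(self, j: int) -> np.ndarray:
        """Row indices of item j's categories, in category order."""
        return np.flatnonzero(self.item_of_row == j)

    @classmethod
    def from_arrays(cls, categories: list[list]) -> "QcMatrix":
        """Build from a per-item list of category q-vectors."""
        rows, items, cats = [], [], []
        for j, cat_list in enumerate(categories):
            for h, qvec in enumerate(cat_list, start=1):
                rows.append(qvec)
                items.append(j)
                cats.append(h)
        return cls(np.asarray(rows), np.asarray(items), np.asarray(cats))

    def to_frame(self) -> pd.DataFrame:
        cols = {f"A{k + 1}": self.q[:, k] for k in range(self.n_attributes)}
        return pd.DataFrame(
            {"item": self.item_of_row + 1, "cat": self.cat_of_row, **cols}
        )


@dataclass(frozen=True)
class PatternSpace:
    """Canonical enumeration of all 2^K binary attribute patterns.

    Patterns are ordered by binary counting with attribute 1 as the most
    significant bit, so pattern index 0 is the all-zero profile and index
    2^K - 1 masters everything.  This fixed ordering is the tie-breaking
    order used by the classifier.
    """

    n_attributes: int

    def __post_init__(self):
        if not 1 <= self.n_attributes <= MAX_ATTRIBUTES:
            raise ValueError(
                f"K must be in [1, {MAX_ATTRIBUTES}] for a dense pattern space"
            )

    @property
    def n_patterns(self) -> int:
        return 2 ** self.n_attributes

    @property
    def patterns(self) -> np.ndarray:
        """(2^K, K) binary matrix; row m is pattern m."""
        K = self.n_attributes
        m = np.arange(2 ** K)
        return (m[:, None] >> np.arange(K - 1, -1, -1)) & 1

    def index_of(self, alpha: np.ndarray) -> np.ndarray:
        """Pattern index/indices of profile row(s) `alpha`."""
        alpha = np.atleast_2d(np.asarray(alpha, dtype=np.int64))
        K = self.n_attributes
        if alpha.shape[1] != K:
            raise ValueError("profile length must equal K")
        weights = 1 << np.arange(K - 1, -1, -1)
        idx = alpha @ weights
        return idx if idx.size > 1 else int(idx[0])


@dataclass(frozen=True)
class CollapsedClassIndex:
    """Partition of patterns into collapsed classes per category row.

    At category h of item j, only the attributes required somewhere in
    categories 1..h can influence the cumulative ideal responses; patterns
    agreeing on that relevant set are indistinguishable there and share one
    class label (and hence one weight).

    Attributes
    ----------
    relevant : list of ndarray
        Per category row, the sorted attribute indices of the relevant set.
    class_of_pattern : ndarray of shape (n_categories, 2^K)
        ``class_of_pattern[c, m]`` is the class label of pattern m at row c,
        in ``0..2^{K*_c} - 1``.
    n_classes : ndarray of shape (n_categories,)
        Number of classes (= 2^{K*_c}) per row.
    """

    relevant: list
    class_of_pattern: np.ndarray
    n_classes: np.ndarray


def build_collapsed_classes(qc: QcMatrix, patterns: PatternSpace) -> CollapsedClassIndex:
    """Group the 2^K patterns into collapsed classes at every category row.

    The relevant attribute set of category h of item j is the union of the
    requirement vectors of categories 1..h (the cumulative ideal responses
    depend on all earlier steps, not just step h itself).  Two patterns fall
    in the same class iff they agree on every relevant attribute.
    """
    if qc.n_attributes != patterns.n_attributes:
        raise ValueError("Q_c and pattern space disagree on K")
    pats = patterns.patterns
    relevant, labels, counts = [], [], []
    for c in range(qc.n_categories):
        j, h = qc.item_of_row[c], qc.cat_of_row[c]
        rows = qc.item_rows(j)[:h]
        rel = np.flatnonzero(qc.q[rows].any(axis=0))
        relevant.append(rel)
        kstar = len(rel)
        if kstar == 0:
            labels.append(np.zeros(patterns.n_patterns, dtype=np.int64))
        else:
            weights = 1 << np.arange(kstar - 1, -1, -1)
            labels.append(pats[:, rel] @ weights)
        counts.append(2 ** kstar)
    return CollapsedClassIndex(
        relevant=relevant,
        class_of_pattern=np.asarray(labels),
        n_classes=np.asarray(counts),
    )


# ---------------------------------------------------------------------------
# I/O


def read_qc_matrix(path) -> QcMatrix:
    """Read a Q_c matrix from long-format CSV.

    Expected columns: ``item,cat,A1..AK`` — one row per (item, category),
    1-based numbering, each item's categories forming 1..S_j.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "item" not in cols or "cat" not in cols:
        raise ValueError("Q_c CSV must have 'item' and 'cat' columns")
    attr_cols = [c for c in df.columns if c not in (cols["item"], cols["cat"])]
    if not attr_cols:
        raise ValueError("Q_c CSV declares no attribute columns")
    df = df.sort_values([cols["item"], cols["cat"]], kind="stable")
    if df.duplicated([cols["item"], cols["cat"]]).any():
        raise ValueError("duplicate (item, cat) pair in Q_c CSV")
    q = df[attr_cols].to_numpy()
    if not np.isin(q, (0, 1)).all():
        raise ValueError("Q_c CSV contains non-binary attribute entries")
    items_1b = df[cols["item"]].to_numpy(dtype=np.int64)
    uniq = np.unique(items_1b)
    remap = {v: i for i, v in enumerate(uniq)}
    item_idx = np.array([remap[v] for v in items_1b])
    return QcMatrix(q, item_idx, df[cols["cat"]].to_numpy(dtype=np.int64))


def write_qc_matrix(qc: QcMatrix, path) -> None:
    qc.to_frame().to_csv(path, index=False)


def read_scores(path, qc: QcMatrix | None = None) -> np.ndarray:
    """Read an N x J integer score matrix from CSV (optional header).

    If `qc` is given, scores are validated against its per-item maxima.
    """
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = first.iloc[0].astype(str).str.contains("[A-Za-z]").any()
    X = pd.read_csv(path, header=0 if has_header else None).to_numpy(dtype=np.int64)
    if qc is not None:
        validate_scores(X, qc)
    return X


def write_scores(X: np.ndarray, path) -> None:
    J = X.shape[1]
    pd.DataFrame(X, columns=[f"item{j + 1}" for j in range(J)]).to_csv(
        path, index=False
    )


def validate_scores(X: np.ndarray, qc: QcMatrix) -> None:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != qc.n_items:
        raise ValueError(f"score matrix must be N x {qc.n_items}")
    if not np.issubdtype(X.dtype, np.integer) or not np.isfinite(X.astype(float)).all():
        raise ValueError("scores must be finite integers")
    smax = qc.max_scores
    bad = (X < 0) | (X > smax[None, :])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"score X[{i},{j}]={X[i, j]} outside 0..{smax[j]} for item {j + 1}"
        )


# ---------------------------------------------------------------------------
# Score dichotomization


def dichotomize_scores(X: np.ndarray, qc: QcMatrix) -> np.ndarray:
    """Expand polytomous scores into binary category responses.

    Returns an (N, n_categories) matrix Y where the column for category h of
    item j is ``1 iff X_ij >= h``.  Within an item the columns are therefore
    non-increasing in h, and ``X_ij`` is recoverable as their sum.
    """
    X = np.asarray(X, dtype=np.int64)
    validate_scores(X, qc)
    return (X[:, qc.item_of_row] >= qc.cat_of_row[None, :]).astype(np.int8)


def undichotomize_scores(Y: np.ndarray, qc: QcMatrix) -> np.ndarray:
    """Inverse of :func:`dichotomize_scores`: X_ij = sum_h y_ijh."""
    Y = np.asarray(Y)
    X = np.zeros((Y.shape[0], qc.n_items), dtype=np.int64)
    for j in range(qc.n_items):
        X[:, j] = Y[:, qc.item_rows(j)].sum(axis=1)
    return X
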