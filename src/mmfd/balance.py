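"""From-scratch SMOTE oversampling in feature space.

Synthetic minority rows are linear interpolations ``x_new = x_i + lambda *
(x_zi - x_i)`` between a minority row and one of its k nearest same-class
neighbors, with ``lambda ~ U[0, 1)``.  Runs on standardized, flattened
feature vectors; the pipeline applies it to training rows only, after the
train/eval split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SmoteSpec", "nearest_neighbors", "smote", "smote_dataset"]


@dataclass(frozen=True)
class SmoteSpec:
    k: int = 5
    target: int | None = None  # per-class count; None = majority count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def nearest_neighbors(rows: np.ndarray, query: int, k: int) -> np.ndarray:
    """Indices of the ``k`` rows closest (Euclidean) to ``rows[query]``.

    The query row itself is excluded; distance ties break toward the lower
    index (lexicographic sort on (distance, index)).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rows = np.asarray(rows, dtype=float)
    n = len(rows)
    if k >= n:
        raise ValueError("k must be smaller than the number of rows")
    d = np.linalg.norm(rows - rows[query], axis=1)
    d[query] = np.inf
    order = np.lexsort((np.arange(n), d))  # stable: distance then index
    return order[:k]


def smote(
    rows: np.ndarray,
    labels: np.ndarray,
    spec: SmoteSpec = SmoteSpec(),
    return_parents: bool = False,
):
    """Oversample every minority class up to ``spec.target`` rows.

    Returns ``(rows_out, labels_out, synthetic_mask)`` where the first
    ``len(rows)`` entries are the untouched originals.  Minority rows are
    visited round-robin; the partner ``x_zi`` is drawn uniformly among the k
    nearest same-class neighbors; ``lambda ~ U[0, 1)``.

    With ``return_parents=True`` a fourth element is returned: one
    ``(i, zi, lam)`` triple per synthetic row (global row indices), so callers
    can audit the interpolation geometry.
    """
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels)
    if rows.ndim != 2 or len(rows) != len(labels):
        raise ValueError("rows must be 2-D and aligned with labels")
    classes, counts = np.unique(labels, return_counts=True)
    target = spec.target if spec.target is not None else int(counts.max())
    rng = np.random.default_rng(spec.seed)

    new_rows: list[np.ndarray] = []
    new_labels: list = []
    parents: list[tuple[int, int, float]] = []
    for cls, count in zip(classes, counts):
        need = target - int(count)
        if need <= 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; cannot interpolate")
        cls_idx = np.flatnonzero(labels == cls)
        cls_rows = rows[cls_idx]
        k = spec.k
        if k >= count:
            k = int(count) - 1
            warnings.warn(
                f"class {cls}: k={spec.k} >= class size {count}; clipped to {k}", stacklevel=2
            )
        neighbor_table = [nearest_neighbors(cls_rows, i, k) for i in range(len(cls_rows))]
        for j in range(need):
            i = j % len(cls_rows)  # round-robin over minority rows
            zi = neighbor_table[i][rng.integers(k)]
            lam = rng.uniform(0.0, 1.0)
            new_rows.append(cls_rows[i] + lam * (cls_rows[zi] - cls_rows[i]))
            new_labels.append(cls)
            parents.append((int(cls_idx[i]), int(cls_idx[zi]), float(lam)))

    if new_rows:
        rows_out = np.vstack([rows, np.array(new_rows)])
        labels_out = np.concatenate([labels, np.array(new_labels, dtype=labels.dtype)])
    else:
        rows_out, labels_out = rows.copy(), labels.copy()
    synthetic = np.zeros(len(rows_out), dtype=bool)
    synthetic[len(rows) :] = True
    if return_parents:
        return rows_out, labels_out, synthetic, parents
    return rows_out, labels_out, synthetic


def smote_dataset(dataset, spec: SmoteSpec = SmoteSpec()):
    """SMOTE over a :class:`~mmfd.features.FeatureDataset`.

    Both branch tensors are flattened and concatenated per row for the
    neighbor search, then unflattened; synthetic rows get provenance
    ``"smote"``.
    """
    from mmfd.features import FeatureDataset

    B = len(dataset)
    t_shape = dataset.X_t.shape[1:]
    f_shape = dataset.X_f.shape[1:]
    nt = int(np.prod(t_shape))
    flat = np.hstack([dataset.X_t.reshape(B, nt), dataset.X_f.reshape(B, -1)])
    rows_out, labels_out, synthetic = smote(flat, dataset.y, spec)
    X_t = rows_out[:, :nt].reshape(-1, *t_shape)
    X_f = rows_out[:, nt:].reshape(-1, *f_shape)
    prov = np.concatenate([dataset.provenance, np.full(synthetic.sum(), "smote")])
    return FeatureDataset(
        X_t=X_t,
        X_f=X_f,
        y=labels_out,
        provenance=prov,
        meta=dict(dataset.meta),
        scaler=dataset.scaler,
    )
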