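"""Polychotomous cell staging/grading by Mahalanobis k-nearest neighbors.

Cells are assigned a pathological category or Gleason group by plurality vote
among the k reference cells (default k=5) closest in Mahalanobis distance

    d(x0, xr) = sqrt((x0 - xr)^T Sigma^{-1} (x0 - xr)),

where Sigma is the pooled (class-agnostic) covariance of the reference
log intensities, i.e. distances are measured in standard deviations of the
reference cloud. To keep the reference portable, it is capped (default
30,000 cells) by seeded, class-stratified proportional subsampling with
largest-remainder rounding.

Neighbor search is an exhaustive scan (reference <= 30,000 cells, <= 5
markers): queries and references are whitened with the Cholesky factor of
Sigma^{-1}, after which Mahalanobis distance is plain Euclidean distance.
Distance ties are broken by reference order; a tie in the plurality vote
yields an explicit ABSTAIN rather than an arbitrary label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cohort import largest_remainder_counts
from .io import CellTable, ConfigurationError, DefinitionError

__all__ = [
    "ABSTAIN",
    "KNNModel",
    "KNNResult",
    "ConfusionReport",
    "build_knn",
    "mahalanobis_distance",
    "classify_cells",
    "knn_accuracy_heatmap",
]

ABSTAIN = "ABSTAIN"

_LABEL_SCHEMES = ("path_category", "gleason_group")
_CHUNK = 2048  # query rows per distance block, bounds peak memory


@dataclass
class KNNModel:
    """Reference cells, pooled-covariance metric, and voting parameters."""

    reference: np.ndarray
    labels: np.ndarray
    cov_inv: np.ndarray
    k: int
    label_scheme: str
    marker_names: tuple[str, ...]
    subsample_size: int
    seed: int

    @property
    def n_ref(self) -> int:
        return len(self.labels)

    def reference_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reference, columns=list(self.marker_names))
        df.insert(0, self.label_scheme, self.labels)
        return df


@dataclass
class KNNResult:
    """Assigned label (or ABSTAIN) plus neighbor bookkeeping per cell."""

    assigned: np.ndarray
    neighbor_counts: pd.DataFrame
    mean_distance: np.ndarray
    k: int
    label_scheme: str

    @property
    def abstain_mask(self) -> np.ndarray:
        return self.assigned == ABSTAIN

    @property
    def abstain_rate(self) -> float:
        return float(self.abstain_mask.mean())


@dataclass
class ConfusionReport:
    """Row-normalized confusion over classified cells, plus abstention."""

    counts: pd.DataFrame
    row_normalized: pd.DataFrame
    per_class_recall: pd.Series
    accuracy: float | None
    abstain_rate: float
    all_abstained: bool


def _stratified_subsample(
    labels: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Proportional per-class subsample indices (largest-remainder counts)."""
    classes, class_counts = np.unique(labels, return_counts=True)
    fractions = class_counts / class_counts.sum()
    take = largest_remainder_counts(fractions, cap)
    chosen: list[np.ndarray] = []
    for cls, n_take in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        if n_take >= len(idx):
            chosen.append(idx)
        else:
            chosen.append(rng.choice(idx, size=n_take, replace=False))
    return np.sort(np.concatenate(chosen))


def build_knn(
    table: CellTable,
    label_scheme: str = "path_category",
    k: int = 5,
    subsample_size: int = 30_000,
    stratify: bool = True,
    seed: int = 0,
    markers: Sequence[str] | None = None,
) -> KNNModel:
    """Build the reference set and the pooled-covariance Mahalanobis metric.

    If the table exceeds ``subsample_size`` cells, a seeded subsample is drawn
    (stratified proportionally by class unless ``stratify`` is False). The
    pooled covariance and its cached inverse are computed on the subsample.
    """
    if label_scheme not in _LABEL_SCHEMES:
        raise DefinitionError(f"label_scheme must be one of {_LABEL_SCHEMES}")
    if k < 1:
        raise DefinitionError("k must be >= 1")
    if not table.is_log:
        raise DefinitionError("k-NN stage expects a log-transformed table")
    markers = table.marker_names if markers is None else tuple(markers)
    if len(markers) < 2:
        raise DefinitionError("k-NN needs at least 2 markers")
    x = table.intensity_matrix(markers)
    labels = table.data[label_scheme].to_numpy()
    if len(x) > subsample_size:
        rng = np.random.default_rng(seed)
        if stratify:
            idx = _stratified_subsample(labels, subsample_size, rng)
        else:
            idx = np.sort(rng.choice(len(x), size=subsample_size, replace=False))
        x, labels = x[idx], labels[idx]
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ConfigurationError(
            f"a class has fewer than k={k} reference cells after subsampling"
        )
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise DefinitionError(
            "singular pooled covariance; jitter intensities or drop a collinear marker"
        ) from exc
    # guard against near-singular metrics that invert without error
    if not np.isfinite(cov_inv).all() or np.linalg.cond(cov) > 1e12:
        raise DefinitionError(
            "singular pooled covariance; jitter intensities or drop a collinear marker"
        )
    return KNNModel(
        reference=x,
        labels=labels,
        cov_inv=cov_inv,
        k=k,
        label_scheme=label_scheme,
        marker_names=tuple(markers),
        subsample_size=subsample_size,
        seed=seed,
    )


def mahalanobis_distance(
    x0: Sequence[float], xr: Sequence[float], cov_inv: np.ndarray
) -> float:
    """d = sqrt((x0-xr)^T cov_inv (x0-xr)); symmetric, zero iff x0 == xr."""
    x0 = np.asarray(x0, dtype=float)
    xr = np.asarray(xr, dtype=float)
    if x0.shape != xr.shape or cov_inv.shape != (x0.size, x0.size):
        raise DefinitionError("dimension mismatch")
    diff = x0 - xr
    return float(np.sqrt(max(diff @ cov_inv @ diff, 0.0)))


def classify_cells(model: KNNModel, table: CellTable) -> KNNResult:
    """Plurality vote among the k Mahalanobis-nearest reference cells.

    Distance ties are resolved by reference order (stable sort); a tie for
    the top vote count yields ABSTAIN. Neighbor label counts and the mean
    neighbor distance are reported per cell.
    """
    if table.n_cells == 0:
        raise DefinitionError("empty input table")
    if not table.is_log:
        raise DefinitionError("k-NN stage expects a log-transformed table")
    x = table.intensity_matrix(model.marker_names)
    # whiten: cov_inv = L L^T  =>  Mahalanobis == Euclidean on X @ L
    chol = np.linalg.cholesky(model.cov_inv)
    q = x @ chol
    r = model.reference @ chol
    classes, codes = np.unique(model.labels, return_inverse=True)
    n_classes = len(classes)
    n = len(q)
    counts = np.zeros((n, n_classes), dtype=int)
    mean_dist = np.empty(n)
    k = min(model.k, model.n_ref)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        d = cdist(q[start:stop], r)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        mean_dist[start:stop] = np.take_along_axis(d, nn, axis=1).mean(axis=1)
        neighbor_codes = codes[nn]
        for j in range(n_classes):
            counts[start:stop, j] = (neighbor_codes == j).sum(axis=1)
    top = counts.max(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    assigned = classes[np.argmax(counts, axis=1)].astype(object)
    assigned[tied] = ABSTAIN
    return KNNResult(
        assigned=np.asarray(assigned, dtype=object),
        neighbor_counts=pd.DataFrame(counts, columns=list(classes)),
        mean_distance=mean_dist,
        k=k,
        label_scheme=model.label_scheme,
    )


def knn_accuracy_heatmap(
    result: KNNResult,
    truth: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> ConfusionReport:
    """Confusion matrix, per-class recall, accuracy and abstain rate.

    Accuracy and the confusion matrix are computed over classified
    (non-abstained) cells only; the abstention rate is reported separately so
    the two numbers can be read together ("of the cells the model classified,
    this fraction was correct").
    """
    truth = np.asarray(truth, dtype=object)
    if truth.shape != result.assigned.shape:
        raise DefinitionError("truth length does not match result")
    classified = ~result.abstain_mask
    abstain_rate = float((~classified).mean())
    if class_order is None:
        class_order = sorted(set(truth))
    else:
        unknown = set(truth) - set(class_order)
        if unknown:
            raise DefinitionError(f"truth labels outside class order: {sorted(unknown)}")
        class_order = list(class_order)
    if not classified.any():
        empty = pd.DataFrame(0, index=class_order, columns=class_order)
        return ConfusionReport(
            counts=empty,
            row_normalized=empty.astype(float),
            per_class_recall=pd.Series(np.nan, index=class_order),
            accuracy=None,
            abstain_rate=1.0,
            all_abstained=True,
        )
    t = truth[classified]
    a = result.assigned[classified]
    counts = pd.crosstab(pd.Series(t, name="truth"), pd.Series(a, name="assigned"))
    counts = counts.reindex(index=class_order, columns=class_order, fill_value=0)
    row_sums = counts.sum(axis=1)
    normalized = counts.div(row_sums.replace(0, np.nan), axis=0)
    recall = pd.Series(np.diag(counts), index=class_order) / row_sums.replace(0, np.nan)
    accuracy = float((t == a).mean())
    return ConfusionReport(
        counts=counts,
        row_normalized=normalized,
        per_class_recall=recall,
        accuracy=accuracy,
        abstain_rate=abstain_rate,
        all_abstained=False,
    )
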