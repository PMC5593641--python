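"""Exploratory PCA over marker panels, optionally stratified by tissue labels.

With at most five markers per panel, components are obtained by a direct
eigendecomposition of the sample covariance (or, by default, correlation)
matrix: y_i = a_i1 x_1 + ... + a_ip x_p with orthonormal loading rows a_i and
eigenvalues in decreasing order. Correlation-matrix PCA is the default since
the channels sit on different intensity scales.

Stratified reports (per compartment, pathological category or Gleason group)
emit one decomposition per stratum plus a tidy PC1/PC2 scatter table, the
tabular equivalent of per-cell score plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellTable, DefinitionError

__all__ = ["PCAResult", "fit_pca", "project", "stratified_pca_report"]

logger = logging.getLogger(__name__)

_STRATUM_KEYS = ("compartment", "path_category", "gleason_group")


@dataclass
class PCAResult:
    """Loadings (rows = components), eigenvalues, per-cell scores.

    ``scale`` is None for covariance-matrix PCA. Sign convention: in each
    component the largest-magnitude loading is positive, making results
    deterministic across runs and platforms.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    center: np.ndarray
    scale: np.ndarray | None
    marker_names: tuple[str, ...]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def loading_frame(self) -> pd.DataFrame:
        """Loading matrix with components as rows, markers as columns."""
        return pd.DataFrame(
            self.loadings,
            index=[f"PC{i + 1}" for i in range(len(self.eigenvalues))],
            columns=list(self.marker_names),
        )


def _design(table: CellTable, markers: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    markers = table.marker_names if markers is None else tuple(markers)
    if not table.is_log:
        raise DefinitionError("PCA expects a log-transformed table")
    return table.intensity_matrix(markers), tuple(markers)


def fit_pca(
    table: CellTable,
    markers: Sequence[str] | None = None,
    standardize: bool = True,
) -> PCAResult:
    """Eigendecomposition of the sample correlation/covariance of log intensities.

    Returns as many components as markers. Eigenvalue ties keep the stable
    marker-order of the symmetric eigensolver; the sum of eigenvalues equals
    the total variance of the (scaled) input.
    """
    x, marker_names = _design(table, markers)
    n, p = x.shape
    if p < 2:
        raise DefinitionError("PCA needs at least 2 markers")
    if n < 3:
        raise DefinitionError("PCA needs at least 3 cells")
    center = x.mean(axis=0)
    scale = None
    z = x - center
    if standardize:
        scale = x.std(axis=0, ddof=1)
        if np.any(scale == 0):
            dead = [m for m, s in zip(marker_names, scale) if s == 0]
            raise DefinitionError(f"zero-variance markers under standardization: {dead}")
        z = z / scale
    s = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(s)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    loadings = eigvecs[:, order].T  # rows = components
    for i in range(p):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = z @ loadings.T
    return PCAResult(loadings, eigvals, scores, center, scale, marker_names)


def project(result: PCAResult, table: CellTable, n_components: int | None = None) -> np.ndarray:
    """Project cells onto the fitted components (centered/scaled data @ loadings^T)."""
    x, markers = _design(table, result.marker_names)
    if markers != result.marker_names:
        raise DefinitionError("marker set does not match the fitted PCA")
    z = x - result.center
    if result.scale is not None:
        z = z / result.scale
    m = len(result.eigenvalues) if n_components is None else n_components
    return z @ result.loadings[:m].T


def stratified_pca_report(
    table: CellTable,
    stratum_key: str,
    markers: Sequence[str] | None = None,
    standardize: bool = True,
    min_cells: int = 3,
) -> tuple[dict[str, PCAResult], pd.DataFrame]:
    """One PCA per stratum plus a tidy PC1/PC2 scatter table.

    Strata with fewer than ``min_cells`` cells are skipped with a logged
    warning. The scatter table carries cell id, stratum, PC1, PC2 and the
    pathological diagnosis label, ready for plotting.
    """
    if stratum_key not in _STRATUM_KEYS:
        raise DefinitionError(
            f"stratum_key must be one of {_STRATUM_KEYS}, got {stratum_key!r}"
        )
    results: dict[str, PCAResult] = {}
    scatter_parts: list[pd.DataFrame] = []
    for stratum, group in table.data.groupby(stratum_key, sort=True):
        if len(group) < min_cells:
            logger.warning(
                "skipping stratum %s=%r with %d < %d cells",
                stratum_key, stratum, len(group), min_cells,
            )
            continue
        sub = CellTable(group.reset_index(drop=True), table.marker_names, dict(table.provenance))
        res = fit_pca(sub, markers=markers, standardize=standardize)
        results[str(stratum)] = res
        scatter_parts.append(
            pd.DataFrame(
                {
                    "cell_id": group["cell_id"].to_numpy(),
                    "patient_id": group["patient_id"].to_numpy(),
                    "stratum": str(stratum),
                    "PC1": res.scores[:, 0],
                    "PC2": res.scores[:, 1] if res.scores.shape[1] > 1 else np.nan,
                    "path_category": group["path_category"].to_numpy(),
                    "gleason_group": group["gleason_group"].to_numpy(),
                }
            )
        )
    scatter = (
        pd.concat(scatter_parts, ignore_index=True)
        if scatter_parts
        else pd.DataFrame(
            columns=["cell_id", "patient_id", "stratum", "PC1", "PC2",
                     "path_category", "gleason_group"]
        )
    )
    return results, scatter
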