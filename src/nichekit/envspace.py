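"""Environmental space: predictor extraction, collinearity pruning, 2-D PCA.

The niche analyses operate in a two-dimensional principal-component space of
the bioclimatic predictors. PCA is fit on the correlation matrix of the
pooled occurrence records (both ranges) because the predictors carry
incommensurable units; an explicit loading sign convention keeps axes
reproducible across linear-algebra backends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import ClimateStack
from .learners import fit_suitability_model
from .occurrences import OccurrenceTable

__all__ = [
    "PredictorMatrix",
    "PCSpace",
    "extract_predictors",
    "variable_importance",
    "prune_collinear",
    "fit_pca",
    "project",
    "compare_predictor_means",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictorMatrix:
    """Predictor values at occurrence (or background) points; no missing values."""

    values: np.ndarray               # (n_records, P)
    layer_names: list[str]
    range_labels: np.ndarray | None = None  # per-record 'native'/'introduced', or None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.layer_names):
            raise ValueError("column count does not match layer_names")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 predictor columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("predictor matrix contains missing values")
        if self.range_labels is not None:
            self.range_labels = np.asarray(self.range_labels)
            if self.range_labels.shape[0] != self.values.shape[0]:
                raise ValueError("range_labels length mismatch")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    def subset_columns(self, names: list[str]) -> "PredictorMatrix":
        idx = [self.layer_names.index(n) for n in names]
        return PredictorMatrix(self.values[:, idx], list(names), self.range_labels)

    def subset_label(self, label: str) -> "PredictorMatrix":
        if self.range_labels is None:
            raise ValueError("matrix has no range labels")
        keep = self.range_labels == label
        return PredictorMatrix(self.values[keep], self.layer_names, self.range_labels[keep])


@dataclass
class PCSpace:
    """Standardization parameters and the first two correlation-PCA axes."""

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray             # (P, 2), unit-norm orthogonal columns
    explained_fraction: np.ndarray   # (2,) fractions of total variance
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        norms = np.linalg.norm(self.loadings, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading columns must be unit-norm")
        if abs(self.loadings[:, 0] @ self.loadings[:, 1]) > 1e-8:
            raise ValueError("loading columns must be orthogonal")
        ef = np.asarray(self.explained_fraction, dtype=float)
        if ef[0] + 1e-12 < ef[1] or ef.sum() > 1 + 1e-12 or np.any(ef < -1e-12):
            raise ValueError("explained fractions must be non-increasing and sum <= 1")


def extract_predictors(stack: ClimateStack, table: OccurrenceTable) -> PredictorMatrix:
    """Predictor values at the raster cell containing each occurrence point.

    Points off-grid or on nodata cells are dropped with a logged count.
    """
    rows, cols = stack.geometry.cell_of(table.lon, table.lat)
    on_grid = rows >= 0
    valid = np.zeros(len(table), dtype=bool)
    valid[on_grid] = stack.valid_mask[rows[on_grid], cols[on_grid]]
    dropped = int((~valid).sum())
    if dropped:
        logger.info("dropped %d occurrence points off-grid or on nodata cells", dropped)
    if not valid.any():
        raise ValueError("all occurrence points fall outside the predictor grid")
    vals = stack.values_at_cells(rows[valid], cols[valid])
    labels = table.range_labels[valid] if "range_label" in table.df else None
    return PredictorMatrix(vals, list(stack.names), labels)


def variable_importance(matrix: PredictorMatrix, background: PredictorMatrix,
                        seed: int, n_permutations: int = 5,
                        learner_id: str = "logit") -> np.ndarray:
    """Permutation importance of each predictor, in [0, 1].

    A reference suitability learner is fit on presences vs background; the
    importance of predictor p is ``1 - r`` where r is the mean Pearson
    correlation (over ``n_permutations`` seeded permutations) between the
    model's predictions on the original data and on data with column p
    permuted. Constant columns get importance 0 with a warning.
    """
    if matrix.layer_names != background.layer_names:
        raise ValueError("presence and background layer names differ")
    if matrix.n_records == 0 or background.n_records == 0:
        raise ValueError("presence and background sets must be non-empty")
    model = fit_suitability_model(learner_id, matrix.values, background.values,
                                  matrix.layer_names)
    X = np.vstack([matrix.values, background.values])
    base = model.predict(X)
    rng = np.random.default_rng(seed)
    P = X.shape[1]
    imp = np.zeros(P)
    for p in range(P):
        col = X[:, p]
        if np.ptp(col) == 0:
            warnings.warn(f"predictor {matrix.layer_names[p]!r} is constant; importance 0",
                          RuntimeWarning, stacklevel=2)
            imp[p] = 0.0
            continue
        rs = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, p] = col[rng.permutation(len(col))]
            pred = model.predict(Xp)
            if np.ptp(pred) == 0 or np.ptp(base) == 0:
                rs.append(1.0)
            else:
                rs.append(np.corrcoef(base, pred)[0, 1])
        imp[p] = 1.0 - float(np.mean(rs))
    return np.clip(imp, 0.0, 1.0)


def prune_collinear(matrix: PredictorMatrix, importances: np.ndarray,
                    r_threshold: float = 0.70) -> list[str]:
    """Iteratively drop the less-important member of the most collinear pair.

    While any pair of surviving predictors has Pearson |r| above
    ``r_threshold``, the pair with the largest |r| is found (ties broken by
    name order) and its lower-importance member removed (ties again by name
    order). Survivors are returned in their original column order.
    """
    importances = np.asarray(importances, dtype=float)
    if importances.shape[0] != len(matrix.layer_names):
        raise ValueError("importances must align with layer_names")
    names = list(matrix.layer_names)
    alive = list(range(len(names)))
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(matrix.values, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)  # constant columns correlate with nothing
    while len(alive) >= 2:
        best = None  # (|r|, i, j) with i < j in column order
        for a_idx, i in enumerate(alive):
            for j in alive[a_idx + 1:]:
                r = abs(R[i, j])
                if r > r_threshold and (best is None or r > best[0] + 1e-15):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        drop = j if importances[j] < importances[i] else (
            i if importances[i] < importances[j] else max(i, j))
        alive.remove(drop)
    if len(alive) < 2:
        warnings.warn("collinearity pruning left fewer than 2 predictors",
                      RuntimeWarning, stacklevel=2)
    return [names[i] for i in alive]


def fit_pca(matrix: PredictorMatrix) -> PCSpace:
    """Correlation-matrix PCA; returns the first two axes.

    Columns are standardized to zero mean and unit variance; loadings are the
    leading two eigenvectors of the correlation matrix, each flipped so its
    largest-magnitude entry is positive; explained fractions are the leading
    eigenvalues divided by P (the trace of a correlation matrix).
    """
    X = matrix.values
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 records")
    sds = X.std(axis=0, ddof=1)
    zero = np.where(sds == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance predictor column: {matrix.layer_names[zero[0]]!r}")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    loadings = evecs[:, :2].copy()
    for k in range(2):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    explained = np.clip(evals[:2], 0.0, None) / X.shape[1]
    return PCSpace(means, sds, loadings, explained, list(matrix.layer_names))


def project(space: PCSpace, matrix: PredictorMatrix) -> np.ndarray:
    """Project records into the 2-D PC space: ((x - mean)/sd) @ loadings."""
    if space.layer_names and matrix.layer_names != space.layer_names:
        raise ValueError("layer names do not match the fitted PC space")
    Z = (matrix.values - space.means) / space.sds
    return Z @ space.loadings


def compare_predictor_means(native_values: np.ndarray,
                            introduced_values: np.ndarray) -> tuple[float, float, float, float]:
    """Welch two-sided t-test on a predictor between ranges.

    Returns (t statistic, p-value, mean_native, mean_introduced); the sign of
    t follows native minus introduced.
    """
    a = np.asarray(native_values, dtype=float)
    b = np.asarray(introduced_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), float(a.mean()), float(b.mean())
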