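"""Suitability modelling: pseudo-absences, split evaluation, TSS-weighted ensemble.

Presence-only occurrence data are contrasted against pseudo-absences (PAs)
drawn uniformly from valid non-presence raster cells. Each learner is
evaluated by repeated stratified 70/30 split sampling with AUC, and with the
true skill statistic (TSS) and Cohen's kappa computed at the
maximum-sensitivity-plus-specificity (MSS) threshold of the held-out scores.
Models passing the retention rule (TSS > 0.7 or AUC > 0.8) enter an ensemble
whose per-cell suitability is the TSS-weighted mean of member predictions;
the ensemble map is classified into unsuitable / low / moderate / high bands
at 0.2, 0.4 and 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import ClimateStack, GridGeometry
from .learners import SuitabilityModel, fit_suitability_model
from .occurrences import OccurrenceTable

__all__ = [
    "PseudoAbsenceSet",
    "ModelEval",
    "SuitabilityMap",
    "generate_pseudo_absences",
    "fit_suitability_model",
    "evaluate_split",
    "auc",
    "confusion_metrics",
    "mss_threshold",
    "ensemble_predict",
    "classify_suitability",
    "SUITABILITY_BINS",
    "SUITABILITY_CLASSES",
]

logger = logging.getLogger(__name__)

# class boundaries for suitability bands: <0.2 unsuitable, 0.2-0.4 low,
# 0.4-0.6 moderate, >0.6 high
SUITABILITY_BINS = (0.2, 0.4, 0.6)
SUITABILITY_CLASSES = ("unsuitable", "low", "moderate", "high")


@dataclass
class PseudoAbsenceSet:
    """Random background points on valid, non-presence cells."""

    points: np.ndarray  # (n, 2) lon/lat of cell centers
    set_id: int
    seed: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class ModelEval:
    """One evaluation repeat of one learner."""

    model_id: str
    repeat_id: int
    auc: float
    tss: float
    kappa: float
    retained: bool = field(init=False)

    def __post_init__(self) -> None:
        self.retained = (self.tss > 0.7) or (self.auc > 0.8)


@dataclass
class SuitabilityMap:
    """Ensemble suitability in [0, 1] per valid cell, plus class bands."""

    geometry: GridGeometry
    values: np.ndarray        # (nrows, ncols), NaN on nodata
    class_map: np.ndarray     # (nrows, ncols) int8: -1 nodata, 0..3 per SUITABILITY_CLASSES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError("values shape does not match geometry")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


def classify_suitability(values: np.ndarray) -> np.ndarray:
    """Band codes per SUITABILITY_CLASSES; -1 where the value is NaN."""
    v = np.asarray(values, dtype=float)
    cls = np.full(v.shape, -1, dtype=np.int8)
    ok = np.isfinite(v)
    cls[ok & (v < SUITABILITY_BINS[0])] = 0
    cls[ok & (v >= SUITABILITY_BINS[0]) & (v < SUITABILITY_BINS[1])] = 1
    cls[ok & (v >= SUITABILITY_BINS[1]) & (v <= SUITABILITY_BINS[2])] = 2
    cls[ok & (v > SUITABILITY_BINS[2])] = 3
    return cls


def default_n_pa(n_presences: int) -> int:
    """1000 PAs when there are at most 1000 presences, else one per presence."""
    return 1000 if n_presences <= 1000 else n_presences


def generate_pseudo_absences(stack: ClimateStack, presences: OccurrenceTable,
                             n_pa: int | None = None, n_sets: int = 2,
                             seed: int = 0) -> list[PseudoAbsenceSet]:
    """Draw ``n_sets`` independent PA sets uniformly over valid non-presence cells.

    Each set is sampled without replacement; sets use distinct sub-seeds
    derived from (seed, set_id) so runs are reproducible yet sets differ.
    """
    rows, cols = stack.geometry.cell_of(presences.lon, presences.lat)
    on = rows >= 0
    presence_cells = np.zeros((stack.geometry.nrows, stack.geometry.ncols), dtype=bool)
    presence_cells[rows[on], cols[on]] = True
    candidates = stack.valid_mask & ~presence_cells
    cand_rows, cand_cols = np.nonzero(candidates)
    if n_pa is None:
        n_pa = default_n_pa(len(presences))
    if cand_rows.size < n_pa:
        raise ValueError(f"only {cand_rows.size} valid non-presence cells for {n_pa} PAs")
    out = []
    for set_id in range(n_sets):
        rng = np.random.default_rng([seed, set_id])
        pick = rng.choice(cand_rows.size, size=n_pa, replace=False)
        lon, lat = stack.geometry.cell_centers(cand_rows[pick], cand_cols[pick])
        out.append(PseudoAbsenceSet(np.column_stack([lon, lat]), set_id, seed))
    return out


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion_metrics(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, TSS, kappa) from binary predictions.

    TSS = sensitivity + specificity - 1; kappa uses the standard
    marginal-product expected agreement.
    """
    pred = np.asarray(pred, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    if tp + fn == 0:
        raise ValueError("no positive labels: sensitivity margin is degenerate")
    if tn + fp == 0:
        raise ValueError("no negative labels: specificity margin is degenerate")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if p_e == 1.0:
        raise ValueError("expected agreement is 1: kappa margin is degenerate")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return sens, spec, tss, kappa


def mss_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity under ``score >= t``.

    Candidates are the unique observed scores; ties resolve to the smallest
    threshold. With only positive labels every case should be predicted
    present, so the minimum score is returned; with no positive labels the
    threshold is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0:
        raise ValueError("MSS threshold undefined without positive labels")
    if n0 == 0:
        return float(scores.min())
    cands = np.unique(scores)
    best_t, best_ss = cands[0], -np.inf
    for t in cands:
        pred = scores >= t
        sens = (pred & labels).sum() / n1
        spec = (~pred & ~labels).sum() / n0
        ss = sens + spec
        if ss > best_ss + 1e-12:
            best_t, best_ss = t, ss
    return float(best_t)


def evaluate_split(learner_id: str, presences, absences,
                   train_fraction: float = 0.7, repeats: int = 4,
                   seed: int = 0, layer_names: list[str] | None = None) -> list[ModelEval]:
    """Repeated stratified split evaluation of one learner.

    Each repeat draws a stratified ``train_fraction`` / remainder split of
    presence and absence rows, fits the learner on the training part and
    scores the held-out part; AUC is threshold-free while TSS and kappa are
    taken at the MSS threshold of the held-out scores. Deterministic per seed.
    """
    P = np.asarray(getattr(presences, "values", presences), dtype=float)
    A = np.asarray(getattr(absences, "values", absences), dtype=float)
    if len(P) < 4 or len(A) < 4:
        raise ValueError("each class needs at least 4 records for split evaluation")
    rng = np.random.default_rng(seed)
    evals = []
    for rep in range(repeats):
        for attempt in range(10):
            ip = rng.permutation(len(P))
            ia = rng.permutation(len(A))
            kp = int(round(train_fraction * len(P)))
            ka = int(round(train_fraction * len(A)))
            kp = min(max(kp, 1), len(P) - 1)
            ka = min(max(ka, 1), len(A) - 1)
            train_p, test_p = P[ip[:kp]], P[ip[kp:]]
            train_a, test_a = A[ia[:ka]], A[ia[ka:]]
            if len(test_p) and len(test_a):
                break
            logger.info("re-drawing split %d: a class was absent from the test part", rep)
        else:
            raise RuntimeError("could not draw a split with both classes in the test part")
        model = fit_suitability_model(learner_id, train_p, train_a, layer_names)
        scores = np.concatenate([model.predict(test_p), model.predict(test_a)])
        labels = np.concatenate([np.ones(len(test_p), bool), np.zeros(len(test_a), bool)])
        t = mss_threshold(scores, labels)
        _, _, tss, kappa = confusion_metrics(scores >= t, labels)
        evals.append(ModelEval(learner_id, rep, auc(scores, labels), tss, kappa))
    return evals


def ensemble_predict(models: list[SuitabilityModel], tss_weights: np.ndarray,
                     stack: ClimateStack) -> SuitabilityMap:
    """TSS-weighted mean of member suitability maps over the stack's valid cells."""
    tss_weights = np.asarray(tss_weights, dtype=float)
    if len(models) == 0:
        raise ValueError("no retained models to ensemble")
    if tss_weights.shape[0] != len(models):
        raise ValueError("weights must align with models")
    if np.any(tss_weights <= 0):
        raise ValueError("ensemble weights must be positive")
    valid = stack.valid_mask
    rows, cols = np.nonzero(valid)
    num = np.zeros(rows.size)
    for model, w in zip(models, tss_weights):
        X = stack.subset(model.layer_names).values_at_cells(rows, cols)
        num += w * model.predict(X)
    vals = np.full(valid.shape, np.nan)
    vals[rows, cols] = num / tss_weights.sum()
    return SuitabilityMap(stack.geometry, vals, classify_suitability(vals))
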