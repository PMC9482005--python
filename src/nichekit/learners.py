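"""Reference suitability learners behind a uniform contract.

Ecological niche modelling platforms fit many algorithms; this package keeps
the surrounding machinery (pseudo-absences, split evaluation, TSS-weighted
ensembles, MSS thresholding) and exposes two mathematically simple reference
learners behind one contract, so third-party learners can be plugged in:

* ``logit`` — ridge-penalized (lambda = 1e-4) maximum-likelihood logistic
  discriminant on standardized predictors, with the two classes weighted to
  contribute equally to the loss regardless of their counts.
* ``envelope`` — Gaussian envelope: suitability exp(-Mahalanobis^2 / 2) to
  the presence mean and covariance, rescaled by its maximum over the
  presence set and clipped to [0, 1].

Both return calibrated scores in [0, 1] via ``predict``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["SuitabilityModel", "LogitModel", "EnvelopeModel", "fit_suitability_model",
           "LEARNERS", "RIDGE_LAMBDA"]

RIDGE_LAMBDA = 1e-4


@dataclass
class SuitabilityModel:
    """A fitted suitability function over named predictor columns."""

    learner_id: str
    layer_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class LogitModel(SuitabilityModel):
    mean_: np.ndarray
    sd_: np.ndarray
    coef_: np.ndarray
    intercept_: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.sd_
        eta = Z @ self.coef_ + self.intercept_
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class EnvelopeModel(SuitabilityModel):
    mean_: np.ndarray
    precision_: np.ndarray
    presence_max_: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = np.asarray(X, dtype=float) - self.mean_
        m2 = np.einsum("...i,ij,...j->...", d, self.precision_, d)
        return np.clip(np.exp(-0.5 * m2) / self.presence_max_, 0.0, 1.0)


def _fit_logit(presences: np.ndarray, absences: np.ndarray,
               layer_names: list[str]) -> LogitModel:
    X = np.vstack([presences, absences])
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(absences))])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    # balanced class weights: each class contributes n/2 effective samples
    clf = LogisticRegression(C=1.0 / RIDGE_LAMBDA, class_weight="balanced",
                             solver="lbfgs", max_iter=10_000, tol=1e-12)
    clf.fit(Z, y)
    return LogitModel("logit", list(layer_names), mean, sd,
                      clf.coef_.ravel().copy(), float(clf.intercept_[0]))


def _fit_envelope(presences: np.ndarray, layer_names: list[str]) -> EnvelopeModel:
    mu = presences.mean(axis=0)
    cov = np.cov(presences, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        prec = np.linalg.inv(cov)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
    except np.linalg.LinAlgError:
        warnings.warn("singular presence covariance; applying 1e-6 * I shrinkage",
                      RuntimeWarning, stacklevel=3)
        prec = np.linalg.inv(cov + 1e-6 * np.eye(cov.shape[0]))
    d = presences - mu
    m2 = np.einsum("ni,ij,nj->n", d, prec, d)
    pmax = float(np.exp(-0.5 * m2).max())
    return EnvelopeModel("envelope", list(layer_names), mu, prec, pmax)


def fit_suitability_model(learner_id: str, presences: np.ndarray, absences: np.ndarray,
                          layer_names: list[str] | None = None) -> SuitabilityModel:
    """Fit a reference learner on presence vs (pseudo-)absence predictor rows."""
    presences = np.asarray(presences, dtype=float)
    absences = np.asarray(absences, dtype=float)
    if presences.size == 0 or absences.size == 0:
        raise ValueError("both presence and absence sets must be non-empty")
    if layer_names is None:
        layer_names = [f"x{i}" for i in range(presences.shape[1])]
    if learner_id == "logit":
        return _fit_logit(presences, absences, layer_names)
    if learner_id == "envelope":
        return _fit_envelope(presences, layer_names)
    raise ValueError(f"unknown learner {learner_id!r}; available: logit, envelope")


LEARNERS = ("logit", "envelope")
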