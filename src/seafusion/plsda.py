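"""Two-class PLS-DA with VIP scores and venetian-blind paired cross-validation.

PLS-DA regresses a +/-1 class response on the (pair-centered, autoscaled)
feature matrix via NIPALS PLS1 and classifies by the sign of the
prediction (control = +1; an exact 0 is broken to control and logged).
Cross-validation follows the paired design: each fold removes one day's
control/treated pair ("venetian blind with paired deletion groups"), the
pair-centering is fold-safe by construction, and the autoscaling
parameters are re-estimated on the training samples of every fold so no
information leaks from the held-out pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Y_CODING = {"control": 1.0, "treated": -1.0}


class PLSDAError(ValueError):
    pass


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int,
            tol: float = 1e-12):
    """NIPALS PLS1: returns (W, P, T, q) with unit-norm weight vectors."""
    Xd = X.astype(float).copy()
    yd = y.astype(float).copy()
    n, p = Xd.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    a = 0
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= tol:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        W[:, a], T[:, a] = w, t
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yd @ t) / tt
        Xd -= np.outer(t, P[:, a])
        yd = yd - q[a] * t
    else:
        a = n_lv
    if a < n_lv:
        W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
    return W, P, T, q


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray,
                  n_lv: int) -> np.ndarray:
    """Regression vector using the first ``n_lv`` latent variables."""
    Wa, Pa, qa = W[:, :n_lv], P[:, :n_lv], q[:n_lv]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model on autoscaled data."""

    n_lv: int
    weights: np.ndarray  # p x A, unit-norm columns
    x_loadings: np.ndarray  # p x A
    scores: np.ndarray  # n x A
    y_loadings: np.ndarray  # A
    coefficients: np.ndarray  # p
    feature_ids: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_coding: dict[str, float] = field(default_factory=lambda: dict(Y_CODING))

    @property
    def ssy(self) -> np.ndarray:
        """Y-variance explained per latent variable."""
        tt = np.einsum("ia,ia->a", self.scores, self.scores)
        return self.y_loadings ** 2 * tt


def plsda_fit(X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series,
              n_lv: int) -> PLSDAModel:
    """Fit PLS-DA on preprocessed data (already pair-centered + autoscaled).

    ``y`` must take both class values (+1/-1); ``n_lv`` may not exceed the
    rank of ``X``.
    """
    ids = (list(X.columns) if isinstance(X, pd.DataFrame)
           else [f"x{j}" for j in range(np.asarray(X).shape[1])])
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(np.unique(np.sign(ya))) < 2:
        raise PLSDAError("y contains a single class")
    rank = np.linalg.matrix_rank(Xa)
    if not 1 <= n_lv <= rank:
        raise PLSDAError(f"n_lv={n_lv} outside [1, rank={rank}]")
    W, P, T, q = _nipals(Xa, ya, n_lv)
    if W.shape[1] < n_lv:
        raise PLSDAError(f"deflation exhausted after {W.shape[1]} LVs")
    b = _coefficients(W, P, q, n_lv)
    return PLSDAModel(n_lv=n_lv, weights=W, x_loadings=P, scores=T,
                      y_loadings=q, coefficients=b, feature_ids=ids,
                      x_mean=np.zeros(Xa.shape[1]),
                      x_scale=np.ones(Xa.shape[1]))


def plsda_predict(model: PLSDAModel, X_new: pd.DataFrame | np.ndarray,
                  return_scores: bool = False):
    """Predict class values: sign of ``X_new @ b`` (0 -> control, logged)."""
    Xa = np.asarray(X_new, dtype=float)
    if Xa.shape[1] != len(model.coefficients):
        raise PLSDAError(
            f"feature mismatch: model has {len(model.coefficients)}, "
            f"input has {Xa.shape[1]}")
    Xs = (Xa - model.x_mean) / model.x_scale
    yhat = Xs @ model.coefficients
    labels = np.where(yhat > 0, 1.0, -1.0)
    ties = yhat == 0
    if ties.any():
        log.warning("prediction tie (y_hat = 0) for %d sample(s); "
                    "assigned to control", int(ties.sum()))
        labels[ties] = 1.0
    return (labels, yhat) if return_scores else labels


def vip(model: PLSDAModel) -> pd.Series:
    """Variable Importance in Projection.

    ``VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a)`` with unit-norm
    weights; squared VIPs sum to the number of features.
    """
    ssy = model.ssy
    total = ssy.sum()
    if total <= 0:
        raise PLSDAError("model explains no Y-variance; VIP undefined")
    p = model.weights.shape[0]
    v = np.sqrt(p * (model.weights ** 2 @ ssy) / total)
    return pd.Series(v, index=model.feature_ids, name="VIP")


@dataclass
class CVResult:
    folds: list[tuple[str, ...]]
    error_by_nlv: pd.Series  # classification error, indexed by n_lv
    rmsecv_by_nlv: pd.Series  # root-mean-square error of the y prediction
    best_nlv: int
    accuracy_cv: float  # percent, at best_nlv
    predictions: pd.Series  # out-of-fold predicted class value per sample

    @property
    def error(self) -> float:
        return float(self.error_by_nlv.loc[self.best_nlv])

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_by_nlv.loc[self.best_nlv])


def _scale_train_test(Xtr: np.ndarray, Xte: np.ndarray):
    """Autoscale with training statistics; inert (constant) columns get
    unit scale so they contribute nothing rather than blow up."""
    m = Xtr.mean(axis=0)
    s = Xtr.std(axis=0, ddof=1)
    s = np.where(s <= 1e-12, 1.0, s)
    return (Xtr - m) / s, (Xte - m) / s


def venetian_blind_cv(X: pd.DataFrame, y: pd.Series,
                      pairing: dict[int, tuple[str, str]],
                      max_lv: int = 5) -> CVResult:
    """Paired venetian-blind CV: one fold per day-pair.

    ``X`` is the pair-centered (unscaled) matrix; within each fold the
    autoscaling is re-estimated on the training pairs only. Returns the
    classification error for 1..max_lv latent variables; the best count is
    the argmin with ties broken toward fewer LVs.
    """
    if max_lv < 1:
        raise PLSDAError("max_lv must be >= 1")
    ids = list(X.index)
    covered = {s for pair in pairing.values() for s in pair}
    if covered != set(ids):
        raise PLSDAError("pairing does not cover the sample set exactly")
    pos = {s: i for i, s in enumerate(ids)}
    Xa = X.to_numpy(dtype=float)
    ya = y.reindex(ids).to_numpy(dtype=float)
    folds = [tuple(pairing[d]) for d in sorted(pairing)]
    max_lv = min(max_lv, len(ids) - 2)  # training rank bound
    preds = np.full((len(ids), max_lv), np.nan)
    for fold in folds:
        te = [pos[s] for s in fold]
        tr = [i for i in range(len(ids)) if i not in te]
        Xtr, Xte = _scale_train_test(Xa[tr], Xa[te])
        W, P, T, q = _nipals(Xtr, ya[tr], max_lv)
        avail = W.shape[1]
        for a in range(1, max_lv + 1):
            b = _coefficients(W, P, q, min(a, avail))
            preds[te, a - 1] = Xte @ b
    errors = {}
    rmse = {}
    for a in range(1, max_lv + 1):
        labels = np.where(preds[:, a - 1] > 0, 1.0, -1.0)
        errors[a] = float(np.mean(labels != np.sign(ya)))
        rmse[a] = float(np.sqrt(np.mean((preds[:, a - 1] - ya) ** 2)))
    error_by_nlv = pd.Series(errors, name="cv_error")
    best = int(error_by_nlv.idxmin())  # ties -> smallest n_lv
    return CVResult(
        folds=folds,
        error_by_nlv=error_by_nlv,
        rmsecv_by_nlv=pd.Series(rmse, name="rmsecv"),
        best_nlv=best,
        accuracy_cv=100.0 * (1.0 - error_by_nlv.loc[best]),
        predictions=pd.Series(preds[:, best - 1], index=ids,
                              name="y_hat_cv"),
    )


def fit_autoscaled(X: pd.DataFrame, y: pd.Series, n_lv: int) -> PLSDAModel:
    """Autoscale ``X`` globally, fit PLS-DA, and store the scaling in the
    model so prediction accepts pair-centered (unscaled) input."""
    m = X.mean(axis=0).to_numpy()
    s = X.std(axis=0, ddof=1).to_numpy()
    s = np.where(s <= 1e-12, 1.0, s)
    Xs = (X.to_numpy(dtype=float) - m) / s
    model = plsda_fit(pd.DataFrame(Xs, index=X.index, columns=X.columns),
                      y.reindex(X.index), n_lv)
    model.x_mean = m
    model.x_scale = s
    return model
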