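"""PLS regression / discriminant analysis and the supporting chemometrics.

The central model is single-response partial least squares (PLS1), fitted by
the NIPALS recursion on centred (optionally autoscaled) data.  With one
response column the NIPALS inner loop is exact in a single pass: each latent
variable's weight vector is the (deflated) covariance ``X' y`` normalised to
unit length.  Coefficients and intercept are always returned on the original
scale, so prediction is a plain affine map ``y = X b + b0``.

Around the model sit latent-variable selection by leave-one-out
cross-validation, residual-based outlier screening, SPXY (Kennard-Stone on
joint X-y distances) sample-set partitioning, PLS-DA with 1/2 dummy coding
and the 0.5/1.5/2.5 decision rule, and the R2/RMSE/accuracy metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PLSModel",
    "ModelMetrics",
    "SplitResult",
    "fit_plsr",
    "predict",
    "predict_by_scores",
    "select_lv_loocv",
    "detect_outliers",
    "spxy_split",
    "fit_plsda",
    "classify_plsda",
    "regression_metrics",
    "metrics",
    "accuracy",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
]

HEALTHY, DAMAGED, UNCLASSIFIED = 1, 2, 0


@dataclass
class PLSModel:
    """Fitted PLS model with original-scale coefficients.

    ``weights``, ``x_loadings`` are (p, a); ``y_loadings`` is (a,).
    ``mode`` is "regression" or "discriminant" (dummy-coded 1/2 response).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray | None
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str] | None = None
    mode: str = "regression"
    metadata: dict = field(default_factory=dict)


@dataclass
class ModelMetrics:
    """Calibration/prediction R2 and RMSE in response units."""

    r2_cal: float
    rmse_cal: float
    n_cal: int
    r2_pred: float | None = None
    rmse_pred: float | None = None
    n_pred: int | None = None

    def as_dict(self) -> dict:
        return {
            "r2_cal": self.r2_cal,
            "rmse_cal": self.rmse_cal,
            "n_cal": self.n_cal,
            "r2_pred": self.r2_pred,
            "rmse_pred": self.rmse_pred,
            "n_pred": self.n_pred,
        }


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray


# ---------------------------------------------------------------------------
# core PLS1
# ---------------------------------------------------------------------------

def _pls1_core(Xc: np.ndarray, yc: np.ndarray, n_lv: int, tol: float = 1e-12):
    """NIPALS PLS1 on already centred/scaled data.

    Returns (W, P, q) with shapes (p, a), (p, a), (a,); ``a`` may fall short
    of ``n_lv`` when the residual X (or its covariance with y) vanishes.
    """
    X = Xc.copy()
    y = yc.copy()
    p = X.shape[1]
    W, P, q = [], [], []
    for _ in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt < tol:
            break
        pl = X.T @ t / tt
        ql = float(y @ t / tt)
        X -= np.outer(t, pl)
        y = y - ql * t
        W.append(w)
        P.append(pl)
        q.append(ql)
    a = len(W)
    if a == 0:
        return np.zeros((p, 0)), np.zeros((p, 0)), np.zeros(0)
    return np.column_stack(W), np.column_stack(P), np.asarray(q)


def _pls1_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vector (centred/scaled space) from the LV decomposition."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    # R = W (P'W)^-1 maps X directly to scores; beta = R q
    R = np.linalg.solve((P.T @ W).T, W.T).T
    return R @ q


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scale: bool = False,
    feature_names: list[str] | None = None,
) -> PLSModel:
    """Fit PLS1 regression; coefficients returned on the original scale.

    ``scale=True`` autoscales columns (unit sample sd) before the
    decomposition -- appropriate for tables with heterogeneous units such
    as fluorescence parameters; spectral matrices are centred only.
    A requested ``n_lv`` beyond the achievable rank fits what is achievable
    and warns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = None
    Xc = (X - x_mean) / (x_scale if x_scale is not None else 1.0)
    W, P, q = _pls1_core(Xc, y - y_mean, n_lv)
    if W.shape[1] < n_lv:
        warnings.warn(
            f"rank allowed only {W.shape[1]} of {n_lv} latent variables",
            stacklevel=2,
        )
    beta = _pls1_coefficients(W, P, q)
    coef = beta / (x_scale if x_scale is not None else 1.0)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_lv=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        intercept=intercept,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Affine prediction ``X @ coefficients + intercept``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coefficients.size:
        if model.feature_names is not None:
            raise ValueError(
                f"feature count {X.shape[1]} does not match model features "
                f"{model.feature_names}"
            )
        raise ValueError("feature count does not match the model")
    return X @ model.coefficients + model.intercept


def predict_by_scores(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Prediction via the latent-variable score recursion.

    Numerically equivalent to :func:`predict`; kept as the independent
    route for verifying the coefficient collapse.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = (X - model.x_mean) / (model.x_scale if model.x_scale is not None else 1.0)
    yhat = np.full(X.shape[0], model.y_mean)
    for a in range(model.weights.shape[1]):
        t = Xc @ model.weights[:, a]
        Xc = Xc - np.outer(t, model.x_loadings[:, a])
        yhat = yhat + model.y_loadings[a] * t
    return yhat


def select_lv_loocv(
    X: np.ndarray, y: np.ndarray, max_lv: int, scale: bool = False
) -> tuple[int, np.ndarray]:
    """Optimal LV count by leave-one-out cross-validation.

    Returns ``(n_lv, rmsecv)`` where ``rmsecv[a-1]`` is the LOO RMSE with
    ``a`` latent variables; ties go to the smaller count (``argmin`` takes
    the first minimum).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_lv < 1 or max_lv > min(n - 2, p):
        raise ValueError(f"max_lv must be in [1, min(n-2, p)] = [1, {min(n - 2, p)}]")
    sq_err = np.zeros((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, yt = X[tr], y[tr]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        if scale:
            sd = Xt.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
        else:
            sd = 1.0
        W, P, q = _pls1_core((Xt - x_mean) / sd, yt - y_mean, max_lv)
        xc = (X[i] - x_mean) / sd
        pred = y_mean
        for a in range(max_lv):
            if a < W.shape[1]:
                t = float(xc @ W[:, a])
                xc = xc - t * P[:, a]
                pred = pred + q[a] * t
            sq_err[i, a] = (y[i] - pred) ** 2
    rmsecv = np.sqrt(sq_err.mean(axis=0))
    return int(np.argmin(rmsecv)) + 1, rmsecv


def detect_outliers(
    X: np.ndarray, y: np.ndarray, n_lv: int, k_sd: float = 3.0, scale: bool = False
) -> np.ndarray:
    """Single-pass residual screen on a fit to all samples.

    Flags samples whose absolute residual from the all-sample PLSR exceeds
    ``k_sd`` residual standard deviations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 10:
        raise ValueError("outlier screening needs at least 10 samples")
    model = fit_plsr(X, y, n_lv, scale=scale)
    resid = y - predict(model, X)
    sd = resid.std(ddof=1)
    if not np.isfinite(k_sd):
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(resid) > k_sd * sd)


# ---------------------------------------------------------------------------
# SPXY partitioning
# ---------------------------------------------------------------------------

def spxy_split(X: np.ndarray, y: np.ndarray, calibration_fraction: float) -> SplitResult:
    """Kennard-Stone max-min selection on normalised joint X-y distances.

    The joint distance is ``d_X(i,j)/max d_X + d_y(i,j)/max d_y`` with
    Euclidean components.  The first two calibration picks are the pair at
    maximal joint distance; thereafter the sample farthest (in min-distance
    sense) from the current calibration set is added until the calibration
    set holds ``round(fraction * n)`` samples.  Fully deterministic; ties
    break toward the lowest index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to split")
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must be in (0, 1)")
    n_cal = int(round(calibration_fraction * n))
    n_cal = min(max(n_cal, 2), n - 1)
    dx = cdist(X, X)
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        warnings.warn("all samples identical; split is arbitrary", stacklevel=2)
        d = np.zeros((n, n))
    else:
        d = (dx / mx if mx > 0 else 0.0) + (dy / my if my > 0 else 0.0)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    selected = [min(i, j), max(i, j)] if i != j else [0, 1]
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, d[nxt])
        min_dist[nxt] = -np.inf
    cal = np.sort(np.asarray(selected))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    n_lv: int,
    scale: bool = False,
    feature_names: list[str] | None = None,
) -> PLSModel:
    """PLS-DA as PLS1 regression on the 1/2 dummy response.

    Class 1 is "healthy", class 2 "glyphosate phytotoxicity damage".
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.array_equal(classes, [HEALTHY, DAMAGED]):
        if classes.size < 2:
            raise ValueError("PLS-DA requires both classes present")
        raise ValueError("labels must be dummy-coded 1 (healthy) / 2 (damaged)")
    model = fit_plsr(X, labels.astype(float), n_lv, scale=scale, feature_names=feature_names)
    model.mode = "discriminant"
    return model


def classify_plsda(model: PLSModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the 0.5/1.5/2.5 decision rule to PLS-DA predictions.

    Predicted values in (0.5, 1.5] are class 1, in (1.5, 2.5] class 2
    (boundaries upper-inclusive); anything else is unclassified (0) and
    counts as incorrect in accuracy.  Returns ``(labels, valid)``.
    """
    if model.mode != "discriminant":
        raise ValueError("model is not a discriminant (PLS-DA) model")
    yhat = predict(model, X)
    labels = np.full(yhat.shape, UNCLASSIFIED, dtype=int)
    labels[(yhat > 0.5) & (yhat <= 1.5)] = HEALTHY
    labels[(yhat > 1.5) & (yhat <= 2.5)] = DAMAGED
    return labels, labels != UNCLASSIFIED


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def regression_metrics(y_true: np.ndarray, y_hat: np.ndarray) -> tuple[float, float]:
    """``(R2, RMSE)`` with R2 = 1 - SS_res/SS_tot and RMSE over n."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size != y_hat.size or y_true.size < 2:
        raise ValueError("metrics need two equal-length vectors, n >= 2")
    ss_res = float(np.sum((y_true - y_hat) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmse = float(np.sqrt(ss_res / y_true.size))
    return r2, rmse


def metrics(
    y_cal: np.ndarray,
    y_cal_hat: np.ndarray,
    y_pred: np.ndarray | None = None,
    y_pred_hat: np.ndarray | None = None,
) -> ModelMetrics:
    """Bundle calibration (and optionally prediction) R2/RMSE."""
    r2c, rmsec = regression_metrics(y_cal, y_cal_hat)
    out = ModelMetrics(r2_cal=r2c, rmse_cal=rmsec, n_cal=len(np.ravel(y_cal)))
    if y_pred is not None:
        r2p, rmsep = regression_metrics(y_pred, y_pred_hat)
        out.r2_pred, out.rmse_pred, out.n_pred = r2p, rmsep, len(np.ravel(y_pred))
    return out


def accuracy(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    """Fraction of correctly classified samples (unclassified never matches)."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(labels_true == labels_pred))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_json(model: PLSModel) -> dict:
    return {
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "x_scale": None if model.x_scale is None else model.x_scale.tolist(),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "feature_names": model.feature_names,
        "mode": model.mode,
        "metadata": model.metadata,
    }


def model_from_json(obj: dict) -> PLSModel:
    p = len(obj["coefficients"])
    return PLSModel(
        n_lv=int(obj["n_lv"]),
        x_mean=np.asarray(obj.get("x_mean") or np.zeros(p), dtype=float),
        y_mean=float(obj.get("y_mean", 0.0)),
        x_scale=(
            None
            if obj.get("x_scale") is None
            else np.asarray(obj["x_scale"], dtype=float)
        ),
        weights=np.asarray(obj.get("weights") or np.zeros((p, 0)), dtype=float).reshape(p, -1),
        x_loadings=np.asarray(obj.get("x_loadings") or np.zeros((p, 0)), dtype=float).reshape(p, -1),
        y_loadings=np.asarray(obj.get("y_loadings") or [], dtype=float),
        coefficients=np.asarray(obj["coefficients"], dtype=float),
        intercept=float(obj["intercept"]),
        feature_names=obj.get("feature_names"),
        mode=obj.get("mode", "regression"),
        metadata=obj.get("metadata", {}),
    )


def save_model(model: PLSModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_json(model), indent=1))


def load_model(path: str | Path) -> PLSModel:
    return model_from_json(json.loads(Path(path).read_text()))
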