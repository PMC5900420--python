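"""Variable selection: SPA, random frog, thresholding, backward refinement.

Two selectors carry the pipeline.  The successive projections algorithm
(SPA) grows, from every possible starting column, chains of wavelengths
with minimal collinearity -- each step appends the column with the largest
norm after projection onto the orthogonal complement of the chain -- and
scores every candidate chain by the validation RMSE of a multiple linear
regression.  Random frog is a reversible-jump-flavoured subset sampler for
the fluorescence table: subsets grow and shrink stochastically, moves are
accepted on cross-validated PLS RMSE, and each feature's visit frequency
becomes its selection probability.  Backward refinement prunes an SPA
selection one wavelength at a time while leave-one-out cross-validated R2
stays above a floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemo import _pls1_core

__all__ = [
    "SelectionResult",
    "spa_select",
    "backward_refine",
    "random_frog",
    "threshold_features",
    "correlation_matrix",
]


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``criterion_trace`` is RMSE per candidate chain length for SPA, the
    cross-validated R2 per retained size for backward refinement, and the
    per-feature selection probability for random frog (also exposed as
    ``probabilities``).
    """

    selected_indices: np.ndarray
    selected_names: list[str]
    method: str
    criterion_trace: dict = field(default_factory=dict)
    probabilities: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if len(np.unique(self.selected_indices)) != self.selected_indices.size:
            raise ValueError("selected indices must be unique")
        if self.probabilities is not None and (
            self.probabilities.min() < 0 or self.probabilities.max() > 1
        ):
            raise ValueError("selection probabilities must lie in [0, 1]")


def _names_for(indices: np.ndarray, names: list[str] | None) -> list[str]:
    if names is None:
        return [str(i) for i in indices]
    return [names[i] for i in indices]


def _mlr_val_rmse(
    X_cal: np.ndarray, y_cal: np.ndarray, X_val: np.ndarray, y_val: np.ndarray,
    cols: list[int],
) -> float:
    A = np.column_stack([np.ones(X_cal.shape[0]), X_cal[:, cols]])
    beta, *_ = np.linalg.lstsq(A, y_cal, rcond=None)
    pred = np.column_stack([np.ones(X_val.shape[0]), X_val[:, cols]]) @ beta
    return float(np.sqrt(np.mean((y_val - pred) ** 2)))


def spa_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    k_min: int = 1,
    k_max: int = 30,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Successive projections algorithm wavelength selection.

    Chains are built from every starting column.  Projection ties break
    toward the lowest column index; a chain that cannot be extended (all
    residual norms ~0) simply stops short.  The returned chain minimizes
    validation RMSE of an intercept-included MLR; ``criterion_trace["rmse_per_k"]``
    records the best RMSE at each chain length.  SPA itself is fully
    deterministic.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    n, p = X_cal.shape
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    k_max = min(k_max, n - 1, p)
    k_min = min(k_min, k_max)

    norms0 = np.linalg.norm(X_cal, axis=0)
    norms0[norms0 == 0] = 1.0
    Xn = X_cal / norms0  # unit-norm columns for the projection phase

    best_rmse = np.inf
    best_chain: list[int] = []
    rmse_per_k = np.full(k_max, np.inf)

    for start in range(p):
        R = Xn.copy()
        chain = [start]
        v = R[:, start]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            continue
        v = v / nv
        R -= np.outer(v, v @ R)
        while len(chain) < k_max:
            res_norms = np.linalg.norm(R, axis=0)
            res_norms[chain] = -1.0
            nxt = int(np.argmax(res_norms))  # argmax takes lowest index on ties
            if res_norms[nxt] < 1e-10:
                break
            chain.append(nxt)
            v = R[:, nxt] / res_norms[nxt]
            R -= np.outer(v, v @ R)
        for k in range(k_min, len(chain) + 1):
            rmse = _mlr_val_rmse(X_cal, y_cal, X_val, y_val, chain[:k])
            if rmse < rmse_per_k[k - 1]:
                rmse_per_k[k - 1] = rmse
            if rmse < best_rmse:
                best_rmse = rmse
                best_chain = chain[:k]

    idx = np.asarray(best_chain, dtype=int)
    return SelectionResult(
        selected_indices=idx,
        selected_names=_names_for(idx, feature_names),
        method="SPA",
        criterion_trace={
            "k": list(range(k_min, k_max + 1)),
            "rmse_per_k": rmse_per_k[k_min - 1 :].tolist(),
            "best_rmse": best_rmse,
        },
    )


def _loo_rmsecv(X: np.ndarray, y: np.ndarray, n_lv: int) -> float:
    """Leave-one-out RMSECV of a centred PLS1 fit (no autoscaling)."""
    n = X.shape[0]
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, yt = X[tr], y[tr]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, q = _pls1_core(Xt - xm, yt - ym, n_lv)
        xc = X[i] - xm
        pred = ym
        for a in range(W.shape[1]):
            t = float(xc @ W[:, a])
            xc = xc - t * P[:, a]
            pred += q[a] * t
        errs[i] = y[i] - pred
    return float(np.sqrt(np.mean(errs**2)))


def backward_refine(
    sel: SelectionResult,
    X: np.ndarray,
    y: np.ndarray,
    max_drop: int = 10,
    r2_floor: float = 0.75,
    n_lv_cap: int = 9,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Prune a selection while cross-validated R2 stays above ``r2_floor``.

    Each round removes the feature whose removal least increases the
    leave-one-out RMSECV of a PLSR on the remaining features; pruning stops
    once the best candidate would push cross-validated R2 below the floor,
    once ``max_drop`` features are gone, or at a single feature.
    """
    if sel.selected_indices.size == 0:
        raise ValueError("cannot refine an empty selection")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def cv_r2(cols: list[int]) -> tuple[float, float]:
        n_lv = max(1, min(n_lv_cap, len(cols), X.shape[0] - 2))
        rmsecv = _loo_rmsecv(X[:, cols], y, n_lv)
        return 1.0 - (rmsecv**2 * y.size) / ss_tot, rmsecv

    current = list(sel.selected_indices)
    trace: dict[int, float] = {}
    r2_now, _ = cv_r2(current)
    trace[len(current)] = r2_now
    drops = 0
    while drops < max_drop and len(current) > 1:
        candidates = []
        for j, col in enumerate(current):
            cols = current[:j] + current[j + 1 :]
            r2, rmsecv = cv_r2(cols)
            candidates.append((rmsecv, j, r2))
        rmsecv_best, j_best, r2_best = min(candidates, key=lambda t: (t[0], t[1]))
        if r2_best < r2_floor:
            break
        del current[j_best]
        drops += 1
        trace[len(current)] = r2_best
    idx = np.asarray(current, dtype=int)
    return SelectionResult(
        selected_indices=idx,
        selected_names=_names_for(idx, feature_names),
        method="backward_refine",
        criterion_trace={"r2cv_per_size": {str(k): v for k, v in sorted(trace.items())}},
    )


def _fast_pls1_coef(Xc: np.ndarray, yc: np.ndarray, n_lv: int) -> np.ndarray:
    from .chemo import _pls1_coefficients

    W, P, q = _pls1_core(Xc, yc, n_lv)
    return _pls1_coefficients(W, P, q)


def _cv_rmse_subset(
    Xs: np.ndarray, y: np.ndarray, cols: np.ndarray, folds: list[np.ndarray], n_lv: int
) -> float:
    """K-fold RMSE of PLS1 on an (already autoscaled) column subset."""
    Xsub = Xs[:, cols]
    sq = 0.0
    n = y.size
    for te in folds:
        tr = np.setdiff1d(np.arange(n), te, assume_unique=True)
        Xt, yt = Xsub[tr], y[tr]
        xm, ym = Xt.mean(axis=0), yt.mean()
        a = max(1, min(n_lv, Xt.shape[1], Xt.shape[0] - 1))
        beta = _fast_pls1_coef(Xt - xm, yt - ym, a)
        pred = (Xsub[te] - xm) @ beta + ym
        sq += float(np.sum((y[te] - pred) ** 2))
    return float(np.sqrt(sq / n))


def random_frog(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 10_000,
    init_size: int = 10,
    size_jitter: float = 0.3,
    accept_damp: float = 0.1,
    seed: int = 0,
    n_lv: int = 3,
    cv_folds: int = 5,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Random-frog selection probabilities for every feature.

    Maintains a current subset V.  Each iteration draws a candidate size
    ``m* ~ round(N(|V|, size_jitter |V|))`` clamped to [1, p]; the candidate
    subset keeps the top-``m*`` features ranked by absolute PLS coefficient
    (fitted on V when shrinking, on V plus a random pool of outside features
    when growing).  A candidate with lower cross-validated RMSE is always
    accepted, a worse one with probability
    ``accept_damp * RMSECV(V) / RMSECV(V*)``.  The selection probability of
    a feature is the fraction of iterations whose subset contains it.

    The inner model is a ``n_lv``-component PLS1 scored by ``cv_folds``-fold
    cross-validated RMSE on autoscaled data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 1 <= init_size <= p:
        raise ValueError("init_size must lie in [1, p]")
    rng = np.random.default_rng(seed)

    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    yc = y - y.mean()

    def draw_folds() -> list[np.ndarray]:
        perm = rng.permutation(n)
        return [perm[k::cv_folds] for k in range(cv_folds)]

    def rank_by_coef(cols: np.ndarray) -> np.ndarray:
        Xsub = Xs[:, cols]
        a = max(1, min(n_lv, cols.size, n - 1))
        beta = _fast_pls1_coef(Xsub - Xsub.mean(axis=0), yc - yc.mean(), a)
        return cols[np.argsort(-np.abs(beta), kind="stable")]

    V = np.sort(rng.choice(p, size=init_size, replace=False))
    counts = np.zeros(p)

    for _ in range(n_iterations):
        m_star = int(np.clip(round(rng.normal(V.size, size_jitter * V.size)), 1, p))
        outside = np.setdiff1d(np.arange(p), V, assume_unique=False)
        if m_star < V.size:
            # shrink: drop the bottom-ranked features
            V_cand = np.sort(rank_by_coef(V)[:m_star])
        elif m_star == V.size or outside.size == 0:
            # same size: swap one random member for one random challenger;
            # the RMSE acceptance rule arbitrates, so features that only
            # rank high by chance keep churning out of the subset while
            # genuinely predictive ones survive every challenge
            if outside.size == 0:
                V_cand = V
            else:
                keep = np.delete(V, rng.integers(V.size))
                challenger = rng.choice(outside, size=1)
                V_cand = np.sort(np.concatenate([keep, challenger]))
        else:
            # grow: rank V against a random pool of outside features
            extra = m_star - V.size
            pool = rng.choice(outside, size=min(outside.size, 2 * extra), replace=False)
            union = np.concatenate([V, pool])
            V_cand = np.sort(rank_by_coef(union)[: min(m_star, union.size)])
        # both subsets are re-scored on freshly drawn folds so a one-off
        # lucky RMSE estimate cannot lock the chain onto a subset
        folds = draw_folds()
        rmse_V = _cv_rmse_subset(Xs, y, V, folds, n_lv)
        if V_cand is V:
            rmse_cand = rmse_V
        else:
            rmse_cand = _cv_rmse_subset(Xs, y, V_cand, folds, n_lv)
        # worse candidates are accepted with probability damped by the
        # *fourth power* of the RMSE ratio: near-neutral swaps still churn
        # (ratio ~ 1) but clearly superior subsets are practically never
        # abandoned, which a linear ratio would do ~damp*ratio of the time
        ratio = rmse_V / rmse_cand
        if rmse_cand <= rmse_V or rng.uniform() < accept_damp * ratio**4:
            V = V_cand
        counts[V] += 1

    probs = counts / n_iterations
    order = np.argsort(-probs, kind="stable")
    return SelectionResult(
        selected_indices=order,
        selected_names=_names_for(order, feature_names),
        method="random_frog",
        criterion_trace={"selection_probability": probs.tolist()},
        probabilities=probs,
    )


def threshold_features(sel: SelectionResult, threshold: float = 0.4) -> SelectionResult:
    """Keep features with selection probability above ``threshold``.

    Result is sorted by descending probability; an empty outcome is legal
    and flagged rather than raised.
    """
    if sel.probabilities is None:
        raise ValueError("threshold_features requires a random-frog result")
    probs = sel.probabilities
    keep = np.flatnonzero(probs > threshold)
    keep = keep[np.argsort(-probs[keep], kind="stable")]
    name_of = dict(zip(sel.selected_indices.tolist(), sel.selected_names))
    return SelectionResult(
        selected_indices=keep,
        selected_names=[name_of[int(i)] for i in keep],
        method="random_frog",
        criterion_trace={"threshold": threshold},
        probabilities=probs[keep] if keep.size else None,
        flags={"empty": keep.size == 0},
    )


def correlation_matrix(X_selected: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix among selected features."""
    X_selected = np.asarray(X_selected, dtype=float)
    if X_selected.ndim != 2 or X_selected.shape[1] < 2:
        raise ValueError("need at least two features")
    if np.any(X_selected.std(axis=0) == 0):
        raise ValueError("correlation undefined for zero-variance features")
    return np.corrcoef(X_selected, rowvar=False)
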