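"""Sparse partial least squares discriminant analysis (sPLS-DA).

The outcome is coded as a centered dummy matrix (one column per class)
and latent components are extracted by a NIPALS-style power iteration
in which the X weight vector is hard-truncated to its ``keepX`` largest
absolute entries and renormalized at every pass; X and Y are deflated
in regression mode after each component. With ``keepX = p`` this is
ordinary dense PLS-DA, whose first weight vector is the leading left
singular vector of ``X_centered.T @ Y_dummy_centered``.

Class prediction uses the maximum-distance rule: the regression
coefficients map a (train-scaled) sample to predicted dummy values and
the class with the largest value wins; ties break toward the first
class in ``class_map`` order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import ClassLabels, ExpressionMatrix

__all__ = ["SplsdaModel", "fit_splsda", "predict_splsda", "tune_splsda", "explained_variance"]

_TOL = 1e-6
_MAX_ITER = 500


@dataclass
class SplsdaModel:
    feature_ids: list[str]
    class_map: tuple[str, str]
    ncomp: int
    keepX: tuple[int, ...]
    x_weights: np.ndarray        # (p, H), unit norm, keepX[h] non-zeros each
    x_scores: np.ndarray         # (n, H)
    x_loadings: np.ndarray       # (p, H) regression loadings
    y_weights: np.ndarray        # (K, H) normalized Y direction per component
    y_loadings: np.ndarray       # (K, H) regression loadings of Y on scores
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    explained_variance_x: np.ndarray  # (H,)

    def selected_features(self, component: int | None = None) -> list[str]:
        """Features with non-zero weight on ``component`` (1-based), or on any."""
        if component is None:
            mask = np.any(self.x_weights != 0, axis=1)
        else:
            mask = self.x_weights[:, component - 1] != 0
        return [f for f, m in zip(self.feature_ids, mask) if m]

    def scores_frame(self, sample_ids) -> pd.DataFrame:
        return pd.DataFrame(
            self.x_scores,
            index=sample_ids,
            columns=[f"comp{h + 1}" for h in range(self.ncomp)],
        )


def _scale_train(values: np.ndarray, feature_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [feature_ids[j] for j in zero[:5]]
        raise ValueError(f"constant feature(s) with zero variance: {names}")
    return (values - mean) / sd, mean, sd


def _truncate(w: np.ndarray, keep: int) -> np.ndarray:
    """Zero all but the ``keep`` largest-|w| entries; ties break by index."""
    if keep >= w.size:
        return w
    order = np.argsort(-np.abs(w), kind="stable")
    out = np.zeros_like(w)
    out[order[:keep]] = w[order[:keep]]
    return out


def fit_splsda(
    x: ExpressionMatrix,
    y: ClassLabels,
    ncomp: int,
    keepX,
) -> SplsdaModel:
    """Fit an sPLS-DA model with ``keepX[h]`` variables on component h.

    ``keepX`` may be a single int (used for every component) or a
    sequence of length ``ncomp``. Features are centered and scaled to
    unit variance internally; constant features raise.
    """
    y.check_matches(x)
    n, p = x.values.shape
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} exceeds min(n-1, p) = {min(n - 1, p)}")
    if np.isscalar(keepX):
        keepX = (int(keepX),) * ncomp
    else:
        keepX = tuple(int(k) for k in keepX)
    if len(keepX) != ncomp:
        raise ValueError("keepX must have one entry per component")
    if any(k < 1 or k > p for k in keepX):
        raise ValueError(f"keepX entries must be in [1, p={p}]")

    Xc, x_mean, x_sd = _scale_train(x.values, x.feature_ids)
    K = 2
    dummy = y.indicator().T.astype(float)  # (n, K), class0 first
    y_mean = dummy.mean(axis=0)
    Yc = dummy - y_mean

    total_var = float((Xc**2).sum())
    Xh, Yh = Xc.copy(), Yc.copy()
    W = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    P = np.zeros((p, ncomp))
    C = np.zeros((K, ncomp))  # y weights
    D = np.zeros((K, ncomp))  # y loadings
    ev = np.zeros(ncomp)

    for h in range(ncomp):
        M = Xh.T @ Yh  # (p, K)
        # initialize Y direction from the dominant right singular vector
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        w = np.zeros(p)
        for _ in range(_MAX_ITER):
            w_new = M @ v
            w_new = _truncate(w_new, keepX[h])
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError(
                    f"component {h + 1}: weight vector collapsed to zero "
                    "(X carries no covariance with the outcome)"
                )
            w_new /= norm
            t = Xh @ w_new
            v_new = Yh.T @ t
            v_norm = np.linalg.norm(v_new)
            if v_norm > 0:
                v_new = v_new / v_norm
            if np.linalg.norm(w_new - w) < _TOL:
                w, v = w_new, v_new
                break
            w, v = w_new, v_new
        # deterministic sign: largest-|weight| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, v = -w, -v
        t = Xh @ w
        tt = float(t @ t)
        p_load = Xh.T @ t / tt
        d_load = Yh.T @ t / tt
        W[:, h], T[:, h], P[:, h], C[:, h], D[:, h] = w, t, p_load, v, d_load
        ev[h] = tt * float(p_load @ p_load) / total_var
        Xh = Xh - np.outer(t, p_load)
        Yh = Yh - np.outer(t, d_load)

    return SplsdaModel(
        feature_ids=list(x.feature_ids),
        class_map=y.classes,
        ncomp=ncomp,
        keepX=keepX,
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_weights=C,
        y_loadings=D,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        explained_variance_x=ev,
    )


def predict_splsda(
    model: SplsdaModel, xnew: ExpressionMatrix, method: str = "max_dist"
) -> tuple[list[str], pd.DataFrame]:
    """Predict classes for new samples with the max-distance rule.

    ``xnew`` may contain extra features; the model's features must all
    be present. Returns the predicted label per sample and the
    per-class predicted dummy values.
    """
    if method != "max_dist":
        raise ValueError(f"unknown prediction method {method!r}")
    missing = [f for f in model.feature_ids if f not in set(xnew.feature_ids)]
    if missing:
        raise KeyError(f"model features missing from new data: {missing}")
    xs = xnew.subset_features(model.feature_ids)
    Xc = (xs.values - model.x_mean) / model.x_sd
    W, P, D = model.x_weights, model.x_loadings, model.y_loadings
    B = W @ np.linalg.inv(P.T @ W) @ D.T  # (p, K)
    pred = Xc @ B + model.y_mean
    scores = pd.DataFrame(pred, index=xs.sample_ids, columns=list(model.class_map))
    # argmax ties break to the first class in class_map order
    idx = np.argmax(pred, axis=1)
    return [model.class_map[i] for i in idx], scores


def tune_splsda(
    x: ExpressionMatrix,
    y: ClassLabels,
    max_ncomp: int = 10,
    keepX_grid=tuple(range(1, 51)),
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, tuple[int, ...], pd.DataFrame]:
    """Sequential cross-validated tuning of component count and keepX.

    For each dimension ``h`` the grid of candidate ``keepX[h]`` values
    is searched (earlier components fixed at their chosen values) for
    the lowest overall misclassification rate under stratified
    ``folds``-fold CV with max-distance prediction. Ties break toward
    smaller keepX, then toward smaller ncomp. Returns ``(best_ncomp,
    best_keepX, table)`` where the table holds the CV error for every
    (ncomp, keepX) pair visited.
    """
    y.check_matches(x)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = [y.labels.count(c) for c in y.classes]
    if min(counts) < folds:
        raise ValueError(
            f"smallest class has {min(counts)} samples < {folds} folds; "
            "use fewer folds so every fold sees both classes"
        )
    keepX_grid = tuple(int(k) for k in keepX_grid)
    max_ncomp = min(max_ncomp, x.n_samples - 1, x.n_features)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(x.n_samples), y.y_index()))

    chosen: list[int] = []
    best_err_per_h: list[float] = []
    records = []
    for h in range(1, max_ncomp + 1):
        best_k, best_err = None, np.inf
        for k in keepX_grid:
            keepX_try = tuple(chosen) + (k,)
            wrong = total = 0
            for train_idx, test_idx in splits:
                xtr = x.subset_samples([x.sample_ids[i] for i in train_idx])
                xte = x.subset_samples([x.sample_ids[i] for i in test_idx])
                ytr = y.for_samples(xtr.sample_ids)
                model = fit_splsda(xtr, ytr, ncomp=h, keepX=keepX_try)
                pred, _ = predict_splsda(model, xte)
                truth = y.for_samples(xte.sample_ids)
                wrong += sum(a != b for a, b in zip(pred, truth.labels))
                total += len(test_idx)
            err = wrong / total
            records.append({"ncomp": h, "keepX": k, "error": err})
            if err < best_err:  # strict: ties keep the smaller keepX
                best_k, best_err = k, err
        chosen.append(best_k)
        best_err_per_h.append(best_err)
    best_ncomp = int(np.argmin(best_err_per_h)) + 1  # argmin ties -> smaller ncomp
    table = pd.DataFrame.from_records(records)
    return best_ncomp, tuple(chosen[:best_ncomp]), table


def explained_variance(model: SplsdaModel) -> pd.DataFrame:
    """Per-component and cumulative fraction of (scaled) X variance."""
    ev = model.explained_variance_x
    return pd.DataFrame(
        {
            "component": np.arange(1, model.ncomp + 1),
            "explained_variance": ev,
            "cumulative": np.cumsum(ev),
        }
    )
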