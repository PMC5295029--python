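"""Regularized canonical correlation analysis (rCCA).

Classical CCA is unusable when features outnumber samples; the ridge
variant replaces the within-block covariances by ``Cov(X) + lambda1*I``
and ``Cov(Z) + lambda2*I`` and solves the same canonical system. The
canonical directions come from the SVD of

    M = (Cxx + l1*I)^(-1/2)  Cxz  (Czz + l2*I)^(-1/2)

with weights rescaled so every variate has unit sample variance; the
reported canonical correlations are the empirical Pearson correlations
of the paired variates (identical to the singular values at lambda=0).

The two penalties are tuned by k-fold cross-validation on a grid: the
score of a (lambda1, lambda2) cell is the mean held-out correlation of
the first pair of variates computed with training-fold weights.
Dimension choice follows the "gap" heuristic: keep the dimensions
before the largest consecutive drop in the canonical correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.model_selection import KFold

from .io import ExpressionMatrix

__all__ = [
    "RccaModel",
    "fit_rcca",
    "tune_rcca",
    "default_lambda_grids",
    "select_dimensions",
    "correlation_circle",
    "cim_similarity",
]


@dataclass
class RccaModel:
    lambda1: float
    lambda2: float
    x_feature_ids: list[str]
    z_feature_ids: list[str]
    canonical_correlations: np.ndarray  # (ncomp,) empirical corr of paired variates
    regularized_correlations: np.ndarray  # (ncomp,) singular values of the system
    x_weights: np.ndarray               # (p, ncomp), unit-variance variates
    z_weights: np.ndarray               # (q, ncomp)
    x_variates: np.ndarray              # (n, ncomp)
    z_variates: np.ndarray              # (n, ncomp)
    x_mean: np.ndarray
    x_sd: np.ndarray
    z_mean: np.ndarray
    z_sd: np.ndarray
    d: int | None = None                # retained dimensions (set by caller)

    @property
    def ncomp(self) -> int:
        return self.canonical_correlations.size


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mean) / sd, mean, sd


def _inv_sqrt(cov: np.ndarray, lam: float, label: str) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(cov)
    shifted = eigval + lam
    if np.min(shifted) <= 1e-12 * max(1.0, np.max(shifted)):
        raise ValueError(
            f"{label} covariance is singular at lambda={lam}; use lambda > 0 "
            "(features outnumber samples)"
        )
    return eigvec @ np.diag(1.0 / np.sqrt(shifted)) @ eigvec.T


def fit_rcca(
    x: ExpressionMatrix, z: ExpressionMatrix, lambda1: float, lambda2: float
) -> RccaModel:
    """Fit rCCA between two matrices measured on the same samples."""
    if list(x.sample_ids) != list(z.sample_ids):
        raise ValueError("x and z must share the same samples in the same order")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("ridge penalties must be non-negative")
    n = x.n_samples
    Xc, x_mean, x_sd = _standardize(x.values)
    Zc, z_mean, z_sd = _standardize(z.values)
    Cxx = (Xc.T @ Xc) / (n - 1)
    Czz = (Zc.T @ Zc) / (n - 1)
    Cxz = (Xc.T @ Zc) / (n - 1)
    Rx = _inv_sqrt(Cxx, lambda1, "X")
    Rz = _inv_sqrt(Czz, lambda2, "Z")
    U, s, Vt = np.linalg.svd(Rx @ Cxz @ Rz, full_matrices=False)
    ncomp = min(x.n_features, z.n_features, n - 1)
    A = Rx @ U[:, :ncomp]
    B = Rz @ Vt[:ncomp].T
    xv = Xc @ A
    zv = Zc @ B
    # unit-variance variates
    xv_sd = xv.std(axis=0, ddof=1)
    zv_sd = zv.std(axis=0, ddof=1)
    xv_sd = np.where(xv_sd == 0, 1.0, xv_sd)
    zv_sd = np.where(zv_sd == 0, 1.0, zv_sd)
    A, B = A / xv_sd, B / zv_sd
    xv, zv = xv / xv_sd, zv / zv_sd
    # deterministic sign: positive correlation of paired variates where possible
    corr = np.array(
        [np.corrcoef(xv[:, k], zv[:, k])[0, 1] for k in range(ncomp)]
    )
    flip = corr < 0
    B[:, flip] *= -1
    zv[:, flip] *= -1
    corr = np.abs(corr)
    return RccaModel(
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        x_feature_ids=list(x.feature_ids),
        z_feature_ids=list(z.feature_ids),
        canonical_correlations=np.clip(corr, 0.0, 1.0),
        regularized_correlations=np.clip(s[:ncomp], 0.0, 1.0),
        x_weights=A,
        z_weights=B,
        x_variates=xv,
        z_variates=zv,
        x_mean=x_mean,
        x_sd=x_sd,
        z_mean=z_mean,
        z_sd=z_sd,
    )


def default_lambda_grids(
    n1: int = 100, n2: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced points strictly inside (0.001, 0.05) x (0.0001, 0.05)."""
    g1 = np.linspace(0.001, 0.05, n1 + 2)[1:-1]
    g2 = np.linspace(0.0001, 0.05, n2 + 2)[1:-1]
    return g1, g2


def tune_rcca(
    x: ExpressionMatrix,
    z: ExpressionMatrix,
    grid1=None,
    grid2=None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Grid-search the two ridge penalties by cross-validation.

    The CV score of a grid cell is the mean over folds of the Pearson
    correlation between held-out first variates computed with
    training-fold weights. Ties break toward smaller penalties. Returns
    ``(lambda1, lambda2, surface)`` with the full score surface in long
    format.
    """
    if grid1 is None or grid2 is None:
        d1, d2 = default_lambda_grids()
        grid1 = d1 if grid1 is None else np.asarray(grid1, dtype=float)
        grid2 = d2 if grid2 is None else np.asarray(grid2, dtype=float)
    grid1 = np.sort(np.asarray(grid1, dtype=float))
    grid2 = np.sort(np.asarray(grid2, dtype=float))
    if grid1.size == 0 or grid2.size == 0:
        raise ValueError("penalty grids must be non-empty")
    if list(x.sample_ids) != list(z.sample_ids):
        raise ValueError("x and z must share the same samples in the same order")
    n = x.n_samples
    if n // folds < 3 and n - (n // folds) * (folds - 1) < 3:
        pass  # correlation needs >=3 held-out points; checked per fold below

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_cache = []
    for train_idx, test_idx in kf.split(np.arange(n)):
        if test_idx.size < 3:
            raise ValueError(
                f"fold with {test_idx.size} samples cannot support a held-out "
                "correlation; use fewer folds"
            )
        Xtr, x_mean, x_sd = _standardize(x.values[train_idx])
        Ztr, z_mean, z_sd = _standardize(z.values[train_idx])
        m = train_idx.size
        Cxx = (Xtr.T @ Xtr) / (m - 1)
        Czz = (Ztr.T @ Ztr) / (m - 1)
        Cxz = (Xtr.T @ Ztr) / (m - 1)
        ex_val, ex_vec = np.linalg.eigh(Cxx)
        ez_val, ez_vec = np.linalg.eigh(Czz)
        Xte = (x.values[test_idx] - x_mean) / x_sd
        Zte = (z.values[test_idx] - z_mean) / z_sd
        fold_cache.append((ex_val, ex_vec, ez_val, ez_vec, Cxz, Xte, Zte))

    surface = np.full((grid1.size, grid2.size), -np.inf)
    for i, l1 in enumerate(grid1):
        for j, l2 in enumerate(grid2):
            scores = []
            for ex_val, ex_vec, ez_val, ez_vec, Cxz, Xte, Zte in fold_cache:
                if np.min(ex_val + l1) <= 0 or np.min(ez_val + l2) <= 0:
                    scores.append(-np.inf)
                    continue
                Rx = ex_vec @ ((1.0 / np.sqrt(ex_val + l1))[:, None] * ex_vec.T)
                Rz = ez_vec @ ((1.0 / np.sqrt(ez_val + l2))[:, None] * ez_vec.T)
                U, s, Vt = np.linalg.svd(Rx @ Cxz @ Rz, full_matrices=False)
                a = Rx @ U[:, 0]
                b = Rz @ Vt[0]
                u, v = Xte @ a, Zte @ b
                if u.std() == 0 or v.std() == 0:
                    scores.append(-np.inf)
                else:
                    scores.append(float(np.corrcoef(u, v)[0, 1]))
            surface[i, j] = float(np.mean(scores))
    best_flat = int(np.argmax(surface))  # row-major: ties -> smaller l1 then l2
    bi, bj = np.unravel_index(best_flat, surface.shape)
    long = pd.DataFrame(
        {
            "lambda1": np.repeat(grid1, grid2.size),
            "lambda2": np.tile(grid2, grid1.size),
            "cv_score": surface.ravel(),
        }
    )
    return float(grid1[bi]), float(grid2[bj]), long


def select_dimensions(
    canonical_correlations, override: int | None = None
) -> int:
    """Dimensions to retain: the index before the largest consecutive drop."""
    rho = np.asarray(canonical_correlations, dtype=float)
    if override is not None:
        if not 1 <= override <= rho.size:
            raise ValueError("dimension override out of range")
        warnings.warn(f"manual dimension override d={override}")
        return int(override)
    if rho.size < 2:
        raise ValueError("need at least two canonical correlations")
    drops = rho[:-1] - rho[1:]
    if drops.size > 1 and np.ptp(drops) < 1e-12:
        # all consecutive drops equal (flat or linear decline): no gap to find
        warnings.warn("no clear gap among canonical correlations; returning d=1")
        return 1
    return int(np.argmax(drops)) + 1


def correlation_circle(
    model: RccaModel,
    x: ExpressionMatrix,
    z: ExpressionMatrix,
    inner_radius: float = 0.3,
    ndim: int = 2,
) -> pd.DataFrame:
    """Correlation-circle coordinates; only features outside the inner circle.

    Each feature's coordinate on dimension h is its Pearson correlation
    with the compromise variate (the mean of the X and Z variates of
    that dimension). Features whose Euclidean norm over the first
    ``ndim`` dimensions is <= ``inner_radius`` are dropped.
    """
    if not 0 < inner_radius < 1:
        raise ValueError("inner_radius must be in (0, 1)")
    ndim = min(ndim, model.ncomp)
    compromise = (model.x_variates[:, :ndim] + model.z_variates[:, :ndim]) / 2.0
    rows = []
    for block, mat in (("mirna", x), ("gene", z)):
        vals = mat.values - mat.values.mean(axis=0)
        norms = np.linalg.norm(vals, axis=0)
        norms = np.where(norms == 0, 1.0, norms)
        comp_c = compromise - compromise.mean(axis=0)
        comp_norm = np.linalg.norm(comp_c, axis=0)
        comp_norm = np.where(comp_norm == 0, 1.0, comp_norm)
        coords = (vals / norms).T @ (comp_c / comp_norm)  # (features, ndim)
        radius = np.linalg.norm(coords, axis=1)
        for fid, coord, rad in zip(mat.feature_ids, coords, radius):
            rows.append((fid, block, *coord, rad))
    cols = ["feature_id", "block", *[f"dim{h + 1}" for h in range(ndim)], "radius"]
    frame = pd.DataFrame(rows, columns=cols)
    return frame[frame["radius"] > inner_radius].reset_index(drop=True)


def cim_similarity(points: pd.DataFrame):
    """Cross-block similarity matrix with bi-clustering orders.

    ``points`` is the output of :func:`correlation_circle`. The
    similarity of miRNA i and gene j is the inner product of their
    circle coordinates over the retained dimensions. Rows/columns are
    clustered with Euclidean distance and average linkage. Returns
    ``(similarity, row_order, col_order)`` where the orders are leaf
    orders of the dendrograms.
    """
    dims = [c for c in points.columns if c.startswith("dim")]
    mir = points[points["block"] == "mirna"]
    gen = points[points["block"] == "gene"]
    if mir.empty or gen.empty:
        raise ValueError("need at least one retained feature per block")
    M = mir[dims].to_numpy()
    G = gen[dims].to_numpy()
    sim = pd.DataFrame(
        M @ G.T, index=list(mir["feature_id"]), columns=list(gen["feature_id"])
    )

    def _order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        link = hierarchy.linkage(mat, method="average", metric="euclidean")
        return list(hierarchy.leaves_list(link))

    row_order = _order(sim.to_numpy())
    col_order = _order(sim.to_numpy().T)
    return sim, row_order, col_order
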