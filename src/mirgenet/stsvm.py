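"""Network-smoothed t-statistic feature selection with SVM evaluation.

Per-feature |t| statistics (random-variance t-test on the combined
miRNA+gene matrix, so both blocks share one scale) are diffused over
the integrated interaction graph with a random-walk kernel

    K = (a * I - L_norm) ** steps,      a >= 2,

where ``L_norm`` is the symmetric normalized Laplacian (eigenvalues in
[0, 2], so the kernel is positive semidefinite for any ``a >= 2``).
Features are selected by a class-label permutation test on the smoothed
scores, then a linear SVM on the selected features is assessed by
repeated stratified cross-validation with rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .diffexp import _ttest_core
from .io import ClassLabels, ExpressionMatrix
from .network import IntegratedNetwork

__all__ = [
    "FeatureGraph",
    "build_feature_graph",
    "random_walk_kernel",
    "smooth_statistics",
    "permutation_select",
    "cv_evaluate",
    "CvResult",
]


@dataclass
class FeatureGraph:
    """Undirected feature graph spanning both expression blocks."""

    nodes: list[str]
    adjacency: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(A < 0):
            raise ValueError("adjacency weights must be non-negative")
        self.adjacency = A

    def normalized_laplacian(self) -> np.ndarray:
        """``I - D^{-1/2} A D^{-1/2}``; isolated nodes get a zero diagonal."""
        deg = self.adjacency.sum(axis=1)
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        L = -inv_sqrt[:, None] * self.adjacency * inv_sqrt[None, :]
        np.fill_diagonal(L, np.where(deg > 0, 1.0, 0.0))
        return L


def build_feature_graph(
    net: IntegratedNetwork, extra_nodes=()
) -> FeatureGraph:
    """Unweighted graph over the network's miRNA and gene nodes.

    ``extra_nodes`` widens the node set (e.g. to all rCCA-retained
    features); added nodes without edges stay isolated.
    """
    nodes = list(net.mirna_nodes) + list(net.gene_nodes)
    for e in extra_nodes:
        if e not in nodes:
            nodes.append(e)
    index = {nd: i for i, nd in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for row in net.edges.itertuples(index=False):
        i, j = index[row.mirna_id], index[row.gene_id]
        A[i, j] = A[j, i] = 1.0
    return FeatureGraph(nodes=nodes, adjacency=A)


def random_walk_kernel(
    graph: FeatureGraph, a: float = 2.0, steps: int = 2
) -> np.ndarray:
    """``K = (a*I - L_norm)**steps``; positive semidefinite for a >= 2."""
    if a < 2:
        raise ValueError(
            "a must be >= 2: the normalized Laplacian spectrum lies in [0, 2], "
            "so smaller a can make a*I - L indefinite"
        )
    if steps < 0 or int(steps) != steps:
        raise ValueError("steps must be a non-negative integer")
    L = graph.normalized_laplacian()
    base = a * np.eye(len(graph.nodes)) - L
    return np.linalg.matrix_power(base, int(steps))


def smooth_statistics(kernel: np.ndarray, raw: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Diffuse per-node scores through the kernel; optionally unit-max scaled."""
    raw = np.asarray(raw, dtype=float)
    if kernel.shape[0] != raw.size:
        raise ValueError("kernel and score vector dimensions differ")
    s = kernel @ raw
    if rescale and s.size and np.max(np.abs(s)) > 0:
        s = s / np.max(np.abs(s))
    return s


def _abs_t(values: np.ndarray, mask0: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    t, *_ = _ttest_core(values, mask0, mask1)
    return np.abs(t)


def permutation_select(
    x_combined: ExpressionMatrix,
    y: ClassLabels,
    kernel: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test on network-smoothed |t| scores.

    ``x_combined`` holds the node features in kernel order. Class labels
    are permuted ``n_perm`` times; a node's p-value is the add-one
    fraction of permutations whose smoothed score reaches its observed
    score. Returns the full per-node table with a ``selected`` column
    (p < ``alpha``); raises if nothing is selected.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y.check_matches(x_combined)
    if kernel.shape[0] != x_combined.n_features:
        raise ValueError("kernel order must match the combined feature matrix")
    mask0, mask1 = y.indicator()
    obs = kernel @ _abs_t(x_combined.values, mask0, mask1)
    rng = np.random.default_rng(seed)
    n = x_combined.n_samples
    exceed = np.zeros(x_combined.n_features)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = kernel @ _abs_t(x_combined.values, mask0[perm], mask1[perm])
        exceed += s >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    table = pd.DataFrame(
        {
            "feature_id": x_combined.feature_ids,
            "smoothed_score": obs / np.max(obs) if np.max(obs) > 0 else obs,
            "p": pvals,
            "selected": pvals < alpha,
        }
    )
    if not table["selected"].any():
        raise ValueError(
            f"no feature passed the permutation test at alpha={alpha}; "
            "consider a larger alpha"
        )
    return table


@dataclass
class CvResult:
    auc_mean: float
    auc_sd: float
    per_repeat_auc: np.ndarray
    roc: pd.DataFrame  # pooled decision-value ROC: fpr, tpr, threshold
    pooled_scores: np.ndarray  # decision values pooled across repeats
    pooled_truth: np.ndarray   # matching class indices (0/1)


def cv_evaluate(
    x_sel: ExpressionMatrix,
    y: ClassLabels,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> CvResult:
    """Repeated stratified k-fold CV of a linear SVM on selected features.

    Decision values are pooled across folds within a repeat; the AUC of
    each repeat is the rank statistic of those pooled values, and the
    reported ROC curve pools decision values across all repeats. The
    SVM uses a fixed regularization constant ``C`` and balanced class
    weights (the study design is 14 vs 26).
    """
    if repeats < 1 or folds < 2:
        raise ValueError("need repeats >= 1 and folds >= 2")
    y.check_matches(x_sel)
    y_idx = y.y_index()
    counts = np.bincount(y_idx)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds"
        )
    aucs = []
    all_scores, all_truth = [], []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        scores = np.empty(x_sel.n_samples)
        for train_idx, test_idx in skf.split(x_sel.values, y_idx):
            scaler = StandardScaler().fit(x_sel.values[train_idx])
            clf = SVC(kernel="linear", C=C, class_weight="balanced")
            clf.fit(scaler.transform(x_sel.values[train_idx]), y_idx[train_idx])
            scores[test_idx] = clf.decision_function(
                scaler.transform(x_sel.values[test_idx])
            )
        aucs.append(roc_auc_score(y_idx, scores))
        all_scores.append(scores)
        all_truth.append(y_idx)
    aucs = np.asarray(aucs)
    pooled_scores = np.concatenate(all_scores)
    pooled_truth = np.concatenate(all_truth)
    fpr, tpr, thr = roc_curve(pooled_truth, pooled_scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return CvResult(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if repeats > 1 else 0.0,
        per_repeat_auc=aucs,
        roc=roc,
        pooled_scores=pooled_scores,
        pooled_truth=pooled_truth,
    )
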