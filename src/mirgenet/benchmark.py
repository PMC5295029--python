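"""Recovery benchmarks against planted synthetic ground truth.

These helpers run the analysis chain on the default synthetic cohort
and score the result against the generator's truth: fraction of planted
component-1 miRNAs recovered by the first sPLS-DA component, F1 of the
integrated network's edges against the planted repression edges,
recovery of the planted signature by stSVM, and the cross-validated AUC
of the resulting classifier. They exist so that calibration and
recovery claims are computed by one code path wherever they are
reported.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import diffexp as de
from . import network as nw
from . import rcca as rc
from . import splsda as sp
from . import stsvm as st
from .io import detection_filter
from .simulate import generate_cohort

__all__ = ["recovery_metrics", "null_type_one_error", "anticorrelation_fpr"]


def recovery_metrics(
    seed: int,
    gene_keepX: int = 30,
    rcca_grid: int = 6,
    rcca_folds: int = 5,
    select_n_perm: int = 500,
    cv_repeats: int = 10,
    cv_folds: int = 10,
    generator_kwargs: dict | None = None,
) -> dict:
    """Run the analysis chain on one default cohort; score against truth.

    The sPLS-DA models are fitted at the planted sparsity (keepX equal
    to the planted component sizes for the miRNA block, ``gene_keepX``
    for the gene block); the rCCA penalties are tuned on a coarse
    ``rcca_grid`` x ``rcca_grid`` grid. Returns a dict of scalar
    metrics.
    """
    kwargs = generator_kwargs or {}
    cohort = generate_cohort(seed=seed, **kwargs)
    truth = cohort.truth
    mirna = detection_filter(cohort.mirna, 0.10)
    labels = cohort.labels

    # miRNA sPLS-DA at the planted sparsity
    k1 = len(truth.component1_mirnas)
    k2 = max(len(truth.component2_mirnas), 2)
    model_m = sp.fit_splsda(mirna, labels, ncomp=2, keepX=(k1, k2))
    comp1_sel = set(model_m.selected_features(1))
    comp1_recovery = len(comp1_sel & set(truth.component1_mirnas)) / k1

    # gene sPLS-DA
    model_g = sp.fit_splsda(cohort.gene, labels, ncomp=2, keepX=gene_keepX)
    x_sel = mirna.subset_features(sorted(set(model_m.selected_features())))
    z_sel = cohort.gene.subset_features(sorted(set(model_g.selected_features())))

    # rCCA -> correlation circle retention
    g1 = np.linspace(0.002, 0.05, rcca_grid)
    g2 = np.linspace(0.001, 0.05, rcca_grid)
    l1, l2, _ = rc.tune_rcca(x_sel, z_sel, g1, g2, folds=rcca_folds, seed=seed)
    model_r = rc.fit_rcca(x_sel, z_sel, l1, l2)
    circle = rc.correlation_circle(model_r, x_sel, z_sel, inner_radius=0.3, ndim=2)
    mir_ids = sorted(circle.loc[circle["block"] == "mirna", "feature_id"])
    top = set(nw.variance_top_fraction(cohort.gene, 0.75))
    gene_ids = [
        g for g in sorted(circle.loc[circle["block"] == "gene", "feature_id"])
        if g in top
    ]

    # integrated network vs planted edges
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anticorr = nw.pairwise_anticorrelation(
            mirna.subset_features(mir_ids), cohort.gene.subset_features(gene_ids)
        )
        consensus = nw.consensus_predictions(cohort.databases, 2)
        net = nw.build_integrated_network(anticorr, consensus, 0.1)
    found = net.edge_set()
    true = truth.true_edges
    tp = len(found & true)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(true)
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0

    # stSVM on the network node set
    graph = st.build_feature_graph(net)
    kernel = st.random_walk_kernel(graph, 2.0, 2)
    from .pipeline import _combined_matrix

    combined = _combined_matrix(mirna, cohort.gene, graph.nodes)
    table = st.permutation_select(
        combined, labels, kernel, n_perm=select_n_perm, alpha=0.05, seed=seed
    )
    selected = set(table.loc[table["selected"], "feature_id"])
    planted = set(truth.signature_features)
    nodes = set(graph.nodes)
    null_nodes = nodes - planted
    signature_recovery = len(selected & planted) / len(planted)
    false_selection = (
        len(selected & null_nodes) / len(null_nodes) if null_nodes else 0.0
    )

    cv = st.cv_evaluate(
        combined.subset_features(sorted(selected)),
        labels,
        repeats=cv_repeats,
        folds=cv_folds,
        seed=seed,
    )
    return {
        "n_false_selected": float(len(selected & null_nodes)),
        "n_null_nodes": float(len(null_nodes)),
        "comp1_recovery": comp1_recovery,
        "edge_precision": precision,
        "edge_recall": recall,
        "edge_f1": f1,
        "signature_recovery": signature_recovery,
        "false_selection_rate": false_selection,
        "planted_in_network": len(nodes & planted) / len(planted),
        "cv_auc": cv.auc_mean,
    }


def null_type_one_error(
    n_features: int = 10000,
    n_class0: int = 14,
    n_class1: int = 26,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the shrunken t-test on pure-noise features."""
    rng = np.random.default_rng(seed)
    n = n_class0 + n_class1
    values = rng.normal(size=(n, n_features)) * rng.uniform(0.5, 2.0, size=n_features)
    mask0 = np.zeros(n, bool)
    mask0[:n_class0] = True
    _, _, p, *_ = de._ttest_core(values, mask0, ~mask0)
    return float((p < alpha).mean())


def anticorrelation_fpr(
    n_pairs: int = 10000, n_samples: int = 40, alpha: float = 0.05, seed: int = 0
) -> float:
    """One-sided negative-correlation false positive rate on null pairs."""
    rng = np.random.default_rng(seed)
    p = int(np.ceil(np.sqrt(n_pairs)))
    from .io import ExpressionMatrix

    x = ExpressionMatrix(
        [f"S{i}" for i in range(n_samples)],
        [f"M{j}" for j in range(p)],
        rng.normal(size=(n_samples, p)),
    )
    z = ExpressionMatrix(
        [f"S{i}" for i in range(n_samples)],
        [f"G{j}" for j in range(p)],
        rng.normal(size=(n_samples, p)),
    )
    table = nw.pairwise_anticorrelation(x, z)
    return float((table["p"] < alpha).mean())
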