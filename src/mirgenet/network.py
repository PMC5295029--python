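"""Integration of expression anticorrelation with target predictions.

A miRNA->gene edge enters the integrated network when (i) the pair is
significantly negatively correlated across samples (one-sided Pearson
test, BH-corrected over all tested pairs) and (ii) the interaction is
predicted by a minimum number of independent target-prediction
databases (2-of-3 consensus by default). Gene candidates are first
restricted to the top fraction by across-sample variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io import ExpressionMatrix, TargetPredictionSet

__all__ = [
    "IntegratedNetwork",
    "variance_top_fraction",
    "pairwise_anticorrelation",
    "consensus_predictions",
    "build_integrated_network",
    "hub_statistics",
    "to_graphml",
]


@dataclass
class IntegratedNetwork:
    """Bipartite miRNA->gene network with correlation and support evidence."""

    edges: pd.DataFrame  # columns mirna_id, gene_id, r, p, q, db_support
    mirna_nodes: list[str] = field(init=False)
    gene_nodes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.mirna_nodes = sorted(self.edges["mirna_id"].unique())
        self.gene_nodes = sorted(self.edges["gene_id"].unique())

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["mirna_id"], self.edges["gene_id"]))


def variance_top_fraction(
    z: ExpressionMatrix, fraction: float = 0.75
) -> list[str]:
    """IDs of the top ``ceil(fraction * q)`` genes by across-sample variance.

    Ties at the cut are resolved toward the lexicographically smaller
    feature identifier.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    var = z.values.var(axis=0, ddof=1)
    frame = pd.DataFrame({"gene_id": z.feature_ids, "var": var})
    frame = frame.sort_values(["var", "gene_id"], ascending=[False, True], kind="stable")
    k = int(np.ceil(fraction * z.n_features))
    return list(frame["gene_id"].iloc[:k])


def pairwise_anticorrelation(
    x_sel: ExpressionMatrix,
    z_sel: ExpressionMatrix,
    alternative: str = "less",
) -> pd.DataFrame:
    """Pearson correlation of every miRNA-gene pair with one-sided tests.

    ``alternative="less"`` (default) tests for negative correlation,
    following the repression hypothesis; ``"two-sided"`` is available.
    Pairs involving a constant vector are skipped with a warning. BH
    q-values are computed over all tested pairs.
    """
    if list(x_sel.sample_ids) != list(z_sel.sample_ids):
        raise ValueError("matrices must share the same samples in the same order")
    n = x_sel.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for a correlation test")
    if alternative not in ("less", "two-sided"):
        raise ValueError("alternative must be 'less' or 'two-sided'")

    xc = x_sel.values - x_sel.values.mean(axis=0)
    zc = z_sel.values - z_sel.values.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    zn = np.linalg.norm(zc, axis=0)
    x_const = xn == 0
    z_const = zn == 0
    if x_const.any() or z_const.any():
        warnings.warn(
            f"skipping {int(x_const.sum())} constant miRNA(s) and "
            f"{int(z_const.sum())} constant gene(s)"
        )
    xn = np.where(x_const, 1.0, xn)
    zn = np.where(z_const, 1.0, zn)
    R = (xc / xn).T @ (zc / zn)  # (p, q)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    if alternative == "less":
        P = stats.t.cdf(tstat, n - 2)
    else:
        P = 2 * stats.t.sf(np.abs(tstat), n - 2)

    mir_idx, gene_idx = np.meshgrid(
        np.arange(x_sel.n_features), np.arange(z_sel.n_features), indexing="ij"
    )
    keep = ~(x_const[mir_idx] | z_const[gene_idx])
    frame = pd.DataFrame(
        {
            "mirna_id": np.asarray(x_sel.feature_ids)[mir_idx.ravel()],
            "gene_id": np.asarray(z_sel.feature_ids)[gene_idx.ravel()],
            "r": R.ravel(),
            "p": P.ravel(),
        }
    )[keep.ravel()].reset_index(drop=True)
    frame["q"] = bh_fdr(frame["p"].to_numpy())
    return frame


def consensus_predictions(
    dbs: list[TargetPredictionSet], min_support: int = 2
) -> pd.DataFrame:
    """Union of database edges with support >= ``min_support``.

    Returns a frame with columns ``mirna_id``, ``gene_id``, ``db_support``.
    """
    if min_support not in (1, 2, 3):
        raise ValueError("min_support must be 1, 2 or 3")
    for db in dbs:
        if len(db) == 0:
            warnings.warn(f"database {db.database_name!r} is empty")
    counts: dict[tuple[str, str], int] = {}
    for db in dbs:
        for e in db.edges:
            counts[e] = counts.get(e, 0) + 1
    rows = [
        (m, g, c) for (m, g), c in sorted(counts.items()) if c >= min_support
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "db_support"])


def build_integrated_network(
    anticorr: pd.DataFrame,
    consensus: pd.DataFrame,
    max_q: float = 0.1,
) -> IntegratedNetwork:
    """Intersect the correlation evidence with the prediction consensus.

    Keeps exactly the edges with ``q < max_q``, ``r < 0`` and database
    support; isolated nodes are excluded by construction.
    """
    sig = anticorr[(anticorr["q"] < max_q) & (anticorr["r"] < 0)]
    edges = sig.merge(consensus, on=["mirna_id", "gene_id"], how="inner")
    edges = edges.sort_values(["mirna_id", "gene_id"], kind="stable").reset_index(drop=True)
    if edges.empty:
        warnings.warn("integrated network is empty under the given thresholds")
    return IntegratedNetwork(edges=edges[["mirna_id", "gene_id", "r", "p", "q", "db_support"]])


def hub_statistics(
    net: IntegratedNetwork, top_k: int = 4, min_cotarget: int = 2
) -> tuple[pd.DataFrame, float, list[str]]:
    """Degree table, top-k miRNA edge coverage, and co-targeted genes.

    Returns ``(degrees, coverage, cotargeted)`` where ``coverage`` is
    the fraction of edges incident to the ``top_k`` highest-degree
    miRNAs (degree ties ranked by node identifier) and ``cotargeted``
    lists genes targeted by at least ``min_cotarget`` miRNAs.
    """
    if net.n_edges == 0:
        raise ValueError("network is empty")
    mir_deg = net.edges["mirna_id"].value_counts()
    gene_deg = net.edges["gene_id"].value_counts()
    degrees = pd.concat(
        [
            pd.DataFrame(
                {"node": mir_deg.index, "block": "mirna", "degree": mir_deg.to_numpy()}
            ),
            pd.DataFrame(
                {"node": gene_deg.index, "block": "gene", "degree": gene_deg.to_numpy()}
            ),
        ]
    )
    degrees = degrees.sort_values(
        ["block", "degree", "node"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    ranked_mirnas = (
        degrees[degrees["block"] == "mirna"]["node"].iloc[:top_k].tolist()
    )
    covered = net.edges["mirna_id"].isin(ranked_mirnas).sum()
    coverage = covered / net.n_edges
    cotargeted = sorted(gene_deg[gene_deg >= min_cotarget].index)
    return degrees, float(coverage), cotargeted


def to_graphml(net: IntegratedNetwork, path) -> None:
    """Export the bipartite network as GraphML for external viewers."""
    import networkx as nx

    g = nx.Graph()
    for m in net.mirna_nodes:
        g.add_node(m, block="mirna")
    for gene in net.gene_nodes:
        g.add_node(gene, block="gene")
    for row in net.edges.itertuples(index=False):
        g.add_edge(
            row.mirna_id,
            row.gene_id,
            r=float(row.r),
            q=float(row.q),
            db_support=int(row.db_support),
        )
    nx.write_graphml(g, path)
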