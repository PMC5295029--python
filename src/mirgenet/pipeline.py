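"""End-to-end orchestration of the integrative miRNA-mRNA analysis.

Stage order: inputs -> detection filter -> miRNA sPLS-DA -> differential
expression -> trait GSEA -> gene sPLS-DA -> rCCA -> target network ->
stSVM signature -> report. Every stage reads its inputs from, and
writes its outputs to, the run directory as plain TSV/JSON, so any
stage can be re-run in isolation and a whole run is byte-reproducible
from (config, seed).

Per-stage randomness is derived from the single global seed via
``SeedSequence((seed, stage_index))``, so a stage re-run sees exactly
the random stream of the original pipeline pass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import diffexp as de
from . import gsea as gs
from . import network as nw
from . import rcca as rc
from . import simulate as sim
from . import splsda as sp
from . import stsvm as st
from .io import (
    ClassLabels,
    ExpressionMatrix,
    GeneSetCollection,
    read_edge_list,
    read_expression,
    read_gmt,
    read_labels,
    write_edge_list,
    write_expression,
    write_gmt,
    write_labels,
)
from .io import detection_filter as _detection_filter
from .io import write_detection

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "run_stage",
    "STAGES",
    "stage_seed",
    "compare_signature_groups",
]

_FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    min_fraction: float = 0.10
    skip: bool = False


@dataclass
class SplsdaParams:
    max_ncomp: int = 10
    keepX_min: int = 1
    keepX_max: int = 50
    keepX_step: int = 1
    folds: int = 10

    @property
    def grid(self) -> tuple[int, ...]:
        return tuple(range(self.keepX_min, self.keepX_max + 1, self.keepX_step))


@dataclass
class DiffexpParams:
    max_q: float = 0.15
    min_abs_log2fc: float = 1.0
    n_perm: int = 1000


@dataclass
class GseaParams:
    n_perm: int = 1000
    weight_exponent: float = 1.0
    min_size: int = 10
    max_size: int = 500
    max_fdr: float = 0.05


@dataclass
class RccaParams:
    grid_size1: int = 100
    grid_size2: int = 100
    folds: int = 10
    inner_radius: float = 0.3
    use_selected: bool = True
    max_dims: int = 2


@dataclass
class NetworkParams:
    variance_fraction: float = 0.75
    min_support: int = 2
    max_q: float = 0.1
    top_k_hubs: int = 4
    min_cotarget: int = 2


@dataclass
class StsvmParams:
    a: float = 2.0
    steps: int = 2
    n_perm: int = 1000
    alpha: float = 0.05
    repeats: int = 10
    folds: int = 10
    C: float = 1.0
    node_set: str = "network"  # or "rcca"


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    inputs: dict | None = None      # paths: mirna, gene, labels, gmt, databases[3]
    synthetic: dict | None = None   # kwargs for simulate.generate_cohort (no seed)
    detection: DetectionParams = field(default_factory=DetectionParams)
    splsda: SplsdaParams = field(default_factory=SplsdaParams)
    diffexp: DiffexpParams = field(default_factory=DiffexpParams)
    gsea: GseaParams = field(default_factory=GseaParams)
    rcca: RccaParams = field(default_factory=RccaParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    stsvm: StsvmParams = field(default_factory=StsvmParams)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'inputs' and 'synthetic' must be configured"
            )
        if self.seed is None:
            raise ValueError("a global seed is mandatory")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sections = {
            "detection": DetectionParams,
            "splsda": SplsdaParams,
            "diffexp": DiffexpParams,
            "gsea": GseaParams,
            "rcca": RccaParams,
            "network": NetworkParams,
            "stsvm": StsvmParams,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in raw:
                kwargs[name] = klass(**raw.pop(name))
        known = {"seed", "outdir", "inputs", "synthetic"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


STAGES = [
    "inputs",
    "detect",
    "splsda_mirna",
    "diffexp",
    "gsea",
    "splsda_gene",
    "rcca",
    "network",
    "stsvm",
    "report",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence((int(global_seed), idx))
    return int(ss.generate_state(1)[0] % (2**31))


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(frame: pd.DataFrame, path, index=False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stage helpers (file-mediated state)
# ---------------------------------------------------------------------------

def _out(cfg: PipelineConfig) -> Path:
    return Path(cfg.outdir)


def _load_mirna(cfg, filtered=True) -> ExpressionMatrix:
    name = "mirna_filtered.tsv" if filtered else "mirna.tsv"
    return read_expression(_out(cfg) / name, orientation="features_in_rows")


def _load_gene(cfg) -> ExpressionMatrix:
    return read_expression(_out(cfg) / "gene.tsv", orientation="features_in_rows")


def _load_labels(cfg) -> ClassLabels:
    return read_labels(_out(cfg) / "labels.tsv")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_inputs(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic is not None:
        cohort = sim.generate_cohort(
            **cfg.synthetic, seed=stage_seed(cfg.seed, "inputs")
        )
        mirna, gene, labels = cohort.mirna, cohort.gene, cohort.labels
        gene_sets, databases = cohort.gene_sets, cohort.databases
        _write_tsv(sim.truth_report(cohort.truth), out / "truth.tsv")
        if mirna.detected is not None:
            write_detection(mirna, out / "mirna_detected.tsv")
    else:
        paths = cfg.inputs
        det = paths.get("mirna_detection")
        mirna = read_expression(paths["mirna"], detected_path=det)
        gene = read_expression(paths["gene"])
        labels = read_labels(paths["labels"])
        gene_sets = read_gmt(paths["gmt"])
        databases = [
            read_edge_list(p, database_name=f"DB{i + 1}")
            for i, p in enumerate(paths["databases"])
        ]
        if mirna.detected is not None:
            write_detection(mirna, out / "mirna_detected.tsv")
    labels.check_matches(mirna)
    labels.check_matches(gene)
    write_expression(mirna, out / "mirna.tsv")
    write_expression(gene, out / "gene.tsv")
    write_labels(labels, out / "labels.tsv")
    write_gmt(gene_sets, out / "gene_sets.gmt")
    for i, db in enumerate(databases):
        write_edge_list(db, out / f"db{i + 1}.tsv")


def _stage_detect(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    det_path = out / "mirna_detected.tsv"
    if cfg.detection.skip or not det_path.exists():
        mirna = _load_mirna(cfg, filtered=False)
        write_expression(mirna, out / "mirna_filtered.tsv")
        _write_json(
            {"filtered": False, "n_features": mirna.n_features},
            out / "detect.json",
        )
        return
    mirna = read_expression(out / "mirna.tsv", detected_path=det_path)
    kept = _detection_filter(mirna, cfg.detection.min_fraction)
    write_expression(kept, out / "mirna_filtered.tsv")
    _write_json(
        {
            "filtered": True,
            "min_fraction": cfg.detection.min_fraction,
            "n_before": mirna.n_features,
            "n_after": kept.n_features,
        },
        out / "detect.json",
    )


def _splsda_block(cfg: PipelineConfig, matrix: ExpressionMatrix, prefix: str, seed: int) -> None:
    out = _out(cfg)
    labels = _load_labels(cfg)
    p = cfg.splsda
    best_ncomp, best_keepX, table = sp.tune_splsda(
        matrix,
        labels,
        max_ncomp=p.max_ncomp,
        keepX_grid=[k for k in p.grid if k <= matrix.n_features],
        folds=p.folds,
        seed=seed,
    )
    model = sp.fit_splsda(matrix, labels, ncomp=best_ncomp, keepX=best_keepX)
    _write_tsv(table, out / f"{prefix}_tuning.tsv")
    loadings = pd.DataFrame(
        model.x_weights,
        index=matrix.feature_ids,
        columns=[f"comp{h + 1}" for h in range(model.ncomp)],
    )
    loadings.index.name = "feature_id"
    _write_tsv(loadings, out / f"{prefix}_loadings.tsv", index=True)
    scores = model.scores_frame(matrix.sample_ids)
    scores.index.name = "sample_id"
    _write_tsv(scores, out / f"{prefix}_scores.tsv", index=True)
    selected = pd.DataFrame(
        [
            (h + 1, f)
            for h in range(model.ncomp)
            for f in model.selected_features(h + 1)
        ],
        columns=["component", "feature_id"],
    )
    _write_tsv(selected, out / f"{prefix}_selected.tsv")
    _write_json(
        {
            "ncomp": model.ncomp,
            "keepX": list(model.keepX),
            "explained_variance": [float(v) for v in model.explained_variance_x],
            "cumulative_variance": float(model.explained_variance_x.sum()),
            "n_selected_unique": len(model.selected_features()),
        },
        out / f"{prefix}_model.json",
    )


def _stage_splsda_mirna(cfg: PipelineConfig) -> None:
    _splsda_block(
        cfg, _load_mirna(cfg), "splsda_mirna", stage_seed(cfg.seed, "splsda_mirna")
    )


def _stage_splsda_gene(cfg: PipelineConfig) -> None:
    _splsda_block(
        cfg, _load_gene(cfg), "splsda_gene", stage_seed(cfg.seed, "splsda_gene")
    )


def _stage_diffexp(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    mirna = _load_mirna(cfg)
    labels = _load_labels(cfg)
    p = cfg.diffexp
    table = de.random_variance_ttest(mirna, labels)
    _write_tsv(table, out / "diffexp_mirna.tsv")
    selected = de.fold_change_filter(table, p.min_abs_log2fc, p.max_q)
    _write_tsv(selected, out / "diffexp_selected.tsv")
    global_p = de.global_permutation_test(
        mirna,
        labels,
        n_perm=p.n_perm,
        fdr_threshold=p.max_q,
        seed=stage_seed(cfg.seed, "diffexp"),
    )
    _write_json(
        {
            "n_significant": int((table["q"] <= p.max_q).sum()),
            "n_after_fold_change": len(selected),
            "n_up": selected.attrs.get("n_up", {}),
            "global_permutation_p": global_p,
            "prior_a": table.attrs["prior_a"],
        },
        out / "diffexp_global.json",
    )


def _stage_gsea(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    gene = _load_gene(cfg)
    gene_sets = read_gmt(out / "gene_sets.gmt")
    scores = pd.read_csv(out / "splsda_mirna_scores.tsv", sep="\t", index_col=0)
    p = cfg.gsea
    seed = stage_seed(cfg.seed, "gsea")
    for h, comp in enumerate(scores.columns[:2], start=1):
        table = gs.gsea_phenotype_permutation(
            gene,
            scores[comp].to_numpy(),
            gene_sets,
            n_perm=p.n_perm,
            weight_exponent=p.weight_exponent,
            min_size=p.min_size,
            max_size=p.max_size,
            seed=seed + h,
        )
        table["significant"] = table["q"] < p.max_fdr
        _write_tsv(table, out / f"gsea_comp{h}.tsv")


def _stage_rcca(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    labels = _load_labels(cfg)  # noqa: F841  (kept for stage symmetry)
    mirna = _load_mirna(cfg)
    gene = _load_gene(cfg)
    p = cfg.rcca
    if p.use_selected:
        sel_m = pd.read_csv(out / "splsda_mirna_selected.tsv", sep="\t")
        sel_g = pd.read_csv(out / "splsda_gene_selected.tsv", sep="\t")
        x = mirna.subset_features(sorted(sel_m["feature_id"].unique()))
        z = gene.subset_features(sorted(sel_g["feature_id"].unique()))
    else:
        x, z = mirna, gene
    g1, g2 = rc.default_lambda_grids(p.grid_size1, p.grid_size2)
    l1, l2, surface = rc.tune_rcca(
        x, z, g1, g2, folds=p.folds, seed=stage_seed(cfg.seed, "rcca")
    )
    model = rc.fit_rcca(x, z, l1, l2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = rc.select_dimensions(model.canonical_correlations)
    model.d = d
    _write_tsv(surface, out / "rcca_surface.tsv")
    _write_tsv(
        pd.DataFrame(
            {
                "dimension": np.arange(1, model.ncomp + 1),
                "canonical_correlation": model.canonical_correlations,
            }
        ),
        out / "rcca_correlations.tsv",
    )
    circle = rc.correlation_circle(
        model, x, z, inner_radius=p.inner_radius, ndim=min(d, p.max_dims)
    )
    _write_tsv(circle, out / "circle_points.tsv")
    try:
        sim_mat, row_order, col_order = rc.cim_similarity(circle)
        sim_mat.index.name = "mirna_id"
        _write_tsv(sim_mat, out / "cim_similarity.tsv", index=True)
        orders = {
            "row_order": [int(i) for i in row_order],
            "col_order": [int(i) for i in col_order],
        }
    except ValueError:
        orders = {"row_order": [], "col_order": []}
    _write_json(
        {
            "lambda1": l1,
            "lambda2": l2,
            "d_selected": int(d),
            "n_retained_mirna": int((circle["block"] == "mirna").sum()),
            "n_retained_gene": int((circle["block"] == "gene").sum()),
            **orders,
        },
        out / "rcca_model.json",
    )


def _stage_network(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    mirna = _load_mirna(cfg)
    gene = _load_gene(cfg)
    p = cfg.network
    circle = pd.read_csv(out / "circle_points.tsv", sep="\t")
    mir_ids = sorted(circle.loc[circle["block"] == "mirna", "feature_id"])
    gene_ids = sorted(circle.loc[circle["block"] == "gene", "feature_id"])
    if not mir_ids or not gene_ids:
        raise ValueError("no retained features to correlate; relax inner_radius")
    top_genes = set(nw.variance_top_fraction(gene, p.variance_fraction))
    gene_ids = [g for g in gene_ids if g in top_genes]
    x_sel = mirna.subset_features(mir_ids)
    z_sel = gene.subset_features(gene_ids)
    anticorr = nw.pairwise_anticorrelation(x_sel, z_sel)
    _write_tsv(anticorr, out / "anticorrelation.tsv")
    dbs = [read_edge_list(out / f"db{i + 1}.tsv", f"DB{i + 1}") for i in range(3)]
    consensus = nw.consensus_predictions(dbs, p.min_support)
    net = nw.build_integrated_network(anticorr, consensus, p.max_q)
    _write_tsv(net.edges, out / "network_edges.tsv")
    nw.to_graphml(net, out / "network.graphml")
    if net.n_edges:
        degrees, coverage, cotargeted = nw.hub_statistics(
            net, top_k=p.top_k_hubs, min_cotarget=p.min_cotarget
        )
        _write_tsv(degrees, out / "network_degrees.tsv")
    else:
        coverage, cotargeted = 0.0, []
    _write_json(
        {
            "n_edges": net.n_edges,
            "n_mirnas": len(net.mirna_nodes),
            "n_genes": len(net.gene_nodes),
            "top_k_coverage": coverage,
            "cotargeted_genes": cotargeted,
        },
        out / "network_summary.json",
    )


def _combined_matrix(
    mirna: ExpressionMatrix, gene: ExpressionMatrix, node_ids
) -> ExpressionMatrix:
    mir_set, gene_set = set(mirna.feature_ids), set(gene.feature_ids)
    cols, ids = [], []
    for nd in node_ids:
        if nd in mir_set:
            cols.append(mirna.values[:, mirna.feature_ids.index(nd)])
        elif nd in gene_set:
            cols.append(gene.values[:, gene.feature_ids.index(nd)])
        else:
            raise KeyError(f"network node {nd!r} found in neither block")
        ids.append(nd)
    return ExpressionMatrix(list(mirna.sample_ids), ids, np.column_stack(cols))


def _stage_stsvm(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    mirna = _load_mirna(cfg)
    gene = _load_gene(cfg)
    labels = _load_labels(cfg)
    p = cfg.stsvm
    edges = pd.read_csv(out / "network_edges.tsv", sep="\t")
    net = nw.IntegratedNetwork(edges=edges)
    if net.n_edges == 0:
        raise ValueError("integrated network is empty; stSVM has no node set")
    extra = []
    if p.node_set == "rcca":
        circle = pd.read_csv(out / "circle_points.tsv", sep="\t")
        extra = [
            f
            for f in circle["feature_id"]
            if f not in set(net.mirna_nodes) | set(net.gene_nodes)
        ]
    graph = st.build_feature_graph(net, extra_nodes=extra)
    kernel = st.random_walk_kernel(graph, a=p.a, steps=p.steps)
    combined = _combined_matrix(mirna, gene, graph.nodes)
    seed = stage_seed(cfg.seed, "stsvm")
    table = st.permutation_select(
        combined, labels, kernel, n_perm=p.n_perm, alpha=p.alpha, seed=seed
    )
    _write_tsv(table, out / "stsvm_selection.tsv")
    selected = list(table.loc[table["selected"], "feature_id"])
    result = st.cv_evaluate(
        combined.subset_features(selected),
        labels,
        repeats=p.repeats,
        folds=p.folds,
        seed=seed + 1,
        C=p.C,
    )
    _write_tsv(result.roc, out / "roc.tsv")
    _write_json(
        {
            "signature": selected,
            "n_selected": len(selected),
            "auc_mean": result.auc_mean,
            "auc_sd": result.auc_sd,
            "per_repeat_auc": [float(a) for a in result.per_repeat_auc],
        },
        out / "stsvm_performance.json",
    )


def _stage_report(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    report = {"stages": STAGES[:-1]}
    for name in [
        "detect.json",
        "splsda_mirna_model.json",
        "diffexp_global.json",
        "splsda_gene_model.json",
        "rcca_model.json",
        "network_summary.json",
        "stsvm_performance.json",
    ]:
        path = out / name
        if path.exists():
            with open(path) as fh:
                report[name.removesuffix(".json")] = json.load(fh)
    _write_json(report, out / "report.json")


_STAGE_FUNCS = {
    "inputs": _stage_inputs,
    "detect": _stage_detect,
    "splsda_mirna": _stage_splsda_mirna,
    "diffexp": _stage_diffexp,
    "gsea": _stage_gsea,
    "splsda_gene": _stage_splsda_gene,
    "rcca": _stage_rcca,
    "network": _stage_network,
    "stsvm": _stage_stsvm,
    "report": _stage_report,
}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    """Run one stage against the serialized state in ``cfg.outdir``."""
    if name not in _STAGE_FUNCS:
        raise PipelineError(name, "validation_error", f"unknown stage {name!r}")
    try:
        _STAGE_FUNCS[name](cfg)
    except PipelineError:
        raise
    except (ValueError, KeyError, FileNotFoundError) as exc:
        raise PipelineError(name, "computation_error", str(exc)) from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the report dictionary."""
    out = _out(cfg)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in STAGES},
    }
    _write_json(manifest, out / "manifest.json")
    for name in STAGES:
        run_stage(name, cfg)
    with open(out / "report.json") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# generic signature comparison across independent sample groups
# ---------------------------------------------------------------------------

def compare_signature_groups(
    expr: ExpressionMatrix, groups: ClassLabels, features
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of signature features between groups.

    Returns per-feature two-sided p, BH q and the direction (which group
    shows the higher median).
    """
    groups.check_matches(expr)
    mask0, mask1 = groups.indicator()
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = expr.subset_features(list(features))
    rows = []
    for j, fid in enumerate(sub.feature_ids):
        v0, v1 = sub.values[mask0, j], sub.values[mask1, j]
        stat, p = stats.mannwhitneyu(v0, v1, alternative="two-sided")
        direction = (
            f"up_in_{groups.classes[0]}"
            if np.median(v0) > np.median(v1)
            else f"up_in_{groups.classes[1]}"
        )
        rows.append((fid, stat, p, direction))
    table = pd.DataFrame(rows, columns=["feature_id", "u_statistic", "p", "direction"])
    table["q"] = de.bh_fdr(table["p"].to_numpy())
    return table
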