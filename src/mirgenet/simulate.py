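"""Synthetic paired miRNA/gene cohorts with planted, recoverable structure.

The generator emulates the study design every downstream stage is built
for: two unbalanced outcome classes (default 14 vs 26 samples), a miRNA
block of strong univariate discriminators ("component 1"), a second
block of miRNA pairs that discriminate only jointly ("component 2"),
linear miRNA->target repression producing negative miRNA-gene
correlations, gene sets marking the planted target block, and three
noisy target-prediction databases with known true/false positive rates.

All intensities are Gaussian on the log2 scale; class structure enters
only through mean shifts, so every downstream statistic (t-based,
correlation-based) sees a model matching its own assumptions.

Design notes
------------
* Component-1 miRNAs are shifted between classes by ``effect_size``
  within-class standard deviations.
* Component-2 miRNAs come in pairs ``(a, b) = (u + s, u - s)`` where
  ``u`` is a shared latent with standard deviation ``masking_sd_factor``
  times the noise level and ``s`` carries the class shift. The contrast
  ``a - b`` cancels ``u`` and separates the classes sharply while each
  marginal shift is masked down to ~``effect_size / (2 *
  masking_sd_factor)`` standardized units -- statistically invisible to
  a per-feature t-test at these sample sizes.
* Each planted target gene is ``baseline - repression_slope * mean(its
  parent miRNAs) + noise``; by default every target is co-targeted by
  all regulator miRNAs, the hub topology typical of real miRNA-target
  networks. With a single parent this reduces to plain linear
  repression.
* Database k contains each true edge with probability ``tpr[k]`` and
  each random non-edge with probability ``fpr[k]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ClassLabels,
    ExpressionMatrix,
    GeneSetCollection,
    TargetPredictionSet,
)

__all__ = ["SyntheticTruth", "SyntheticCohort", "generate_cohort", "truth_report"]

_CLASS0, _CLASS1 = "long", "short"  # alphabetical order fixes class0 = long


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    component1_mirnas: list[str]
    component2_mirnas: list[str]
    component2_pairs: list[tuple[str, str]]
    regulator_mirnas: list[str]
    target_genes: list[str]
    target_map: list[tuple[str, str, float]]  # (mirna, gene, slope)
    enriched_sets: dict[str, list[str]]
    low_detection_mirnas: list[str]
    class_assignment: dict[str, str]
    tpr: tuple[float, float, float]
    fpr: tuple[float, float, float]

    def __post_init__(self) -> None:
        if set(self.component1_mirnas) & set(self.component2_mirnas):
            raise ValueError("component-1 and component-2 miRNA lists overlap")
        known = set(self.component1_mirnas) | set(self.component2_mirnas)
        for m, g, _ in self.target_map:
            if m not in known:
                raise ValueError(f"target_map references unknown miRNA {m!r}")

    @property
    def true_edges(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.target_map}

    @property
    def signature_features(self) -> list[str]:
        return list(self.regulator_mirnas) + list(self.target_genes)


@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`."""

    mirna: ExpressionMatrix
    gene: ExpressionMatrix
    labels: ClassLabels
    gene_sets: GeneSetCollection
    databases: list[TargetPredictionSet]
    truth: SyntheticTruth


def generate_cohort(
    n_class0: int = 14,
    n_class1: int = 26,
    p_mirna: int = 614,
    q_gene: int = 2000,
    n_component1: int = 10,
    n_component2_pairs: int = 6,
    n_regulators: int = 3,
    n_targets: int = 5,
    effect_size: float = 2.0,
    repression_slope: float = 1.0,
    noise_sd: float = 1.0,
    target_noise_sd: float | None = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    masking_sd_factor: float = 10.0,
    contrast_noise_factor: float = 0.2,
    co_targeting: bool = True,
    n_null_sets: int = 20,
    tpr: tuple[float, float, float] = (0.8, 0.8, 0.8),
    fpr: tuple[float, float, float] = (0.02, 0.02, 0.02),
    n_low_detection: int = 10,
    low_detection_rate: float = 0.02,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate one paired miRNA/gene cohort with planted ground truth.

    Defaults reproduce the reference study design: 14 + 26 samples, 614
    miRNAs, 2,000 genes, standardized effect size 2, three regulator
    miRNAs repressing five target genes, and three prediction databases
    at TPR 0.8 / FPR 0.02.

    Returns a :class:`SyntheticCohort`; determinism is total in ``seed``.
    """
    if n_class0 < 2 or n_class1 < 2:
        raise ValueError("each class needs at least 2 samples")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if target_noise_sd is None:
        target_noise_sd = noise_sd
    if target_noise_sd < 0:
        raise ValueError("target_noise_sd must be non-negative")
    if n_regulators > n_component1:
        raise ValueError("n_regulators cannot exceed n_component1")
    n_planted_mirna = n_component1 + 2 * n_component2_pairs
    if p_mirna < n_planted_mirna + n_low_detection:
        raise ValueError("p_mirna too small for the requested planted structure")
    if q_gene < n_targets + (n_null_sets + 1) * n_targets:
        raise ValueError("q_gene too small for the requested gene sets")

    rng = np.random.default_rng(seed)
    n = n_class0 + n_class1
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = ClassLabels(
        sample_ids, [_CLASS0] * n_class0 + [_CLASS1] * n_class1
    )
    cls = np.asarray([0] * n_class0 + [1] * n_class1)

    mirna_ids = [f"miR-{j + 1:04d}" for j in range(p_mirna)]
    gene_ids = [f"GENE{j + 1:05d}" for j in range(q_gene)]

    # planted positions, drawn without replacement so ordering artifacts
    # cannot help recovery
    planted_idx = rng.choice(p_mirna, size=n_planted_mirna + n_low_detection, replace=False)
    comp1_idx = planted_idx[:n_component1]
    comp2_idx = planted_idx[n_component1:n_planted_mirna]
    lowdet_idx = planted_idx[n_planted_mirna:]
    comp1 = [mirna_ids[j] for j in comp1_idx]
    comp2_pairs_idx = comp2_idx.reshape(n_component2_pairs, 2) if n_component2_pairs else np.empty((0, 2), int)
    comp2 = [mirna_ids[j] for j in comp2_idx]

    # --- miRNA matrix -------------------------------------------------
    baselines_m = rng.normal(baseline_mean, baseline_sd, size=p_mirna)
    X = baselines_m[None, :] + rng.normal(0.0, noise_sd, size=(n, p_mirna))
    # component 1: shift class1 up by effect_size within-class SDs
    X[:, comp1_idx] += (effect_size * noise_sd) * cls[:, None]
    # component 2: masked contrast pairs
    for a_idx, b_idx in comp2_pairs_idx:
        u = rng.normal(0.0, masking_sd_factor * noise_sd, size=n)
        s = (effect_size * noise_sd / 2.0) * (cls - 0.5) + rng.normal(
            0.0, contrast_noise_factor * noise_sd, size=n
        )
        X[:, a_idx] = baselines_m[a_idx] + u + s
        X[:, b_idx] = baselines_m[b_idx] + u - s

    # --- gene matrix --------------------------------------------------
    regulators = comp1[:n_regulators]
    target_idx = rng.choice(q_gene, size=n_targets, replace=False)
    targets = [gene_ids[j] for j in target_idx]
    baselines_g = rng.normal(baseline_mean, baseline_sd, size=q_gene)
    Z = baselines_g[None, :] + rng.normal(0.0, noise_sd, size=(n, q_gene))
    target_map: list[tuple[str, str, float]] = []
    for k, g_idx in enumerate(target_idx):
        if co_targeting:
            parents = regulators
        else:
            parents = [regulators[k % n_regulators]]
        parent_cols = [mirna_ids.index(m) for m in parents]
        pressure = X[:, parent_cols].mean(axis=1) - baselines_m[parent_cols].mean()
        Z[:, g_idx] = (
            baselines_g[g_idx]
            - repression_slope * pressure
            + rng.normal(0.0, target_noise_sd, size=n)
        )
        for m in parents:
            target_map.append((m, gene_ids[g_idx], repression_slope))

    # --- detection flags ----------------------------------------------
    detected = np.ones((n, p_mirna), dtype=bool)
    if n_low_detection:
        detected[:, lowdet_idx] = rng.random((n, len(lowdet_idx))) < low_detection_rate

    # --- gene sets ----------------------------------------------------
    sets: dict[str, list[str]] = {"TARGET_BLOCK_C1": list(targets)}
    descriptions = {"TARGET_BLOCK_C1": "planted targets of regulator miRNAs"}
    non_target = [g for g in gene_ids if g not in set(targets)]
    null_pool = rng.permutation(non_target)
    for k in range(n_null_sets):
        name = f"NULL_SET_{k + 1:02d}"
        sets[name] = list(null_pool[k * n_targets : (k + 1) * n_targets])
        descriptions[name] = "size-matched random gene set"
    gene_sets = GeneSetCollection(sets=sets, descriptions=descriptions)

    # --- prediction databases -----------------------------------------
    true_edges = {(m, g) for m, g, _ in target_map}
    databases = []
    for k in range(3):
        edges: set[tuple[str, str]] = set()
        for e in sorted(true_edges):
            if rng.random() < tpr[k]:
                edges.add(e)
        total_pairs = p_mirna * q_gene
        n_false = rng.binomial(total_pairs - len(true_edges), fpr[k])
        flat = rng.choice(total_pairs, size=n_false, replace=False)
        for f in flat:
            e = (mirna_ids[f // q_gene], gene_ids[f % q_gene])
            if e not in true_edges:
                edges.add(e)
        databases.append(TargetPredictionSet(f"DB{k + 1}", edges))

    truth = SyntheticTruth(
        component1_mirnas=comp1,
        component2_mirnas=comp2,
        component2_pairs=[
            (mirna_ids[a], mirna_ids[b]) for a, b in comp2_pairs_idx
        ],
        regulator_mirnas=list(regulators),
        target_genes=list(targets),
        target_map=target_map,
        enriched_sets={"component1": ["TARGET_BLOCK_C1"]},
        low_detection_mirnas=[mirna_ids[j] for j in lowdet_idx],
        class_assignment=dict(zip(sample_ids, labels.labels)),
        tpr=tuple(tpr),
        fpr=tuple(fpr),
    )
    mirna = ExpressionMatrix(sample_ids, mirna_ids, X, detected=detected)
    gene = ExpressionMatrix(sample_ids, gene_ids, Z)
    return SyntheticCohort(mirna, gene, labels, gene_sets, databases, truth)


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Tidy table of everything planted, for test assertions and logs.

    Columns: ``kind``, ``name``, ``partner``, ``value``. Round-trips
    through TSV unchanged.
    """
    rows: list[tuple[str, str, str, float]] = []
    for m in truth.component1_mirnas:
        rows.append(("component1_mirna", m, "", np.nan))
    for m in truth.component2_mirnas:
        rows.append(("component2_mirna", m, "", np.nan))
    for a, b in truth.component2_pairs:
        rows.append(("component2_pair", a, b, np.nan))
    for m in truth.regulator_mirnas:
        rows.append(("regulator_mirna", m, "", np.nan))
    for g in truth.target_genes:
        rows.append(("target_gene", g, "", np.nan))
    for m, g, slope in truth.target_map:
        rows.append(("target_edge", m, g, slope))
    for comp, names in truth.enriched_sets.items():
        for s in names:
            rows.append(("enriched_set", s, comp, np.nan))
    for m in truth.low_detection_mirnas:
        rows.append(("low_detection_mirna", m, "", np.nan))
    for s, c in truth.class_assignment.items():
        rows.append(("class_assignment", s, c, np.nan))
    return pd.DataFrame(rows, columns=["kind", "name", "partner", "value"])
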