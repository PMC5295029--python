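"""Gene-set enrichment against a continuous per-sample trait.

Genes are ranked by Pearson correlation with the trait (here typically
an sPLS-DA component score), the enrichment score is the signed
extremum of the weighted Kolmogorov-Smirnov running sum, and
significance comes from phenotype permutation: the trait vector is
permuted across samples, the whole ranking is recomputed, and nominal
p, NES and FDR follow the standard same-sign normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ClassLabels, ExpressionMatrix, GeneSetCollection

__all__ = [
    "rank_by_trait_correlation",
    "enrichment_score",
    "gsea_phenotype_permutation",
    "goplot_zscore",
]


def _pearson_with_trait(values: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r of ``values`` with ``trait``; constant columns -> 0."""
    t = trait - trait.mean()
    t_norm = np.linalg.norm(t)
    if t_norm == 0:
        raise ValueError("trait is constant; correlation ranking undefined")
    v = values - values.mean(axis=0)
    v_norm = np.linalg.norm(v, axis=0)
    const = v_norm == 0
    v_norm = np.where(const, 1.0, v_norm)
    r = (v.T @ t) / (v_norm * t_norm)
    r[const] = 0.0
    return r


def rank_by_trait_correlation(
    z: ExpressionMatrix, trait: np.ndarray
) -> pd.DataFrame:
    """Rank genes by decreasing Pearson correlation with ``trait``.

    Ties break by gene identifier. Constant genes get r = 0 with a
    warning. Returns a frame with columns ``gene_id`` and ``score``.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape != (z.n_samples,):
        raise ValueError("trait length must equal the number of samples")
    r = _pearson_with_trait(z.values, trait)
    if np.any((z.values.std(axis=0) == 0)):
        warnings.warn("constant gene(s) assigned correlation 0")
    frame = pd.DataFrame({"gene_id": z.feature_ids, "score": r})
    frame = frame.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return frame


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of ``gene_set`` on a ranked list.

    ``ranked`` is the output of :func:`rank_by_trait_correlation`. Hits
    advance the running sum by ``|score|**weight_exponent`` (normalized
    over hits), misses retreat by ``1 / (N - N_hits)``. Returns the
    signed maximum deviation and the full running sum.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == len(genes):
        raise ValueError("gene set overlap must satisfy 1 <= overlap < N")
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to equal steps
        hit_w = hit.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit) / (len(genes) - n_hit)
    running = np.cumsum(steps)
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


def _leading_edge(ranked, gene_set, running) -> list[str]:
    genes = ranked["gene_id"].to_numpy()
    members = set(gene_set)
    peak = int(np.argmax(np.abs(running)))
    if running[peak] >= 0:
        region = genes[: peak + 1]
    else:
        region = genes[peak:]
    return [g for g in region if g in members]


def goplot_zscore(n_up: int, n_down: int) -> float:
    """Bubble-plot z-score ``(n_up - n_down) / sqrt(n_up + n_down)``."""
    total = n_up + n_down
    if total == 0:
        raise ValueError("empty gene set has no z-score")
    return (n_up - n_down) / np.sqrt(total)


def gsea_phenotype_permutation(
    z: ExpressionMatrix,
    trait: np.ndarray,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Full GSEA of ``sets`` against a continuous trait.

    The trait is permuted across samples ``n_perm`` times; nominal p and
    NES use same-sign permuted scores, FDR q follows the standard
    NES-pooling procedure. Sets falling outside ``[min_size, max_size]``
    after intersection with the expression matrix are dropped with a
    warning. Columns: ``set``, ``size``, ``es``, ``nes``, ``p``, ``q``,
    ``z_score``, ``direction``, ``leading_edge``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    trait = np.asarray(trait, dtype=float)
    universe = set(z.feature_ids)
    kept: dict[str, list[str]] = {}
    for name, members in sets:
        inter = sorted(set(members) & universe)
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
        else:
            warnings.warn(
                f"gene set {name!r} dropped (size {len(inter)} outside "
                f"[{min_size}, {max_size}] after intersection)"
            )
    if not kept:
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p", "q", "z_score", "direction", "leading_edge"]
        )

    ranked = rank_by_trait_correlation(z, trait)
    obs = {}
    for name, members in kept.items():
        es, running = enrichment_score(ranked, members, weight_exponent)
        direction_scores = ranked.set_index("gene_id")["score"]
        n_up = int((direction_scores.loc[members] > 0).sum())
        n_down = len(members) - n_up
        obs[name] = {
            "es": es,
            "z": goplot_zscore(n_up, n_down),
            "lead": _leading_edge(ranked, members, running),
        }

    rng = np.random.default_rng(seed)
    names = list(kept)
    perm_es = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        perm_trait = rng.permutation(trait)
        ranked_b = rank_by_trait_correlation(z, perm_trait)
        for j, name in enumerate(names):
            es_b, _ = enrichment_score(ranked_b, kept[name], weight_exponent)
            perm_es[b, j] = es_b

    # per-set same-sign normalization
    nes_obs = np.empty(len(names))
    p_nom = np.empty(len(names))
    pos_mean = np.empty(len(names))
    neg_mean = np.empty(len(names))
    nes_perm = np.full_like(perm_es, np.nan)
    for j, name in enumerate(names):
        col = perm_es[:, j]
        pos = col[col >= 0]
        neg = col[col < 0]
        pos_mean[j] = pos.mean() if pos.size else np.nan
        neg_mean[j] = np.abs(neg).mean() if neg.size else np.nan
        es = obs[name]["es"]
        if es >= 0:
            same = pos
            p_nom[j] = (1 + int((same >= es).sum())) / (1 + same.size)
            nes_obs[j] = es / pos_mean[j] if pos.size else np.nan
        else:
            same = neg
            p_nom[j] = (1 + int((same <= es).sum())) / (1 + same.size)
            nes_obs[j] = -abs(es) / neg_mean[j] if neg.size else np.nan
        with np.errstate(invalid="ignore"):
            nes_perm[:, j] = np.where(
                col >= 0,
                col / pos_mean[j] if pos.size else np.nan,
                -np.abs(col) / neg_mean[j] if neg.size else np.nan,
            )

    # FDR on pooled normalized scores
    pool = nes_perm[np.isfinite(nes_perm)]
    q = np.empty(len(names))
    for j in range(len(names)):
        nes = nes_obs[j]
        if not np.isfinite(nes):
            q[j] = 1.0
            continue
        if nes >= 0:
            num_pool = pool[pool >= 0]
            frac_perm = (num_pool >= nes).mean() if num_pool.size else 1.0
            obs_pos = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            frac_obs = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            num_pool = pool[pool < 0]
            frac_perm = (num_pool <= nes).mean() if num_pool.size else 1.0
            obs_neg = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
            frac_obs = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        q[j] = min(1.0, frac_perm / frac_obs) if frac_obs > 0 else 1.0

    table = pd.DataFrame(
        {
            "set": names,
            "size": [len(kept[n]) for n in names],
            "es": [obs[n]["es"] for n in names],
            "nes": nes_obs,
            "p": p_nom,
            "q": q,
            "z_score": [obs[n]["z"] for n in names],
            "direction": ["positive" if obs[n]["es"] >= 0 else "negative" for n in names],
            "leading_edge": ["|".join(obs[n]["lead"]) for n in names],
        }
    )
    return table.sort_values(["q", "p", "set"], kind="stable").reset_index(drop=True)
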