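"""Differential expression with a random-variance (shrunken) t-test.

The per-feature pooled variance ``s2`` is shrunk toward an
inverse-gamma prior fitted across all features: assuming ``1/sigma2 ~
Gamma(a, rate=r)`` and ``(n-2) * s2 / sigma2 ~ chi2(n-2)``, the
posterior point estimate is

    s2_shrunk = ((n - 2) * s2 + 2 * r) / (n - 2 + 2 * a)

and the t-statistic built on it gains ``2a`` degrees of freedom. The
prior is fitted by a closed-form method of moments on ``log s2``:

    E[log s2]   = log r - psi(a) + psi(d/2) - log(d/2)
    Var[log s2] = psi'(a) + psi'(d/2)          with d = n - 2,

so ``a`` solves ``psi'(a) = Var[log s2] - psi'(d/2)`` (trigamma is
strictly decreasing, giving a unique root) and ``r`` follows from the
mean equation. When the observed log-variance spread is smaller than
the chi-square sampling spread the moments are inconsistent; the prior
weight is then set to zero and the statistic falls back to the ordinary
pooled-variance t-test with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import ClassLabels, ExpressionMatrix

__all__ = [
    "fit_variance_prior",
    "random_variance_ttest",
    "bh_fdr",
    "fold_change_filter",
    "global_permutation_test",
]


def fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Fit the inverse-gamma variance prior; returns ``(a, rate)``.

    ``a = 0`` signals the ordinary-t fallback (no shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 3:
        return 0.0, 0.0
    logs = np.log(s2)
    v = float(np.var(logs, ddof=1))
    target = v - float(special.polygamma(1, d / 2.0))
    if not np.isfinite(target) or target <= 0:
        return 0.0, 0.0
    # trigamma(a) is strictly decreasing from +inf to 0 on (0, inf)
    f = lambda a: float(special.polygamma(1, a)) - target
    lo, hi = 1e-8, 1e8
    if f(lo) < 0 or f(hi) > 0:
        return 0.0, 0.0
    a = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    m = float(np.mean(logs))
    rate = np.exp(
        m + special.digamma(a) - special.digamma(d / 2.0) + np.log(d / 2.0)
    )
    return float(a), float(rate)


def _ttest_core(
    values: np.ndarray,
    mask0: np.ndarray,
    mask1: np.ndarray,
    prior: tuple[float, float] | None = None,
):
    """Vectorized shrunken t over the columns of ``values``.

    Returns ``(t, df, p, s2, s2_shrunk, mean0, mean1, a, rate)``. When
    ``prior`` is given it is reused (training statistics); otherwise it
    is fitted from the data at hand.
    """
    n0, n1 = int(mask0.sum()), int(mask1.sum())
    d = n0 + n1 - 2
    x0, x1 = values[mask0], values[mask1]
    mean0, mean1 = x0.mean(axis=0), x1.mean(axis=0)
    ss0 = ((x0 - mean0) ** 2).sum(axis=0)
    ss1 = ((x1 - mean1) ** 2).sum(axis=0)
    s2 = (ss0 + ss1) / d
    if prior is None:
        a, rate = fit_variance_prior(s2, d)
    else:
        a, rate = prior
    if a > 0:
        s2_shrunk = (d * s2 + 2.0 * rate) / (d + 2.0 * a)
        df = d + 2.0 * a
    else:
        s2_shrunk = s2
        df = float(d)
    se = np.sqrt(s2_shrunk * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean0 - mean1) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p, s2, s2_shrunk, mean0, mean1, a, rate


def random_variance_ttest(
    x: ExpressionMatrix, y: ClassLabels, shrink: bool = True
) -> pd.DataFrame:
    """Two-sample shrunken-variance t-test per feature.

    Returns a table indexed like ``x.feature_ids`` with columns
    ``mean_<class0>``, ``mean_<class1>``, ``log2_fc`` (positive = higher
    in class0), ``var_pooled``, ``var_shrunk``, ``t``, ``df``, ``p``,
    ``q``. The fitted prior is exposed in ``table.attrs["prior_a"]`` and
    ``attrs["prior_rate"]`` (with ``b = a / rate`` matching the
    shrinkage form ``2a/b = 2 * rate``).
    """
    y.check_matches(x)
    mask0, mask1 = y.indicator()
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    prior = (0.0, 0.0) if not shrink else None
    t, df, p, s2, s2_shrunk, mean0, mean1, a, rate = _ttest_core(
        x.values, mask0, mask1, prior
    )
    if shrink and a == 0.0:
        warnings.warn(
            "variance prior could not be fitted (log-variance spread consistent "
            "with a common variance); using the ordinary pooled t-test"
        )
    table = pd.DataFrame(
        {
            "feature_id": x.feature_ids,
            f"mean_{y.classes[0]}": mean0,
            f"mean_{y.classes[1]}": mean1,
            "log2_fc": mean0 - mean1,
            "var_pooled": s2,
            "var_shrunk": s2_shrunk,
            "t": t,
            "df": df,
            "p": p,
        }
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    table.attrs["prior_a"] = a
    table.attrs["prior_rate"] = rate
    table.attrs["classes"] = y.classes
    return table


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_filter(
    table: pd.DataFrame, min_abs_log2fc: float = 1.0, max_q: float = 0.15
) -> pd.DataFrame:
    """Select features with ``q <= max_q`` and ``|log2_fc| > min_abs_log2fc``.

    The fold-change inequality is strict, so a feature at exactly the
    threshold is excluded. The returned table keeps the input columns
    and adds ``direction`` (``up_in_<class>``); counts per direction are
    in ``result.attrs["n_up"]``.
    """
    classes = table.attrs.get("classes", ("class0", "class1"))
    sel = table[(table["q"] <= max_q) & (table["log2_fc"].abs() > min_abs_log2fc)].copy()
    sel["direction"] = np.where(
        sel["log2_fc"] > 0, f"up_in_{classes[0]}", f"up_in_{classes[1]}"
    )
    sel.attrs["n_up"] = {
        classes[0]: int((sel["log2_fc"] > 0).sum()),
        classes[1]: int((sel["log2_fc"] < 0).sum()),
    }
    sel.attrs["classes"] = classes
    return sel


def _significant_count(values, mask0, mask1, fdr_threshold) -> int:
    _, _, p, *_ = _ttest_core(values, mask0, mask1)
    q = bh_fdr(p)
    return int((q <= fdr_threshold).sum())


def global_permutation_test(
    x: ExpressionMatrix,
    y: ClassLabels,
    n_perm: int = 1000,
    fdr_threshold: float = 0.15,
    seed: int = 0,
) -> float:
    """Global class-difference test by label permutation.

    Re-runs the full shrunken t-test + BH correction under ``n_perm``
    random label permutations and returns the add-one permutation
    p-value for observing at least as many features significant at
    ``fdr_threshold`` as under the true labels.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y.check_matches(x)
    mask0, mask1 = y.indicator()
    observed = _significant_count(x.values, mask0, mask1, fdr_threshold)
    if observed == 0:
        warnings.warn("no significant features under the true labels; p = 1")
        return 1.0
    rng = np.random.default_rng(seed)
    n = x.n_samples
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _significant_count(x.values, mask0[perm], mask1[perm], fdr_threshold) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
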