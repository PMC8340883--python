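"""Negative-binomial differential expression for small three-group designs.

The model follows the standard count-based DE recipe: per-sample size factors
by median-of-ratios, per-feature NB dispersion by method of moments shrunk
halfway toward a mean-dispersion trend, and a Wald test on the log2 ratio of
normalized group means (delta-method standard error from the NB variance
mu + phi*mu^2). Benjamini-Hochberg correction is applied per contrast.

Fold changes are reported in the signed linear convention common in
differential-expression tables: 2^log2fc when up, -2^(-log2fc) when down, so
a halving prints as -2 and |signed fold change| >= 1 always.

This is a self-contained NB Wald pipeline tuned for desk-scale designs
(n = 3 per group); numerical agreement with any particular large DE framework
is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "DECriteria",
    "DEResult",
    "size_factors",
    "estimate_dispersion",
    "de_test",
    "signed_fold_change",
    "bh_fdr",
    "filter_de",
]


@dataclass(frozen=True)
class DECriteria:
    """Significance gate for calling a feature differentially expressed."""

    fdr_max: float = 0.05
    min_abs_fc: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError(f"fdr_max must be in (0, 1), got {self.fdr_max}")
        if self.min_abs_fc < 1.0:
            raise ValueError(f"min_abs_fc must be >= 1, got {self.min_abs_fc}")


@dataclass
class DEResult:
    """Per-feature DE statistics for one contrast (B vs A).

    ``table`` is indexed by feature with columns ``base_mean``, ``log2fc``,
    ``signed_fc``, ``p_value`` and ``fdr``.
    """

    table: pd.DataFrame
    contrast: str

    @property
    def features(self) -> pd.Index:
        return self.table.index


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For features with nonzero counts in every sample, factor_j is the median
    of count_ij / geometric-mean_i over those features.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no feature has nonzero counts in all samples")
    sub = mat[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def estimate_dispersion(counts: CountMatrix, factors: pd.Series) -> pd.Series:
    """Per-feature NB dispersion phi (variance = mu + phi*mu^2).

    Method of moments on size-factor-normalized counts, with the residual
    variance pooled within groups: phi_raw = max(0, (s^2 - mean) / mean^2).
    Raw estimates are then shrunk halfway toward a mean-dispersion trend
    obtained by regressing phi_raw on 1/mean, which stabilises the noisy
    per-feature moments at n = 3 per group.
    """
    norm = counts.counts.to_numpy(dtype=float) / factors.loc[counts.samples].to_numpy()
    groups = counts.design.to_numpy()
    mean_all = norm.mean(axis=1)

    # pooled within-group variance
    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in np.unique(groups):
        cols = groups == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        sub = norm[:, cols]
        ss += sub.var(axis=1, ddof=1) * (n_g - 1)
        dof += n_g - 1
    if dof == 0:
        raise ValueError("dispersion estimation requires >= 2 samples in some group")
    s2 = ss / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(mean_all > 0, (s2 - mean_all) / mean_all**2, 0.0)
    phi_raw = np.maximum(phi_raw, 0.0)

    # trend: phi ~ a + b / mean, fitted on expressed features
    ok = mean_all > 0
    if ok.sum() >= 2:
        x = 1.0 / mean_all[ok]
        design = np.column_stack([np.ones(ok.sum()), x])
        coef, *_ = np.linalg.lstsq(design, phi_raw[ok], rcond=None)
        with np.errstate(divide="ignore"):
            trend = np.where(mean_all > 0, coef[0] + coef[1] / mean_all, 0.0)
        trend = np.maximum(trend, 0.0)
    else:
        trend = phi_raw
    phi = np.maximum(0.5 * phi_raw + 0.5 * trend, 0.0)
    phi[~ok] = 0.0
    return pd.Series(phi, index=counts.features, name="dispersion")


def signed_fold_change(log2fc):
    """Signed linear fold change: 2^lfc when up, -2^(-lfc) when down."""
    arr = np.asarray(log2fc, dtype=float)
    out = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    if np.isscalar(log2fc) or arr.ndim == 0:
        return float(out)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min over j >= i of min(1, m * p_(j) / j), order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def de_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> DEResult:
    """NB Wald test of group B vs group A on normalized counts.

    log2fc is the shrinkage-free log2 ratio of normalized group means with a
    +0.5 pseudocount (fold changes stay finite when one group is all zeros).
    The Wald statistic divides log2fc by a delta-method SE propagated from the
    NB variance of each group mean; p-values are two-sided normal.
    """
    for g in (group_a, group_b):
        n = len(counts.samples_in(g))
        if n == 0:
            raise ValueError(f"empty group {g!r}")
        if n < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples, has {n}")
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, factors)
    if not counts.features.equals(dispersions.index):
        raise ValueError("dispersion vector does not match the feature universe")

    sf = factors.loc[counts.samples].to_numpy(dtype=float)
    norm = counts.counts.to_numpy(dtype=float) / sf
    phi = dispersions.to_numpy(dtype=float)

    cols_a = np.asarray([s in set(counts.samples_in(group_a)) for s in counts.samples])
    cols_b = np.asarray([s in set(counts.samples_in(group_b)) for s in counts.samples])

    def _group_stats(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_g = int(cols.sum())
        mean = norm[:, cols].mean(axis=1)
        # Var(mean of x_j/s_j) with Var(x_j) = mu_j + phi mu_j^2, mu_j = q s_j
        inv_s = 1.0 / sf[cols]
        var = (mean * inv_s.sum() + phi * mean**2 * n_g) / n_g**2
        return mean, var

    mean_a, var_a = _group_stats(cols_a)
    mean_b, var_b = _group_stats(cols_b)

    ln2 = np.log(2.0)
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)
    se2 = var_a / ((mean_a + 0.5) ** 2) + var_b / ((mean_b + 0.5) ** 2)
    se = np.sqrt(se2) / ln2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # degenerate features: zero SE with zero fold change is a perfect null
    p = np.where((se == 0) & (log2fc == 0), 1.0, p)
    p = np.where((se == 0) & (log2fc != 0), 0.0, p)
    p = np.clip(p, 0.0, 1.0)

    base_mean = norm[:, cols_a | cols_b].mean(axis=1)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "signed_fc": signed_fold_change(log2fc),
            "p_value": p,
            "fdr": bh_fdr(p),
        },
        index=counts.features,
    )
    return DEResult(table=table, contrast=f"{group_b}_vs_{group_a}")


def filter_de(result: DEResult, criteria: DECriteria = DECriteria()) -> pd.DataFrame:
    """Features passing the DE gate (fdr < fdr_max and |signed fc| >= min),
    returned with a ``direction`` column of +1 (up) / -1 (down)."""
    tab = result.table
    keep = (tab["fdr"] < criteria.fdr_max) & (
        np.abs(tab["signed_fc"]) >= criteria.min_abs_fc
    )
    out = tab.loc[keep, ["log2fc", "signed_fc", "fdr"]].copy()
    out["direction"] = np.where(out["log2fc"] > 0, 1, -1).astype(int)
    # reproducible ordering: significance first, ties broken by identifier
    out = out.rename_axis("feature").sort_values(
        ["fdr", "feature"], kind="stable"
    )
    return out
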