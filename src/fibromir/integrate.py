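"""Reversal-pattern filtering and miRNA-mRNA negative-correlation pairing.

The central procedure of the pipeline:

1. ``reversal_filter`` keeps features that are differentially expressed in
   fibrosis (fibrotic vs control) AND differentially expressed in the
   opposite direction during recovery (recovery vs fibrotic) — the Venn
   intersection that defines fibrosis-reversal candidates.
2. ``intersect_targets`` restricts predicted miRNA->gene target edges to
   reversal miRNAs and reversal genes, reporting the overlapped-gene count.
3. ``correlate_pairs`` computes the Pearson correlation of each candidate
   pair across samples (by default all samples of all three groups, on
   log2(abundance + 1)) and retains pairs with |PCC| >= 0.8 and p < 0.05.
4. ``classify_pairs`` partitions the retained negative pairs by the recovery
   direction of the miRNA (up-miRNA/down-gene vs down-miRNA/up-gene);
   positively correlated pairs are reported but excluded downstream, since a
   repressive miRNA-target interaction implies anti-correlation.

Directional labels follow the recovery-vs-fibrotic orientation ("up" = up
during reversal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DECriteria, DEResult, filter_de
from .io import TargetMap
from .normalize import ExpressionMatrix

__all__ = [
    "ReversalSet",
    "reversal_filter",
    "intersect_targets",
    "pearson_with_p",
    "correlate_pairs",
    "classify_pairs",
    "CLASS_UP_MIR_DOWN_GENE",
    "CLASS_DOWN_MIR_UP_GENE",
    "CLASS_POSITIVE",
]

CLASS_UP_MIR_DOWN_GENE = "upMiR-downGene"
CLASS_DOWN_MIR_UP_GENE = "downMiR-upGene"
CLASS_POSITIVE = "positive"


@dataclass
class ReversalSet:
    """Features with opposite DE directions in fibrosis and recovery.

    ``table`` is indexed by feature with integer columns ``fibrosis_dir`` and
    ``recovery_dir`` in {+1, -1}; the two are opposite for every member.
    """

    table: pd.DataFrame
    platform: str  # "miRNA" | "mRNA"

    def __post_init__(self) -> None:
        if len(self.table) and not (
            self.table["fibrosis_dir"] * self.table["recovery_dir"] < 0
        ).all():
            raise ValueError("reversal member with concordant contrast signs")

    @property
    def features(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def recovery_direction(self, feature: str) -> int:
        return int(self.table.loc[feature, "recovery_dir"])

    def up_in_recovery(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["recovery_dir"] > 0])

    def down_in_recovery(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["recovery_dir"] < 0])


def reversal_filter(
    de_fibrosis: DEResult,
    de_recovery: DEResult,
    criteria: DECriteria = DECriteria(),
    platform: str = "mRNA",
    sign_only: bool = False,
) -> ReversalSet:
    """Features DE in fibrosis whose change is undone during recovery.

    With ``sign_only`` (relaxed mode) the recovery contrast only needs an
    opposite-signed fold change, not full significance; the default requires
    the feature to pass ``criteria`` in BOTH contrasts with opposite signs.
    """
    if set(de_fibrosis.features) != set(de_recovery.features):
        raise ValueError("contrasts cover different feature universes")
    fib = filter_de(de_fibrosis, criteria)
    if sign_only:
        rec_dir = np.sign(de_recovery.table["log2fc"]).astype(int)
        rec = pd.DataFrame({"direction": rec_dir[rec_dir != 0]})
    else:
        rec = filter_de(de_recovery, criteria)
    common = fib.index.intersection(rec.index)
    opposite = common[
        (fib.loc[common, "direction"] * rec.loc[common, "direction"]) < 0
    ]
    table = pd.DataFrame(
        {
            "fibrosis_dir": fib.loc[opposite, "direction"].astype(int),
            "recovery_dir": rec.loc[opposite, "direction"].astype(int),
        },
        index=opposite,
    ).sort_index()
    table.index.name = "feature"
    return ReversalSet(table=table, platform=platform)


def intersect_targets(
    target_map: TargetMap,
    mirna_set: ReversalSet,
    gene_set: ReversalSet,
) -> tuple[pd.DataFrame, int]:
    """Candidate (miRNA, gene) pairs: predicted target edges whose miRNA is a
    reversal miRNA and whose gene is a reversal gene.

    Returns the candidate table (columns ``mirna``, ``gene``) and the
    overlapped-gene count |predicted targets of reversal miRNAs ∩ reversal
    genes|.
    """
    if len(target_map.table) == 0:
        raise ValueError("empty target map")
    tab = target_map.table
    keep = tab["mirna"].isin(mirna_set.features) & tab["gene"].isin(gene_set.features)
    cand = (
        tab.loc[keep, ["mirna", "gene"]]
        .sort_values(["mirna", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    n_overlap = cand["gene"].nunique()
    return cand, n_overlap


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; r = +/-1 yields
    p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0 or ssy == 0:
        raise ValueError("undefined correlation: constant input vector")
    r = float(dx @ dy) / np.sqrt(ssx * ssy)
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def correlate_pairs(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    candidates: pd.DataFrame,
    pcc_min: float = 0.8,
    p_max: float = 0.05,
    log_transform: bool = True,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate each candidate pair across samples; keep the pairs with
    |PCC| >= ``pcc_min`` and p < ``p_max``.

    Correlations are computed on log2(abundance + 1) by default, across all
    shared samples (``samples`` restricts the scope, e.g. to two groups).
    Returns retained pairs with ``pcc``, ``p_value`` and ``n_samples``.
    """
    if samples is None:
        if list(mirna_expr.values.columns) != list(gene_expr.values.columns):
            raise ValueError("miRNA and gene matrices have different sample sets")
        samples = list(mirna_expr.values.columns)
    mx = mirna_expr.log2p1() if log_transform else mirna_expr.values
    gx = gene_expr.log2p1() if log_transform else gene_expr.values
    mx = mx[samples]
    gx = gx[samples]
    n = len(samples)
    if n < 3:
        raise ValueError("correlation needs >= 3 samples")

    # vectorized product-moment correlation of the candidate rows
    xm = mx.loc[candidates["mirna"]].to_numpy(dtype=float)
    yg = gx.loc[candidates["gene"]].to_numpy(dtype=float)
    xm = xm - xm.mean(axis=1, keepdims=True)
    yg = yg - yg.mean(axis=1, keepdims=True)
    ssx = (xm * xm).sum(axis=1)
    ssy = (yg * yg).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xm * yg).sum(axis=1) / np.sqrt(ssx * ssy)
    r = np.where((ssx == 0) | (ssy == 0), np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)

    out = candidates[["mirna", "gene"]].copy()
    out["pcc"] = r
    out["p_value"] = p
    out["n_samples"] = n
    keep = (np.abs(out["pcc"]) >= pcc_min) & (out["p_value"] < p_max)
    keep &= out["pcc"].notna()
    return out.loc[keep].reset_index(drop=True)


def classify_pairs(
    pairs: pd.DataFrame,
    mirna_reversal: ReversalSet,
    gene_reversal: ReversalSet,
) -> tuple[pd.DataFrame, dict]:
    """Partition retained pairs into directional classes and summarise.

    Negative pairs (pcc < 0) split by the recovery direction of the miRNA:
    miRNA up in recovery -> ``upMiR-downGene``; miRNA down -> ``downMiR-upGene``.
    Positive pairs are labelled ``positive`` and excluded from downstream
    network stages. The summary reports, per negative class, the pair count
    and the distinct miRNA/gene counts, plus the negative total as the sum of
    the two classes.
    """
    pairs = pairs.copy()
    missing_m = set(pairs["mirna"]) - mirna_reversal.features
    if missing_m:
        raise ValueError(f"pair miRNA without direction label: {sorted(missing_m)[0]!r}")
    missing_g = set(pairs["gene"]) - gene_reversal.features
    if missing_g:
        raise ValueError(f"pair gene without direction label: {sorted(missing_g)[0]!r}")

    mdir = mirna_reversal.table["recovery_dir"]
    mir_dir = mdir.loc[pairs["mirna"]].to_numpy()
    negative = pairs["pcc"].to_numpy() < 0
    cls = np.where(
        ~negative,
        CLASS_POSITIVE,
        np.where(mir_dir > 0, CLASS_UP_MIR_DOWN_GENE, CLASS_DOWN_MIR_UP_GENE),
    )
    pairs["pair_class"] = cls

    def _summary(label: str) -> dict:
        sub = pairs[pairs["pair_class"] == label]
        return {
            "pairs": int(len(sub)),
            "mirnas": int(sub["mirna"].nunique()),
            "genes": int(sub["gene"].nunique()),
        }

    up_cls = _summary(CLASS_UP_MIR_DOWN_GENE)
    down_cls = _summary(CLASS_DOWN_MIR_UP_GENE)
    summary = {
        "retained": int(len(pairs)),
        "negative": int(negative.sum()),
        "positive": int((~negative).sum()),
        CLASS_UP_MIR_DOWN_GENE: up_cls,
        CLASS_DOWN_MIR_UP_GENE: down_cls,
        "negative_total_check": up_cls["pairs"] + down_cls["pairs"],
    }
    return pairs, summary
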