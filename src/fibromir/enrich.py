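"""Hypergeometric over-representation analysis (ORA) of gene sets.

Given a query gene list (e.g. the reversal genes engaged in negative
miRNA-mRNA pairs) and a GMT collection, each set is scored by the upper tail
of the hypergeometric distribution — the probability of drawing at least the
observed overlap when sampling the query size without replacement from the
universe. Benjamini-Hochberg correction is applied across the tested sets of
a collection, and sets with FDR < 0.05 are flagged significant.

The universe defaults to the collection's own universe, optionally
intersected with the measured genes (``universe_mode="measured"``); a smaller,
assay-aware universe is the conservative standard choice for RNA-seq ORA.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import GeneSetCollection

__all__ = ["hypergeom_upper_tail", "ora"]

#: minimum overlap for a set to be reported at all / to be flagged significant
MIN_OVERLAP_REPORT = 1
MIN_OVERLAP_FLAG = 3


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n).

    ``N`` universe size, ``K`` annotated-set size, ``n`` query size, ``k``
    observed overlap. Computed via the survival function of the
    hypergeometric distribution (stable in log space internally).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n, K)={min(n, K)}]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe_mode: str = "collection",
    measured: Iterable[str] | None = None,
    fdr_max: float = 0.05,
    min_overlap_report: int = MIN_OVERLAP_REPORT,
    min_overlap_flag: int = MIN_OVERLAP_FLAG,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    Returns one row per set with overlap >= ``min_overlap_report``, sorted by
    (fdr, p_value, set_name), with columns ``set_name, k, K, n, N, p_value,
    fdr, significant, genes``. ``significant`` requires fdr < ``fdr_max`` and
    overlap >= ``min_overlap_flag``.
    """
    if universe_mode not in ("collection", "measured"):
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    universe = set(collection.universe)
    if universe_mode == "measured":
        if measured is None:
            raise ValueError("universe_mode='measured' requires the measured genes")
        universe &= set(measured)
    q = set(query) & universe
    if not q:
        raise ValueError("query is empty after restriction to the universe")

    rows = []
    n = len(q)
    N = len(universe)
    for name, genes in collection.sets.items():
        gs = genes & universe
        overlap = sorted(q & gs)
        k = len(overlap)
        if k < min_overlap_report:
            continue
        p = hypergeom_upper_tail(k, len(gs), n, N)
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": len(gs),
                "n": n,
                "N": N,
                "p_value": p,
                "genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_value", "fdr", "significant", "genes"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["fdr"] < fdr_max) & (out["k"] >= min_overlap_flag)
    out = out.sort_values(
        ["fdr", "p_value", "set_name"], kind="stable"
    ).reset_index(drop=True)
    return out[["set_name", "k", "K", "n", "N", "p_value", "fdr", "significant", "genes"]]
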