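"""Worked-example fixtures encoding the published stage counts of the mouse
TAA liver-fibrosis reversal study (GSE173961 / GSE173962).

The study reports a cascade of bookkeeping counts: 206 fibrosis DEMs of which
102 reverse on recovery (53 up-then-suppressed, 49 down-then-rescued); 4,118
fibrosis DEGs (3,025 up, 1,093 down) of which 2,845 reverse (2,100 + 745);
2,492 genes overlapping the predicted targets of the reversal DEMs; and 3,769
negative miRNA-mRNA pairs split into 2,168 (23 miRNAs x 1,056 genes, miRNA up
in recovery) and 1,601 (53 miRNAs x 434 genes, miRNA down in recovery).
The hub analysis recovers the four lysyl-oxidase-family genes (Lox, Loxl1,
Loxl2, Loxl3) shared by the collagen- and elastin-formation sets, and four
key miRNAs (mmu-miR-1843a-5p, mmu-miR-193a-5p, mmu-miR-194-2-3p,
mmu-miR-30c-2-3p) whose targets span the ECM-component, HSC-activation and
LOX-regulation categories.

The builders below construct in-memory inputs that encode exactly those
compositions, so the pipeline's own operations (reversal filter, target
intersection, pair classification, hub and key-miRNA mining) can recompute
the published counts as arithmetic consequences. Statistical columns
(p-values, fold changes) are schematic placeholders on the passing side of
every threshold; these fixtures exercise the bookkeeping, not the estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import DEResult, signed_fold_change
from .integrate import ReversalSet
from .io import GeneSetCollection, TargetMap

__all__ = [
    "dem_de_tables",
    "deg_de_tables",
    "dem_target_map",
    "negative_pair_table",
    "lox_hub_fixture",
    "lox_key_mirna_fixture",
]

# published cascade counts (study inputs, not outputs of this package)
N_DEM_FIBROSIS_UP = 53
N_DEM_FIBROSIS_DOWN = 49
N_DEM_FIBROSIS = 206
N_DEG_FIBROSIS_UP = 3025
N_DEG_FIBROSIS_DOWN = 1093
N_DEG_REVERSED_FROM_UP = 2100
N_DEG_REVERSED_FROM_DOWN = 745
N_OVERLAP_GENES = 2492
N_PAIRS_UP_MIR = 2168
N_PAIRS_UP_MIR_MIRNAS = 23
N_PAIRS_UP_MIR_GENES = 1056
N_PAIRS_DOWN_MIR = 1601
N_PAIRS_DOWN_MIR_MIRNAS = 53
N_PAIRS_DOWN_MIR_GENES = 434

_SIG_FDR = 1e-6
_NS_FDR = 0.6
_SIG_LFC = 2.0  # |signed fc| = 4, comfortably past the 2-fold gate
_NS_LFC = 0.1


def _de_tables(
    universe: list[str],
    fib_up: list[str],
    fib_down: list[str],
    rec_down: list[str],
    rec_up: list[str],
    contrast_prefix: str,
) -> tuple[DEResult, DEResult]:
    """Assemble fibrosis and recovery DE tables over ``universe`` in which
    exactly the named features pass the default DE gate per contrast."""

    def _table(up: set[str], down: set[str]) -> pd.DataFrame:
        lfc = np.full(len(universe), _NS_LFC)
        fdr = np.full(len(universe), _NS_FDR)
        for i, feat in enumerate(universe):
            if feat in up:
                lfc[i], fdr[i] = _SIG_LFC, _SIG_FDR
            elif feat in down:
                lfc[i], fdr[i] = -_SIG_LFC, _SIG_FDR
        return pd.DataFrame(
            {
                "base_mean": np.full(len(universe), 100.0),
                "log2fc": lfc,
                "signed_fc": signed_fold_change(lfc),
                "p_value": fdr,
                "fdr": fdr,
            },
            index=pd.Index(universe, name="feature"),
        )

    fib = DEResult(_table(set(fib_up), set(fib_down)), f"{contrast_prefix}:fibrotic_vs_control")
    rec = DEResult(_table(set(rec_up), set(rec_down)), f"{contrast_prefix}:recovery_vs_fibrotic")
    return fib, rec


def dem_de_tables(n_background: int = 300) -> tuple[DEResult, DEResult]:
    """miRNA DE tables for both contrasts encoding the 206 fibrosis DEMs, of
    which 53 + 49 = 102 reverse on recovery."""
    up = [f"miR-EX-up-{i:03d}" for i in range(N_DEM_FIBROSIS_UP)]
    down = [f"miR-EX-down-{i:03d}" for i in range(N_DEM_FIBROSIS_DOWN)]
    n_extra = N_DEM_FIBROSIS - len(up) - len(down)  # fibrosis-only DEMs
    extra = [f"miR-EX-persist-{i:03d}" for i in range(n_extra)]
    bg = [f"miR-EX-null-{i:03d}" for i in range(n_background)]
    universe = up + down + extra + bg
    # persistently changed DEMs stay flat in recovery; reversal members flip
    return _de_tables(universe, up + extra[: n_extra // 2], down + extra[n_extra // 2 :],
                      rec_down=up, rec_up=down, contrast_prefix="miRNA")


def deg_de_tables(n_background: int = 800) -> tuple[DEResult, DEResult]:
    """mRNA DE tables encoding 4,118 fibrosis DEGs (3,025 up / 1,093 down)
    with 2,100 + 745 = 2,845 reversing on recovery."""
    up = [f"gene-EX-up-{i:04d}" for i in range(N_DEG_FIBROSIS_UP)]
    down = [f"gene-EX-down-{i:04d}" for i in range(N_DEG_FIBROSIS_DOWN)]
    bg = [f"gene-EX-null-{i:04d}" for i in range(n_background)]
    universe = up + down + bg
    rec_down = up[:N_DEG_REVERSED_FROM_UP]
    rec_up = down[:N_DEG_REVERSED_FROM_DOWN]
    return _de_tables(universe, up, down, rec_down=rec_down, rec_up=rec_up,
                      contrast_prefix="mRNA")


def dem_target_map(
    mirna_reversal: ReversalSet,
    gene_reversal: ReversalSet,
    n_nontarget_genes: int = 353,
) -> TargetMap:
    """Predicted-target map whose overlap with the reversal genes is exactly
    the published 2,492: edges from every reversal miRNA cover 2,492 of the
    reversal genes (round-robin) plus decoy edges to non-DE genes."""
    mirnas = sorted(mirna_reversal.features)
    genes = sorted(gene_reversal.features)[:N_OVERLAP_GENES]
    decoys = [f"gene-EX-offtarget-{i:04d}" for i in range(n_nontarget_genes)]
    rows = []
    for i, g in enumerate(genes):
        rows.append((mirnas[i % len(mirnas)], g, 1, 1, 0))
    for i, g in enumerate(decoys):
        rows.append((mirnas[i % len(mirnas)], g, 1, 0, 0))
    return TargetMap(
        pd.DataFrame(rows, columns=["mirna", "gene", "targetscan", "mirdb", "mirtarbase"])
    )


def _spread_pairs(mirnas: list[str], genes: list[str], n_pairs: int) -> list[tuple[str, str]]:
    """Deterministic bipartite pair layout covering every miRNA and gene with
    no duplicate edges."""
    if n_pairs < max(len(mirnas), len(genes)):
        raise ValueError("cannot cover both sides with that few pairs")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    shift = 0
    j = 0
    while len(pairs) < n_pairs:
        g = genes[j % len(genes)]
        m = mirnas[(j + shift) % len(mirnas)]
        j += 1
        if j % len(genes) == 0:
            shift += 1
        if (m, g) not in seen:
            seen.add((m, g))
            pairs.append((m, g))
    return pairs


def negative_pair_table() -> tuple[pd.DataFrame, ReversalSet, ReversalSet]:
    """Retained negative pairs with the published class compositions.

    2,168 pairs over 23 recovery-up miRNAs x 1,056 recovery-down genes and
    1,601 pairs over 53 recovery-down miRNAs x 434 recovery-up genes, all
    with PCC on the passing side of the dual threshold. Returns the pair
    table plus matching miRNA/gene reversal sets carrying direction labels.
    """
    up_mirs = [f"miR-EX-recup-{i:02d}" for i in range(N_PAIRS_UP_MIR_MIRNAS)]
    down_genes = [f"gene-EX-recdown-{i:04d}" for i in range(N_PAIRS_UP_MIR_GENES)]
    down_mirs = [f"miR-EX-recdown-{i:02d}" for i in range(N_PAIRS_DOWN_MIR_MIRNAS)]
    up_genes = [f"gene-EX-recup-{i:04d}" for i in range(N_PAIRS_DOWN_MIR_GENES)]

    pairs = _spread_pairs(up_mirs, down_genes, N_PAIRS_UP_MIR)
    pairs += _spread_pairs(down_mirs, up_genes, N_PAIRS_DOWN_MIR)
    tab = pd.DataFrame(pairs, columns=["mirna", "gene"])
    tab["pcc"] = -0.9
    tab["p_value"] = 1e-3
    tab["n_samples"] = 9

    mir_table = pd.DataFrame(
        {
            "fibrosis_dir": [-1] * len(up_mirs) + [1] * len(down_mirs),
            "recovery_dir": [1] * len(up_mirs) + [-1] * len(down_mirs),
        },
        index=pd.Index(up_mirs + down_mirs, name="feature"),
    )
    gene_table = pd.DataFrame(
        {
            "fibrosis_dir": [1] * len(down_genes) + [-1] * len(up_genes),
            "recovery_dir": [-1] * len(down_genes) + [1] * len(up_genes),
        },
        index=pd.Index(down_genes + up_genes, name="feature"),
    )
    return (
        tab,
        ReversalSet(mir_table, platform="miRNA"),
        ReversalSet(gene_table, platform="mRNA"),
    )


LOX_FAMILY = ("Lox", "Loxl1", "Loxl2", "Loxl3")
KEY_MIRNAS = (
    "mmu-miR-1843a-5p",
    "mmu-miR-193a-5p",
    "mmu-miR-194-2-3p",
    "mmu-miR-30c-2-3p",
)


def lox_hub_fixture() -> tuple[ReversalSet, GeneSetCollection]:
    """Reversal genes and the collagen/elastin-formation sets whose shared
    members among the reversal genes are exactly the LOX family."""
    collagen_only = ["Col1a1", "Col7a1", "Col8a1", "Col12a1"]
    elastin_only = ["Eln", "Fbn1", "Emilin1"]
    members = list(LOX_FAMILY) + collagen_only + elastin_only + ["Acta2", "Pdgfrb"]
    table = pd.DataFrame(
        {"fibrosis_dir": 1, "recovery_dir": -1},
        index=pd.Index(members, name="feature"),
    )
    collection = GeneSetCollection(
        {
            "collagen formation": frozenset(LOX_FAMILY) | frozenset(collagen_only),
            "elastin formation": frozenset(LOX_FAMILY) | frozenset(elastin_only),
        }
    )
    return ReversalSet(table, platform="mRNA"), collection


def lox_key_mirna_fixture() -> tuple[pd.DataFrame, GeneSetCollection]:
    """Negative pairs and target categories whose triple-Venn intersection is
    exactly the four key miRNAs; decoy DEMs cover at most two categories."""
    ecm = ["Col1a1", "Col3a1", "Eln", "Fn1"]
    hsc = ["Acta2", "Pdgfrb", "Tgfbr1"]
    lox = list(LOX_FAMILY)
    collection = GeneSetCollection(
        {
            "ECM component": frozenset(ecm),
            "HSCs activation": frozenset(hsc),
            "LOXs regulation": frozenset(lox),
        }
    )
    rows: list[tuple[str, str]] = []
    for i, m in enumerate(KEY_MIRNAS):
        rows.append((m, lox[i]))
        rows.append((m, ecm[i % len(ecm)]))
        rows.append((m, hsc[i % len(hsc)]))
    # shared targets, as in the published network (Loxl1 hit by three miRNAs)
    rows.append(("mmu-miR-1843a-5p", "Loxl1"))
    rows.append(("mmu-miR-30c-2-3p", "Loxl1"))
    # decoys spanning fewer than three categories
    rows.append(("mmu-miR-29c-3p", "Col1a1"))
    rows.append(("mmu-miR-122-5p", "Acta2"))
    rows.append(("mmu-miR-455-3p", "Col3a1"))
    rows.append(("mmu-miR-455-3p", "Lox"))
    tab = pd.DataFrame(sorted(set(rows)), columns=["mirna", "gene"])
    tab["pcc"] = -0.85
    tab["p_value"] = 2e-3
    tab["n_samples"] = 9
    return tab, collection
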