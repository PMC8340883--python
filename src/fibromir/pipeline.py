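"""End-to-end orchestration: normalize -> DE (two contrasts) -> reversal ->
target intersection -> correlation pairing -> enrichment -> network mining.

One :class:`PipelineConfig` (YAML) holds every input path and threshold; the
run emits every intermediate table plus a machine-readable stage-count report
whose internal consistency can be checked with :func:`validate_report`.
Identical config and seed give byte-identical reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import diffexpr, enrich, integrate, network, normalize
from .diffexpr import DECriteria, DEResult
from .io import (
    GROUP_CONTROL,
    GROUP_FIBROTIC,
    GROUP_RECOVERY,
    export_network,
    read_count_matrix,
    read_gmt,
    read_ppi,
    read_target_map,
    write_json,
    write_pairs_table,
)
from .simulate import CATEGORY_ECM, CATEGORY_HSC, CATEGORY_LOX, SET_COLLAGEN, SET_ELASTIN

log = logging.getLogger("fibromir")

__all__ = ["PipelineConfig", "run_all", "validate_report"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the study's printed criteria: DE at FDR < 0.05 with
    |fold change| >= 2, pair retention at |PCC| >= 0.8 with p < 0.05,
    enrichment at FDR < 0.05.
    """

    mirna_counts: str
    gene_counts: str
    design: str
    targets: str
    gene_sets: str
    ppi: str
    outdir: str
    gene_lengths: str | None = None
    fdr_max: float = 0.05
    min_abs_fc: float = 2.0
    pcc_min: float = 0.8
    p_max: float = 0.05
    min_programs: int = 1
    score_min: float = 400.0
    universe_mode: str = "collection"
    correlation_groups: list[str] | None = None  # None = all three groups
    log_transform: bool = True
    sign_only_reversal: bool = False
    hub_set_names: list[str] = field(default_factory=lambda: [SET_COLLAGEN, SET_ELASTIN])
    category_names: list[str] = field(
        default_factory=lambda: [CATEGORY_ECM, CATEGORY_HSC, CATEGORY_LOX]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        DECriteria(self.fdr_max, self.min_abs_fc)  # range check
        if not 0.0 <= self.pcc_min <= 1.0:
            raise ValueError(f"pcc_min must be in [0, 1], got {self.pcc_min}")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.min_programs not in (1, 2, 3):
            raise ValueError(f"min_programs must be 1, 2 or 3, got {self.min_programs}")
        if self.score_min < 0 or self.score_min > 1000:
            raise ValueError(f"score_min must be in [0, 1000], got {self.score_min}")
        if self.universe_mode not in ("collection", "measured"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        for attr in ("mirna_counts", "gene_counts", "design", "targets", "gene_sets", "ppi"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: no such file {p!r}")
        if self.gene_lengths is not None and not Path(self.gene_lengths).exists():
            raise FileNotFoundError(f"gene_lengths: no such file {self.gene_lengths!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(**raw)

    @property
    def criteria(self) -> DECriteria:
        return DECriteria(self.fdr_max, self.min_abs_fc)


def _de_pair(counts, platform: str) -> tuple[DEResult, DEResult]:
    """Both contrasts (fibrotic vs control, recovery vs fibrotic) with shared
    size factors and dispersions."""
    factors = diffexpr.size_factors(counts)
    phi = diffexpr.estimate_dispersion(counts, factors)
    fib = diffexpr.de_test(counts, GROUP_CONTROL, GROUP_FIBROTIC, factors, phi)
    rec = diffexpr.de_test(counts, GROUP_FIBROTIC, GROUP_RECOVERY, factors, phi)
    log.info("%s DE: %d features", platform, len(fib.table))
    return fib, rec


def _dir_counts(rev: integrate.ReversalSet) -> dict:
    return {
        "total": int(len(rev.table)),
        "up": int((rev.table["recovery_dir"] > 0).sum()),
        "down": int((rev.table["recovery_dir"] < 0).sum()),
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage, write all outputs under ``config.outdir`` and
    return the stage-count report (also written as ``report.json``)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    criteria = config.criteria

    log.info("loading inputs")
    cm_mirna = read_count_matrix(config.mirna_counts, config.design)
    cm_gene = read_count_matrix(config.gene_counts, config.design)
    tmap = read_target_map(config.targets, min_programs=config.min_programs)
    collection = read_gmt(config.gene_sets)
    ppi = read_ppi(config.ppi, score_min=config.score_min)

    # --- differential expression ------------------------------------------
    de_mir_fib, de_mir_rec = _de_pair(cm_mirna, "miRNA")
    de_gene_fib, de_gene_rec = _de_pair(cm_gene, "mRNA")
    for de, name in (
        (de_mir_fib, "dem_fibrotic_vs_control"),
        (de_mir_rec, "dem_recovery_vs_fibrotic"),
        (de_gene_fib, "deg_fibrotic_vs_control"),
        (de_gene_rec, "deg_recovery_vs_fibrotic"),
    ):
        de.table.rename_axis("feature").to_csv(outdir / f"{name}.tsv", sep="\t")

    # --- reversal filtering ------------------------------------------------
    mir_rev = integrate.reversal_filter(
        de_mir_fib, de_mir_rec, criteria, platform="miRNA",
        sign_only=config.sign_only_reversal,
    )
    gene_rev = integrate.reversal_filter(
        de_gene_fib, de_gene_rec, criteria, platform="mRNA",
        sign_only=config.sign_only_reversal,
    )
    mir_rev.table.to_csv(outdir / "reversal_mirnas.tsv", sep="\t")
    gene_rev.table.to_csv(outdir / "reversal_genes.tsv", sep="\t")
    log.info("reversal: %d miRNAs, %d genes", len(mir_rev.table), len(gene_rev.table))

    # --- target intersection and correlation ------------------------------
    candidates, n_overlap = integrate.intersect_targets(tmap, mir_rev, gene_rev)
    mirna_expr = normalize.tpm_mirna(cm_mirna)
    if config.gene_lengths is not None:
        lengths = normalize.read_lengths(config.gene_lengths)
        gene_expr = normalize.fpkm(cm_gene, lengths)
    else:
        gene_expr = normalize.tpm_mirna(cm_gene)

    samples = None
    if config.correlation_groups is not None:
        wanted = set(config.correlation_groups)
        samples = [s for s in cm_mirna.samples if cm_mirna.design[s] in wanted]
    retained = integrate.correlate_pairs(
        mirna_expr, gene_expr, candidates,
        pcc_min=config.pcc_min, p_max=config.p_max,
        log_transform=config.log_transform, samples=samples,
    )
    pairs, pair_summary = integrate.classify_pairs(retained, mir_rev, gene_rev)
    write_pairs_table(pairs, outdir / "pairs.tsv")
    log.info(
        "pairs: %d candidates -> %d retained (%d negative)",
        len(candidates), pair_summary["retained"], pair_summary["negative"],
    )

    negative = pairs[pairs["pair_class"] != integrate.CLASS_POSITIVE]

    # --- enrichment --------------------------------------------------------
    query = sorted(set(negative["gene"]))
    measured = list(cm_gene.features)
    if query:
        enr = enrich.ora(
            query, collection, universe_mode=config.universe_mode, measured=measured
        )
    else:
        enr = None  # no negative pairs, nothing to enrich
    if enr is not None:
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    n_enr_sig = int(enr["significant"].sum()) if enr is not None else 0

    # --- networks and hubs --------------------------------------------------
    if len(negative) > 0:
        reg_net = network.build_bipartite(negative, de_mir_rec, de_gene_rec)
        export_network(reg_net, outdir / "network.graphml", "graphml")
        export_network(reg_net, outdir / "network.sif", "sif")
        net_counts = {
            "nodes": reg_net.number_of_nodes(),
            "edges": reg_net.number_of_edges(),
        }
    else:
        net_counts = {"nodes": 0, "edges": 0}

    missing_hub_sets = [n for n in config.hub_set_names if n not in collection]
    if missing_hub_sets:
        log.warning("hub sets %s absent from the collection; no hub genes", missing_hub_sets)
        hubs: frozenset[str] = frozenset()
    else:
        hubs = network.hub_genes_by_intersection(gene_rev, collection, config.hub_set_names)
    restrict = gene_rev.down_in_recovery()
    if hubs:
        sub = network.ppi_first_degree(
            ppi, hubs, restrict_to=restrict, score_min=config.score_min
        )
        export_network(sub, outdir / "ppi_subnetwork.graphml", "graphml")
        ppi_counts = {"nodes": sub.number_of_nodes(), "edges": sub.number_of_edges()}
    else:
        ppi_counts = {"nodes": 0, "edges": 0}

    missing_cats = [n for n in config.category_names if n not in collection]
    if missing_cats:
        log.warning("categories %s absent from the collection; no key miRNAs", missing_cats)
        key_mirnas: frozenset[str] = frozenset()
    else:
        key_mirnas = network.key_mirnas_by_triple_venn(
            negative, collection, config.category_names
        )

    fib_dems = diffexpr.filter_de(de_mir_fib, criteria)
    fib_degs = diffexpr.filter_de(de_gene_fib, criteria)
    report = {
        "seed": config.seed,
        "config": asdict(config),
        "dems": {
            "fibrosis": {
                "total": int(len(fib_dems)),
                "up": int((fib_dems["direction"] > 0).sum()),
                "down": int((fib_dems["direction"] < 0).sum()),
            },
            "reversed": _dir_counts(mir_rev),
        },
        "degs": {
            "fibrosis": {
                "total": int(len(fib_degs)),
                "up": int((fib_degs["direction"] > 0).sum()),
                "down": int((fib_degs["direction"] < 0).sum()),
            },
            "reversed": _dir_counts(gene_rev),
        },
        "overlap_genes": int(n_overlap),
        "candidate_pairs": int(len(candidates)),
        "pairs": pair_summary,
        "enrichment": {
            "tested": int(len(enr)) if enr is not None else 0,
            "significant": n_enr_sig,
        },
        "hub_genes": sorted(hubs),
        "key_mirnas": sorted(key_mirnas),
        "network": net_counts,
        "ppi_subnetwork": ppi_counts,
    }
    write_json(report, outdir / "report.json")
    log.info("pipeline done in %.1fs", time.time() - t0)
    violations = validate_report(report)
    if violations:
        raise RuntimeError(f"inconsistent stage report: {violations}")
    return report


def validate_report(report: dict) -> list[str]:
    """Check the internal consistency of a stage-count report; returns the
    list of violated invariants (empty = pass)."""
    bad: list[str] = []

    def _get(path: str, default=None):
        cur = report
        for part in path.split("."):
            if not isinstance(cur, dict) or part not in cur:
                return default
            cur = cur[part]
        return cur

    for platform in ("dems", "degs"):
        fib = _get(f"{platform}.fibrosis.total")
        rev = _get(f"{platform}.reversed.total")
        if fib is None or rev is None:
            bad.append(f"{platform}: missing fibrosis/reversed counts")
        elif rev > fib:
            bad.append(f"{platform}: reversed ({rev}) exceeds fibrosis DE ({fib})")
        up, down, tot = (
            _get(f"{platform}.reversed.up"),
            _get(f"{platform}.reversed.down"),
            _get(f"{platform}.reversed.total"),
        )
        if None not in (up, down, tot) and up + down != tot:
            bad.append(f"{platform}: reversed up + down != total")
    retained = _get("pairs.retained")
    negative = _get("pairs.negative")
    positive = _get("pairs.positive")
    if None in (retained, negative, positive):
        bad.append("pairs: missing retained/negative/positive")
    elif negative + positive != retained:
        bad.append("pairs: negative + positive != retained")
    cls_sum = (_get(f"pairs.{integrate.CLASS_UP_MIR_DOWN_GENE}.pairs", 0) or 0) + (
        _get(f"pairs.{integrate.CLASS_DOWN_MIR_UP_GENE}.pairs", 0) or 0
    )
    if negative is not None and cls_sum != negative:
        bad.append("pairs: class pair counts do not sum to the negative total")
    cand = _get("candidate_pairs")
    if None not in (cand, retained) and cand < retained:
        bad.append("pairs: retained exceeds candidates")
    return bad
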