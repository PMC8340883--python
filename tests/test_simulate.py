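"""Synthetic-data generator: determinism, distributional calibration,
planted-structure guarantees."""

import numpy as np
import pandas as pd
import pytest

from fibromir.integrate import correlate_pairs
from fibromir.normalize import tpm_mirna
from fibromir.simulate import (
    CATEGORY_ECM,
    CATEGORY_HSC,
    CATEGORY_LOX,
    SET_COLLAGEN,
    SET_ELASTIN,
    SimulationParams,
    SyntheticTruth,
    simulate_counts,
    simulate_gene_sets,
    simulate_ppi,
    simulate_target_map,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_group": 1},
            {"n_mirna": 0},
            {"frac_reversal": 1.5},
            {"planted_fc": 0.5},
            {"coupling_strength": 2.0},
            {"dispersion": -0.1},
            {"seed": None},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises((ValueError, TypeError)):
            SimulationParams(**{"seed": 1, **kwargs})

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            SimulationParams()  # no seed


class TestDeterminism:
    def test_same_seed_bit_identical(self, default_sim):
        cm_mirna, cm_gene, truth = default_sim
        m2, g2, t2 = simulate_counts(SimulationParams(seed=42))
        assert cm_mirna.counts.equals(m2.counts)
        assert cm_gene.counts.equals(g2.counts)
        assert truth.planted_pairs == t2.planted_pairs
        assert truth.to_json_dict() == t2.to_json_dict()

    def test_different_seed_differs(self, default_sim):
        cm_mirna, _, _ = default_sim
        m2, _, _ = simulate_counts(SimulationParams(seed=43))
        assert not cm_mirna.counts.equals(m2.counts)

    def test_target_map_and_gene_sets_deterministic(self, default_sim):
        *_, truth = default_sim
        a = simulate_target_map(truth, 0.1, seed=5)
        b = simulate_target_map(truth, 0.1, seed=5)
        assert a.table.equals(b.table)
        ga = simulate_gene_sets(truth, seed=5)
        gb = simulate_gene_sets(truth, seed=5)
        assert ga.sets == gb.sets


class TestCountDistribution:
    def test_poisson_limit_variance_equals_mean(self):
        params = SimulationParams(
            seed=8, n_mirna=10_000, n_gene=10, frac_reversal=0.0,
            base_mean_log_range=(3.0, 3.0), dispersion=0.0,
        )
        cm, _, _ = simulate_counts(params)
        arr = cm.counts.to_numpy(dtype=float)
        ratio = arr.var(axis=1, ddof=1) / arr.mean(axis=1)
        assert 0.9 <= ratio.mean() <= 1.1

    def test_planted_fold_change_recovered_in_group_means(self):
        params = SimulationParams(
            seed=9, n_mirna=2000, n_gene=10, frac_reversal=0.3, planted_fc=4.0,
        )
        cm, _, truth = simulate_counts(params)
        up = [m for m, d in truth.reversal_mirnas.items() if d > 0]
        assert len(up) >= 200
        fib = cm.counts.loc[up, cm.samples_in("fibrotic")].mean(axis=1)
        ctrl = cm.counts.loc[up, cm.samples_in("control")].mean(axis=1)
        assert (fib / ctrl).mean() == pytest.approx(4.0, abs=0.4)

    def test_background_groups_have_equal_means(self):
        params = SimulationParams(seed=10, n_mirna=3000, n_gene=10, frac_reversal=0.0)
        cm, _, _ = simulate_counts(params)
        fib = cm.counts[cm.samples_in("fibrotic")].to_numpy().mean()
        ctrl = cm.counts[cm.samples_in("control")].to_numpy().mean()
        assert fib / ctrl == pytest.approx(1.0, abs=0.05)

    def test_counts_are_nonnegative_integers(self, default_sim):
        cm_mirna, cm_gene, _ = default_sim
        for cm in (cm_mirna, cm_gene):
            assert (cm.counts.to_numpy() >= 0).all()
            assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)


class TestTruthStructure:
    def test_planted_pairs_within_reversal_sets_with_opposite_directions(self, default_sim):
        *_, truth = default_sim
        for m, g in truth.planted_pairs:
            assert truth.reversal_mirnas[m] * truth.reversal_genes[g] < 0

    def test_hub_genes_are_reversal_genes(self, default_sim):
        *_, truth = default_sim
        assert truth.hub_genes <= set(truth.reversal_genes)
        assert len(truth.hub_genes) == 4 and len(truth.key_mirnas) == 4

    def test_truth_json_round_trip(self, default_sim):
        *_, truth = default_sim
        back = SyntheticTruth.from_json_dict(truth.to_json_dict())
        assert back.planted_pairs == truth.planted_pairs
        assert back.key_categories == truth.key_categories


class TestTargetMap:
    def test_zero_density_yields_exactly_planted(self, default_sim):
        *_, truth = default_sim
        tm = simulate_target_map(truth, 0.0, seed=1)
        assert tm.edges == truth.planted_pairs

    def test_full_density_saturates(self, default_sim):
        *_, truth = default_sim
        mirnas = sorted(truth.reversal_mirnas)[:5]
        genes = sorted(truth.reversal_genes)[:7]
        tm = simulate_target_map(truth, 1.0, seed=1, mirnas=mirnas, genes=genes)
        expect = {(m, g) for m in mirnas for g in genes} | truth.planted_pairs
        assert tm.edges == expect

    def test_background_count_binomial(self):
        truth = SyntheticTruth()  # background-only map is allowed
        mirnas = [f"m{i}" for i in range(100)]
        genes = [f"g{i}" for i in range(100)]
        tm = simulate_target_map(truth, 0.1, seed=2, mirnas=mirnas, genes=genes)
        n, p = 10_000, 0.1
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(tm.table) - n * p) <= 3 * sigma

    def test_planted_edges_carry_full_evidence(self, default_sim):
        *_, truth = default_sim
        tm = simulate_target_map(truth, 0.05, seed=3)
        planted = tm.table.set_index(["mirna", "gene"]).loc[sorted(truth.planted_pairs)]
        assert (planted[["targetscan", "mirdb", "mirtarbase"]].to_numpy() == 1).all()

    def test_invalid_density_rejected(self, default_sim):
        *_, truth = default_sim
        with pytest.raises(ValueError):
            simulate_target_map(truth, 1.5, seed=1)


class TestGeneSets:
    def test_designated_intersection_is_exactly_hub_genes(self, default_sim):
        *_, truth = default_sim
        col = simulate_gene_sets(truth, seed=4)
        assert col[SET_COLLAGEN] & col[SET_ELASTIN] == truth.hub_genes

    def test_two_sets_only(self, default_sim):
        *_, truth = default_sim
        col = simulate_gene_sets(truth, n_sets=2, seed=4)
        assert set(col.names()) == {SET_COLLAGEN, SET_ELASTIN}

    def test_categories_match_truth(self, default_sim):
        *_, truth = default_sim
        col = simulate_gene_sets(truth, seed=4)
        for name in (CATEGORY_ECM, CATEGORY_HSC, CATEGORY_LOX):
            assert truth.key_categories[name] <= col[name]

    def test_set_size_below_hub_count_rejected(self, default_sim):
        *_, truth = default_sim
        with pytest.raises(ValueError, match="set_size"):
            simulate_gene_sets(truth, set_size=2, seed=4)

    def test_random_set_pairwise_overlap_matches_hypergeometric_mean(self):
        truth = SyntheticTruth()
        genes = [f"g{i}" for i in range(1000)]
        overlaps = []
        for seed in range(100):
            col = simulate_gene_sets(truth, n_sets=4, set_size=20, seed=seed, genes=genes)
            a, b = col["random-set-001"], col["random-set-002"]
            overlaps.append(len(a & b))
        # E[overlap] = 20 * 20 / 1000 = 0.4; 3 sigma of the mean of 100 draws
        sd = np.sqrt(0.4)  # ~Poisson-like variance of a single overlap
        assert abs(np.mean(overlaps) - 0.4) <= 3 * sd / np.sqrt(100)


class TestPlantedCorrelationProperties:
    def _frac_above(self, coupling, dispersion=0.02):
        params = SimulationParams(
            seed=3, n_mirna=300, n_gene=1500, frac_reversal=0.9,
            dispersion=dispersion, coupling_strength=coupling,
        )
        cmm, cmg, truth = simulate_counts(params)
        cand = pd.DataFrame(sorted(truth.planted_pairs), columns=["mirna", "gene"])
        assert len(cand) >= 200
        ret = correlate_pairs(
            tpm_mirna(cmm), tpm_mirna(cmg), cand, pcc_min=0.0, p_max=1.1
        )
        return (ret["pcc"].abs() >= 0.8).mean()

    @pytest.mark.parametrize("coupling", [0.9, 0.95])
    def test_strongly_coupled_pairs_mostly_pass_pcc_gate(self, coupling):
        assert self._frac_above(coupling) >= 0.8

    def test_latent_coupling_engages_at_high_dispersion(self):
        # the reversal pattern alone is not enough here; the latent factor is
        assert self._frac_above(0.9, dispersion=0.15) >= 0.8

    def test_background_pairs_rarely_pass_dual_gate(self):
        params = SimulationParams(seed=9, n_mirna=100, n_gene=200, frac_reversal=0.0)
        cmm, cmg, _ = simulate_counts(params)
        rng = np.random.default_rng(0)
        cand = pd.DataFrame(
            {
                "mirna": rng.choice(list(cmm.features), 6000),
                "gene": rng.choice(list(cmg.features), 6000),
            }
        ).drop_duplicates()
        assert len(cand) >= 5000
        ret = correlate_pairs(tpm_mirna(cmm), tpm_mirna(cmg), cand)
        assert len(ret) / len(cand) <= 0.02


class TestPPISimulation:
    def test_hub_neighborhood_is_densely_scored(self, default_sim):
        *_, truth = default_sim
        ppi = simulate_ppi(truth, seed=6)
        hub_edges = ppi.table[
            ppi.table["gene_a"].isin(truth.hub_genes)
            | ppi.table["gene_b"].isin(truth.hub_genes)
        ]
        partners = truth.key_categories[CATEGORY_ECM] | truth.key_categories[CATEGORY_HSC]
        strong = hub_edges[hub_edges["combined_score"] >= 700]
        covered = set(strong["gene_a"]) | set(strong["gene_b"])
        assert partners <= covered
        assert truth.hub_genes <= covered
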