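"""Reversal filtering, target intersection, correlation pairing, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fibromir.diffexpr import DECriteria, DEResult, signed_fold_change
from fibromir.integrate import (
    CLASS_DOWN_MIR_UP_GENE,
    CLASS_POSITIVE,
    CLASS_UP_MIR_DOWN_GENE,
    ReversalSet,
    classify_pairs,
    correlate_pairs,
    intersect_targets,
    pearson_with_p,
    reversal_filter,
)
from fibromir.io import TargetMap
from fibromir.normalize import ExpressionMatrix


def _de(spec: dict[str, tuple[float, float]], contrast="test") -> DEResult:
    """DEResult from {feature: (log2fc, fdr)}."""
    feats = list(spec)
    lfc = np.array([spec[f][0] for f in feats])
    fdr = np.array([spec[f][1] for f in feats])
    return DEResult(
        pd.DataFrame(
            {
                "base_mean": 10.0,
                "log2fc": lfc,
                "signed_fc": signed_fold_change(lfc),
                "p_value": fdr,
                "fdr": fdr,
            },
            index=pd.Index(feats, name="feature"),
        ),
        contrast,
    )


SIG, NS = 1e-4, 0.5


class TestReversalFilter:
    def test_sign_logic(self):
        fib = _de({"A": (2, SIG), "B": (-2, SIG), "C": (2, SIG)})
        rec = _de({"A": (-2, SIG), "B": (-2, NS), "C": (2, SIG)})
        rev = reversal_filter(fib, rec)
        assert set(rev.table.index) == {"A"}
        assert rev.table.loc["A", "fibrosis_dir"] == 1
        assert rev.table.loc["A", "recovery_dir"] == -1

    def test_fibrosis_only_feature_excluded(self):
        fib = _de({"A": (3, SIG)})
        rec = _de({"A": (-3, NS)})  # opposite sign but not significant
        assert len(reversal_filter(fib, rec).table) == 0

    def test_sign_only_mode_relaxes_recovery_significance(self):
        fib = _de({"A": (3, SIG)})
        rec = _de({"A": (-0.3, NS)})
        assert set(reversal_filter(fib, rec, sign_only=True).table.index) == {"A"}

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            reversal_filter(_de({"A": (2, SIG)}), _de({"B": (2, SIG)}))

    def test_order_independent(self):
        spec_f = {f"f{i}": ((-1) ** i * 2, SIG) for i in range(20)}
        spec_r = {f"f{i}": ((-1) ** (i + 1) * 2, SIG if i % 3 else NS) for i in range(20)}
        fwd = reversal_filter(_de(spec_f), _de(spec_r))
        shuffled_f = dict(reversed(list(spec_f.items())))
        shuffled_r = dict(reversed(list(spec_r.items())))
        bwd = reversal_filter(_de(shuffled_f), _de(shuffled_r))
        assert fwd.table.sort_index().equals(bwd.table.sort_index())

    def test_concordant_members_rejected_by_container(self):
        table = pd.DataFrame({"fibrosis_dir": [1], "recovery_dir": [1]}, index=["x"])
        with pytest.raises(ValueError, match="concordant"):
            ReversalSet(table, platform="miRNA")


def _revset(features: dict[str, int], platform="mRNA") -> ReversalSet:
    """ReversalSet from {feature: recovery_dir}."""
    table = pd.DataFrame(
        {
            "fibrosis_dir": [-d for d in features.values()],
            "recovery_dir": list(features.values()),
        },
        index=pd.Index(list(features), name="feature"),
    )
    return ReversalSet(table, platform=platform)


def _tmap(edges) -> TargetMap:
    return TargetMap(
        pd.DataFrame(
            [(m, g, 1, 1, 1) for m, g in edges],
            columns=["mirna", "gene", "targetscan", "mirdb", "mirtarbase"],
        )
    )


class TestIntersectTargets:
    def test_simple_overlap(self):
        cand, n = intersect_targets(
            _tmap([("m1", "g1"), ("m1", "g2")]),
            _revset({"m1": 1}, "miRNA"),
            _revset({"g2": -1, "g3": -1}),
        )
        assert list(map(tuple, cand.values)) == [("m1", "g2")]
        assert n == 1

    def test_disjoint_sets_give_empty(self):
        cand, n = intersect_targets(
            _tmap([("m1", "g1")]), _revset({"m2": 1}, "miRNA"), _revset({"g2": -1})
        )
        assert len(cand) == 0 and n == 0

    def test_enumerated_pairs_and_overlap_count(self):
        cand, n = intersect_targets(
            _tmap([("m1", "g1"), ("m2", "g1"), ("m2", "g2")]),
            _revset({"m1": 1, "m2": 1}, "miRNA"),
            _revset({"g1": -1, "g2": -1}),
        )
        assert len(cand) == 3 and n == 2

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty target map"):
            intersect_targets(
                TargetMap(
                    pd.DataFrame(columns=["mirna", "gene", "targetscan", "mirdb", "mirtarbase"])
                ),
                _revset({"m1": 1}, "miRNA"),
                _revset({"g1": -1}),
            )


class TestPearsonWithP:
    def test_perfect_positive_linear(self):
        x = np.arange(9.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, p = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0) and p == 0.0

    def test_p_at_r08_n9_matches_t_distribution(self):
        # construct a 9-sample pair with r very close to 0.8
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.standard_normal(9)
            y = 0.8 * (x - x.mean()) / x.std() + rng.standard_normal(9) * 0.75
            r, p = pearson_with_p(x, y)
            if abs(r - 0.8) < 5e-3:
                break
        assert abs(r - 0.8) < 5e-3
        t = r * np.sqrt(7 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(t, 7), rel=1e-12)
        assert p == pytest.approx(0.0097, abs=5e-4)

    @given(st.integers(0, 10_000))
    def test_matches_scipy_pearsonr(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        r, p = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    @given(st.integers(0, 2_000))
    def test_fisher_transform_approximation_large_n(self, seed):
        # the large-sample normal approximation agrees in the moderate-p
        # regime; relative agreement degrades in the far tail by construction
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        r, p = pearson_with_p(x, y)
        z = np.arctanh(r) * np.sqrt(n - 3)
        p_fisher = 2 * stats.norm.sf(abs(z))
        if 0.01 < p_fisher < 0.95:
            assert p == pytest.approx(p_fisher, rel=0.10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])


def _expr(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(len(next(iter(rows.values()))))]).T,
        unit="TPM",
    )


class TestCorrelatePairs:
    def test_strong_negative_pair_retained(self):
        x = list(np.geomspace(1, 100, 9))
        y = list(np.geomspace(100, 1, 9))
        me = _expr({"m1": x})
        ge = _expr({"g1": y})
        cand = pd.DataFrame({"mirna": ["m1"], "gene": ["g1"]})
        out = correlate_pairs(me, ge, cand)
        assert len(out) == 1
        assert out["pcc"].iloc[0] < -0.8 and out["p_value"].iloc[0] < 0.05

    def test_weak_pair_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(9) + 5
        y = rng.standard_normal(9) + 5
        out = correlate_pairs(
            _expr({"m1": list(np.abs(x))}),
            _expr({"g1": list(np.abs(y))}),
            pd.DataFrame({"mirna": ["m1"], "gene": ["g1"]}),
        )
        assert len(out) == 0

    def test_sample_mismatch_rejected(self):
        me = _expr({"m1": [1, 2, 3]})
        ge = ExpressionMatrix(
            pd.DataFrame({"x0": [1.0], "x1": [2.0], "x2": [3.0]}, index=["g1"]), "TPM"
        )
        with pytest.raises(ValueError, match="different sample sets"):
            correlate_pairs(me, ge, pd.DataFrame({"mirna": ["m1"], "gene": ["g1"]}))


class TestClassifyPairs:
    def _pairs(self, rows):
        tab = pd.DataFrame(rows, columns=["mirna", "gene", "pcc"])
        tab["p_value"] = 0.01
        tab["n_samples"] = 9
        return tab

    def test_partition_sum(self):
        pairs = self._pairs(
            [("mU1", "gD1", -0.9), ("mU1", "gD2", -0.85),
             ("mD1", "gU1", -0.9), ("mD2", "gU1", -0.9), ("mD2", "gU2", -0.95)]
        )
        mir = _revset({"mU1": 1, "mD1": -1, "mD2": -1}, "miRNA")
        gene = _revset({"gD1": -1, "gD2": -1, "gU1": 1, "gU2": 1})
        out, summary = classify_pairs(pairs, mir, gene)
        assert summary["negative"] == 5
        assert summary[CLASS_UP_MIR_DOWN_GENE]["pairs"] == 2
        assert summary[CLASS_DOWN_MIR_UP_GENE]["pairs"] == 3
        assert summary["negative_total_check"] == summary["negative"]
        assert summary[CLASS_UP_MIR_DOWN_GENE]["mirnas"] == 1
        assert summary[CLASS_DOWN_MIR_UP_GENE]["genes"] == 2

    def test_concordant_pair_is_positive_and_excluded(self):
        pairs = self._pairs([("mU1", "gU1", 0.92)])
        out, summary = classify_pairs(
            pairs, _revset({"mU1": 1}, "miRNA"), _revset({"gU1": 1})
        )
        assert out["pair_class"].iloc[0] == CLASS_POSITIVE
        assert summary["positive"] == 1 and summary["negative"] == 0

    def test_missing_direction_label_rejected(self):
        pairs = self._pairs([("mX", "gD1", -0.9)])
        with pytest.raises(ValueError, match="without direction label"):
            classify_pairs(pairs, _revset({"mU1": 1}, "miRNA"), _revset({"gD1": -1}))

    def test_classes_partition_negative_pairs_exactly(self, pipeline_report):
        report, outdir = pipeline_report
        pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t")
        neg = pairs[pairs["pcc"] < 0]
        up = pairs[pairs["pair_class"] == CLASS_UP_MIR_DOWN_GENE]
        down = pairs[pairs["pair_class"] == CLASS_DOWN_MIR_UP_GENE]
        assert len(up) + len(down) == len(neg)
        assert set(up.index).isdisjoint(set(down.index))
        assert set(up.index) | set(down.index) == set(neg.index)
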