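"""Observed/expected dosage ratios, log2FC and rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from monolens.dosage import (
    CountsTable,
    benjamini_hochberg,
    dosage_ratio,
    expected_counts_uniform,
    fitness_expression_correlation,
    log2fc,
    size_factors,
    spearman,
)
from monolens import synthetic_data as synth


def table_with_counts(annotation, **columns):
    return CountsTable(
        counts=pd.DataFrame(columns, index=annotation.index),
        annotation=annotation,
    )


class TestExpectedCounts:
    def test_equal_lengths_split_library_evenly(self, tiny_annotation):
        t = table_with_counts(tiny_annotation, s=[70, 110, 90, 130, 5, 5])
        exp = expected_counts_uniform(t, "s")
        np.testing.assert_allclose(exp.to_numpy(), [100.0] * 4)

    def test_length_proportional_split(self, tiny_annotation):
        ann = tiny_annotation.copy()
        ann.loc[["gA", "gB", "gC", "gD"], "length"] = [100, 200, 300, 400]
        t = table_with_counts(ann, s=[25, 25, 25, 25, 0, 0])
        exp = expected_counts_uniform(t, "s")
        np.testing.assert_allclose(exp.to_numpy(), [10.0, 20.0, 30.0, 40.0])

    def test_equal_weight_option(self, tiny_annotation):
        ann = tiny_annotation.copy()
        ann.loc[["gA", "gB", "gC", "gD"], "length"] = [100, 200, 300, 400]
        t = table_with_counts(ann, s=[25, 25, 25, 25, 0, 0])
        exp = expected_counts_uniform(t, "s", length_weighted=False)
        np.testing.assert_allclose(exp.to_numpy(), [25.0] * 4)

    def test_conservation_on_random_tables(self, tiny_annotation):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 500, size=6)
            counts[:4] = np.maximum(counts[:4], 1)
            t = table_with_counts(tiny_annotation, s=counts)
            exp = expected_counts_uniform(t, "s")
            assert exp.sum() == pytest.approx(counts[:4].sum(), rel=1e-12)

    def test_spikes_excluded(self, tiny_annotation):
        t = table_with_counts(tiny_annotation, s=[100, 100, 100, 100, 900, 900])
        exp = expected_counts_uniform(t, "s")
        assert set(exp.index) == {"gA", "gB", "gC", "gD"}
        assert exp.sum() == pytest.approx(400)


class TestDosageRatio:
    def test_uniform_table_all_ratios_one(self, tiny_annotation):
        t = table_with_counts(tiny_annotation, s=[100, 100, 100, 100, 0, 0])
        res = dosage_ratio(t, "s")
        np.testing.assert_allclose(res.gene_ratios.to_numpy(), 1.0)
        assert res.chrom_ratios == {"I": 1.0, "II": 1.0}

    def test_zero_count_gene_keeps_zero_ratio(self, tiny_annotation):
        t = table_with_counts(tiny_annotation, s=[0, 200, 100, 100, 0, 0])
        res = dosage_ratio(t, "s")
        assert res.gene_ratios["gA"] == 0.0

    def test_noiseless_generator_gives_exact_ratios(self, genome_annotation):
        # dispersion 0 + uniform baseline: every non-spike ratio exactly 1
        truth = synth.TruthRecord(monosomic_chromosome=None, seed=2)
        table = synth.simulate_counts(
            truth, genome_annotation, lib_size=1e6, dispersion=0.0, baseline=1.0
        )
        res = dosage_ratio(table, "ctrl_1")
        np.testing.assert_allclose(res.gene_ratios.to_numpy(), 1.0, rtol=1e-9)

    def test_halved_chromosome_ratio_on_synthetic_monosomic(
        self, genome_annotation
    ):
        truth = synth.TruthRecord(
            monosomic_chromosome="III", rp_upregulation=1.0, seed=4
        )
        table = synth.simulate_counts(
            truth, genome_annotation, lib_size=5e6, dispersion=0.05
        )
        res = dosage_ratio(table, "mono_1")
        # single sample: NB + baseline scatter plus the small structural
        # inflation from the halved chromosome shrinking its own library
        assert res.chrom_ratios["III"] == pytest.approx(0.5, abs=0.03)
        others = [
            r for c, r in res.chrom_ratios.items() if c not in ("III",)
        ]
        assert np.mean(others) == pytest.approx(1.0, abs=0.03)


class TestLog2FC:
    def test_identical_groups_zero(self, tiny_counts):
        lfc = log2fc(tiny_counts, ["ctrl"], ["ctrl"])
        np.testing.assert_allclose(lfc.to_numpy(), 0.0)

    def test_exact_halving_with_zero_pseudocount(self, tiny_annotation):
        t = table_with_counts(
            tiny_annotation,
            ctrl=[100, 100, 100, 100, 0, 0],
            mono=[50, 100, 100, 100, 0, 0],
        )
        # equal effective libraries arranged so size factors are 1
        lfc = log2fc(t, ["mono"], ["ctrl"], pseudocount=0.0)
        assert lfc["gA"] == pytest.approx(-1.0, abs=0.1)
        assert lfc["gC"] == pytest.approx(0.0, abs=0.1)

    def test_library_scaling_invariance(self, tiny_annotation):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, size=6)
        t1 = table_with_counts(
            tiny_annotation, a=base, b=rng.integers(50, 500, size=6)
        )
        t2 = table_with_counts(
            tiny_annotation, a=base * 3, b=t1.counts["b"].to_numpy()
        )
        # pseudocount 0: with a pseudocount the invariance is only
        # approximate (the common scale shifts when one library triples)
        l1 = log2fc(t1, ["a"], ["b"], pseudocount=0.0)
        l2 = log2fc(t2, ["a"], ["b"], pseudocount=0.0)
        np.testing.assert_allclose(l1.to_numpy(), l2.to_numpy(), atol=1e-9)

    def test_size_factors_match_median_of_ratios_oracle(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(50, 3)), columns=["a", "b", "c"]
        )
        sf = size_factors(counts)
        # independent oracle: explicit geometric-mean reference
        ref = np.exp(np.mean(np.log(counts.to_numpy()), axis=1))
        for j, s in enumerate(counts.columns):
            oracle = np.median(counts[s].to_numpy() / ref)
            assert sf[s] == pytest.approx(oracle, rel=1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_ties_match_permutation_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0]
        rs, p = spearman(x, y)
        # oracle: naive average ranks + full enumeration of y relabelings
        def naive_ranks(v):
            v = list(v)
            return [
                (sum(1 for u in v if u < w)
                 + (sum(1 for u in v if u == w) + 1) / 2)
                for w in v
            ]

        def pearson(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            a, b = a - a.mean(), b - b.mean()
            return float(a @ b / np.sqrt((a @ a) * (b @ b)))

        rx, ry = naive_ranks(x), naive_ranks(y)
        rs_oracle = pearson(rx, ry)
        assert rs == pytest.approx(rs_oracle, abs=1e-12)
        count = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(pearson(rx, perm)) >= abs(rs_oracle) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_matches_scipy_at_large_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rs, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rs == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        data=st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
            min_size=5,
            max_size=12,
            unique_by=lambda t: round(t[0], 3),
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, data):
        # coarse x spacing keeps exp(x) values distinct in float64
        x = [round(t[0], 3) for t in data]
        y = [t[1] for t in data]
        try:
            rs1, _ = spearman(x, y)
        except ValueError:
            return  # degenerate rank variance
        rs2, _ = spearman([np.exp(v) for v in x], y)
        assert rs1 == pytest.approx(rs2, abs=1e-9)


class TestFitnessExpressionCorrelation:
    def test_monotone_relation_gives_unit_correlation(self, tiny_annotation):
        ann = pd.concat(
            [
                tiny_annotation,
                pd.DataFrame(
                    {
                        "chrom": ["I", "I"],
                        "start": [2001, 3001],
                        "end": [2500, 3500],
                        "length": [500, 500],
                        "is_spike": [False, False],
                        "is_rp": [False, False],
                    },
                    index=pd.Index(["gE", "gF"], name="gene_id"),
                ),
            ]
        )
        fitness = {"gA": -0.3, "gB": -0.1, "gE": -0.2, "gF": 0.0, "gC": -0.5}
        expression = {g: 2 * d + 1 for g, d in fitness.items()}
        rs, p, n = fitness_expression_correlation(
            fitness, expression, ann, chromosome="I"
        )
        assert rs == pytest.approx(1.0)
        assert n == 4  # gC is on chromosome II and must be excluded

    def test_off_chromosome_genes_never_enter(self, tiny_annotation):
        fitness = {"gA": -0.3, "gB": -0.1, "gC": -0.2, "gD": 0.0}
        expression = dict.fromkeys(fitness, 0.1)
        with pytest.raises(ValueError, match="chromosome I"):
            # only 2 of the 4 genes are on chromosome I
            fitness_expression_correlation(
                fitness, expression, tiny_annotation, chromosome="I"
            )

    def test_null_p_values_roughly_uniform(self):
        # independent d and log2FC: p should be ~U(0,1)
        rng = np.random.default_rng(8)
        ann = pd.DataFrame(
            {
                "chrom": "I",
                "start": 1,
                "end": 100,
                "length": 100,
                "is_spike": False,
                "is_rp": False,
            },
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        )
        pvals = []
        for _ in range(200):
            fitness = {g: rng.normal() for g in ann.index}
            expr = {g: rng.normal() for g in ann.index}
            _, p, _ = fitness_expression_correlation(fitness, expr, ann, "I")
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(size=30)
    q = benjamini_hochberg(p)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, ref, atol=1e-12)
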