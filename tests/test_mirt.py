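"""Normalization, gene grouping, expression comparison and Fisher's test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rddscout import mirt
from rddscout.io_model import ExpressionTable, GeneModel


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration (test oracle)."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    weights = {
        k: math.comb(col1, k) * math.comb(n - col1, row1 - k)
        for k in range(lo, hi + 1)
    }
    total = sum(weights.values())
    w_obs = weights[a]
    acc = sum(
        w for w in weights.values()
        if w <= w_obs or Fraction(w, w_obs) <= 1 + Fraction(1, 10**7)
    )
    return float(Fraction(acc, total))


class TestNormalizeCounts:
    def test_hand_computed_size_factors(self):
        counts = pd.DataFrame({"s1": [2, 8], "s2": [4, 16]},
                              index=["g1", "g2"])
        table = mirt.normalize_counts(ExpressionTable(counts=counts))
        assert table.size_factors["s1"] == pytest.approx(1 / math.sqrt(2))
        assert table.size_factors["s2"] == pytest.approx(math.sqrt(2))
        pd.testing.assert_series_equal(
            table.normalized["s1"], table.normalized["s2"], check_names=False
        )

    def test_identical_specimens_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 9, 100], "s2": [5, 9, 100]},
                              index=list("abc"))
        table = mirt.normalize_counts(ExpressionTable(counts=counts))
        assert np.allclose(table.size_factors, 1.0)

    def test_scaling_one_specimen_is_absorbed_up_to_a_common_factor(self):
        """Rescaling one library leaves all between-specimen ratios of the
        normalized matrix unchanged (the whole matrix shifts by the common
        factor c**(1/n) because the geometric-mean reference itself moves)."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 4)),
            columns=["s1", "s2", "s3", "s4"],
        )
        base = mirt.normalize_counts(ExpressionTable(counts=counts))
        c = 3.0
        scaled_counts = counts.copy()
        scaled_counts["s2"] = scaled_counts["s2"] * c
        scaled = mirt.normalize_counts(ExpressionTable(counts=scaled_counts))
        n = counts.shape[1]
        assert scaled.size_factors["s2"] == pytest.approx(
            c ** ((n - 1) / n) * base.size_factors["s2"]
        )
        ratio = scaled.normalized / base.normalized
        assert np.allclose(ratio, c ** (1 / n))

    def test_no_universally_expressed_gene_is_error(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
        with pytest.raises(ValueError):
            mirt.normalize_counts(ExpressionTable(counts=counts))


class TestGeneCoverage:
    @pytest.mark.parametrize(
        "reads,length,cov,evaluable",
        [(1000, 5000, 15.0, True), (100, 5000, 1.5, False),
         (667, 5002.5, 10.0, False)],  # exactly 10X is excluded (strict >)
    )
    def test_coverage_proxy(self, reads, length, cov, evaluable):
        got = mirt.gene_coverage(reads, 75, length)
        assert got == pytest.approx(cov, abs=1e-6)
        assert (got > 10) is evaluable

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError):
            mirt.gene_coverage(10, 75, 0)


def _models():
    def gene(gid, biotype="coding"):
        kw = {"cds_start": 110, "cds_end": 190} if biotype == "coding" else {}
        return GeneModel(gene_id=gid, transcript_id=gid + ".t", chrom="c",
                         strand="+", exons=[(100, 200)], biotype=biotype, **kw)
    return [gene("GA"), gene("GB"), gene("GC"), gene("NC", "ncRNA")]


def _call(sp, gene, mirt_flag):
    return {
        "specimen": sp, "chrom": "c", "pos": 150, "ref": "A", "alt": "G",
        "feature": "UTR3" if mirt_flag else "CDS",
        "gene_id": gene,
        "in_mirna_target": mirt_flag,
        "in_mirna_target_gene": gene if mirt_flag else "",
    }


class TestAssignGroups:
    def test_mirt_and_control_and_dual_removal(self):
        calls = pd.DataFrame([
            _call("S1", "GA", True),            # mirT gene
            _call("S1", "GB", False),           # crRDD control gene
            _call("S1", "GC", True), _call("S2", "GC", False),  # dual-status
            _call("S1", "NC", True),            # ncRNA: excluded
        ])
        groups = mirt.assign_groups(calls, _models())
        by_cat = groups.groupby("category")["gene_id"].apply(set).to_dict()
        assert by_cat == {"mirT": {"GA"}, "crRDD": {"GB"}}

    def test_specimens_listed_per_gene(self):
        calls = pd.DataFrame([_call("S1", "GA", True), _call("S3", "GA", True)])
        groups = mirt.assign_groups(calls, _models())
        assert set(groups["specimen"]) == {"S1", "S3"}


class TestCompareExpression:
    def _expr(self, values):
        counts = pd.DataFrame(
            {f"S{i+1}": [v] for i, v in enumerate(values)}, index=["GA"]
        )
        table = ExpressionTable(counts=counts)
        table.normalized = counts.astype(float)  # identity normalization
        return table

    def _groups(self, specimens):
        return pd.DataFrame(
            [{"gene_id": "GA", "category": "mirT", "specimen": s}
             for s in specimens]
        )

    def test_identical_groups_give_zero_logfc_p_one(self):
        table = self._expr([100, 100, 100, 100, 100, 100])
        comps = mirt.compare_expression(self._groups(["S1", "S2", "S3"]), table)
        assert comps[0].log_fc == 0.0 and comps[0].p_value == 1.0

    def test_doubling_with_pseudocount_zero_is_logfc_one(self):
        table = self._expr([200, 200, 100, 100])
        comps = mirt.compare_expression(
            self._groups(["S1", "S2"]), table, pseudocount=0.0
        )
        assert comps[0].log_fc == pytest.approx(1.0)

    def test_small_group_reports_logfc_without_p(self):
        table = self._expr([210, 190, 100, 110, 90, 105])
        comps = mirt.compare_expression(self._groups(["S1", "S2"]), table)
        assert comps[0].p_value is None and comps[0].n_with == 2

    def test_welch_p_matches_scipy(self):
        table = self._expr([210, 190, 205, 100, 110, 90])
        comps = mirt.compare_expression(self._groups(["S1", "S2", "S3"]), table)
        expected = stats.ttest_ind(
            [210, 190, 205], [100, 110, 90], equal_var=False
        ).pvalue
        assert comps[0].p_value == pytest.approx(expected)

    def test_empty_group_skips_gene(self):
        table = self._expr([100, 100])
        comps = mirt.compare_expression(self._groups(["S1", "S2"]), table)
        assert comps == []


class TestProportionTable:
    def _comps(self, logfcs, category="crRDD"):
        return [
            mirt.GeneComparison(f"g{i}", category, 3, 3, 1, 1, fc, None)
            for i, fc in enumerate(logfcs)
        ]

    def test_counts_at_each_cutoff(self):
        table = mirt.proportion_table(self._comps([1.2, 0.6, -0.2]))
        at = table.set_index("cutoff")
        assert at.loc[0.0, "n_up"] == 2 and at.loc[0.0, "frac_up"] == pytest.approx(2 / 3)
        assert at.loc[0.5, "n_up"] == 2
        assert at.loc[1.0, "n_up"] == 1

    def test_zero_logfc_counts_as_not_up(self):
        table = mirt.proportion_table(self._comps([0.0, 0.0, 1.0]))
        at = table.set_index("cutoff")
        assert at.loc[0.0, "n_up"] == 1 and at.loc[0.0, "n_down"] == 0

    def test_empty_category_absent(self):
        assert mirt.proportion_table([]).empty


class TestFisherExact:
    def test_symmetric_example(self):
        _, p = mirt.fisher_exact_2x2(8, 2, 2, 8)
        assert p == pytest.approx(fisher_oracle(8, 2, 2, 8), rel=1e-9)
        assert p == pytest.approx(0.0230, abs=5e-4)

    def test_balanced_table_p_one(self):
        odds, p = mirt.fisher_exact_2x2(5, 5, 5, 5)
        assert p == 1.0 and odds == 1.0

    def test_zero_margin_p_one(self):
        assert mirt.fisher_exact_2x2(0, 0, 3, 4)[1] == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mirt.fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            _, p = mirt.fisher_exact_2x2(a, b, c, d)
            sp = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert p == pytest.approx(sp, rel=1e-7, abs=1e-12)

    def test_reconstructed_study_scale_table_order_of_magnitude(self):
        # 65.1% of 1,068 mirT genes up vs 592 of 1,139 control genes up:
        # the difference is significant at the 1e-10 scale
        _, p = mirt.fisher_exact_2x2(695, 373, 592, 547)
        assert 1e-13 < p < 1e-8


class TestUpProportionTest:
    def test_contrast_between_categories(self):
        comps = (
            [mirt.GeneComparison(f"m{i}", "mirT", 3, 3, 1, 1, 0.8, None)
             for i in range(18)]
            + [mirt.GeneComparison("m18", "mirT", 3, 3, 1, 1, -0.5, None)]
            + [mirt.GeneComparison(f"c{i}", "crRDD", 3, 3, 1, 1,
                                   0.5 if i % 2 else -0.5, None)
               for i in range(20)]
        )
        out = mirt.up_proportion_test(comps)
        assert out["mirT_frac_up"] > out["crRDD_frac_up"]
        assert out["p_value"] == pytest.approx(
            fisher_oracle(out["mirT_up"], out["mirT_not_up"],
                          out["crRDD_up"], out["crRDD_not_up"]), rel=1e-9
        )
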