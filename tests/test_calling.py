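"""Genotype classification, coverage thresholds and the rescue rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rddscout import calling
from rddscout.calling import RescueParams, rescue_test


class TestCallGenotype:
    @pytest.mark.parametrize(
        "counts,ref,expected,variant",
        [
            ({"nA": 10, "nC": 0, "nG": 0, "nT": 0}, "A", "AA", None),
            ({"nA": 5, "nC": 0, "nG": 5, "nT": 0}, "A", "AB", "G"),
            ({"nA": 0, "nC": 0, "nG": 10, "nT": 0}, "A", "BB", "G"),
            ({"nA": 1, "nC": 0, "nG": 0, "nT": 0}, "A", "NoCall", None),
            ({"nA": 9, "nC": 0, "nG": 1, "nT": 0}, "A", "AA", None),
            ({"nA": 5, "nC": 0, "nG": 1, "nT": 0}, "A", "AB", "G"),
        ],
    )
    def test_classification(self, counts, ref, expected, variant):
        cls, var = calling.call_genotype(counts, ref)
        assert cls == expected
        if expected in ("AB", "BB"):
            assert var == variant

    def test_variant_tie_broken_alphabetically(self):
        cls, var = calling.call_genotype(
            {"nA": 4, "nC": 3, "nG": 0, "nT": 3}, "A"
        )
        assert cls == "AB" and var == "C"

    def test_bad_ref_raises(self):
        with pytest.raises(ValueError):
            calling.call_genotype({"nA": 1, "nC": 0, "nG": 0, "nT": 0}, "N")


def _counts_row(sp, chrom, pos, assay, **kw):
    row = {"specimen": sp, "chrom": chrom, "pos": pos, "assay": assay,
           "nA": 0, "nC": 0, "nG": 0, "nT": 0}
    row.update(kw)
    return row


class TestThresholds:
    def _table(self):
        rows = []
        # concordant AA sites with DNA ref counts 2, 4, 6 -> c_dna_aa = 4
        for pos, x in ((1, 2), (2, 4), (3, 6)):
            rows.append(_counts_row("S1", "c", pos, "DNA", nA=x))
            rows.append(_counts_row("S1", "c", pos, "RNA", nA=20))
        # concordant AB sites with RNA variant counts 3, 5 -> c_rna_ab = 4
        for pos, y in ((4, 3), (5, 5)):
            rows.append(_counts_row("S1", "c", pos, "DNA", nA=5, nG=5))
            rows.append(_counts_row("S1", "c", pos, "RNA", nA=6, nG=y))
        return pd.DataFrame(rows)

    def test_means_and_empty_bb_category(self, caplog):
        genome = {"c": "A" * 10}
        with caplog.at_level("WARNING"):
            th = calling.cohort_thresholds(self._table(), genome)["S1"]
        assert th.c_dna_aa == pytest.approx(4.0)
        assert th.c_rna_ab == pytest.approx(4.0)
        assert th.c_rna_bb == 0.0  # declared default for an empty category
        assert "BB" in caplog.text

    def test_no_concordant_sites_is_error(self):
        rows = [
            _counts_row("S1", "c", 1, "DNA", nA=10),
            _counts_row("S1", "c", 1, "RNA", nG=10),  # discordant only
        ]
        with pytest.raises(ValueError, match="concordant"):
            calling.cohort_thresholds(pd.DataFrame(rows), {"c": "A"})


class TestHighCoverage:
    TH = calling.CoverageThresholds("S1", c_dna_aa=4, c_rna_ab=3, c_rna_bb=12)

    def test_strict_inequalities_make_a_call(self):
        call = calling.call_high_coverage(
            {"nA": 6, "nC": 0, "nG": 0, "nT": 0},
            {"nA": 5, "nC": 0, "nG": 5, "nT": 0},
            "A", self.TH,
        )
        assert call is not None
        assert call["alt"] == "G" and call["status"] == "high_coverage"

    def test_boundary_equal_to_threshold_fails(self):
        call = calling.call_high_coverage(
            {"nA": 4, "nC": 0, "nG": 0, "nT": 0},
            {"nA": 5, "nC": 0, "nG": 5, "nT": 0},
            "A", self.TH,
        )
        assert call is None

    def test_bb_class_uses_bb_threshold(self):
        call = calling.call_high_coverage(
            {"nA": 6, "nC": 0, "nG": 0, "nT": 0},
            {"nA": 0, "nC": 0, "nG": 10, "nT": 0},
            "A", self.TH,
        )
        assert call is None  # 10 <= c_rna_bb = 12


class TestPooledRatio:
    def test_pool_over_specimens(self):
        counts = np.array([[7, 0, 3, 0], [8, 0, 2, 0], [10, 0, 0, 0]])
        r, alt_idx, t = calling.pooled_editing_ratio(counts, ref_idx=0)
        assert r == pytest.approx(5 / 30)
        assert alt_idx == 2 and t == 30

    def test_single_specimen(self):
        r, _, _ = calling.pooled_editing_ratio(np.array([[4, 0, 4, 0]]), 0)
        assert r == pytest.approx(0.5)

    def test_zero_total(self):
        r, _, t = calling.pooled_editing_ratio(np.zeros((2, 4), int), 0)
        assert r == 0.0 and t == 0


class TestRescueTest:
    @pytest.mark.parametrize(
        "x,y,r,accepted",
        [
            (5, 5, 0.5, True),    # 0.03125 < 0.05 on both sides
            (4, 5, 0.5, False),   # (0.5)^4 = 0.0625 fails the DNA side
            (14, 4, 0.2, True),   # 0.8^14 ~ 0.044
            (13, 4, 0.2, False),  # 0.8^13 ~ 0.055
            (50, 3, 0.5, False),  # y > 3 is required regardless
            (50, 50, 0.0, False), # r=0: (1-r)^x = 1, never rescued
            (0, 50, 1.0, False),  # r=1, x=0: 0^0 = 1 fails the DNA side
            (1, 50, 1.0, False),  # r=1: r^y = 1 fails the RNA side
        ],
    )
    def test_examples(self, x, y, r, accepted):
        assert rescue_test(x, y, r) is accepted

    def test_alpha_and_min_edited_are_configurable(self):
        loose = RescueParams(alpha=0.2, min_edited=2)
        assert rescue_test(3, 3, 0.5, loose)  # both sides 0.125 < 0.2, y >= 2
        assert not rescue_test(3, 3, 0.5)     # defaults require y > 3

    def test_invalid_r_raises(self):
        with pytest.raises(ValueError):
            rescue_test(1, 5, 1.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        x=st.integers(0, 60), y=st.integers(0, 60),
        dx=st.integers(0, 10), dy=st.integers(0, 10),
        r=st.floats(0.01, 0.99),
    )
    def test_monotone_in_x_and_y(self, x, y, dx, dy, r):
        if rescue_test(x, y, r):
            assert rescue_test(x + dx, y + dy, r)

    def test_agrees_with_log_space_evaluation(self):
        rng = np.random.default_rng(7)
        p = RescueParams()
        for _ in range(2000):
            x, y = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            r = float(rng.uniform(0.001, 0.999))
            expect = (
                y >= p.min_edited
                and x * math.log1p(-r) < math.log(p.alpha)
                and y * math.log(r) < math.log(p.alpha)
            )
            assert rescue_test(x, y, r) is expect


class TestCallRdds:
    """A hand-built three-specimen cohort exercising both call routes."""

    def _cohort(self):
        rows = []
        genome = {"c": "A" * 40}
        for sp in ("S1", "S2", "S3"):
            # threshold calibration: concordant AA sites, DNA ref 5 and 7
            for pos, x in ((1, 5), (2, 7)):
                rows.append(_counts_row(sp, "c", pos, "DNA", nA=x))
                rows.append(_counts_row(sp, "c", pos, "RNA", nA=25))
            # concordant AB site (het SNP): RNA variant count 6
            rows.append(_counts_row(sp, "c", 3, "DNA", nA=5, nG=5))
            rows.append(_counts_row(sp, "c", 3, "RNA", nA=6, nG=6))
        # candidate edit at pos 10: DNA AA everywhere
        rows.append(_counts_row("S1", "c", 10, "DNA", nA=5))
        rows.append(_counts_row("S1", "c", 10, "RNA", nA=5, nG=5))
        rows.append(_counts_row("S2", "c", 10, "DNA", nA=10))
        rows.append(_counts_row("S2", "c", 10, "RNA", nA=6, nG=14))
        rows.append(_counts_row("S3", "c", 10, "DNA", nA=10))
        rows.append(_counts_row("S3", "c", 10, "RNA", nA=10))
        return pd.DataFrame(rows), genome

    def test_rescued_and_high_coverage_composition(self):
        counts, genome = self._cohort()
        calls = calling.call_rdds(counts, genome)
        at_site = calls[calls["pos"] == 10].set_index("specimen")

        # S1: x=5 <= c_dna_aa=6 blocks the high-coverage route; pooled
        # r = (5+14+0)/(10+20+10) = 0.475 gives (1-r)^5 ~ 0.040 and
        # r^5 ~ 0.024, y=5 > 3 -> rescued.
        assert at_site.loc["S1", "status"] == "rescued"
        assert at_site.loc["S1", "y_rna_alt"] == 5
        # S2: x=10 > 6 and y=14 > c_rna_ab=6 -> high coverage.
        assert at_site.loc["S2", "status"] == "high_coverage"
        # S3: no edited reads -> no call.
        assert "S3" not in at_site.index

    def test_calls_are_deterministic(self):
        counts, genome = self._cohort()
        a = calling.call_rdds(counts, genome)
        b = calling.call_rdds(counts, genome)
        pd.testing.assert_frame_equal(a, b)

    def test_dna_alt_reads_block_calling(self):
        counts, genome = self._cohort()
        # give S1 a non-reference DNA read pushing it out of AA
        idx = counts[(counts.specimen == "S1") & (counts.pos == 10)
                     & (counts.assay == "DNA")].index[0]
        counts.loc[idx, "nG"] = 1  # 5A/1G -> ref fraction 0.83 -> AB
        calls = calling.call_rdds(counts, genome)
        assert not ((calls.specimen == "S1") & (calls.pos == 10)).any()

    def test_rescue_disabled_drops_rescued_calls(self):
        counts, genome = self._cohort()
        calls = calling.call_rdds(counts, genome, enable_rescue=False)
        assert (calls["status"] == "high_coverage").all()

    def test_explicit_thresholds_override(self):
        counts, genome = self._cohort()
        strict = {
            sp: calling.CoverageThresholds(sp, c_dna_aa=100, c_rna_ab=100,
                                           c_rna_bb=100)
            for sp in ("S1", "S2", "S3")
        }
        calls = calling.call_rdds(counts, genome, thresholds=strict)
        # high-coverage route is closed; only the rescue route remains
        assert set(calls["status"]) <= {"rescued"}
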