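"""Substitution classes, strata, genic features, consequences, clusters and
recurrence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rddscout import annotation as ann
from rddscout.io_model import AnnotationSet, GeneModel, IntervalTrack


def brute_clusters(positions, d1=50, w=100, m=3):
    """Oracle: enumerate all pairs and windows, then take components."""
    pos = sorted(set(positions))
    n = len(pos)
    adj = {p: set() for p in pos}
    marked = set()

    def link(a, b):
        adj[a].add(b)
        adj[b].add(a)
        marked.update((a, b))

    for i in range(n - 1):
        if pos[i + 1] - pos[i] <= d1:
            link(pos[i], pos[i + 1])
    for start in set(pos):  # windows [start, start + w - 1]
        inside = [p for p in pos if start <= p <= start + w - 1]
        if len(inside) >= m:
            for a, b in zip(inside, inside[1:]):
                link(a, b)

    comps, seen = [], set()
    for p in pos:
        if p in seen or p not in marked:
            continue
        stack, comp = [p], []
        while stack:
            q = stack.pop()
            if q in seen:
                continue
            seen.add(q)
            comp.append(q)
            stack.extend(adj[q])
        comps.append(sorted(comp))
    return sorted(comps)


class TestSubstitutionClass:
    def test_canonical_pairing(self):
        assert ann.substitution_class("A", "G") == "A>G|T>C"
        assert ann.substitution_class("T", "C") == "A>G|T>C"

    def test_complement_collapse(self):
        assert ann.substitution_class("C", "T") == ann.substitution_class("G", "A")

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError):
            ann.substitution_class("A", "A")

    def test_twelve_pairs_partition_into_six_classes(self):
        classes = {
            ann.substitution_class(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        }
        assert classes == set(ann.SUBSTITUTION_CLASSES)
        for r, a in itertools.permutations("ACGT", 2):
            assert ann.substitution_class(r, a) == ann.substitution_class(
                ann.COMPLEMENT[r], ann.COMPLEMENT[a]
            )


class TestRegionStratum:
    def _ann(self):
        a = AnnotationSet()
        a.alu = IntervalTrack("alu", [("c", 100, 200)])
        a.non_alu_repeat = IntervalTrack("r", [("c", 150, 300)])
        return a

    def test_three_strata_with_alu_precedence(self):
        a = self._ann()
        assert ann.region_stratum("c", 120, a) == "Alu"
        assert ann.region_stratum("c", 250, a) == "non-Alu repeat"
        assert ann.region_stratum("c", 400, a) == "non-repeat"
        assert ann.region_stratum("c", 180, a) == "Alu"  # in both tracks


class TestGenicFeature:
    CODING = GeneModel(
        gene_id="G1", transcript_id="t1", chrom="c", strand="+",
        exons=[(100, 200), (300, 400), (500, 600)],
        cds_start=150, cds_end=550,
    )
    NCRNA = GeneModel(
        gene_id="N1", transcript_id="n1", chrom="c", strand="+",
        exons=[(210, 290)], biotype="ncRNA",
    )

    @pytest.mark.parametrize(
        "pos,feature,gene",
        [
            (160, "CDS", "G1"),
            (120, "UTR5", "G1"),
            (580, "UTR3", "G1"),
            (450, "intron", "G1"),
            (250, "ncRNA", "N1"),   # ncRNA exon wins over G1's intron
            (700, "intergenic", None),
        ],
    )
    def test_precedence(self, pos, feature, gene):
        models = [self.CODING, self.NCRNA]
        got_feature, got_gene = ann.genic_feature("c", pos, models)
        assert (got_feature, got_gene) == (feature, gene)

    def test_minus_strand_utrs_swap(self):
        minus = GeneModel(
            gene_id="G2", transcript_id="t2", chrom="c", strand="-",
            exons=[(100, 200), (300, 400)], cds_start=150, cds_end=350,
        )
        assert ann.genic_feature("c", 120, [minus])[0] == "UTR3"
        assert ann.genic_feature("c", 380, [minus])[0] == "UTR5"

    def test_every_site_gets_exactly_one_feature(self):
        models = [self.CODING, self.NCRNA]
        for pos in range(90, 620, 7):
            feature, _ = ann.genic_feature("c", pos, models)
            assert feature in ann.GENIC_FEATURES


class TestCodingConsequence:
    def _genome_and_model(self, cds_seq, strand="+"):
        # gene: single exon covering the CDS plus 10 bp UTR on each side
        genome = {"c": "T" * 10 + cds_seq + "T" * 10}
        model = GeneModel(
            gene_id="G", transcript_id="t", chrom="c", strand=strand,
            exons=[(1, len(genome["c"]))],
            cds_start=11, cds_end=10 + len(cds_seq),
        )
        return genome, model

    def test_q_to_r_missense(self):
        genome, model = self._genome_and_model("ATGCAGTAA")  # M Q *
        out = ann.coding_consequence("c", 15, "A", "G", model, genome)
        assert out == {"consequence": "missense", "aa_ref": "Q", "aa_alt": "R"}

    def test_synonymous_third_position(self):
        genome, model = self._genome_and_model("ATGCAATAA")  # M Q *
        out = ann.coding_consequence("c", 16, "A", "G", model, genome)
        assert out["consequence"] == "synonymous"
        assert out["aa_ref"] == out["aa_alt"] == "Q"

    def test_stop_gain(self):
        genome, model = self._genome_and_model("ATGTGGTAA")  # M W *
        # TGG -> TGA: reference-strand G>A at codon position 3
        out = ann.coding_consequence("c", 16, "G", "A", model, genome)
        assert out["consequence"] == "stop_gain" and out["aa_alt"] == "*"

    def test_minus_strand_q_to_r(self):
        # coding strand CDS = ATG CAG TAA; genomic reference holds its
        # reverse complement, and the edit appears as T>C on that strand
        from rddscout.io_model import reverse_complement

        cds = "ATGCAGTAA"
        genome = {"c": "G" * 10 + reverse_complement(cds) + "G" * 10}
        model = GeneModel(
            gene_id="G", transcript_id="t", chrom="c", strand="-",
            exons=[(1, len(genome["c"]))], cds_start=11, cds_end=19,
        )
        # coding-strand codon position: CDS index 4 (the Q's middle A);
        # genomic position = 11 + (9 - 1 - 4) = 15, reference T, edit T>C
        out = ann.coding_consequence("c", 15, "T", "C", model, genome)
        assert out == {"consequence": "missense", "aa_ref": "Q", "aa_alt": "R"}

    def test_cds_not_multiple_of_three_is_unknown(self):
        genome, model = self._genome_and_model("ATGCAGTA")
        out = ann.coding_consequence("c", 15, "A", "G", model, genome)
        assert out["consequence"] == "unknown"


class TestFindClusters:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([100, 140, 180], [[100, 140, 180]]),   # consecutive 50 bp rule
            ([100, 190, 260], []),                  # no rule applies
            ([1, 61, 100], [[1, 61, 100]]),         # 3 sites in one 100 bp window
            ([10], []),
            ([], []),
        ],
    )
    def test_examples(self, positions, expected):
        assert ann.find_clusters(positions) == expected

    def test_window_rule_boundary(self):
        # span 99 fits a 100 bp window; with all gaps > 50 and span > 99
        # neither rule applies
        assert ann.find_clusters([1, 50, 100]) == [[1, 50, 100]]
        assert ann.find_clusters([1, 52, 103]) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(0, 30))
            positions = sorted(rng.choice(600, size=n, replace=False).tolist())
            assert ann.find_clusters(positions) == brute_clusters(positions)


class TestRecurrence:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["specimen", "chrom", "pos", "ref", "alt"]
        )

    def test_two_specimens_recurrent(self):
        calls = self._calls(
            [("S1", "c", 10, "A", "G"), ("S2", "c", 10, "A", "G"),
             ("S1", "c", 20, "A", "G")]
        )
        out = ann.recurrence(calls)
        assert out.loc[0, "recurrence"] == 2 and out.loc[0, "recurrent"]
        assert out.loc[2, "recurrence"] == 1 and not out.loc[2, "recurrent"]

    def test_opposite_strand_reports_count_together(self):
        # A>G in one specimen, T>C in another at the same position: the
        # strand-ambiguous class makes them the same recurrent event
        calls = self._calls(
            [("S1", "c", 10, "A", "G"), ("S2", "c", 10, "T", "C")]
        )
        out = ann.recurrence(calls)
        assert out["recurrent"].all()

    def test_different_classes_stay_separate(self):
        calls = self._calls(
            [("S1", "c", 10, "A", "G"), ("S2", "c", 10, "A", "C")]
        )
        out = ann.recurrence(calls)
        assert not out["recurrent"].any()


class TestOverlapAnnotate:
    def test_membership_and_carried_ids(self):
        track = IntervalTrack("mirna_targets", [("c", 100, 120)],
                              data=[("mir-1", "GENE1")])
        calls = pd.DataFrame(
            {"specimen": ["S1"] * 3, "chrom": ["c"] * 3,
             "pos": [100, 110, 121], "ref": ["A"] * 3, "alt": ["G"] * 3}
        )
        out = ann.overlap_annotate(calls, track, "in_mirna_target",
                                   carry_ids=True)
        # boundary base 100 is inside (closed intervals); 121 is outside
        assert out["in_mirna_target"].tolist() == [True, True, False]
        assert out.loc[0, "in_mirna_target_mirna"] == "mir-1"
        assert out.loc[0, "in_mirna_target_gene"] == "GENE1"
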