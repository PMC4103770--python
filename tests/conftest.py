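"""Shared fixtures: a deterministic five-site toy cohort for the filter
cascade and small reusable inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rddscout.io_model import GeneModel

BASES = "ACGT"


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def toy_cascade():
    """Five candidate RDDs of which exactly one should survive filtering.

    Sites (one specimen, S1):
      * true edit         -- unique locus, clean flanks
      * known SNP         -- position present in the dbSNP-like mask
      * splice-proximal   -- intronic, 5 bp from an exon end
      * decoy-matching    -- decoy genome contains the substituted 61-mer
      * duplicated locus  -- host genome carries a copy with the edited base
    """
    rng = np.random.default_rng(20140718)
    host_a = _rand_seq(rng, 900)
    host_b = _rand_seq(rng, 400)

    def set_base(seq: str, pos: int, base: str) -> str:
        return seq[: pos - 1] + base + seq[pos:]

    # positions on hostA (1-based), >=150 bp apart
    p_true, p_snp, p_splice, p_decoy, p_dup = 120, 300, 470, 620, 790
    for p in (p_true, p_snp, p_splice, p_decoy, p_dup):
        host_a = set_base(host_a, p, "A")

    # gene with an exon ending at 465: site 470 is intronic base 5
    gene = GeneModel(
        gene_id="TOYG",
        transcript_id="TOYG.t1",
        chrom="hostA",
        strand="+",
        exons=[(420, 465), (560, 580)],
        cds_start=425,
        cds_end=575,
        biotype="coding",
    )

    # decoy: substituted 61-mer flank of the decoy site, verbatim
    flank = host_a[p_decoy - 31 : p_decoy + 30]
    sub_flank = flank[:30] + "G" + flank[31:]
    decoy_seq = _rand_seq(rng, 150) + sub_flank + _rand_seq(rng, 150)

    # duplicated locus: copy of the dup site's 61-mer with the edited base,
    # dropped into hostB
    dup_window = host_a[p_dup - 31 : p_dup + 30]
    dup_sub = dup_window[:30] + "G" + dup_window[31:]
    host_b = host_b[:200] + dup_sub + host_b[261:]

    genome = {"hostA": host_a, "hostB": host_b}
    decoy = {"mm_decoy": decoy_seq}
    dbsnp_mask = {("hostA", p_snp)}

    calls = pd.DataFrame(
        {
            "specimen": ["S1"] * 5,
            "chrom": ["hostA"] * 5,
            "pos": [p_true, p_snp, p_splice, p_decoy, p_dup],
            "ref": ["A"] * 5,
            "alt": ["G"] * 5,
            "x_dna_ref": [6] * 5,
            "y_rna_alt": [5] * 5,
            "rna_depth": [20] * 5,
            "status": ["high_coverage"] * 5,
        }
    )

    # cohort DNA records: reference-only reads at every candidate site
    counts = pd.DataFrame(
        [
            {
                "specimen": sp,
                "chrom": "hostA",
                "pos": p,
                "assay": "DNA",
                "nA": 8,
                "nC": 0,
                "nG": 0,
                "nT": 0,
            }
            for sp in ("S1", "S2")
            for p in (p_true, p_snp, p_splice, p_decoy, p_dup)
        ]
    )

    return {
        "genome": genome,
        "decoy": decoy,
        "dbsnp_mask": dbsnp_mask,
        "gene_models": [gene],
        "calls": calls,
        "counts": counts,
        "true_pos": p_true,
        "positions": {
            "snp": p_snp,
            "splice": p_splice,
            "decoy": p_decoy,
            "dup": p_dup,
        },
    }
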