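"""Local alignment used by the flank-realignment filters.

A thin, deterministic wrapper around Smith-Waterman local alignment
(match +1, mismatch -2, linear gap -3 by default), searching both strands.
Scores and coordinates are exposed through :class:`Hit`; score-only queries
avoid traceback for speed.  Test genomes are kilobase-scale, so full dynamic
programming per target is affordable; no k-mer indexing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .io_model import reverse_complement


@dataclass
class Hit:
    """One local-alignment hit on a named target sequence.

    Coordinates are 0-based half-open on the forward strand of the target.
    ``identity`` is matches divided by aligned query length.
    """

    target: str
    score: float
    identity: float
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str  # '+' : query as given; '-' : reverse complement aligned


class LocalAligner:
    """Deterministic local aligner over {A,C,G,T,N} sequences."""

    def __init__(self, match: float = 1.0, mismatch: float = -2.0,
                 gap: float = -3.0) -> None:
        self.match = match
        self.mismatch = mismatch
        self.gap = gap
        self._aligner = Align.PairwiseAligner(
            mode="local",
            match_score=match,
            mismatch_score=mismatch,
            open_gap_score=gap,
            extend_gap_score=gap,
        )
        # N never rewarded: treat as mismatch against everything
        self._aligner.wildcard = None

    def score(self, query: str, target: str, both_strands: bool = True) -> float:
        """Best local score of query against target (optionally both strands)."""
        if not query:
            raise ValueError("empty query")
        if not target:
            return 0.0
        s = self._aligner.score(target, query)
        if both_strands:
            s = max(s, self._aligner.score(target, reverse_complement(query)))
        return float(s)

    def best_hit(self, query: str, targets: dict[str, str],
                 both_strands: bool = True, min_score: float = 0.0) -> Hit | None:
        """Best hit across targets; ties broken by (target name, start)."""
        hits = self.align(query, targets, both_strands=both_strands,
                          min_score=min_score)
        return hits[0] if hits else None

    def align(self, query: str, targets: dict[str, str],
              both_strands: bool = True, min_score: float = 16.0) -> list[Hit]:
        """Best local alignment per target (and strand), sorted best-first.

        Sorting is by descending score, then target name, then leftmost
        target start -- fully deterministic for fixed inputs.
        """
        if not query:
            raise ValueError("empty query")
        out: list[Hit] = []
        strands = ("+", "-") if both_strands else ("+",)
        for name, target in targets.items():
            if not target:
                continue
            for strand in strands:
                q = query if strand == "+" else reverse_complement(query)
                alignments = self._aligner.align(target, q)
                if alignments.score <= 0 or alignments.score < min_score:
                    continue
                best = alignments[0]
                counts = best.counts()
                (tstart, tend) = (int(best.aligned[0][0][0]),
                                  int(best.aligned[0][-1][1]))
                (qstart, qend) = (int(best.aligned[1][0][0]),
                                  int(best.aligned[1][-1][1]))
                if strand == "-":
                    qstart, qend = len(query) - qend, len(query) - qstart
                aligned_q = max(qend - qstart, 1)
                out.append(
                    Hit(
                        target=name,
                        score=float(alignments.score),
                        identity=counts.identities / aligned_q,
                        target_start=tstart,
                        target_end=tend,
                        query_start=qstart,
                        query_end=qend,
                        strand=strand,
                    )
                )
        out.sort(key=lambda h: (-h.score, h.target, h.target_start))
        return out


@lru_cache(maxsize=4)
def default_aligner() -> LocalAligner:
    return LocalAligner()
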