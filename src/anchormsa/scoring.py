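"""Sum-of-pairs identity score for multiple alignments.

For each pair of rows i, j the identity is S_ij = 100 * M_ij / L, where
M_ij counts alignment columns in which the two rows carry the same
non-gap character and L is the alignment width including gap columns.
The alignment score is the unweighted arithmetic mean of S_ij over all
N*(N-1)/2 pairs.  Columns where either row is gapped — including columns
gapped in both — contribute to L but never to M_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TextIO

import numpy as np

from .seqio import GAP, Alignment

__all__ = ["PairScore", "ScoreReport", "sp_identity_score"]


@dataclass(frozen=True)
class PairScore:
    i: int
    j: int
    matches: int  # M_ij
    identity: float  # S_ij, percent


@dataclass(frozen=True)
class ScoreReport:
    pairs: tuple[PairScore, ...]
    mean_score: float
    width: int  # L

    def to_tsv(self, out: TextIO, ids: tuple[str, ...] | None = None) -> None:
        out.write("pair\tM_ij\tS_ij\n")
        for p in self.pairs:
            a = ids[p.i] if ids else str(p.i)
            b = ids[p.j] if ids else str(p.j)
            out.write(f"{a},{b}\t{p.matches}\t{p.identity:.4f}\n")
        out.write(f"mean\t\t{self.mean_score:.4f}\n")


def sp_identity_score(aln: Alignment) -> ScoreReport:
    """Mean pairwise identity of an alignment (percent, gap-inclusive L).

    Residue comparison is case-insensitive; identical non-ACGT characters
    (e.g. an N aligned to an N) count as matches.  A width-0 alignment is
    defined as score 0, with a warning.
    """
    if aln.N < 2:
        raise ValueError("sum-of-pairs score needs at least two rows")
    L = aln.width
    if L == 0:
        warnings.warn("scoring a width-0 alignment; score defined as 0")
        pairs = tuple(
            PairScore(i, j, 0, 0.0)
            for i in range(aln.N)
            for j in range(i + 1, aln.N)
        )
        return ScoreReport(pairs, 0.0, 0)

    mat = np.frombuffer(
        "".join(r.upper() for r in aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.N, L)
    gap = ord(GAP)
    pairs: list[PairScore] = []
    total = 0.0
    for i in range(aln.N):
        for j in range(i + 1, aln.N):
            both = (mat[i] != gap) & (mat[j] != gap)
            m = int(np.count_nonzero(both & (mat[i] == mat[j])))
            s = 100.0 * m / L
            pairs.append(PairScore(i, j, m, s))
            total += s
    mean = total / len(pairs)
    return ScoreReport(tuple(pairs), mean, L)
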