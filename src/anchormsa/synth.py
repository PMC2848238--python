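"""Synthetic sequence data with known ground truth.

Two generators: uniform i.i.d. random sequences (the unalignable-data
control) and homologous families evolved from one random ancestor by a
star phylogeny — each descendant independently accumulates per-site
substitutions and geometric-length indels, and the exact edit list plus
the monotone ancestor-to-descendant coordinate map are recorded.

The star phylogeny (no tree structure) is deliberate: it is sufficient
for anchor-recovery and score properties, and the per-site rates are then
directly the expected ancestor-to-descendant divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import numpy as np

from .seqio import SequenceRecord, SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "Edit",
    "FamilyTruth",
    "random_sequences",
    "evolve_family",
    "random_kmer",
    "plant_kmer",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class Edit:
    """One mutation event, in ancestor coordinates.

    kind: "sub" (payload = new base), "ins" (payload = inserted residues,
    placed immediately before ancestor position *pos*), or "del"
    (length = number of ancestor residues removed starting at *pos*).
    """

    kind: str
    pos: int
    payload: str = ""
    length: int = 0


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for one descendant of the common ancestor."""

    ancestor: str
    edits: tuple[Edit, ...]
    #: anc2desc[p] = descendant coordinate of ancestor position p, -1 if deleted
    anc2desc: tuple[int, ...]

    def check(self, descendant: str) -> None:
        """Verify the truth map is monotone and consistent with *descendant*."""
        last = -1
        for p, q in enumerate(self.anc2desc):
            if q < 0:
                continue
            if q <= last:
                raise AssertionError("truth map is not strictly monotone")
            last = q
            if descendant[q] != self._derived_base(p):
                raise AssertionError(
                    f"truth map mismatch at ancestor position {p}"
                )

    def _derived_base(self, p: int) -> str:
        base = self.ancestor[p]
        for e in self.edits:
            if e.kind == "sub" and e.pos == p:
                base = e.payload
        return base


def random_sequences(n: int, length: int, rng_seed: int) -> SequenceSet:
    """n i.i.d. uniform A/C/G/T sequences of the given length."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(rng_seed)
    records = []
    for i in range(n):
        codes = rng.integers(0, 4, size=length)
        residues = _BASES[codes].tobytes().decode("ascii")
        records.append(SequenceRecord(f"rand{i + 1}", residues))
    return SequenceSet(tuple(records))


def _mutate(
    ancestor: np.ndarray,
    rng: np.random.Generator,
    sub_rate: float,
    indel_rate: float,
    mean_indel_len: float,
) -> tuple[str, tuple[Edit, ...], tuple[int, ...]]:
    n = len(ancestor)
    out: list[int] = []
    edits: list[Edit] = []
    anc2desc = np.full(n, -1, dtype=np.int64)
    geom_p = 1.0 / max(mean_indel_len, 1.0)
    p = 0
    while p < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            glen = int(rng.geometric(geom_p))
            if rng.random() < 0.5:  # insertion before position p
                ins_codes = rng.integers(0, 4, size=glen)
                ins = _BASES[ins_codes].tobytes().decode("ascii")
                edits.append(Edit("ins", p, payload=ins))
                out.extend(int(c) for c in ins_codes)
            else:  # deletion of glen ancestor residues
                glen = min(glen, n - p)
                edits.append(Edit("del", p, length=glen))
                p += glen
                continue
        base = int(ancestor[p])
        if sub_rate > 0 and rng.random() < sub_rate:
            new = (base + int(rng.integers(1, 4))) % 4
            edits.append(
                Edit("sub", p, payload=_BASES[new : new + 1].tobytes().decode())
            )
            base = new
        anc2desc[p] = len(out)
        out.append(base)
        p += 1
    residues = _BASES[np.array(out, dtype=np.int64)].tobytes().decode("ascii") if out else ""
    return residues, tuple(edits), tuple(int(q) for q in anc2desc)


def evolve_family(
    ancestor_length: int,
    n: int,
    sub_rate: float,
    indel_rate: float,
    mean_indel_len: float = 3.0,
    rng_seed: int = 0,
) -> tuple[SequenceSet, list[FamilyTruth]]:
    """Evolve *n* descendants independently from one random ancestor.

    Substitutions flip a site to a uniformly chosen different base with
    per-site probability *sub_rate*; with probability *indel_rate* a site
    hosts an indel event (insertion or deletion, 50/50) whose length is
    geometric with the given mean.  Returns the descendants and one
    :class:`FamilyTruth` per descendant.
    """
    if n < 2:
        raise ValueError("a family needs at least two descendants")
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    ancestor = rng.integers(0, 4, size=ancestor_length)
    anc_str = _BASES[ancestor].tobytes().decode("ascii")
    records = []
    truths = []
    for i in range(n):
        residues, edits, anc2desc = _mutate(
            ancestor, rng, sub_rate, indel_rate, mean_indel_len
        )
        if not residues:  # pathological high-rate draw; keep set well-formed
            residues = anc_str[:1]
            edits = ()
            anc2desc = (0,) + (-1,) * (ancestor_length - 1)
        records.append(SequenceRecord(f"desc{i + 1}", residues))
        truths.append(FamilyTruth(anc_str, edits, anc2desc))
    return SequenceSet(tuple(records)), truths


def random_kmer(k: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=k)].tobytes().decode("ascii")


def plant_kmer(seqs: SequenceSet, kmer: str, position: int) -> SequenceSet:
    """Overwrite the window at *position* with *kmer* in every sequence.

    Intended for substitution-only families, where a shared coordinate is
    homologous across the whole set; the planted tuple then has an exact
    occurrence at the same known coordinate in every sequence.
    """
    k = len(kmer)
    records = []
    for rec in seqs:
        if position + k > rec.length:
            raise ValueError(
                f"cannot plant {k}-mer at {position} in sequence of length "
                f"{rec.length}"
            )
        s = rec.residues[:position] + kmer + rec.residues[position + k :]
        records.append(SequenceRecord(rec.id, s))
    return SequenceSet(tuple(records))


def write_truth_tsv(truths: list[FamilyTruth], out: TextIO) -> None:
    """Edit lists as TSV: descendant index, kind, ancestor pos, detail."""
    out.write("descendant\tkind\tanc_pos\tlength\tpayload\n")
    for i, t in enumerate(truths):
        for e in t.edits:
            out.write(f"{i}\t{e.kind}\t{e.pos}\t{e.length}\t{e.payload}\n")
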