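"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (quadratic scans, memoized
recursion over all alignment paths, column-by-column counting) and share
no code with the package implementation they are used to check.
"""

from __future__ import annotations

import functools
from collections import defaultdict

import pytest

from anchormsa import SequenceSet

ACGT = "ACGT"


@pytest.fixture
def make_set():
    def _make(*residues: str, ids=None) -> SequenceSet:
        ids = ids or [f"s{i + 1}" for i in range(len(residues))]
        return SequenceSet.from_pairs(zip(ids, residues))

    return _make


# ---------------------------------------------------------------- oracles


def naive_kmer_counts(strings, M):
    """Quadratic window scan: exact counts and per-sequence presence."""
    exact = defaultdict(int)
    seqs_with = defaultdict(set)
    for si, s in enumerate(strings):
        for k in range(1, M + 1):
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if all(c in ACGT for c in w):
                    exact[w] += 1
                    seqs_with[w].add(si)
    return exact, seqs_with


def naive_inexact_count(strings, ktuple):
    """Direct scan for windows within Hamming distance 1 of *ktuple*."""
    k = len(ktuple)
    total = 0
    for s in strings:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if all(c in ACGT for c in w):
                if sum(a != b for a, b in zip(w, ktuple)) <= 1:
                    total += 1
    return total


def naive_hamming1_positions(string, ktuple):
    """All window starts in *string* within Hamming distance 1 of *ktuple*."""
    k = len(ktuple)
    out = []
    for i in range(len(string) - k + 1):
        w = string[i : i + k]
        if all(c in ACGT for c in w) and sum(a != b for a, b in zip(w, ktuple)) <= 1:
            out.append(i)
    return out


def optimal_affine_score(a, b, match=1.0, mismatch=-1.0, gap_open=-4.0,
                         gap_extend=-1.0):
    """Optimum global affine-gap alignment score by memoized recursion.

    All state transitions are allowed (including gap-to-gap switches), so
    this is the true optimum over every monotone alignment path; a gap of
    length l costs gap_open + (l - 1) * gap_extend.
    """
    na, nb = len(a), len(b)

    @functools.lru_cache(maxsize=None)
    def best(i, j, prev):
        if i == na and j == nb:
            return 0.0
        cands = []
        if i < na and j < nb:
            s = match if a[i] == b[j] else mismatch
            cands.append(s + best(i + 1, j + 1, "M"))
        if i < na:  # gap in b
            g = gap_extend if prev == "I" else gap_open
            cands.append(g + best(i + 1, j, "I"))
        if j < nb:  # gap in a
            g = gap_extend if prev == "D" else gap_open
            cands.append(g + best(i, j + 1, "D"))
        return max(cands)

    return best(0, 0, "start")


def naive_sp_score(rows):
    """Column-by-column sum-of-pairs identity, straight off the formula."""
    n = len(rows)
    L = len(rows[0])
    if L == 0:
        return 0.0
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            m = 0
            for c1, c2 in zip(rows[i].upper(), rows[j].upper()):
                if c1 != "-" and c2 != "-" and c1 == c2:
                    m += 1
            total += 100.0 * m / L
            npairs += 1
    return total / npairs


def minimal_removal_sizes(seeds_list, distance):
    """Smallest number of removals achieving zero pairwise incompatibility.

    Exhaustive over subsets; only for tiny inputs.
    """
    import itertools

    n = len(seeds_list)
    for drop in range(n):
        for removed in itertools.combinations(range(n), drop):
            kept = [s for i, s in enumerate(seeds_list) if i not in removed]
            if all(
                distance(a, b) == 0
                for x, a in enumerate(kept)
                for b in kept[x + 1 :]
            ):
                return drop
    return n - 1
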