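"""Seed location, ranking, and order-compatibility resolution.

A *seed* is a k-tuple that occurs exactly once — allowing one substitution
— in every input sequence; its per-sequence positions are putative
homologous coordinates.  Two seeds are compatible when every sequence
shows them in the same relative order without overlap; the
*incompatibility distance* between two seeds counts the sequences whose
order deviates from the majority.  Iteratively discarding the seed that
contributes the most incompatibility leaves a mutually compatible,
collinear anchor set that can partition the sequences into independently
alignable segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as TSequence

import numpy as np

from .kdict import encode_ktuple, encode_sequence
from .seqio import SequenceSet

DEFAULT_T = 600

__all__ = [
    "DEFAULT_T",
    "Seed",
    "IncompatibilityMatrix",
    "AnchorSet",
    "locate_seeds",
    "rank_seeds",
    "incompatibility_distance",
    "build_incompatibility_matrix",
    "resolve_conflicts",
    "write_anchor_tsv",
]


@dataclass(frozen=True)
class Seed:
    """A verified seed: one (inexact) match position in every sequence.

    ``n_exact`` is the number of sequences whose matching window equals the
    k-tuple exactly (the remainder differ by a single substitution).
    """

    ktuple: str
    positions: tuple[int, ...]
    n_exact: int

    @property
    def k(self) -> int:
        return len(self.ktuple)

    @property
    def rank_key(self) -> tuple:
        """Total order for "best seed" selection: smaller is better.

        Longer tuples first, then exact matches in more sequences, then
        smaller position in sequence 0; the tuple string breaks any
        remaining tie so the order is total and input-order independent.
        """
        return (-self.k, -self.n_exact, self.positions[0], self.ktuple)

    def interval(self, i: int) -> tuple[int, int]:
        """Half-open residue interval occupied in sequence *i*."""
        return (self.positions[i], self.positions[i] + self.k)


def _encode_many(ktuples: list[str], k: int) -> np.ndarray:
    """Vectorized 2-bit packing of equal-length tuples."""
    flat = encode_sequence("".join(ktuples)).reshape(len(ktuples), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return flat @ powers


def _neighbourhood_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """Per row: the tuple's own code then its 3k one-sub neighbour codes."""
    out = np.empty((len(codes), 3 * k + 1), dtype=np.int64)
    out[:, 0] = codes
    j = 1
    for p in range(k):
        shift = 4 ** (k - 1 - p)
        digit = (codes // shift) % 4
        for delta in (1, 2, 3):
            nd = (digit + delta) % 4
            out[:, j] = codes + (nd - digit) * shift
            j += 1
    return out


def locate_seeds(
    seqs: SequenceSet, candidates: TSequence[str]
) -> tuple[list[Seed], int]:
    """Second pass: verify candidates occur exactly once per sequence.

    For each candidate k-tuple every sequence is scanned for windows within
    Hamming distance 1; the candidate survives iff every sequence contains
    exactly one such window, whose start becomes the seed position.
    Returns the surviving seeds and the number of candidates dropped.

    The scan is organised as one pass over the residues: window codes are
    computed per sequence and all candidates of a given length are checked
    against them together.
    """
    if not candidates:
        return [], 0

    by_k: dict[int, list[str]] = {}
    for c in candidates:
        by_k.setdefault(len(c), []).append(c)

    # per k: sorted flat neighbourhood codes plus per-candidate state
    sorted_q: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    alive: dict[int, np.ndarray] = {}
    positions: dict[int, np.ndarray] = {}
    exact: dict[int, np.ndarray] = {}
    for k, cands in by_k.items():
        codes = _encode_many(cands, k)
        q = _neighbourhood_matrix(codes, k)  # (n_cand, 3k+1), self first
        flat = q.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_q[k] = (flat[order], order)
        alive[k] = np.ones(len(cands), dtype=bool)
        positions[k] = np.full((len(cands), seqs.N), -1, dtype=np.int64)
        exact[k] = np.zeros((len(cands), seqs.N), dtype=bool)

    maxk = max(by_k)
    for si, rec in enumerate(seqs):
        enc = encode_sequence(rec.residues)
        n = len(enc)
        prev = enc
        prev_valid = enc >= 0
        per_k_codes: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if 1 in by_k:
            per_k_codes[1] = (prev, prev_valid)
        for k in range(2, maxk + 1):
            if n < k:
                prev = np.empty(0, np.int64)
                prev_valid = np.empty(0, bool)
            else:
                prev = prev[: n - k + 1] * 4 + enc[k - 1 :]
                prev_valid = prev_valid[: n - k + 1] & (enc[k - 1 :] >= 0)
            if k in by_k:
                per_k_codes[k] = (prev, prev_valid)
        for k, cands in by_k.items():
            n_cand = len(cands)
            width = 3 * k + 1
            codes, valid = per_k_codes.get(k, (np.empty(0, np.int64), None))
            wpos = np.nonzero(valid)[0] if valid is not None else np.empty(0, np.int64)
            wcodes = codes[wpos] if len(wpos) else np.empty(0, np.int64)
            sq, qorder = sorted_q[k]
            left = np.searchsorted(sq, wcodes, side="left")
            right = np.searchsorted(sq, wcodes, side="right")
            cnt = right - left
            nz = np.nonzero(cnt)[0]
            reps = cnt[nz]
            total = int(reps.sum())
            if total:
                # expand each window's [left, right) range of query entries
                offs = np.concatenate(([0], np.cumsum(reps)[:-1]))
                entry = np.repeat(left[nz], reps) + (
                    np.arange(total) - np.repeat(offs, reps)
                )
                flat_idx = qorder[entry]
                cand_id = flat_idx // width
                slot = flat_idx % width
                win = np.repeat(nz, reps)
                totals = np.bincount(cand_id, minlength=n_cand)
                possum = np.bincount(
                    cand_id, weights=wpos[win].astype(np.float64),
                    minlength=n_cand,
                )
                exact_here = (
                    np.bincount(cand_id[slot == 0], minlength=n_cand) > 0
                )
            else:
                totals = np.zeros(n_cand, dtype=np.int64)
                possum = np.zeros(n_cand)
                exact_here = np.zeros(n_cand, dtype=bool)
            once = totals == 1
            alive[k] &= once
            positions[k][once, si] = possum[once].astype(np.int64)
            exact[k][once, si] = exact_here[once]

    out: list[Seed] = []
    dropped = 0
    for k in sorted(by_k, reverse=True):
        cands = by_k[k]
        for ci in range(len(cands)):
            if alive[k][ci] and (positions[k][ci] >= 0).all():
                out.append(
                    Seed(
                        cands[ci],
                        tuple(int(p) for p in positions[k][ci]),
                        int(exact[k][ci].sum()),
                    )
                )
            else:
                dropped += 1
    return out, dropped


def rank_seeds(seeds: TSequence[Seed], T: int = DEFAULT_T) -> list[Seed]:
    """Select the T best seeds under the deterministic rank order."""
    return sorted(seeds, key=lambda s: s.rank_key)[:T]


def incompatibility_distance(a: Seed, b: Seed) -> int:
    """Number of sequences whose a/b order deviates from the majority.

    A sequence supports a->b only when a's window ends at or before b's
    start; overlapping windows support neither order and therefore count
    against both.  The distance is N minus the majority support (ties in
    the majority are resolved toward the order seen in sequence 0, which
    leaves the distance value unchanged).
    """
    n = len(a.positions)
    n_ab = 0
    n_ba = 0
    for i in range(n):
        if a.positions[i] + a.k <= b.positions[i]:
            n_ab += 1
        elif b.positions[i] + b.k <= a.positions[i]:
            n_ba += 1
    return n - max(n_ab, n_ba)


@dataclass(frozen=True)
class IncompatibilityMatrix:
    """Symmetric pairwise incompatibility distances over ranked seeds."""

    seeds: tuple[Seed, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.seeds)
        if self.D.shape != (m, m):
            raise ValueError("distance matrix shape does not match seed count")


def build_incompatibility_matrix(seeds: TSequence[Seed]) -> IncompatibilityMatrix:
    seeds = tuple(seeds)
    m = len(seeds)
    if m == 0:
        return IncompatibilityMatrix(seeds, np.zeros((0, 0), dtype=np.int64))
    N = len(seeds[0].positions)
    starts = np.array([s.positions for s in seeds], dtype=np.int64)  # (m, N)
    ends = starts + np.array([[s.k] for s in seeds], dtype=np.int64)
    # ab[x, y, i]: in sequence i, seed x strictly before seed y
    ab = (ends[:, None, :] <= starts[None, :, :]).sum(axis=2)
    D = N - np.maximum(ab, ab.T)
    np.fill_diagonal(D, 0)
    return IncompatibilityMatrix(seeds, D.astype(np.int64))


@dataclass(frozen=True)
class AnchorSet:
    """Mutually compatible, non-overlapping seeds, by position in seq 0."""

    anchors: tuple[Seed, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchors", tuple(self.anchors))

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)

    def validate(self) -> None:
        """Assert strict collinearity: same order, no overlap, everywhere."""
        if not self.anchors:
            return
        N = len(self.anchors[0].positions)
        for i in range(N):
            prev_end = -1
            for a in self.anchors:
                s, e = a.interval(i)
                if s < prev_end:
                    raise AssertionError(
                        f"anchors overlap or are out of order in sequence {i}"
                    )
                prev_end = e


def _removal_loop(
    seeds: list[Seed], D: np.ndarray
) -> tuple[list[Seed], np.ndarray]:
    """Drop max-row-sum seeds until the matrix is all zero.

    Ties on the row sum are broken by removing the worst-ranked seed.
    Removing a seed cannot change the distances between the remaining
    seeds (the distance is pairwise), so recalculation is row/column
    deletion.
    """
    seeds = list(seeds)
    D = D.copy()
    while len(seeds) > 1:
        sums = D.sum(axis=1)
        worst = sums.max()
        if worst == 0:
            break
        tied = np.nonzero(sums == worst)[0]
        drop = max(tied, key=lambda i: seeds[i].rank_key)
        del seeds[drop]
        D = np.delete(np.delete(D, drop, axis=0), drop, axis=1)
    return seeds, D


def resolve_conflicts(mat: IncompatibilityMatrix) -> AnchorSet:
    """Iteratively remove the most incompatible seed until none remain.

    A second pass enforces pairwise non-overlap in every sequence with the
    same removal loop (the order-distance pass already precludes overlap,
    so this is a safety net); if every pair conflicted, exactly one anchor
    survives.  The result is sorted by position in sequence 0.
    """
    if not mat.seeds:
        return AnchorSet(())
    kept, _ = _removal_loop(list(mat.seeds), mat.D)

    # overlap post-pass: count sequences where windows intersect
    m = len(kept)
    if m > 1:
        starts = np.array([s.positions for s in kept], dtype=np.int64)
        ends = starts + np.array([[s.k] for s in kept], dtype=np.int64)
        disjoint = (ends[:, None, :] <= starts[None, :, :]) | (
            ends[None, :, :] <= starts[:, None, :]
        )
        O = (~disjoint).sum(axis=2).astype(np.int64)
        np.fill_diagonal(O, 0)
        kept, _ = _removal_loop(kept, O)

    anchors = AnchorSet(tuple(sorted(kept, key=lambda s: s.positions[0])))
    anchors.validate()
    return anchors


def write_anchor_tsv(anchors: AnchorSet, path) -> None:
    """Anchor report: ktuple, k, then the N 0-based start positions."""
    with open(path, "w") as fh:
        for a in anchors:
            pos = "\t".join(str(p) for p in a.positions)
            fh.write(f"{a.ktuple}\t{a.k}\t{pos}\n")
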