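"""The k-tuple dictionary: occurrence statistics for all k-mers up to M.

A single pass over the dataset records, for every k in 1..M and every
length-k window made solely of A/C/G/T, the total occurrence count
(``exact_count``), the number of distinct sequences containing the tuple
(``seq_count``) and the index of the last sequence where it was seen
(``last_seq_index`` — the bookkeeping that makes ``seq_count`` computable
in one pass).  A second step adds ``inexact_count``: the exact count plus
the exact counts of all 3k tuples one substitution away.

Expected occurrences of a given k-tuple in L = A*N random bases are L/4^k,
so tuples shared exactly once per sequence (the homology signal this
package looks for) become plausible once 4^k is comparable to the average
sequence length; using all k up to a memory-bounded M (default 12) avoids
having to guess the right k in advance.

Storage is sparse: only tuples that actually occur are materialized, as
per-k sorted arrays of 2-bit-packed integer codes with parallel count
arrays.  String-keyed access is provided on top of that representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .seqio import SequenceSet

DEFAULT_M = 12
HARD_M_CAP = 14  # 4^M addressing beyond this is refused

_BASES = "ACGT"
_BASE_CODE = {c: i for i, c in enumerate(_BASES)}

__all__ = [
    "DEFAULT_M",
    "HARD_M_CAP",
    "KTupleStats",
    "KDictionary",
    "build_dictionary",
    "augment_inexact",
    "candidate_seeds",
    "encode_sequence",
    "encode_ktuple",
    "decode_ktuple",
    "one_substitution_neighbours",
]


def encode_sequence(residues: str) -> np.ndarray:
    """Map residues to codes 0..3; any non-ACGT character becomes -1."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        out[raw == ord(base)] = code
    return out


def encode_ktuple(ktuple: str) -> int:
    code = 0
    for c in ktuple:
        code = code * 4 + _BASE_CODE[c]
    return code


def decode_ktuple(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def one_substitution_neighbours(ktuple: str) -> list[str]:
    """The 3k tuples at Hamming distance exactly 1 from *ktuple*."""
    out = []
    for i, c in enumerate(ktuple):
        for b in _BASES:
            if b != c:
                out.append(ktuple[:i] + b + ktuple[i + 1 :])
    return out


@dataclass(frozen=True)
class KTupleStats:
    """Occurrence statistics of one k-tuple across the whole dataset."""

    ktuple: str
    exact_count: int
    seq_count: int
    last_seq_index: int
    inexact_count: int | None = None  # None until augment_inexact has run


class _KLevel:
    """Sorted-code columnar storage for all materialized tuples of one k."""

    __slots__ = ("k", "codes", "exact", "seq_count", "last_seq", "inexact")

    def __init__(
        self,
        k: int,
        codes: np.ndarray,
        exact: np.ndarray,
        seq_count: np.ndarray,
        last_seq: np.ndarray,
    ) -> None:
        self.k = k
        self.codes = codes  # sorted, unique
        self.exact = exact
        self.seq_count = seq_count
        self.last_seq = last_seq
        self.inexact: np.ndarray | None = None

    def lookup(self, code: int) -> int | None:
        i = int(np.searchsorted(self.codes, code))
        if i < len(self.codes) and self.codes[i] == code:
            return i
        return None


class KDictionary:
    """Sparse dictionary of k-tuple statistics for all k in 1..M."""

    def __init__(self, M: int, N: int, levels: dict[int, _KLevel]) -> None:
        self.M = M
        self.N = N
        self._levels = levels
        #: number of passes over the raw residues (single-pass contract)
        self.residue_passes = 0

    def get(self, ktuple: str) -> KTupleStats | None:
        k = len(ktuple)
        level = self._levels.get(k)
        if level is None or any(c not in _BASE_CODE for c in ktuple):
            return None
        i = level.lookup(encode_ktuple(ktuple))
        if i is None:
            return None
        inexact = None if level.inexact is None else int(level.inexact[i])
        return KTupleStats(
            ktuple,
            int(level.exact[i]),
            int(level.seq_count[i]),
            int(level.last_seq[i]),
            inexact,
        )

    def __contains__(self, ktuple: str) -> bool:
        return self.get(ktuple) is not None

    @property
    def has_inexact(self) -> bool:
        return all(lv.inexact is not None for lv in self._levels.values())

    def exact_count(self, ktuple: str) -> int:
        st = self.get(ktuple)
        return 0 if st is None else st.exact_count

    def inexact_count(self, ktuple: str) -> int:
        st = self.get(ktuple)
        if st is None:
            return 0
        if st.inexact_count is None:
            raise RuntimeError("augment_inexact has not been run")
        return st.inexact_count

    def n_entries(self, k: int | None = None) -> int:
        if k is not None:
            lv = self._levels.get(k)
            return 0 if lv is None else len(lv.codes)
        return sum(len(lv.codes) for lv in self._levels.values())

    def items(self, k: int | None = None) -> Iterator[KTupleStats]:
        """Iterate materialized tuples (optionally of one length).

        Intended for small dictionaries (tests, TSV dumps); large inputs
        should stay on the columnar arrays.
        """
        ks = [k] if k is not None else sorted(self._levels)
        for kk in ks:
            lv = self._levels.get(kk)
            if lv is None:
                continue
            for i, code in enumerate(lv.codes):
                inexact = None if lv.inexact is None else int(lv.inexact[i])
                yield KTupleStats(
                    decode_ktuple(int(code), kk),
                    int(lv.exact[i]),
                    int(lv.seq_count[i]),
                    int(lv.last_seq[i]),
                    inexact,
                )

    def to_tsv(self, path) -> None:
        """Dump (ktuple, k, exact_count, seq_count, inexact_count) rows."""
        with open(path, "w") as fh:
            fh.write("ktuple\tk\texact_count\tseq_count\tinexact_count\n")
            for st in self.items():
                ic = "" if st.inexact_count is None else st.inexact_count
                fh.write(
                    f"{st.ktuple}\t{len(st.ktuple)}\t{st.exact_count}\t"
                    f"{st.seq_count}\t{ic}\n"
                )

    # internal: used by the seed locator, which shares the encoding
    def level(self, k: int) -> _KLevel | None:
        return self._levels.get(k)


def _window_codes(codes: np.ndarray, M: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rolling k-mer codes for k = 1..M from a 2-bit encoded sequence.

    Returns, per k, the integer code of every window start and a validity
    mask that is False wherever the window overlaps a non-ACGT character.
    """
    n = len(codes)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    prev = codes.copy()
    prev_valid = codes >= 0
    out.append((prev, prev_valid))
    for k in range(2, M + 1):
        if n < k:
            out.append((np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)))
            prev = out[-1][0]
            prev_valid = out[-1][1]
            continue
        cur = prev[: n - k + 1] * 4 + codes[k - 1 :]
        cur_valid = prev_valid[: n - k + 1] & (codes[k - 1 :] >= 0)
        out.append((cur, cur_valid))
        prev, prev_valid = cur, cur_valid
    return out


def build_dictionary(seqs: SequenceSet, M: int = DEFAULT_M) -> KDictionary:
    """Count every ACGT-only window of length 1..M in one pass.

    Windows overlapping any non-ACGT character are skipped entirely.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > HARD_M_CAP:
        raise ValueError(
            f"M={M} exceeds the supported maximum of {HARD_M_CAP}: "
            f"4^{M} k-tuple codes are infeasible to address"
        )
    for rec in seqs:
        if rec.length == 0:
            raise ValueError(f"sequence {rec.id!r} is empty")

    N = seqs.N
    passes = 0
    # per k: window codes per sequence, plus per-sequence unique codes
    all_codes: list[list[np.ndarray]] = [[] for _ in range(M + 1)]
    uniq_codes: list[list[np.ndarray]] = [[] for _ in range(M + 1)]
    uniq_seq: list[list[np.ndarray]] = [[] for _ in range(M + 1)]
    for si, rec in enumerate(seqs):
        enc = encode_sequence(rec.residues)  # the single read of the residues
        passes += 1
        for k, (codes, valid) in enumerate(_window_codes(enc, M), start=1):
            v = codes[valid]
            all_codes[k].append(v)
            u = np.unique(v)
            uniq_codes[k].append(u)
            uniq_seq[k].append(np.full(len(u), si, dtype=np.int64))

    levels: dict[int, _KLevel] = {}
    for k in range(1, M + 1):
        flat = np.concatenate(all_codes[k]) if all_codes[k] else np.empty(0, np.int64)
        codes_k, exact_k = np.unique(flat, return_counts=True)
        if len(codes_k) == 0:
            levels[k] = _KLevel(
                k,
                codes_k,
                exact_k,
                np.empty(0, np.int64),
                np.empty(0, np.int64),
            )
            continue
        ucodes = np.concatenate(uniq_codes[k])
        useq = np.concatenate(uniq_seq[k])
        order = np.argsort(ucodes, kind="stable")  # stable: seq index ascending
        ucodes = ucodes[order]
        useq = useq[order]
        grp_codes, grp_start, grp_size = np.unique(
            ucodes, return_index=True, return_counts=True
        )
        assert np.array_equal(grp_codes, codes_k)
        seq_count_k = grp_size
        last_seq_k = useq[grp_start + grp_size - 1]
        levels[k] = _KLevel(k, codes_k, exact_k, seq_count_k, last_seq_k)

    d = KDictionary(M, N, levels)
    d.residue_passes = passes
    return d


def augment_inexact(d: KDictionary) -> KDictionary:
    """Add one-substitution inexact counts to every materialized tuple.

    inexact_count(t) = exact_count(t) + sum of exact_count over the 3k
    tuples one substitution away; absent neighbours contribute zero.
    Insertions, deletions and double substitutions are never considered.
    """
    for k in range(1, d.M + 1):
        lv = d.level(k)
        if lv is None or len(lv.codes) == 0:
            if lv is not None:
                lv.inexact = lv.exact.copy()
            continue
        codes = lv.codes
        inexact = lv.exact.astype(np.int64).copy()
        for p in range(k):
            shift = 4 ** (k - 1 - p)
            digit = (codes // shift) % 4
            for delta in (1, 2, 3):
                nd = (digit + delta) % 4
                ncodes = codes + (nd - digit) * shift
                idx = np.searchsorted(codes, ncodes)
                idx_c = np.minimum(idx, len(codes) - 1)
                hit = codes[idx_c] == ncodes
                inexact[hit] += lv.exact[idx_c[hit]]
        lv.inexact = inexact
    return d


def candidate_seeds(d: KDictionary) -> list[str]:
    """Tuples whose inexact count equals N, ordered longest-k first.

    This is the aggregate prefilter for seeds ("one inexact match in every
    sequence"); per-sequence exactly-once verification happens during the
    second pass over the data (:func:`anchormsa.seeds.locate_seeds`).
    Within one k, candidates are in lexicographic (code) order.
    """
    if not d.has_inexact:
        raise RuntimeError("augment_inexact must run before candidate_seeds")
    out: list[str] = []
    for k in range(d.M, 0, -1):
        lv = d.level(k)
        if lv is None or lv.inexact is None or len(lv.codes) == 0:
            continue
        for code in lv.codes[lv.inexact == d.N]:
            out.append(decode_ktuple(int(code), k))
    return out
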