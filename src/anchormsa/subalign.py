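"""Segment aligners: a builtin progressive DP aligner and external tools.

The builtin aligner makes the whole pipeline runnable without third-party
binaries: sequences are added longest-first to a growing profile, each by
affine-gap global alignment (Gotoh three-state recurrence) against profile
columns, a column being scored by the mean substitution score against its
residues.  The external adapter shells out to any FASTA-in/FASTA-out
multiple aligner through a command template with ``{in}``/``{out}``
placeholders; canonical templates for MAFFT and CLUSTAL W are provided.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqio
from .seqio import Alignment, SequenceSet

NEG_INF = -1.0e18

CANONICAL_TEMPLATES = {
    "mafft": "mafft --quiet --retree 2 --maxiterate 0 {in} > {out}",
    "clustalw": (
        "clustalw -INFILE={in} -OUTFILE={out} -OUTPUT=FASTA "
        "-OUTORDER=INPUT -QUIET"
    ),
}

__all__ = [
    "Scoring",
    "AlignerSpec",
    "AlignerError",
    "builtin_align",
    "external_align",
    "run_subaligner",
    "CANONICAL_TEMPLATES",
]


class AlignerError(RuntimeError):
    """Sub-aligner failure (bad output, nonzero exit, size cap, ...)."""


@dataclass(frozen=True)
class Scoring:
    """Affine-gap nucleotide scoring; a length-l gap costs open+(l-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0   # charged on the first gap character
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignerSpec:
    """Which aligner to run on segments.

    kind "builtin" uses the progressive DP aligner below; kind "external"
    runs *command_template* through the shell with {in}/{out} replaced by
    FASTA paths.
    """

    kind: str = "builtin"
    command_template: str = ""
    scoring: Scoring = field(default_factory=Scoring)
    size_cap: int = 200_000  # rows x max row length, builtin only

    def __post_init__(self) -> None:
        if self.kind not in ("builtin", "external"):
            raise ValueError(f"unknown aligner kind {self.kind!r}")
        if self.kind == "external":
            if "{in}" not in self.command_template or "{out}" not in self.command_template:
                raise ValueError(
                    "external command template must contain {in} and {out}"
                )

    @staticmethod
    def from_cli(token: str) -> "AlignerSpec":
        """Parse ``builtin`` / ``mafft`` / ``clustalw`` / ``cmd:<template>``."""
        if token == "builtin":
            return AlignerSpec("builtin")
        if token in CANONICAL_TEMPLATES:
            return AlignerSpec("external", CANONICAL_TEMPLATES[token])
        if token.startswith("cmd:"):
            return AlignerSpec("external", token[4:])
        raise ValueError(
            f"unknown aligner {token!r}; expected builtin, mafft, clustalw "
            "or cmd:\"...{in}...{out}...\""
        )


def _vocab(strings: list[str]) -> dict[str, int]:
    chars = sorted({c for s in strings for c in s})
    return {c: i for i, c in enumerate(chars)}


def _gotoh_profile(
    profile: list[str],
    counts: np.ndarray,
    nres: np.ndarray,
    seq_codes: np.ndarray,
    sc: Scoring,
) -> tuple[list[str], float]:
    """Align one sequence against a profile; returns (edit ops, score).

    States: D consumes (seq char, profile column); U consumes a seq char
    inserting a gap column into the profile; L consumes a profile column
    putting a gap into the new row.  Rows of the DP run over the sequence
    so U vectorizes directly, and L is recovered from the prefix maximum
    of the current D/U row (an affine gap along j opens once from D or U).
    Tie-breaking during traceback prefers diagonal, then up, then left.
    """
    n = len(seq_codes)
    w = len(profile[0]) if profile else 0
    nrows = len(profile)
    go, ge = sc.gap_open, sc.gap_extend

    # substitution score of seq char i against profile column j
    if w and n:
        hits = counts[:, seq_codes].T.astype(np.float64)  # (n, w)
        S = (sc.match * hits + sc.mismatch * (nres[None, :] - hits)) / nrows
    else:
        S = np.zeros((n, w))

    D = np.full((n + 1, w + 1), NEG_INF)
    U = np.full((n + 1, w + 1), NEG_INF)
    L = np.full((n + 1, w + 1), NEG_INF)
    D[0, 0] = 0.0
    if w:
        L[0, 1:] = go + ge * np.arange(w)
    for i in range(1, n + 1):
        U[i, :] = np.maximum(D[i - 1, :] + go, U[i - 1, :] + ge)
        if w:
            best_prev = np.maximum(np.maximum(D[i - 1, :-1], U[i - 1, :-1]), L[i - 1, :-1])
            D[i, 1:] = S[i - 1, :] + best_prev
        # L[i, j] = max_{j' < j} D_or_U[i, j'] + go + (j - 1 - j') * ge
        if w:
            base = np.maximum(D[i, :-1], U[i, :-1])
            t = base - ge * np.arange(w)
            pref = np.maximum.accumulate(t)
            L[i, 1:] = pref + go + ge * (np.arange(w))
    end_state = int(np.argmax([D[n, w], U[n, w], L[n, w]]))
    score = float([D[n, w], U[n, w], L[n, w]][end_state])

    # traceback
    ops: list[str] = []  # 'D', 'U', 'L'
    i, j = n, w
    state = "DUL"[end_state]
    while i > 0 or j > 0:
        if state == "D":
            if i == 0 or j == 0:
                # only gap states can reach the border
                state = "L" if i == 0 else "U"
                continue
            ops.append("D")
            prev = (D[i - 1, j - 1], U[i - 1, j - 1], L[i - 1, j - 1])
            cur = D[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            # choose predecessor with diag > up > left preference
            state = "D"
            for cand, val in zip("DUL", prev):
                if abs(val - cur) <= 1e-9:
                    state = cand
                    break
        elif state == "U":
            ops.append("U")
            from_d = D[i - 1, j] + go
            cur = U[i, j]
            i -= 1
            state = "D" if abs(from_d - cur) <= 1e-9 else "U"
        else:  # L
            ops.append("L")
            from_d = D[i, j - 1] + go
            from_u = U[i, j - 1] + go
            cur = L[i, j]
            j -= 1
            if abs(from_d - cur) <= 1e-9:
                state = "D"
            elif abs(from_u - cur) <= 1e-9:
                state = "U"
            else:
                state = "L"
    ops.reverse()
    return ops, score


def _apply_ops(
    profile: list[str], seq: str, ops: list[str]
) -> tuple[list[str], str]:
    new_rows = [[] for _ in profile]
    new_seq: list[str] = []
    i = j = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(profile):
                new_rows[r].append(row[j])
            new_seq.append(seq[i])
            i += 1
            j += 1
        elif op == "U":
            for r in range(len(profile)):
                new_rows[r].append(seqio.GAP)
            new_seq.append(seq[i])
            i += 1
        else:  # L
            for r, row in enumerate(profile):
                new_rows[r].append(row[j])
            new_seq.append(seqio.GAP)
            j += 1
    return ["".join(r) for r in new_rows], "".join(new_seq)


def builtin_align(
    seqs: SequenceSet,
    scoring: Scoring | None = None,
    size_cap: int = 200_000,
) -> Alignment:
    """Progressive profile alignment with affine gaps.

    Sequences are added in length-descending order (stable on input order)
    so the profile starts from the most informative sequence; output rows
    are restored to input order.  Refuses inputs whose rows x max-length
    product exceeds *size_cap* to avoid accidental quadratic blowups.
    """
    sc = scoring or Scoring()
    maxlen = max((r.length for r in seqs), default=0)
    if seqs.N * maxlen > size_cap:
        raise AlignerError(
            f"builtin aligner size cap exceeded ({seqs.N} rows x {maxlen} bp "
            f"> {size_cap}); configure an external aligner for inputs this "
            "large"
        )
    order = sorted(range(seqs.N), key=lambda i: (-seqs[i].length, i))
    strings = [seqs[i].residues for i in order]
    vocab = _vocab([s for s in strings if s])

    profile: list[str] = []
    for s in strings:
        if not profile:
            profile = [s]
            continue
        w = len(profile[0])
        counts = np.zeros((w, max(len(vocab), 1)), dtype=np.int64)
        nres = np.zeros(w, dtype=np.int64)
        for row in profile:
            arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
            for c, ci in vocab.items():
                counts[arr == ord(c), ci] += 1
            nres += arr != ord(seqio.GAP)
        seq_codes = np.array([vocab[c] for c in s], dtype=np.int64)
        ops, _score = _gotoh_profile(profile, counts, nres, seq_codes, sc)
        profile, new_row = _apply_ops(profile, s, ops)
        profile.append(new_row)

    rows_by_input: list[str | None] = [None] * seqs.N
    for rank, i in enumerate(order):
        rows_by_input[i] = profile[rank]
    aln = Alignment(seqs.ids, tuple(rows_by_input))  # type: ignore[arg-type]
    aln.check_roundtrip(seqs)
    return aln


def external_align(
    seqs: SequenceSet,
    spec: AlignerSpec,
    workdir: str | Path | None = None,
) -> Alignment:
    """Run an external FASTA-in/FASTA-out aligner on *seqs*.

    Empty sequences are withheld from the tool (most aligners reject
    them) and restored as all-gap rows; output records are re-sorted to
    input id order and the degap round-trip is verified.  The temp
    directory is removed on success and kept on failure for inspection.
    """
    nonempty = [r for r in seqs if r.length > 0]
    if not nonempty:
        return Alignment(seqs.ids, tuple("" for _ in seqs.records))
    if len(nonempty) == 1:
        only = nonempty[0]
        rows = tuple(
            r.residues if r.id == only.id else seqio.GAP * only.length
            for r in seqs
        )
        aln = Alignment(seqs.ids, rows)
        aln.check_roundtrip(seqs)
        return aln

    own_dir = workdir is None
    tmp = Path(tempfile.mkdtemp(prefix="anchormsa-")) if own_dir else Path(workdir)
    tmp.mkdir(parents=True, exist_ok=True)
    in_path = tmp / "segment.fasta"
    out_path = tmp / "segment.aln.fasta"
    seqio.write_fasta(SequenceSet(tuple(nonempty)), in_path)
    cmd = spec.command_template.replace("{in}", shlex.quote(str(in_path)))
    cmd = cmd.replace("{out}", shlex.quote(str(out_path)))
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignerError(
            f"external aligner failed (exit {proc.returncode}): {cmd}\n"
            f"stderr: {proc.stderr[-2000:]}"
        )
    try:
        raw = seqio.read_alignment(out_path)
    except seqio.FastaError as e:
        raise AlignerError(f"unparseable aligner output from {cmd}: {e}") from e

    by_id = dict(zip(raw.ids, raw.rows))
    missing = [r.id for r in nonempty if r.id not in by_id]
    if missing:
        raise AlignerError(
            f"aligner output is missing records {missing} (command: {cmd})"
        )
    width = len(next(iter(by_id.values())))
    rows = []
    for r in seqs:
        if r.length == 0:
            rows.append(seqio.GAP * width)
        else:
            rows.append(by_id[r.id])
    aln = Alignment(seqs.ids, tuple(rows))
    try:
        aln.check_roundtrip(seqs)
    except seqio.FastaError as e:
        raise AlignerError(
            f"aligner output violates the degap round-trip: {e} (command: {cmd})"
        ) from e
    if own_dir:
        for p in (in_path, out_path):
            p.unlink(missing_ok=True)
        try:
            tmp.rmdir()
        except OSError:
            pass
    return aln


def run_subaligner(seqs: SequenceSet, spec: AlignerSpec) -> Alignment:
    """Dispatch to the configured aligner, handling trivial cases."""
    if all(r.length == 0 for r in seqs):
        return Alignment(seqs.ids, tuple("" for _ in seqs.records))
    if spec.kind == "builtin":
        # builtin handles empty rows natively
        return builtin_align(seqs, spec.scoring, spec.size_cap)
    return external_align(seqs, spec)
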