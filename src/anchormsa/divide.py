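"""Divide-and-conquer pipeline: anchor, split, align segments, assemble.

One anchoring round builds the k-tuple dictionary, finds and verifies
seeds, resolves them into a collinear anchor set, and splits every
sequence at the anchors.  Each anchor contributes a gap-free block of k
columns (every sequence's window is the seed tuple or one substitution
away, so no indel is possible inside a block); each inter-anchor segment
is aligned independently — recursively with further anchoring rounds
while it stays long, by the configured sub-aligner once it is short
enough or the depth budget is exhausted, or by plain gap-padding in
seeds-only mode — and the partial alignments are concatenated in order.

The central correctness property, asserted on every run: degapping any
row of the result reproduces the corresponding input sequence exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from . import kdict, seeds as seeds_mod, subalign
from .seqio import GAP, Alignment, SequenceRecord, SequenceSet
from .subalign import AlignerSpec

__all__ = [
    "PipelineConfig",
    "DepthStats",
    "RunLog",
    "SegmentSet",
    "AnchorBlock",
    "align",
    "align_segment",
    "seeds_only_alignment",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the alignment pipeline.

    max_depth limits the number of recursive anchoring rounds (the top
    level is depth 1); None means unlimited.  Segments no longer than
    segment_threshold residues go straight to the sub-aligner.
    """

    M: int = kdict.DEFAULT_M
    T: int = seeds_mod.DEFAULT_T
    max_depth: int | None = None
    segment_threshold: int = 2000
    aligner: AlignerSpec = field(default_factory=AlignerSpec)
    seeds_only: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1 or self.T < 1 or self.segment_threshold < 1:
            raise ValueError("M, T and segment_threshold must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 when finite")


@dataclass
class DepthStats:
    """Per-anchoring-round diagnostics (one row per recursion event)."""

    depth: int
    n_candidates: int
    n_verified: int
    n_dropped: int
    n_anchors: int
    n_segments: int
    max_segment_len: int


@dataclass
class RunLog:
    """Manifest of one pipeline run; written on success and on failure."""

    config: PipelineConfig | None = None
    input_digest: str = ""
    input_n: int = 0
    input_total_length: int = 0
    depth_stats: list[DepthStats] = field(default_factory=list)
    #: every anchor used anywhere in the recursion, with global coordinates
    anchors: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)
    subaligner_calls: int = 0
    status: str = "incomplete"

    @property
    def total_anchors(self) -> int:
        return len(self.anchors)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# anchormsa run manifest\n")
            fh.write(f"status\t{self.status}\n")
            fh.write(f"input_digest\tsha256:{self.input_digest}\n")
            fh.write(f"n_sequences\t{self.input_n}\n")
            fh.write(f"total_length\t{self.input_total_length}\n")
            if self.config is not None:
                c = self.config
                depth = "unlimited" if c.max_depth is None else c.max_depth
                fh.write(
                    f"config\tM={c.M} T={c.T} --max-depth={depth} "
                    f"(-max-depth = {depth}) "
                    f"--segment-threshold={c.segment_threshold} "
                    f"aligner={c.aligner.kind} seeds_only={c.seeds_only} "
                    f"rng_seed={c.random_seed}\n"
                )
            fh.write(f"subaligner_calls\t{self.subaligner_calls}\n")
            fh.write(f"total_anchors\t{self.total_anchors}\n")
            fh.write(
                "depth\tcandidates\tverified\tdropped\tanchors\tsegments"
                "\tmax_segment_len\n"
            )
            for d in self.depth_stats:
                fh.write(
                    f"{d.depth}\t{d.n_candidates}\t{d.n_verified}\t"
                    f"{d.n_dropped}\t{d.n_anchors}\t{d.n_segments}\t"
                    f"{d.max_segment_len}\n"
                )


@dataclass(frozen=True)
class SegmentSet:
    """One homologous inter-anchor region: an interval per sequence."""

    parent: SequenceSet
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for (s, e), rec in zip(self.intervals, self.parent):
            if not (0 <= s <= e <= rec.length):
                raise ValueError(f"interval ({s},{e}) out of bounds")

    @property
    def max_length(self) -> int:
        return max(e - s for s, e in self.intervals)

    @property
    def all_empty(self) -> bool:
        return all(s == e for s, e in self.intervals)

    @property
    def any_empty(self) -> bool:
        return any(s == e for s, e in self.intervals)

    def extract(self) -> SequenceSet:
        return SequenceSet(
            tuple(
                SequenceRecord(rec.id, rec.residues[s:e])
                for (s, e), rec in zip(self.intervals, self.parent)
            )
        )


@dataclass(frozen=True)
class AnchorBlock:
    """The k gap-free columns contributed by one anchor."""

    ktuple: str
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.ktuple)
        for r in self.rows:
            if len(r) != k or GAP in r:
                raise ValueError("anchor block rows must be gap-free width k")


def _digest(seqs: SequenceSet) -> str:
    h = hashlib.sha256()
    for rec in seqs:
        h.update(rec.id.encode())
        h.update(b"\0")
        h.update(rec.residues.encode())
        h.update(b"\0")
    return h.hexdigest()


def _find_anchors(
    seqs: SequenceSet, cfg: PipelineConfig, depth: int, log: RunLog
) -> seeds_mod.AnchorSet:
    d = kdict.build_dictionary(seqs, cfg.M)
    kdict.augment_inexact(d)
    candidates = kdict.candidate_seeds(d)
    verified, dropped = seeds_mod.locate_seeds(seqs, candidates)
    ranked = seeds_mod.rank_seeds(verified, cfg.T)
    mat = seeds_mod.build_incompatibility_matrix(ranked)
    anchors = seeds_mod.resolve_conflicts(mat)
    log.depth_stats.append(
        DepthStats(depth, len(candidates), len(verified), dropped,
                   len(anchors), 0, 0)
    )
    return anchors


def _segments_and_blocks(
    seqs: SequenceSet, anchors: seeds_mod.AnchorSet
) -> tuple[list[SegmentSet], list[AnchorBlock]]:
    blocks: list[AnchorBlock] = []
    segments: list[SegmentSet] = []
    prev_end = [0] * seqs.N
    for a in anchors:
        intervals = tuple(
            (prev_end[i], a.positions[i]) for i in range(seqs.N)
        )
        segments.append(SegmentSet(seqs, intervals))
        blocks.append(
            AnchorBlock(
                a.ktuple,
                tuple(
                    seqs[i].residues[a.positions[i] : a.positions[i] + a.k]
                    for i in range(seqs.N)
                ),
            )
        )
        prev_end = [a.positions[i] + a.k for i in range(seqs.N)]
    segments.append(
        SegmentSet(
            seqs, tuple((prev_end[i], seqs[i].length) for i in range(seqs.N))
        )
    )
    return segments, blocks


def _pad_segment(seg_seqs: SequenceSet) -> Alignment:
    """Left-justify each row and pad with gaps to the longest row."""
    width = max(r.length for r in seg_seqs)
    rows = tuple(r.residues + GAP * (width - r.length) for r in seg_seqs)
    return Alignment(seg_seqs.ids, rows)


def _leaf_align(
    seg_seqs: SequenceSet,
    cfg: PipelineConfig,
    log: RunLog,
    where: str,
) -> Alignment:
    if cfg.seeds_only:
        return _pad_segment(seg_seqs)
    log.subaligner_calls += 1
    try:
        return subalign.run_subaligner(seg_seqs, cfg.aligner)
    except subalign.AlignerError as e:
        raise subalign.AlignerError(f"sub-aligner failed on {where}: {e}") from e


def _concat(parts: list[Alignment], seqs: SequenceSet) -> Alignment:
    rows = ["".join(p.rows[i] for p in parts) for i in range(seqs.N)]
    aln = Alignment(seqs.ids, tuple(rows))
    aln.check_roundtrip(seqs)  # the central invariant, on every assembly
    return aln


def align_segment(
    seg: SegmentSet,
    cfg: PipelineConfig,
    depth: int,
    log: RunLog | None = None,
    offsets: tuple[int, ...] | None = None,
) -> Alignment:
    """Align one inter-anchor segment according to the depth rules.

    All-empty segments yield a width-0 alignment.  A segment recurses
    into another anchoring round only while every interval is non-empty,
    it is longer than the segment threshold, and the depth budget allows;
    otherwise it goes to the sub-aligner (or is gap-padded in seeds-only
    mode).  A recursion that finds zero anchors also falls through to the
    sub-aligner.
    """
    if log is None:
        log = RunLog()
    if offsets is None:
        offsets = tuple(s for s, _ in seg.intervals)
    seg_seqs = seg.extract()
    if seg.all_empty:
        return Alignment(seg_seqs.ids, tuple("" for _ in range(seg_seqs.N)))
    where = (
        "segment at "
        + ", ".join(f"{i}:{s}-{e}" for i, (s, e) in enumerate(seg.intervals))
    )
    depth_exhausted = cfg.max_depth is not None and depth >= cfg.max_depth
    if seg.any_empty or seg.max_length <= cfg.segment_threshold or depth_exhausted:
        return _leaf_align(seg_seqs, cfg, log, where)
    return _align_rec(seg_seqs, cfg, depth + 1, offsets, log, where)


def _align_rec(
    seqs: SequenceSet,
    cfg: PipelineConfig,
    depth: int,
    offsets: tuple[int, ...],
    log: RunLog,
    where: str,
) -> Alignment:
    anchors = _find_anchors(seqs, cfg, depth, log)
    if len(anchors) == 0:
        # whole-dataset fallback, applied per segment
        return _leaf_align(seqs, cfg, log, where)
    for a in anchors:
        log.anchors.append(
            (a.ktuple, tuple(offsets[i] + p for i, p in enumerate(a.positions)))
        )
    segments, blocks = _segments_and_blocks(seqs, anchors)
    stats = log.depth_stats[-1]
    stats.n_segments = len(segments)
    stats.max_segment_len = max(s.max_length for s in segments)

    parts: list[Alignment] = []
    for si, seg in enumerate(segments):
        seg_offsets = tuple(
            offsets[i] + s for i, (s, _) in enumerate(seg.intervals)
        )
        parts.append(align_segment(seg, cfg, depth, log, seg_offsets))
        if si < len(blocks):
            b = blocks[si]
            parts.append(Alignment(seqs.ids, b.rows))
    return _concat(parts, seqs)


def align(seqs: SequenceSet, cfg: PipelineConfig | None = None) -> tuple[Alignment | None, RunLog]:
    """Run the full pipeline on *seqs*.

    Returns the alignment and the run manifest.  When no seeds exist at
    the top level the whole dataset goes to the sub-aligner — except in
    seeds-only mode, where no alignment is produced and the manifest
    status is ``no-seeds`` (the recommended screening signal that the
    data may be very hard or impossible to align).
    """
    cfg = cfg or PipelineConfig()
    if seqs.N < 2:
        raise ValueError("alignment needs at least two sequences")
    log = RunLog(
        config=cfg,
        input_digest=_digest(seqs),
        input_n=seqs.N,
        input_total_length=seqs.total_length,
    )
    offsets = tuple(0 for _ in range(seqs.N))
    anchors = _find_anchors(seqs, cfg, 1, log)
    if len(anchors) == 0:
        if cfg.seeds_only:
            log.status = "no-seeds"
            return None, log
        aln = _leaf_align(seqs, cfg, log, "whole dataset (no seeds found)")
        aln.check_roundtrip(seqs)
        log.status = "ok"
        return aln, log
    for a in anchors:
        log.anchors.append((a.ktuple, tuple(a.positions)))
    segments, blocks = _segments_and_blocks(seqs, anchors)
    stats = log.depth_stats[-1]
    stats.n_segments = len(segments)
    stats.max_segment_len = max(s.max_length for s in segments)
    parts: list[Alignment] = []
    for si, seg in enumerate(segments):
        seg_offsets = tuple(s for s, _ in seg.intervals)
        parts.append(align_segment(seg, cfg, 1, log, seg_offsets))
        if si < len(blocks):
            parts.append(Alignment(seqs.ids, blocks[si].rows))
    aln = _concat(parts, seqs)
    log.status = "ok"
    return aln, log


def seeds_only_alignment(
    seqs: SequenceSet, anchors: seeds_mod.AnchorSet
) -> Alignment:
    """Rough alignment: anchor blocks aligned, segments gap-padded.

    Each inter-anchor segment is rendered without alignment — every row
    left-justified and right-padded to the longest interval — so the
    result still degaps to the inputs but only the anchors are truly
    aligned.  Useful for rapid triage of a new dataset.
    """
    segments, blocks = _segments_and_blocks(seqs, anchors)
    parts: list[Alignment] = []
    for si, seg in enumerate(segments):
        parts.append(_pad_segment(seg.extract()))
        if si < len(blocks):
            parts.append(Alignment(seqs.ids, blocks[si].rows))
    return _concat(parts, seqs)
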