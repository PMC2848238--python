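"""Pipeline orchestration: splitting, recursion, assembly, round trips."""

import pytest

from anchormsa import (
    PipelineConfig,
    SequenceSet,
    align,
    seeds_only_alignment,
    sp_identity_score,
)
from anchormsa.divide import RunLog, SegmentSet, align_segment
from anchormsa.seeds import AnchorSet, Seed
from anchormsa.synth import evolve_family, random_sequences


def _set(*residues):
    return SequenceSet.from_pairs((f"s{i}", r) for i, r in enumerate(residues))


def test_identical_pair_aligns_gap_free_with_score_100():
    s = random_sequences(1, 300, rng_seed=1)[0].residues
    seqs = _set(s, s)
    aln, log = align(seqs, PipelineConfig(M=6, segment_threshold=10))
    assert "-" not in "".join(aln.rows)
    assert sp_identity_score(aln).mean_score == 100.0
    assert log.status == "ok"
    assert log.total_anchors >= 1


def test_roundtrip_on_families():
    cases = [
        (3, 0.0, 0.0, 4000),
        (3, 0.05, 0.002, 3000),
        (5, 0.003, 0.001, 5000),
    ]
    for i, (n, sub, indel, length) in enumerate(cases):
        seqs, _ = evolve_family(length, n, sub, indel, rng_seed=600 + i)
        aln, log = align(seqs, PipelineConfig(segment_threshold=500))
        for row_i, rec in enumerate(seqs):
            assert aln.degapped(row_i) == rec.residues
        assert log.status == "ok"


def test_final_width_is_sum_of_block_widths():
    seqs, _ = evolve_family(3000, 4, 0.01, 0.0, rng_seed=8)
    cfg = PipelineConfig(max_depth=1, seeds_only=True)
    aln, log = align(seqs, cfg)
    anchor_cols = sum(len(kt) for kt, _ in log.anchors)
    # segment widths: rebuild from anchors (sorted by seq-0 position)
    anchors = sorted(log.anchors, key=lambda a: a[1][0])
    seg_widths = []
    prev_end = [0] * seqs.N
    for kt, pos in anchors:
        seg_widths.append(max(p - pe for p, pe in zip(pos, prev_end)))
        prev_end = [p + len(kt) for p in pos]
    seg_widths.append(max(r.length - pe for r, pe in zip(seqs, prev_end)))
    assert aln.width == anchor_cols + sum(seg_widths)


def test_empty_interval_renders_all_gap_row():
    parent = _set("AAATTT", "AAA")
    seg = SegmentSet(parent, ((3, 6), (3, 3)))
    aln = align_segment(seg, PipelineConfig(), depth=1)
    assert aln.rows[0] == "TTT"
    assert aln.rows[1] == "---"


def test_all_empty_segment_width_zero():
    parent = _set("AAA", "CCC")
    seg = SegmentSet(parent, ((3, 3), (3, 3)))
    aln = align_segment(seg, PipelineConfig(), depth=1)
    assert aln.width == 0


def test_max_depth_one_never_recurses():
    seqs, _ = evolve_family(8000, 4, 0.003, 0.0, rng_seed=15)
    cfg = PipelineConfig(max_depth=1, seeds_only=True)
    aln, log = align(seqs, cfg)
    depths = [d.depth for d in log.depth_stats]
    assert depths == [1]


def test_unlimited_depth_recurses_on_long_tail():
    seqs, _ = evolve_family(16000, 4, 0.003, 0.0, rng_seed=15)
    cfg = PipelineConfig(seeds_only=True)
    aln, log = align(seqs, cfg)
    assert max(d.depth for d in log.depth_stats) > 1
    # anchor columns at depth 1 are shared with the max_depth=1 run
    cfg1 = PipelineConfig(max_depth=1, seeds_only=True)
    _, log1 = align(seqs, cfg1)
    n1 = log1.depth_stats[0].n_anchors
    assert [a for a in log.anchors[:n1]] == [a for a in log1.anchors[:n1]]


def test_random_data_seeds_only_reports_no_seeds():
    # at N=20 a spurious candidate would need its matches spread exactly
    # one per sequence (probability ~ 20!/20^20), so zero seeds survive
    seqs = random_sequences(20, 2000, rng_seed=77)
    aln, log = align(seqs, PipelineConfig(seeds_only=True))
    assert aln is None
    assert log.status == "no-seeds"
    assert log.subaligner_calls == 0


def test_random_data_full_mode_falls_back_to_subaligner():
    seqs = random_sequences(2, 600, rng_seed=78)
    aln, log = align(seqs, PipelineConfig())
    assert aln is not None
    assert log.subaligner_calls >= 1
    aln.check_roundtrip(seqs)


def test_seeds_only_padding_rule():
    # two anchors, middle segment with interval lengths 3 and 5
    parent = _set("GGGGAAATTTT", "GGGGCACGCTTTT")
    anchors = AnchorSet(
        (Seed("GGGG", (0, 0), 2), Seed("TTTT", (7, 9), 2))
    )
    aln = seeds_only_alignment(parent, anchors)
    assert aln.rows[0] == "GGGG" + "AAA--" + "TTTT"
    assert aln.rows[1] == "GGGG" + "CACGC" + "TTTT"


def test_determinism_of_full_runs():
    seqs, _ = evolve_family(4000, 5, 0.01, 0.002, rng_seed=31)
    cfg = PipelineConfig(segment_threshold=800)
    a1, l1 = align(seqs, cfg)
    a2, l2 = align(seqs, cfg)
    assert a1.rows == a2.rows
    assert l1.anchors == l2.anchors


def test_pipeline_score_close_to_whole_builtin():
    seqs, _ = evolve_family(1500, 3, 0.01, 0.002, rng_seed=44)
    aln, _ = align(seqs, PipelineConfig(segment_threshold=300))
    from anchormsa import builtin_align

    whole = builtin_align(seqs)
    s_pipe = sp_identity_score(aln).mean_score
    s_whole = sp_identity_score(whole).mean_score
    assert s_pipe >= s_whole - 1.0


def test_manifest_written_and_parsable(tmp_path):
    seqs, _ = evolve_family(2000, 3, 0.003, 0.0, rng_seed=2)
    aln, log = align(seqs, PipelineConfig(seeds_only=True))
    p = tmp_path / "run.manifest"
    log.write(p)
    text = p.read_text()
    assert "status\tok" in text
    assert "total_anchors" in text
    assert "sha256:" in text
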