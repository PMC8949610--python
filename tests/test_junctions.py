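"""Junction mapping: segment detection, flank extraction, breakpoint arithmetic."""

import numpy as np
import pytest

from tismap.align import KmerIndex
from tismap.config import PipelineConfig
from tismap.io_formats import SequenceRecord, revcomp
from tismap.junctions import (
    Flank,
    PlasmidSegment,
    detect_plasmid_segments,
    extract_flanks,
    infer_breakpoint,
    map_flank,
    merge_segments,
)

CFG = PipelineConfig()


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(99)
    genome = SequenceRecord("chr1", _rand(rng, 60_000))
    plasmid = SequenceRecord("plasmid", _rand(rng, 5_000))
    return rng, genome, plasmid


def test_read_with_exact_fragment_yields_one_matching_segment(toy):
    rng, genome, plasmid = toy
    frag = plasmid.sequence[1000:3000]
    read = SequenceRecord("r", genome.sequence[5000:7000] + frag + genome.sequence[7000:9000])
    (seg,) = detect_plasmid_segments(read, plasmid, CFG)
    assert seg.plasmid_interval == (1000, 3000)
    assert seg.read_interval == (2000, 4000)
    assert seg.strand == "+"
    assert seg.evalue < CFG.evalue_max


def test_genome_only_read_has_no_segments(toy):
    rng, genome, plasmid = toy
    read = SequenceRecord("r", genome.sequence[10_000:18_000])
    assert detect_plasmid_segments(read, plasmid, CFG) == []


def test_two_disjoint_fragments_read_ordered(toy):
    rng, genome, plasmid = toy
    read = SequenceRecord(
        "r",
        genome.sequence[20_000:21_000]
        + plasmid.sequence[3000:3800]
        + genome.sequence[21_000:23_000]
        + revcomp(plasmid.sequence[500:1200])
        + genome.sequence[23_000:24_000],
    )
    segs = detect_plasmid_segments(read, plasmid, CFG)
    assert len(segs) == 2
    assert segs[0].read_interval[1] <= segs[1].read_interval[0]
    assert segs[0].strand == "+"
    assert segs[1].strand == "-"
    # chance single-base matches at a junction may extend a hit by a few bp
    for seg, want in zip(segs, [(3000, 3800), (500, 1200)]):
        assert abs(seg.plasmid_interval[0] - want[0]) <= 4
        assert abs(seg.plasmid_interval[1] - want[1]) <= 4


def _seg(read_iv, plasmid_iv, strand="+"):
    return PlasmidSegment(read_iv, plasmid_iv, strand, 100, 1e-40, 0.95)


def test_collinear_segments_merge():
    merged = merge_segments([_seg((100, 500), (0, 400)), _seg((510, 900), (410, 800))])
    assert len(merged) == 1
    assert merged[0].read_interval == (100, 900)
    assert merged[0].plasmid_interval == (0, 800)


def test_opposite_strand_segments_do_not_merge():
    merged = merge_segments([_seg((100, 500), (0, 400), "+"), _seg((510, 900), (410, 800), "-")])
    assert len(merged) == 2


def test_distant_segments_do_not_merge():
    merged = merge_segments([_seg((100, 500), (0, 400)), _seg((700, 900), (410, 610))])
    assert len(merged) == 2


def test_flank_arithmetic_mid_read():
    read = SequenceRecord("r", "A" * 5000)
    ev = extract_flanks(read, [_seg((1000, 3000), (0, 2000))], flank_len=500)
    assert ev.upstream_flank.read_interval == (500, 1000)
    assert ev.downstream_flank.read_interval == (3000, 3500)
    for f in ev.flanks:
        for seg in ev.segments:
            assert f.read_interval[1] <= seg.read_interval[0] or \
                f.read_interval[0] >= seg.read_interval[1]


def test_segment_at_read_start_marks_left_clipped():
    read = SequenceRecord("r", "A" * 5000)
    ev = extract_flanks(read, [_seg((0, 3000), (0, 3000))])
    assert ev.left_clipped
    assert ev.upstream_flank is None
    assert ev.downstream_flank is not None


def test_short_tail_flank_is_truncated():
    read = SequenceRecord("r", "A" * 3200)
    ev = extract_flanks(read, [_seg((1000, 3000), (0, 2000))])
    assert ev.downstream_flank.read_interval == (3000, 3200)


def test_tiny_flanks_are_dropped():
    read = SequenceRecord("r", "A" * 3030)
    ev = extract_flanks(read, [_seg((1000, 3000), (0, 2000))], min_flank_len=50)
    assert ev.downstream_flank is None  # 30 bp < 50 bp floor


def test_internal_flanks_are_tagged():
    read = SequenceRecord("r", "A" * 10_000)
    ev = extract_flanks(read, [_seg((1000, 2000), (0, 1000)),
                               _seg((5000, 6000), (2000, 3000))])
    sides = {f.side for f in ev.flanks}
    assert {"upstream", "downstream", "internal_left", "internal_right"} <= sides


def test_map_flank_unique_sequence_anchors_exactly(toy):
    rng, genome, plasmid = toy
    index = KmerIndex([genome], k=CFG.seed_k)
    flank = Flank("upstream", (0, 500), genome.sequence[30_000:30_500])
    map_flank(flank, index, CFG)
    assert flank.anchor is not None
    assert (flank.anchor.s_start, flank.anchor.s_end) == (30_000, 30_500)
    assert not flank.ambiguous
    assert flank.anchor.evalue < CFG.evalue_max


def test_map_flank_duplicated_locus_is_flagged_ambiguous(toy):
    rng, genome, plasmid = toy
    dup = genome.sequence[40_000:40_500]
    genome2 = SequenceRecord("chr1", genome.sequence + "T" * 50 + dup)
    index = KmerIndex([genome2], k=CFG.seed_k)
    flank = Flank("upstream", (0, 500), dup)
    map_flank(flank, index, CFG)
    assert flank.anchor is not None
    assert flank.anchor.s_start == 40_000  # tie resolved to the smaller coordinate
    assert flank.ambiguous


def test_map_flank_random_sequence_finds_nothing(toy):
    rng, genome, plasmid = toy
    other = np.random.default_rng(12345)
    flank = Flank("upstream", (0, 500), _rand(other, 500))
    map_flank(flank, KmerIndex([genome], k=CFG.seed_k), CFG)
    assert flank.anchor is None


def _chimeric_read(genome, plasmid, pos, frag, rc=False):
    insert = revcomp(plasmid.sequence[frag[0]:frag[1]]) if rc else plasmid.sequence[frag[0]:frag[1]]
    return SequenceRecord("r", genome.sequence[pos - 2000:pos] + insert
                          + genome.sequence[pos:pos + 2000])


def _clean_pos(genome, plasmid, frag, start):
    """First insertion point >= start with no chance microhomology."""
    from tismap.simulate import _clean_junction, _insert_contexts

    insert, lctx, rctx = _insert_contexts(plasmid.sequence, frag[0], frag[1], "+")
    for pos in range(start, start + 5000):
        if _clean_junction(insert, lctx, rctx,
                           genome.sequence[pos - 4:pos], genome.sequence[pos:pos + 4]):
            return pos
    raise AssertionError("no clean insertion point found")


def test_breakpoints_bracket_a_clean_insertion(toy):
    rng, genome, plasmid = toy
    index = KmerIndex([genome], k=CFG.seed_k)
    pos = _clean_pos(genome, plasmid, (1000, 2500), 35_000)
    read = _chimeric_read(genome, plasmid, pos, (1000, 2500))
    segs = merge_segments(detect_plasmid_segments(read, plasmid, CFG))
    ev = extract_flanks(read, segs)
    for f in ev.flanks:
        map_flank(f, index, CFG, read_id=read.id)
    bps = infer_breakpoint(ev)
    assert len(bps) == 2
    positions = sorted(b.position for b in bps)
    assert max(positions) - min(positions) <= 1
    assert all(abs(b.position - pos) <= 1 for b in bps)


def test_breakpoint_inference_mirrors_under_read_reverse_complement(toy):
    rng, genome, plasmid = toy
    index = KmerIndex([genome], k=CFG.seed_k)
    pos = _clean_pos(genome, plasmid, (2000, 3500), 45_000)
    read = _chimeric_read(genome, plasmid, pos, (2000, 3500))
    flipped = SequenceRecord("r_rc", revcomp(read.sequence))
    results = []
    for r in (read, flipped):
        segs = merge_segments(detect_plasmid_segments(r, plasmid, CFG))
        ev = extract_flanks(r, segs)
        for f in ev.flanks:
            map_flank(f, index, CFG, read_id=r.id)
        results.append(sorted(b.position for b in infer_breakpoint(ev)))
    assert results[0] == results[1]


def test_upstream_anchor_end_is_the_breakpoint():
    from tismap.align import LocalAlignment
    from tismap.junctions import PlasmidEvidence

    anchor = LocalAlignment("f", "chr9", 0, 500, 9500, 10_000, "+", 1000, 1e-60, 1.0,
                            ops=[("=", 500)])
    ev = PlasmidEvidence("r", 5000)
    ev.flanks.append(Flank("upstream", (0, 500), "A" * 500, anchor=anchor))
    (bp,) = infer_breakpoint(ev)
    assert bp.position == 10_000
    assert bp.locus.pos1 == 10_001  # 1-based rendering
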