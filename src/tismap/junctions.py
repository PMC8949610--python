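"""Chimeric-read junction mapping.

Three steps per read: (i) find plasmid-derived segments in the read with the
seed-and-extend engine at the E-value gate; (ii) extract up to 500 bases of
read sequence flanking the (merged) plasmid segments; (iii) anchor each flank
on the reference genome, keeping a single best target/HSP, and convert the
anchor edge adjacent to the plasmid into a genomic breakpoint.

Orientation conventions: the plasmid is the query against the read (so the
E-value search space is m = plasmid length, n = read length, matching the
original search direction), while each flank is the query against the genome.
Reads are processed in native orientation; strands are normalised only at
breakpoint inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from tismap.align import (
    KarlinAltschulParams,
    KmerIndex,
    LocalAlignment,
    calibrate_karlin_altschul,
    seed_and_extend,
)
from tismap.config import PipelineConfig
from tismap.io_formats import GenomicInterval, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class PlasmidSegment:
    """A plasmid-derived stretch of one read (read-centric coordinates)."""

    read_interval: tuple[int, int]
    plasmid_interval: tuple[int, int]
    strand: str
    score: int
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.read_interval[0] >= self.read_interval[1]:
            raise ValueError("empty read interval")
        if self.plasmid_interval[0] >= self.plasmid_interval[1]:
            raise ValueError("empty plasmid interval")


@dataclass
class Flank:
    """Host-derived read sequence adjacent to a plasmid segment.

    ``side`` is 'upstream' (left of the leftmost segment on the read),
    'downstream' (right of the rightmost), or the internal variants
    'internal_left'/'internal_right' (between two segments; tagged, they
    support fragmented-integration calls).  ``anchor`` is the genome
    alignment once mapped; ``ambiguous`` flags a runner-up genome hit
    within 95% of the best score.
    """

    side: str
    read_interval: tuple[int, int]
    sequence: str
    anchor: LocalAlignment | None = None
    ambiguous: bool = False


@dataclass
class PlasmidEvidence:
    """Everything one read says about plasmid integration."""

    read_id: str
    read_length: int
    segments: list[PlasmidSegment] = field(default_factory=list)
    flanks: list[Flank] = field(default_factory=list)
    left_clipped: bool = False   # leftmost segment starts at read position 0
    right_clipped: bool = False  # rightmost segment ends at the read end

    @property
    def upstream_flank(self) -> Flank | None:
        return next((f for f in self.flanks if f.side == "upstream"), None)

    @property
    def downstream_flank(self) -> Flank | None:
        return next((f for f in self.flanks if f.side == "downstream"), None)

    @property
    def anchored_flanks(self) -> list[Flank]:
        return [f for f in self.flanks if f.anchor is not None]


@dataclass(frozen=True)
class Breakpoint:
    """One genomic junction implied by an anchored flank."""

    locus: GenomicInterval  # single-base
    side: str               # flank side that produced it
    strand: str             # anchor strand
    read_id: str

    @property
    def position(self) -> int:
        return self.locus.start


def detect_plasmid_segments(
    read: SequenceRecord,
    plasmid: SequenceRecord | KmerIndex,
    config: PipelineConfig | None = None,
    ka: KarlinAltschulParams | None = None,
) -> list[PlasmidSegment]:
    """Find plasmid-derived segments of a read below the E-value gate.

    The plasmid is the query and the read the subject; hits are converted to
    read-centric coordinates and returned ordered along the read.
    """
    config = config or PipelineConfig()
    plasmid_index = plasmid if isinstance(plasmid, KmerIndex) else KmerIndex([plasmid], k=config.seed_k)
    read_index = KmerIndex([read], k=config.seed_k)
    plasmid_len = plasmid_index.total_length
    # plasmid as query, read as subject: swap roles for the engine call, which
    # wants the indexed sequence as subject.  Equivalent hits, same E-value
    # search space (m = plasmid, n = read) supplied explicitly.
    plasmid_rec = plasmid if isinstance(plasmid, SequenceRecord) else None
    if plasmid_rec is None:
        raise TypeError("detect_plasmid_segments needs the plasmid SequenceRecord")
    hits = seed_and_extend(
        plasmid_rec,
        read_index,
        scoring=config.scoring,
        seed_k=config.seed_k,
        x_drop=config.x_drop,
        ka=ka,
        search_space=(plasmid_len, len(read)),
        evalue_prefilter=config.evalue_max,
    )
    segments = []
    for h in hits:
        if h.evalue >= config.evalue_max:
            continue
        segments.append(
            PlasmidSegment(
                read_interval=(h.s_start, h.s_end),
                plasmid_interval=(h.q_start, h.q_end),
                strand=h.strand,
                score=h.score,
                evalue=h.evalue,
                identity=h.identity,
            )
        )
    segments.sort(key=lambda s: s.read_interval)
    return segments


def merge_segments(segments: list[PlasmidSegment], merge_gap: int = 50) -> list[PlasmidSegment]:
    """Merge read-adjacent, plasmid-collinear segments on the same strand.

    Noisy reads split one integrated fragment into several HSPs; segments
    whose read intervals lie within ``merge_gap`` of each other and whose
    plasmid intervals continue in the same direction on the same strand are
    merged, the plasmid interval becoming the union span.
    """
    if not segments:
        return []
    merged = [segments[0]]
    for seg in segments[1:]:
        last = merged[-1]
        read_gap = seg.read_interval[0] - last.read_interval[1]
        collinear = False
        if seg.strand == last.strand and read_gap <= merge_gap:
            if seg.strand == "+":
                collinear = seg.plasmid_interval[0] >= last.plasmid_interval[0]
            else:
                collinear = seg.plasmid_interval[1] <= last.plasmid_interval[1]
        if collinear:
            merged[-1] = PlasmidSegment(
                read_interval=(last.read_interval[0],
                               max(last.read_interval[1], seg.read_interval[1])),
                plasmid_interval=(
                    min(last.plasmid_interval[0], seg.plasmid_interval[0]),
                    max(last.plasmid_interval[1], seg.plasmid_interval[1]),
                ),
                strand=last.strand,
                score=last.score + seg.score,
                evalue=min(last.evalue, seg.evalue),
                identity=(last.identity + seg.identity) / 2,
            )
        else:
            merged.append(seg)
    return merged


def extract_flanks(
    read: SequenceRecord,
    segments: list[PlasmidSegment],
    flank_len: int = 500,
    min_flank_len: int = 50,
) -> PlasmidEvidence:
    """Extract up to ``flank_len`` read bases on each side of the segments.

    The upstream flank ends where the leftmost segment starts; the
    downstream flank begins where the rightmost segment ends.  Gaps between
    internal segments yield tagged internal flanks (one adjacent to each
    segment edge).  Flanks shorter than ``min_flank_len`` are discarded as
    unanchorable.
    """
    if not segments:
        raise ValueError(f"read {read.id!r}: no segments to flank")
    ev = PlasmidEvidence(read_id=read.id, read_length=len(read), segments=list(segments))

    def add(side: str, start: int, end: int) -> None:
        if end - start >= min_flank_len:
            ev.flanks.append(Flank(side, (start, end), read.sequence[start:end]))

    first, last = segments[0], segments[-1]
    up_start = max(0, first.read_interval[0] - flank_len)
    if first.read_interval[0] == 0:
        ev.left_clipped = True
    else:
        add("upstream", up_start, first.read_interval[0])
    if last.read_interval[1] >= len(read):
        ev.right_clipped = True
    else:
        add("downstream", last.read_interval[1],
            min(len(read), last.read_interval[1] + flank_len))
    for left_seg, right_seg in zip(segments, segments[1:]):
        gap_start, gap_end = left_seg.read_interval[1], right_seg.read_interval[0]
        if gap_end <= gap_start:
            continue
        add("internal_right", gap_start, min(gap_end, gap_start + flank_len))
        add("internal_left", max(gap_start, gap_end - flank_len), gap_end)
    return ev


def map_flank(
    flank: Flank,
    genome_index: KmerIndex,
    config: PipelineConfig | None = None,
    ka: KarlinAltschulParams | None = None,
    read_id: str = "flank",
) -> Flank:
    """Anchor one flank on the genome: best hit only (one target, one HSP).

    Ties go to the smallest genomic coordinate (the engine's ordering); when
    the runner-up scores >= 95% of the best the flank is flagged ambiguous,
    since keeping a single target silently discards near-ties.
    """
    config = config or PipelineConfig()
    seq = flank.sequence
    if len(seq) < config.min_flank_len:
        return flank
    rec = SequenceRecord(f"{read_id}:{flank.side}", seq)
    hits = seed_and_extend(
        rec,
        genome_index,
        scoring=config.scoring,
        seed_k=config.seed_k,
        x_drop=config.x_drop,
        ka=ka,
        search_space=(len(seq), genome_index.total_length),
        evalue_prefilter=config.evalue_max,
        reduce_query_overlap=False,  # keep runner-up placements for the ambiguity flag
    )
    hits = [h for h in hits if h.evalue < config.evalue_max]
    if not hits:
        return flank
    flank.anchor = hits[0]
    if len(hits) > 1 and hits[1].score >= config.ambiguity_frac * hits[0].score:
        flank.ambiguous = True
    return flank


def infer_breakpoint(evidence: PlasmidEvidence) -> list[Breakpoint]:
    """Convert anchored flanks into genomic breakpoints.

    The breakpoint is the genome coordinate adjacent to the anchor edge that
    touches the plasmid segment: for a flank left of its segment ('upstream'
    or 'internal_left') anchored on the + strand that is the anchor end
    (``s_end``); for a flank right of its segment on + it is the anchor
    start; - strand anchors mirror these rules.  The resulting coordinate is
    the 0-based insertion point (the base before which plasmid sequence was
    inserted).
    """
    breakpoints: list[Breakpoint] = []
    for flank in evidence.anchored_flanks:
        a = flank.anchor
        left_of_segment = flank.side in ("upstream", "internal_left")
        if (left_of_segment and a.strand == "+") or (not left_of_segment and a.strand == "-"):
            pos = a.s_end
        else:
            pos = a.s_start
        breakpoints.append(
            Breakpoint(
                locus=GenomicInterval(a.subject_id, pos, pos + 1),
                side=flank.side,
                strand=a.strand,
                read_id=evidence.read_id,
            )
        )
    return breakpoints
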