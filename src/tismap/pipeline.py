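"""End-to-end pipeline: qc -> junction mapping -> site calling -> annotation.

``run_pipeline`` is deterministic: identical inputs and configuration
produce byte-identical site TSV, BED and density TSV outputs (fixed tie
rules and sort orders throughout; no randomness anywhere downstream of the
input reads).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tismap import __version__ as _version
from tismap.align import KmerIndex, calibrate_karlin_altschul
from tismap.annotate import (
    GeneIndex,
    annotate_gene_context,
    attach_expression,
    overlap_peaks,
)
from tismap.config import PipelineConfig
from tismap.io_formats import (
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    revcomp,
    write_bed,
    write_sites_tsv,
)
from tismap.junctions import (
    Breakpoint,
    PlasmidEvidence,
    detect_plasmid_segments,
    extract_flanks,
    infer_breakpoint,
    map_flank,
    merge_segments,
)
from tismap.qc import filter_reads
from tismap.sites import IntegrationSite, classify_site, cluster_sites, density_map
from tismap.sites import _unit_coverage

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Machine-readable run summary with internally consistent counts."""

    config: dict
    version: str = _version
    n_reads_in: int = 0
    n_reads_kept: int = 0
    n_plasmid_bearing: int = 0
    n_flanks_extracted: int = 0
    n_flanks_anchored: int = 0
    n_breakpoints: int = 0
    n_sites: int = 0
    n_sites_full_unit: int = 0
    n_sites_fragment: int = 0
    qc: dict = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_reads_kept <= self.n_reads_in
        assert self.n_plasmid_bearing <= self.n_reads_kept
        assert self.n_flanks_anchored <= self.n_flanks_extracted
        assert self.n_breakpoints == self.n_flanks_anchored
        assert self.n_sites == self.n_sites_full_unit + self.n_sites_fragment

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def map_reads(
    reads: list[SequenceRecord],
    plasmid: SequenceRecord,
    genome_index: KmerIndex,
    config: PipelineConfig,
) -> tuple[dict[str, PlasmidEvidence], list[Breakpoint], dict[str, int]]:
    """Junction-map every read; return evidences, breakpoints and counts."""
    ka = calibrate_karlin_altschul(config.scoring)
    # fast membership pre-screen over both plasmid orientations
    screen = KmerIndex(
        [plasmid, SequenceRecord("plasmid_rc", revcomp(plasmid.sequence))],
        k=config.seed_k,
    )
    from tismap.align import _kmer_codes, encode

    evidences: dict[str, PlasmidEvidence] = {}
    breakpoints: list[Breakpoint] = []
    counts = {"plasmid_bearing": 0, "flanks": 0, "anchored": 0}
    for read in reads:
        codes, valid = _kmer_codes(encode(read.sequence), config.seed_k)
        if codes.size == 0 or not screen.any_hit(codes[valid]):
            continue
        segments = detect_plasmid_segments(read, plasmid, config, ka=ka)
        if not segments:
            continue
        counts["plasmid_bearing"] += 1
        merged = merge_segments(segments, config.merge_gap)
        ev = extract_flanks(read, merged, config.flank_len, config.min_flank_len)
        for flank in ev.flanks:
            counts["flanks"] += 1
            map_flank(flank, genome_index, config, ka=ka, read_id=read.id)
            if flank.anchor is not None:
                counts["anchored"] += 1
        evidences[read.id] = ev
        breakpoints.extend(infer_breakpoint(ev))
    return evidences, breakpoints, counts


def run_pipeline(
    config: PipelineConfig,
    reads: list[SequenceRecord],
    plasmid: SequenceRecord,
    unit_interval: tuple[int, int] | None,
    genome: list[SequenceRecord],
    genes: list[GeneModel] | None = None,
    peaks: list[GenomicInterval] | None = None,
    expression: dict[str, float] | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[IntegrationSite], pd.DataFrame, RunReport]:
    """Run the full integration-site pipeline on in-memory inputs.

    Writes ``sites.tsv``, ``sites.bed``, ``density.tsv`` and
    ``report.json`` when ``outdir`` is given.
    """
    report = RunReport(config=config.to_dict())
    report.n_reads_in = len(reads)

    kept, qc_summary = filter_reads(reads, config.qc)
    report.n_reads_kept = len(kept)
    report.qc = dataclasses.asdict(qc_summary)
    logger.info("qc: kept %d / %d reads", len(kept), len(reads))

    genome_index = KmerIndex(genome, k=config.seed_k)
    evidences, breakpoints, counts = map_reads(kept, plasmid, genome_index, config)
    report.n_plasmid_bearing = counts["plasmid_bearing"]
    report.n_flanks_extracted = counts["flanks"]
    report.n_flanks_anchored = counts["anchored"]
    report.n_breakpoints = len(breakpoints)
    logger.info("map: %d plasmid-bearing reads, %d anchored flanks",
                counts["plasmid_bearing"], counts["anchored"])

    sites = cluster_sites(breakpoints, config.cluster_window, config.min_support)
    for site in sites:
        classify_site(site, evidences, unit_interval, config.unit_cover_frac)
    report.n_sites = len(sites)
    report.n_sites_full_unit = sum(s.site_class == "full_unit" for s in sites)
    report.n_sites_fragment = sum(s.site_class == "fragment" for s in sites)
    logger.info("call: %d sites (%d full-unit, %d fragment)",
                report.n_sites, report.n_sites_full_unit, report.n_sites_fragment)

    gene_index = GeneIndex(genes) if genes else None
    for site in sites:
        if gene_index is not None:
            ann = annotate_gene_context(site.locus, gene_index)
        else:
            from tismap.annotate import SiteAnnotation
            ann = SiteAnnotation()
        if peaks is not None:
            ann.in_peak, dist = overlap_peaks(site.locus, peaks, config.peak_near_bp)
            ann.nearest_peak_distance = dist
        if expression is not None:
            attach_expression(ann, expression)
        site.annotation = ann

    chrom_lengths = {r.id: len(r) for r in genome}
    density = density_map(sites, chrom_lengths, config.density_bin)
    report.check()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sites_tsv(sites, outdir / "sites.tsv")
        write_bed(
            [s.locus for s in sites],
            outdir / "sites.bed",
            names=[f"{s.site_class}:{s.support}" for s in sites],
            scores=[s.support for s in sites],
        )
        density.to_csv(outdir / "density.tsv", sep="\t", index=False)
        report.to_json(outdir / "report.json")
    return sites, density, report


# ---------------------------------------------------------------------------
# evidence table (CLI interchange between `map` and `call`)
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "read_id", "side", "flank_start", "flank_end", "chrom", "anchor_start",
    "anchor_end", "anchor_strand", "score", "evalue", "ambiguous",
    "breakpoint", "unit_cover",
]


def evidences_to_table(
    evidences: dict[str, PlasmidEvidence],
    unit_interval: tuple[int, int] | None,
) -> pd.DataFrame:
    """One row per anchored flank, with its breakpoint and the read's
    expression-unit coverage fraction."""
    rows = []
    for ev in evidences.values():
        cover = _unit_coverage(ev, unit_interval) if unit_interval else 0.0
        bps = {(b.side, b.read_id): b for b in infer_breakpoint(ev)}
        for flank in ev.anchored_flanks:
            a = flank.anchor
            bp = bps[(flank.side, ev.read_id)]
            rows.append({
                "read_id": ev.read_id, "side": flank.side,
                "flank_start": flank.read_interval[0],
                "flank_end": flank.read_interval[1],
                "chrom": a.subject_id, "anchor_start": a.s_start,
                "anchor_end": a.s_end, "anchor_strand": a.strand,
                "score": a.score, "evalue": a.evalue,
                "ambiguous": int(flank.ambiguous),
                "breakpoint": bp.position, "unit_cover": round(cover, 6),
            })
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def call_from_table(df: pd.DataFrame, config: PipelineConfig) -> list[IntegrationSite]:
    """Cluster and classify sites from an evidence table (CLI path)."""
    breakpoints = [
        Breakpoint(
            locus=GenomicInterval(row.chrom, int(row.breakpoint), int(row.breakpoint) + 1),
            side=row.side, strand=row.anchor_strand, read_id=row.read_id,
        )
        for row in df.itertuples()
    ]
    cover = dict(zip(df["read_id"], df["unit_cover"]))
    ambiguous = df.groupby("read_id")["ambiguous"].max().to_dict()
    sites = cluster_sites(breakpoints, config.cluster_window, config.min_support)
    for site in sites:
        classes = set()
        amb = False
        for rid in site.contributing_read_ids:
            if cover.get(rid, 0.0) >= config.unit_cover_frac:
                classes.add("full_unit")
            else:
                classes.add("fragment")
            amb = amb or bool(ambiguous.get(rid, 0))
        site.classes_present = classes or {"fragment"}
        site.site_class = "full_unit" if "full_unit" in classes else "fragment"
        site.ambiguous = amb
    return sites


def compare_site_lists(
    a: list[IntegrationSite],
    b: list[IntegrationSite],
    window: int = 100,
) -> dict[str, int]:
    """Union / intersection of two site lists within a matching window.

    The study sequenced two clonal lines separately; this reports how their
    candidate lists relate without deciding how they should be combined.
    """
    matched = 0
    for s in a:
        if any(t.locus.chrom == s.locus.chrom and abs(t.locus.start - s.locus.start) <= window
               for t in b):
            matched += 1
    return {
        "a_total": len(a),
        "b_total": len(b),
        "intersection": matched,
        "union": len(a) + len(b) - matched,
    }
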