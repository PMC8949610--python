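"""Genomic-context annotation of integration sites.

Each site (a single-base locus) is placed in exon / intron / intergenic
space with priority exon > intron, linked to its host gene, optionally to a
user-supplied expression value for that gene, and tested for overlap with
(or proximity to) accessibility peaks such as ATAC-seq intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from tismap.io_formats import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

UNBOUNDED = -1  # sentinel distance when no peak exists on the chromosome


@dataclass
class SiteAnnotation:
    """Context, host gene, expression and peak proximity for one site."""

    context: str = "intergenic"  # {intergenic, intron, exon}
    host_gene: str | None = None
    host_gene_expression: float | None = None
    in_peak: bool = False
    nearest_peak_distance: int | None = None  # UNBOUNDED when no peaks given

    def __post_init__(self) -> None:
        if self.context not in ("intergenic", "intron", "exon"):
            raise ValueError(f"invalid context {self.context!r}")
        if (self.host_gene is not None) != (self.context != "intergenic"):
            raise ValueError("host_gene is set iff context is not intergenic")


class GeneIndex:
    """Interval trees over gene spans and exons, per chromosome."""

    def __init__(self, gene_models: list[GeneModel]):
        self.span_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        for gm in gene_models:
            self.span_trees.setdefault(gm.span.chrom, IntervalTree()).addi(
                gm.span.start, gm.span.end, gm
            )
            for exon in gm.exons:
                self.exon_trees.setdefault(exon.chrom, IntervalTree()).addi(
                    exon.start, exon.end, gm
                )


def annotate_gene_context(
    site_locus: GenomicInterval,
    genes: list[GeneModel] | GeneIndex,
) -> SiteAnnotation:
    """Exon / intron / intergenic context of a single-base site.

    Priority exon > intron; among several overlapping genes the first by
    coordinate (then by id) wins.  UTRs, when present in the input GFF, were
    already folded into exons on read.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    pos = site_locus.start
    chrom = site_locus.chrom

    def first_gene(tree: IntervalTree | None) -> GeneModel | None:
        if tree is None:
            return None
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return None
        hits.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))
        return hits[0]

    gene = first_gene(index.exon_trees.get(chrom))
    if gene is not None:
        return SiteAnnotation(context="exon", host_gene=gene.gene_id)
    gene = first_gene(index.span_trees.get(chrom))
    if gene is not None:
        return SiteAnnotation(context="intron", host_gene=gene.gene_id)
    return SiteAnnotation(context="intergenic")


def overlap_peaks(
    site_locus: GenomicInterval,
    peaks: list[GenomicInterval],
    near_bp: int = 1000,
) -> tuple[bool, int]:
    """(in_peak, distance) of a site against accessibility peaks.

    ``in_peak`` is true when the site lies inside a peak (distance 0) or
    within ``near_bp`` of a peak edge.  With no peak on the chromosome the
    distance is the UNBOUNDED sentinel (-1) and in_peak is false.
    """
    pos = site_locus.start
    chrom_peaks = [p for p in peaks if p.chrom == site_locus.chrom]
    if not chrom_peaks:
        return False, UNBOUNDED
    starts = np.array([p.start for p in chrom_peaks])
    ends = np.array([p.end for p in chrom_peaks])
    inside = (starts <= pos) & (pos < ends)
    if inside.any():
        return True, 0
    dist = int(np.minimum(np.abs(starts - pos), np.abs(ends - 1 - pos)).min())
    return dist <= near_bp, dist


def attach_expression(
    annotation: SiteAnnotation,
    expression_table: dict[str, float],
) -> SiteAnnotation:
    """Copy the host gene's expression value onto the annotation.

    Intergenic sites keep no value; genes missing from the table log a
    warning and leave the field unset.
    """
    if annotation.host_gene is None:
        return annotation
    value = expression_table.get(annotation.host_gene)
    if value is None:
        logger.warning("gene %s absent from expression table", annotation.host_gene)
    else:
        annotation.host_gene_expression = float(value)
    return annotation


def read_expression_table(path) -> dict[str, float]:
    """Two-column TSV (gene_id, value) -> dict."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                table[fields[0]] = float(fields[1])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise
    return table
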