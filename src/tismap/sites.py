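"""Breakpoint clustering, site classification and density summaries.

Per-read breakpoints are clustered by single-linkage along each chromosome
(default window 100 bp); each cluster becomes an integration site located at
the median member coordinate.  A site is classified ``full_unit`` when at
least one supporting read carries plasmid segments covering >= 90% of the
annotated expression unit, otherwise ``fragment`` — the distinction between
a functional insertion and scattered plasmid debris.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from tismap.io_formats import GenomicInterval

if TYPE_CHECKING:
    from tismap.annotate import SiteAnnotation
    from tismap.junctions import Breakpoint, PlasmidEvidence

logger = logging.getLogger(__name__)


@dataclass
class IntegrationSite:
    """A clustered genomic integration locus."""

    locus: GenomicInterval  # single-base
    support: int
    contributing_read_ids: list[str]
    site_class: str = "fragment"
    classes_present: set[str] = field(default_factory=set)
    ambiguous: bool = False
    left_junction: int | None = None   # smallest member breakpoint (0-based)
    right_junction: int | None = None  # largest member breakpoint (0-based)
    n_breakpoints: int = 0
    annotation: "SiteAnnotation | None" = None

    def __post_init__(self) -> None:
        if self.support != len(self.contributing_read_ids):
            raise ValueError("support must equal the number of contributing reads")


def cluster_sites(
    breakpoints: list["Breakpoint"],
    cluster_window: int = 100,
    min_support: int = 1,
) -> list[IntegrationSite]:
    """Single-linkage clustering of breakpoints along each chromosome.

    Breakpoints within ``cluster_window`` bp of the previous one (sorted)
    join the same cluster.  The site locus is the median member coordinate
    (even counts take the smaller middle).  Support counts distinct reads;
    clusters with fewer supporting reads than ``min_support`` are dropped.
    """
    by_chrom: dict[str, list["Breakpoint"]] = {}
    for bp in breakpoints:
        by_chrom.setdefault(bp.locus.chrom, []).append(bp)
    sites: list[IntegrationSite] = []
    for chrom in sorted(by_chrom):
        bps = sorted(by_chrom[chrom], key=lambda b: (b.position, b.read_id, b.side))
        cluster: list["Breakpoint"] = []

        def flush() -> None:
            if not cluster:
                return
            positions = sorted(b.position for b in cluster)
            k = len(positions)
            median = positions[(k - 1) // 2]  # lower middle on even counts
            reads = sorted({b.read_id for b in cluster})
            if len(reads) < min_support:
                return
            sites.append(
                IntegrationSite(
                    locus=GenomicInterval(chrom, median, median + 1),
                    support=len(reads),
                    contributing_read_ids=reads,
                    left_junction=positions[0],
                    right_junction=positions[-1],
                    n_breakpoints=k,
                )
            )

        for bp in bps:
            if cluster and bp.position - cluster[-1].position > cluster_window:
                flush()
                cluster = []
            cluster.append(bp)
        flush()
    sites.sort(key=lambda s: (s.locus.chrom, s.locus.start))
    return sites


def _unit_coverage(evidence: "PlasmidEvidence", unit: tuple[int, int]) -> float:
    """Fraction of the expression-unit interval covered by a read's segments."""
    u0, u1 = unit
    if u1 <= u0:
        raise ValueError("empty unit interval")
    ivals = sorted(
        (max(u0, s.plasmid_interval[0]), min(u1, s.plasmid_interval[1]))
        for s in evidence.segments
    )
    covered = 0
    cursor = u0
    for a, b in ivals:
        if b <= cursor:
            continue
        covered += b - max(a, cursor)
        cursor = b
    return covered / (u1 - u0)


def classify_site(
    site: IntegrationSite,
    evidences: dict[str, "PlasmidEvidence"],
    unit_interval: tuple[int, int] | None,
    unit_cover_frac: float = 0.9,
) -> IntegrationSite:
    """Set site_class from the plasmid content of the supporting reads.

    A read is unit-bearing when its merged plasmid segments cover at least
    ``unit_cover_frac`` of the expression unit.  A site with any
    unit-bearing read is ``full_unit`` (classes_present still records any
    fragment reads); with no unit annotation everything is ``fragment``.
    Ambiguity of any supporting flank anchor propagates to the site.
    """
    classes: set[str] = set()
    ambiguous = False
    for read_id in site.contributing_read_ids:
        ev = evidences.get(read_id)
        if ev is None:
            continue
        if any(f.ambiguous for f in ev.flanks):
            ambiguous = True
        if unit_interval is not None and _unit_coverage(ev, unit_interval) >= unit_cover_frac:
            classes.add("full_unit")
        else:
            classes.add("fragment")
    if unit_interval is None:
        logger.warning("no expression-unit annotation: site %s:%d classified fragment",
                       site.locus.chrom, site.locus.pos1)
    site.classes_present = classes or {"fragment"}
    site.site_class = "full_unit" if "full_unit" in classes else "fragment"
    site.ambiguous = ambiguous
    return site


def density_map(
    sites: list[IntegrationSite],
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Binned site counts per chromosome, one track per site class.

    Returns a tidy frame with columns chrom, bin_start, bin_end, full_unit,
    fragment, total over half-open bins.  Counts are conserved: the grand
    total equals the number of sites.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bins = max(1, -(-length // bin_size))
        counts = {cls: np.zeros(n_bins, dtype=int) for cls in ("full_unit", "fragment")}
        for site in sites:
            if site.locus.chrom != chrom:
                continue
            if site.locus.start >= length:
                raise ValueError(
                    f"site {chrom}:{site.locus.pos1} beyond chromosome length {length}"
                )
            counts[site.site_class][site.locus.start // bin_size] += 1
        for b in range(n_bins):
            rows.append({
                "chrom": chrom,
                "bin_start": b * bin_size,
                "bin_end": min((b + 1) * bin_size, length),
                "full_unit": counts["full_unit"][b],
                "fragment": counts["fragment"][b],
            })
    df = pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "full_unit", "fragment"])
    df["total"] = df["full_unit"] + df["fragment"]
    unknown = {s.locus.chrom for s in sites} - set(chrom_lengths)
    if unknown:
        raise ValueError(f"sites on chromosomes without lengths: {sorted(unknown)}")
    return df


def plot_density(df: pd.DataFrame, path) -> None:
    """Optional per-chromosome density plot (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(df["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = df[df["chrom"] == chrom]
        ax.bar(sub["bin_start"], sub["fragment"], width=sub["bin_end"] - sub["bin_start"],
               align="edge", label="fragment", color="#888888")
        ax.bar(sub["bin_start"], sub["full_unit"], width=sub["bin_end"] - sub["bin_start"],
               align="edge", label="full unit", color="#c03030",
               bottom=sub["fragment"])
        ax.set_ylabel(chrom)
    axes[0, 0].legend()
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
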