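"""Clustering, classification and density-map conservation properties."""

import numpy as np
import pytest

from tismap.io_formats import GenomicInterval
from tismap.junctions import Breakpoint, PlasmidEvidence, PlasmidSegment
from tismap.sites import classify_site, cluster_sites, density_map


def _bp(chrom, pos, read_id, side="upstream"):
    return Breakpoint(GenomicInterval(chrom, pos, pos + 1), side, "+", read_id)


def test_single_breakpoint_single_site():
    (site,) = cluster_sites([_bp("chr1", 1000, "r1")])
    assert site.locus.start == 1000
    assert site.support == 1
    assert site.contributing_read_ids == ["r1"]


def test_jittered_breakpoints_collapse_to_one_site(rng):
    truth = 50_000
    bps = [_bp("chr1", truth + int(j), f"r{i}")
           for i, j in enumerate(rng.integers(-10, 11, 10))]
    (site,) = cluster_sites(bps, cluster_window=100)
    assert abs(site.locus.start - truth) <= 10
    assert site.support == 10
    assert site.left_junction <= site.locus.start <= site.right_junction


def test_distant_clusters_stay_separate():
    bps = [_bp("chr1", 10_000 + j, f"a{j}") for j in range(3)] + \
          [_bp("chr1", 20_000 + j, f"b{j}") for j in range(3)]
    sites = cluster_sites(bps, cluster_window=100)
    assert len(sites) == 2
    assert [s.locus.start for s in sites] == [10_001, 20_001]  # median of 3


def test_median_takes_lower_middle_on_even_counts():
    bps = [_bp("chr1", p, f"r{p}") for p in (100, 104, 108, 120)]
    (site,) = cluster_sites(bps)
    assert site.locus.start == 104


def test_support_counts_distinct_reads_not_breakpoints():
    bps = [_bp("chr1", 1000, "r1", "upstream"), _bp("chr1", 1001, "r1", "downstream"),
           _bp("chr1", 1002, "r2")]
    (site,) = cluster_sites(bps)
    assert site.support == 2
    assert site.n_breakpoints == 3


def test_min_support_drops_thin_clusters():
    bps = [_bp("chr1", 1000, "r1"), _bp("chr1", 50_000, "a"), _bp("chr1", 50_010, "b"),
           _bp("chr1", 50_020, "c")]
    sites = cluster_sites(bps, min_support=3)
    assert len(sites) == 1
    assert sites[0].locus.start == 50_010


def test_every_breakpoint_lands_in_exactly_one_cluster(rng):
    bps = [_bp(f"chr{int(c)}", int(p), f"r{i}")
           for i, (c, p) in enumerate(zip(rng.integers(1, 4, 300),
                                          rng.integers(0, 200_000, 300)))]
    sites = cluster_sites(bps, cluster_window=100, min_support=1)
    assert sum(s.n_breakpoints for s in sites) == len(bps)


def test_clustering_is_deterministic(rng):
    bps = [_bp("chr1", int(p), f"r{i}") for i, p in enumerate(rng.integers(0, 100_000, 200))]
    a = cluster_sites(list(bps))
    b = cluster_sites(list(reversed(bps)))
    assert [(s.locus.start, s.support, tuple(s.contributing_read_ids)) for s in a] == \
        [(s.locus.start, s.support, tuple(s.contributing_read_ids)) for s in b]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _evidence(read_id, plasmid_ivs):
    ev = PlasmidEvidence(read_id, 10_000)
    for iv in plasmid_ivs:
        ev.segments.append(PlasmidSegment((0, iv[1] - iv[0]), iv, "+", 100, 1e-40, 0.99))
    return ev


def test_full_unit_coverage_classifies_full_unit():
    (site,) = cluster_sites([_bp("chr1", 100, "r1")])
    classify_site(site, {"r1": _evidence("r1", [(1400, 3600)])}, (1500, 3500))
    assert site.site_class == "full_unit"
    assert site.classes_present == {"full_unit"}


def test_backbone_only_read_is_fragment():
    (site,) = cluster_sites([_bp("chr1", 100, "r1")])
    classify_site(site, {"r1": _evidence("r1", [(0, 1200)])}, (1500, 3500))
    assert site.site_class == "fragment"


def test_partial_unit_coverage_below_threshold_is_fragment():
    (site,) = cluster_sites([_bp("chr1", 100, "r1")])
    # 1500 of 2000 unit bases covered = 75% < 90%
    classify_site(site, {"r1": _evidence("r1", [(1500, 3000)])}, (1500, 3500))
    assert site.site_class == "fragment"


def test_split_segments_sum_their_unit_coverage():
    (site,) = cluster_sites([_bp("chr1", 100, "r1")])
    ev = _evidence("r1", [(1500, 2500), (2550, 3500)])  # 1950/2000 = 97.5%
    classify_site(site, {"r1": ev}, (1500, 3500))
    assert site.site_class == "full_unit"


def test_mixed_support_reports_full_unit_with_both_classes():
    bps = [_bp("chr1", 100, "r1"), _bp("chr1", 105, "r2")]
    (site,) = cluster_sites(bps)
    evs = {"r1": _evidence("r1", [(1400, 3600)]), "r2": _evidence("r2", [(0, 500)])}
    classify_site(site, evs, (1500, 3500))
    assert site.site_class == "full_unit"
    assert site.classes_present == {"full_unit", "fragment"}


def test_missing_unit_annotation_warns_and_defaults_to_fragment(caplog):
    (site,) = cluster_sites([_bp("chr1", 100, "r1")])
    classify_site(site, {"r1": _evidence("r1", [(1400, 3600)])}, None)
    assert site.site_class == "fragment"
    assert "unit" in caplog.text


# ---------------------------------------------------------------------------
# density map
# ---------------------------------------------------------------------------

CHROMS = {"chr1": 1_000_000, "chr2": 800_000}


def _site(chrom, pos, klass):
    from tismap.sites import IntegrationSite

    return IntegrationSite(GenomicInterval(chrom, pos, pos + 1), 1, ["r"], site_class=klass)


def test_empty_density_is_all_zero():
    df = density_map([], CHROMS, bin_size=100_000)
    assert df["total"].sum() == 0
    assert len(df) == 10 + 8


def test_density_conserves_site_counts(rng):
    sites = [_site("chr1", int(p), "fragment") for p in rng.integers(0, 1_000_000, 5)] + \
            [_site("chr2", int(p), "full_unit") for p in rng.integers(0, 800_000, 3)]
    df = density_map(sites, CHROMS)
    assert df["total"].sum() == 8
    assert df["fragment"].sum() == 5
    assert df["full_unit"].sum() == 3


def test_density_tracks_separate_classes_by_chromosome():
    sites = [_site("chr1", 10, "full_unit"), _site("chr1", 500_000, "fragment"),
             _site("chr2", 10, "fragment")]
    df = density_map(sites, CHROMS)
    assert df.loc[df.chrom == "chr2", "full_unit"].sum() == 0
    assert df.loc[df.chrom == "chr1", "full_unit"].sum() == 1
    assert df.loc[df.chrom == "chr2", "fragment"].sum() == 1


def test_site_beyond_chromosome_end_raises():
    with pytest.raises(ValueError, match="beyond"):
        density_map([_site("chr2", 900_000, "fragment")], CHROMS)
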