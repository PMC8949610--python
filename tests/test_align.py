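"""Aligner correctness: oracle properties, engine-vs-oracle, E-value statistics."""

import math

import numpy as np
import pytest

from tismap.align import (
    KmerIndex,
    calibrate_karlin_altschul,
    evalue,
    seed_and_extend,
    smith_waterman_oracle,
)
from tismap.config import ScoringScheme
from tismap.io_formats import SequenceRecord, revcomp

DEFAULT = ScoringScheme()


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, s, identity):
    out = []
    for c in s:
        r = rng.random()
        if r < identity:
            out.append(c)
        elif r < identity + (1 - identity) * 0.8:
            out.append(rng.choice([x for x in "ACGT" if x != c]))
        elif r < identity + (1 - identity) * 0.9:
            continue
        else:
            out.extend([c, rng.choice(list("ACGT"))])
    return "".join(out)


def _planted_pair(rng, max_len=300, min_core=80, identity=0.88):
    """Random pair sharing one homologous segment with >=1 exact 11-mer."""
    while True:
        core = _rand(rng, int(rng.integers(min_core, 200)))
        hom = _mutate(rng, core, identity)
        a = (_rand(rng, int(rng.integers(0, 60))) + core
             + _rand(rng, int(rng.integers(0, 60))))[:max_len]
        b = (_rand(rng, int(rng.integers(0, 60))) + hom
             + _rand(rng, int(rng.integers(0, 60))))[:max_len]
        kmers = {a[i:i + 11] for i in range(len(a) - 10)}
        if any(b[i:i + 11] in kmers for i in range(len(b) - 10)):
            return a, b


# ---------------------------------------------------------------------------
# Smith–Waterman oracle
# ---------------------------------------------------------------------------

def test_oracle_self_alignment_is_perfect(rng):
    s = _rand(rng, 50)
    aln = smith_waterman_oracle(s, s)
    assert aln.score == 100  # 50 matches x +2
    assert (aln.q_start, aln.q_end) == (0, 50)
    assert aln.identity == 1.0
    assert aln.ops == [("=", 50)]


def test_oracle_reports_no_alignment_for_disjoint_composition():
    assert smith_waterman_oracle("AAAAAAAA", "CCCCCCCC") is None


def test_oracle_size_guard():
    with pytest.raises(ValueError, match="seed_and_extend"):
        smith_waterman_oracle("A" * 4000, "C" * 4000)


def test_oracle_score_bounds_every_ungapped_pairing(rng):
    """SW >= the best ungapped substring score, enumerated exhaustively."""
    for _ in range(100):
        a = _rand(rng, int(rng.integers(30, 300)))
        b = _rand(rng, int(rng.integers(30, 300)))
        aln = smith_waterman_oracle(a, b)
        sw = aln.score if aln else 0
        ac = np.frombuffer(a.encode(), np.uint8)
        bc = np.frombuffer(b.encode(), np.uint8)
        best_ungapped = 0
        for d in range(-(len(a) - 1), len(b)):
            i0, j0 = (0, d) if d >= 0 else (-d, 0)
            n = min(len(a) - i0, len(b) - j0)
            s = np.where(ac[i0:i0 + n] == bc[j0:j0 + n], 2, -3)
            cs = np.concatenate(([0], np.cumsum(s)))
            seg = (cs[1:] - np.minimum.accumulate(cs[:-1])).max()
            best_ungapped = max(best_ungapped, int(seg))
        assert sw >= best_ungapped


def test_oracle_agrees_with_biopython_pairwise_aligner(rng):
    """Independent library cross-check of the oracle's optimal scores."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7  # first gap base: open 5 + extend 2
    aligner.extend_gap_score = -2
    for _ in range(30):
        a, b = _planted_pair(rng, identity=0.9)
        mine = smith_waterman_oracle(a, b)
        assert mine.score == int(aligner.score(a, b))
        assert mine.score == mine.rescore(DEFAULT)


# ---------------------------------------------------------------------------
# seed-and-extend engine
# ---------------------------------------------------------------------------

def test_exact_substring_recovers_full_query(rng):
    genome = _rand(rng, 10_000)
    query = genome[3000:5000]
    (hit,) = seed_and_extend(SequenceRecord("q", query), SequenceRecord("s", genome))
    assert (hit.q_start, hit.q_end) == (0, 2000)
    assert (hit.s_start, hit.s_end) == (3000, 5000)
    assert hit.strand == "+"
    assert hit.identity == 1.0
    assert hit.score == 4000


def test_reverse_complement_query_flips_strand_same_score(rng):
    genome = _rand(rng, 10_000)
    query = genome[3000:5000]
    (fwd,) = seed_and_extend(SequenceRecord("q", query), SequenceRecord("s", genome))
    (rev,) = seed_and_extend(SequenceRecord("q", revcomp(query)), SequenceRecord("s", genome))
    assert rev.strand == "-"
    assert rev.score == fwd.score
    assert (rev.s_start, rev.s_end) == (fwd.s_start, fwd.s_end)


def test_engine_matches_oracle_on_planted_homologies(rng):
    agree = 0
    for _ in range(50):
        a, b = _planted_pair(rng)
        oracle = smith_waterman_oracle(a, b)
        hits = seed_and_extend(SequenceRecord("q", a), SequenceRecord("s", b))
        if hits and hits[0].score == oracle.score:
            agree += 1
    assert agree >= 49


def test_every_hit_rescores_to_its_stored_score(rng):
    for _ in range(20):
        a, b = _planted_pair(rng, identity=0.85)
        for hit in seed_and_extend(SequenceRecord("q", a), SequenceRecord("s", b)):
            assert hit.rescore(DEFAULT) == hit.score
            assert 0 <= hit.identity <= 1


def test_query_shorter_than_seed_yields_nothing(rng):
    hits = seed_and_extend(SequenceRecord("q", "ACGTACGT"), SequenceRecord("s", _rand(rng, 1000)))
    assert hits == []


def test_hits_do_not_overlap_by_more_than_half_on_query(rng):
    genome = _rand(rng, 20_000)
    # query = two copies of the same genome stretch: two valid placements
    query = genome[2000:3000] + genome[9000:9800]
    hits = seed_and_extend(SequenceRecord("q", query), SequenceRecord("s", genome))
    assert len(hits) >= 2
    for i, h in enumerate(hits):
        for g in hits[i + 1:]:
            ov = min(h.q_end, g.q_end) - max(h.q_start, g.q_start)
            assert ov <= 0.5 * min(h.q_len, g.q_len)


def test_multi_sequence_index_maps_hits_to_the_right_contig(rng):
    chroms = [SequenceRecord(f"c{i}", _rand(rng, 5000)) for i in range(3)]
    index = KmerIndex(chroms, k=11)
    query = chroms[2].sequence[1000:2500]
    (hit,) = seed_and_extend(SequenceRecord("q", query), index)
    assert hit.subject_id == "c2"
    assert (hit.s_start, hit.s_end) == (1000, 2500)


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------

def test_lambda_closed_form_plus_one_minus_one():
    ka = calibrate_karlin_altschul(ScoringScheme(1, -1, 5, 2))
    assert ka.lam == pytest.approx(math.log(3), abs=1e-6)


def test_lambda_scale_invariance():
    base = calibrate_karlin_altschul(ScoringScheme(1, -1, 5, 2))
    doubled = calibrate_karlin_altschul(ScoringScheme(2, -2, 5, 2))
    assert doubled.lam == pytest.approx(base.lam / 2, rel=1e-9)


def test_default_scheme_parameter_ranges():
    ka = calibrate_karlin_altschul(DEFAULT)
    assert 0 < ka.lam < 2
    assert 0 < ka.K < 1


def test_karlin_altschul_matches_blast_published_values():
    # ungapped nucleotide (lambda, K) as printed by BLAST for these schemes
    for scheme, lam, K in [
        (ScoringScheme(1, -1, 5, 2), 1.10, 0.333),
        (ScoringScheme(2, -3, 5, 2), 0.634, 0.408),
        (ScoringScheme(1, -2, 5, 2), 1.33, 0.621),
    ]:
        ka = calibrate_karlin_altschul(scheme)
        assert ka.lam == pytest.approx(lam, abs=0.005)
        assert ka.K == pytest.approx(K, rel=0.02)


def test_invalid_scheme_rejected():
    with pytest.raises(ValueError, match="negative"):
        ScoringScheme(3, -1, 5, 2)  # expected score positive under uniform bg


def test_evalue_formula_and_monotonicity():
    ka = calibrate_karlin_altschul(ScoringScheme(1, -1, 5, 2))
    assert evalue(0, 100, 200, ka) == pytest.approx(ka.K * 100 * 200)
    assert evalue(10, 100, 400, ka) == pytest.approx(2 * evalue(10, 100, 200, ka))
    scores = [evalue(s, 1000, 1000, ka) for s in range(0, 60, 5)]
    assert all(a > b for a, b in zip(scores, scores[1:]))  # decreasing in score
    assert evalue(30, 2000, 1000, ka) > evalue(30, 1000, 1000, ka)


def test_evalue_hand_computed_case():
    # lambda = ln 3, K = 0.35, m = n = 1000, score 50
    from tismap.align import KarlinAltschulParams

    params = KarlinAltschulParams(lam=1.0986122886681098, K=0.35, H=0.55)
    assert evalue(50, 1000, 1000, params) == pytest.approx(4.87e-19, rel=5e-3)
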