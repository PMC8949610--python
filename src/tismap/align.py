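"""Local alignment: seed-and-extend engine with Karlin–Altschul statistics.

The engine replaces an external BLASTN call with an in-package
implementation: exact k-mer seeds (default k=11) against an indexed subject,
greedy chaining of seeds on nearby diagonals, banded affine-gap extension
with X-drop termination, and E-values from ungapped Karlin–Altschul
statistics calibrated to the scoring scheme,

    E = K * m * n * exp(-lambda * S).

A full Smith–Waterman (Gotoh) implementation with deterministic traceback is
provided as a testing oracle for the engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from tismap._dp import (
    OP_DIAG,
    OP_LEFT,
    OP_UP,
    extend_xdrop,
    extend_xdrop_score,
    sw_traceback,
)
from tismap.config import ScoringScheme
from tismap.io_formats import SequenceRecord, revcomp

logger = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

SW_CELL_GUARD = 10**7


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Ungapped local-alignment statistics for a scoring scheme.

    ``lam`` (nats per score unit) solves sum_ij p_i p_j exp(lam*s_ij) = 1;
    ``K`` comes from the classical lattice series approximation (see
    :func:`calibrate_karlin_altschul`).
    """

    lam: float
    K: float
    H: float  # relative entropy, nats per aligned pair


@dataclass
class LocalAlignment:
    """One local alignment hit (an HSP).

    Coordinates are 0-based half-open on the forward strands of both
    sequences.  ``strand`` is the subject orientation of the match: '-'
    means the reverse complement of the query interval aligns to the
    forward subject interval.  ``ops`` is a run-length op list over
    ('=', 'X', 'I', 'D') in subject-forward order, where 'I' consumes query
    only and 'D' consumes subject only.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    evalue: float
    identity: float
    ops: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("alignment intervals must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.ops)

    def rescore(self, scoring: ScoringScheme) -> int:
        """Score implied by the op list (must equal ``score``)."""
        total = 0
        for op, n in self.ops:
            if op == "=":
                total += scoring.match * n
            elif op == "X":
                total += scoring.mismatch * n
            else:
                total -= scoring.gap_open + scoring.gap_extend * n
        return total


# ---------------------------------------------------------------------------
# Karlin–Altschul calibration
# ---------------------------------------------------------------------------

def _score_pmf(scoring: ScoringScheme, background: tuple[float, ...]):
    """(values, probabilities) of the per-pair score under the background."""
    p = np.asarray(background, dtype=float)
    p_match = float(np.sum(p * p))
    return (
        np.array([scoring.mismatch, scoring.match], dtype=np.int64),
        np.array([1.0 - p_match, p_match]),
    )


@lru_cache(maxsize=32)
def calibrate_karlin_altschul(
    scoring: ScoringScheme = ScoringScheme(),
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> KarlinAltschulParams:
    """Solve for lambda and K of ungapped local-alignment statistics.

    lambda is found by bisection on ``sum_s P(s) exp(lambda*s) = 1`` over
    (0, 10] to 1e-12.  K uses the classical lattice-variable series: with
    S_k the k-step score-sum distribution, delta the score lattice span and
    H the relative entropy,

        sigma = sum_k (1/k) * [ P(S_k >= 0) + E(exp(lambda*S_k); S_k < 0) ]
        K     = delta * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*delta)))

    truncated when terms fall below 1e-12.  This is the ungapped K; it is
    applied to gapped scores as well, a documented simplification adequate
    for a pass/fail gate spanning many orders of magnitude.
    """
    values, probs = _score_pmf(scoring, background)
    expected = float(np.sum(values * probs))
    if expected >= 0:
        raise ValueError("scoring scheme invalid for local statistics "
                         "(non-negative expected score)")

    def f(lam: float) -> float:
        return float(np.sum(probs * np.exp(lam * values))) - 1.0

    lo, hi = 1e-12, 10.0
    if f(hi) < 0:
        raise ValueError("no lambda root in (0, 10]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-13:
            break
    lam = 0.5 * (lo + hi)

    H = float(lam * np.sum(values * probs * np.exp(lam * values)))

    # lattice span of the step-score support (gcd of attainable scores)
    delta = int(np.gcd.reduce(np.abs(values)))
    if delta == 0:
        delta = 1

    # series over k-step sums via convolution on the integer lattice
    vmin, vmax = int(values.min()), int(values.max())
    base = np.zeros(vmax - vmin + 1)
    for v, p in zip(values, probs):
        base[int(v) - vmin] += p
    pmf = base.copy()
    offset = vmin  # pmf[i] = P(S_k = offset + i)
    sigma = 0.0
    for k in range(1, 400):
        idx = np.arange(pmf.size) + offset
        pos = float(pmf[idx >= 0].sum())
        neg = float(np.sum(pmf[idx < 0] * np.exp(lam * idx[idx < 0])))
        term = (pos + neg) / k
        sigma += term
        if term < 1e-12 and k > 10:
            break
        pmf = np.convolve(pmf, base)
        offset += vmin
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return KarlinAltschulParams(lam=lam, K=K, H=H)


def evalue(score: int, m: int, n: int, params: KarlinAltschulParams) -> float:
    """E-value of an alignment score in an m x n search space.

    Search-space lengths are raw sequence lengths (no edge-effect
    correction).
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    return params.K * m * n * math.exp(-params.lam * score)


# ---------------------------------------------------------------------------
# Smith–Waterman oracle
# ---------------------------------------------------------------------------

def _ops_from_codes(codes: np.ndarray, a: np.ndarray, b: np.ndarray,
                    a_start: int, b_start: int) -> tuple[list[tuple[str, int]], int]:
    """Expand traceback op codes into a run-length ('=','X','I','D') list.

    Returns (ops, n_identical).  `a` is the query axis (OP_UP consumes a).
    """
    ops: list[tuple[str, int]] = []
    i, j = a_start, b_start
    n_eq = 0
    for code in codes:
        if code == OP_DIAG:
            sym = "=" if (a[i] == b[j] and a[i] < 4) else "X"
            i += 1
            j += 1
            if sym == "=":
                n_eq += 1
        elif code == OP_UP:
            sym = "I"
            i += 1
        else:
            sym = "D"
            j += 1
        if ops and ops[-1][0] == sym:
            ops[-1] = (sym, ops[-1][1] + 1)
        else:
            ops.append((sym, 1))
    return ops, n_eq


def smith_waterman_oracle(
    a: str | SequenceRecord,
    b: str | SequenceRecord,
    scoring: ScoringScheme = ScoringScheme(),
) -> LocalAlignment | None:
    """Optimal local alignment by full Gotoh DP (testing oracle).

    Returns None when no alignment scores >= 1.  Guarded to
    len(a)*len(b) <= 1e7 cells; use the seed-and-extend engine beyond that.
    Deterministic: first-best cell in row-major order, traceback ties
    diagonal > up > left.
    """
    a_id = a.id if isinstance(a, SequenceRecord) else "a"
    b_id = b.id if isinstance(b, SequenceRecord) else "b"
    a_seq = a.sequence if isinstance(a, SequenceRecord) else a
    b_seq = b.sequence if isinstance(b, SequenceRecord) else b
    if len(a_seq) * len(b_seq) > SW_CELL_GUARD:
        raise ValueError(
            "sequence pair exceeds the Smith-Waterman size guard "
            f"({len(a_seq)}x{len(b_seq)} cells); use seed_and_extend"
        )
    ac, bc = encode(a_seq), encode(b_seq)
    score, a0, a1, b0, b1, codes = sw_traceback(
        ac, bc, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score < 1:
        return None
    ops, n_eq = _ops_from_codes(codes, ac, bc, a0, b0)
    ncols = sum(n for _, n in ops)
    return LocalAlignment(
        query_id=a_id, subject_id=b_id,
        q_start=a0, q_end=a1, s_start=b0, s_end=b1,
        strand="+", score=score, evalue=math.nan,
        identity=n_eq / ncols, ops=ops,
    )


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(packed k-mer codes, validity mask) for every k-window of `codes`."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    val = np.zeros(n, np.uint64)
    for off in range(k):
        val = val * np.uint64(4) + codes[off:off + n].astype(np.uint64)
    inv = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(inv)))
    valid = (cs[k:] - cs[:-k]) == 0
    return val, valid


class KmerIndex:
    """Exact k-mer index over one or more subject sequences.

    Sequences are concatenated with runs of N long enough that neither
    seeding nor X-drop extension can cross a boundary; positions map back to
    (sequence name, local coordinate).
    """

    SEP = 64  # separator length; 64 * |mismatch| far exceeds any x_drop in use

    def __init__(self, sequences: Sequence[SequenceRecord], k: int = 11):
        if k < 4 or k > 31:
            raise ValueError("seed k must be in [4, 31]")
        self.k = k
        self.names = [s.id for s in sequences]
        self.lengths = {s.id: len(s) for s in sequences}
        sep = np.full(self.SEP, 4, np.uint8)
        parts = []
        self.offsets = np.zeros(len(sequences) + 1, np.int64)
        pos = 0
        for i, s in enumerate(sequences):
            self.offsets[i] = pos
            parts.append(encode(s.sequence))
            pos += len(s)
            if i != len(sequences) - 1:
                parts.append(sep)
                pos += self.SEP
        self.offsets[-1] = pos
        self.codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        kmers, valid = _kmer_codes(self.codes, k)
        positions = np.nonzero(valid)[0]
        packed = kmers[positions]
        order = np.argsort(packed, kind="stable")
        self._sorted = packed[order]
        self._pos = positions[order]

    @property
    def total_length(self) -> int:
        """Total subject length (sum of sequence lengths, no separators)."""
        return int(sum(self.lengths.values()))

    def lookup(self, code: np.uint64, max_occ: int = 64) -> np.ndarray:
        lo = np.searchsorted(self._sorted, code, "left")
        hi = np.searchsorted(self._sorted, code, "right")
        if hi - lo > max_occ:
            return np.empty(0, np.int64)
        return self._pos[lo:hi]

    def lookup_many(self, codes: np.ndarray, max_occ: int = 64):
        """Yield (index into `codes`, global subject positions) per k-mer."""
        lo = np.searchsorted(self._sorted, codes, "left")
        hi = np.searchsorted(self._sorted, codes, "right")
        cnt = hi - lo
        for i in np.nonzero((cnt > 0) & (cnt <= max_occ))[0]:
            yield int(i), self._pos[lo[i]:hi[i]]

    def any_hit(self, codes: np.ndarray) -> bool:
        """Fast membership screen: does any of `codes` occur in the subject?"""
        if codes.size == 0:
            return False
        lo = np.searchsorted(self._sorted, codes, "left")
        hi = np.searchsorted(self._sorted, codes, "right")
        return bool(np.any(hi > lo))

    def locate(self, gpos: int) -> tuple[str, int]:
        """Map a global concatenated position to (name, local position)."""
        i = int(np.searchsorted(self.offsets, gpos, "right")) - 1
        i = min(i, len(self.names) - 1)
        local = gpos - int(self.offsets[i])
        if local >= self.lengths[self.names[i]]:
            raise ValueError(f"position {gpos} falls in a separator region")
        return self.names[i], local


# ---------------------------------------------------------------------------
# seed-and-extend engine
# ---------------------------------------------------------------------------

_CHAIN_DIAG_TOL = 32
_CHAIN_MAX_GAP = 200


def _chain_seeds(qpos: np.ndarray, gpos: np.ndarray, k: int):
    """Greedy chaining of seed matches on nearby diagonals.

    Seeds sharing a diagonal and abutting within k bases merge into runs;
    runs chain greedily when query-ordered, gap <= _CHAIN_MAX_GAP and
    diagonal shift <= _CHAIN_DIAG_TOL.  Returns a list of chains, each a
    dict with anchor coordinates and diagonal spread.
    """
    diag = gpos - qpos
    order = np.lexsort((qpos, diag))
    q = qpos[order]
    g = gpos[order]
    d = diag[order]
    # merge same-diagonal runs
    runs = []  # (q_start, q_end, g_start, diag, seed_bases)
    i = 0
    n = q.size
    while i < n:
        j = i + 1
        while j < n and d[j] == d[i] and q[j] - q[j - 1] <= k:
            j += 1
        runs.append((int(q[i]), int(q[j - 1]) + k, int(g[i]), int(d[i]),
                     int(q[j - 1]) + k - int(q[i])))
        i = j
    runs.sort(key=lambda r: (r[0], r[2]))
    chains: list[dict] = []
    for r in runs:
        attached = False
        for ch in chains[-1:-65:-1]:  # only recent chains can still accept runs
            last = ch["runs"][-1]
            qgap = r[0] - last[1]
            if -k < qgap <= _CHAIN_MAX_GAP and abs(r[3] - last[3]) <= _CHAIN_DIAG_TOL \
                    and r[2] > last[2]:
                ch["runs"].append(r)
                ch["seed_bases"] += r[4]
                attached = True
                break
        if not attached:
            chains.append({"runs": [r], "seed_bases": r[4]})
    for ch in chains:
        first = ch["runs"][0]
        diags = [r[3] for r in ch["runs"]]
        ch["q0"], ch["g0"] = first[0], first[2]
        ch["diag_spread"] = max(diags) - min(diags)
    chains.sort(key=lambda c: (-c["seed_bases"], c["g0"], c["q0"]))
    return chains


def _extend_chain(qcodes: np.ndarray, subject_codes: np.ndarray, chain: dict,
                  scoring: ScoringScheme, x_drop: int, min_score: int = 0):
    """Extend left+right from the chain anchor.

    A score-only rolling-memory pass runs first; the traceback DP (which
    allocates banded matrices) is paid only when the combined score can
    reach ``min_score``.  Returns either a full tuple
    (q_start, q_end, g_start, g_end, op codes) or, for sub-threshold
    chains, (q_start, q_end, g_start, g_end, None) so callers can still
    mark the region as claimed.
    """
    q0, g0 = chain["q0"], chain["g0"]
    band = max(48, chain["diag_spread"] + 24)
    band = min(band, 256)
    m, mm, go, ge = scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    a_r = qcodes[q0:]
    b_r = subject_codes[g0:g0 + a_r.size + band + 1]
    a_l = qcodes[:q0][::-1].copy()
    b_l = subject_codes[max(0, g0 - q0 - band - 1):g0][::-1].copy()
    sc_r, ar, br = extend_xdrop_score(a_r, b_r, m, mm, go, ge, x_drop, band)
    sc_l, al, bl = extend_xdrop_score(a_l, b_l, m, mm, go, ge, x_drop, band)
    if sc_r + sc_l < 1:
        return None
    q_start, q_end = q0 - al, q0 + ar
    g_start, g_end = g0 - bl, g0 + br
    if sc_r + sc_l < min_score:
        return q_start, q_end, g_start, g_end, None
    # traceback pass, replayed on the rectangles the score pass bounded
    sc_r2, ar2, br2, ops_r = extend_xdrop(
        a_r[:ar], b_r[:max(br, ar) + band + 1], m, mm, go, ge, x_drop, band)
    sc_l2, al2, bl2, ops_l = extend_xdrop(
        a_l[:al], b_l[:max(bl, al) + band + 1], m, mm, go, ge, x_drop, band)
    codes = np.concatenate((ops_l[::-1], ops_r))
    q_start, q_end = q0 - al2, q0 + ar2
    g_start, g_end = g0 - bl2, g0 + br2
    return q_start, q_end, g_start, g_end, codes


def seed_and_extend(
    query: SequenceRecord,
    subject: SequenceRecord | KmerIndex,
    scoring: ScoringScheme = ScoringScheme(),
    seed_k: int = 11,
    x_drop: int = 100,
    ka: KarlinAltschulParams | None = None,
    search_space: tuple[int, int] | None = None,
    max_occ: int = 64,
    evalue_prefilter: float | None = None,
    reduce_query_overlap: bool = True,
) -> list[LocalAlignment]:
    """Find local alignments of `query` against `subject` (both strands).

    Both orientations of the query are searched against the forward subject.
    Hits are reduced so that no two overlap by more than 50% on the query
    (the shorter hit's length is the denominator), sorted by score
    descending with ties broken by smaller subject start.

    ``search_space`` overrides the (m, n) lengths used for E-values; by
    default m = query length and n = total subject length.
    ``evalue_prefilter``, when set, lets the engine discard chains whose
    extension score cannot reach that E-value without computing their
    tracebacks (a pure optimisation: the returned set of hits at or below
    the threshold is unchanged).
    """
    index = subject if isinstance(subject, KmerIndex) else KmerIndex([subject], k=seed_k)
    if index.k != seed_k:
        raise ValueError(f"index built with k={index.k}, requested {seed_k}")
    if len(query) < seed_k:
        logger.warning("query %s shorter than seed length %d; no hits", query.id, seed_k)
        return []
    ka = ka or calibrate_karlin_altschul(scoring)
    m, n = search_space or (len(query), index.total_length)
    min_score = 0
    if evalue_prefilter is not None and evalue_prefilter > 0:
        # smallest score whose E-value is still above the threshold
        min_score = max(0, int(math.ceil(math.log(ka.K * m * n / evalue_prefilter) / ka.lam)))

    hits: list[LocalAlignment] = []
    for strand in "+-":
        qseq = query.sequence if strand == "+" else revcomp(query.sequence)
        qcodes = encode(qseq)
        kcodes, valid = _kmer_codes(qcodes, seed_k)
        if not valid.any():
            continue
        probe = kcodes.copy()
        probe[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
        qp_list, gp_list = [], []
        for qi, positions in index.lookup_many(probe, max_occ=max_occ):
            if not valid[qi]:
                continue
            qp_list.append(np.full(positions.size, qi, np.int64))
            gp_list.append(positions)
        if not qp_list:
            continue
        qpos = np.concatenate(qp_list)
        gpos = np.concatenate(gp_list)
        claimed: list[tuple[int, int, int, int]] = []  # (q_s, q_e, g_s, g_e)
        for chain in _chain_seeds(qpos, gpos, seed_k):
            q0, g0 = chain["q0"], chain["g0"]
            if any(qs <= q0 < qe and gs <= g0 < ge for qs, qe, gs, ge in claimed):
                continue
            ext = _extend_chain(qcodes, index.codes, chain, scoring, x_drop, min_score)
            if ext is None:
                continue
            q_start, q_end, g_start, g_end, codes = ext
            claimed.append((q_start, q_end, g_start, g_end))
            if codes is None:
                continue  # below the E-value prefilter; region still claimed
            try:
                chrom_s, loc_s = index.locate(g_start)
                chrom_e, loc_e = index.locate(g_end - 1)
            except ValueError:
                continue  # extension strayed into a separator edge
            if chrom_s != chrom_e:
                continue
            ops, n_eq = _ops_from_codes(codes, qcodes, index.codes, q_start, g_start)
            if strand == "+":
                oq_start, oq_end = q_start, q_end
            else:
                oq_start, oq_end = len(query) - q_end, len(query) - q_start
            aln = LocalAlignment(
                query_id=query.id, subject_id=chrom_s,
                q_start=oq_start, q_end=oq_end,
                s_start=loc_s, s_end=loc_e + 1,
                strand=strand, score=0, evalue=math.nan,
                identity=n_eq / max(1, sum(c for _, c in ops)), ops=ops,
            )
            aln.score = aln.rescore(scoring)
            if aln.score < 1:
                continue
            aln.evalue = evalue(aln.score, m, n, ka)
            hits.append(aln)

    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_start, h.strand))
    if not reduce_query_overlap:
        # callers ranking alternative placements of the same query region
        # (e.g. ambiguity detection) need the unreduced list
        return hits
    kept: list[LocalAlignment] = []
    for h in hits:
        ok = True
        for g in kept:
            ov = min(h.q_end, g.q_end) - max(h.q_start, g.q_start)
            if ov > 0 and ov > 0.5 * min(h.q_len, g.q_len):
                ok = False
                break
        if ok:
            kept.append(h)
    return kept
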