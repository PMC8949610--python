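"""Synthetic data: toy genomes, plasmids, planted integrations, noisy reads.

The generator emulates the study design at desk scale: a multi-chromosome
random genome with gene models, a plasmid carrying an annotated expression
unit (promoter + CDS + polyA surrogate), planted insertions of (a) the
complete expression unit — on chromosome 1 only — and (b) random plasmid
fragments genome-wide, and nanopore-like long reads with i.i.d. per-base
substitution/insertion/deletion errors and Phred quality strings.  A truth
table records every planted event so each pipeline stage is testable
without any external download.

Junctions are constructed *clean*: the four bases on either side of every
insertion point are pairwise mismatched against the sequence an alignment
could otherwise extend into (the insert edges vs the genomic continuation,
and the plasmid context vs the genome).  Random junctions carry chance
microhomology ~25% of the time, which makes the true coordinate ambiguous
by a few bases; clean junctions keep the planted coordinate well defined so
exact-recovery tests are meaningful.  Real junctions do not enjoy this
property — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tismap.io_formats import (
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    revcomp,
    write_bed,
    write_fasta,
    write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CLEAN_JUNCTION_BASES = 4


@dataclass(frozen=True)
class IntegrationTruth:
    """Ground truth for one planted insertion.

    ``position`` is the 0-based insertion point in the *original* genome
    coordinates (the reference the pipeline maps against): the inserted
    sequence sits immediately before the base at ``position``.
    """

    chrom: str
    position: int
    plasmid_start: int
    plasmid_end: int
    insert_strand: str
    klass: str  # {full_unit, fragment}


@dataclass
class ReadSimParams:
    """Long-read simulation parameters.

    Lengths are log-normal with the given mean/sd (bp), truncated below at
    ``length_min`` and above at the chromosome end.  Error rates are i.i.d.
    per-base probabilities; insertions and deletions are single-base.
    ``q_ok``/``q_err`` are the mean Phred scores assigned to error-free and
    erroneous bases.  Defaults give ~8% total error at 15x coverage, the
    regime noisy-recovery tests run in.
    """

    coverage: float = 15.0
    length_mean: float = 8000.0
    length_sd: float = 6000.0
    length_min: int = 200
    sub_rate: float = 0.04
    ins_rate: float = 0.02
    del_rate: float = 0.02
    q_ok: float = 20.0
    q_err: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if not (0 <= getattr(self, name) <= 0.2):
                raise ValueError(f"{name} must be in [0, 0.2]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def total_error(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    def error_free(self) -> "ReadSimParams":
        """Copy of these parameters with all error rates zeroed."""
        return ReadSimParams(
            coverage=self.coverage, length_mean=self.length_mean,
            length_sd=self.length_sd, length_min=self.length_min,
            sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            q_ok=self.q_ok, q_err=self.q_err, rng_seed=self.rng_seed,
        )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def make_toy_genome(
    n_chrom: int = 3,
    lengths: tuple[int, ...] | None = None,
    gc: float = 0.4,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[GeneModel]]:
    """Random multi-chromosome genome plus non-overlapping gene models.

    Genes (2-6 exons each) cover roughly 30% of each chromosome.  All
    output is a deterministic function of the arguments.
    """
    lengths = lengths or tuple([1_000_000] * n_chrom)
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    if any(l < 100_000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 100 kb")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    gene_no = 0
    for ci, length in enumerate(lengths):
        chrom = f"chr{ci + 1}"
        records.append(SequenceRecord(chrom, _random_seq(rng, length, gc)))
        target = 0.30 * length
        covered = 0
        cursor = int(rng.integers(500, 5000))
        while covered < target and cursor < length - 20_000:
            glen = int(rng.integers(2_000, 10_001))
            if cursor + glen > length - 1000:
                break
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            # split the gene into alternating exon/intron blocks
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 1, replace=False))
            bounds = np.concatenate(([0], cuts, [glen]))
            exons = []
            for e in range(n_exons):
                s = cursor + int(bounds[2 * e])
                t = cursor + int(bounds[2 * e + 1])
                if t > s:
                    exons.append(GenomicInterval(chrom, s, t, strand))
            span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            genes.append(GeneModel(f"g{gene_no:05d}", span, exons))
            covered += glen
            cursor += glen + int(rng.integers(1_000, 8_000))
    return records, genes


def write_gff(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            s = gm.span
            fh.write(f"{s.chrom}\ttismap\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t"
                     f"ID={gm.gene_id}\n")
            for i, e in enumerate(gm.exons, 1):
                fh.write(f"{e.chrom}\ttismap\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                         f"ID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n")


def make_plasmid(
    backbone_len: int = 3000,
    unit_len: int = 2000,
    gc: float = 0.5,
    seed: int = 1,
) -> tuple[SequenceRecord, tuple[int, int]]:
    """Random plasmid surrogate (linearised circle) with its expression unit.

    The unit — the promoter + CDS + polyA span whose complete presence marks
    a functional insertion — occupies an annotated internal interval; the
    rest is backbone.
    """
    if backbone_len < 500 or unit_len < 500:
        raise ValueError("backbone and unit must each be >= 500 bp")
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, backbone_len + unit_len, gc)
    unit_start = backbone_len // 2
    return SequenceRecord("plasmid", seq), (unit_start, unit_start + unit_len)


def _insert_contexts(plasmid: str, f0: int, f1: int, strand: str):
    """(insert, left context, right context) in insert orientation."""
    w = CLEAN_JUNCTION_BASES
    if strand == "+":
        return (plasmid[f0:f1], plasmid[max(0, f0 - w):f0], plasmid[f1:f1 + w])
    return (revcomp(plasmid[f0:f1]), revcomp(plasmid[f1:f1 + w]),
            revcomp(plasmid[max(0, f0 - w):f0]))


def _clean_junction(insert: str, lctx: str, rctx: str, g_left: str, g_right: str) -> bool:
    """True when no alignment can extend across either junction.

    Checks that the first CLEAN_JUNCTION_BASES comparisons at each of the
    four boundary pairings are all mismatches.
    """
    pairs = [
        (lctx[::-1], g_left[::-1]),    # plasmid context vs genome, leftward
        (insert, g_right),             # insert start vs genomic continuation
        (insert[::-1], g_left[::-1]),  # insert end vs preceding genome
        (rctx, g_right),               # plasmid context vs genome, rightward
    ]
    for a, b in pairs:
        for x, y in zip(a[:CLEAN_JUNCTION_BASES], b[:CLEAN_JUNCTION_BASES]):
            if x == y:
                return False
    return True


def plant_integrations(
    genome: list[SequenceRecord],
    plasmid: SequenceRecord,
    unit: tuple[int, int],
    n_full: int = 4,
    n_fragment: int = 4,
    fragment_len_range: tuple[int, int] = (200, 1500),
    unit_pad: int = 100,
    min_spacing: int = 10_000,
    seed: int = 2,
) -> tuple[list[SequenceRecord], list[IntegrationTruth]]:
    """Insert full-unit and fragment plasmid sequence into the genome.

    Full-unit insertions (the unit plus ``unit_pad`` plasmid context each
    side) go on chromosome 1 only; fragments are uniform over all
    chromosomes.  Insertion points are >= ``min_spacing`` apart and from
    chromosome ends, with clean junctions (see module docstring).  Returns
    the modified genome and the truth table sorted by (chrom, position).
    """
    if fragment_len_range[1] >= 0.9 * (unit[1] - unit[0]):
        raise ValueError("fragment length range must stay below unit coverage")
    rng = np.random.default_rng(seed)
    chrom_seqs = {r.id: r.sequence for r in genome}
    names = [r.id for r in genome]
    if any(len(s) < 2 * min_spacing + min_spacing * (n_full + n_fragment)
           for s in [chrom_seqs[names[0]]]):
        raise ValueError("chromosome 1 too small for the spacing constraints")

    placed: dict[str, list[int]] = {name: [] for name in names}
    truths: list[IntegrationTruth] = []

    def place(chrom: str, f0: int, f1: int, strand: str, klass: str) -> None:
        seq = chrom_seqs[chrom]
        insert, lctx, rctx = _insert_contexts(plasmid.sequence, f0, f1, strand)
        w = CLEAN_JUNCTION_BASES
        for _ in range(20_000):
            pos = int(rng.integers(min_spacing, len(seq) - min_spacing))
            if any(abs(pos - p) < min_spacing for p in placed[chrom]):
                continue
            if _clean_junction(insert, lctx, rctx, seq[pos - w:pos], seq[pos:pos + w]):
                placed[chrom].append(pos)
                truths.append(IntegrationTruth(chrom, pos, f0, f1, strand, klass))
                return
        raise RuntimeError(f"could not place a clean {klass} insertion on {chrom}")

    u0, u1 = unit
    full_f0 = max(0, u0 - unit_pad)
    full_f1 = min(len(plasmid), u1 + unit_pad)
    for _ in range(n_full):
        strand = "+" if rng.random() < 0.5 else "-"
        place(names[0], full_f0, full_f1, strand, "full_unit")
    for _ in range(n_fragment):
        chrom = names[int(rng.integers(0, len(names)))]
        flen = int(rng.integers(fragment_len_range[0], fragment_len_range[1] + 1))
        f0 = int(rng.integers(0, len(plasmid) - flen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        place(chrom, f0, f0 + flen, strand, "fragment")

    truths.sort(key=lambda t: (t.chrom, t.position))
    modified: list[SequenceRecord] = []
    for name in names:
        seq = chrom_seqs[name]
        parts = []
        cursor = 0
        for t in [t for t in truths if t.chrom == name]:
            parts.append(seq[cursor:t.position])
            insert, _, _ = _insert_contexts(plasmid.sequence, t.plasmid_start,
                                            t.plasmid_end, t.insert_strand)
            parts.append(insert)
            cursor = t.position
        parts.append(seq[cursor:])
        modified.append(SequenceRecord(name, "".join(parts)))
    return modified, truths


def write_truth_tsv(truths: list[IntegrationTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tplasmid_start\tplasmid_end\tinsert_strand\tclass\n")
        for t in truths:
            fh.write(f"{t.chrom}\t{t.position}\t{t.plasmid_start}\t{t.plasmid_end}\t"
                     f"{t.insert_strand}\t{t.klass}\n")


def read_truth_tsv(path: str | Path) -> list[IntegrationTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            c, p, s, e, st, k = line.rstrip("\n").split("\t")
            truths.append(IntegrationTruth(c, int(p), int(s), int(e), st, k))
    return truths


def _apply_errors(rng: np.random.Generator, codes: np.ndarray, params: ReadSimParams):
    """Apply i.i.d. per-base errors; return (out codes, out qualities)."""
    n = codes.size
    r = rng.random(n)
    sub = r < params.sub_rate
    ins = (~sub) & (r < params.sub_rate + params.ins_rate)
    dele = (~sub) & (~ins) & (r < params.total_error)
    out_base = codes.copy()
    if sub.any():
        out_base[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    rep = np.ones(n, dtype=np.int64)
    rep[dele] = 0
    rep[ins] = 2
    idx = np.repeat(np.arange(n), rep)
    out = out_base[idx]
    is_err = (sub | ins)[idx]
    # the second copy at an insertion becomes a random base
    dup = np.zeros(idx.size, dtype=bool)
    dup[1:] = idx[1:] == idx[:-1]
    if dup.any():
        out[dup] = rng.integers(0, 4, size=int(dup.sum()))
        is_err |= dup
    q_mean = np.where(is_err, params.q_err, params.q_ok)
    quals = np.clip(np.rint(rng.normal(q_mean, 2.0)), 2, 41).astype(np.int64)
    return out, quals


@dataclass
class ReadOrigin:
    """Source interval of a simulated read, in modified-genome coordinates."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str


def simulate_reads(
    genome: list[SequenceRecord],
    params: ReadSimParams,
) -> tuple[list[SequenceRecord], list[ReadOrigin]]:
    """Simulate long reads to the requested fold coverage.

    Read starts are uniform over the genome, lengths log-normal (truncated
    at ``length_min`` and at the chromosome end), strands equiprobable.
    Reads are emitted until total bases reach coverage x genome length.
    Fully deterministic given ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    lengths = np.array([len(r) for r in genome], dtype=float)
    total_len = lengths.sum()
    target = params.coverage * total_len
    mu = np.log(params.length_mean**2 / np.sqrt(params.length_mean**2 + params.length_sd**2))
    sigma = np.sqrt(np.log(1 + (params.length_sd / params.length_mean) ** 2))
    codes_by_chrom = {}
    from tismap.align import encode
    for r in genome:
        codes_by_chrom[r.id] = encode(r.sequence)
    reads: list[SequenceRecord] = []
    origins: list[ReadOrigin] = []
    emitted = 0.0
    i = 0
    while emitted < target:
        ci = int(rng.choice(len(genome), p=lengths / total_len))
        chrom = genome[ci]
        L = len(chrom)
        start = int(rng.integers(0, L))
        rlen = int(max(params.length_min, np.rint(rng.lognormal(mu, sigma))))
        end = min(L, start + rlen)
        if end - start < params.length_min:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        template = codes_by_chrom[chrom.id][start:end]
        if strand == "-":
            template = (3 - template)[::-1]
        out, quals = _apply_errors(rng, template, params)
        i += 1
        rid = f"read{i:06d}"
        reads.append(SequenceRecord(rid, _BASES[out].tobytes().decode("ascii"),
                                    quals.tolist()))
        origins.append(ReadOrigin(rid, chrom.id, start, end, strand))
        emitted += out.size
    return reads, origins


def write_origins_tsv(origins: list[ReadOrigin], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\n")
        for o in origins:
            fh.write(f"{o.read_id}\t{o.chrom}\t{o.start}\t{o.end}\t{o.strand}\n")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    """All artifacts of one simulated study."""

    genome: list[SequenceRecord]
    genes: list[GeneModel]
    plasmid: SequenceRecord
    unit: tuple[int, int]
    modified_genome: list[SequenceRecord]
    truths: list[IntegrationTruth]
    reads: list[SequenceRecord]
    origins: list[ReadOrigin]
    params: ReadSimParams
    peaks: list[GenomicInterval] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gff(self.genes, outdir / "genes.gff3")
        write_fasta([self.plasmid], outdir / "plasmid.fa")
        write_bed([GenomicInterval(self.plasmid.id, self.unit[0], self.unit[1])],
                  outdir / "unit.bed", names=["expression_unit"])
        write_fasta(self.modified_genome, outdir / "modified_genome.fa")
        write_truth_tsv(self.truths, outdir / "truth.tsv")
        write_fastq(self.reads, outdir / "reads.fastq.gz")
        write_origins_tsv(self.origins, outdir / "origins.tsv")
        if self.peaks:
            write_bed(self.peaks, outdir / "peaks.bed")


def paperlike_simulation(
    seed: int = 42,
    params: ReadSimParams | None = None,
    n_chrom: int = 3,
    chrom_len: int = 1_000_000,
    with_peaks: bool = True,
) -> Simulation:
    """The standard desk-scale scenario: 3 x 1 Mb chromosomes, 4 full-unit
    insertions on chromosome 1 plus 4 fragments genome-wide, 15x coverage.

    ``seed`` drives every stage (sub-seeds are derived from it).  Optional
    accessibility peaks are planted around fragment insertion sites plus
    random background peaks, mirroring the observation that random
    integrations favour open chromatin.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_plasmid, s_plant, s_reads, s_peaks = [
        int(x) for x in ss.generate_state(5) % (2**31)
    ]
    genome, genes = make_toy_genome(n_chrom, tuple([chrom_len] * n_chrom), seed=s_genome)
    plasmid, unit = make_plasmid(seed=s_plasmid)
    modified, truths = plant_integrations(genome, plasmid, unit, seed=s_plant)
    if params is None:
        params = ReadSimParams(rng_seed=s_reads)
    elif params.rng_seed == 0:
        params = ReadSimParams(**{**params.__dict__, "rng_seed": s_reads})
    reads, origins = simulate_reads(modified, params)
    peaks: list[GenomicInterval] = []
    if with_peaks:
        prng = np.random.default_rng(s_peaks)
        for t in truths:
            if t.klass == "fragment":
                half = int(prng.integers(200, 800))
                peaks.append(GenomicInterval(t.chrom, max(0, t.position - half),
                                             t.position + half))
        for r in genome:
            for _ in range(20):
                s = int(prng.integers(0, len(r) - 1500))
                peaks.append(GenomicInterval(r.id, s, s + int(prng.integers(300, 1500))))
        peaks.sort(key=lambda p: (p.chrom, p.start))
    return Simulation(genome, genes, plasmid, unit, modified, truths,
                      reads, origins, params, peaks)
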