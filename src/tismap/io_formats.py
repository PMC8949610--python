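"""Sequence and annotation I/O.

Coordinate conventions, fixed once for the whole package:

* every in-memory coordinate is **0-based, half-open** ``[start, end)``;
* the only 1-based surfaces are GFF3 input (converted on read) and the
  human-readable ``Chr:pos`` rendering used in reports (``pos = start + 1``
  for a single-base locus).

FASTQ is Phred+33 and strictly 4-line (the format modern nanopore basecallers
emit); wrapped FASTA is accepted.  Gzip-compressed inputs are detected by the
``.gz`` extension and opened transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}

PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """One read or reference sequence, with optional per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def pos1(self) -> int:
        """1-based rendering of the start coordinate (``Chr:pos`` style)."""
        return self.start + 1


@dataclass
class GeneModel:
    """A gene span with its (sorted, non-overlapping) exons."""

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom or exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon {exon} outside span {self.span}")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = exon.end


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read (possibly wrapped, possibly gzipped) FASTA into SequenceRecords.

    Sequences are uppercased; qualities are absent.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as handle:
        SeqIO.write(
            (_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
            handle,
            "fasta",
        )


def read_fastq(path: str | Path, offset: int = PHRED_OFFSET) -> list[SequenceRecord]:
    """Read strict 4-line FASTQ (Phred+33).

    Phred+64 input is not supported: passing ``offset=64`` raises immediately,
    and there is no auto-detection (the offsets are not reliably
    distinguishable from content).
    """
    if offset != PHRED_OFFSET:
        raise FormatError("only Phred+33 FASTQ is supported (Phred+64 rejected)")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if header == "":
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@") or len(header) < 2:
                raise FormatError(f"{path}:{lineno}: expected '@<id>' header, got {header!r}")
            rec_id = header[1:].split()[0]
            seq = handle.readline().rstrip("\n")
            plus = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            lineno += 3
            if not seq or not plus or qual == "":
                raise FormatError(f"{path}: truncated FASTQ record {rec_id!r}")
            if not plus.startswith("+"):
                raise FormatError(
                    f"{path}: record {rec_id!r}: expected '+' separator "
                    f"(multi-line FASTQ is not supported)"
                )
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record {rec_id!r}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            if rec_id in seen:
                raise FormatError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            quals = [ord(c) - offset for c in qual]
            if any(q < 0 for q in quals):
                raise FormatError(f"{path}: record {rec_id!r}: quality character below '!'")
            records.append(SequenceRecord(rec_id, seq.upper(), quals))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for r in records:
            if r.qualities is None:
                raise ValueError(f"record {r.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.qualities)
            handle.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from GFF3 into GeneModels.

    GFF3 is 1-based inclusive; coordinates are converted to 0-based half-open.
    Exons attach to their parent gene via the ``Parent`` attribute; an exon
    whose parent cannot be resolved is skipped with a warning.  UTR features,
    if present, are treated as exonic by downstream annotation and are not
    modelled separately here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        genes[feat.id] = GeneModel(feat.id, span, [])
    orphan = 0
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent", [])
        parent = next((p for p in parents if p in genes), None)
        if parent is None:
            orphan += 1
            logger.warning("exon at %s:%d-%d has no resolvable gene parent; skipped",
                           feat.seqid, feat.start, feat.end)
            continue
        genes[parent].exons.append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        )
    models = []
    for gm in genes.values():
        gm.exons.sort(key=lambda e: (e.start, e.end))
        models.append(GeneModel(gm.gene_id, gm.span, gm.exons))  # re-validate
    if orphan:
        logger.warning("%d orphan exon(s) skipped in %s", orphan, path)
    models.sort(key=lambda g: (g.span.chrom, g.span.start))
    return models


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3+ columns) intervals; strand taken from column 6 if present."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in _VALID_STRANDS else "."
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6 (0-based half-open, tab-separated)."""
    with _open_text(path, "wt") as handle:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Site report
# ---------------------------------------------------------------------------

SITES_TSV_COLUMNS = [
    "chrom",
    "position",
    "support",
    "class",
    "context",
    "host_gene",
    "in_peak",
    "classes_present",
    "ambiguous",
    "left_junction",
    "right_junction",
    "host_gene_expression",
    "nearest_peak_distance",
]


def write_sites_tsv(sites, path: str | Path) -> None:
    """Write the per-site report, one row per integration site.

    ``position`` and the auxiliary junction columns are 1-based (``Chr:pos``
    convention); everything else in the package stays 0-based.
    """
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(SITES_TSV_COLUMNS) + "\n")
        for s in sites:
            ann = s.annotation
            row = [
                s.locus.chrom,
                str(s.locus.pos1),
                str(s.support),
                s.site_class,
                ann.context if ann else ".",
                (ann.host_gene or ".") if ann else ".",
                (str(int(ann.in_peak)) if ann else "."),
                ",".join(sorted(s.classes_present)),
                str(int(s.ambiguous)),
                str(s.left_junction + 1) if s.left_junction is not None else ".",
                str(s.right_junction + 1) if s.right_junction is not None else ".",
                (f"{ann.host_gene_expression:g}"
                 if ann and ann.host_gene_expression is not None else "."),
                (str(ann.nearest_peak_distance)
                 if ann and ann.nearest_peak_distance is not None else "."),
            ]
            handle.write("\t".join(row) + "\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]
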