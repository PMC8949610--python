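"""Read filtering: drop low-quality and short reads before the junction search.

Mean read quality is computed in probability space,

    Q_mean = -10 * log10( mean_i 10^(-Q_i / 10) ),

the definition used by standard long-read filtering tools.  Because
``-log10`` is convex, this mean is always <= the arithmetic mean of the
per-base Phred scores, i.e. it is dominated by the worst bases — the
behaviour one wants when the goal is to drop genuinely bad reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tismap.config import QcThresholds
from tismap.io_formats import SequenceRecord


@dataclass
class QcSummary:
    """Counts from one filtering pass (inclusion–exclusion consistent)."""

    n_input: int = 0
    n_kept: int = 0
    removed_short_only: int = 0
    removed_lowq_only: int = 0
    removed_both: int = 0
    no_quality: int = 0  # kept via the quality rule by definition, but flagged

    @property
    def n_removed(self) -> int:
        return self.removed_short_only + self.removed_lowq_only + self.removed_both

    def as_tsv(self) -> str:
        rows = [
            ("input", self.n_input),
            ("kept", self.n_kept),
            ("removed_short_only", self.removed_short_only),
            ("removed_lowq_only", self.removed_lowq_only),
            ("removed_both", self.removed_both),
            ("no_quality", self.no_quality),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows)


def mean_read_quality(record: SequenceRecord, arithmetic: bool = False) -> float:
    """Mean Phred quality of a read (probability-space by default)."""
    if not record.qualities:
        raise ValueError(
            f"read {record.id!r} has no base qualities; supply FASTQ input"
        )
    q = np.asarray(record.qualities, dtype=float)
    if arithmetic:
        return float(q.mean())
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def filter_reads(
    records: list[SequenceRecord], thresholds: QcThresholds | None = None
) -> tuple[list[SequenceRecord], QcSummary]:
    """Keep reads with length >= min_length AND mean quality >= min_mean_q.

    Reads without qualities (FASTA input) pass the quality rule by definition
    and are counted in ``no_quality``.  Idempotent: filtering kept reads again
    removes nothing.
    """
    thresholds = thresholds or QcThresholds()
    summary = QcSummary(n_input=len(records))
    kept: list[SequenceRecord] = []
    for rec in records:
        short = len(rec) < thresholds.min_length
        if rec.qualities:
            lowq = mean_read_quality(rec, thresholds.arithmetic_mean) < thresholds.min_mean_q
        else:
            lowq = False
            summary.no_quality += 1
        if short and lowq:
            summary.removed_both += 1
        elif short:
            summary.removed_short_only += 1
        elif lowq:
            summary.removed_lowq_only += 1
        else:
            kept.append(rec)
    summary.n_kept = len(kept)
    return kept, summary
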