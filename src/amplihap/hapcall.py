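"""Haplotype calling: dereplication, truncated-primer removal, frequencies.

A haplotype here is the exact full-length sequence of one amplicon copy.
Oriented merged reads are collapsed by exact string identity; groups seen
fewer than ``min_unique_size`` times (default 5) are discarded so that
isolated sequencing errors cannot create novel haplotypes.  Haplotypes not
anchored by the complete primer at both ends are PCR artifacts from
truncated primer oligos and are removed.  Frequencies are computed over
the reads that survive both filters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .readproc import MergedRead
from .refpanel import LocusRef, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HapRow:
    sequence: str
    count: int
    frequency: float


@dataclass(frozen=True)
class HaplotypeTable:
    """Retained haplotypes of one (sample, locus) with counts and
    frequencies summing to 1."""

    sample_id: str
    locus: str
    rows: tuple[HapRow, ...]
    total_retained_count: int

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.rows]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences must be unique within a table")
        if self.rows:
            if sum(r.count for r in self.rows) != self.total_retained_count:
                raise ValueError("counts do not sum to total_retained_count")
            if abs(sum(r.frequency for r in self.rows) - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1")

    def freq_map(self) -> dict[str, float]:
        return {r.sequence: r.frequency for r in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [r.sequence for r in self.rows],
                "count": [r.count for r in self.rows],
                "frequency": [r.frequency for r in self.rows],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, sample_id: str, locus: str) -> "HaplotypeTable":
        frame = pd.read_csv(path, dtype={"sequence": str})
        rows = tuple(
            HapRow(r.sequence, int(r.count), float(r.frequency))
            for r in frame.itertuples()
        )
        return cls(sample_id, locus, rows, sum(r.count for r in rows))


def dereplicate(
    merged_reads: Iterable[MergedRead | str], min_unique_size: int = 5
) -> tuple[list[tuple[str, int]], int]:
    """Collapse reads by exact sequence; drop groups below the abundance
    floor.

    Returns ``(rows, discarded_read_count)`` where rows are ``(sequence,
    count)`` sorted by descending count, ties lexicographic.  Conservation:
    retained + discarded reads = input reads.
    """
    if min_unique_size < 1:
        raise ValueError("min_unique_size must be >= 1")
    counts: Counter = Counter(
        read.sequence if isinstance(read, MergedRead) else read
        for read in merged_reads
    )
    rows = [
        (seq, count) for seq, count in counts.items() if count >= min_unique_size
    ]
    rows.sort(key=lambda row: (-row[1], row[0]))
    discarded = sum(c for c in counts.values() if c < min_unique_size)
    if discarded:
        log.info(
            "dereplication discarded %d reads in groups below size %d",
            discarded, min_unique_size,
        )
    return rows, discarded


def remove_truncated(
    raw_counts: Sequence[tuple[str, int]], locus_ref: LocusRef
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Drop haplotypes not anchored by complete, exact primers at both ends.

    A haplotype is retained iff it begins with the full forward primer and
    ends with the full reverse complement of the reverse primer.  This also
    removes primer-interior substitutions: primer-derived bases are
    dictated by the oligo, so a mismatch there is a synthesis/PCR artifact.
    Returns ``(kept, removed)``.
    """
    tail = revcomp(locus_ref.rev_primer)
    kept, removed = [], []
    for seq, count in raw_counts:
        if seq.startswith(locus_ref.fwd_primer) and seq.endswith(tail):
            kept.append((seq, count))
        else:
            removed.append((seq, count))
    if removed:
        log.info(
            "%s: removed %d truncated-primer haplotypes (%d reads)",
            locus_ref.name, len(removed), sum(c for _, c in removed),
        )
    return kept, removed


def haplotype_frequencies(
    rows: Sequence[tuple[str, int]], sample_id: str, locus: str
) -> HaplotypeTable:
    """Turn retained ``(sequence, count)`` rows into a frequency table.

    Frequencies are counts over retained reads (post-filter denominator).
    Raises if no haplotype survived, naming the stage that emptied the
    table.
    """
    if not rows:
        raise ValueError(
            f"{sample_id}/{locus}: no haplotypes retained after dereplication "
            "and truncated-primer removal; nothing to tabulate"
        )
    total = sum(count for _, count in rows)
    table_rows = tuple(
        HapRow(seq, count, count / total) for seq, count in rows
    )
    return HaplotypeTable(sample_id, locus, table_rows, total)


def call_haplotypes(
    merged_reads: Iterable[MergedRead | str],
    locus_ref: LocusRef,
    sample_id: str,
    min_unique_size: int = 5,
) -> tuple[HaplotypeTable, dict[str, int]]:
    """Dereplicate -> remove truncated -> frequencies, with a stage summary."""
    raw, discarded = dereplicate(merged_reads, min_unique_size)
    kept, removed = remove_truncated(raw, locus_ref)
    table = haplotype_frequencies(kept, sample_id, locus_ref.name)
    stats = {
        "derep_discarded_reads": discarded,
        "truncated_haplotypes_removed": len(removed),
        "truncated_reads_removed": sum(c for _, c in removed),
        "retained_haplotypes": len(table.rows),
        "retained_reads": table.total_retained_count,
    }
    return table, stats


def combine_long(tables: Iterable[HaplotypeTable]) -> pd.DataFrame:
    """Long-format table across samples: sample_id, locus, sequence, count,
    frequency."""
    frames = []
    for table in tables:
        frame = table.to_frame()
        frame.insert(0, "locus", table.locus)
        frame.insert(0, "sample_id", table.sample_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "locus", "sequence", "count", "frequency"]
        )
    return pd.concat(frames, ignore_index=True)


def pooled_frequencies(
    tables: Sequence[HaplotypeTable], weights: Sequence[float]
) -> dict[str, float]:
    """Weight per-sample haplotype frequencies (e.g. by individuals
    sequenced) and sum; result sums to 1 over the union of haplotypes."""
    if len(tables) != len(weights):
        raise ValueError("one weight per table required")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("weights must sum to > 0")
    pooled: dict[str, float] = {}
    for table, weight in zip(tables, weights):
        w = weight / total
        for row in table.rows:
            pooled[row.sequence] = pooled.get(row.sequence, 0.0) + w * row.frequency
    return pooled
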