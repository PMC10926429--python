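"""Read-level processing: length filter, locus binning, perfect-overlap
merging, and orientation normalization.

Amplicons are short enough (400-425 bp) that a 2x250 bp read pair spans
the whole molecule with a 75-100 bp overlap.  Instead of quality trimming,
the pipeline demands an exact sequence match over the entire overlap; the
merged read then covers the full amplicon and is treated as one observed
haplotype.
"""

from __future__ import annotations

import gzip
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .refpanel import LocusRef, ReferencePanel, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with Phred+33 qualities."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    """A full-length amplicon sequence assembled from one read pair."""

    id: str
    locus: str | None
    sequence: str
    overlap_len: int


@dataclass(frozen=True)
class MergeRejected:
    """A pair that could not be merged; ``reason`` is ``"no_overlap"`` or
    ``"ambiguous"`` (two or more distinct exact overlaps)."""

    id: str
    reason: str


def _open_text(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")


def load_read_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Load mate-paired FASTQ files (gzip-aware, Phred+33)."""
    pairs: list[ReadPair] = []
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        for rec1, rec2 in zip(
            SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq"), strict=True
        ):
            pairs.append(
                ReadPair(
                    id=rec1.id,
                    seq1=str(rec1.seq).upper(),
                    qual1="".join(
                        chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                    ),
                    seq2=str(rec2.seq).upper(),
                    qual2="".join(
                        chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                    ),
                )
            )
    return pairs


def filter_by_length(pairs: Iterable[ReadPair], min_len: int = 240) -> list[ReadPair]:
    """Keep a pair iff BOTH mates are at least ``min_len`` bases long
    (inclusive boundary); retained pairs are unmodified."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    pairs = list(pairs)
    kept = [p for p in pairs if len(p.seq1) >= min_len and len(p.seq2) >= min_len]
    if len(kept) < len(pairs):
        log.info("length filter dropped %d of %d pairs", len(pairs) - len(kept), len(pairs))
    return kept


def _kmers(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i:i + k]


class KmerIndex:
    """Maps every k-mer of every reference to the loci containing it."""

    def __init__(self, panel: ReferencePanel, k: int = 31):
        self.k = k
        self.names = panel.names
        index: dict[str, tuple[str, ...]] = {}
        for locus in panel:
            for kmer in set(_kmers(locus.sequence, k)):
                index[kmer] = index.get(kmer, ()) + (locus.name,)
        self._index = index

    def scores(self, *seqs: str) -> dict[str, int]:
        """Shared-k-mer score per locus, summed over the given sequences and
        both orientations of each."""
        scores: dict[str, int] = defaultdict(int)
        get = self._index.get
        for seq in seqs:
            for oriented in (seq, revcomp(seq)):
                for kmer in _kmers(oriented, self.k):
                    for name in get(kmer, ()):
                        scores[name] += 1
        return scores


def bin_read_pairs(
    pairs: Iterable[ReadPair],
    panel: ReferencePanel,
    k: int = 31,
    min_score: int = 10,
    max_n_frac: float = 0.1,
    index: KmerIndex | None = None,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair], dict[str, int]]:
    """Assign each pair to the locus maximizing the shared-k-mer score.

    A pair is assigned only if the best score is at least ``min_score`` and
    strictly exceeds the runner-up; otherwise it lands in the unassigned
    bin.  Pairs where either mate is more than ``max_n_frac`` N are dropped
    up front (N cannot take part in exact overlaps).  Returns
    ``(bins, unassigned, stats)``.
    """
    if index is None:
        index = KmerIndex(panel, k)
    bins: dict[str, list[ReadPair]] = {name: [] for name in panel.names}
    unassigned: list[ReadPair] = []
    n_dropped = 0
    for pair in pairs:
        if (
            pair.seq1.count("N") > max_n_frac * len(pair.seq1)
            or pair.seq2.count("N") > max_n_frac * len(pair.seq2)
        ):
            n_dropped += 1
            continue
        scores = index.scores(pair.seq1, pair.seq2)
        if not scores:
            unassigned.append(pair)
            continue
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best_name, best = ranked[0]
        runner_up = ranked[1][1] if len(ranked) > 1 else 0
        if best >= min_score and best > runner_up:
            bins[best_name].append(pair)
        else:
            unassigned.append(pair)
    if n_dropped:
        log.info("dropped %d pairs with >%.0f%% N", n_dropped, 100 * max_n_frac)
    stats = {
        "dropped_n_rich": n_dropped,
        "unassigned": len(unassigned),
        **{f"binned_{name}": len(reads) for name, reads in bins.items()},
    }
    return bins, unassigned, stats


def merge_pair(pair: ReadPair, min_overlap: int = 20) -> MergedRead | MergeRejected:
    """Merge a read pair requiring a perfect overlap.

    Let R2' be the reverse complement of mate 2.  An overlap length ``v``
    (``min_overlap <= v <= min(len1, len2)``) is valid iff the last ``v``
    bases of mate 1 equal the first ``v`` bases of R2' exactly, with no N
    anywhere in the overlap (N matches nothing, not even N).  Exactly one
    valid ``v`` merges the pair into ``seq1 + R2'[v:]``; two or more valid
    overlaps reject the pair as ambiguous; none rejects it as no-overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq1 = pair.seq1
    r2p = revcomp(pair.seq2)
    hi = min(len(seq1), len(r2p))
    if min_overlap > hi:
        return MergeRejected(pair.id, "no_overlap")
    probe = r2p[:min_overlap]
    valid: list[int] = []
    # any valid overlap of length v starts at i = len1 - v and must open
    # with `probe`; scan occurrences of the probe instead of every v
    i = seq1.find(probe, len(seq1) - hi)
    while i != -1:
        v = len(seq1) - i
        segment = r2p[:v]
        if seq1.endswith(segment) and "N" not in segment:
            valid.append(v)
        i = seq1.find(probe, i + 1)
    if not valid:
        return MergeRejected(pair.id, "no_overlap")
    if len(valid) > 1:
        return MergeRejected(pair.id, "ambiguous")
    v = valid[0]
    return MergedRead(
        id=pair.id, locus=None, sequence=seq1 + r2p[v:], overlap_len=v
    )


def merge_all(
    pairs: Iterable[ReadPair], min_overlap: int = 20, locus: str | None = None
) -> tuple[list[MergedRead], dict[str, int]]:
    """Merge every pair; returns merged reads (tagged with ``locus``) and a
    summary of rejection reasons."""
    merged: list[MergedRead] = []
    stats = {"merged": 0, "rejected_no_overlap": 0, "rejected_ambiguous": 0}
    for pair in pairs:
        result = merge_pair(pair, min_overlap)
        if isinstance(result, MergedRead):
            if locus is not None:
                result = MergedRead(result.id, locus, result.sequence, result.overlap_len)
            merged.append(result)
            stats["merged"] += 1
        else:
            stats[f"rejected_{result.reason}"] += 1
    return merged, stats


def kmer_match_count(seq: str, ref_kmers: frozenset[str], k: int) -> int:
    """Number of positions of ``seq`` whose k-mer occurs in the reference."""
    return sum(1 for kmer in _kmers(seq, k) if kmer in ref_kmers)


def orient(merged: MergedRead, locus_ref: LocusRef, k: int = 31) -> MergedRead:
    """Flip a merged read onto the reference strand.

    The sequence is replaced by its reverse complement iff the reverse
    complement shares strictly more k-mers with the reference; ties keep
    the original orientation.
    """
    ref_kmers = frozenset(_kmers(locus_ref.sequence, k))
    fwd = kmer_match_count(merged.sequence, ref_kmers, k)
    rev = kmer_match_count(revcomp(merged.sequence), ref_kmers, k)
    if rev > fwd:
        return MergedRead(
            merged.id, merged.locus, revcomp(merged.sequence), merged.overlap_len
        )
    return merged


def orient_all(
    merged: Iterable[MergedRead], locus_ref: LocusRef, k: int = 31
) -> list[MergedRead]:
    ref_kmers = frozenset(_kmers(locus_ref.sequence, k))
    out = []
    for read in merged:
        fwd = kmer_match_count(read.sequence, ref_kmers, k)
        rev = kmer_match_count(revcomp(read.sequence), ref_kmers, k)
        if rev > fwd:
            read = MergedRead(read.id, read.locus, revcomp(read.sequence), read.overlap_len)
        out.append(read)
    return out


def write_fasta(merged: Iterable[MergedRead], path: str | Path) -> None:
    """Write merged reads as FASTA (id includes the overlap length)."""
    with open(path, "w") as handle:
        for read in merged:
            handle.write(f">{read.id} overlap={read.overlap_len}\n{read.sequence}\n")


def read_merged_fasta(path: str | Path, locus: str | None = None) -> list[MergedRead]:
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        overlap = 0
        for token in record.description.split():
            if token.startswith("overlap="):
                overlap = int(token.split("=", 1)[1])
        out.append(MergedRead(record.id, locus, str(record.seq).upper(), overlap))
    return out
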