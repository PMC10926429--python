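"""Per-base SNP profiling: alignment, pileup, weighted combination, entropy.

Retained haplotypes are globally aligned to the reference amplicon
(full-length, primer-anchored sequences justify global rather than local
alignment) and each aligned column contributes the haplotype's read count
to a per-position nucleotide tally.  The variant model is SNP-only:
insertions relative to the reference are ignored and deletions simply
reduce depth.  Profiles from several samples combine as a weighted mean of
per-position base frequencies, weighted by the number of individuals
sequenced per pool, so that every fly contributes equally to the
population profile regardless of its sample's read depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .hapcall import HaplotypeTable
from .refpanel import LocusRef, SampleMeta

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

_NEG = -1e18  # effectively -inf; stays exact under float addition of small ints


@dataclass(frozen=True)
class AlignScores:
    """Affine-gap scoring: a gap of length k costs open + (k-1)*extend."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment of a haplotype against the reference."""

    score: float
    ref_aln: str
    hap_aln: str


def align_haplotype(
    haplotype: str, locus_ref: LocusRef | str, scores: AlignScores = AlignScores()
) -> Alignment:
    """Global affine-gap alignment (Gotoh) with deterministic traceback.

    Ties prefer match/mismatch over gaps, then gap-in-reference over
    gap-in-haplotype.  Row-vectorized over the haplotype axis; the
    horizontal gap state is resolved with a running-maximum scan, so the
    whole DP is O(n) numpy passes.
    """
    ref = locus_ref.sequence if isinstance(locus_ref, LocusRef) else locus_ref
    hap = haplotype
    n, m = len(ref), len(hap)
    sc = scores
    open_, ext = sc.gap_open, sc.gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in haplotype (consumes ref)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in reference (consumes hap)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = open_ + np.arange(m) * ext
    hap_arr = np.frombuffer(hap.encode(), dtype=np.uint8)
    js = np.arange(m)

    for i in range(1, n + 1):
        sub = np.where(hap_arr == ord(ref[i - 1]), sc.match, sc.mismatch)
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + sub
        M[i, 0] = _NEG
        Ix[i] = np.maximum(
            np.maximum(M[i - 1], Iy[i - 1]) + open_, Ix[i - 1] + ext
        )
        if m:
            # Iy[i, j] = max_{k<j} (max(M[i,k], Ix[i,k]) + open) + (j-1-k)*ext
            base = np.maximum(M[i, :-1], Ix[i, :-1]) + open_
            running = np.maximum.accumulate(base - js * ext)
            Iy[i, 1:] = running + js * ext

    # deterministic state preference: M, then Iy (gap in ref), then Ix
    def best_state(i: int, j: int) -> str:
        value = max(M[i, j], Iy[i, j], Ix[i, j])
        if M[i, j] == value:
            return "M"
        if Iy[i, j] == value:
            return "Iy"
        return "Ix"

    score = max(M[n, m], Iy[n, m], Ix[n, m])
    state = best_state(n, m)
    i, j = n, m
    ref_parts: list[str] = []
    hap_parts: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ref_parts.append(ref[i - 1])
            hap_parts.append(hap[j - 1])
            i, j = i - 1, j - 1
            state = best_state(i, j)
        elif state == "Iy":
            ref_parts.append("-")
            hap_parts.append(hap[j - 1])
            value = Iy[i, j]
            j -= 1
            if M[i, j] + open_ == value:
                state = "M"
            elif Iy[i, j] + ext == value:
                state = "Iy"
            else:
                state = "Ix"
        else:  # Ix
            ref_parts.append(ref[i - 1])
            hap_parts.append("-")
            value = Ix[i, j]
            i -= 1
            if M[i, j] + open_ == value:
                state = "M"
            elif Iy[i, j] + open_ == value:
                state = "Iy"
            else:
                state = "Ix"
    return Alignment(float(score), "".join(reversed(ref_parts)), "".join(reversed(hap_parts)))


@dataclass(frozen=True)
class SNPProfile:
    """Per-position nucleotide counts for one (sample, locus).

    ``counts[pos, b]`` is haplotype-count-weighted read support for base b
    at reference position pos; depth is the row sum; ``snp_freq`` the
    fraction of support differing from the reference base.  Primer-interval
    positions are flagged non-informative via ``primer_mask``.
    """

    locus: str
    ref: str
    counts: np.ndarray  # (L, 4) int
    primer_mask: np.ndarray  # (L,) bool

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.ref), 4):
            raise ValueError("counts must have shape (len(ref), 4)")
        if self.primer_mask.shape != (len(self.ref),):
            raise ValueError("primer_mask must have shape (len(ref),)")

    @property
    def length(self) -> int:
        return len(self.ref)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def ref_idx(self) -> np.ndarray:
        return np.array([_BASE_IDX[b] for b in self.ref])

    @property
    def base_freqs(self) -> np.ndarray:
        depth = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = self.counts / depth[:, None]
        freqs[depth == 0] = 0.0
        return freqs

    @property
    def snp_freq(self) -> np.ndarray:
        depth = self.depth.astype(float)
        ref_counts = self.counts[np.arange(self.length), self.ref_idx]
        out = np.zeros(self.length)
        covered = depth > 0
        out[covered] = (depth[covered] - ref_counts[covered]) / depth[covered]
        return out


@dataclass(frozen=True)
class CombinedProfile:
    """Population SNP profile: individual-weighted mean base frequencies."""

    locus: str
    ref: str
    freqs: np.ndarray  # (L, 4) float, rows sum to <= 1
    primer_mask: np.ndarray
    n_individuals: int

    @property
    def length(self) -> int:
        return len(self.ref)

    @property
    def ref_idx(self) -> np.ndarray:
        return np.array([_BASE_IDX[b] for b in self.ref])

    @property
    def base_freqs(self) -> np.ndarray:
        return self.freqs

    @property
    def snp_freq(self) -> np.ndarray:
        row_sum = self.freqs.sum(axis=1)
        ref_freq = self.freqs[np.arange(self.length), self.ref_idx]
        return row_sum - ref_freq


Profile = Union[SNPProfile, CombinedProfile]


def pileup(
    table: HaplotypeTable,
    locus_ref: LocusRef,
    scores: AlignScores = AlignScores(),
    score_floor: float = 0.0,
) -> SNPProfile:
    """Align every retained haplotype and tally per-position base support.

    Match/mismatch columns add the haplotype's count at the reference
    position; insertions are ignored; deleted reference positions receive
    nothing from that haplotype (SNP-only model).  Haplotypes aligning
    below ``score_floor`` are excluded and logged.
    """
    length = len(locus_ref.sequence)
    counts = np.zeros((length, 4), dtype=np.int64)
    for row in table.rows:
        aln = align_haplotype(row.sequence, locus_ref, scores)
        if aln.score < score_floor:
            log.warning(
                "%s/%s: haplotype (count %d) alignment score %.1f below floor "
                "%.1f; excluded from pileup",
                table.sample_id, table.locus, row.count, aln.score, score_floor,
            )
            continue
        ref_pos = 0
        for ref_char, hap_char in zip(aln.ref_aln, aln.hap_aln):
            if ref_char != "-":
                if hap_char != "-" and hap_char in _BASE_IDX:
                    counts[ref_pos, _BASE_IDX[hap_char]] += row.count
                ref_pos += 1
    return SNPProfile(
        locus=locus_ref.name,
        ref=locus_ref.sequence,
        counts=counts,
        primer_mask=locus_ref.primer_mask(),
    )


def combine_weighted(
    profiles_with_meta: Sequence[tuple[SNPProfile, SampleMeta]],
) -> CombinedProfile:
    """Combine per-sample profiles into a population profile.

    Each sample contributes its per-position base frequencies with weight
    ``n_individuals / total_individuals``.  Positions a sample does not
    cover contribute zero while the weight stays unchanged (logged), so
    combined rows can sum below 1 there.
    """
    if not profiles_with_meta:
        raise ValueError("no profiles to combine")
    first = profiles_with_meta[0][0]
    total_n = sum(meta.n_individuals for _, meta in profiles_with_meta)
    freqs = np.zeros((first.length, 4))
    for profile, meta in profiles_with_meta:
        if profile.locus != first.locus or profile.length != first.length:
            raise ValueError(
                f"cannot combine profiles for {profile.locus}({profile.length}) "
                f"and {first.locus}({first.length})"
            )
        uncovered = int((profile.depth == 0).sum())
        if uncovered:
            log.info(
                "%s/%s: %d uncovered positions contribute 0 at weight %d/%d",
                meta.sample_id, profile.locus, uncovered,
                meta.n_individuals, total_n,
            )
        freqs += (meta.n_individuals / total_n) * profile.base_freqs
    return CombinedProfile(
        locus=first.locus,
        ref=first.ref,
        freqs=freqs,
        primer_mask=first.primer_mask,
        n_individuals=total_n,
    )


def shannon_entropy(profile: Profile) -> tuple[np.ndarray, float]:
    """Per-position Shannon entropy in bits and its mean over covered
    non-primer positions.

    ``H(pos) = -sum_b p_b log2 p_b`` with ``0 log 0 = 0``; base frequencies
    are renormalized per position (combined profiles can have row sums
    below 1 at partially covered positions).
    """
    freqs = profile.base_freqs
    row_sum = freqs.sum(axis=1)
    covered = row_sum > 0
    p = np.zeros_like(freqs)
    p[covered] = freqs[covered] / row_sum[covered, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    entropy = terms.sum(axis=1)
    informative = covered & ~profile.primer_mask
    mean = float(entropy[informative].mean()) if informative.any() else 0.0
    return entropy, mean


def write_vcf(profile: SNPProfile, path: str | Path, sample_id: str = "") -> None:
    """Write one record per position with any alternate support (VCF v4.2,
    1-based POS; INFO carries DP and per-alternate AF)."""
    header = pysam.VariantHeader()
    header.add_meta("source", value="amplihap")
    if sample_id:
        header.add_meta("amplihap_sample", value=sample_id)
    header.contigs.add(profile.locus, length=profile.length)
    header.info.add("DP", number=1, type="Integer", description="Read-support depth")
    header.info.add("AF", number="A", type="Float", description="Alternate base frequency")
    depth = profile.depth
    ref_idx = profile.ref_idx
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos in range(profile.length):
            alt_counts = [
                (int(self_count), b)
                for b, self_count in zip(BASES, profile.counts[pos])
                if _BASE_IDX[b] != ref_idx[pos] and self_count > 0
            ]
            if not alt_counts:
                continue
            alt_counts.sort(key=lambda cb: (-cb[0], cb[1]))
            alts = tuple(b for _, b in alt_counts)
            record = vcf.new_record(
                contig=profile.locus,
                start=pos,
                stop=pos + 1,
                alleles=(profile.ref[pos],) + alts,
            )
            record.info["DP"] = int(depth[pos])
            record.info["AF"] = tuple(
                count / depth[pos] for count, _ in alt_counts
            )
            vcf.write(record)


def _profile_frame(positions: np.ndarray, ref: str, matrix: np.ndarray,
                   depth_col: np.ndarray, snp_freq: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pos": positions,
            "ref": list(ref),
            "A": matrix[:, 0],
            "C": matrix[:, 1],
            "G": matrix[:, 2],
            "T": matrix[:, 3],
            "depth": depth_col,
            "snp_freq": snp_freq,
        }
    )


def write_profile_tsv(profile: Profile, path: str | Path) -> None:
    """Per-position TSV: pos (0-based), ref, A, C, G, T, depth, snp_freq.

    Per-sample profiles store integer counts; combined profiles store
    weighted frequencies with depth = total individuals.
    """
    positions = np.arange(profile.length)
    if isinstance(profile, SNPProfile):
        frame = _profile_frame(positions, profile.ref, profile.counts,
                               profile.depth, profile.snp_freq)
    else:
        depth_col = np.full(profile.length, profile.n_individuals)
        frame = _profile_frame(positions, profile.ref, profile.freqs,
                               depth_col, profile.snp_freq)
    frame.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path, locus_ref: LocusRef) -> SNPProfile:
    """Read back a per-sample (integer-count) profile TSV."""
    frame = pd.read_csv(path, sep="\t")
    counts = frame[["A", "C", "G", "T"]].to_numpy()
    if not np.allclose(counts, np.rint(counts)):
        raise ValueError(f"{path}: expected integer counts (per-sample profile)")
    return SNPProfile(
        locus=locus_ref.name,
        ref=locus_ref.sequence,
        counts=counts.astype(np.int64),
        primer_mask=locus_ref.primer_mask(),
    )


def read_combined_tsv(path: str | Path, locus_ref: LocusRef) -> CombinedProfile:
    """Read back a combined (frequency) profile TSV."""
    frame = pd.read_csv(path, sep="\t")
    return CombinedProfile(
        locus=locus_ref.name,
        ref=locus_ref.sequence,
        freqs=frame[["A", "C", "G", "T"]].to_numpy(dtype=float),
        primer_mask=locus_ref.primer_mask(),
        n_individuals=int(frame["depth"].iloc[0]) if len(frame) else 0,
    )
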