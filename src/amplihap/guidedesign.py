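"""Conserved-region calling and population-aware CRISPR guide scanning.

Genetic biocontrol designs that bind a specific promoter sequence (e.g. a
dCas9-based programmable transcription activator) fail on individuals
carrying SNPs in the binding site.  This module finds promoter windows
where every base, with a 15-bp flank on both sides, is free of SNPs above
a frequency threshold, enumerates all 20-nt protospacer + NGG PAM sites in
the non-primer interior, scores each by its summed SNP percentage, and
measures the frequency-weighted fraction of observed haplotypes that an
exact-match guide would still bind.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hapcall import HaplotypeTable
from .refpanel import LocusRef, revcomp
from .snpcall import Profile


@dataclass(frozen=True)
class ConservedWindow:
    """Maximal run of conserved bases (0-based half-open, reference
    coordinates, entirely inside the non-primer interior)."""

    locus: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("window must span at least one base")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GuideCandidate:
    """A 23-mer protospacer+PAM site scored against the population.

    ``start`` is the reference coordinate of the site's leftmost base;
    ``strand`` is '+' when the NGG is read on the reference strand and '-'
    when on its reverse complement.  ``summed_snp_pct`` sums the population
    SNP frequency (x100) over the 20 protospacer positions and the two G
    positions of the PAM; the N position is unconstrained and excluded.
    ``coverage`` is the frequency-weighted fraction of haplotypes carrying
    the site exactly (None until scored against a haplotype table).
    """

    locus: str
    strand: str
    start: int
    protospacer: str
    pam: str
    summed_snp_pct: float
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.protospacer) != 20 or len(self.pam) != 3:
            raise ValueError("expected a 20-nt protospacer and 3-nt PAM")
        if self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG on the scanned strand")
        if self.summed_snp_pct < 0:
            raise ValueError("summed_snp_pct must be >= 0")


def conserved_bases(
    profile: Profile, flank: int = 15, max_freq: float = 0.002
) -> list[ConservedWindow]:
    """Maximal runs of conserved bases under the flank rule.

    Base i is conserved iff every position j with ``|j - i| <= flank``
    exists, lies in the non-primer interior, and has SNP frequency strictly
    below ``max_freq`` (a SNP at exactly the threshold disqualifies).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not 0 < max_freq <= 1:
        raise ValueError("max_freq must be in (0, 1]")
    ok = (~profile.primer_mask) & (profile.snp_freq < max_freq)
    length = profile.length
    window = 2 * flank + 1
    if length < window:
        return []
    # conserved[i] = all(ok[i-flank : i+flank+1]) for full in-bounds flanks
    cumulative = np.concatenate(([0], np.cumsum(ok.astype(int))))
    run_sums = cumulative[window:] - cumulative[:-window]  # sum over each window
    conserved = np.zeros(length, dtype=bool)
    conserved[flank:length - flank] = run_sums == window
    windows: list[ConservedWindow] = []
    start = None
    for i in range(length + 1):
        if i < length and conserved[i]:
            if start is None:
                start = i
        elif start is not None:
            windows.append(ConservedWindow(profile.locus, start, i))
            start = None
    return windows


def has_pta_window(windows: Iterable[ConservedWindow], min_len: int = 30) -> bool:
    """Whether any conserved window is long enough for PTA targeting
    (strictly more than ``min_len`` bases)."""
    return any(len(w) > min_len for w in windows)


def _assessed_positions(strand: str, start: int) -> list[int]:
    """Reference coordinates scored for a site at ``start``: the 23-mer
    minus the PAM N position."""
    if strand == "+":
        skip = start + 20  # N of NGG on the reference strand
    else:
        skip = start + 2   # N of NGG reads at the right end in ref coords
    return [p for p in range(start, start + 23) if p != skip]


def enumerate_guides(locus_ref: LocusRef, profile: Profile) -> list[GuideCandidate]:
    """Scan both strands for 20-nt protospacers followed by NGG.

    The whole 23-mer must lie inside the non-primer interior (conservation
    inside primers is a primer-anchoring artifact).  SNP frequencies are
    strand-symmetric, so reverse-strand candidates score reference-strand
    ``snp_freq`` at their mapped coordinates.  Candidates are sorted by
    reference start, '+' before '-'.
    """
    if profile.locus != locus_ref.name:
        raise ValueError("profile and locus_ref must describe the same locus")
    seq = locus_ref.sequence
    length = len(seq)
    snp_pct = 100.0 * profile.snp_freq
    lo, hi = locus_ref.interior
    out: list[GuideCandidate] = []
    for strand, scanned in (("+", seq), ("-", revcomp(seq))):
        for s in range(len(scanned) - 22):
            if scanned[s + 21:s + 23] != "GG":
                continue
            if strand == "+":
                start = s
            else:
                start = length - 23 - s
            if not (lo <= start and start + 23 <= hi):
                continue
            out.append(
                GuideCandidate(
                    locus=locus_ref.name,
                    strand=strand,
                    start=start,
                    protospacer=scanned[s:s + 20],
                    pam=scanned[s + 20:s + 23],
                    summed_snp_pct=float(
                        sum(snp_pct[p] for p in _assessed_positions(strand, start))
                    ),
                )
            )
    out.sort(key=lambda g: (g.start, g.strand))
    return out


def guide_coverage(candidate: GuideCandidate, table: HaplotypeTable) -> float:
    """Frequency-weighted fraction of haplotypes an exact-match guide hits.

    A haplotype is covered iff protospacer+PAM occurs exactly in it on
    either strand, with the PAM N position as a wildcard.
    """
    if table.locus != candidate.locus:
        raise ValueError("candidate and table must describe the same locus")
    pattern = re.compile(
        candidate.protospacer + "[ACGTN]" + candidate.pam[1:]
    )
    covered = 0.0
    for row in table.rows:
        if pattern.search(row.sequence) or pattern.search(revcomp(row.sequence)):
            covered += row.frequency
    return covered


def score_coverage(
    candidates: Iterable[GuideCandidate], table: HaplotypeTable
) -> list[GuideCandidate]:
    """Return candidates with ``coverage`` filled in."""
    out = []
    for candidate in candidates:
        out.append(
            GuideCandidate(
                locus=candidate.locus,
                strand=candidate.strand,
                start=candidate.start,
                protospacer=candidate.protospacer,
                pam=candidate.pam,
                summed_snp_pct=candidate.summed_snp_pct,
                coverage=guide_coverage(candidate, table),
            )
        )
    return out


def classify_guides(
    candidates: Sequence[GuideCandidate],
    thresholds: Sequence[float] = (5.0, 1.0, 0.5),
) -> dict[float, int]:
    """Count candidates with summed SNP percentage strictly below each
    threshold.  Thresholds must be descending; counts are nested
    (monotone non-increasing)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be in descending order")
    return {
        t: sum(1 for c in candidates if c.summed_snp_pct < t) for t in thresholds
    }


def write_bed(windows: Iterable[ConservedWindow], path: str | Path) -> None:
    """Conserved windows as BED (0-based half-open; name = locus)."""
    with open(path, "w") as handle:
        for w in windows:
            handle.write(f"{w.locus}\t{w.start}\t{w.end}\t{w.locus}\n")


def write_guides_tsv(candidates: Iterable[GuideCandidate], path: str | Path) -> None:
    rows = list(candidates)
    pd.DataFrame(
        {
            "locus": [g.locus for g in rows],
            "strand": [g.strand for g in rows],
            "start": [g.start for g in rows],
            "protospacer": [g.protospacer for g in rows],
            "pam": [g.pam for g in rows],
            "summed_snp_pct": [g.summed_snp_pct for g in rows],
            "coverage": [g.coverage for g in rows],
        }
    ).to_csv(path, sep="\t", index=False)
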