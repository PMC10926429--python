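"""Comparing haplotype tables across sites and seasons, and pool-design
power arithmetic.

The headline comparisons are deliberately simple: a coefficient of
determination measured against the identity line y = x (how close two
populations' haplotype frequencies are to being *the same*, not merely
correlated), a through-origin regression (for technical replicates where
proportionality is the question), and a top-N rank overlap.  Detection
limits follow from the minimum-support filter: a haplotype at frequency f
in a pool of n individuals receives about f*n*(reads per individual)
merged reads under even amplification, and must clear the minimum support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .hapcall import HaplotypeTable


@dataclass(frozen=True)
class FrequencyPairing:
    """Frequencies of the same haplotypes in two tables (0 when absent)."""

    keys: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class DetectionDesign:
    """Design point for the detection-limit arithmetic."""

    f: float
    n_individuals: int
    min_support: int = 5
    merge_rate: float = 0.40

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("target frequency f must be in (0, 1]")
        if not 0 < self.merge_rate <= 1:
            raise ValueError("merge_rate must be in (0, 1]")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass(frozen=True)
class DepthRequirement:
    """Sequencing depth needed to detect a haplotype at frequency f."""

    merged_per_individual: Fraction
    read_pairs_per_individual: Fraction

    @property
    def merged_per_individual_ceil(self) -> int:
        return math.ceil(self.merged_per_individual)

    @property
    def read_pairs_per_individual_ceil(self) -> int:
        return math.ceil(self.read_pairs_per_individual)


def pair_frequencies(
    table_a: HaplotypeTable, table_b: HaplotypeTable, mode: str = "union"
) -> FrequencyPairing:
    """Pair haplotype frequencies from two tables.

    ``union`` includes haplotypes present in either table (0 if absent);
    ``shared`` restricts to the intersection (the convention for
    identity-line comparison of two field sites).
    """
    fa, fb = table_a.freq_map(), table_b.freq_map()
    if mode == "union":
        keys = sorted(set(fa) | set(fb))
    elif mode == "shared":
        keys = sorted(set(fa) & set(fb))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FrequencyPairing(
        keys=tuple(keys),
        x=np.array([fa.get(k, 0.0) for k in keys]),
        y=np.array([fb.get(k, 0.0) for k in keys]),
    )


def identity_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination with residuals measured from y = x.

    ``R^2 = 1 - sum((y-x)^2) / sum((y-ybar)^2)``; equals 1 iff y = x
    exactly, and can be negative when the identity line fits worse than the
    mean.  Undefined (raises) when y is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with at least 2 points")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("identity-line R^2 undefined: y has zero variance")
    ss_res = float(((y - x) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def origin_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares regression through the origin.

    Returns ``(slope, R^2)`` with ``slope = sum(xy)/sum(x^2)`` and the
    uncentered total sum of squares in the denominator, as required for a
    fixed-intercept fit: ``R^2 = 1 - sum((y - b x)^2) / sum(y^2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be equal length")
    sxx = float((x * x).sum())
    if sxx == 0:
        raise ValueError("through-origin regression undefined: all x are zero")
    slope = float((x * y).sum()) / sxx
    syy = float((y * y).sum())
    if syy == 0:
        return slope, 1.0 if np.allclose(y, slope * x) else 0.0
    ss_res = float(((y - slope * x) ** 2).sum())
    return slope, 1.0 - ss_res / syy


def _ranked(table: HaplotypeTable) -> list[str]:
    return [
        row.sequence
        for row in sorted(table.rows, key=lambda r: (-r.frequency, r.sequence))
    ]


def rank_overlap(
    table_a: HaplotypeTable, table_b: HaplotypeTable, n_max: int = 250
) -> np.ndarray:
    """Fraction of the top-N haplotypes shared between two samples.

    Haplotypes are rank-ordered by descending frequency (ties lexicographic
    by sequence); ``overlap[N-1] = |topN(A) & topN(B)| / N`` for N from 1
    to ``min(n_max, |A|, |B|)``.  Symmetric in its two tables.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not table_a.rows or not table_b.rows:
        raise ValueError("rank overlap undefined for empty tables")
    ranked_a, ranked_b = _ranked(table_a), _ranked(table_b)
    limit = min(n_max, len(ranked_a), len(ranked_b))
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    out = np.zeros(limit)
    shared = 0
    for n in range(1, limit + 1):
        a, b = ranked_a[n - 1], ranked_b[n - 1]
        if a == b:
            shared += 1
        else:
            if a in seen_b:
                shared += 1
            if b in seen_a:
                shared += 1
        seen_a.add(a)
        seen_b.add(b)
        out[n - 1] = shared / n
    return out


def partition_shared(
    table_a: HaplotypeTable, table_b: HaplotypeTable
) -> tuple[list[tuple[str, float, float]], dict[str, float], dict[str, float]]:
    """Split two tables into shared pairings and site-unique haplotypes.

    Returns ``(shared, a_only, b_only)`` where shared rows are
    ``(sequence, freq_in_a, freq_in_b)``.
    """
    fa, fb = table_a.freq_map(), table_b.freq_map()
    shared = [(k, fa[k], fb[k]) for k in sorted(set(fa) & set(fb))]
    a_only = {k: fa[k] for k in sorted(set(fa) - set(fb))}
    b_only = {k: fb[k] for k in sorted(set(fb) - set(fa))}
    return shared, a_only, b_only


def _fraction(value: float) -> Fraction:
    return Fraction(value).limit_denominator(10**6)


def required_depth(
    f: float,
    n_individuals: int,
    min_support: int = 5,
    merge_rate: float = 0.40,
) -> DepthRequirement:
    """Sequencing depth per individual needed to detect frequency ``f``.

    Under even amplification a haplotype at frequency f in n individuals
    captures fraction f of the pool's merged reads, so it needs
    ``min_support / (f * n)`` merged reads per individual, and
    ``merge_rate`` of raw pairs merging inflates that to
    ``merged / merge_rate`` raw read pairs per individual.  Exact rationals
    are kept; ceilings are available on the result.
    """
    design = DetectionDesign(f, n_individuals, min_support, merge_rate)
    denom = _fraction(design.f) * design.n_individuals
    if denom == 0:
        raise ValueError("f * n_individuals must be > 0")
    merged = Fraction(design.min_support) / denom
    return DepthRequirement(
        merged_per_individual=merged,
        read_pairs_per_individual=merged / _fraction(design.merge_rate),
    )


def max_pool_size(
    read_pairs_available: int,
    merge_rate: float = 0.40,
    min_support: int = 5,
    ploidy_accounting: bool = False,
) -> int:
    """Largest pool in which a single-carrier haplotype still clears the
    support floor.

    ``n_max = floor(read_pairs * merge_rate / min_support)`` counts each
    individual as one sequencing unit (per-individual accounting).  With
    ``ploidy_accounting=True`` each diploid individual contributes two
    haplotype copies that must each reach the floor, halving the answer.
    """
    if read_pairs_available < 0:
        raise ValueError("read_pairs_available must be >= 0")
    if not 0 < merge_rate <= 1:
        raise ValueError("merge_rate must be in (0, 1]")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    units = _fraction(merge_rate) * read_pairs_available / min_support
    if ploidy_accounting:
        units /= 2
    return math.floor(units)
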