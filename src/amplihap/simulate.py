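"""Synthetic amplicon pools with known haplotype composition.

Stands in for field-caught insect pools: a population of amplicon
haplotypes at specified frequencies is sampled into a pool of diploid
individuals, and paired-end reads are generated from pool molecules with
the PCR and sequencing artifacts the pipeline must be robust to —
polymerase substitution errors, template switching (PCR chimeras),
truncated-primer amplicons, and position-dependent sequencing error that
increases toward the read ends.

Ground truth (nominal frequencies and realized copy counts) is kept
alongside the reads so every downstream estimate can be checked against
what was actually in the pool rather than what was asked for.
"""

from __future__ import annotations

import gzip
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .refpanel import DNA, LocusRef, ReferencePanel, TARGET_PROMOTERS, revcomp

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Artifact rates for one simulated sequencing run.

    sub_rate_start / sub_rate_end
        Per-base substitution probability at the first and last read
        position; intermediate positions interpolate linearly (models
        end-of-read quality decay).
    polymerase_error_rate
        Per-base substitution probability introduced during amplification
        (a high-fidelity proofreading polymerase sits near 6.7e-7).
    truncated_primer_fraction
        Probability that an amplicon derives from a primer oligo missing
        1-5 terminal bases, shortening the molecule at one end.
    template_switch_rate
        Probability that an amplicon is a PCR chimera: a crossover of two
        pool molecules at a uniform interior breakpoint.
    amplification_sigma
        Log-normal sigma for per-template amplification factors (PCR
        stochasticity).  Default 0 = even amplification.
    """

    sub_rate_start: float = 1e-3
    sub_rate_end: float = 1e-2
    polymerase_error_rate: float = 6.7e-7
    truncated_primer_fraction: float = 0.02
    template_switch_rate: float = 2e-3
    amplification_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "sub_rate_start",
            "sub_rate_end",
            "polymerase_error_rate",
            "truncated_primer_fraction",
            "template_switch_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.amplification_sigma < 0:
            raise ValueError("amplification_sigma must be >= 0")

    @classmethod
    def none(cls) -> "ErrorModel":
        """Artifact-free model: reads reproduce pool molecules exactly."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Haplotype:
    label: str
    sequence: str
    frequency: float


@dataclass(frozen=True)
class PopulationSpec:
    """The haplotypes segregating at one locus and their frequencies."""

    locus: str
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("population must contain at least one haplotype")
        freqs = [h.frequency for h in self.haplotypes]
        if min(freqs) <= 0:
            raise ValueError("haplotype frequencies must be > 0")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {sum(freqs)}, not 1")
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences must be unique")
        labels = [h.label for h in self.haplotypes]
        if len(set(labels)) != len(labels):
            raise ValueError("haplotype labels must be unique")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(h.label for h in self.haplotypes)

    def sequence(self, label: str) -> str:
        return next(h.sequence for h in self.haplotypes if h.label == label)

    def frequency(self, label: str) -> float:
        return next(h.frequency for h in self.haplotypes if h.label == label)

    def validate_against(self, locus_ref: LocusRef) -> None:
        """Check every haplotype keeps the reference primer prefix/suffix."""
        tail = revcomp(locus_ref.rev_primer)
        for h in self.haplotypes:
            if not (h.sequence.startswith(locus_ref.fwd_primer) and h.sequence.endswith(tail)):
                raise ValueError(
                    f"haplotype {h.label} does not carry the {locus_ref.name} primers"
                )


@dataclass(frozen=True)
class PoolSample:
    """A pool of individuals: the multiset of haplotype copies actually drawn."""

    individuals: int
    ploidy: int
    copies: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.copies) != self.individuals * self.ploidy:
            raise ValueError("copies must have size individuals * ploidy")

    @property
    def realized_counts(self) -> Counter:
        return Counter(self.copies)

    def realized_frequency(self, label: str) -> float:
        return self.realized_counts[label] / len(self.copies)


def _mutate(rng: np.random.Generator, sequence: str, positions: Iterable[int]) -> str:
    chars = list(sequence)
    for pos in positions:
        current = chars[pos]
        options = [b for b in _BASES if b != current]
        chars[pos] = options[rng.integers(len(options))]
    return "".join(chars)


def make_population(
    locus_ref: LocusRef,
    mode: str,
    seed: int,
    *,
    n_discriminatory_snps: int = 5,
    ratio: tuple[float, float] = (1.0, 1.0),
    n_haplotypes: int = 10,
    snp_rate: float = 0.01,
    freq_scheme: str = "dirichlet",
) -> PopulationSpec:
    """Construct a known haplotype population for one locus.

    ``spike_in`` yields exactly two haplotypes (the reference and a variant
    differing at ``n_discriminatory_snps`` interior positions) at
    frequencies ``ratio``, emulating a two-line genomic-DNA mixing control.
    ``random`` yields ``n_haplotypes`` unique haplotypes whose interior
    bases mutate independently at ``snp_rate``, with frequencies from
    ``freq_scheme`` ("uniform", "dirichlet", or "geometric").
    """
    rng = np.random.default_rng(seed)
    lo, hi = locus_ref.interior
    interior = np.arange(lo, hi)

    if mode == "spike_in":
        if n_discriminatory_snps > len(interior):
            raise ValueError(
                f"{n_discriminatory_snps} discriminatory SNPs exceed the "
                f"{len(interior)} non-primer positions of {locus_ref.name}"
            )
        positions = rng.choice(interior, size=n_discriminatory_snps, replace=False)
        variant = _mutate(rng, locus_ref.sequence, sorted(int(p) for p in positions))
        a, b = float(ratio[0]), float(ratio[1])
        total = a + b
        haps = (
            Haplotype("A", locus_ref.sequence, a / total),
            Haplotype("B", variant, b / total),
        )
    elif mode == "random":
        if n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")
        seqs = [locus_ref.sequence]
        attempts = 0
        while len(seqs) < n_haplotypes:
            attempts += 1
            if attempts > 100 * n_haplotypes:
                raise ValueError(
                    "could not generate unique haplotypes; raise snp_rate"
                )
            hits = interior[rng.random(len(interior)) < snp_rate]
            candidate = _mutate(rng, locus_ref.sequence, (int(p) for p in hits))
            if candidate not in seqs:
                seqs.append(candidate)
        if freq_scheme == "uniform":
            freqs = np.full(n_haplotypes, 1.0 / n_haplotypes)
        elif freq_scheme == "dirichlet":
            freqs = rng.dirichlet(np.ones(n_haplotypes))
        elif freq_scheme == "geometric":
            freqs = 0.5 ** np.arange(n_haplotypes, dtype=float)
            freqs /= freqs.sum()
        else:
            raise ValueError(f"unknown freq_scheme {freq_scheme!r}")
        width = len(str(n_haplotypes - 1))
        haps = tuple(
            Haplotype(f"H{i:0{width}d}", seq, float(f))
            for i, (seq, f) in enumerate(zip(seqs, freqs))
        )
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'spike_in' or 'random'")

    population = PopulationSpec(locus=locus_ref.name, haplotypes=haps)
    population.validate_against(locus_ref)
    return population


def sample_pool(
    population: PopulationSpec,
    n_individuals: int,
    ploidy: int = 2,
    seed: int = 0,
) -> PoolSample:
    """Draw a pool of individuals: haplotype copies i.i.d. from the
    population frequencies."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.array(population.labels)
    freqs = np.array([h.frequency for h in population.haplotypes])
    freqs = freqs / freqs.sum()
    draws = rng.choice(len(labels), size=n_individuals * ploidy, p=freqs)
    return PoolSample(
        individuals=n_individuals,
        ploidy=ploidy,
        copies=tuple(labels[draws]),
        seed=seed,
    )


def _quality_string(rates: np.ndarray) -> str:
    with np.errstate(divide="ignore"):
        q = np.where(rates > 0, -10.0 * np.log10(np.maximum(rates, 1e-12)), 41.0)
    q = np.clip(np.rint(q), 2, 41).astype(int)
    return "".join(chr(int(v) + 33) for v in q)


def sequence_pool(
    pool: PoolSample,
    population: PopulationSpec,
    error_model: ErrorModel,
    read_length: int,
    n_read_pairs: int,
    seed: int,
    id_prefix: str = "sim",
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Simulate paired-end reads from pool molecules.

    Each read pair derives from one amplicon molecule: a haplotype copy
    drawn (uniformly, or log-normally weighted when PCR stochasticity is
    on) from the pool, optionally corrupted by a template switch,
    polymerase errors, or a terminal primer truncation.  Read 1 is the
    first ``read_length`` bases of the molecule; read 2 the reverse
    complement of the last ``read_length`` bases.  Per-base substitution
    errors are applied at linearly interpolated rates, and the quality
    string deterministically encodes the position-dependent rate
    (Phred+33).  Returns two equal-length lists of ``(id, seq, qual)``.
    """
    if n_read_pairs < 1:
        raise ValueError("n_read_pairs must be >= 1")
    seqs = {h.label: h.sequence for h in population.haplotypes}
    for label, seq in seqs.items():
        if read_length > len(seq):
            raise ValueError(
                f"read_length {read_length} exceeds haplotype {label} "
                f"length {len(seq)}"
            )
    rng = np.random.default_rng(seed)
    em = error_model
    copies = pool.copies
    n_copies = len(copies)

    if em.amplification_sigma > 0:
        weights = rng.lognormal(0.0, em.amplification_sigma, n_copies)
        copy_p = weights / weights.sum()
    else:
        copy_p = None

    def draw_copy_index() -> int:
        if copy_p is None:
            return int(rng.integers(n_copies))
        return int(rng.choice(n_copies, p=copy_p))

    def draw_molecule() -> str:
        redraws = 0
        while True:
            mol = seqs[copies[draw_copy_index()]]
            if em.template_switch_rate and rng.random() < em.template_switch_rate:
                partner = seqs[copies[draw_copy_index()]]
                breakpoint_ = int(rng.integers(1, min(len(mol), len(partner))))
                mol = mol[:breakpoint_] + partner[breakpoint_:]
            if em.polymerase_error_rate:
                n_err = rng.binomial(len(mol), em.polymerase_error_rate)
                if n_err:
                    mol = _mutate(
                        rng, mol, rng.choice(len(mol), size=n_err, replace=False)
                    )
            if em.truncated_primer_fraction and rng.random() < em.truncated_primer_fraction:
                k = int(rng.integers(1, 6))
                mol = mol[k:] if rng.integers(2) == 0 else mol[:-k]
            if len(mol) >= read_length:
                return mol
            redraws += 1
            if redraws % 1000 == 0:
                log.warning("molecule redrawn %d times (truncation below read length)", redraws)

    if read_length > 1:
        positions = np.arange(read_length) / (read_length - 1)
    else:
        positions = np.zeros(1)
    sub_rates = em.sub_rate_start + (em.sub_rate_end - em.sub_rate_start) * positions
    qual = _quality_string(sub_rates)
    apply_sub = bool(np.any(sub_rates > 0))

    def sequencing_errors(read: str) -> str:
        hits = np.nonzero(rng.random(read_length) < sub_rates)[0]
        if hits.size == 0:
            return read
        return _mutate(rng, read, (int(p) for p in hits))

    reads1: list[tuple[str, str, str]] = []
    reads2: list[tuple[str, str, str]] = []
    width = len(str(n_read_pairs - 1))
    for i in range(n_read_pairs):
        mol = draw_molecule()
        r1 = mol[:read_length]
        r2 = revcomp(mol)[:read_length]
        if apply_sub:
            r1 = sequencing_errors(r1)
            r2 = sequencing_errors(r2)
        rid = f"{id_prefix}:{i:0{width}d}"
        reads1.append((rid, r1, qual))
        reads2.append((rid, r2, qual))
    return reads1, reads2


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(id, seq, qual)`` records as FASTQ; gzipped iff the path ends
    in ``.gz``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for rid, seq, qual in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth(
    population: PopulationSpec, pool: PoolSample, path: str | Path
) -> None:
    """Ground-truth sidecar CSV: label, sequence, nominal and realized
    composition of the pool."""
    counts = pool.realized_counts
    pd.DataFrame(
        {
            "label": [h.label for h in population.haplotypes],
            "sequence": [h.sequence for h in population.haplotypes],
            "nominal_freq": [h.frequency for h in population.haplotypes],
            "realized_copies": [counts[h.label] for h in population.haplotypes],
        }
    ).to_csv(path, index=False)


def simulate_run(
    locus_ref: LocusRef,
    population: PopulationSpec,
    pool: PoolSample,
    error_model: ErrorModel,
    read_length: int,
    n_read_pairs: int,
    seed: int,
    out_prefix: str | Path,
    gzipped: bool = False,
) -> dict[str, Path]:
    """Simulate one sequencing run and write R1/R2 FASTQ plus the truth CSV.

    Returns the written paths keyed by ``r1``/``r2``/``truth``.
    """
    reads1, reads2 = sequence_pool(
        pool, population, error_model, read_length, n_read_pairs, seed,
        id_prefix=f"{locus_ref.name}",
    )
    suffix = ".fastq.gz" if gzipped else ".fastq"
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": Path(f"{prefix}_R1{suffix}"),
        "r2": Path(f"{prefix}_R2{suffix}"),
        "truth": Path(f"{prefix}_truth_haplotypes.csv"),
    }
    write_fastq(reads1, paths["r1"])
    write_fastq(reads2, paths["r2"])
    write_truth(population, pool, paths["truth"])
    return paths


def demo_panel(seed: int = 11, amplicon_len: int = 410) -> ReferencePanel:
    """Synthetic nine-locus reference panel.

    Locus names and chromosome/kb notes follow the nine target promoters,
    but the sequences are random synthetic stand-ins (uniform A/C/G/T),
    not real promoter sequences.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASES))
    loci = []
    for name in sorted(TARGET_PROMOTERS):
        fwd_len = int(rng.integers(18, 27))
        rev_len = int(rng.integers(18, 27))
        seq = "".join(bases[rng.integers(0, 4, size=amplicon_len)])
        loci.append(
            LocusRef(
                name=name,
                sequence=seq,
                fwd_primer=seq[:fwd_len],
                rev_primer=revcomp(seq[-rev_len:]),
                genome_note=TARGET_PROMOTERS[name],
            )
        )
    return ReferencePanel.from_loci(loci)
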