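"""Reference amplicon panel, primer geometry, and sample metadata.

An amplicon pool-seq experiment is defined by a small panel of PCR
amplicons (here, promoter fragments of developmental genes in the pest fly
*Drosophila suzukii*), each bracketed by a forward and a reverse primer.
Every downstream coordinate in the package refers to the reference amplicon
on the forward-primer strand, 0-based and half-open.  Primer-derived bases
carry no template information (they are dictated by the oligo), so every
stage needs to know the primer intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DNA = frozenset("ACGT")
DNA_N = frozenset("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: Design range of amplicon lengths (bp); loci outside it load with a warning.
AMPLICON_LENGTH_RANGE = (400, 425)
#: Allowed primer oligo lengths (nt), inclusive.
PRIMER_LENGTH_RANGE = (18, 26)

#: Chromosome/kb annotation of the nine target promoters (metadata only;
#: coordinates are never used computationally).
TARGET_PROMOTERS: Mapping[str, str] = {
    "pEve": "chr2R 6292.3-6292.7 kb",
    "pHh": "chr3R 948.1-948.5 kb",
    "pJeb": "chr2R 11041.0-11041.4 kb",
    "pPyr": "chr2R 10582.6-10583.0 kb",
    "pUpd1": "chrX 2077.4-2077.8 kb",
    "pUpd2": "chrX 2148.7-2149.0 kb",
    "pUpd3": "chrX 2110.7-2111.1 kb",
    "pWg": "chr2L 8270.2-8270.6 kb",
    "pWnt4": "chr2L 8306.6-8307.0 kb",
}


def revcomp(sequence: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence.

    Raises ``ValueError`` on any other character.  An involution:
    ``revcomp(revcomp(s)) == s``.
    """
    bad = set(sequence) - DNA_N
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return sequence.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LocusRef:
    """One reference amplicon with its primer geometry.

    ``sequence`` is the full amplicon 5'->3' on the forward-primer strand;
    it must begin with ``fwd_primer`` and end with the reverse complement
    of ``rev_primer``.  ``genome_note`` is free-text provenance (e.g. a
    chromosome/kb annotation) and is never interpreted.
    """

    name: str
    sequence: str
    fwd_primer: str
    rev_primer: str
    genome_note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if set(self.sequence) - DNA:
            raise ValueError(
                f"{self.name}: reference must be unambiguous A/C/G/T "
                "(N is allowed in reads, not in references)"
            )
        lo, hi = PRIMER_LENGTH_RANGE
        for primer, label in ((self.fwd_primer, "forward"), (self.rev_primer, "reverse")):
            if set(primer) - DNA:
                raise ValueError(f"{self.name}: {label} primer must be A/C/G/T")
            if not lo <= len(primer) <= hi:
                raise ValueError(
                    f"{self.name}: {label} primer length {len(primer)} outside "
                    f"[{lo}, {hi}]"
                )
        if not self.sequence.startswith(self.fwd_primer):
            raise ValueError(f"{self.name}: sequence does not begin with forward primer")
        if not self.sequence.endswith(revcomp(self.rev_primer)):
            raise ValueError(
                f"{self.name}: sequence does not end with reverse complement "
                "of reverse primer"
            )
        if len(self.fwd_primer) + len(self.rev_primer) > len(self.sequence):
            raise ValueError(f"{self.name}: primer intervals overlap")

    @property
    def fwd_interval(self) -> tuple[int, int]:
        """Half-open span of the forward-primer-derived bases."""
        return (0, len(self.fwd_primer))

    @property
    def rev_interval(self) -> tuple[int, int]:
        """Half-open span of the reverse-primer-derived bases."""
        return (len(self.sequence) - len(self.rev_primer), len(self.sequence))

    @property
    def interior(self) -> tuple[int, int]:
        """Half-open span of the non-primer (template-informative) bases."""
        return (self.fwd_interval[1], self.rev_interval[0])

    def __len__(self) -> int:
        return len(self.sequence)

    def primer_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.sequence), dtype=bool)
        mask[: self.fwd_interval[1]] = True
        mask[self.rev_interval[0]:] = True
        return mask


@dataclass(frozen=True)
class ReferencePanel:
    """A set of :class:`LocusRef` keyed by unique locus name."""

    loci: Mapping[str, LocusRef]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("reference panel must contain at least one locus")
        for name, locus in self.loci.items():
            if name != locus.name:
                raise ValueError(f"panel key {name!r} != locus name {locus.name!r}")

    @classmethod
    def from_loci(cls, loci: Iterable[LocusRef]) -> "ReferencePanel":
        out: dict[str, LocusRef] = {}
        for locus in loci:
            if locus.name in out:
                raise ValueError(f"duplicate locus name {locus.name!r}")
            out[locus.name] = locus
        return cls(out)

    def __getitem__(self, name: str) -> LocusRef:
        return self.loci[name]

    def __iter__(self) -> Iterator[LocusRef]:
        return iter(self.loci.values())

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.loci)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one pooled sample: where/when it was collected and how
    many individuals contributed DNA to the pool."""

    sample_id: str
    site: str
    period: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"{self.sample_id}: n_individuals must be >= 1")


def load_references(
    fasta_source: str | Path | IO[str],
    primer_manifest: str | Path | IO[str],
) -> ReferencePanel:
    """Load a reference panel from a FASTA file and a primer manifest CSV.

    The manifest has header ``locus,fwd_primer,rev_primer`` and must carry a
    row for every FASTA record.  Loci whose total length falls outside the
    400-425 bp design range are accepted with a logged warning.
    """
    manifest = pd.read_csv(primer_manifest, dtype=str)
    required = {"locus", "fwd_primer", "rev_primer"}
    if not required <= set(manifest.columns):
        raise ValueError(f"primer manifest must have columns {sorted(required)}")
    if manifest["locus"].duplicated().any():
        dupes = manifest.loc[manifest["locus"].duplicated(), "locus"].tolist()
        raise ValueError(f"duplicate locus names in primer manifest: {dupes}")
    primers = {
        row.locus: (row.fwd_primer, row.rev_primer) for row in manifest.itertuples()
    }
    genome_notes = (
        dict(zip(manifest["locus"], manifest["genome_note"]))
        if "genome_note" in manifest.columns
        else {}
    )

    loci: list[LocusRef] = []
    seen: set[str] = set()
    for record in SeqIO.parse(fasta_source, "fasta"):
        name = record.id
        if name in seen:
            raise ValueError(f"duplicate locus name in FASTA: {name!r}")
        seen.add(name)
        if name not in primers:
            raise ValueError(f"FASTA record {name!r} has no primer manifest row")
        fwd, rev = primers[name]
        locus = LocusRef(
            name=name,
            sequence=str(record.seq).upper(),
            fwd_primer=fwd,
            rev_primer=rev,
            genome_note=str(genome_notes.get(name, "") or ""),
        )
        lo, hi = AMPLICON_LENGTH_RANGE
        if not lo <= len(locus) <= hi:
            log.warning(
                "locus %s length %d bp outside design range %d-%d bp",
                name, len(locus), lo, hi,
            )
        loci.append(locus)
    return ReferencePanel.from_loci(loci)


def write_references(
    panel: ReferencePanel,
    fasta_path: str | Path,
    manifest_path: str | Path,
) -> None:
    """Write a panel back to FASTA + primer manifest (round-trips with
    :func:`load_references`)."""
    records = [
        SeqRecord(Seq(locus.sequence), id=locus.name, description="")
        for locus in panel
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "locus": [l.name for l in panel],
            "fwd_primer": [l.fwd_primer for l in panel],
            "rev_primer": [l.rev_primer for l in panel],
            "genome_note": [l.genome_note for l in panel],
        }
    ).to_csv(manifest_path, index=False)


def load_sample_manifest(source: str | Path | IO[str]) -> dict[str, SampleMeta]:
    """Load sample metadata from a CSV with header
    ``sample_id,site,period,n_individuals``."""
    frame = pd.read_csv(source, dtype={"sample_id": str, "site": str, "period": str})
    required = {"sample_id", "site", "period", "n_individuals"}
    if not required <= set(frame.columns):
        raise ValueError(f"sample manifest must have columns {sorted(required)}")
    out: dict[str, SampleMeta] = {}
    for row in frame.itertuples():
        if row.sample_id in out:
            raise ValueError(f"duplicate sample_id {row.sample_id!r}")
        out[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            site=row.site,
            period=row.period,
            n_individuals=int(row.n_individuals),
        )
    return out


def _count(x: int | Sequence) -> int:
    return x if isinstance(x, int) else len(x)


@dataclass(frozen=True)
class ExperimentManifest:
    """Bookkeeping for a pooled-amplicon experiment layout.

    ``n_sites x n_periods`` gDNA pools (plus controls) are each amplified by
    ``primer_pairs_per_pool`` primer pairs, and amplicon pools are combined
    ``pools_per_sample`` at a time into sequencing samples.
    """

    n_sites: int
    n_periods: int
    n_loci: int
    n_control_pools: int = 0
    primer_pairs_per_pool: int = 0
    pools_per_sample: int = 1

    @property
    def n_experimental_pools(self) -> int:
        """Experimental amplicon pools: loci x periods x sites."""
        return self.n_sites * self.n_periods * self.n_loci

    @property
    def n_gdna_pools(self) -> int:
        return self.n_sites * self.n_periods + self.n_control_pools

    @property
    def n_amplicon_pools(self) -> int:
        return self.n_gdna_pools * self.primer_pairs_per_pool

    @property
    def n_samples(self) -> int:
        if self.n_amplicon_pools % self.pools_per_sample:
            raise ValueError(
                f"{self.n_amplicon_pools} amplicon pools cannot be combined "
                f"{self.pools_per_sample} per sample"
            )
        return self.n_amplicon_pools // self.pools_per_sample


def build_manifest(
    sites: int | Sequence,
    periods: int | Sequence,
    loci: int | Sequence,
    n_control_pools: int = 0,
    primer_pairs_per_pool: int | None = None,
    pools_per_sample: int = 1,
) -> ExperimentManifest:
    """Build the experiment layout from site/period/locus counts (or label
    lists).  ``primer_pairs_per_pool`` defaults to the locus count."""
    n_sites, n_periods, n_loci = _count(sites), _count(periods), _count(loci)
    if min(n_sites, n_periods, n_loci) < 0 or n_control_pools < 0:
        raise ValueError("counts must be >= 0")
    if pools_per_sample < 1:
        raise ValueError("pools_per_sample must be >= 1")
    return ExperimentManifest(
        n_sites=n_sites,
        n_periods=n_periods,
        n_loci=n_loci,
        n_control_pools=n_control_pools,
        primer_pairs_per_pool=(
            n_loci if primer_pairs_per_pool is None else primer_pairs_per_pool
        ),
        pools_per_sample=pools_per_sample,
    )
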