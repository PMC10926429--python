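"""End-to-end pipeline runner.

Executes, per sample: length filter -> locus binning -> perfect-overlap
merge -> orientation -> dereplication -> truncated-primer removal ->
frequencies; then, per locus: pileup -> individual-weighted combination ->
entropy -> conserved windows -> guide enumeration/coverage -> pairwise
sample comparisons.  Every stage appends a JSON-serializable summary, and
outputs are bit-for-bit reproducible for identical inputs and seed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import guidedesign, hapcall, popcompare, readproc, snpcall
from .config import PipelineConfig
from .hapcall import HaplotypeTable
from .refpanel import ReferencePanel, SampleMeta
from .snpcall import write_profile_tsv, write_vcf

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Fatal pipeline failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SampleInput:
    sample_id: str
    r1: Path
    r2: Path


def run_pipeline(
    config: PipelineConfig,
    samples: Sequence[SampleInput],
    panel: ReferencePanel,
    sample_manifest: Mapping[str, SampleMeta],
    outdir: str | Path,
) -> dict:
    """Run the full pipeline and write all outputs under ``outdir``.

    Returns the stage-summary dict (also written to
    ``outdir/pipeline_log.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "samples": {}, "loci": {}}
    index = readproc.KmerIndex(panel, config.bin_k)

    tables: dict[tuple[str, str], HaplotypeTable] = {}
    profiles: dict[str, list[tuple[snpcall.SNPProfile, SampleMeta]]] = {}

    for sample in sorted(samples, key=lambda s: s.sample_id):
        if sample.sample_id not in sample_manifest:
            raise PipelineError("manifest", f"sample {sample.sample_id} not in manifest")
        meta = sample_manifest[sample.sample_id]
        stats: dict = {}
        try:
            pairs = readproc.load_read_pairs(sample.r1, sample.r2)
        except (OSError, ValueError) as exc:
            raise PipelineError("load", f"{sample.sample_id}: {exc}") from exc
        stats["input_pairs"] = len(pairs)
        if not pairs:
            raise PipelineError(
                "filter", f"{sample.sample_id}: zero read pairs in input FASTQ"
            )

        pairs = readproc.filter_by_length(pairs, config.min_len)
        stats["passed_length"] = len(pairs)

        bins, unassigned, bin_stats = readproc.bin_read_pairs(
            pairs, panel, config.bin_k, config.bin_min_score,
            config.max_n_frac, index=index,
        )
        stats["binning"] = bin_stats

        for locus_name in panel.names:
            binned = bins.get(locus_name, [])
            if not binned:
                continue
            merged, merge_stats = readproc.merge_all(
                binned, config.min_overlap, locus=locus_name
            )
            stats[f"merge_{locus_name}"] = merge_stats
            if not merged:
                continue
            oriented = readproc.orient_all(merged, panel[locus_name], config.bin_k)
            try:
                table, hap_stats = hapcall.call_haplotypes(
                    oriented, panel[locus_name], sample.sample_id,
                    config.min_unique_size,
                )
            except ValueError as exc:
                raise PipelineError("frequencies", str(exc)) from exc
            stats[f"haplotypes_{locus_name}"] = hap_stats
            tables[(sample.sample_id, locus_name)] = table
            table.write_csv(
                outdir / f"haplotypes_{sample.sample_id}_{locus_name}.csv"
            )
            profile = snpcall.pileup(
                table, panel[locus_name], config.align_scores, config.score_floor
            )
            profiles.setdefault(locus_name, []).append((profile, meta))
            write_vcf(
                profile,
                outdir / f"snps_{sample.sample_id}_{locus_name}.vcf",
                sample_id=sample.sample_id,
            )
            write_profile_tsv(
                profile, outdir / f"profile_{sample.sample_id}_{locus_name}.tsv"
            )
        summary["samples"][sample.sample_id] = stats

    if tables:
        hapcall.combine_long(
            [tables[key] for key in sorted(tables)]
        ).to_csv(outdir / "haplotypes_all_samples.csv", index=False)

    comparison_rows = []
    for locus_name in sorted(profiles):
        locus_ref = panel[locus_name]
        locus_summary: dict = {}
        combined = snpcall.combine_weighted(profiles[locus_name])
        write_profile_tsv(combined, outdir / f"combined_profile_{locus_name}.tsv")

        entropy, mean_entropy = snpcall.shannon_entropy(combined)
        locus_summary["mean_entropy_bits"] = mean_entropy
        pd.DataFrame({"pos": np.arange(combined.length), "entropy_bits": entropy}).to_csv(
            outdir / f"entropy_{locus_name}.tsv", sep="\t", index=False
        )

        windows = guidedesign.conserved_bases(
            combined, config.flank, config.window_max_freq
        )
        guidedesign.write_bed(windows, outdir / f"conserved_{locus_name}.bed")
        locus_summary["conserved_windows"] = len(windows)
        locus_summary["has_pta_window_gt30"] = guidedesign.has_pta_window(windows)

        candidates = guidedesign.enumerate_guides(locus_ref, combined)
        locus_tables = [
            tables[key] for key in sorted(tables) if key[1] == locus_name
        ]
        weights = [
            sample_manifest[key[0]].n_individuals
            for key in sorted(tables) if key[1] == locus_name
        ]
        pooled = hapcall.pooled_frequencies(locus_tables, weights)
        pooled_table = hapcall.HaplotypeTable(
            sample_id="pooled",
            locus=locus_name,
            rows=tuple(
                hapcall.HapRow(seq, 0, freq / sum(pooled.values()))
                for seq, freq in sorted(pooled.items())
            ),
            total_retained_count=0,
        )
        candidates = guidedesign.score_coverage(candidates, pooled_table)
        guidedesign.write_guides_tsv(candidates, outdir / f"guides_{locus_name}.tsv")
        locus_summary["n_guides"] = len(candidates)
        locus_summary["guide_classes"] = {
            str(t): n
            for t, n in guidedesign.classify_guides(
                candidates, config.guide_thresholds
            ).items()
        }

        sample_ids = sorted({key[0] for key in tables if key[1] == locus_name})
        for a, b in itertools.combinations(sample_ids, 2):
            ta, tb = tables[(a, locus_name)], tables[(b, locus_name)]
            pair_label = f"{a}|{b}"
            shared = popcompare.pair_frequencies(ta, tb, "shared")
            if len(shared.keys) >= 2 and np.ptp(shared.y) > 0:
                comparison_rows.append(
                    ("identity_r2_shared", locus_name, pair_label,
                     popcompare.identity_r2(shared.x, shared.y))
                )
            union = popcompare.pair_frequencies(ta, tb, "union")
            slope, r2 = popcompare.origin_r2(union.x, union.y)
            comparison_rows.append(("origin_slope", locus_name, pair_label, slope))
            comparison_rows.append(("origin_r2", locus_name, pair_label, r2))
            overlap = popcompare.rank_overlap(ta, tb, config.rank_n_max)
            comparison_rows.append(
                ("rank_overlap_final", locus_name, pair_label, float(overlap[-1]))
            )
        summary["loci"][locus_name] = locus_summary

    pd.DataFrame(
        comparison_rows, columns=["statistic", "locus", "sample_pair", "value"]
    ).to_csv(outdir / "comparisons.csv", index=False)

    with open(outdir / "pipeline_log.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    return summary
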