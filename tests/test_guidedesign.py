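import re

import numpy as np
import pytest

from amplihap.guidedesign import (
    classify_guides,
    conserved_bases,
    enumerate_guides,
    guide_coverage,
    has_pta_window,
    score_coverage,
)
from amplihap.hapcall import haplotype_frequencies
from amplihap.refpanel import revcomp
from amplihap.snpcall import CombinedProfile


def profile_with(wg, snp_freqs: dict[int, float]) -> CombinedProfile:
    """Combined profile carrying the given alt frequencies (rest reference)."""
    length = len(wg.sequence)
    freqs = np.zeros((length, 4))
    idx = {b: i for i, b in enumerate("ACGT")}
    for pos, base in enumerate(wg.sequence):
        freqs[pos, idx[base]] = 1.0
    for pos, f in snp_freqs.items():
        ref_i = idx[wg.sequence[pos]]
        alt_i = (ref_i + 1) % 4
        freqs[pos, ref_i] = 1.0 - f
        freqs[pos, alt_i] = f
    return CombinedProfile(
        locus=wg.name, ref=wg.sequence, freqs=freqs,
        primer_mask=wg.primer_mask(), n_individuals=100,
    )


def brute_force_conserved(profile, flank, max_freq):
    """Oracle: direct per-base evaluation of the flank rule."""
    length = profile.length
    snp = profile.snp_freq
    mask = profile.primer_mask
    conserved = []
    for i in range(length):
        neighborhood = range(i - flank, i + flank + 1)
        conserved.append(
            all(0 <= j < length and not mask[j] and snp[j] < max_freq
                for j in neighborhood)
        )
    runs = []
    start = None
    for i, c in enumerate(conserved + [False]):
        if c and start is None:
            start = i
        elif not c and start is not None:
            runs.append((start, i))
            start = None
    return runs


class TestConservedBases:
    def test_zero_snp_profile_single_full_window(self, wg):
        profile = profile_with(wg, {})
        windows = conserved_bases(profile, flank=15, max_freq=0.002)
        lo, hi = wg.interior
        assert len(windows) == 1
        assert (windows[0].start, windows[0].end) == (lo + 15, hi - 15)
        assert len(windows[0]) == (hi - lo) - 30

    def test_snp_at_threshold_blocks_flanked_span(self, wg):
        lo, hi = wg.interior
        pos = (lo + hi) // 2
        profile = profile_with(wg, {pos: 0.002})
        windows = conserved_bases(profile, flank=15, max_freq=0.002)
        blocked = set(range(pos - 15, pos + 16))
        covered = set()
        for w in windows:
            covered.update(range(w.start, w.end))
        assert not (blocked & covered)
        # positions just outside the flanked span stay conserved
        assert pos - 16 in covered and pos + 16 in covered

    def test_below_threshold_snp_ignored(self, wg):
        lo, hi = wg.interior
        pos = (lo + hi) // 2
        baseline = conserved_bases(profile_with(wg, {}), 15, 0.002)
        with_snp = conserved_bases(profile_with(wg, {pos: 0.0019}), 15, 0.002)
        assert with_snp == baseline

    def test_matches_brute_force_on_random_profiles(self, wg):
        rng = np.random.default_rng(8)
        lo, hi = wg.interior
        for _ in range(10):
            n_snps = int(rng.integers(0, 12))
            positions = rng.choice(np.arange(lo, hi), size=n_snps, replace=False)
            freqs = rng.choice([0.0005, 0.0019, 0.002, 0.01, 0.2], size=n_snps)
            profile = profile_with(wg, dict(zip((int(p) for p in positions), freqs)))
            windows = conserved_bases(profile, flank=15, max_freq=0.002)
            assert [(w.start, w.end) for w in windows] == brute_force_conserved(
                profile, 15, 0.002
            )

    def test_pta_window_utility(self, wg):
        profile = profile_with(wg, {})
        windows = conserved_bases(profile, 15, 0.002)
        assert has_pta_window(windows, min_len=30)
        assert not has_pta_window([], min_len=30)


def brute_force_sites(wg):
    """Oracle: regex enumeration of interior 20N+NGG sites on both strands."""
    lo, hi = wg.interior
    seq = wg.sequence
    sites = set()
    for strand, scanned in (("+", seq), ("-", revcomp(seq))):
        for m in re.finditer(r"(?=([ACGT]{21}GG))", scanned):
            s = m.start()
            start = s if strand == "+" else len(seq) - 23 - s
            if lo <= start and start + 23 <= hi:
                sites.add((strand, start))
    return sites


class TestEnumerateGuides:
    def test_matches_regex_oracle(self, wg):
        guides = enumerate_guides(wg, profile_with(wg, {}))
        assert {(g.strand, g.start) for g in guides} == brute_force_sites(wg)
        assert len(guides) == len(brute_force_sites(wg))

    def test_pam_and_protospacer_consistent_with_reference(self, wg):
        for g in enumerate_guides(wg, profile_with(wg, {})):
            site = wg.sequence[g.start:g.start + 23]
            if g.strand == "-":
                site = revcomp(site)
            assert site == g.protospacer + g.pam
            assert g.pam[1:] == "GG"

    def test_zero_snp_profile_scores_zero(self, wg):
        guides = enumerate_guides(wg, profile_with(wg, {}))
        assert guides and all(g.summed_snp_pct == 0.0 for g in guides)

    def test_single_snp_in_protospacer_scores_one_percent(self, wg):
        clean = enumerate_guides(wg, profile_with(wg, {}))
        g = clean[0]
        # plant a 1% SNP in the middle of this guide's protospacer
        if g.strand == "+":
            pos = g.start + 10
        else:
            pos = g.start + 12
        scored = enumerate_guides(wg, profile_with(wg, {pos: 0.01}))
        match = next(c for c in scored if (c.strand, c.start) == (g.strand, g.start))
        assert match.summed_snp_pct == pytest.approx(1.0)

    def test_pam_n_position_excluded_from_score(self, wg):
        clean = enumerate_guides(wg, profile_with(wg, {}))
        g = next(c for c in clean if c.strand == "+")
        n_pos = g.start + 20
        scored = enumerate_guides(wg, profile_with(wg, {n_pos: 0.5}))
        match = next(c for c in scored if (c.strand, c.start) == (g.strand, g.start))
        assert match.summed_snp_pct == 0.0

    def test_sites_inside_conserved_windows_are_clean(self, wg):
        """Window/guide consistency: every assessed position of a 23-mer
        inside a conserved window has SNP frequency below the cutoff."""
        rng = np.random.default_rng(9)
        lo, hi = wg.interior
        positions = rng.choice(np.arange(lo, hi), size=8, replace=False)
        profile = profile_with(
            wg, {int(p): 0.01 for p in positions}
        )
        windows = conserved_bases(profile, 15, 0.002)
        snp = profile.snp_freq
        for g in enumerate_guides(wg, profile):
            inside = any(
                w.start <= g.start and g.start + 23 <= w.end for w in windows
            )
            if inside:
                assert all(
                    snp[p] < 0.002
                    for p in range(g.start, g.start + 23)
                )


class TestGuideCoverage:
    def test_all_reference_haplotypes_covered(self, wg):
        table = haplotype_frequencies([(wg.sequence, 10)], "s", wg.name)
        guides = enumerate_guides(wg, profile_with(wg, {}))
        assert guide_coverage(guides[0], table) == 1.0

    def test_snp_in_protospacer_drops_coverage(self, wg):
        guides = enumerate_guides(wg, profile_with(wg, {}))
        g = next(c for c in guides if c.strand == "+")
        variant = list(wg.sequence)
        pos = g.start + 5
        variant[pos] = "A" if variant[pos] != "A" else "C"
        table = haplotype_frequencies(
            [(wg.sequence, 90), ("".join(variant), 10)], "s", wg.name
        )
        assert guide_coverage(g, table) == pytest.approx(0.9)

    def test_snp_at_pam_n_is_wildcard(self, wg):
        guides = enumerate_guides(wg, profile_with(wg, {}))
        g = next(c for c in guides if c.strand == "+")
        variant = list(wg.sequence)
        pos = g.start + 20  # the N of NGG
        variant[pos] = next(b for b in "ACGT" if b != variant[pos])
        table = haplotype_frequencies(
            [(wg.sequence, 50), ("".join(variant), 50)], "s", wg.name
        )
        assert guide_coverage(g, table) == 1.0

    def test_coverage_lower_bound_from_snp_carriers(self, wg):
        """Coverage >= 1 - (total frequency of haplotypes with a SNP in the
        assessed site), with equality when SNPs are the only differences."""
        guides = enumerate_guides(wg, profile_with(wg, {}))
        g = next(c for c in guides if c.strand == "+")
        rng = np.random.default_rng(10)
        rows = [(wg.sequence, 60)]
        carrier_freq = 0.0
        for i, count in enumerate((20, 15, 5)):
            variant = list(wg.sequence)
            pos = int(rng.integers(g.start, g.start + 20))
            variant[pos] = next(b for b in "ACGT" if b != variant[pos])
            rows.append(("".join(variant), count))
            carrier_freq += count / 100
        table = haplotype_frequencies(rows, "s", wg.name)
        assert guide_coverage(g, table) >= 1.0 - carrier_freq - 1e-12

    def test_score_coverage_fills_field(self, wg):
        table = haplotype_frequencies([(wg.sequence, 10)], "s", wg.name)
        guides = score_coverage(enumerate_guides(wg, profile_with(wg, {}))[:3], table)
        assert all(g.coverage == 1.0 for g in guides)


class TestClassifyGuides:
    def test_all_clean(self, wg):
        guides = enumerate_guides(wg, profile_with(wg, {}))
        counts = classify_guides(guides, (5.0, 1.0, 0.5))
        assert counts == {5.0: len(guides), 1.0: len(guides), 0.5: len(guides)}

    def test_strict_thresholds(self, wg):
        guides = enumerate_guides(wg, profile_with(wg, {}))
        g = next(c for c in guides if c.strand == "+")
        profile = profile_with(wg, {g.start + 3: 0.007})  # 0.7 percent
        scored = enumerate_guides(wg, profile)
        match = next(c for c in scored if (c.strand, c.start) == (g.strand, g.start))
        counts = classify_guides([match], (5.0, 1.0, 0.5))
        assert counts == {5.0: 1, 1.0: 1, 0.5: 0}

    def test_nested_counts_on_random_profiles(self, wg):
        rng = np.random.default_rng(11)
        lo, hi = wg.interior
        for _ in range(5):
            positions = rng.choice(np.arange(lo, hi), size=15, replace=False)
            freqs = rng.uniform(0, 0.05, size=15)
            profile = profile_with(wg, dict(zip((int(p) for p in positions), freqs)))
            guides = enumerate_guides(wg, profile)
            counts = classify_guides(guides, (5.0, 1.0, 0.5))
            brute = {
                t: sum(1 for g in guides if g.summed_snp_pct < t)
                for t in (5.0, 1.0, 0.5)
            }
            assert counts == brute
            values = [counts[t] for t in (5.0, 1.0, 0.5)]
            assert values == sorted(values, reverse=True)

    def test_ascending_thresholds_fatal(self):
        with pytest.raises(ValueError):
            classify_guides([], (0.5, 1.0, 5.0))
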