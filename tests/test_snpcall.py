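import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplihap.hapcall import haplotype_frequencies
from amplihap.refpanel import SampleMeta
from amplihap.snpcall import (
    AlignScores,
    align_haplotype,
    combine_weighted,
    pileup,
    read_combined_tsv,
    read_profile_tsv,
    shannon_entropy,
    write_profile_tsv,
    write_vcf,
)

SCORES = AlignScores()


def exhaustive_align_score(ref, hap, scores=SCORES):
    """Oracle: exhaustive recursion over all global alignments (affine gaps
    scored as open + (k-1)*extend)."""

    @functools.cache
    def best(i, j, state):
        if i == len(ref) and j == len(hap):
            return 0.0
        options = []
        if i < len(ref) and j < len(hap):
            s = scores.match if ref[i] == hap[j] else scores.mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if i < len(ref):
            cost = scores.gap_extend if state == "D" else scores.gap_open
            options.append(cost + best(i + 1, j, "D"))
        if j < len(hap):
            cost = scores.gap_extend if state == "I" else scores.gap_open
            options.append(cost + best(i, j + 1, "I"))
        return max(options)

    return best(0, 0, "M")


class TestAlignHaplotype:
    def test_identity(self, wg):
        aln = align_haplotype(wg.sequence, wg)
        assert aln.score == 2 * len(wg)
        assert aln.ref_aln == aln.hap_aln == wg.sequence

    def test_single_substitution(self, wg):
        seq = list(wg.sequence)
        seq[100] = "A" if seq[100] != "A" else "C"
        aln = align_haplotype("".join(seq), wg)
        mismatches = sum(
            1 for a, b in zip(aln.ref_aln, aln.hap_aln)
            if a != b and "-" not in (a, b)
        )
        assert mismatches == 1
        assert aln.score == 2 * (len(wg) - 1) - 1

    def test_alignment_reconstructs_inputs(self, wg):
        hap = wg.sequence[:150] + wg.sequence[155:]  # 5-bp deletion
        aln = align_haplotype(hap, wg)
        assert aln.ref_aln.replace("-", "") == wg.sequence
        assert aln.hap_aln.replace("-", "") == hap

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        ref=st.text(alphabet="ACGT", min_size=1, max_size=10),
        hap=st.text(alphabet="ACGT", min_size=1, max_size=10),
    )
    def test_score_matches_exhaustive_oracle(self, ref, hap):
        assert align_haplotype(hap, ref).score == exhaustive_align_score(ref, hap)

    def test_score_matches_biopython_on_longer_strings(self):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = SCORES.match
        aligner.mismatch_score = SCORES.mismatch
        aligner.open_gap_score = SCORES.gap_open
        aligner.extend_gap_score = SCORES.gap_extend
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for _ in range(150):
            ref = "".join(bases[rng.integers(0, 4, rng.integers(1, 31))])
            hap = "".join(bases[rng.integers(0, 4, rng.integers(1, 31))])
            assert align_haplotype(hap, ref).score == aligner.score(ref, hap)


def _variant(locus, pos, count, base=None):
    seq = list(locus.sequence)
    seq[pos] = base or ("A" if seq[pos] != "A" else "C")
    return "".join(seq), count


class TestPileup:
    def test_single_alt_haplotype(self, wg):
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 7, 10)
        table = haplotype_frequencies([(variant, 10)], "s", "pWg")
        profile = pileup(table, wg)
        assert profile.depth[lo + 7] == 10
        assert profile.snp_freq[lo + 7] == 1.0

    def test_two_haplotype_frequencies(self, wg):
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 3, 10)
        table = haplotype_frequencies(
            [(wg.sequence, 90), (variant, 10)], "s", "pWg"
        )
        profile = pileup(table, wg)
        assert profile.snp_freq[lo + 3] == pytest.approx(0.1)
        other = np.delete(profile.snp_freq, lo + 3)
        assert (other == 0).all()

    def test_column_sums_equal_depth(self, wg):
        lo, _ = wg.interior
        v1, _ = _variant(wg, lo + 1, 0)
        v2, _ = _variant(wg, lo + 9, 0)
        table = haplotype_frequencies(
            [(wg.sequence, 50), (v1, 30), (v2, 20)], "s", "pWg"
        )
        profile = pileup(table, wg)
        assert (profile.counts.sum(axis=1) == profile.depth).all()
        assert (profile.depth == 100).all()

    def test_deletion_reduces_depth(self, wg):
        hap = wg.sequence[:200] + wg.sequence[205:]
        table = haplotype_frequencies([(wg.sequence, 10), (hap, 5)], "s", "pWg")
        profile = pileup(table, wg)
        assert profile.depth[202] == 10  # deleted span covered only by ref hap
        assert profile.depth[100] == 15


class TestCombineWeighted:
    def _profile(self, wg, rows):
        return pileup(haplotype_frequencies(rows, "s", "pWg"), wg)

    def test_equal_weights_average(self, wg):
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 2, 0)
        p0 = self._profile(wg, [(wg.sequence, 10)])
        p1 = self._profile(wg, [(wg.sequence, 80), (variant, 20)])
        meta = [SampleMeta("a", "x", "t", 100), SampleMeta("b", "y", "t", 100)]
        combined = combine_weighted([(p0, meta[0]), (p1, meta[1])])
        assert combined.snp_freq[lo + 2] == pytest.approx(0.1)

    def test_single_sample_identity(self, wg):
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 2, 0)
        p = self._profile(wg, [(wg.sequence, 3), (variant, 1)])
        combined = combine_weighted([(p, SampleMeta("a", "x", "t", 50))])
        np.testing.assert_allclose(combined.freqs, p.base_freqs)
        np.testing.assert_allclose(combined.snp_freq, p.snp_freq)

    def test_fly_count_weighting(self, wg):
        """Two pools of 1928 and 1052 individuals weight positionwise as
        1928/2980 and 1052/2980."""
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 4, 0)
        p_big = self._profile(wg, [(wg.sequence, 10)])
        p_small = self._profile(wg, [(variant, 10)])
        combined = combine_weighted([
            (p_big, SampleMeta("waverly", "W", "jul19e", 1928)),
            (p_small, SampleMeta("forestlake", "F", "jul19e", 1052)),
        ])
        assert combined.n_individuals == 2980
        assert combined.snp_freq[lo + 4] == pytest.approx(1052 / 2980)

    def test_idempotent_on_identical_profiles(self, wg):
        p = self._profile(wg, [(wg.sequence, 10)])
        metas = [SampleMeta(s, "x", "t", 7) for s in "abc"]
        combined = combine_weighted([(p, m) for m in metas])
        np.testing.assert_allclose(combined.freqs, p.base_freqs)

    def test_mismatched_locus_fatal(self, wg, panel):
        p1 = self._profile(wg, [(wg.sequence, 10)])
        hh = panel["pHh"]
        p2 = pileup(haplotype_frequencies([(hh.sequence, 5)], "s", "pHh"), hh)
        with pytest.raises(ValueError, match="combine"):
            combine_weighted([
                (p1, SampleMeta("a", "x", "t", 1)),
                (p2, SampleMeta("b", "x", "t", 1)),
            ])


class TestShannonEntropy:
    def test_monomorphic_zero(self, wg):
        profile = pileup(haplotype_frequencies([(wg.sequence, 10)], "s", "pWg"), wg)
        entropy, mean = shannon_entropy(profile)
        assert (entropy == 0).all()
        assert mean == 0.0

    def test_two_state_one_bit(self, wg):
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 5, 0)
        profile = pileup(
            haplotype_frequencies([(wg.sequence, 10), (variant, 10)], "s", "pWg"), wg
        )
        entropy, _ = shannon_entropy(profile)
        assert entropy[lo + 5] == pytest.approx(1.0)

    def test_uniform_four_state_two_bits(self, wg):
        lo, _ = wg.interior
        pos = lo + 6
        rows = [(wg.sequence, 10)]
        for base in "ACGT":
            if base != wg.sequence[pos]:
                rows.append(_variant(wg, pos, 10, base))
        profile = pileup(haplotype_frequencies(rows, "s", "pWg"), wg)
        entropy, _ = shannon_entropy(profile)
        assert entropy[pos] == pytest.approx(2.0)


class TestIO:
    def _profile(self, wg):
        lo, _ = wg.interior
        variant, _ = _variant(wg, lo + 2, 0)
        table = haplotype_frequencies([(wg.sequence, 90), (variant, 10)], "s", "pWg")
        return pileup(table, wg)

    def test_profile_tsv_round_trip(self, wg, tmp_path):
        profile = self._profile(wg)
        path = tmp_path / "profile.tsv"
        write_profile_tsv(profile, path)
        back = read_profile_tsv(path, wg)
        np.testing.assert_array_equal(back.counts, profile.counts)

    def test_combined_tsv_round_trip(self, wg, tmp_path):
        profile = self._profile(wg)
        combined = combine_weighted([(profile, SampleMeta("a", "x", "t", 100))])
        path = tmp_path / "combined.tsv"
        write_profile_tsv(combined, path)
        back = read_combined_tsv(path, wg)
        np.testing.assert_allclose(back.freqs, combined.freqs)
        assert back.n_individuals == 100

    def test_vcf_output_parses_and_reports_af(self, wg, tmp_path):
        import pysam

        lo, _ = wg.interior
        profile = self._profile(wg)
        path = tmp_path / "out.vcf"
        write_vcf(profile, path, sample_id="s")
        records = list(pysam.VariantFile(str(path)))
        assert len(records) == 1
        record = records[0]
        assert record.pos == lo + 3  # VCF is 1-based
        assert record.ref == wg.sequence[lo + 2]
        assert record.info["DP"] == 100
        assert record.info["AF"][0] == pytest.approx(0.1)
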