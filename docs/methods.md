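# Methods

## Problem setting

`amplihap` analyzes deep amplicon sequencing of pooled individuals
(pool-seq). A small panel of PCR amplicons — in the motivating
application, 400–425 bp promoter fragments of nine developmental genes in
the invasive fruit pest *Drosophila suzukii* — is amplified from bulk
genomic DNA extracted from hundreds to thousands of individuals, and
sequenced 2×250 bp paired-end. Because the amplicon is shorter than the
summed read length, each read pair spans the whole molecule and, after
merging, constitutes one observed *haplotype*: the exact sequence of one
amplicon copy. The package turns raw read pairs into haplotype frequency
tables, per-base SNP profiles, population comparison statistics,
conserved-region calls, and candidate CRISPR guide sites whose population
coverage can be quantified — the design inputs for genetic biocontrol
strategies (e.g. engineered genetic incompatibility) that depend on a
guide binding site being conserved across the wild population.

## Pipeline model and assumptions

1. **Length filter.** A pair is kept iff both mates are ≥ `min_len`
   (default 240) bases. Quality scores are *not* used after this point:
   the stringency of the pipeline comes from exact-match overlap, not
   quality trimming, so reads stay intact.
2. **Locus binning.** Each pair is assigned to the reference locus
   maximizing a shared 31-mer count (summed over both mates and both
   orientations), requiring a minimum score (default 10) and a strict win
   over the runner-up. For amplicons of distinct genes this is fully
   discriminative; it replaces alignment-based read splitting with an
   index-free exact method. Pairs with more than 10% N in either mate are
   dropped first, since N cannot participate in exact overlaps.
3. **Perfect-overlap merging.** With R2′ the reverse complement of mate
   2, an overlap length v (≥ `min_overlap`, default 20) is valid iff the
   last v bases of mate 1 equal the first v bases of R2′ exactly; N
   matches nothing, not even N. Exactly one valid v merges the pair into
   `seq1 + R2′[v:]`. Two or more valid overlaps (possible for repetitive
   or periodic molecules) reject the pair as *ambiguous* rather than
   guessing; no valid overlap rejects it as *no-overlap*. Rejecting
   ambiguity is conservative and makes the operation a pure function of
   the pair, testable against exhaustive enumeration.
4. **Orientation.** A merged read is flipped to its reverse complement
   iff the flip strictly increases the shared 31-mer count against the
   reference; ties keep the original orientation.
5. **Dereplication.** Merged reads collapse by exact string identity.
   Groups seen fewer than `min_unique_size` (default 5) times are
   discarded, so an isolated sequencing error cannot found a novel
   haplotype. Identity is exact — no clustering radius, no denoising —
   which means PCR chimeras that survive the floor are reported as
   haplotypes; the method over-counts unique haplotypes by design and the
   documentation of any downstream use must account for that.
6. **Truncated-primer removal.** A haplotype is retained iff it begins
   with the complete forward primer and ends with the complete reverse
   complement of the reverse primer, both exact. This removes amplicons
   synthesized from incomplete primer oligos *and* haplotypes with
   substitutions inside the primer span: primer-derived bases are
   dictated by the oligo and carry no template information, so a mismatch
   there cannot be biological. (Whether to remove only length-truncated
   sequences was genuinely open; the stricter rule is adopted because the
   removed bases are non-informative either way.)
7. **Frequencies.** Computed after both filters; the denominator is
   retained reads.

## SNP profiling

Haplotypes align to the reference amplicon with a global affine-gap
aligner (Gotoh; match +2, mismatch −1, gap open −6, gap extend −1, a gap
of length k costing `open + (k−1)·extend`). Global rather than local
alignment is justified because hapcall guarantees full-length
primer-anchored input. Traceback is deterministic: on score ties,
match/mismatch beats a gap, and a gap in the reference beats a gap in the
haplotype. Alignments scoring below a floor (default 0) are excluded from
the pileup and logged.

The pileup adds each haplotype's *count* to the tally of its base at each
matched/mismatched reference position. The variant model is SNP-only:
insertions relative to the reference are ignored and deleted reference
positions receive no contribution (depth drops there). `snp_freq(pos)` is
the fraction of support differing from the reference base. Primer-interval
positions are flagged non-informative.

Profiles from several samples combine as a weighted mean of per-position
base frequencies, with weights proportional to the number of individuals
sequenced per pool (so a 1,928-fly pool outweighs a 1,052-fly pool
1928:1052 at every position). Positions a sample does not cover contribute
zero at unchanged weight; combined rows can therefore sum below 1 there,
and entropy renormalizes per position. Shannon entropy is reported in bits
(log₂; the base is a convention choice) and averaged over covered
non-primer positions.

VCF output (v4.2, 1-based positions, `DP`/`AF` in INFO) is written via
pysam; all other coordinates in the package are 0-based half-open.

## Population comparison and detection limits

- `identity_r2`: R² with residuals measured from the line y = x
  (`1 − Σ(y−x)²/Σ(y−ȳ)²`); equals 1 only when the two samples have
  identical frequencies, and can be negative. Undefined for constant y.
  The shared-haplotype convention (intersection only) is used when
  comparing field sites.
- `origin_r2`: least squares through the origin, with the *uncentered*
  total sum of squares in R² as required for a fixed-intercept fit.
- `rank_overlap`: haplotypes rank-ordered by descending frequency (ties
  lexicographic for determinism); overlap(N) = |topN(A) ∩ topN(B)|/N for
  N up to 250 by default.
- Frequencies are compared on the linear scale.
- `required_depth`: under even amplification, a haplotype at frequency f
  in a pool of n individuals needs `min_support/(f·n)` merged reads per
  individual, and `merge_rate` of raw pairs merging inflates this to
  `merged/merge_rate` raw pairs per individual. Kept as exact rationals.
  At the standard design point (f = 0.002, n = 250, support 5, merge rate
  0.40) this gives 10 merged reads and 25 raw read pairs per individual.
- `max_pool_size`: `floor(read_pairs · merge_rate / min_support)` — the
  largest pool in which a single-carrier haplotype still clears the
  support floor; 3,200 individuals at 40,000 read pairs. This counts each
  individual as one sequencing unit; a diploid-copy accounting option
  halves the answer. The two detection models (frequency-based and
  per-individual) coincide exactly when f = 1/n, which the test suite
  asserts; they are deliberately both exposed because they answer
  different design questions.

## Guide design

A base is *conserved* iff every position within a 15-bp flank on both
sides exists, lies in the non-primer interior, and has SNP frequency
strictly below 0.002 (a SNP at exactly the threshold disqualifies).
Maximal conserved runs are reported as windows (BED), with a utility flag
for windows longer than 30 bases — large enough for programmable
transcription activator targeting.

Guide enumeration scans both strands for a 20-nt protospacer immediately
followed by an NGG PAM, the whole 23-mer inside the non-primer interior
(conservation inside primers is an artifact of primer anchoring). The
summed SNP percentage adds `100 × snp_freq` over the 20 protospacer
positions and the two G positions of the PAM; the N position is
unconstrained by the guide chemistry and is excluded (switchable). SNP
frequencies are strand-symmetric, so reverse-strand candidates read the
reference-strand profile at mapped coordinates. Guide *coverage* is the
frequency-weighted fraction of haplotypes containing the exact
protospacer+PAM (N wildcarded) on either strand — an exact-match,
single-SNP-defeats-binding conservatism. Threshold classification (below
5%, 1%, 0.5% summed SNP) uses strict inequality. The window cutoff
(0.002) and guide cutoff (0.0023) are the same kind of threshold with
different defaults, both configurable.

## Synthetic data generator

The simulator emulates the full causal chain the pipeline inverts:

- **Population** (`make_population`): either a two-haplotype *spike-in*
  (reference plus a variant differing at a chosen number of interior
  SNPs, default 5, at a chosen ratio — the in-silico analog of mixing
  genomic DNA of two inbred lines) or *random* populations (n unique
  haplotypes, interior bases mutating at a per-base rate, frequencies
  uniform/Dirichlet/geometric).
- **Pool** (`sample_pool`): individuals×ploidy haplotype copies drawn
  i.i.d. from population frequencies; realized counts are recorded, and
  all recovery tests compare against *realized*, not nominal,
  frequencies.
- **Reads** (`sequence_pool`): each pair derives from one molecule drawn
  uniformly from the pool (or log-normally weighted when the PCR
  stochasticity knob is on), optionally corrupted by a template switch
  (crossover with a second molecule at a uniform interior breakpoint),
  polymerase substitutions, or a 1–5 base truncation at a random end.
  Substitution sequencing errors apply at rates interpolated linearly
  from `sub_rate_start` (read start) to `sub_rate_end` (read end) —
  a linear form is assumed because only the decay itself is observed in
  real data, not its shape. Quality strings deterministically encode the
  positional error rate (Phred+33); downstream stages ignore qualities,
  so this is cosmetic but reproducible.

Default rates are chosen once as realistic for a high-fidelity
amplicon/Illumina workflow: substitution 1e-3→1e-2 (≈Q30→Q20),
polymerase 6.7e-7 per base (a proofreading polymerase's ~1 in 1.5
million), truncated-primer fraction 0.02, template switch 2e-3,
amplification sigma 0 (even amplification; measured haplotype ratios in
the motivating data track input ratios, so stochastic amplification is
off by default). Truncation lengths are uniform on 1–5 bases because only
the artifact class, not its length distribution, is characterized.

What the simulator does **not** model: lure/trap capture bias, sex
ratios, indel sequencing errors (the variant model is SNP-only),
chimeric multi-locus reads, and repeat-driven merge failure (a locus with
a long internal repeat can legitimately merge poorly; the simulator's
molecules merge unless an artifact intervenes). Passing tests therefore
demonstrate correctness of the inference given this generative model, not
robustness to every failure mode of real libraries.

## Numerical and design choices

- Coordinates 0-based half-open everywhere except VCF (1-based by
  convention). References must be unambiguous A/C/G/T; N is allowed in
  reads only.
- Dereplication sorts by descending count, ties lexicographic; rank
  ordering ties are lexicographic; all iteration over samples/loci is
  sorted — outputs are byte-identical across reruns for fixed inputs and
  seed.
- Detection-limit arithmetic uses `fractions.Fraction` (floats like 0.4
  are snapped to small rationals) so floors and ceilings cannot be
  corrupted by binary rounding.
- The aligner stores all three Gotoh matrices and recomputes decisions
  during traceback with exact float comparison (all scores are sums of
  small integers, exact in float64).
- Zero retained haplotypes after filtering is a hard error naming the
  stage, not an empty table.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make 3-standard-deviation
binomial bands tight enough to be meaningful while keeping the suite
quick: spike-in ratio recovery (1:1 to 999:1) at 1e5 read pairs per
mixture from 2,000-individual pools; planted-SNP recovery at 1e4 pairs
from 500 individuals; truncation-rate recovery at 1e4 pairs; the
end-to-end pipeline fixture at 2 samples × 2 loci × 1,000 pairs.

## Known limitations

- Haplotype identity is exact; sequencing errors above the abundance
  floor and PCR chimeras inflate haplotype counts (no denoising or
  chimera removal, by design).
- The k-mer binner assumes panel loci are mutually distinguishable at
  k = 31; near-duplicated loci would need alignment-based splitting.
- Guide coverage uses exact matching; one or two mismatches far from the
  PAM may in reality still permit dCas9 binding, so coverage is a lower
  bound on biological efficacy.
- The detection-limit arithmetic assumes even amplification across
  templates; real PCR bias shifts the effective per-individual depth.
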