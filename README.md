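# amplihap

Haplotype-resolution analysis of amplicon pool-seq data.

`amplihap` is for researchers who sequence PCR amplicons from *pooled*
DNA of many individuals — population surveys of an agricultural pest,
spike-in controls, rare-variant hunting — and need exact, full-length
haplotype frequencies rather than positionwise allele calls. The
motivating application is designing genetic biocontrol for the invasive
fruit pest *Drosophila suzukii* (spotted wing drosophila), where a CRISPR
guide binding site in a promoter must be conserved across essentially the
whole wild population to work.

The pipeline: paired-end FASTQ → length filter → k-mer locus binning →
**perfect-overlap read merging** (2×250 bp reads of a 400–425 bp amplicon
overlap by 75–100 bp; the overlap must match exactly) → orientation →
**exact dereplication with a minimum-abundance floor** (a haplotype must
be seen ≥5 times) → truncated-primer artifact removal → haplotype
frequency tables → global-alignment pileup into per-base SNP profiles →
individual-weighted population profiles, Shannon entropy, conserved
windows, and NGG-PAM guide candidates scored by summed SNP percentage and
population coverage. A synthetic amplicon-pool simulator with known
ground truth (PCR chimeras, truncated primers, polymerase error,
end-of-read quality decay) makes every stage testable without any
external data.

## Core quantities

For a haplotype at population frequency *f* in a pool of *n* individuals,
with a minimum support of *s* merged reads and a merge rate *m*:

- merged reads per individual required: `s / (f·n)`
- raw read pairs per individual required: `s / (f·n·m)`
- largest pool supportable from *R* read pairs: `n_max = ⌊R·m/s⌋`

Per-position SNP frequency is `1 − count(ref)/depth`; population profiles
are `F(pos,b) = Σ_k w_k f_k(pos,b)` with `w_k ∝` individuals sequenced in
pool *k*; per-position diversity is Shannon entropy
`H = −Σ_b p_b log₂ p_b`. A base is conserved iff every position within a
15-bp flank has SNP frequency `< 0.002`; a guide candidate is a 20-nt
protospacer + NGG with summed SNP percentage
`100·Σ snp_freq` over its 22 sequence-constrained positions, and coverage
= frequency-weighted fraction of haplotypes containing the site exactly.

## Worked example

Simulate a 9:1 two-haplotype spike-in pool of 500 diploid flies at one
locus, artifact-free, and run the full pipeline:

```python
from amplihap import demo_panel, make_population, sample_pool, ErrorModel
from amplihap.simulate import simulate_run
from amplihap.pipeline import run_pipeline, SampleInput
from amplihap.refpanel import SampleMeta
from amplihap.config import PipelineConfig

panel = demo_panel()                      # synthetic nine-locus panel
wg = panel["pWg"]
pop = make_population(wg, "spike_in", seed=1, ratio=(9, 1))
pool = sample_pool(pop, 500, seed=2)
paths = simulate_run(wg, pop, pool, ErrorModel.none(), 250, 20000, 3, "demo/spike")
print("realized minor freq:", pool.realized_frequency("B"))
run_pipeline(PipelineConfig(), [SampleInput("spike", paths["r1"], paths["r2"])],
             panel, {"spike": SampleMeta("spike", "lab", "control", 500)}, "demo/out")
```

Output:

```
realized minor freq: 0.108
```

and `demo/out/haplotypes_spike_pWg.csv` holds exactly two haplotypes:

```
count  frequency
17822     0.8911
 2178     0.1089
```

The recovered minor-haplotype frequency (0.1089) matches the realized
pool composition (0.108, itself a binomial draw around the nominal 0.1)
within read-sampling noise. The per-locus summary reports the mean
entropy (0.0068 bits — five discriminatory SNPs at ~0.11 in an otherwise
monomorphic 410-bp amplicon), 3 conserved windows (the five SNPs break
the interior into SNP-free stretches), and 54 NGG guide sites of which 32
have a summed SNP percentage below 0.5%.

The same arithmetic from the shell:

```
$ amplihap detect --freq 0.002 --n 250 --merge-rate 0.40
target frequency:                0.002
individuals in pool:             250
merged reads per individual:     10 (ceil 10)
read pairs per individual:       25 (ceil 25)
max pool size at 40000 read pairs: 3200
```

i.e. finding a 1-in-500 haplotype among 250 flies needs 10 merged reads
per fly — 25 raw read pairs per fly at a 40% merge rate — and a 40,000
read-pair sample supports pools up to 3,200 individuals.

Other subcommands (`simulate`, `filter`, `bin`, `merge`, `derep`,
`profile`, `aggregate`, `entropy`, `windows`, `guides`, `compare`, `run`)
each wrap one library stage; see `amplihap --help`.

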