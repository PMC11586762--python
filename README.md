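# burdensim

Empirical rare-variant burden testing for small, ancestrally heterogeneous
sequencing cohorts, using Monte-Carlo control cohorts simulated from
population allele-count summary statistics (gnomAD-style AC/AN tables) —
no matched control genotypes required.

For each aggregation unit (gene, protein domain, pathway or custom variant
set) and each continental ancestry group, the engine draws, per variant and
iteration, a hypergeometric variate for the alternate alleles captured in
`2*N` allele draws from the database's `AN` alleles (`AC` of which are
alternate), sums over variants, and reports the empirical tail probability
`Pr(X >= B)` of the observed cohort burden `B` with the add-one estimator
`(r + 1) / (iterations + 1)`. A combined p-value comes from the joint
per-iteration burden across ancestries.

Around the engine the package implements the full supporting stack:

- **core types & I/O** — reversible 64-bit variant keys, interval algebra,
  population TSV / annotation TSV / VCF readers and writers, and worked-example
  summaries over packaged variant and clinical tables
  (`burdensim.keys`, `burdensim.intervals`, `burdensim.io`, `burdensim.tables`)
- **complexity masking** — symmetric DUST (score >= 28), homopolymer runs
  (>= 7 bp), satellite BED input; merged, 10 bp-padded low-complexity track
  (`burdensim.mask`)
- **ancestry assignment** — projection onto reference principal components
  plus a random-forest classifier with an UNKNOWN fallback and a minimum
  group size of 10 for testing (`burdensim.ancestry`)
- **reciprocal variant filters** — database QC / coverage / call-rate
  filters, cohort SOR / ExcessHet / exact-HWE / missingness / AC0 filters,
  qualifying-variant selection (AF < 1% per ancestry, CADD >= 20, non-synonymous),
  and harmonization so an exclusion on either side applies to both
  (`burdensim.filters`)
- **LD pruning** — pairwise r² from database co-occurrence counts (per
  ancestry, 10 kb windows, r² >= 0.95) and from cohort dosage correlation
  (r² > 0.95) (`burdensim.ld`)
- **burden engine** — simulation, exact convolution oracle, empirical and
  combined p-values, `var1`/`af5` result annotations, gene- and domain-level
  drivers (`burdensim.engine`)
- **effect sizes** — collapsed 0/1/2 genotype scores, logistic-regression
  odds ratios with a Firth fallback, simulated control scores, replication
  permutation testing, and simulation-based power curves (`burdensim.effect`)
- **MTR profiling** — missense tolerance ratio in sliding codon windows
  (`burdensim.mtr`)
- **synthetic data** — deterministic generation of the population database,
  annotations, cohorts with an optional spiked gene (target odds ratio),
  ancestry fixtures and sequences with planted low-complexity features,
  each with a truth manifest (`burdensim.simulate`)

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
table counts, engine-vs-oracle agreement, null calibration on 2,000
synthetic genes, effect-size recovery, filter semantics, masking and LD
properties). The full suite runs in a few minutes on one CPU.

## CLI

The `burdensim` entry point exposes one subcommand per pipeline stage:

```sh
burdensim simulate --seed 1 --n-genes 50 --spike-gene GENE00007 --spike-or 8 --outdir demo/
burdensim mask --fasta demo/reference.fa --out demo/lcr.bed
burdensim filter --vcf demo/cohort.vcf --population demo/population.tsv \
    --ancestry-tsv demo/ancestry.tsv --out demo/flags.tsv
burdensim burden --vcf demo/cohort.vcf --population demo/population.tsv \
    --annotations demo/annotations.tsv --ancestry-tsv demo/ancestry.tsv \
    --iterations 100000 --seed 1 --out demo/burden.tsv
```

Other subcommands: `ancestry`, `ld`, `domain-burden`, `effect`,
`replicate`, `power`, `mtr`. Every command echoes its seed and thresholds
(burden results also write a JSON run manifest).

## Data notes

- Intervals are 0-based half-open internally (BED convention); VCF
  positions are converted on ingest, `chr` prefixes are stripped and
  chrM/MT unified.
- Multiallelic VCF records must be split upstream (`bcftools norm -m-`);
  the reader refuses to guess allele pairing.
- The population database is a flat TSV
  (`chrom pos ref alt pop AC AN nhomalt qc_pass covered n_called`), one row
  per variant per ancestry; all readers accept gzip.
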