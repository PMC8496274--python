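# methpore

Downstream analysis of nanopore per-read CpG methylation calls, built for
studies of sparse invertebrate methylomes: per-read log-likelihood ratios →
per-site methylation frequencies → CpG-depletion (CpG O/E) validation →
two-group differential methylation with FDR control and perfect-difference
region detection — plus a ground-truthed synthetic-data generator for every
input the pipeline consumes.

## The problem

Signal-level nanopore callers emit, for every read and every CpG group, a
log-likelihood ratio (LLR) comparing 5-methylcytosine against unmethylated
cytosine; positive values support methylation. CpGs closer than ~6 bases
cannot be resolved individually and are reported as one k-mer group sharing
a single call. Turning these per-read calls into biology requires:

1. **Site frequencies.** A read is called methylated when LLR > *t*,
   unmethylated when LLR < −*t* (default *t* = 2), ambiguous otherwise
   (excluded from both counts). Per group,
   `frequency = called_methylated / called_sites`, with counts reported as
   reads × motifs. Low-coverage sites are removed (10 called reads per CpG
   motif for transcriptome work; ≥ 3 called reads per k-mer **per sample**
   for multi-sample comparisons).
2. **Validation against CpG depletion.** Germline 5mC deaminates to T over
   evolutionary time, so historically methylated sequence is CpG-poor. Per
   sequence of length *l*:

   CpG O/E = n<sub>CpG</sub> / (n<sub>C</sub> · n<sub>G</sub>) · *l*² / (*l* − 1)

   with outliers excluded outside the strict bounds (0.001, 2). If the
   nanopore frequencies are real biology, transcript-level methylation must
   correlate **negatively** with CpG O/E, and fully unmethylated transcripts
   (frequency exactly 0) must show higher O/E than fully methylated ones
   (exactly 1).
3. **Two-group comparison.** A positions × samples matrix (strict
   intersection over the per-sample coverage threshold), per-sample
   genome-wide means with a two-sample t-test, PCA of methylation patterns,
   per-position Welch t-tests with Benjamini–Hochberg FDR at α = 0.05, and a
   separate channel for **perfect differences** — positions where both
   groups have zero within-group variance and different means, so the
   t statistic is undefined. Runs of flagged positions within 2 kb merge
   into differentially methylated regions (DMRs), exported as TSV + BED6.

## Worked example

Everything below runs from synthetic data with known truth (seeds make runs
byte-reproducible). Genome-wide arm — a 4 aposymbiotic vs 4 symbiotic design
with true group means 0.055 vs 0.059:

```bash
methpore simulate --seed 42 --out-dir demo/sim --n-positions 2000
methpore diffmeth --sample-sheet demo/sim/sample_sheet.tsv --out-dir demo/dm
```

```
2000 positions, groups means {'aposymbiotic': 0.0546, 'symbiotic': 0.0582}, t=-2.295 p=0.0715;
0 positions pass FDR at alpha=0.05; 0 perfect differences in 0 regions -> demo/dm
```

The recovered group means sit on the generator's truth, the genome-wide
t-test is borderline (real between-individual variation, n = 4 per group),
no single position survives FDR at this effect size, and a jittered null
yields no zero-variance perfect differences. Transcriptome arm — sequences
whose CpG content decayed in proportion to their methylation level:

```bash
methpore simulate --seed 42 --out-dir demo/tx --mode transcriptome
methpore freq demo/tx/transcriptome.calls.tsv --out demo/tx/sites.tsv --min-called 10
methpore transcript-validate --sites demo/tx/sites.tsv \
    --fasta demo/tx/transcripts.fasta --out demo/tx/transcripts.tsv
```

```
pearson r=-0.9610 p=1.58e-112 n=200
extremes t=40.896 p=1.38e-06 means={'fully_unmethylated': 1.0117, 'fully_methylated': 0.1581}
```

Methylation and CpG O/E are strongly inversely related, and fully
unmethylated transcripts sit at O/E ≈ 1 (no historical depletion) while
fully methylated ones are depleted to ≈ 0.16 — the expected signature of
gene-body methylation.

## Package layout

| module | contents |
| --- | --- |
| `methpore.formats` | FASTA, per-read call tables, site tables, sample sheets, BED6 |
| `methpore.cpg_oe` | CpG O/E statistic and outlier bounds |
| `methpore.sites` | LLR calling, group aggregation/splitting, coverage filters |
| `methpore.transcripts` | transcript-level methylation, correlation, extremes t-test |
| `methpore.differential` | matrix build, genome-wide means, PCA, per-site tests, BH, DMRs |
| `methpore.simulate` | ground-truthed generators for sequences, reads, experiments |
| `methpore.cli` | `methpore` console script (simulate / oe / freq / transcript-validate / diffmeth) |

See `docs/methods.md` for the statistical model, generator assumptions and
numerical conventions.
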