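# Methods

## Scope and model

`methpore` implements the downstream half of a nanopore methylome study: it
consumes per-read × per-CpG-group call tables (one log-likelihood ratio per
read per group, positive supporting 5mC) and carries them through site
frequencies, CpG-depletion validation and a two-group comparison. Signal
processing, basecalling, mapping and the caller's HMM are out of scope; the
call table is the interface.

All internal coordinates are 0-based with inclusive ends; only the BED
writer converts to half-open intervals.

## Per-read calling and site aggregation

A read is methylated when LLR > *t*, unmethylated when LLR < −*t*, ambiguous
otherwise; ambiguous reads are excluded from numerator **and** denominator.
The threshold *t* defaults to 2.0 — there is no canonical published value
and helper tools in the wild have used 2.0–2.5 — and is echoed into every
output header so a run is reproducible from its files. Counts are reported
per group as reads × motifs (`called_sites`), matching the layout of the
standard frequency-summarising helpers; coverage filters always count
*reads* (`called_sites / n_motifs`), so multi-CpG groups gain no advantage.

Groups are keyed by (contig, start, end). Calls on the '−' strand are
collapsed by default onto the forward-strand C of the palindromic CpG
(position − 1); a switch keeps strands separate, since published analyses do
not always state which convention they used. Duplicate (read, group) pairs
keep the first occurrence. Optional group splitting expands a multi-CpG
group into single-CpG records at each CG offset of the group context, each
inheriting the group's read counts — the caller made one shared call, so the
counts are genuinely shared, not divided.

The coverage thresholds follow the two analysis arms: 10 called reads per
CpG motif for the transcriptome arm, and ≥ 3 called reads per k-mer per
sample for the genome-wide arm, applied as a strict intersection (a single
under-covered sample drops the position for everyone). Whether the 10-read
rule should apply before or after group splitting is not externally fixed;
it is applied per group (reads per group), before any splitting.

## CpG O/E

For a sequence of length *l* with n<sub>C</sub> C's, n<sub>G</sub> G's and
n<sub>CpG</sub> CG dinucleotides:

    CpG O/E = n_CpG / (n_C · n_G) · l² / (l − 1)

evaluated in exact rational arithmetic with a single final float conversion.
Note the *l*²/(*l*−1) normalisation: some literature uses *l*/(*l*−1)
variants, so values are not directly comparable across studies using the
other form. Counting is case-insensitive and forward-strand only
(transcripts are sense sequences); IUPAC ambiguity codes count toward *l*
but not toward any base or dinucleotide count — the formula's "length of
the sequence" is taken literally without inventing phantom CpGs. Sequences
where the statistic is undefined (no C, no G, or *l* < 2) are flagged, not
silently dropped, so filter funnels stay auditable. Outlier bounds are
strict on both sides: a record is kept iff 0.001 < O/E < 2.

## Transcript-level validation

Transcript methylation pools read counts over the transcript's covered
groups (Σ methylated / Σ called), weighting deeply covered sites more; an
unweighted mean of site frequencies is available via flag. "Fully
unmethylated/methylated" means frequency exactly 0 or exactly 1 after
aggregation — no tolerance band. Transcripts with calls at fewer than 20% of
their CpGs are excluded ("fewer than" is strict: exactly 20% survives).

The validation statistics are the Pearson correlation of O/E against
transcript methylation (two-sided p from the t distribution, n − 2 df) and a
two-sample t-test of O/E between the two extreme classes (Welch by default,
pooled optional). Zero variance in both classes with differing means is
reported as perfect separation rather than a fabricated statistic.

## Two-group comparison

* **Genome-wide means**: per-sample mean frequency over all retained
  positions; two-sample t-test on the per-group sample means.
* **PCA**: samples are observations, positions variables; per-position
  centering, no scaling (frequencies already share the [0, 1] scale);
  computed by SVD; variance-explained fractions sum to 1 over computed
  components; deterministic sign convention (largest-magnitude loading of
  each component is positive).
* **Per-position tests**: Welch by default — per-position variances at
  n = 4 are unstable, so assuming equal variances buys little — with a
  pooled option. Implemented vectorised across positions; unit tests pin it
  to `scipy.stats.ttest_ind` at 1e-10.
* **Perfect differences**: both group variances < ε = 1e-12 and means
  differing by > ε. Frequencies are ratios of small integers, so exact zeros
  are representable and ε only guards floating-point dust. Perfect positions
  are excluded from the BH family (m counts only testable positions) and
  reported separately — the t statistic is undefined there, and treating an
  "infinitely significant" position as p → 0 would distort the FDR family.
  Degenerate positions with equal means get t = 0, p = 1.
* **BH FDR**: standard step-up, q<sub>(i)</sub> = min<sub>j≥i</sub>
  m·p<sub>(j)</sub>/j capped at 1, significant iff q ≤ α = 0.05. Tested
  against both a brute-force evaluation of the definition and
  `statsmodels.stats.multitest`.
* **DMR merge**: single-linkage over flagged positions on one contig,
  joining successive positions with gap (next start − previous end)
  ≤ 2000 bp. The merge rule and gap are pipeline parameters, not an
  externally fixed convention; 2 kb reflects the position spacing at which
  a ~10 kb block remains one region while isolated stray flags stay
  singletons. Regions export with per-group mean frequencies; the BED score
  is the absolute between-group difference scaled to 0–1000.

## The synthetic-data generator

The generator exists so every stage can be tested against known truth. What
it emulates, and what it does not:

* **Sequences.** Transcripts draw a true methylation level from a sparse
  bimodal prior — 90% near 0 (Beta(1, 15)), 10% near 1 (Beta(15, 1)), each
  mode inflated with a point mass at its extreme (30% of the mode) because
  many invertebrate genes carry no gene-body methylation at all and a few
  are uniformly methylated; the point masses are what make the "fully
  unmethylated/methylated" classes non-empty. Bases are iid equiprobable;
  each CpG is then replaced by TpG with probability decay_rate × level
  (default 0.9), the mutational mechanism behind CpG depletion. Real
  transcriptomes have codon structure, GC heterogeneity and isoform
  redundancy; none of that is modelled, so passing tests demonstrate the
  statistics recover a *planted* depletion signal, not that they would be
  equally powered on real composition.
* **Reads.** Per group, read states are Bernoulli(truth) and LLRs Gaussian
  at ±5 (sd 1) — a stylised version of the caller's empirically bimodal LLR
  distribution. At these defaults miscalls are ~Φ(−3) ≈ 0.13% per read
  (ambiguity) and ~Φ(−7) for a sign flip, so calling is near-perfect unless
  the user degrades the modes. CpGs within 6 bases merge into one group
  with a shared call, with 5 bp flank contexts. No read-length, error-profile
  or strand-bias realism.
* **Experiments.** Default design: 4 aposymbiotic + 4 symbiotic samples
  with genome-wide baselines 0.055 and 0.059. Between-sample variation has
  two parts: a per-sample genome-wide offset (sd 0.002) — individual biology
  and run effects that do not average away across positions, and the reason
  reported per-sample mean SDs are ~0.002 — plus independent per-position
  jitter (sd 0.002), both truncated to [0, 1] after adding to the baseline.
  Injected DMR blocks override per-group frequencies on an interval; a block
  with jitter 0 is fully deterministic (the sample offset is suppressed
  there), producing textbook perfect differences. The prescribed FDR
  calibration design (`simulate_null_signal_matrix`) is jitter-only
  (sd 0.05) with no sample offset, so its per-position null is exactly iid.
* **Fast path.** `simulate_frequency_matrix` and `simulate_transcript_sites`
  draw per-read LLRs vectorised and aggregate with the same thresholding
  rule as `aggregate_sites`, skipping the per-read table; the scalar and
  vectorised summarisers are unit-tested for exact agreement, and the full
  per-read → parse → aggregate route is exercised by the aggregation-oracle
  and decay-recovery tests. All generators are byte-deterministic under a
  fixed seed.

## Problem sizes

Test and acceptance simulations run at: 20 replicates of 5050 positions for
FDR calibration; 1000 random sequences (lengths 50–5000) for the O/E
oracle; 10⁴ call rows for the aggregation oracle; 500 sites × 30 reads for
frequency recovery; 20 + 200 replicates of 200 × 2 kb transcripts for the
depletion correlation and its null calibration; and 10⁵ positions for
perfect-difference specificity. These sizes give stable Monte-Carlo
estimates for the properties checked while keeping the default suite quick
to iterate on.

## Known limitations

* No beta-binomial or regression-based methylation model, no smoothing DMR
  caller, no covariates — the pipeline reproduces a specific published
  procedure (per-position t-tests + BH + perfect-difference channel), not
  alternatives to it.
* Per-position t-tests at n = 4 with frequencies in [0, 1] are approximate;
  the perfect-difference channel exists precisely because the t statistic
  degenerates at zero variance.
* The FASTA reader is a linear scan (no indexing); inputs beyond a few
  hundred MB of sequence are better pre-sliced.
* Strand collapsing assumes the caller reports the CpG group's forward
  coordinates or the reverse C at +1; other dialect conventions need the
  `--keep-strands` switch and external handling.
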