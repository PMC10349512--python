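# crossfdr

Cross-trait pleiotropy analysis of GWAS summary statistics.

Given per-SNP p-values for two traits, `crossfdr` harmonizes the two summary
tables on their common rsIDs, optionally LD-prunes the merged set (removing
the smaller-MAF member of each linked pair at r² > 0.2), computes stratified
conditional Q-Q curves, the empirical conditional FDR (cFDR) in both
conditioning directions, and the conjunctional FDR (ccFDR, the larger of the
two cFDRs), selects significant and pleiotropic SNPs at configurable
thresholds, and estimates the causal effect between the traits with five
two-sample Mendelian-randomization estimators (IVW, Egger, weighted median,
simple and weighted mode). A synthetic-data module generates paired summary
statistics from a four-component z-score mixture (and MR instrument sets
under a known causal effect) so every stage can be tested against ground
truth.

The cFDR for SNP *i* with primary p-value *p* and conditioning p-value *q* is
the counting estimator

```
cfdr_i = min(1, p_i * #{j : q_j <= q_i} / #{j : p_j <= p_i and q_j <= q_i})
```

with inclusive comparisons (the denominator is never zero) and values capped
at 1.

## CLI

`crossfdr` exposes one subcommand per stage plus an end-to-end runner:

```bash
# simulate paired sumstats with known pleiotropic structure
crossfdr simulate --n-snps 100000 --pi 0.9 0.04 0.04 0.02 --seed 1 \
    --out-a a.tsv --out-b b.tsv

# merge on common SNPs, compute cFDR/ccFDR, select pleiotropic SNPs
crossfdr merge --sumstats-a a.tsv --sumstats-b b.tsv --out merged.tsv
crossfdr qq    --paired merged.tsv --strata 1,0.1,0.01,0.001,0.0001 --out qq.tsv
crossfdr cfdr  --paired merged.tsv --out cfdr.tsv
crossfdr select --cfdr-table cfdr.tsv --column ccfdr --ccfdr-threshold 0.05 --out sel.tsv

# LD pruning (genotype-score matrix or precomputed pair list)
crossfdr prune --paired merged.tsv --genotype-matrix scores.tsv \
    --r2 0.2 --ld-window 50 --ld-step 5 --out pruned.tsv

# two-sample MR (five methods)
crossfdr mr --exposure exp.tsv --outcome out.tsv --seed 1 --out mr.tsv

# everything from a YAML config
crossfdr run-all --config run.yaml
```

A minimal `run.yaml`:

```yaml
out_dir: run1
seed: 5
synthetic:
  pi00: 0.9
  pi10: 0.04
  pi01: 0.04
  pi11: 0.02
  n_snps: 100000
mr:
  n_instruments: 50
  true_effect: 0.3
```

Real inputs replace the `synthetic` block with `sumstats_a:`/`sumstats_b:`
paths (whitespace/tab/comma-delimited text with SNP, CHR, POS, P columns).
Re-running with the same config and seed reproduces the output tree
byte-for-byte.

## Layout

- `src/crossfdr/simulate.py` — mixture / LD-block / MR generators
- `src/crossfdr/sumstats.py` — sumstats IO and validation
- `src/crossfdr/harmonize.py`, `prune.py` — merge and LD pruning
- `src/crossfdr/cfdr.py` — conditional Q-Q, cFDR, ccFDR
- `src/crossfdr/select.py` — threshold selection, Manhattan/BED exports, annotation joins
- `src/crossfdr/mr.py` — five MR estimators and plot data
- `src/crossfdr/pipeline.py`, `cli.py` — orchestration and CLI
- `src/crossfdr/data/pleiotropic_loci.tsv` — bundled 62-row published locus table
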