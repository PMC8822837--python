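# crossld

Two-locus linkage disequilibrium (LD) for crossbred (F1) populations:
closed-form theory, sample estimators, and a Monte-Carlo study of their
bias and precision.

When two parental lines are crossed at random, the crossbred population
deviates from Hardy–Weinberg proportions (negative, locus-specific
inbreeding coefficients), so the classical argument for estimating LD
from unphased genotype dosages does not directly apply. `crossld`
implements:

* **core** — crossbred allele frequencies and inbreeding coefficients;
  haplotype-frequency construction from (allele frequency, r², phase);
  the true crossbred r², D and D′ computed two ways: from the per-line
  haplotype covariances, and from unphased genotype-dosage moments. The
  two routes are algebraically identical, and the package tests this to
  1e-12.
* **estimators** — a per-line plug-in haplotype-route estimator and the
  dosage-correlation (genotype-route) estimator, plus the 4×4
  haplotype-pair and 3×3 dosage-count containers and vectorized batch
  versions.
* **simulate** — multinomial sampling of crossbred samples, a
  reproducible scenario grid (default: 15 unordered frequency pairs from
  {0.05…0.45} × r² ∈ {0.2,0.4,0.6,0.8} × n ∈ {900,1800,2700} = 180
  scenarios), and per-scenario replicate runs.
* **summarize** — per-scenario bias/SD/precision-ratio summaries,
  one-sample t-tests against the true value, across-scenario aggregation,
  and static figures.
* **io / cli** — TSV and two-site VCF readers (phased GT + line map →
  haplotypes; unphased GT → dosages), a fixture generator, and the
  `crossld` command.

## CLI

```sh
# true crossbred LD and inbreeding coefficients from parameters
crossld predict --pa-m 0.05 --pb-m 0.09 --pa-n 0.05 --pb-n 0.09 \
                --r2-a 0.2 --r2-b 0.2

# estimate LD from data (three input forms)
crossld estimate --haplotypes haps.tsv
crossld estimate --genotypes dosages.tsv
crossld estimate --vcf sites.vcf --locus-m 1:1000 --locus-n 1:2000 \
                 --line-map linemap.tsv

# run a scenario grid and summarize it
crossld simulate --config grid.yaml --out run/ --keep-replicates
crossld summarize --in run/ --out summary.tsv --figures figs/

# write a small demo dataset (TSV + VCF + truth JSON)
crossld fixture -n 100 --seed 1 --out fixtures/
```

`grid.yaml` keys: `freq_levels`, `r2_levels`, `sample_sizes`, `n_reps`,
`seed`, `phase_A`, `phase_B`, `keep_replicates`; unknown keys are
rejected. Omitting `--config` runs the default 180-scenario grid.

Haplotype TSV columns: `individual_id, line (A|B), allele_M (0|1),
allele_N (0|1)`, two rows per individual. Dosage TSV columns:
`individual_id, dosage_M, dosage_N` with dosages in {0,1,2}.

## Reproducibility

All randomness flows through `numpy.random.default_rng`; per-scenario
seeds derive from the master seed and the scenario's grid position via
`SeedSequence`, so any scenario can be re-run in isolation and full runs
are bit-identical for a fixed seed.
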