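# rohped

Pedigree- and ROH-based inbreeding monitoring for genetically rescued wild
populations.

## The problem

Small, isolated wildlife populations accumulate inbreeding; managers
counter it with *genetic rescue* — translocating unrelated animals into the
population. Judging whether a rescue worked requires tracking individual
inbreeding over decades, and the two standard estimators can disagree:

- **F_PED**, the pedigree inbreeding coefficient: the kinship of an
  individual's parents, computed by the recursive tabular algorithm on the
  additive relationship matrix. It is an *expectation* given recorded
  ancestry, and it is blind to any shared ancestry outside the records.
- **F_ROH**, the genomic inbreeding coefficient: the fraction of the
  autosomal genome lying in runs of homozygosity (ROH) at least 1 Mb long,
  `F_ROH = ΣL_ROH / ΣL_auto` (default `ΣL_auto` = 2.46 Gb), with ROH called
  by a two-state hidden Markov model (autozygous vs non-autozygous) over
  genotypes and allele frequencies.

In long-term field studies, parentage records deepen over time (e.g.
paternity becomes assignable only once genetic markers are adopted), so
F_PED *detects* more inbreeding in recent cohorts even when true
autozygosity is falling. A monitoring program relying on pedigrees alone
can conclude that inbreeding rose during a successful rescue. `rohped`
implements both estimators, the statistical comparisons between them, and —
because no real dataset ships with the package — a gene-dropping simulator
that generates a multi-decade bottleneck-and-rescue population with exact,
known autozygosity for every individual, so every stage of the pipeline is
verifiable against ground truth.

## What is in the box

| module | contents |
|---|---|
| `rohped.pedigree` | CSV pedigree parsing/validation, kinship & F_PED recursion (memoized, value-identical to the tabular method), complete generation equivalents `CGE = Σ(0.5)^g`, grandparent-completeness retention filter, record censoring |
| `rohped.genotypes` | VCF in/out (via cyvcf2), the ordered site filter cascade (biallelic SNPs, QUAL ≥ 30, depth ≥ 20, missingness ≤ 10%, MAC ≥ 8, exact HWE p ≥ 0.01, 100-bp thinning), individual missingness filter, O_hom/E_hom/F_IS, ascertainment-outlier flagging |
| `rohped.roh` | distance-dependent two-state HMM (Viterbi + forward–backward), ROH segment extraction, F_ROH with 1–5 / 5–20 / >20 Mb length bins |
| `rohped.simulate` | phase-structured demography (burn-in, expansion, 83% decline, rescue with 35 immigrants over 13 years), gene dropping with Poisson recombination, Balding–Nichols-diverged immigrant allele frequencies, genotype emission with error and QC metadata, exact IBD-tract truth |
| `rohped.inference` | Wilcoxon signed-rank (tie-aware exact p) and Kendall τ_b, beta regression (logit link) with natural cubic splines over time, beta mixed models with a year random intercept (Laplace ML), Welch's t and the F_PED~CGE depth-bias regression |
| `rohped.cli` | `rohped` command with `simulate / analyze / replay` plus per-stage subcommands |

## Worked example

Simulate a scaled-down study population, censor its records the way a real
records system accumulates (no parentage before observation starts in 1979,
nearly no paternity before genotyping starts in 1987), and run the full
analysis:

```sh
rohped simulate --seed 5 --small --out demo/sim
rohped analyze --pedigree demo/sim/pedigree.csv --vcf demo/sim/genotypes.vcf \
    --out demo/analysis --censor --seed 5 --autosome-length 247500000
```

(`--autosome-length` is the simulated genome size; leave it at its 2.46 Gb
default for a full-scale genome.) From `demo/analysis/models.json`:

```
paired:   n=285  V=670  p<0.001   Kendall tau=0.434  p<0.001
prepost F_ROH: beta=-0.462 (SE 0.136, z=-3.40, p<0.001)  0.173 -> 0.116  (-33%)
prepost F_PED: beta=+0.184 (SE 0.177)                    0.042 -> 0.050  (+19%)
depth bias:    CGE pre=2.71  post=4.11  (Welch t=-10.4, p<0.001)
               F_PED ~ CGE slope = +0.397 (SE 0.050, p<0.001)
```

Reading this the way a monitoring program would: genomic inbreeding dropped
by a third after rescue began (the signed-rank V far below its null mean
says F_ROH almost always exceeds F_PED individual-by-individual), while the
pedigree coefficient *rose* — and the last two lines show why: post-rescue
cohorts have deeper pedigrees (higher CGE), and deeper pedigrees detect
more inbreeding. The pedigree trend is a records artifact, not biology.
The simulator's truth table (`demo/sim/truth.tsv`) contains each
individual's exact gene-drop autozygosity, against which the per-cohort
mean F_ROH is accurate to well under ±0.01 at default settings.

`rohped replay --seed 0 --out demo/replay` runs the whole loop and checks
the three signs (F_ROH down, censored F_PED up, CGE slope positive)
explicitly; its exit code is the number of failed checks.

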