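# Methods

## Pedigree inbreeding

Kinship φ is computed by the standard recursive identities of the additive
relationship matrix: φ(i,i) = ½(1 + φ(sire_i, dam_i)); for i not an
ancestor of j, φ(i,j) = ½(φ(i, sire_j) + φ(i, dam_j)); φ against an
unknown parent is 0. F_PED(i) = φ(sire_i, dam_i), and 0 if either parent is
unknown. Founders are assumed non-inbred and mutually unrelated — in a wild
pedigree this is exactly the assumption that record censoring violates, and
quantifying the resulting bias is the point of the package. Rather than
materializing the full n×n relationship matrix, pairs are evaluated lazily
with memoization; the recursion always expands the member of the pair with
the deeper ancestry, which guarantees the "i not an ancestor of j"
precondition and gives values identical to the tabular method (verified
against a Wright path-counting oracle in the tests).

Completeness is summarized as complete generation equivalents,
CGE = Σ over known-ancestor paths (0.5)^g, computed by the recursion
CGE_i = Σ_{known parents p} 0.5·(1 + CGE_p). This counts an ancestor once
per path occurrence, the standard "equivalent complete generations"
measure; a distinct-ancestor variant (each ancestor counted only at its
shortest distance) is available as an option for sensitivity analysis.

The retention rule for F_PED analyses keeps an individual iff all four
grandparents are known, or F_PED > 0, or it is translocated or a direct
offspring of a translocated animal. Translocated animals are treated as
truly outbred (F_PED = 0) rather than merely unobserved.

`censor_records(ped, era_start, p_pat, p_mat, seed)` removes parent links
of pre-era births with one independent draw per link in topological order,
so a fixed seed is reproducible. The simulator composes two censoring
passes (`apply_record_censoring`): before observation begins (default
1979) no parentage exists; between observation start and the genotyping
era (default 1987) maternity survives at 0.5 (field observation) and
paternity at 0.05 (essentially unassignable without markers). The pre-era
rates are back-calculated from a records system in which overall maternity
is known for ~78% and paternity for ~51% of a pedigree whose post-era
links are nearly complete.

## Genotype filtering

The site cascade applies, in order: drop indels and non-biallelic records;
QUAL < 30; mean site depth < 20; per-site missingness > 10%; minor allele
count < 8; exact Hardy–Weinberg test p < 0.01. The HWE test is the exact
conditional test (Levene/Haldane distribution of the heterozygote count
given allele counts, summing outcomes no more probable than observed),
computed by the standard recurrence and verified against the closed-form
factorial formula. After the cascade, sites are thinned greedily by
physical distance so that no two retained sites on a chromosome are within
100 bp (the behaviour of the common VCF toolkit's `--thin`). Order matters
and the removal report records attrition per criterion; re-running the
cascade on its own output removes nothing (fixed point). Individuals with
more than 25% missing genotypes are dropped and allele frequencies are
recomputed from the remaining cohort.

Observed homozygosity O_hom, its Hardy–Weinberg expectation
E_hom = mean over sites of (p² + q²), and F_IS = (O_hom − E_hom)/(1 − E_hom)
are computed per individual over its non-missing sites with cohort allele
frequencies. Individuals with strongly negative F_IS (default threshold
−0.3, configurable because such outliers are identified ad hoc in
practice) are flagged as SNP-ascertainment artifacts and excluded from
homozygosity/F_IS summaries but kept for ROH calling, which depends on
extended tracts and is far less sensitive to panel ascertainment.

## ROH hidden Markov model

Two states: HW (non-autozygous) emits genotypes at Hardy–Weinberg
proportions pushed through a per-allele flip-error confusion matrix; AZ
(autozygous) emits homRef with probability (1−p)(1−ε), het with ε, homAlt
with p(1−ε) — heterozygotes arise in AZ only through error. Missing
genotypes are uninformative (likelihood 1 in both states). Between
adjacent sites at distance d bp, each direction switches with probability
1 − exp(−rate·d); defaults h2a = 6.7e-8 (HW→AZ) and a2h = 5e-9 (AZ→HW) per
bp follow the widely used genotype-based ROH caller's documented defaults,
and ε defaults to 0.01. Chromosomes are decoded independently from the
stationary distribution h2a/(h2a+a2h). Viterbi decoding (ties resolved to
HW) defines segments — first to last site of each maximal AZ run, 1-based
inclusive — while scaled forward–backward posteriors are retained for QC.
Both algorithms are verified against exhaustive path enumeration on short
chromosomes. The implementation is vectorized across individuals, so a
37,000-site, ~1,000-individual dataset decodes in seconds.

F_ROH discards segments shorter than 1 Mb (short ROH reflect ancient
haplotype sharing rather than recent inbreeding) and divides by the
autosomal genome length (default 2.46 Gb, configurable). Length bins are
[1, 5], (5, 20] and (20, ∞) Mb; the total is computed as the sum of the
bins so the partition identity is exact. A segment of exactly 1 Mb is kept
and falls in the first bin.

## Simulator

The generator emulates a small, long-isolated mountain ungulate population
under monitoring:

- **Demography.** Piecewise-linear population targets: burn-in from 1950
  at ~70 animals (so 1979+ cohorts already carry background autozygosity
  from long isolation), growth 1979–1992 to ~200, an 83% decline to ~55 by
  2002, recovery under rescue to ~110 by 2022. Each year, survival is
  age- and sex-dependent (lamb 0.7, ewe 0.92, ram 0.85, maximum age 16)
  with culling toward the target; females breed at ages 3–12; sires are
  drawn with Gamma(1)-weighted polygynous skew increasing with age.
  Rescue translocations follow the schedule 26 animals over 2002–2007 and
  9 in 2015 (35 over 13 years), entering as unrelated founders aged 2–7
  with the translocated flag and an introduction year.
- **Within-deme mate choice.** Each individual carries an
  immigrant-ancestry fraction q (founders 0, immigrants 1, offspring the
  parental mean); a dam's sire weights are scaled by exp(−a·|q_dam −
  q_sire|) with a = 2 by default, so resident and introduced lineages mix
  over years rather than instantaneously — matching the observed
  persistence of a substantial endemic breeding core after real rescues.
- **Gene dropping.** Every founder receives two unique haplotype labels;
  each meiosis draws a Poisson crossover count from the chromosome's
  genetic length (default map 1 cM/Mb, no interference), uniform crossover
  positions and a random start homolog. True autozygosity is the exact
  fraction of base pairs where the two homolog labels match; IBD tracts
  are recorded per individual. E[autozygosity] equals F_PED by theory,
  which the tests confirm by Monte Carlo.
- **Genotypes.** Default genome: 26 autosomes totalling 2.46 Gb, ~15
  SNPs/Mb placed uniformly at random. Endemic founder haplotypes draw
  alleles from ancestral frequencies uniform on (0.05, 0.95); translocated
  founder haplotypes from a Balding–Nichols distribution around the same
  ancestral frequencies with F_ST = 0.05 (the real source-population
  divergence is not published; 0.05 is a plausible within-region value).
  Per-allele flip error ε = 0.01, per-genotype missingness 2%, and planted
  low-QUAL / low-depth site fractions (3% each) exercise the filter
  cascade. Individuals born before 1979 are not genotyped.
- **Determinism.** All randomness derives from one seed through spawned
  SeedSequences; identical config + seed reproduce byte-identical outputs.

What the simulator does *not* emulate: linkage disequilibrium within
founder haplotypes (alleles are drawn independently per site, so
background LD-driven ROH in founders is absent), crossover interference,
overlapping-generation subtleties of real ungulate life history, sex-biased
dispersal, natural immigration, genotype-likelihood uncertainty, and any
fitness consequences of inbreeding. Passing tests therefore demonstrate
that the estimators and models behave correctly under a faithful IBD
process with known truth — not that the genotyping-error or LD structure of
any particular assay is reproduced.

A scaled-down configuration (`SimConfig.small()`: ~half-size population,
nine chromosomes totalling 247.5 Mb at the same SNP density, per-capita
rescue intensity preserved) is used for replicated end-to-end runs; the
full default genome is used where genome scale itself matters (F_ROH
recovery). These problem sizes are the package's chosen test conditions
and are stated in the relevant test docstrings.

## Statistical layer

Proportions are modelled with a beta likelihood, mean logit-linked,
precision φ constant. Exact zeros are nudged to 0.0005 (any value < 0.001
is accepted; no individual is expected to be entirely devoid of
autozygosity). Fixed-effects fits delegate to statsmodels' BetaModel with
internal column scaling for conditioning; a fit failing both BFGS and
Nelder–Mead with a non-trivial score norm raises.

The pre/post-rescue contrasts and the F_PED~CGE regression add a scalar
random intercept per birth-year. The marginal likelihood integrates each
year's intercept u_g ~ N(0, σ²) by a one-dimensional Laplace approximation
(per-group posterior modes found by simultaneous Newton steps with
analytic beta-likelihood derivatives), maximized by Nelder–Mead over
(β, log φ, log σ); standard errors come from the numerical observed
information. When σ̂ hits the zero boundary (< 1e-3) the model reduces
exactly to the fixed-effects fit, which is returned instead. The
implementation is cross-checked against an independent R mixed-model
fitter on simulated data in the tests. Predicted group means fix u = 0;
percent change is 100·(μ_post − μ_pre)/μ_pre on the response scale.

Temporal trends use a natural cubic spline of year with 3 degrees of
freedom (truncated-power natural basis; internal knots at the 1/3 and 2/3
quantiles of observed years, boundary knots at min/max, linear beyond
them; the spanned space is verified against R's `splines::ns` fitted
values). Era assignment: born in or before 2002 → pre; later births and
all translocated individuals (regardless of birth year) → post; the year
covariate for translocated individuals is their introduction year.

The paired comparison uses the Wilcoxon signed-rank statistic V = sum of
ranks of positive F_PED − F_ROH differences, zeros dropped, mid-ranks for
ties; for ≤ 25 nonzero pairs the two-sided p comes from the exact
tie-aware null distribution built by dynamic programming (scipy's exact
method ignores ties), otherwise from the normal approximation with
continuity correction. Kendall's τ_b (tie-corrected, appropriate given the
many zero F_PED values) comes from scipy. CGE is compared between eras
with Welch's unequal-variance t; the depth-bias regression of
boundary-adjusted F_PED on CGE uses only individuals with CGE > 1, whose
F_PED is not structurally pinned at zero. p-values are reported
unadjusted; α = 0.05.

## Numerical and design notes

- Viterbi ties resolve to the non-autozygous state; segment endpoints are
  the first/last site positions of the run (length = end − start + 1),
  since the data do not locate state changes between sites.
- The depth filter reads "mean site depth across samples"; per-genotype
  depth is not required of input VCFs. Site missingness is the fraction of
  samples with missing genotypes.
- Allele frequencies for the HMM are cohort estimates from the filtered
  dataset; external frequencies can be supplied by overwriting
  `sites['alt_freq']`.
- Undeclared parents in a pedigree CSV are auto-added as founders with a
  warning (field pedigrees routinely reference unsampled sires); a strict
  mode raises instead.
- `emission_probs` normalizes exactly in both states; monomorphic sites
  are clipped to frequencies in [1e-6, 1−1e-6] before decoding.

## Known limitations

- The Laplace approximation can understate random-intercept variance with
  very few observations per year; at this package's cohort sizes the
  agreement with an independent fitter is within a few percent.
- F_ROH recovery degrades if SNP density falls well below ~10/Mb, since
  1 Mb segments then contain too few sites to overcome emission noise.
- The grandparent-completeness filter interacts with censoring: in heavily
  censored pedigrees the nonzero-F_PED retention channel over-represents
  detectable close inbreeding, exactly as it does in real studies; this is
  a property of the rule, not of the implementation.
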