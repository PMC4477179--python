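# triadppi

Parent-phenotype informed association tests for case-parent triad studies.

## The problem

In the case-parents design an affected child and both biological parents are
genotyped, and genetic association is inferred from distortion in the
transmission of alleles to the affected offspring. Such studies routinely
record whether the parents themselves have had the disease — family history is
usually why the study exists — but the standard analyses ignore that
information. For diseases with substantial lifetime risk (breast cancer,
prostate cancer), the parents' own phenotypes carry real signal: if a variant
raises disease risk, the affected parents of cases should carry more copies of
it than the unaffected parents. `triadppi` implements a coherent likelihood
framework that uses both generations at once, is robust to population
stratification, yields relative-risk estimates, and tolerates missing parental
genotypes.

## Models and tests

Let M, F, C be the variant-allele counts (0/1/2) of mother, father and
affected child, and D_M the mother's disease indicator. Two factors are
modeled:

**Transmission (offspring) model** — a log-linear model for the triad
genotypes conditional on the child being affected:

    ln Pr(M, F, C | D_C) = μ_(M,F) + γ₁ I(C=1) + γ₂ I(C=2) + ln(2) I(M=1,F=1,C=1)

with six mating-type parameters μ indexed by the unordered parental pair.
exp(γ_j) = R_j is the offspring relative risk; the mating-type stratification
makes the γ inference depend only on transmissions, conferring robustness to
population stratification. Adding ρ₁ I(M=1) + ρ₂ I(M=2) captures
maternally-mediated genetic effects (exp(ρ_j) = S_j).

**Parent-phenotype model** — a log-binomial model for disease in the mother
of a case:

    ln Pr(D_M = 1 | M, F, D_C) = α_(M,F) + β₁ I(M=1) + β₂ I(M=2)

with exp(β_j) = R_mj the maternal relative risk. The mating-type intercepts
α are a proxy adjustment for subpopulation membership; only parents whose
genotypes differ within a mating type inform β. A two-sex extension adds
father-specific intercept offsets and paternal coefficients θ, and can test
mother/father equality of relative risks.

**Combining generations.** The joint likelihood factors as
Pr(M,F,C|D_C)·Pr(D_M|M,F,D_C). Constraining R = R_m and testing the shared
log-additive coefficient gives the parent-phenotype informed likelihood ratio
test (**PPI-LRT**), fitted by EM when parental genotypes are missing.
Alternatively, with complete data the two independent 1-df tests are combined
into the composite statistic

    Z_C = (S_t √X_t / σ_t + S_p √X_p / σ_p) / √(1/σ_t² + 1/σ_p²)

(**PPI-CT**), where X, S and σ are each component's LRT statistic, coefficient
sign and Wald SE; Z_C is standard normal under the null. The package also
implements the reference tests TDT, parenTDT (parental discordance) and
combTDT for comparison, a fully specified scenario simulator (HWE
subpopulation admixture, maternal effects, missingness), and a
noncentrality-parameter power engine based on expected-count pseudo-data.

## Worked example

Simulate one study of 300 triads from a homogeneous population (allele
frequency 0.3, maternal baseline risk 0.2, R₁ = R_m1 = 1.4) and analyze it:

```sh
$ triadppi simulate --scenario scenario.toml --reps 1 --seed 11 --out demo
$ triadppi test --in demo/rep00001.tsv --tests transmission,parent,ppi-ct,ppi-lrt,tdt,combtdt
test          statistic  df  pvalue        RR       ci_low    ci_high
transmission  26.647     1   2.442261e-07  1.92222  1.48996   2.47989
parent        12.9165    1   3.257038e-04  2.09808  1.34025   3.28443
ppi_ct        39.2343    1   3.758695e-10  NA       NA        NA
ppi_lrt       39.451     1   3.363882e-10  1.96485  1.57628   2.44921
tdt           26.1939    1   3.087938e-07  NA       NA        NA
combtdt       33.0471    1   8.995502e-09  NA       NA        NA
```

The transmission model estimates an offspring relative risk of 1.92 per
allele, and — independently — the parents' own phenotypes give a maternal
relative risk of 2.10: the two generations replicate each other. The joint
PPI-LRT pools them into a shared estimate of 1.96 with a smaller p-value than
either component or the TDT-based combination.

The same scenario's asymptotic power at α = 0.05, via NCPs on expected
counts:

```sh
$ triadppi power --scenario scenario.toml --tests parent,parentdt,ppi_ct,combtdt
test      n    ncp      df  alpha  power
parent    300  2.79254  1   0.05   0.38648
parentdt  300  1.99009  1   0.05   0.291789
ppi_ct    300  10.3267  1   0.05   0.894999
combtdt   300  9.48982  1   0.05   0.868769
```

The likelihood-based Parent test beats the parenTDT, and the composite PPI-CT
beats the combTDT, at this and every allele frequency.

The same analyses are available as a library — `TransmissionModel`,
`ParentPhenotypeModel` and `JointTriadModel` objects with `fit()` returning
results objects carrying estimates, standard errors and `summary()` tables;
see the docstrings and `docs/methods.md`.

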