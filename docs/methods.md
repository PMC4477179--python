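# Methods

This note documents the statistical models implemented in `triadppi`, the
numerical choices behind the fitters, what the scenario simulator does and
does not emulate, and the design decisions taken where more than one
reasonable reading existed.

## Data and cell space

A triad is an affected child plus both biological parents, genotyped at one
autosomal biallelic locus; genotypes are counts of a designated variant
allele. Ascertainment is always "child affected", so the child's phenotype is
implicit. Exactly 15 ordered (M, F, C) combinations are Mendelian-consistent;
crossed with the mother's phenotype they give a 30-cell table (60 with the
father's phenotype). All likelihoods in the package are functions of these
cell counts, which may be fractional: expected counts under a scenario and
E-step completions enter the same code path as observed data.

Mating types are the six unordered parental genotype pairs
{0,0}, {0,1}, {0,2}, {1,1}, {1,2}, {2,2}. Mating symmetry — equal population
frequency of (M=m, F=f) and (M=f, F=m) — is assumed throughout, as it is in
the models' derivation.

## Transmission model

The log-linear model for Pr(M,F,C | child affected) has six free mating-type
terms μ, the child risk terms (γ, with codominant, log-additive, dominant or
recessive coding), optional maternally-mediated terms ρ on the mother's
genotype, and a fixed ln(2) offset on the (1,1,1) cell reflecting the two ways
two heterozygotes produce a heterozygote.

Because μ enters as a free intercept per mating type, it is profiled out
exactly: at any value of the risk coefficients the fitted mating-type totals
equal the observed totals, leaving a product of within-mating-type conditional
multinomials. The fitter is a damped Newton iteration on that profile
likelihood (1–4 free parameters), with analytic gradient and Hessian; the
reported log-likelihood adds back the multinomial margin term so that
log-likelihoods are comparable across models fitted to the same table. Wald
standard errors come from the observed information of the profile likelihood,
which coincides with the Schur complement of the full information. The test
suite cross-checks estimates, standard errors and LRT statistics against the
equivalent Poisson log-linear regression (the multinomial–Poisson trick) in
statsmodels, and the log-likelihood itself against generic numerical
maximization of the fully parameterized multinomial.

Mating types with zero total count carry no information and drop out of the
profile likelihood automatically (with a warning). The transmission LRT tests
γ = 0; with `maternal=True` the ρ terms stay in both null and alternative so
the test remains a transmission test adjusted for maternal effects.

## Parent-phenotype model

The log-binomial model for disease in a case's mother has per-mating-type
intercepts α and maternal risk coefficients β; the two-sex extension adds
father rows with their own per-mating-type intercepts (parameterized directly
as mother-intercept-plus-offset, which is equivalent to the α + δ form but
avoids a non-identified divergence when one sex has no affected parents in a
stratum) and either separate paternal coefficients θ or, when pooled, the
shared coefficients. `mating_intercepts=False` fits the single-intercept
ablation.

The log link constrains every fitted probability to (0, 1], i.e. every linear
predictor η ≤ 0. Three structural reductions are applied before optimization:

* strata (sex × mating type) with no affected parent sit at the α → −∞
  boundary, contribute zero log-likelihood for any β, and are removed;
* strata whose rows share identical risk covariates (the genotype-concordant
  mating types, and e.g. the {1,2} type under dominant coding) are saturated
  by their own intercept; their contribution is the closed-form binomial
  maximum and their profile information about β is exactly zero, so they are
  profiled out;
* what remains — at most the three discordant mating types per sex — is
  maximized by damped Newton constrained to η ≤ −10⁻⁹, with step halving and
  a sequential-quadratic (SLSQP) fallback whenever Newton stalls against the
  boundary. The better of the two solutions is kept, so the optimizer never
  returns less likelihood than its starting point.

Starting values are β = 0 with each intercept at the log of its stratum's
affected fraction, which is always feasible. Standard errors use observed
information; statsmodels' log-binomial GLM (expected information) agrees to a
fraction of a percent on typical tables and is used as the independent oracle
in the tests. The null fit (β = 0) is closed-form — each intercept stratum is
saturated — which makes the LRT cheap. Degenerate tables (no affected
mothers, or no genotype-discordant informative strata) yield an NA test
result with an explanatory message rather than an error.

## Joint model, PPI-LRT and EM

The joint likelihood is the product of the two factors above. With complete
data and free parameters it separates, and the implementation fits the two
factors independently (the test suite asserts the additivity identity to
1e-8). Under the shared constraint (γ ≡ β per coding) a joint Newton
iteration maximizes the sum of the transmission profile likelihood and the
parent likelihood over (shared coefficient, parent intercepts). The PPI-LRT
compares the shared fit against the null (coefficient 0, both factors
closed-form); the generation-equality test compares free against shared, and
the three statistics obey the nested-model deviance additivity identity
exactly.

With missing parental genotypes the model is fitted by EM over weighted
observation groups (m-or-missing, f-or-missing, c, d):

* **E-step** — each incomplete group is distributed over its
  Mendelian-compatible completions proportionally to the current fitted cell
  probabilities times the parent-phenotype likelihood of the observed D_M.
  Completions enumerate at most 3 genotypes for one missing parent, 9 for
  two; both-parents-missing families are supported even though the reference
  simulations only remove fathers.
* **M-step** — the complete-data fitters run on the fractional table,
  warm-started at the previous parameters. Because the Newton line search
  only ever accepts non-decreasing steps, the M-step cannot lose likelihood,
  making the procedure a generalized EM with a guaranteed nondecreasing
  observed-data log-likelihood; the fitter raises an internal error if the
  trace ever decreases beyond numerical slack (1e-6 relative), and the test
  suite exercises this on a thousand random incomplete datasets.
* Convergence: relative change in observed log-likelihood below 1e-8, cap
  500 iterations. Complete data short-circuits to a single direct fit.

The mating-type probabilities are profiled in the same way as μ (they equal
the fractional mating-type totals), so the E-step cell probabilities are the
profiled totals times the fitted within-type conditionals.

`em_fit(model="transmission")` drops the parent factor (EM over genotypes
only); `model="parent"` is fitted as the free joint model — a genotype model
is unavoidable when genotypes are missing — and the parent coefficients are
read from the result.

With missing data the reported Wald standard errors of the shared coefficient
come from the final M-step's complete-data information and therefore slightly
understate the true uncertainty; the PPI-LRT p-value itself uses the
observed-data likelihood ratio and is unaffected. A Louis-type correction was
judged out of proportion for the intended use.

## Composite test (PPI-CT)

For complete data the transmission and parent tests are independent, and the
composite statistic combines their signed roots:

Z_C = (S_t √X_t / σ_t + S_p √X_p / σ_p) / √(1/σ_t² + 1/σ_p²),

with S the coefficient signs (zero mapped to +1), X the 1-df LRT statistics
and σ the Wald SEs of the log-additive coefficients. Any fixed weights give
unit null variance after this normalization; the 1/σ weights are used because
under a shared-relative-risk alternative each component's drift is
proportional to 1/σ, making this the asymptotically optimal combination — on
expected-count pseudo-data the composite noncentrality then equals the
PPI-LRT noncentrality at every allele frequency, matching the observed
near-equivalence of the two tests. Inverse-variance (1/σ²) weights were
considered and rejected: they underweight the parent component and break that
equivalence. With incomplete triads the two components are no longer
independent and the composite is refused in favor of the PPI-LRT.

## Reference tests

TDT: b and c count transmissions and non-transmissions of the variant from
heterozygous parents; the statistic is (b−c)²/(b+c). parenTDT: over families
with exactly one affected parent, the statistic is (Σd)²/(Σd²) with
d = (allele count of affected parent) − (allele count of unaffected parent);
families with both parents affected, or genotype-concordant parents, are
uninformative. The observed-second-moment variance is a McNemar-style
robust form; the exact normalization of the PLINK implementation is not
published alongside the verbal description, so small discrepancies from PLINK
are possible — the simulation reference values are reproduced within
Monte-Carlo error, which is the criterion that matters here. combTDT sums
the counts: (b−c+Σd)²/(b+c+Σd²). In one-sex designs the father is treated as
unaffected. All three discard families with missing genotypes. Every
family's contribution is a deterministic function of its cell, so the
statistics are computed from cell tables; record-level wrappers tabulate
first.

## Scenario simulator

A scenario is a mixture of Hardy–Weinberg subpopulations, each with a weight,
allele frequency, maternal baseline risk (MBR — the disease risk in
non-carrier mothers of cases), an optional father baseline risk, and a
relative child baseline risk used when subpopulations differ. Per
subpopulation, parental genotypes are HWE, the child is Mendelian, and the
affected-child ascertainment weights each cell by child_risk × R_C × S_M.
Subpopulations contribute triads in proportion to weight × probability of
producing an affected child — the natural reading of admixture under
child-based ascertainment (the alternative, fixed 50/50 allocation, would
make the baseline-risk ratio inert, contradicting the reference ablation
results). The mother of an affected child is herself affected with
probability MBR × Rm_M × g(M), independently across families; fathers
analogously in two-sex designs.

The factor g(M) deserves emphasis. A maternally-mediated effect S acts on
every child through its mother's genotype — including on the study parents,
through the grandmothers. Conditional on a parent's genotype G the
grandmaternal genotype is not independent of G, so S induces an *apparent*
association between the parent's genotype and phenotype even when the variant
has no inherited effect: g(G) = E[S^Ggm | G] / E[S^Ggm | G=0], computed
exactly under HWE. At allele frequency 0.3 and S₁ = 1.4 this gives apparent
risks 1 : 1.2 : 1.4 — note the *linear*, not log-linear, progression, which
is why the fitted log-additive maternal RR drifts from ~1.25 at n=300 toward
~1.20 asymptotically, and why the parental tests (but not the transmission
tests) lose validity under maternal effects. Parameterizing the apparent
risks directly as (1.2, 1.44) instead was tried and produces uniformly
stronger inflation than the reference values; the mechanistic factor is the
correct generative story. The `rm` parameters remain the *direct* effect of
a parent's own genotype on their phenotype and multiply g.

Studies are simulated as one multinomial draw over the cell table;
missingness masks each parent independently at the given rate and never
touches phenotypes. A master seed drives every random quantity; replicate
seeds are spawned deterministically.

What the generator does **not** emulate: linkage disequilibrium with other
causal loci, genotyping error, informative missingness, correlated parental
phenotypes (shared environment), effects of disease on reproduction, and
real ascertainment quirks. Passing reproduction tests therefore shows that
the estimators and tests behave as designed under the stated sampling model,
not that they are immune to these real-data complications.

## Power engine

NCPs are computed by the expected-counts device: the scenario's expected cell
table is treated as data; for LRTs the NCP is the deviance change between
null and alternative fits on this pseudo-data, and for the TDT family it is
the statistic evaluated on the expected counts. Power is the upper tail of
the noncentral chi-square beyond the central critical value. NCPs are exactly
linear in the study size, so `scale_ncp` rescales to any n. With missingness,
the discarding tests scale by the completeness fraction, while the PPI-LRT
NCP is computed by deterministic EM on the expected incomplete groups — at
100% missing fathers it remains positive while combTDT's is zero.

`type_i_error_study` is the Monte-Carlo companion: per-test rejection rates
with binomial Monte-Carlo standard errors, and mean relative-risk estimates
with a normal 95% interval for the mean across replicates. Replicates with
degenerate fits are excluded per test; if they exceed 1% the study is flagged.

## Problem sizes and tolerances in the test suite

Reproduction tests use the original study conditions: 5000 replicates of 300,
600 or 1200 triads per scenario (seconds per study, as each replicate is a
30-cell table). Monte-Carlo comparisons use two binomial standard errors
where a specific reference value is asserted; the asymptotic-vs-simulated
power comparison runs 1000 replicates at each of nine allele frequencies and
allows the expected number of two-standard-error excursions. Optimizer
tolerances: Newton gradient 1e-8 (soft stall threshold 1e-4 triggers the
constrained fallback), EM 1e-8 relative, oracle agreement 1e-6.

## Known limitations

* X-linked variants, parent-of-origin/imprinting effects and multi-locus
  analyses are out of scope.
* Correlated parental phenotypes would require dependent-data methods (GEE);
  independence conditional on mating type is assumed.
* The parent-model relative risks conflate inherited and grandmaternally
  mediated effects when both are present; without grandmaternal genotypes
  they are not separable, and the estimates should be read accordingly.
* EM standard errors are complete-data-information approximations (see
  above).
* The log-binomial boundary (fitted probability → 1) is handled by
  constrained optimization; in pathological small-sample tables the reported
  optimum can sit on the boundary, and the convergence flag should be
  checked.
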