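# Methods

## Model and tests

Genotypes enter as minor-allele half-counts `Y ∈ {0, ½, 1}`.  For a variant
with population frequency `p`, gene dropping through a pedigree gives
exactly `E[Y] = p·1` and `Cov(Y) = p(1 − p)Φ`, where `Φ` is the kinship
matrix with diagonal `(1 + h_i)/2`.  Both association tests are score
tests built on this first- and second-moment structure only (no full
likelihood):

* the quasi-likelihood allele-frequency estimate is the generalized
  least-squares mean `p̂ = (1ᵀΦ⁻¹Y)/(1ᵀΦ⁻¹1)`.  In a pedigree where both
  parents of an individual are sampled, that individual receives weight
  zero: founders carry all the information about `p`, which is also why
  founders-only frequencies are the package's stand-in when no external
  population MAF is supplied.
* **MQLS** contrasts genotypes against `V = Z − k·1`: cases get weight
  `1 − k`, controls `−k`, so with prevalence `k < ½` a case carries more
  evidence than a control.  `k` is a *user input*; the package deliberately
  provides no default, because mis-specifying it changes the weighting
  (with `k` equal to the sample case fraction and unrelated individuals the
  statistic is exactly the allelic chi-square).  Simulations here use
  `k = 0.3`, the case fraction of the study design the simulator emulates.
* **WQLS** is the score test of `E[Y] = p·1 + r·Z` at `r = 0` with
  covariance `σ²Φ`; its weights `Φ⁻¹Z` are the GLS regression weights.

The variance of either score uses the plug-in `p̂(1 − p̂)` and subtracts the
component absorbed by estimating `p̂`.  Statistics are referred to the
upper tail of χ²₁ without continuity correction; there is no small-sample
permutation fallback (an advisory is logged below 30 analyzed
individuals).

Assumptions: autosomal variants, founders mutually unrelated and
non-inbred, phenotype treated as fixed (the tests condition on `Z`), no
covariates or ascertainment correction.  Sex is parsed but unused.

### Untestable units and degenerate inputs

A marker monomorphic in the analyzed subset, a subset with a single
phenotype class, or a variance below `10⁻¹² · p̂(1 − p̂)` yields a flagged
result with no p-value rather than being dropped; power estimation counts
such replicates as non-hits and reports the count separately.  The
single-class rule is an explicit check: with `p̂` estimated from the same
individuals, an all-case family can produce a nonzero score with no
case-control contrast behind it, which would be meaningless rather than
conservative.  Missing phenotypes (per replicate) and missing genotypes
(per marker) are dropped listwise with their kinship rows, with a logged
warning; the original method's enhanced weighting of genotyped relatives
of unphenotyped affected individuals is **not** implemented — a documented
limitation, not an approximation of it.

### Numerical choices

All kinship algebra is block-diagonal per family and goes through Cholesky
factorizations (`O(Σ n_f³)`, no explicit inverses); a non-positive-definite
family block raises an error naming the family.  `p̂` is clipped to [0, 1]
against floating drift.  Kinship coefficients come from the standard
parents-first recursion over an internally computed topological order, so
file row order never matters, and ties in minor-allele determination from
.ped files go to the lexicographically later allele symbol.

## Collapsing

A gene's qualifying rare variants (population MAF strictly < 0.01 by
default, optionally nonsynonymous-only) collapse to the carrier indicator
`G = 1{any member dosage > 0}`, coded 0/½ so it runs through the same
tests.  Rare homozygotes count as carriers, nothing more: at these
frequencies the two-allele genotype is negligible and presence is the
signal.  An individual missing a member genotype is missing in `G` unless
an observed member genotype already makes them a carrier.  Weighted
collapsing schemes (frequency- or function-weighted scores) are
deliberately out of scope: the package implements the plain
presence/absence indicator.

Note the indicator is *not* a true locus: its covariance among relatives
is only approximately `p(1 − p)Φ` (exact in the single-member limit, and
to first order when members are rare and on distinct haplotypes).  The
calibration study below quantifies the consequence: the collapsed-gene
WQLS size sits at ≈ 0.060 at α = 0.05, at the edge of nominal.

## The simulator

The gene-drop simulator is the package's fixture factory and defines the
study conditions the tests are evaluated under:

* **Pedigrees** — three-generation families: a founder couple, their `c`
  children each married to a founder spouse, each couple again with
  children.  The canned scenario uses 8 families with variable sibship
  sizes (2–10 children per couple, ~300 individuals total, families of
  ~25–50); the calibration study uses the regular template with `c = 8`
  (656 individuals), close to the ~700-subject 8-family design it
  emulates.
* **Genotypes** — founder haplotypes are independent Bernoulli(MAF) draws;
  each non-founder receives one allele from each parent uniformly at
  random per marker.  No within-gene LD and no recombination model: rare
  variants sit on distinct haplotypes and the collapsing indicator uses no
  LD.  A marker may instead specify an exact number of founder copies,
  optionally confined to one family — the conditional-gene-drop device
  used to construct variants private to a family.
* **Phenotypes** — additive liability `L = (2·dosage)·β + ε`,
  `ε ~ N(0, 1)` i.i.d., redrawn per replicate; the `round(k·n)` largest
  liabilities are cases, so every replicate has the exact target case
  fraction (an empirical-quantile threshold rather than a fixed
  theoretical one: it stabilizes power estimates at these sample sizes).
  Genotypes are held fixed across a scenario's phenotype replicates,
  matching replicate-phenotype study designs.
* **Seeding** — one integer seed drives everything through explicit
  `SeedSequence` spawn keys (`(0,)` gene drop, `(1, r)` phenotype
  replicate `r`, `(9,)` scenario construction), so any replicate can be
  regenerated in isolation and identical seeds give bit-identical data.

The canned 8-family scenario (`gaw17_like_scenario`) contains: `GENE01`
with three causal rare variants (β = 0.8, two founder copies each) private
to families F01–F03; `GENE02` with one strong causal variant (β = 1.5,
three founder copies, private to F05) plus twenty neutral rare members
(MAF 0.004); one private causal background variant (β = 1.0) in each
remaining family; and 38 neutral background genes of 1–3 rare SNPs with
MAF log-uniform on [0.001, 0.008].  Every family hosts exactly one private
causal source.  That heterogeneity is load-bearing: it makes case status
cluster within every family, which inflates the combined analysis's
kinship variance term and reproduces the dilution phenomenon — a private
causal variant is usually at least as significant within its carrier
family as in all families combined.  Effect sizes were chosen to keep the
collapsed-versus-single comparisons in the informative power range
(roughly 0.1–0.9) rather than at the floor or ceiling, where the
comparison degenerates.

**What the simulator does not emulate:** covariates and ascertainment,
polygenic background within families beyond the private causal variants,
genotyping error and missingness, LD, population structure, and the actual
(non-public) generating model of the workshop data set the scenario is
styled after.  Passing tests therefore show that the statistics behave as
designed under clean Mendelian transmission with liability phenotypes —
not that they are robust to the full messiness of real family studies.

## Calibration and power studies

The null calibration study draws **fresh genotypes for every replicate**
(unlike the fixed-genotype scenario): with genotypes fixed, the statistic
conditioned on one genotype configuration is purely discrete and a
distributional check against χ²₁ is uninformative.  Conditions, fixed in
advance: 8 regular three-generation families (n = 656), `k = 0.3`, twelve
single null SNPs at MAF 0.0095 (the informative top of the rare band),
one collapsed gene of fifteen null SNPs at MAF 0.004, 5,000 replicates
for the type-I error and 2,000 for the distributional check, single-SNP
results pooled over the twelve markers among testable draws.

Measured behaviour (recomputed by `scripts/acceptance.py`): empirical
sizes at α = 0.05 for MQLS/WQLS on rare SNPs and the collapsed gene all
fall in [0.04, 0.06]; the collapsed-gene statistic is consistent with χ²₁
by KS at the 0.01 level for both tests.  The **single-rare-SNP statistic
is not χ²₁-distributed** in any sample of this size: with one or two
founder copies per draw the statistic lives on a lattice (KS distance
≈ 0.05, concentrated in the distribution's center; mean ≈ 1.00, variance
≈ 2.3, and a *correct* 0.05 tail).  This is not an implementation defect
but the sparse-data failure mode of asymptotic tests on rare variants —
the very phenomenon gene-level collapsing exists to fix — and the
corresponding distributional check is expected to fail at desk scale.

Power is the fraction of replicates with `p < threshold` (strict),
thresholds 0.05 (loose) or Bonferroni `α/n` (the gene-count denominator by
default).  Problem sizes used by the shipped studies: 200 phenotype
replicates for power tables, 100 for the single-family comparison, 500
per grid point for the effect-size monotonicity check — sizes at which
every study in the test suite completes in seconds to tens of seconds on
one CPU.

## Known limitations

* No correction for phenotype-based ascertainment of families.
* Unphenotyped-relative weighting of the original modified test is absent
  (see above); results for pedigrees with many unphenotyped members will
  be conservative relative to it.
* The collapsed indicator's covariance model is first-order; for genes
  with common collapsed carrier frequency (≳ 0.1) WQLS sizes drift
  slightly above nominal.
* Single rare variants with < ~10 carriers have honest but lattice-valued
  p-values; treat per-variant p-values near a stringent threshold with
  caution and prefer the collapsed test.
* X-linked inheritance, quantitative traits, covariates, VCF input, and
  multiallelic sites are out of scope.
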