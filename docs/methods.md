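# Methods

`sievekit` studies a question posed by long-lived broadcast spawners such
as Pacific ocean perch (*Sebastes alutus*): when a multi-decade adult
population releases a larval cohort every year, and each cohort passes
through the year-specific mortality regime of its first months at sea,
does the surviving cohort carry a selection signature unique to its birth
year — a *selective sieve* — and can that signature be detected from SNP
genotypes of surveyed young-of-the-year fish? The package couples a
forward simulator of this process with the inference chain used to detect
it: quality control, year-private-allele analysis, permutation-tested
pairwise FST, a latent-factor genotype–environment scan, and a
length–weight condition-index contrast.

## The generative model

**Divergence.** K spawning populations (default 4) derive from a common
ancestor. Ancestral alternate-allele frequencies are uniform on
[0.1, 0.9], mimicking a panel already filtered at global minor-allele
frequency 0.1. Each population's frequency at each locus is a
Balding–Nichols draw, `p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`. Under
independent drift the expected pairwise Nei FST between two such
populations is `F/(2-F)`; the drift parameter is solved numerically from
the configured `target_fst` (default 0.02, the middle of the 0.008–0.031
range typical of rockfish spawning populations). Simulation checks show
the realized mean pairwise estimate lands within 20% of the target for
L ≥ 2000 loci.

**Cohorts and age structure.** Each survey year every population releases
a larval cohort by Hardy–Weinberg sampling from its frequency vector. The
adult pool spans reproductive ages ~8–100, so the allele pool feeding a
cohort is effectively the stable population vector; that implicit
representation is the default. An explicit age-structured mode is
provided for portfolio-effect experiments: each parental age class
contributes a frequency vector shaped by the (configured or
reproducibly randomized) sieve of its own birth year, and the larval
source is their average.

**The sieve.** A year's sieve is a map locus → (disfavored allele,
selection coefficient s). Larval viability is multiplicative,
`w = prod_l (1-s_l)^(copies of the disfavored allele)`. Two survival
modes exist:

- `relative` (default): soft, density-regulated selection. A fixed
  number `round(tau * N)` of survivors (`sieve_survivor_fraction`,
  default tau = 0.5) is drawn by viability-weighted sampling without
  replacement; zero-viability larvae never survive. This keeps cohorts
  at desk scale no matter how many loci are selected: with the default
  regime (s = 0.5 on 2% of loci) the *absolute* joint survival
  probability is astronomically small (~1e-25 at L = 5000), which is
  realistic for r-selected marine larvae but would leave no individuals
  to survey. Soft selection preserves the relative-viability tilt of the
  survivor genotype distribution, which is all the downstream inference
  sees.
- `absolute`: independent Bernoulli survival at `w` itself, appropriate
  for experiments with one or a few sieve loci where the literal
  single-locus arithmetic (heterozygote at s = 0.5 survives with
  probability 0.5; s = 1 is absorbing) should hold exactly.

The default regime puts no sieve on the first year (an average year) and
s = 0.5 on 2% of loci in the second (an anomalously warm year), acting
against the alternate allele.

**Survey assembly.** Survivors of all populations mix during pelagic
dispersal. Stations (default 10) sit on a south-to-north transect;
latitude and sampling date increase together, reproducing the
latitude/date collinearity of a survey that works northward through the
season. Each station's population composition is a Dirichlet draw
(concentration 1 by default; infinity gives equal mixtures). Two
mechanisms tilt who is caught where:

- *Gradient loci* (default five, log-odds 0.6 per alternate-allele copy
  per SD of latitude) model survival during dispersal along the
  latitude/date axis. The 0.6 log-odds tilt corresponds to roughly a
  0.3 genotype-mean shift per SD at intermediate frequencies — chosen so
  a planted cline is reliably the top association hit in a survey of
  ~300 fish while remaining a modest per-locus effect.
- *Sieve temperature tilt*: in a sieve year, carriers of disfavored
  alleles are additionally under-sampled at warm stations (tilt scales
  with s). This represents spatial heterogeneity of the same mortality
  regime and is what gives the anomalous year its within-year
  temperature associations.

Sampling within a station is weighted sampling without replacement via
the Gumbel-max trick, so the whole survey is an exact weighted draw from
the survivor pool. Default survey sizes are 321 and 77 fish — a normal
year versus a collapse year.

**Environments.** Year-2 is +2 °C warmer with halved chlorophyll; within
a year, temperature and chlorophyll carry a weak latitudinal trend plus
station-level mesoscale noise (SD 0.5 °C, 0.3 mg/m³), so they are
correlated with, but not duplicates of, latitude.

**Phenotypes.** Length is lognormal around a seasonal growth curve
(25 mm + 0.6 mm/day, log-scale SD 0.15 — within-date spread dominates,
as in real young-of-the-year samples). Log weight follows the year's
allometric line `log W = a + b log L + eps` with defaults
a = −11.36, b = 3.00 (year 1) and a = −12.38, b = 3.25 (year 2),
residual SD 0.10. The lines cross at 60 mm: smaller fish are lighter in
the anomalous year, the largest are unaffected. The contrast size was
fixed a priori so that the interaction model detects both terms at
p < 0.05 with ~0.9 power at survey sizes 300/75; it is an assumption, not
an estimate. Lipid content is an affine function of the allometric
residual and temperature plus noise, clamped to [0, 60]%, minus a genetic
load term: the first three sieve loci of a year ("condition-coupled"
loci) each cost 4 percentage points of lipid per disfavored copy,
centered within year. This plants the anomalous-year association between
body condition and genotype without disturbing the length–weight
contrast.

**Missingness and replicates.** Genotypes are masked missing completely
at random (default 5%); a configurable number of individuals (default 4)
is duplicated as technical replicate pairs with shared genotypes and
independent missingness.

**Seeding.** One master seed; every stochastic stage draws from an
independent child stream keyed by stage name (CRC-hashed into the numpy
`SeedSequence` entropy), so any stage can be re-run in isolation and the
whole dataset is byte-reproducible.

## The inference chain

**QC.** Four rules in a fixed, logged order: (1) drop loci genotyped in
fewer than 10% of individuals in every population; (2) drop loci missing
in ≥ 15% of individuals; (3) drop individuals missing > 20% of retained
loci; (4) drop loci with global minor-allele frequency < 0.10, computed
over non-missing calls of the survivors. The order is a package decision
(the two locus rules sandwich the individual rule so individual
missingness is judged on usable loci); filtering is idempotent, and the
log reconciles exactly with the removals. Replicate pairs are scored by
concordance over co-genotyped loci; the better-genotyped member is kept,
ties breaking to the lexicographically smaller id. Residual missingness
is imputed with the per-locus modal genotype (ties to the lower value):
at the few-percent residual rates left after filtering, the matrix
methods downstream are insensitive to the imputation rule, and the mode
is deterministic and dependency-free — a deliberate simplification
relative to model-based imputation.

**Private alleles.** Within each population, an allele (tracked as a
(locus, allele) identity) is private to year A if some non-missing
genotype in year A carries it and none in year B does. Because the
smaller year loses rare alleles by chance, significance uses a
subsampling null: B draws (default 1000) of the smaller sample size,
without replacement, from the pooled two-year sample, counting alleles of
the pooled sample missed by each draw. Add-one permutation p-values are
reported in both directions (more year-A-private than expected; fewer
year-B-private than expected), uncorrected across populations (noted in
the output). Sharing between populations is exact set intersection of
their year-A-private sets.

*Power limitation.* The lost-allele statistic only responds to alleles
whose within-population frequency is below ~0.03 (otherwise a sample of
even 25 fish virtually never misses them). Under the uniform-[0.1, 0.9]
ancestral regime with realistic drift, almost no loci sit in that band,
so moderate per-locus selection (s ≈ 0.5) shifts frequencies without
producing detectable extra losses: the test's power against such a sieve
is near its size. Real RADseq panels carry a much heavier
within-population rare tail (ascertained across structured populations),
which is why empirical surveys report hundreds of year-private alleles;
the simulator deliberately does not reproduce that tail, and synthetic
power results must be read accordingly. Allele *elimination* (s → 1 on
rare variants) is detectable.

**Differentiation.** Pairwise FST uses the Nei (1987)-family estimator
with the Nei & Chesser small-sample corrections. Per locus, with n_i
genotyped individuals, allele frequency p_i and observed heterozygosity
Ho_i in each of k = 2 groups and harmonic mean ñ:

    Hs = ñ/(ñ−1) · (mean_i 2 p_i (1−p_i) − Ho/(2ñ))
    Ht = 2 p̄(1−p̄) + Hs/(ñk) − Ho/(2ñk)
    Dst = Ht − Hs,   FST = Σ Dst / Σ Ht

aggregated as a ratio of averages over loci polymorphic in the pooled
pair (loci with any group under 2 genotyped individuals are excluded).
Negative estimates are reported as computed; the display table floors
them at zero, and both forms are retained. Significance comes from B
label permutations of the pooled pair with the add-one correction; the
permutation statistic is computed by batched matrix products over all
permutations at once. PCA centers and scales loci to unit variance
(matching the convention of the standard genotype-PCA toolchain; scaling
is a recorded choice because centering-only changes the eigenstructure),
drops zero-variance loci, and fixes component signs by making the
dominant loading coordinate positive. The balanced-subsampling contrast
draws R equal-size subsamples per group and records the pairwise FST
distribution alongside PC1/PC2 eigenvalue shares and group centroid
geometry — the diagnostic for "FST is stable, PCA is not" under
unbalanced group sizes.

**Genotype–environment scan.** Population structure is absorbed by K
latent factors (default 4): the leading left singular vectors of the
centered, scaled genotype matrix, scaled by their singular values. This
is the deterministic least-squares counterpart of a latent-factor mixed
model fitted by MCMC; it targets the same adjustment without the
Monte-Carlo machinery, and no fidelity to any specific sampler is
claimed. Each locus is tested by OLS of genotype on the standardized
variable plus factors; the variable's t statistic is mapped through the
Student-t tail onto a z-score. Per variable, the genomic inflation
factor lambda = median(z²)/0.456 rescales z², calibrated p-values come
from the chi-squared(1) tail, and candidates are Benjamini–Hochberg calls
at q = 0.05 (the threshold is a package default; scans are run per year
and per variable separately). Scanning collinear variables separately is
deliberate — latitude and date are collinear by survey design — and a
warning is emitted whenever two scanned variables exceed |r| = 0.8.
Cross-year overlap intersects the per-year unions of candidate sets (and
each variable's sets separately).

**Condition index.** The index is the residual of log weight from the
pooled (both years) OLS of log weight on log length — pooling is a
package decision so that one residual vector serves both the index
consumers and the GEA scan. The year contrast refits with year main
effect and year × log-length interaction; "lower intercept, steeper
slope" in the second year is the anomalous-year pattern. Natural
logarithms throughout (the base only shifts the intercept).

**Pipeline.** `run_all` chains simulate → load → QC → impute → private
alleles → FST/PCA → condition → GEA → report. Stage wall times go to
`run.log` only; every report artifact (TSV tables mirroring the
four result tables and the allometry figure summary, plus a JSON
summary with a config hash that excludes paths) is written in canonical
order with sorted keys, so re-running a configuration reproduces the
report byte for byte.

## Numerical choices and degenerate inputs

- Missing genotypes never count as allele presence; a locus missing in a
  whole year group is excluded from that population's private-allele
  comparison.
- Permutation p-values use the add-one rule, so p ∈ (0, 1] always.
- Mode-imputation ties take the lower genotype; loci entirely missing
  raise an error pointing back to the filters.
- FST pairs with a group under 2 genotyped individuals at every locus,
  empty survivor sets, all-loci-removed filters and over-large surveys
  raise typed errors (`DegenerateDataError`) rather than returning
  silently degenerate results.
- Constant scan variables and over-large latent dimensions are rejected;
  zero-residual-variance loci are flagged and given p = 1.
- The oracle tests lock the FST estimator to an independently coded
  textbook implementation at 1e-12 and the subsampling null to exhaustive
  enumeration at N ≤ 8.

## Problem sizes used by the test suite and acceptance script

The statistical checks run at reduced but honest sizes chosen by the
package: calibration of the private-allele test uses 400 replicates of a
125-fish, 2000-locus population (B = 999); estimator-consistency and
pattern checks use L = 1000–2000 with tens of fish per group and
B = 199–999; the acceptance script runs the full pipeline at L = 2000
with surveys of 321 and 77 fish, B_private = 999 and B_fst = 499, plus
150 calibration replicates and 60 planted-cline surveys. A full default
run (L = 5000, B = 1000) completes in a few minutes on one CPU.

## Known limitations

- Loci are unlinked; there is no linkage disequilibrium, no allele
  surfing, and no sequence-level error model.
- The site-frequency spectrum lacks the rare within-population tail of
  real ascertained panels (see the private-allele power note above).
- Ocean transport is reduced to Dirichlet station mixtures and inclusion
  tilts; there is no spatially explicit circulation.
- The latent-factor scan is a least-squares approximation; heavily
  non-Gaussian genotype residuals at extreme frequencies are handled only
  through the genomic-inflation calibration.
- Ancestry estimation is out of scope: population labels come from
  metadata or simulator truth.
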