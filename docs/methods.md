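# Methods

This note documents the statistical models, the numerical conventions, and
the design choices behind `sweepcline`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. EHH, iHH and iHS

For a core SNP and one allele class (ancestral or derived), the extended
haplotype homozygosity at flanking marker *t* is

EHH(t) = Σ_h C(c_h, 2) / C(n, 2),

where the sum runs over the distinct extended haplotypes observed from the
core through *t*, c_h counts carriers sharing haplotype h, and n is the
number of carriers still evaluable at *t*. EHH(core) = 1 by construction
and, on complete data, the curve is non-increasing outward.

Conventions and edge cases:

- **Missing data.** A carrier is dropped from both numerator and
  denominator at the first marker where its allele is missing and at all
  markers beyond, per side. This keeps each retained pair's identity
  well defined; with heavy missingness the curve can terminate early
  (fewer than two evaluable carriers), which truncates integration there.
- **Carrier minimum.** Fewer than two carriers of the core allele gives a
  flagged result with no curve; iHS additionally requires the core derived
  allele frequency (DAF) to lie in [0.05, 0.95], since the score is
  unstable near fixation.
- **Haplotype identity** is exact string equality of allele codes; there is
  no wildcard matching, so results are deterministic.
- **Integration.** iHH is the trapezoidal area under EHH against distance,
  summed over the two sides. Integration stops at the first marker where
  EHH < 0.05, including the sliver up to the linearly interpolated crossing
  point; a curve that ends at exactly 0.05 is complete. A side still above
  the cutoff at the end of the curve (region edge, or early termination by
  missingness) is truncated there and flagged `edge_truncated`.
  Distances are physical bp by default; supplying a genetic map switches
  the integrand to cM. The analyses here are desk-scale single regions, so
  bp keeps the pipeline self-contained; a map file is the right choice
  whenever one exists for the region.
- **Unphased input.** Orientation happens at I/O: VCF genotypes must be
  phased for heterozygotes (an unphased heterozygote is an error naming
  sample and site); unphased homozygotes are accepted because their two
  haplotypes are unambiguous.

The unstandardized score is ln(iHH_A / iHH_D) (ancestral over derived); it
is undefined (flagged, no score) when either area is zero. Standardization
subtracts the mean and divides by the SD of the unstandardized score within
DAF bins — by default 20 equal-count (quantile) bins fit to the scan
itself, each needing at least 5 members. Because a small candidate region
cannot self-calibrate, an **external bin table** (means/SDs per DAF bin
from a genome-wide or simulated neutral background) can be supplied and
takes precedence; `BinTable.from_results` builds one from pooled neutral
scans. Edge-truncated SNPs are excluded from standardization by default —
their areas are systematically biased low — and the candidate screen keeps
SNPs with |iHS| strictly greater than 2.

## 2. F_ST estimators

Single-SNP, two-population estimates from allele frequencies p₁, p₂ and
allele sample sizes n₁, n₂:

- **Hudson** (default): numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
  p₂(1−p₂)/(n₂−1), denominator p₁(1−p₂) + p₂(1−p₁). Multi-SNP summaries
  use the ratio of summed numerators to summed denominators, which
  converges to the Balding–Nichols parameter F (the numerator has
  expectation 2Fp(1−p), the denominator 2p(1−p)). Negative single-SNP
  estimates are reported as-is; clipping would bias the averages.
- **Nei G_ST**: 1 − H_S/H_T. For two populations its expectation is
  F/(2−F), i.e. it compresses strong differentiation; this is verified by
  simulation in the test suite and is why Hudson is the default.
- **Weir–Cockerham**: the two-population ANOVA estimator applied to allele
  counts.

A site monomorphic for the same allele in both populations carries no
information and is flagged rather than estimated.

## 3. Climate-cline association

The response is the per-population DAF itself (no transform by default;
logit and arcsine–square-root are options). Each of the four climate
covariates — daily sunshine duration (h/day), temperature (°C), UV
radiation, precipitation (mm) — is tested by Pearson correlation with a
two-sided p from t = r√((n−2)/(1−r²)) on n−2 df, Bonferroni-adjusted over
the four climate hypotheses only; longitude, latitude (degrees) and
altitude (m) are adjustment covariates in the joint OLS model, not
hypotheses, and so do not enter the Bonferroni factor. The joint model is
ordinary least squares with intercept on all seven covariates (per-
covariate models are available); a rank-deficient design is flagged with a
condition-number diagnostic. Populations missing from either the DAF map
or the climate table are dropped from the intersection with a logged
count, never imputed.

## 4. Case-control allelic association

Genotypes are risk-allele counts; the 2×2 allele table is a = risk alleles
in cases, b = 2·(non-missing cases) − a, and likewise c, d for controls.
OR = ad/bc with 95% Wald CI exp(ln OR ± 1.959964·SE),
SE = √(1/a+1/b+1/c+1/d); cells receive the Haldane–Anscombe +0.5 only when
some cell is zero (flagged). The test is the Pearson chi-square on the
observed table, 1 df, no continuity correction by default (Yates is a
flag), matching common replication practice. The allelic (per-allele)
model is the deliberate default because a single odds ratio without a
stated genetic model is most naturally read as allelic; genotypic /
dominant / recessive models are out of scope. The risk allele is fixed by
configuration — in the motivating analysis it is the *ancestral* allele —
and never inferred from the data, which would bias the OR away from 1.
Hardy–Weinberg checking is omitted (a possible extension).

## 5. Synthetic-data generators

All generators take an explicit seed (single RNG per call) and are
bit-reproducible.

**Forward Wright–Fisher sweep simulator.** A population of N diploids (2N
haplotypes) over L sites spanning `region_length` bp evolves with:
fitness 1 : 1+s : 1+2s by derived-allele count at the reserved central core
site; single-crossover recombination at r·region_length per meiosis
(crossover point uniform); infinite-sites-style mutation on the grid
(Poisson 2N·μ·region_length new mutations per generation, each placed on a
currently-unmutated non-core site; derived fixations are recoded back to
the ancestral background, as a substitution). Neutral burn-in runs
`generations` generations from a monomorphic start; with s > 0 a single
derived copy is then introduced at the core and the run is restarted from
the burn-in state (bounded rejection, retry count logged) until the sweep
survives to a target frequency drawn uniformly from `sweep_freq_range`
(default [0.4, 0.8], i.e. an ongoing sweep sampled at intermediate
frequency, where iHS is most interpretable). Ancestral/derived orientation
is exact by construction and a truth record (core SNP, realized frequency,
retries) accompanies every sample.

Default parameters (N = 500 diploids, L = 200 sites over 100 kb, r = 2×10⁻⁶
per bp per generation, μ = 6×10⁻⁷ per bp per generation, burn-in 3000 ≈ 6N
generations, samples of 100 haplotypes) were chosen on two explicit
constraints, not fitted to any expected test outcome: (i) the expected
sweep footprint, roughly (s/r)/ln(2Ns) ≈ 4 kb per side at s = 0.05, must
sit well inside the 50 kb half-region so the derived-class EHH curve
resolves before the edge; and (ii) mutation must keep the 500 bp marker
grid dense enough that haplotype identity is observable marker by marker.
These are deliberately compressed, desk-scale populations: they reproduce
the *relative* structure iHS assumes (long swept haplotypes against a
recombining neutral background) but not human genome-scale LD, diversity
or demography. Consequences worth knowing: a sizeable fraction of scored
neutral SNPs (young, low-frequency alleles on long shared haplotypes) are
edge-truncated and excluded from standardization, exactly as short real
regions behave; and single-SNP power of the |iHS| > 2 screen at s = 0.05
(2Ns = 50) is intrinsically moderate (noticeably below 1), with the signal
often carried by linked SNPs bracketing the selected site. Passing tests
therefore demonstrate correctness and calibration of the statistics on
data satisfying their assumptions, not performance on real human panels.

**Balding–Nichols.** Per SNP an ancestral frequency p ~ Uniform(0.1, 0.9)
(bounds configurable; the lower bound keeps sites informative), then per
population p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F) and counts
Binomial(alleles_per_pop, p_i). E[p_i] = p, Var(p_i) = Fp(1−p).

**Climate gradient.** (z₁, z₂) bivariate standard normal with correlation
ρ; covariate = z₁, DAF = 0.5 + 0.15·z₂ clipped to [0.02, 0.98]. Clipping
is a ≈1/1500 event per draw, so the induced correlation bias is < 0.005;
the dominant systematic effect is the usual small-sample attenuation of
the mean sample correlation, E[r] ≈ ρ − ρ(1−ρ²)/(2n) ≈ ρ − 0.004 at
n = 40, ρ = 0.431. The truncated-normal (rather than logit) construction
keeps the Pearson correlation interpretable on the natural frequency
scale.

**Case-control.** With control risk-allele frequency p₀ and target allelic
OR, the case frequency is p₁ = OR·o₀/(1+OR·o₀), o₀ = p₀/(1−p₀); genotypes
are Binomial(2, p) per individual (Hardy–Weinberg within group). There is
no linkage between this locus and the haplotype simulations.

**Pipeline bundle.** `simulate_pipeline_bundle` wires the generators into
one on-disk input set. In the planted configuration, scan group A carries
the sweep, group B is an independent neutral population (which makes the
core — and, liberally, the background — differentiated between groups; the
planted-recovery check is therefore about signal propagation, not
false-positive control, which the null bundle covers), 40 extra
populations give the core a precipitation cline at ρ = 0.431 with 60
haplotypes each (binomial sampling attenuates the realized correlation
somewhat), and genotypes at the core follow OR = 1.23 at 1,016 + 1,016.
The null configuration splits a single neutral sample into the two scan
groups (true differentiation ≈ 0), sets ρ = 0 and OR = 1.

## 6. Pipeline semantics

Stage 1 screens |iHS| > 2 (strict, per scan group). Stage 2 retains
screened SNPs whose pairwise F_ST reaches a configurable threshold
(default 0.15) in at least one group pair; since no canonical significance
test exists for a single-SNP differentiation screen, the report also
carries each candidate's empirical percentile against all SNPs of the same
pair in the input. Stages 3 (climate) and 4 (case-control) annotate the
stage-2 survivors; they do not filter, so the final table is the joined
record of every surviving SNP. SNPs absent from a downstream input are
noted, never fatal. Filter bookkeeping is exact (counts in/out per stage)
and a fixed config reproduces `report.json` byte for byte.

## 7. Validation strategy and problem sizes

- EHH equals an independent pairwise-enumeration oracle exactly on random
  matrices (including missing data); trapezoid, interpolation, ln-ratio
  and standardization arithmetic are checked against hand-computed values.
- Hudson recovers the Balding–Nichols F (2,000 SNPs, 200 allele copies per
  population) within ±0.01; Nei G_ST recovers F/(2−F).
- With genome-background standardization over 30 pooled neutral
  replicates, the neutral |iHS| > 2 fraction is compared to the N(0,1)
  tail 2Φ(−2) ≈ 0.0455 (±0.01); sweep replicates at s = 0.05 must exceed
  the threshold at the core at ≥ 3× the neutral rate (20 replicates).
- The cline generator's mean sample r over 5,000 replicates at n = 40 must
  recover ρ = 0.431 within ±0.02; the case-control generator's median OR
  over 2,000 replicates at the study sizes must recover 1.23 within
  ±0.02, with 95% Wald coverage within 95% ± 1.5% over 5,000 replicates.
- End-to-end: because single-run planted recovery is limited by the
  intrinsic iHS power above, the planted-bundle check runs ten seeded
  bundles and requires recovery in at least two (with complete
  annotations whenever recovered); twenty null bundles must yield an
  empty final table at least nineteen times.

OLS goes through statsmodels, the chi-square through scipy; both are
cross-checked in the tests against from-scratch normal-equations and
Σ(O−E)²/E oracles at 10⁻⁸ / 10⁻¹⁰ tolerances. Replicate counts and
population sizes above are the package's chosen problem sizes: large
enough that Monte-Carlo error sits well inside each tolerance, small
enough to run comfortably on a laptop.

## 8. Known limitations

- No demographic histories (bottlenecks, growth, migration), no coalescent
  machinery, no genetic-map heterogeneity in the simulator.
- XP-EHH, nSL, iHH12, haplotype networks, phasing, imputation, liftover
  and multiallelic sites are out of scope.
- The climate association has no spatial-autocorrelation or population-
  structure correction; it reproduces the plain correlation/OLS analysis,
  not a Bayenv-style model.
- Case-control analysis is allelic only: no covariates, no logistic
  regression, no meta-analysis, no HWE test.
- The ancestral allele is an input (sidecar table or INFO/AA tag), never
  inferred; sites without an assignment are dropped and counted.
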