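# Methods

## Crossover model

Chiasmata on the four-strand bundle are modelled as a stationary renewal
process with Gamma(shape ν, rate 2ν) inter-event distances per Morgan, so
the mean inter-chiasma distance is 1/2 Morgan regardless of ν. Each
chiasma resolves into a sampled gamete independently with probability 1/2
("thinning"), which makes the transmitted crossover process have unit
intensity per Morgan — the definition of genetic map distance. ν is the
unitless interference strength: ν = 1 gives a Poisson process (no
interference); for integer ν, ν − 1 equals the number of non-crossover
intermediates between adjacent crossovers in the counting model.

The gamete inter-crossover density is the mixture
f*(y) = Σ_{k≥1} 2^(−k) Gamma(y; kν, 2ν): a gamete gap spans k chiasma
gaps when k − 1 intervening chiasmata went to the other chromatids.

**Chromosome likelihood.** Each observed chromosome is a window [0, L]
with L the genetic span of the retained markers (the HMM cannot see
beyond them, so the span — not the full chromosome — is the correct
censoring window). With crossovers x₁ < … < xₙ:

- first factor: equilibrium (residual-life) density h(x₁) = S*(x₁)/μ*
  with μ* = 1 Morgan;
- interior factors f*(gaps); terminal factor S*(L − xₙ);
- n = 0: ∫_L^∞ S*(x) dx / μ*, each gamma term integrated in closed form
  via its partial expectation.

At ν = 1 the whole likelihood collapses to exp(−ΣL), which the tests
check to machine precision. Zero-crossover chromosomes are always part of
the likelihood; excluding them would bias ν̂ because they carry
information about long gaps.

**Gamma-escape model.** A proportion p of crossovers comes from a
non-interfering Poisson pathway with intensity p per Morgan; the
interfering pathway is scaled to chiasma rate 2ν(1 − p) so total
intensity stays 1. The likelihood sums over all 2ⁿ assignments of the
observed crossovers to the two pathways (log-sum-exp, enumeration bounded
at 12 crossovers per chromosome — never approached by real maps). At
p = 0 it equals the gamma likelihood exactly.

**Numerics.** All computation is in log space. The mixture series is
truncated adaptively: K is chosen so the dropped gamma terms carry less
than 10⁻¹⁵ of their mass below the largest distance evaluated (K ≈ 8–16
for ν in the mouse range, growing as ~2·y_max for long windows; hard cap
1024), and the survival sums add their analytic geometric tails, keeping
truncation error below ~10⁻¹³ everywhere. Repeated values (chromosome
lengths, subset-shared positions) are deduplicated before the
special-function calls.

## Fitting

The gamma model is maximized by bounded Brent search on log ν over
[0.1, 100] (tolerance 10⁻⁶); a fit at the bracket boundary is flagged
non-interior. The escape model uses Nelder-Mead on (log ν, logit p),
restarted from the best five points of a coarse 4×4 grid; because p = 0
is unreachable on the logit scale, the gamma-only optimum is always
evaluated as a candidate so the nested-model inequality holds exactly.

Uncertainty comes from a nonparametric bootstrap resampling individuals
(all their chromosomes together) with replacement; intervals are
percentile (2.5/97.5 and 25/75). Bootstrap replicates of the escape model
start Nelder-Mead from the full-data MLE (a single start) — the replicate
surface differs little from the full data's, and the 25-fold saving makes
1000 replicates routine. Replicates with no crossovers at all are
recorded as non-converged and excluded with a reported count.

Model comparison uses AIC = 2·df − 2·LL and likelihood-ratio tests for
the nested pairs among {gamma, gamma-escape} × {null = shared parameters,
full = per-genotype parameters}, with df 1/k/2/2k.

## Hierarchical Bayesian model

log(ν_i) = β₀ + β_i + α·[old sire], with β₀ ~ N(μ = 1, σ² = 0.5),
β_i ~ N(0, σ²) for each of k genotypes, and α ~ N(0, σ²) entering only
for the old cohort. No sum-to-zero constraint is placed on the β_i; the
prior alone resolves the intercept redundancy. The prior mean μ = 1
(median ν ≈ 2.7 on the natural scale) is deliberately weak relative to
the mouse range ν ≈ 10–15; with study-scale data the likelihood
dominates.

Sampling is component-wise random-walk Metropolis with N(0, τ² = 0.005)
proposals, 25 000 iterations (5 000 burn-in) in 4 replicate chains by
default; reduced runs are used throughout the tests. Convergence is
monitored with the classic (non-split) Gelman–Rubin factor; R̂ > 1.1
produces a warning, not an error, because the β₀/β_i ridge mixes slowly
even when the identified group-level ν draws have converged. Every ν
summary (posterior mean, 95%/50% HPDI, contrasts) is computed on
exponentiated draws, never by transforming interval endpoints. Contrasts
are ratios of ν: genotype pairs difference the β_i per draw (the age term
cancels), and the young/old contrast is exp(−α).

Because each group's log-likelihood depends on the parameters only
through its scalar ν, the sampler pre-evaluates it on a 601-point log-ν
grid ([e⁻⁵, e⁷]) and interpolates with a cubic spline during sampling
(interpolation error ~10⁻⁷, far below Monte Carlo noise). The splines
are validated after sampling against exact recomputation on 20 random
kept draws (warning above 10⁻⁴), proposals outside the grid fall back to
exact evaluation, and `cache_grid=False` disables the device entirely;
`log_posterior` is always exact.

## Synthetic cohorts

The generator emulates the study design: N2 offspring of reciprocal F1
sires across 6 genotypes × 2 age cohorts, genotyped on a dense (1 cM
mean spacing) or sparse (5 cM) array with 1% genotyping error and 0.2%
missingness. The default autosome set is 19 chromosomes from 90 down to
40 cM, rescaled to total 1 230 cM, so a meiosis transmits 12.3 crossovers
in expectation. The default group table places ν between 9 (WSB×PWK) and
14.5 (PWK×WSB) with escape fractions 0.04–0.07, interference 1.2× weaker
in old sires, and sample sizes following the study's usage (503
offspring); all of it is config-overridable. The stationary first
interval is sampled exactly as U·G with G ~ Gamma(ν + 1, 2ν) — a uniform
fraction of the length-biased gap — avoiding burn-in. Per-offspring RNG
substreams are keyed by (seed, group index, offspring index), so growing
a group never reshuffles earlier individuals.

What the generator does **not** emulate: distal concentration of
crossovers, hotspot structure, map-expansion differences between
genotypes, X-linked transmission, or intensity-level array artifacts.
Consequences observed in testing: conditional on the 40–90 cM windows,
mean inter-crossover distance is ~43 cM, below the 49–59 cM seen in the
real data's distance tables — the pure stationary model with a common
map cannot reach that band, so passing tests validate the machinery and
the model's own predictions, not those real-data values.

## Haplotype inference

Genotypes recoded against the two paternal grandparents feed a two-state
HMM (expected state frequencies 1/2, as in a backcross). Emissions allow
a genotyping error rate ε (default 1%); missing calls are uninformative.
Transitions use the Haldane map function r = (1 − e^(−2d/100))/2 (the
map-function choice is swappable; at ≤5 cM spacing the alternatives are
numerically indistinguishable). Viterbi runs in log space with
deterministic ties: prefer the current state, initial tie prefers
grandparent A. Crossovers are placed at the genetic midpoint of the
flanking marker interval, coordinates shifted so the first retained
marker is 0.

A known, inherent limitation: at 1 cM spacing a crossover in the single
outermost marker interval is marginally *less* likely than one miscall
under ε = 0.01 (log r = −4.615 vs log ε = −4.605), so Viterbi absorbs
it; recovery is assessed on the interior marker span, where error-free
agreement exceeds 99%.

## Marker QC

Filters run separately per paternal-genotype × platform partition, in a
fixed order with disjoint counts: missingness (< 10%, strict), founder
informativeness (fixed for opposite alleles), segregation distortion
(non-reference frequency strictly inside (0.20, 0.80), reference = the
founder listed first in the cross label). Two-platform genotypes are
then harmonized — each sparse marker keeps its nearest dense marker by
physical position (ties toward the proximal) — and trimmed per
chromosome to the span covered by both platforms. No distance cap is
imposed on the nearest-marker match.

## Problem sizes and test design

Test and acceptance runs use reduced but honest sizes chosen so that the
stated tolerances sit at ≥3σ of the relevant sampling error: 1 000
meioses for the 10% MLE-recovery check (ν̂ sampling SD ≈ 3%), 200
meioses per group for the 20% hierarchical-recovery check (group SD
≈ 6%), 100 outer replications × 120 bootstrap replicates for interval
coverage (Monte Carlo SE ≈ 2%, small-sample percentile intervals
undercover slightly, hence the 0.85 lower bound), and 25-individual
groups for the escape-model non-identifiability check — the (ν̂, p̂)
ridge correlation is a modest-sample phenomenon that weakens as data
grow, matching the per-genotype sizes where it was originally observed.
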