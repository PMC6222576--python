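# Methods

## Data model

Genotypes are haploid 0/1 calls per inbred line. Diploid VCF input is
collapsed: 0/0 → 0, 1/1 → 1, heterozygous and `./.` → missing. Treating
residual heterozygotes as missing is deliberately conservative — the lines
are nearly fully homozygous, and statistical phasing of the residue is out
of scope — and it only shrinks per-site sample sizes slightly. Positions are
1-based and bp windows are closed intervals throughout.

Site filtering removes multi-allelic records at read time, then drops sites
whose missing fraction exceeds 0.18 (*strictly*: a site at exactly 18% is
kept; the comparison is done on integer counts so the boundary survives
floating-point representation) and, by default, sites not showing both
alleles among observed calls. Indels are kept or dropped by flag, because
frequency analyses need them (one known resistance allele is a deletion)
while haplotype statistics conventionally exclude them.

Imputation default is `major_allele`: every missing call becomes the
per-site modal observed allele, ties to the reference. It is deterministic,
so the haplotype statistics downstream are reproducible without a seed; a
seeded `frequency` mode (draw alt with the observed alt frequency) exists
for sensitivity checks. Since imputation feeds the exact-match haplotype
statistics, the imputation mode is part of any reported provenance.

## Phenotype models

**Censored lognormal AFT.** Time-to-death assays are inspected at 2.5, 5,
11, 24 and 48 h. Each death is assigned the checkpoint at which it was first
observed and treated as an exact time (not interval-censored), matching the
"hour of death" convention of such assays; survivors at 48 h are
right-censored. Per site the model is

    log T = β₀ + β_W·Wolbachia + β_G·SNP + β_GW·SNP×Wolbachia
            + u_line + u_experiment + ε,   ε ~ N(0, σ²)

with Gaussian random intercepts u. The likelihood sums normal log-densities
for deaths and `log Φ((η − log 48)/σ)` for censored flies. Random effects
are fitted as Gaussian-penalized parameters by a damped Newton iteration on
the joint penalized log-likelihood (analytic gradient and Hessian; the
Hessian is ridged to positive definiteness when indefinite away from the
mode). Variance components maximize the Laplace-approximated marginal
likelihood (penalized optimum minus half the log-determinant of the
u-block curvature). The per-fly data collapse exactly to per-(line,
experiment, vial) cells with death counts per checkpoint, so the fit cost is
independent of the number of flies.

p_snp is a likelihood-ratio test of the SNP and interaction terms jointly
(2 df; 1 df when the interaction is not fitted) against the Wolbachia-only
reduced model; p_interaction tests the interaction alone (1 df). A Wald test
would also be defensible; the LRT is the documented choice. Complete
separation (an allele class with zero deaths) is flagged, as is
non-convergence; flagged rows keep their coordinates but carry NaN p-values
and are excluded from threshold bookkeeping.

**Binomial GLMM.** 48-h alive/dead counts are modelled as
`dead ~ Binomial(n, logit⁻¹(β₀ + β_W·W + β_G·G + u_line))`,
`u_line ~ N(0, σ²_line)`. There is deliberately no experiment term and no
interaction in this model. Because covariates are line-level, vials collapse
to per-line totals. The marginal likelihood is integrated per line by
15-node adaptive Gauss–Hermite quadrature centred at the per-line
conditional mode (found by a step-clamped 1-D Newton; clamping avoids the
classic logistic overshoot oscillation). σ²_line = 0 reduces exactly to
ordinary logistic regression, which is verified against an independent GLM
implementation in the tests. Optimizer convergence is judged from the
measured gradient relative to the log-likelihood scale rather than the
optimizer's own flag, with a numeric Newton polish so limiting-case
identities hold to ~1e-8.

**Scans.** The inclusion filter runs first at every site: the 2×2
Wolbachia-by-allele table fails as `collinear` when exactly two cells are
nonzero and they lie in different rows *and* columns (each allele confined
to one symbiont class), and as `sparse` when fewer than three cells hold at
least five lines ("had five lines" read as *at least* five). Zero rows or
columns that are not of the diagonal form fall through to the sparsity rule.
In genome scans the variance components are estimated once under the no-SNP
null on the full line set and held fixed across sites — the standard
two-step shortcut for mixed-model GWAS — and the reduced-model fit is cached
per missing-data pattern. Standalone per-site fits re-estimate variance
components themselves. Raw p-values are reported against the conventional
fixed thresholds (p < 1e-4 candidates; −log10 p marks at 4, 5, 8); a
Benjamini–Hochberg q-value column is emitted as a clearly-separate extra.

**Nested scan.** The default subset drops every line carrying the resistant
allele at the top variant (the allele associated with longer survival /
lower mortality, inferred from the fitted sign when not supplied); lines
with a missing genotype there are dropped and logged, and the inclusion
filter is re-applied on the subset before re-scanning. An alternative
`full_survival` mode drops lines at 100% survival instead, since the
procedure is sometimes described that way; the allele-based subset is the
default because it is the operational definition used for both insecticide
analyses.

## Sweep statistics

H1 = Σpᵢ² and H12 = (p₁+p₂)² + Σ_{i≥3}pᵢ² over the frequencies of *exact*
haplotype classes in a window. Windows live in segregating-site index space:
length exactly 800 sites by default, centred as [i−400, i+400) (the
asymmetric split is the documented convention for even windows), edge
windows skipped, stride configurable (default 1; the stride is a
convenience, not an inferred convention). Each homozygous line contributes
one haplotype. The split contrast classifies lines as resistant (≥1
resistant allele across a locus set) or susceptible (none; missing calls
exclude the line), down-samples the larger class uniformly without
replacement under a seed, and scans each class independently — within a
subsample the segregating-site list is recomputed, so the same window index
spans more bp in a swept subsample.

## NJ trees

Distances are raw counts of differing sites over a bp window (no
multiple-hit correction, deliberately). Neighbor joining is the Saitou–Nei
algorithm on the Q-criterion with deterministic lowest-index tie-breaking.
Negative branch lengths, possible on non-additive matrices, are clamped to
zero with the deficit moved to the sister branch — standard practice. The
tree is left unrooted and serialized with a trailing trifurcation; no
midpoint rooting. On additive matrices the implementation recovers topology
and branch lengths exactly (verified entry-wise against patristic
distances, and round-tripped through an independent Newick parser).

## Heritability and summaries

Broad-sense heritability uses one-way random-effects ANOVA with
method-of-moments components: V_e = MSW, V_g = (MSB − MSW)/n₀ with the
standard unbalanced-design n₀ = (N − Σnᵢ²/N)/(k−1), clamped at zero, and
h² = V_g/(V_g+V_e). For inbred lines the among-line variance is entirely
genetic, so this is the appropriate broad-sense estimator. Published
variance tables rarely state the phenotype scale, so the scale is an
explicit parameter: death-hour per fly (survivors scored at 48) for
survival data, per-vial proportion alive for 48-h mortality data.
Combination-frequency tables tally presence/absence strings over an ordered
locus set per population; lines with missing set-locus calls are counted
separately under `?` so observed frequencies still sum to 1. Spearman
correlation (mid-rank ties, t-approximation p) comes from scipy.

## The synthetic panel generator

The generator emulates the statistical structure the analysis assumes:
~200 fully homozygous lines; biallelic sites with alternate-allele
frequencies drawn from the U-shaped Beta(0.2, 0.2); 5% missing calls; half
the lines *Wolbachia*-positive; planted resistance loci forced to their
target carrier counts (rounded exactly); lognormal time-to-death binned up
to the next checkpoint with line, experiment and residual variance
components; binomial 48-h mortality with a line random effect; and soft
sweeps in which every carrier haplotype is overwritten by one of n founder
haplotypes plus independent per-site flips. Default survival variances
(σ_line = 0.5, σ_exp = 0.1, σ_noise = 0.3 on the log-hour scale) put
broad-sense heritability around 0.7, inside the 0.6–0.9 band typical of
these assays.

What it does *not* emulate: background linkage disequilibrium (sites are
independent outside sweep windows), relatedness structure among lines,
coalescent genealogies, demography, or genotyping error beyond uniform
missingness. Passing tests therefore demonstrate correctness and
calibration of the estimators under the assumed model — type-I error, power
against planted effects, sweep-contrast behaviour — not robustness to LD or
population structure in real panels.

Sweep-simulation geometry matters for exact-match H12: within the resistant
subsample the swept sites are nearly monomorphic and drop out of the
segregating-site index, so an 800-site window there spans far more bp than
in the full panel. The canonical sweep condition therefore uses a 200-kb
region at 30 sites/kb (the density at which such windows hold 6000–8500
SNPs) with the sweep spanning the region, and a founder-copy flip rate of
5×10⁻⁴ per site, chosen so haplotypes within a sweep cluster differ at a
handful of sites across the window — the "short within-cluster distances"
regime. Randomness is split into named per-(stream, line, experiment)
substreams of one seed, so enlarging a design never perturbs draws already
made.

## Numerical choices and degenerate inputs

* AFT Newton: analytic gradient/Hessian, Cholesky with adaptive ridge,
  backtracking line search; convergence at max|grad| < 1e-8·max(1, |ll|).
  Data with zero within-group variance drive σ̂ → 0 and are flagged rather
  than reported.
* GLMM: quadrature-node count 15; σ = 0 handled as a separate exact branch.
* Imputation tie-break: reference allele, so results are invariant to line
  order.
* Filter boundary: integer-count comparison with 1e-9 slack.
* NJ ties: lowest (row, column) index; all-zero matrices yield a star tree.
* Pipeline artifacts are byte-stable under fixed config and seed; the
  manifest records SHA-256 digests, the config hash and per-stage seeds.

## Problem sizes used in the shipped checks

Null calibration uses 200-line panels with ~550 filtered test sites per
model (rejection fraction at α = 0.05 expected in [0.03, 0.07]); recovery
and nesting use 20 replicate 200-line, 300-site panels with a planted major
(−3 log-odds, frequency 0.40) and secondary (−1.5, 0.30) locus; the sweep
contrast uses 20 replicates of the canonical sweep condition above; and
parameter recovery averages 50 replicates. These sizes give tight
Monte-Carlo bands while keeping the default suite comfortably runnable on
one CPU.

## Known limitations

* No kinship or relatedness correction in the scans, and no covariates
  beyond *Wolbachia*.
* Exact-match haplotype identity makes H12 sensitive to upstream imputation
  and to any mismatch tolerance a practitioner might prefer.
* The AFT model treats checkpoint deaths as exact times; with only five
  distinct observed times the residual distribution is coarsely discretized
  (calibration is nevertheless verified empirically).
* How residual heterozygous calls should be collapsed in indel-inclusive
  frequency analyses is left flagged rather than guessed.
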