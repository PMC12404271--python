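# Methods

This note documents the models implemented in `iciqtl`, the assumptions
they make, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Growth model and the RTC statistic

Tumor volume is modeled as exponential between the first dosing day and the
end of follow-up: `log10 V(t) = log10 V0 + b·t + ε`. The slope `b` is
estimated by ordinary least squares on log10 volume, restricted to
measurements with `day ≥ start_day` (default 7, a typical MC38 dosing
start) and `volume ≥ detection_limit` (default 1 mm³; a recorded volume of
exactly 0 always counts as below the limit). Sub-limit points are excluded
because their logarithm is undefined, not imputed — censoring is handled at
the level of whole-series special cases:

* **Grew once, then regressed.** A series whose post-dosing measurements
  contain exactly one detectable volume followed by at least one sub-limit
  measurement cannot be fit but plainly responded. It receives the 10th
  quantile (linear interpolation between order statistics, `h = (n−1)p+1`)
  of the *fitted* slopes in its own treatment arm. Computing the quantile
  separately per arm matters: treated-arm slopes are systematically lower,
  and pooling would understate the imputed response.
* **Never grew (CR\*).** No usable slope exists and none is invented. These
  mice are excluded from slope-based statistics and captured by the CR\*
  enrichment test below. Whether "never grew" is judged from engraftment or
  from the dosing start is ambiguous in principle; this implementation uses
  the dosing start, consistent with everything else in the stage.

The per-mouse response statistic is `RTC = 10^((b_i − μ_C)·s)` with
`s = rtc_scale_days = 21`; `μ_C` is the mean over the same line's
control-arm fitted-plus-imputed slopes. Two exact consequences, used as
tests: within each line the control-arm mean of `log RTC` is 0 (so the
geometric mean of control RTC is 1), and `log RTC` is linear in `b_i` with
slope `s`.

**Response classes.** From the post-dosing window: CR\* if never
detectable; CR if detectable at some point but below the limit at the final
measurement; partial responder if the final volume is below the first
post-dosing volume but still detectable; non-responder otherwise. The
CR/partial boundary definitions are explicit package choices (configurable
via `detection_limit` and `start_day`); classification is invariant to
rescaling all volumes and the detection limit by a common factor.

**CR\* enrichment and the combined trait.** Per line, the treated-arm CR\*
count is tested against an upper-tail exact binomial with null rate `p0` =
the line's control-arm CR\* fraction; when that fraction is degenerate (0
or 1, including empty control arms) the pooled control fraction across all
lines is substituted with add-one smoothing `(k+1)/(n+2)`, which keeps the
test defined without asserting an arbitrary rate. The large-sample Z
approximation of the same test is standardized across lines and blended
with the standardized mean log RTC as `0.8·Z_rtc − 0.2·Z_CR*`; the CR\*
term is subtracted so that smaller combined values mean stronger response
on the same polarity as log RTC. A component that is constant across lines
contributes a zero Z-vector rather than an error, so panels with no CR\*
variation fall back to the RTC trait.

## Heritability

Raw per-mouse RTC is rank-based inverse-normal transformed
(`Φ⁻¹((r−0.5)/n)`, tie-averaged ranks) before ANOVA; every statistic
downstream is therefore invariant to monotone transforms of the phenotype.
Broad-sense heritability is

    H² = MS_strain / (MS_strain + (n̄ − 1)·MS_resid)

with `n̄` the mean per-strain count. Note this statistic does not subtract
`MS_resid` from the numerator, so its estimand under a balanced design with
intraclass correlation `f` is `1/n̄ + f·(1 − 1/n̄)`: it has a null floor of
`1/n̄` and cannot fall below it. The default analysis uses treated-arm RTC
only (the control contrast is already inside RTC); pooling both arms is
available.

**Permutation test.** Strain labels are shuffled over mice (the label
multiset is fixed) and H² recomputed; `p = #{H²_perm ≥ H²_obs}/n_perm`,
with zero exceedances reported as the bound `< 1/n_perm`. An add-one
convention is available behind a flag. A constant phenotype is rejected as
degenerate rather than assigned p = 1, since H² itself is undefined there.

**Bootstrap interval.** The default scheme is a two-stage cluster
bootstrap: strains are resampled with replacement, then mice within each
drawn strain, with within-strain deviations inflated by `1/√(1 − 1/c)` —
the exact correction for the inner resample's variance shrinkage
(`E[SS*] = (1−1/c)·SS`). This choice is deliberate: a variance-ratio
statistic's sampling variability is dominated by which strains were drawn,
so resampling only within strains produces intervals that are both too
narrow and biased upward; in calibration simulations at 34 strains × 8 mice
with a planted H² of 0.4, within-strain-only percentile intervals covered
the truth ~50% of the time, cluster-only ~91%, and the two-stage scheme
~97% at nominal 95%. The within-strain and unstratified row schemes remain
available via `scheme=`. Degenerate replicates are redrawn with a retry
cap. The percentile interval is reported.

**Synthetic truth.** `simulate_strain_phenotypes(n_strains, n_per_strain,
h2)` plants variance components such that the estimand of the ANOVA
statistic equals the requested `h2` (the requested value is inverted to
`f = (h2 − 1/n̄)/(1 − 1/n̄)`). Defining the planted value on the
estimator's own scale is what makes "recover the planted value" a
well-posed test; a raw variance-fraction parameterization would bake the
`1/n̄` floor into every comparison as apparent bias. Consequently `h2` must
lie in `[1/n_per_strain, 1]`.

## QTL mapping

**CCF1 founder scan.** At each marker the per-line phenotype is regressed
on the eight founder-dosage columns with no separate intercept — the
columns sum to one, so the intercept-only null model is nested and
`LOD = (N/2)·log10(RSS₀/RSS₁)` is nonnegative by construction.
Rank-deficient dosage submatrices (monomorphic or near-monomorphic markers)
are fit through an SVD basis, equivalent to the pseudoinverse solution; a
fully monomorphic marker collapses to the intercept and scores LOD 0. No
kinship/polygenic correction is applied. The Gaussian LOD is invariant to
affine transforms of the phenotype.

**CCF1N1 scans.** Three traits mirror the mapping designs: the raw slope
(Gaussian), the binary CR indicator (logistic), and the ordinal response
class coded 0–3 and treated as numeric (Gaussian; proportional-odds models
are out of scope as the simplest defensible reading). With a single binary
covariate the logistic MLE is the pair of genotype-group response
fractions, so the logistic LOD (`LRT/(2·ln 10)`) is computed in closed form
with the convention `0·log 0 = 0`. This makes the statistic exact, fast
inside permutation loops, and finite under complete separation — the
likelihood of the saturated two-group fit is finite even when a group is
pure; separated markers are recorded on the result rather than capped.
Missing genotypes are dropped marker-wise.

**Permutation thresholds.** The genome-wide threshold is the empirical
`1−α` quantile (linear interpolation) of the maximum LOD over phenotype
permutations — over lines for CCF1, over mice for CCF1N1 — leaving genotype
structure intact. Defaults: 1000 permutations, α = 0.05. Requesting α
below `1/n_perm` is a parameter error. No covariate structure is assumed in
the permutations.

**Epistasis.** For loci with binary ancestry, response is modeled by
logistic regression; the LRT compares additive to additive-plus-interaction
models, with `p` from χ² on the number of added parameters. For three loci
the default adds the single 3-way product to the pairwise model (df = 1);
testing all interactions jointly against the purely additive model (df = 4)
is behind a flag. Every full genotype cell must be occupied (the error
names the missing cell). Fits use iteration-capped Newton (BFGS fallback)
and flag nonconvergence on the result instead of raising, keeping
simulation loops total. Data exactly additive on the logit scale yield an
LRT of 0 to numerical precision.

**Group comparisons.** Response fractions between haplotype-defined groups
are compared with a two-sided rank-sum test: exhaustive enumeration of the
rank-sum permutation distribution when the number of label assignments is
small (exact in the presence of the heavy ties that 0/1 data produce; for
binary data it coincides with a two-sided hypergeometric tail), and the
tie-corrected normal approximation otherwise.

## Microenvironment statistics

**Colocalization.** A spot counts only if every gate gene (default
{Ptprc}) is detected. Two cell types are colocalized in a spot when both
marker sets are present; set presence uses an `any` or `all` policy. The
defaults — CTL = {Thy1, Cd8a} with policy `all` (Gzmb is listed on the
panel but not required), macrophage = {Adgre1, Cd68, Itgam, Cxcl9} and
DC = {Batf3, Zbtb46} with policy `any` — reconcile the two natural readings
of a CTL definition (two essential lineage markers vs three listed ones);
both are configurable and neither is asserted as canonical. Detection is
binary: any count ≥ 1 counts, so fractions are invariant to count
magnitude and spot order.

**Permutation test.** The statistic is the mean per-sample colocalization
fraction in responders minus non-responders. Permutations shuffle the
spot-to-sample assignment globally (sample sizes and each sample's group
preserved); a permutation that leaves a sample without gate-positive spots
is redrawn with a retry cap, so the reported p is conditioned on
evaluability. The default comparison is two-sided on |diff| ("as or more
extreme"); one-sided is behind a flag. Zero exceedances are reported as the
bound `< 1/n_perm`.

**Expression ratio.** Counts are normalized to counts-per-million per
sample; the ratio is `(CPM_Cxcl9 + ε)/(CPM_Spp1 + ε)` with ε = 0.5 on the
CPM scale so zero-count samples stay finite; group comparisons use the
rank-sum test above. The normalization is a package choice — CPM is the
minimal library-size correction and the rank-based comparison is invariant
to any common monotone renormalization.

**MHC heterozygosity.** For a line carrying a founder haplotype across the
MHC interval and an inbred partner strain, the score is the fraction of
interval SNVs whose two alleles differ, over SNVs called on both sides
(missing calls shrink the denominator, never the numerator). The score is
symmetric in the two allele sources and bounded in [0, 1]; SNVs are
unweighted. Interval boundaries come from configuration, not hard-coded
coordinates.

## Synthetic data generator

The generator exists to give every stage inputs with the statistical
structure it assumes, plus a recorded ground truth for recovery tests. It
is deliberately not a population-genetics simulator:

* **CC-like genomes** are founder mosaics from a first-order Markov chain
  along each chromosome: uniform founder at the first marker, then a mosaic
  event between adjacent markers with probability `1 − exp(−λ·d)` (`d` in
  Morgans, `λ = map_expansion = 7`, the approximate realized map expansion
  of an eight-way recombinant inbred panel), redrawing the founder
  uniformly. Marginal founder frequencies are exactly 1/8. No funnel
  pedigree, no linkage disequilibrium between lines, no shared ancestry —
  the statistical target is the dosage structure a scan consumes, not
  pedigree realism.
* **N1 crosses** place crossovers at single-meiosis density via the
  Haldane (no-interference) map function; the genotype records which
  intercross parent transmitted each marker.
* **Growth studies** draw per-line baseline deviations and per-line
  treatment effects (the latter carry planted QTL effects), then emit
  log-normal-noise exponential trajectories (noise SD 0.08 on the log10
  scale, ~20% CV; caliper schedule every 3 days from day 7 to 28; V₀ = 60
  mm³ at dosing start; baseline slope 0.10 log10 mm³/day ≈ 3-day doubling).
  Volumes below the detection limit are written as 0. Treated tumors whose
  slope falls below a threshold become grew-once-then-regressed or
  never-detected series with configured probabilities — the mechanism is a
  trajectory-shape rule, not a biological model of immune clearance.
  Because baseline strain effects appear in both arms, they cancel in RTC;
  heritable *response* must be planted through line-specific treatment
  effects.
* **Expression tables** are negative-binomial counts (variance
  `μ + φμ²`, default dispersion φ = 0.3) with group-specific fold changes
  on designated marker genes; other genes are exchangeable noise. No
  gene–gene correlation, no library-size gradients.
* **Spot tables** draw gate positivity per spot and, conditional on it, the
  joint presence of two cell types from a group-specific 2×2 table;
  present types switch on all their marker genes, satisfying either
  presence policy. No spatial autocorrelation between spots.

All generators are deterministic under a fixed seed and write their planted
parameters alongside the data (`truth.json`). What passing recovery tests
shows is therefore that the estimators recover the parameters of *these*
models at study-scale sample sizes — not that real caliper data are
exponential, real CC genomes are Markovian, or real spots are independent.

### Study-scale choices for recovery checks

Recovery and calibration checks run at the scale of the motivating study:
32 CCF1 lines, three ~60 cM chromosomes (the lengths of the QTL-bearing
mouse chromosomes) of 50 markers, 8 mice per arm per line, 250 N1 mice for
epistasis, 1000-permutation thresholds. The planted founder-allelic QTL
strength is anchored to the study scale as well: a genome-scan peak of
LOD 8.9 at N = 32 corresponds to a marker R² of `1 − 10^(−8.9/16)` ≈ 0.72,
i.e. a raw carrier-variance share of ≈ 0.64 after accounting for the
expected 7-df overfit share of the founder model. At this strength the
planted QTL is localized to within ±5 markers and clears the genome-wide
threshold in roughly 3 of 4 to 4 of 5 replicates; weaker QTLs (e.g. a 50%
share) fall below the permutation threshold most of the time because the
8-founder model at N = 32 spends 7 residual degrees of freedom per marker,
inflating both the null maximum LOD (thresholds near 7) and per-marker
noise. This df-driven power cliff is a property of the design, and is the
reason multiparent panels of ~32 lines are followed up with N1-style
crosses in practice.

## Numerical conventions

* Quantiles: linear interpolation between order statistics throughout
  (slope imputation, bootstrap percentiles, permutation thresholds).
* Permutation p-values: plain fraction of exceedances, floored reporting
  as `< 1/n_perm` at zero exceedances; comparisons use a 1e-12 slack so
  ties with the observed statistic count as exceedances.
* `0·log 0 = 0` in all Bernoulli log-likelihoods; perfect Gaussian fits are
  floored at `RSS₁ ≥ RSS₀·1e−15` to keep LOD finite.
* Degenerate inputs (constant phenotypes, zero library sizes, empty
  genotype cells, samples without gate-positive spots) raise typed errors
  naming the offending unit rather than returning sentinel values.
* All randomness flows through `numpy.random.default_rng` seeded from the
  study configuration; stage outputs are byte-identical for identical
  (input, config, seed).

## Known limitations

* No kinship or polygenic background correction in scans; with strong
  population structure the permutation threshold controls only the
  exchangeable-phenotype null.
* The ordinal response trait is scanned as numeric; a proportional-odds
  model might use it more efficiently.
* The X chromosome is treated as autosomal (the motivating design uses
  female mice only).
* The bootstrap CI is a percentile interval; BCa-style acceleration
  corrections are not implemented.
* The generator's independence assumptions (lines, spots, genes) make
  calibration checks cleaner than real data would be; effect sizes
  estimated on real studies should be validated with design-specific
  simulations.
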