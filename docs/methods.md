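# Methods

`rilqtl` implements the statistical pipeline for mapping *constitutive* and
*water-deficit-responsive* QTLs in a biparental maize RIL population
(F271 × Cm484) evaluated in a multi-year, two-irrigation-scenario field
trial, together with a synthetic-trial generator that gives every stage a
known ground truth.

## Models

Throughout, plots are indexed by line *i*, year *j*, irrigation scenario
*k* ∈ {I, NI} and bloc *l*; all random effects are independent zero-mean
Gaussians.

**Bloc correction.**  Raw plot values follow

    Y_ijkl = mu + g_i(1 - t_i) + C_i t_i + y_j + e_k + (ye)_jk
             + B_jkl + (gy)_ij + (ge)_ik + E_ijkl

with year, scenario, their interaction and the check-line means C_i fixed
(t_i = 1 for the replicated parental checks), and the RIL genetic effect g_i,
bloc effect B_jkl, G×year and G×scenario interactions random.  The model is
fitted by REML and every plot is corrected by subtracting the BLUP of its
bloc; the BLUP shrinks raw bloc-mean deviations toward zero, so the
correction removes field heterogeneity without absorbing genetic signal.

**Variance decomposition and heritability.**  On corrected RIL data,

    Y'_ijk = mu + g_i + (gy)_ij + (ge)_ik + y_j + e_k + (ye)_jk + E_ijk

is fitted by REML with g, gy, ge random, yielding σ²g, σ²gy, σ²ge, σ²E.
Broad-sense heritability on a line-mean basis is

    h² = σ²g / (σ²g + σ²ge/k + σ²gy/j + σ²E/(obs/i))

where k and j are the numbers of scenarios and years and obs/i the average
number of observations per line.  Negative component estimates are truncated
at zero (the variance-ratio parameterisation enforces this naturally).

**Least-square means.**  Per-line adjusted means come from fixed-effects
linear models: genotype + year + scenario + year×scenario jointly ("all"), or
genotype + year within one scenario ("I", "NI").  Each ls-mean is the model
prediction averaged over the full reference grid of adjustment factors, so on
balanced data it equals the arithmetic line mean.

**Genome scan.**  Each of the map's markers is tested one at a time on
corrected plot data with

    Y'_ijkp = mu + g_i + y_j + e_k + (ye)_jk + m_p x_ip + (me)_pk x_ip + E_ijkp

where x_ip ∈ {+1 (F271 allele), −1 (Cm484 allele)} and g_i is the residual
polygenic line effect, random.  A significant marker main effect m_p declares
a *constitutive* QTL; a significant marker×scenario term declares a
*responsive* QTL (a locus controlling the trait's response to water deficit).
Lines missing the genotype at a marker are dropped for that marker only; a
marker with a single surviving allele class is flagged untestable (p = 1).

**Declaration.**  Markers with p < 5×10⁻⁵ (a literal reading of a "0.005 %"
threshold; strict inequality) are significant.  Per chromosome, each maximal
run of consecutive significant markers forms one QTL; a single
non-significant marker terminates a run.  The peak is the run's smallest
p-value (ties resolved toward the run midpoint, then the lower position); the
support interval spans the run's first and last markers.  No genome-wide
multiplicity correction is applied beyond the fixed threshold.

**QTL r² and normalized effects.**  On per-line ls-means stacked over both
scenarios, the fixed model `y ~ scenario + marker + marker×scenario` is
fitted by OLS; the QTL r² is the drop in R² when the marker main effect
(constitutive) or the interaction (responsive) is removed.  The normalized
effect is the difference between the two allele-class means of the joint
ls-means (constitutive) or of the per-line NI−I responses (responsive),
divided by the max−min range of the corresponding quantity over the progeny;
positive values mean the F271 allele increases the trait or its response.

**Clustering.**  Same-kind QTLs on a chromosome whose closed support
intervals overlap (touching endpoints included) are chained by single
linkage; chains with at least two members from at least two distinct traits
are reported as clusters, the rest as singletons.  The rule is a
reconstruction — co-localization criteria are rarely printed — and cluster
counts on real data are not treated as a benchmark.

## Significance testing: why Wald t with stratum df

The marker contrast is constant within a line, so its information comes from
the between-line stratum (hundreds of lines), while the marker×scenario
contrast lives in the within-line stratum (over a thousand plots).  A
χ²-referenced likelihood-ratio test between nested ML fits ignores this
distinction; at 261 lines it ran measurably anticonservative in our
calibration study (≈1.3× the nominal rate at the 1% level).  The scan
therefore uses Wald t-tests on the REML fit with containment degrees of
freedom: lines − 2 for the marker term and plots − lines − (within-line fixed
effects) for the interaction.  On balanced data these are exactly the
classical stratum F-tests (line-mean regression; within-line ANOVA), which
the test suite verifies marker-by-marker against an independently coded
oracle.  The interaction column uses a centred scenario code (±½) so the
marker main effect estimates the allele effect *averaged* over scenarios —
the constitutive estimand — rather than the irrigated-scenario simple effect.

## REML engine

All mixed models run through one profiled-likelihood engine for models with
independent grouping random factors.  The residual variance and fixed effects
are profiled out; the criterion is optimised over log variance ratios
γ_f = σ²_f/σ²_E (L-BFGS-B, bounds e^±15, criterion tolerance 1e-8, max 200
iterations, non-convergence raises).  Every evaluation solves the q×q system
A = Z'Z + diag(1/γ): diagonal for the single-factor scan model, sparse LU
with symmetric minimum-degree ordering for crossed designs (the bloc factor
couples all lines; the ordering keeps fill-in ~40× below the naive
factorisation).  The response is internally mean-centred during optimisation
when the constant is in the fixed-effect span, making estimates location
invariant to within optimiser tolerance (~1e-4, the engine's documented
stability contract).  Ratios pinned at the lower bound are reported as exact
zeros (boundary REML).

## Synthetic trial generator

The generator emulates the trial the analysis assumes, with these defaults:

* **Map**: 10 chromosomes × 100 markers, 235.5 cM each (2,355 cM, 1,000
  markers); first/last markers pinned at the ends, interior positions
  uniform.
* **Genotypes**: 261 fully homozygous RILs; along each chromosome a
  first-order Markov mosaic with marker-to-marker switch probability
  R = 2r/(1+2r), Haldane r = (1 − e^(−2d/100))/2, no interference — the
  standard expected recombination for selfing-derived RILs.  Residual
  heterozygosity (~3 % after six selfing generations) is ignored: the scan
  contrasts two allele classes and a third class would be untested.
* **Design**: years 2013/2014/2015 with 15/8/8 blocs per irrigation
  scenario; each RIL once per (year, scenario), dealt across blocs after a
  random shuffle; both parents replicated once in every bloc (augmented
  design).  Realized replication after field losses is not in the public
  record, so obs/i is configurable rather than fixed.
* **Phenotypes**: value = mu + year + scenario + year×scenario + bloc draw +
  polygenic line draw + G×Y draw + G×E draw + planted QTL effects + residual.
  Default variances (σ²g, σ²gy, σ²ge, σ²bloc, σ²E) = (4, 1, 1, 1, 4) in
  squared trait units give h² ≈ 0.73, inside the 0.5–0.9 range typical of
  cell-wall traits in this kind of trial; the default NI shift (−5) mirrors a
  strong scenario main effect.  All values are configurable.
* **QTLs**: a planted QTL adds ±a (allele sign) everywhere and ±d
  additionally under NI, so allele-class contrasts equal exactly 2a
  (constitutive) and 2d (response) in the noise-free limit — the generator's
  own oracle identities.
* **Seeding**: one master seed with named child streams (map, genotypes,
  missingness, phenotypes); identical seeds give bit-identical tables.

What the generator does *not* emulate: spatial field trend within blocs
(blocs are exchangeable Gaussian effects, as the correction model assumes),
genotyping-error and segregation-distortion processes, check-line G×E, and
trait-specific non-Gaussian noise.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to field pathologies outside it.

## Numerical and procedural choices

* Marker filter: keep markers polymorphic between the parents with missing
  fraction ≤ 0.15 (boundary kept at equality).
* ANOVA r² table: sequential (type-I) sums of squares with all terms fixed,
  in the order genetic, scenario, G×scenario, year, G×year, year×scenario —
  the order the trait tables print — so rows sum to 100 %.
* PCA: eigen-decomposition of the correlation matrix of centred, unit-scaled
  trait columns; percent variance = 100·eigenvalue/#traits; the
  largest-magnitude loading of each component is made positive.
* Percent response: 100·|NI − I|/I, validated against published parental
  trait means; a signed variant (without the absolute value) is exposed for
  direction-aware analyses.  Reported percentages round to one decimal.
* Missing trait values are dropped casewise per trait; obs/i is recomputed
  after dropping.  Checks are excluded from ls-means, components and scans.
* Calibration/power studies in the test suite and acceptance script simulate
  trials without bloc effects and feed them directly to the scan: the scan
  consumes bloc-corrected data by construction, and bloc-BLUP recovery is
  verified separately against the generator's truth.  Study sizes — 20 null
  replicate traits for calibration, 50 replicates for power (scanning the
  causal chromosome, since declaration is per-chromosome), 20 replicates at
  250 lines for component recovery — were chosen as the smallest giving
  stable Monte-Carlo means.

## Known limitations

* One interval per significant run: closely linked QTLs inside one run are
  not split at internal p-value minima.
* No interval mapping / MQM, no multi-QTL models, no epistasis.
* The joint (cross-year) bloc-correction model is the only one implemented;
  a per-year variant would need its own estimability handling.
* Wald containment df are exact for balanced strata; under heavy missingness
  they are an approximation (no Satterthwaite adjustment).
* Ls-means for lines absent from a subset are simply not emitted (reported
  in diagnostics) rather than imputed.
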