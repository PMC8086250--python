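# Methods

`rvburden` implements a candidate-gene rare-variant case-control analysis of
the kind used to evaluate moderate-risk cancer susceptibility genes (the
worked examples throughout use epithelial ovarian cancer, EOC, and its
high-grade serous histotype, HGSOC). This note records the models, the
defaults and why, the numerical choices, and what the synthetic cohorts do
and do not establish.

## Genotype acceptance and sample QC

Amplicon/exome candidate calls are accepted if **any** of four clauses holds:
(1) an orthogonal chip genotype exists for the sample, (2) the variant is
seen on more than one amplicon, (3) read depth ≥ 15 with alternate allele
fraction (AAF) ≥ 0.40, (4) depth ≥ 100 with AAF ≥ 0.25. All boundaries are
inclusive. The chip clause is unconditional: a chip genotype stands even
when the read evidence alone would fail clauses 2–4 (the QC report counts
how often that happened). The rule is monotone in depth and AAF, which the
property tests exercise.

Samples are retained only if ≥ 80% of the target footprint is covered at
15×; the comparison is `frac ≥ 0.80`, so a sample at exactly 80% stays.

Duplicate concordance aggregates over duplicate-sequenced pairs: the
numerator is calls made in both members, the denominator the union of calls
in either member, summed over pairs before dividing. This reproduces the
"concordant variants / total variants called" semantics without needing
per-site genotypes.

## Deleterious classification

A variant is deleterious if any of three clauses holds (an order-independent
disjunction — ClinVar-benign never rescues a truncating consequence):

* **truncation**: consequence ∈ {frameshift indel, nonsense, canonical
  splice site, start loss};
* **clinvar**: ClinVar pathogenic or likely pathogenic;
* **splice**: inside the splice-candidate window *and* MaxEntScan-style
  score drop > 40% from a reference score ≥ 3 (strict inequality on the
  drop, inclusive on the reference threshold; a non-positive reference score
  makes the relative drop undefined and the rule declines with a warning).

The candidate window is: exonic SNVs within 3 bp of an exon–intron boundary;
intronic positions within 20 bp on the acceptor side and 6 bp on the donor
side. The acceptor/donor asymmetry matches the footprints of the
maximum-entropy splice models (23-mer acceptor, 9-mer donor). Splice scores
are **inputs**: the package implements the decision rule, not the scoring
model, and any scorer producing reference/alternate scores on a common scale
can be plugged in.

Rare missense variants (MAF < 1%) that are not deleterious form a separate
analysis set. Each is labelled *damaging* when at least two of three
in-silico predictions agree: SIFT < 0.05, PolyPhen-2 ∈ {probably damaging,
damaging}, PROVEAN ≤ −2.5. With fewer than two predictions available the
variant is *indeterminate* and excluded from the damaging set rather than
guessed — a repository decision, since consensus rules rarely state their
missing-data policy.

Missense QC applies, in order: subject call rate ≥ 80% over the missense
set, then per-variant call rate ≥ 80%, MAF < 1% (recomputed from observed
genotypes), and an exact Hardy–Weinberg test at p ≥ 1e-5. HWE is computed on
controls only — deviation in cases can be signal, in controls it flags
genotyping artefacts. The exact test sums conditional probabilities of
heterozygote counts as or less probable than observed (computed by the
standard recurrence; the test suite checks it against an independent
exact-rational enumeration to 1e-12).

## Carrier-collapse burden test

A subject is a carrier of a gene (or gene set) if it has ≥ 1 accepted
deleterious genotype there; each subject counts once per gene regardless of
how many qualifying variants it carries. Histotype subsets restrict the
case column only; controls are shared across subsets.

* **Crude OR**: (a·d)/(b·c) with the Haldane–Anscombe 0.5 added to all four
  cells iff any cell is zero; two zero cells on a diagonal are flagged
  non-estimable. The 95% CI is Wald on the log scale
  (lnOR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **Adjusted OR**: unconditional logistic regression of case status on the
  carrier indicator plus indicator-coded covariates (country stratum,
  sequencing platform), Newton–Raphson to log-likelihood tolerance 1e-10
  within 100 iterations (statsmodels). Constant covariates are dropped;
  complete separation falls back to the crude table with a warning. Without
  covariates the fit equals the crude OR to well below 1e-8 (saturated
  equivalence, tested).

**Two p-values are reported.** The Wald p pairs with the Wald CI and matches
published summary tables of this design. But at the carrier frequencies this
field works with (0.05–0.5%), expected carrier counts of a handful make the
Wald p markedly conservative (measured null rejection ~0.012 at nominal
0.05 with ~4 expected carriers per arm). The Pearson score chi-square
(`p_score`, crude tables) is calibrated there (~0.045 measured) and is the
package's recommended test at sparse counts; the calibration tests use it.

No multiple-testing adjustment is applied: error control is handled
downstream by the Bayes false discovery probability, so tables list nominal
p only.

## Admixture maximum likelihood (AML) test for rare missense sets

For a filtered set of V rare missense variants, the likelihood treats each
variant's k carriers as a binomial split between cases and controls. Under
a common log odds ratio θ, a carrier is a case with probability
n₁·e^θ / (n₁·e^θ + n₀). A proportion α of variants shares θ, the rest are
null:

  L(α, θ) = Π_v [(1−α)·Binom(x_v; k_v, p(0)) + α·Binom(x_v; k_v, p(θ))]

The statistic is 2·(max log L − log L(α=0)), maximised over an (α, θ) grid
(defaults α ∈ [0,1] in 51 steps, θ ∈ [−3,3] in 61 steps; the binomial
coefficients cancel in the ratio). Because α sits on the boundary under the
null, no chi-square reference applies; significance comes from case-control
label permutations **within stratum** (margins preserved), with
p = (1 + #{permuted ≥ observed}) / (n_perm + 1). This is exact-valid by
exchangeability, which the 200-cohort null simulation confirms. An empty
variant set is an error, not p = 1.

## Evidence synthesis

Stratum ORs with 95% CIs are converted to (lnOR, SE) by SE =
(ln hi − ln lo)/3.92 and pooled with fixed-effect inverse-variance weights.
Summation runs in canonical sorted order so results are bit-identical under
input permutation. Fixed-effect (not random-effects) pooling is deliberate:
with 3–4 strata and rare carriers, between-stratum variance is not
estimable, and the pooled values reproduce the published combined estimates
to within rounding of their 2-dp inputs. Heterogeneity statistics are out of
scope.

Wakefield's approximate Bayes factor for the null against a normal prior on
lnOR with variance W is

  ABF = √((V+W)/V) · exp(−z²W / (2(V+W))),  V = SE², z = lnOR/SE,

i.e. the ratio of normal marginal likelihoods N(lnOR; 0, V) / N(lnOR; 0,
V+W); the suite checks it against direct quadrature to 1e-10. W comes from a
plausibility cap on the OR: the prior's 97.5th percentile is set to ln(cap),
so cap = 4 gives W = (ln 4 / 1.96)² ≈ 0.50. The same symmetric prior serves
protective effects. BFDP = ABF·PO/(1 + ABF·PO) with prior odds of the null
PO = (1−π)/π, evaluated by default at π ∈ {0.1, 0.05, 0.01}.

Recomputing BFDPs from 2-dp rounded published inputs reproduces most printed
values within 0.02; one known exception is a strongly associated gene whose
printed 0.14 (π = 0.1) recomputes as ≈ 0.157 — rounding of the inputs, not a
formula difference.

## Cumulative risk

With age-band incidence rates λ (events per person-year, piecewise-constant,
rectangle integration) and the rare-carrier approximation λ_carrier = OR·λ
(sound when carriers are ≤ 0.5% of the population, so the OR ≈ hazard
ratio and the population rate ≈ non-carrier rate), the cumulative risk to
age T is 1 − exp(−OR·Σ λ·width). CI bounds for the risk apply the same map
to the OR's CI bounds.

The packaged `data/incidence_synthetic_flat.csv` is a **synthetic**
flat-hazard table: sixteen 5-year bands to age 80 with total cumulative
hazard 0.0108, back-solved so that an OR of 3.01 yields a 3.2% risk by age
80 on a ~1.07% baseline — a desk-testable stand-in for registry incidence
curves (e.g. national cancer statistics), which users should supply for real
analyses. Because the real incidence curve is age-varying, CI endpoints
computed on the flat table agree with published ones only approximately
(~0.017/0.060 vs 0.018/0.057).

## Power

`burden_power` defaults to **exact enumeration**: the rejection probability
of the two-sided Wald test (with the same Haldane rule as `crude_or`) under
binomial carrier counts in each arm, summing the joint pmf over tables
beyond the critical value (tails truncated at 1e-12 mass). A Monte Carlo
oracle at 20 000 replicates agrees within 2 MC SE across the default 5×5
grid (f₀ ∈ [0.001, 0.01], OR ∈ [1.5, 6]).

The textbook normal approximation (Z centred at lnOR/se_expected from
expected cell counts) is kept as `method="normal"`; it satisfies the
identity power(OR=1) = α but misstates power by several points at α = 1e-4
with expected carrier counts below ~50, which is exactly this design's
regime — hence the exact default.

Defaults are 5951 cases / 6115 controls at α = 1e-4, the analysed study
scale. (One published figure caption pairs 5951 cases with 6385 controls,
inconsistent with the 6115 analysed controls stated elsewhere; the package
defaults to 6115.)

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Carrier model**: dominant single-carrier (genotype 0/1), control
  frequency f per gene, case frequency f·OR/(1 + f·(OR−1)). Homozygous
  deleterious carriers are ignored — at f ≤ 0.5% they are ≤ 1-in-40 000.
* **Strata**: country-like labels with per-stratum frequency multipliers and
  case:control ratios, which is what makes crude-vs-adjusted differences
  testable.
* **Read evidence**: depth ~ negative binomial (default mean 200, size 50 —
  a deep amplicon panel), heterozygote AAF ~ beta-binomial centred at 0.5
  (concentration 50), non-carrier alt reads at a 0.5% error rate, 10% of
  calls on > 1 amplicon, optional chip-genotype flags. Under these defaults
  a heterozygous carrier site passes the acceptance rule > 99% of the time;
  at mean depth 10 most sites fail the depth clauses.
* **Annotations**: each gene gets six deleterious variants cycling through
  the truncation/ClinVar/splice clauses, plus configurable rare missense
  variants (MAF uniform in [0.0005, 0.005] by default) with consistent
  SIFT/PolyPhen-2/PROVEAN triples; a configurable fraction of missense
  variants can carry a common OR for AML power studies.
* **Reproducibility**: one RNG per bundle seeded from the config; per-gene
  sub-streams keyed by a stable hash of the gene name, so editing the gene
  list does not perturb other genes' draws. Identical seeds give
  byte-identical written bundles.

Per-stratum baseline frequencies in real cohorts are unknown; the synthetic
defaults are free parameters chosen in the plausible 0.05–0.5% range, not
estimates of any real population. Passing tests on these cohorts establish
that the statistics are implemented correctly and calibrated under the
stated generative model; they say nothing about alignment artefacts, batch
effects, population stratification beyond country labels, or large
deletions/rearrangements, none of which are simulated.

## Simulation sizes used in the test suite

Type-I calibration uses 200 null cohorts of 2000 cases / 2000 controls at
f = 0.002 (burden) and 200 two-stratum cohorts of 1000/1000 with 20 missense
variants at 999 permutations (AML); CI coverage uses 200 study-scale cohorts
(5951/6115) at f = 0.0017, OR = 3. These sizes put the Monte Carlo noise
well inside the asserted bands while keeping the suite around a minute.

## Known limitations

* Wald intervals throughout; no profile-likelihood or Firth correction, so
  single-stratum tables with zero cells rely on the Haldane correction.
* The AML grid maximisation bounds |θ| at 3 (OR ≈ 20) by default; effects
  beyond that are clipped to the boundary.
* No competing mortality in the risk conversion; cumulative risk to age 80
  slightly overstates lifetime risk.
* The pipeline assumes one platform label per sample and does not model
  cross-platform genotype reconciliation beyond the chip-wins acceptance
  clause.
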