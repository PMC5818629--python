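# Methods

## Scope and data model

`genetoxbmd` analyses animal-level dose–response data from multi-endpoint
genetic toxicology studies: a continuous positive response (DNA adducts per
10⁸ nucleotides) or a count/denominator pair (mutant pfu / total pfu for the
*lacZ* transgene, mutant cells per cells interrogated for *Pig-a*,
micronucleated cells per cells scored). One dataset is one tissue × endpoint
combination; doses are continuous covariates in mg/kg BW/day and dose 0
(vehicle control) participates in every fit through the background
parameter.

Count endpoints enter the dose–response modelling as per-animal frequencies
scaled to the endpoint's reporting unit (mutants per 10⁵ pfu, per 10⁶ cells,
% micronucleated). A zero count is replaced by half the smallest nonzero
per-animal value in the same dataset (configurable to `exclude`, which
refuses to empty a dose group). This rule is a package convention: zero
mutant counts are a real feature of low-background endpoints and log-scale
modelling needs a positive value; half-minimum is the common small-value
imputation and keeps the affected animals in the fit.

## The exponential family

Five nested members (increasing response orientation):

    m1: y = a
    m2: y = a·exp(b·x)
    m3: y = a·exp(b·x^d)
    m4: y = a·[c − (c−1)·exp(−b·x)]
    m5: y = a·[c − (c−1)·exp(−b·x^d)]

with `a > 0` the background, `c > 1` the maximum response as a multiple of
background (the asymptote of the saturating members is `a·c`), and the shape
`d ∈ [1, 4]` — the lower bound keeps the slope at dose 0 finite, the upper
bound is the conventional cap for this family (the constraint settings of
other BMD software are not published, so these are package choices).
Residuals are log-normal, `ln y ~ N(ln f(x), σ²)`, with a single σ shared
across dose groups.

The algebraic nestings are m1 ⊂ m2 ⊂ m3 and m1 ⊂ m4 ⊂ m5 (m3/m5 reduce at
`d = 1`; m2 at `b = 0` and m4 at `c → 1` reduce to m1). The two chains meet
only at m1: the convex growth models m2/m3 are *not* contained in the
concave saturating models m4/m5, whose closure adds only linear growth
(`c → ∞`, `b → 0`). Consequently `loglik(m4) < loglik(m2)` is legitimate on
strictly convex data; the fitting code guarantees monotone likelihood only
along the true chains (each extension is warm-started from its nested
submodel's optimum).

One deliberate deviation from a pure "increasing-only" parameterisation: the
slope `b` of m2/m3 is left sign-unconstrained during fitting. With `b`
bounded at zero, the null distribution of the m2-vs-m1 likelihood-ratio test
is the boundary mixture ½δ₀ + ½χ²₁ and the nominal 5% step would actually
reject ~2.5% of the time. Freeing the sign restores the χ²₁ null and the
nominal type-I error of the selection ladder. BMD inversion refuses
non-increasing fits (`b ≤ 0`) with an explicit "no increasing
dose–response" result.

## Fitting

On the log scale each model is `ln y = ln a + ln g(x; θ)` with `g = f/a`, so
`ln a` (the residual mean) and σ (the RMS residual) have closed-form profile
MLEs for any θ. The optimiser therefore works in ≤ 3 dimensions:

- m1 and m2 are exact (geometric mean; OLS of ln y on x);
- m3 is a 1-D search over d (OLS of ln y on x^d at fixed d; 31-point grid
  plus bounded local refinement);
- m4/m5 are L-BFGS-B over (ln b, ln(c−1)[, d]) from 10 starts: data-driven
  heuristics (c from the top-group/control geometric-mean ratio, b spanning
  the dose range, a near-flat c → 1 start) plus seeded Latin-hypercube
  draws. Fits are invariant to row order (inputs are canonically sorted) and
  deterministic given the seed.

σ̂ is floored at 10⁻⁶ so noiseless data keep a finite likelihood.

## Model selection

The likelihood-ratio ladder: m2 vs m1 (df = 1, accept when
2ΔLL > χ²₁,₀.₉₅ = 3.841); if accepted, m3 vs m2 and m4 vs m2 (each df = 1),
carrying the higher-log-likelihood accepted 3-parameter model (exact ties
prefer m4, the saturating member); finally m5 vs the carried model (df = 1).
The selected model is the most complex accepted one, and the full ladder
trace (comparison, 2ΔLL, df, decision) is part of the result for audit. The
m4-vs-m2 and m5-vs-m3 steps compare non-nested pairs of adjacent parameter
count; treating them as df = 1 LRTs is the standing convention for this
family and is recorded as such. Non-convergent fits are pruned from the
ladder.

## BMD and profile-likelihood CI

The benchmark response is a fractional increase over background (CES = 1.0,
i.e. a two-fold increase, by default). The BMD solves `f(BMD) = a(1+CES)`
in closed form:

    m2: ln(1+CES)/b          m3: (ln(1+CES)/b)^(1/d)
    m4: ln[(c−1)/(c−1−CES)]/b    m5: that quantity^(1/d)

For m4/m5 the benchmark must be reachable (`c > 1+CES`); otherwise an error
carries the asymptote value.

For the two-sided 90% CI (BMDL, BMDU) the selected model is reparameterised
with the BMD as an explicit parameter (b eliminated via the inversion
above). At each fixed BMD the nuisance parameters are maximised — a and σ
in closed form, c and/or d numerically with warm starts carried along the
search path — and the bounds solve
`2·(LL_max − LL_profile(BMD)) = χ²₁,₀.₉₀ = 2.7055` by geometric bracket
expansion plus Brent root-finding. The upper search stops at 100× the top
dose and flags the bound unbounded if the profile never crosses; the χ²
cutoff uses 1 df (scalar profile). The precision of a BMD is summarised by
the BMDU/BMDL ratio, and CI plots/rankings order estimates by the geometric
midpoint √(BMDL·BMDU).

## Trend tests

Counts are Poisson with log link and log-denominator offset; dose is a
categorical factor. For that saturated-by-group design the MLE is closed
form (group rate = total count / total denominator), so the LR statistics
are exact: overall test against intercept-only with df = (#groups − 1)
("Type-3-style" chi-square), and per-dose contrasts against the model that
pools the contrasted group's rate with control (df = 1). We implement the LR
(not Wald) chi-square; which of the two the original SAS analysis used is
not documented. Significance tiers: a < 0.0001, b < 0.001, c < 0.01,
d < 0.05, else ns; no multiplicity adjustment across the ten contrasts (raw
tiered p-values per dose are the reporting convention). Continuous adduct
responses are tested by rounding each animal's response to an integer count
on its reporting denominator (one unit of 10⁸ nucleotides). No
overdispersion term is fitted; between-animal dispersion beyond Poisson
inflates these statistics, which matches the reporting convention being
emulated but should be kept in mind when reading the tiers.

## Ranking, cross-endpoint comparison, proportionality

Two BMDs are *distinguishable* exactly when their BMDL–BMDU intervals do not
overlap. Ranking sorts by geometric midpoint (unbounded-BMDU estimates
last) and forms sensitivity groups by chaining adjacent estimates with
overlapping CIs (transitive closure in midpoint order). Cross-endpoint
comparison reports per-endpoint midpoints, CI ranges and — where the
selected model saturates — the maximum-response multiple c; models without
an asymptote report c as absent.

The proportionality analysis formalises the double-log unity-slope
construction: the slope-1 offset is the mean paired difference of log₁₀
BMDs (10^offset is the proportionality constant), the free slope is
ordinary least squares, and unity is *adequate* when the extra residual sum
of squares of the constrained fit is not significant by an F(1, n−2) test at
0.05. The F-test is an extension: the visual criterion it replaces has no
numeric form, and this is one defensible formalisation. The offset is
unweighted by default (CI widths are displayed, not used); a
precision-weighted variant (weights 1/log₁₀(BMDU/BMDL)²) sits behind a
flag. The Ki-67 check is the Pearson correlation of a per-tissue
proliferation index against the adduct-BMD/mutation-BMD ratio, with an
attached small-sample caveat (n is typically 3) and a flagged degenerate
result when either side has zero variance.

## Synthetic data

The generator emulates the stated design: doses 0, 0.10, 0.20, 0.39, 0.78,
1.56, 3.13, 6.25, 12.50, 25.00, 50.00 mg/kg BW/day, 7 animals per treated
group, 14 controls (84 animals). Each animal's expected value is the true
mean curve times a log-normal biological factor (SD `biological_cv` on the
log scale); the measurement layer is endpoint-appropriate (log-normal noise
for adducts; Poisson counts on a per-animal denominator for mutant
frequencies; binomial counts for micronuclei).

Presets anchor the dynamic-range parameter c to the published top
fold-changes (spleen adducts 506, lung 433, …, SI *lacZ* 208, …, MN-RET 4.5,
MN-NCE 3.7, *Pig-a* RET 385.5 / RBC 69.7). True BMDs, noise levels and assay
denominators are package conventions chosen once (raw data and the original
BMD table are unpublished): adduct BMDs 0.04–0.35, mutation BMDs 3–26, MN
BMDs 16–18 mg/kg BW/day, so the qualitative structure reproduces — the
*lacZ* three-group ranking (SI < {BM, Sp} < {GS, Lg, Kd, Lv}) and the
hematopoietic progression adducts < mutation < micronuclei. Within a
ranking group the true BMDs are placed close together and the groups are
separated by ≥ 2.5×, since CI-overlap grouping is only reproducible when
between-group gaps exceed the attainable CI widths (precision ratios run
~1.4 for high-dynamic-range presets and ~2 for shallow ones, consistent
with the reported precision ranges). Denominators: total pfu uniform
2–5×10⁵; *Pig-a* RET 2–4×10⁵ and RBC 2.5–3.5×10⁶ cells; MN 2×10⁴ cells
scored; adducts are frequencies on a fixed 10⁸-nucleotide unit.
`biological_cv` defaults to 0.2 (0.3 for the low-count *Pig-a* endpoints,
0.15 for MN); adduct measurement σ is 0.25.

What the generator does **not** emulate: pharmacokinetics, litter or cage
effects, assay-specific detection artefacts, inter-laboratory components,
or real *Pig-a* scoring losses. A green pipeline test therefore establishes
statistical correctness of the analysis chain under the stated noise model,
not agreement with any animal dataset.

Two properties of the stated world are worth knowing when reading test
output:

- fitting a log-normal model to count-derived frequencies carries a small
  Jensen bias (E ln X < ln E X, larger where counts are small, i.e. at low
  dose), which biases BMD estimates a few per cent low and drags 90% CI
  coverage for count presets to the anticonservative edge of the nominal
  band (~86–88% observed);
- the very-low-count *Pig-a* presets (background < 1 mutant per animal)
  additionally stress the zero-imputation rule and show visibly biased,
  wide-CI estimates — deliberately, since imprecise blood-cell mutant
  BMDs with precision ratios above 2 are exactly the behaviour being
  emulated.

## Numerical conventions

- optimiser tolerances: 1e-14 on the concentrated RSS, σ floor 1e-6, refit
  tolerance 1e-6 on log-likelihood monotonicity;
- profile bounds: Brent to relative 1e-9 in dose, verified to reproduce the
  defining drop 1.3528 within 1e-4;
- ties in model selection at exactly equal log-likelihood prefer the
  saturating member (m4 over m3);
- degenerate inputs: datasets need ≥ 3 distinct dose levels including 0;
  all-zero count datasets are rejected; a flat (m1) selection yields an
  explicit no-BMD result object rather than an exception; flat profiles
  yield a capped, flagged BMDU.
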