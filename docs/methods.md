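# Methods

`clinekit` analyses allele-frequency variation along a one-dimensional
geographic transect crossing a contact zone — the region where two
post-glacial recolonization lineages meet and admix, as in the boreal
tree transects (Norway spruce, Scots pine, silver birch) that motivate
the package's defaults. This note records the models, the estimators,
the numerical choices, and what the synthetic data do and do not show.

## Cline models

The transect coordinate x is the geodesic distance (km) from a northern
reference point (default 69.06° N, 22.55° E). The frequency of the
focal allele at position x is modelled as

    P(x) = pmin + (pmax − pmin) · g(x),
    g(x) = 1 / (1 + exp(−4 (x − c) / w)),

where c is the cline centre (position of steepest change) and w the
cline width, defined as the inverse of the maximum slope of g — so the
maximum slope of P is (pmax − pmin)/w. Stepped variants replace g
beyond distances δL (left) and δR (right) of the centre with
exponential tails whose decay is controlled by slope ratios τL, τR ∈
[0, 1]; the tails are constructed to join the sigmoid core continuously
(the junction value and the tail amplitude share the same logistic
factor). Continuity at the junctions is the enforced contract and is
property-tested to 1e−9.

The model ladder, with structural parameter counts:

| model  | free parameters                      | k |
|--------|--------------------------------------|---|
| NULL   | p0 (uniform frequency)               | 1 |
| LINEAR | intercept, slope (diagnostic)        | 2 |
| I      | c, w (pmin/pmax fixed)               | 2 |
| II     | c, w, pmin, pmax                     | 4 |
| III    | model I + δL, τL, δR, τR             | 6 |
| IV     | model II + tails                     | 8 |

Model I/III fix the end frequencies; by default they are pinned to the
observed frequencies of the two transect-end populations ("observed"
mode), with 0/1 pinning available as a configuration switch. The
LINEAR model is not part of the published ladder; it exists to detect
gradients with no sharp transition (below).

## Likelihoods and model choice

Counts are modelled per population as k_i ~ Binomial(n_i, P(x_i)),
where n_i is the number of successfully genotyped allele copies; the
log binomial coefficient is included so log-likelihoods are absolute
(it cancels from every comparison). Predicted frequencies are clamped
to [1e−6, 1 − 1e−6]. Continuous responses (normalized environmental
variables) use a Gaussian likelihood with the noise s.d. profiled out
by MLE and floored at 1e−4, which adds one free parameter per model.

Models are compared by AICc with n = number of populations (the
response units are population frequencies; total allele copies is noted
as an alternative). The best model is the converged cline fit (I–IV)
with the lowest AICc, ties resolved toward fewer parameters. Support
against the uniform null is the evidence ratio exp((AICc_null −
AICc_best)/2), the pairwise Akaike-weight ratio. Fit quality is
summarized by the residual standard error between observed and fitted
frequencies, RSE = sqrt(Σ(f_i − P(x_i))² / (n_pops − k)).

Before fitting, each locus is re-polarized so the southern transect
half has the higher mean frequency; the flip is recorded and can be
undone in reports.

## Optimization

Fitting is bounded multistart maximum likelihood: 20 Latin-hypercube
starts (seeded) plus a moment-based start (steepest observed adjacent
frequency change) and warm starts from simpler already-fitted models
are screened by likelihood, and the best two are polished with
L-BFGS-B (ftol 1e−8). Bounds: c ∈ [x_min − 0.5L, x_min + 1.5L] with L
the transect length, w ∈ [1, 10L] km, δ ∈ [0, L], τ ∈ [0, 1], pmin/pmax
∈ [0, 1]. A deterministic optimizer was chosen over MCMC because it is
reproducible, fast at desk scale, and directly testable against a grid
oracle: on sigmoid data the multistart solution is never below a
101×101 (c, w) grid search by more than 1e−3 log-likelihood units. A
fit is flagged non-converged when the optimizer fails or ŵ lands on its
upper bound.

### Linear-gradient exclusion

A frequency gradient that is linear across the whole transect has no
centre or width; such loci must never be called clinal. Under MCMC
fitting with bounded priors these loci fail to converge or pile up at
the width bound, but a bounded deterministic MLE converges happily to
an interior sigmoid approximation of the line. The package therefore
makes the exclusion explicit: the LINEAR diagnostic model is fitted
alongside the ladder, and a locus whose best cline model fails to beat
the straight line by more than 2 AICc units (the conventional
"substantial support" band) is flagged `linear_gradient` and excluded
from clinal classification. For strictly linear frequency profiles the
flag is deterministic — no cline model can exceed the line's likelihood
at equal or higher parameter count. Under binomial sampling the
exclusion is statistical: measured on the default design, >95% of
sampled linear loci are flagged while <1% of default-strength clinal
loci are.

### Which model to read (c, w) from

Model I's fixed ends pin the curve to the two end populations' observed
frequencies, so their sampling noise propagates into ŵ; at 15
diploids/population this inflates the median relative width error to
~0.29 (measured), versus ~0.20 for the free-end sigmoid (Model II).
Parameter-recovery checks therefore use the Model II MLE; Model I
remains the default for classification, where only relative model
support matters.

## Clinal classification, enrichment, selection

A locus is clinal when its evidence ratio strictly exceeds the 99th
percentile (linear interpolation) of the evidence-ratio distribution
over all loci with a converged best fit — an outlier rule, so ~1% of
loci qualify by construction. Non-converged and linear-flagged loci are
never clinal.

Externally derived candidate sets (genome scans, genotype–environment
association hits) are tested for clinal enrichment with an upper-tail
hypergeometric test. The background is matched on the fitted
end-frequency difference Δp = |pmax − pmin|: every fitted locus whose
Δp falls in the same 0.05-wide bin as some candidate enters the
background (union over candidates). Both the matching metric and the
bin width are conventions — the quantitative definition of "similar
frequency difference" is open — and both are configuration-exposed.
Bonferroni adjustment multiplies by the number of candidate sets tested
in one invocation.

For clinal selection candidates, cline width converts to a selection
intensity via migration–selection balance: w scales as σ/√s, and with
neighbourhood size N_S standing in for σ², s = N_S/w². N_S itself is
estimated from isolation by distance as exactly 1/slope of the OLS
regression of F_ST/(1−F_ST) on ln(distance km) (Rousset
linearization); the 4πDσ² proportionality constant is deliberately not
disentangled, since N_S enters downstream only through s = N_S/w².
When the IBD slope is non-positive, N_S is undefined and all s values
are reported missing with an explanatory status.

## F_ST and the Mantel test

Weir–Cockerham θ is computed from allele counts under random union of
gametes (the genotype-level among-individual component is unavailable
once genotypes are collapsed to counts): with MSP the among-population
and MSG the within-population mean squares and n_c the usual sample-size
correction, θ = (MSP − MSG)/(MSP + (n_c − 1) MSG). Multilocus and
pairwise values combine loci as a ratio of summed components; negative
estimates are retained (not truncated), and monomorphic loci contribute
zero to both sums. This allele-count form differs numerically from
genotype-aware implementations (e.g. VCFtools) when inbreeding is
present; under the Hardy–Weinberg synthetic data the two coincide in
expectation.

The Mantel test correlates the upper-triangular entries of the two
distance matrices (Pearson) and permutes rows/columns of the second
matrix simultaneously; the p-value is two-sided on |ρ| with the
add-one rule, default 9,999 permutations, seed required. Sidedness and
permutation count are package conventions (the source procedure leaves
them unstated). Type-I error is calibrated by simulation: at α = 0.05
the rejection rate over 1,000 null datasets lies in [0.035, 0.065].

Geodesic distances are haversine great-circle distances with Earth
radius 6371.0088 km.

## Synthetic data

The generator emulates the transect design: 12 populations spaced
evenly (±2% jitter) along a southward meridian over 1,400 km from the
reference point, 15 diploids per population, contact zone centred near
650 km. Locus classes:

* **clinal** — sigmoid clines, c ~ U(550, 750) km, w ~ U(150, 450) km,
  pmin ~ U(0, 0.15), pmax ~ U(0.85, 1); 10 loci by default (1% of the
  1,000-locus default dataset, matching the outlier rule's design);
* **linear** — straight gradients clipped to [0.02, 0.98] (30 loci);
* **flat** — uniform frequency U(0.05, 0.95) (460 loci);
* **ibd_neutral** — a Gaussian process on the logit scale with
  covariance exp(−d/ρ), ρ = 300 km, variance scaled analytically so the
  expected mean pairwise θ hits a 0.01 target (500 loci). This is a
  pragmatic stand-in for stepping-stone coalescent structure: its
  F_ST-versus-distance curve is calibrated empirically (realized
  multilocus θ within [0.005, 0.02]), not claimed to follow the Rousset
  slope exactly.

Genotypes are drawn per individual as Binomial(2, p) (Hardy–Weinberg
within populations; inbreeding not modelled) and written as plain-text
VCF v4.2 with a truth table. Everything is bit-reproducible from the
seed. The environmental table has 19 bioclimatic-style variables: six
sigmoidal at the contact zone, six linear in latitude, seven flat, all
with Gaussian noise (s.d. 0.02 on the normalized scale) and arbitrary
per-variable offsets/scales to exercise min-max normalization.

What the synthetic data do **not** contain: linkage disequilibrium and
inversions, inbreeding, missing-data structure correlated with
geography, multi-copy regions, or coalescent noise shared across loci.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the stated sampling model, not robustness to those
real-data complications.

## Problem sizes and determinism

Test and acceptance simulations use the design scale of the emulated
studies (12 populations, 15–20 diploids) with locus counts chosen per
check: 100 loci for parameter-recovery and model-selection checks,
100 replicates × 100 loci for classification specificity, 1,000 null
simulations × 999 permutations for Mantel calibration, and the
1,000-locus default dataset for the end-to-end run. All randomness
flows from explicit seeds; reruns are bit-identical.

## Known limitations

* The pipeline's F_ST/IBD stage uses all loci in the count matrix; the
  emulated studies used pre-filtered neutral SNP sets. On the default
  synthetic mix the clinal/linear minority inflates mean pairwise θ
  (~0.02 vs the 0.01 neutral target) and hence deflates N_S; supplying
  a neutral-only counts table reproduces the neutral calibration.
* Parameter uncertainty is not routinely computed; the parametric
  bootstrap hooks exist at the API level (refit on counts resampled
  from the fitted cline) but no confidence intervals are emitted in the
  standard tables.
* The evidence-ratio percentile rule is relative by construction: with
  no truly clinal loci it still labels ~1% of loci clinal unless their
  ratios tie; interpretation should always combine the call with the
  evidence ratio itself.
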