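# Methods

This note documents the statistical models implemented in `gencmr`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## Individual identification

Noninvasive genotypes carry error — allelic dropout (a heterozygote
recorded homozygous), false alleles (PCR stutter creating an allele ±2
repeat units), and whole-locus failure — so exact genotype identity is too
strict a recapture criterion. The matching rule is the one standard in
noninvasive genetics:

- samples typed at fewer than `min_loci = 7` of the 8 loci are discarded
  (few loci cannot separate relatives; see P(ID)sib below);
- two samples match when, over the loci typed in both (at least
  `min_loci − 1`), their unordered allele pairs differ at no more than
  `max_mismatch = 1` locus, their sexes are compatible (unknown is
  compatible with anything; an observed conflict vetoes), and their mtDNA
  haplotypes are identical whenever both are known;
- individuals are the connected components of the match graph (single
  linkage). The rule is pairwise only, so transitivity can fail; a cluster
  containing a pair that differs at ≥ 2 loci is *flagged* rather than
  split, because silently splitting inflates abundance. Consensus
  genotypes are per-locus majority votes, ties broken toward the allele
  pair most frequent in the dataset.

Accuracy of this rule is a function of recapture intensity: each extra
sample of an individual is another chance to accumulate two dropout
differences against a clustermate. At the capture rates the pipeline is
designed around (s/k ≈ 1.2–1.3 events per individual) and dropout ≤ 0.05
per heterozygous locus observation, identification error stays below 5%
of the true detected count, and is exactly zero without genotyping error;
both properties are exercised in the test suite over replicate
simulations (5 and 20 surveys of a 16-point grid).

Same-day samples of one individual at the same place (within
`same_place_radius`, default 0 m — exact point identity) are one capture
event: a defecating elephant is one observation, not three.

## Capture-class abundance models

Let k individuals be observed in s capture events, with capture counts
c_1..c_k. All three models treat events as independent draws over N
individuals with per-individual weights; the likelihood of the observed
labelled outcome, up to terms constant in the parameters, is

    logL = log(#ways to choose which individuals were observed)
         + sum_i c_i log w_i  -  s log(sum_j w_j).

- **ECM.** All weights equal: logL(N) = log C(N, k) − s·log N, maximized
  by exhaustive integer search over [k, maxpop] (maxpop default 10,000).
  The MLE agrees, within one individual, with inverting the occupancy
  moment equation E[distinct] = N(1 − (1 − 1/N)^s).
- **TIRM.** Individuals captured once form class A (weight 1, together
  with all N − k unobserved individuals); individuals captured more than
  once form class B (weight α ≥ 1):

      logL(N; α) = log C(N − k_B, k_A) + s_B log α − s log(N − k_B + α k_B).

  α and N are **not** jointly identifiable from a single spectrum: the
  profile likelihood in α increases without bound as N grows (ever-larger
  populations of ever-rarer captures with an ever-more-extreme high
  class fit ever "better"). The estimator is therefore two-stage:
  α₀ = (s_B/k_B)/(s_A/k_A) from the observed class means; N₁ = argmax
  logL(·; α₀); then class A's mean rate is corrected for the individuals
  never captured, α₁ = (s_B/k_B)/(s_A/(N₁ − k_B)), and N is maximized
  once more. With no repeats (or no singletons) the model collapses to
  ECM with α = 1. Empirically the two-stage fit never scores below ECM
  (property-tested on random spectra), though that is not a theorem here.
- **TIRMpart.** Very heavily recaptured individuals (habitual latrine
  users, territory holders) violate the two-rate assumption. A third
  class is found by evaluating the three-weight analog of the same
  likelihood (two-stage, moments then one correction) over every
  contiguous two-threshold partition of the count values; the partition
  with the highest likelihood defines the removed class. TIRM is refitted
  to the remaining spectrum and the removed individuals are added back to
  the point estimate. The reported log-likelihood refers to the reduced
  data and is not comparable with full-spectrum fits.

Model comparison is a parametric-bootstrap likelihood-ratio test: LR is
reported as the plain difference of maximized log-likelihoods, and p is
the fraction of spectra simulated under the simpler model whose refitted
LR reaches the observed one (with the +1/(n+1) correction). Confidence
intervals are percentile intervals over spectra simulated from the fitted
model with the observed s held fixed — sampling effort is conditioned on,
not resampled. A fit at the maxpop boundary (e.g. an all-singleton
spectrum, whose likelihood increases in N indefinitely) flags itself and
its interval as unreliable.

Area extrapolation is linear in area with truncation toward zero,
defaults 891 km² sampled → 3,585 km² target; it assumes homogeneous
density, which the reports state rather than hide.

## Spatially explicit density (SECR)

Activity centers X follow a homogeneous Poisson process with density D
over a habitat mask: square cells (default spacing 1000 m in the
pipeline) whose centers lie within 2000 m of any detector. The 2 km
buffer keeps centers out of unusable habitat (ocean, lagoon) while being
comfortably wider than the distance at which detection remains
measurable. Detectors are the survey grid points, treated as count-type
proximity detectors with effort = number of visits; per-detector counts
are Poisson with mean effort × λ(d), λ(d) = λ0 e^{−d/σ} (exponential
detection — heavier-tailed than half-normal, appropriate for wide-ranging
foragers). Integrating over centers and over the Poisson population:

    logL = −D Σ_x a·p·(x) + n log D + Σ_i log Σ_x a·Pr(ω_i | x) + const,

with p·(x) = 1 − exp(−Σ_d effort_d λ(d(x,d))) and a the cell area. The
implementation keeps density in individuals/ha internally (mask-native)
and reports per km².

The sex model makes λ0 sex-specific with a mixing proportion ψ; known
sexes contribute their class term, unknown sexes marginalize. σ is shared
— with ~1.2 captures per individual the data cannot support sex-specific
range sizes, and the choice is configurable. Optimization is L-BFGS-B on
(log D, log λ0, log σ [, logit ψ]); the D interval is Wald on the log
scale from a central-difference Hessian at the optimum. Non-convergence
and boundary ψ are flagged on the fit object, never silently dropped.
Models are ranked by AICc = −2 logL + 2k + 2k(k+1)/(n−k−1), n = number of
individuals, models within ΔAICc < 2 marked competitive.

Numerical notes: the likelihood at fixed parameters changes by < 0.5%
when a 500 m mask is refined to 250 m on the survey scales tested, so the
pipeline's 1000–1500 m spacings sit on the flat part of that curve for
σ ≥ ~1200 m; the vectorized likelihood is verified to 1e-10 against a
naive direct-sum implementation; and translation invariance is tested
(only distances enter).

Parameter recovery is the test surface: 100 surveys simulated at
D = 0.62/km², λ0 = 0.2/visit, σ = 1500 m on a 10×10 grid at 3 km spacing
(2 visits/point) recover the density with median within 10% and
log-scale Wald 95% coverage ≥ 88%. These sizes mirror a realistic forest
survey while keeping the whole suite quick.

## Population-genetic statistics

All estimators run on identified individuals, not raw samples — repeated
captures would pseudoreplicate genotypes and drag allele frequencies
toward heavily resampled animals.

- Diversity per locus: Na; Ne = 1/Σp²; He = 1 − Σp²; unbiased
  UHe = 2n/(2n−1)·He; Ho = fraction of typed individuals heterozygous;
  F_IS = (He − Ho)/He (undefined for monomorphic loci, flagged).
- P(ID) = Σp_i⁴ + Σ_{i<j}(2p_ip_j)²;
  P(ID)sib = 0.25 + 0.5Σp_i² + 0.5(Σp_i²)² − 0.25Σp_i⁴. Cumulative
  values are running products in caller-chosen locus order; the pipeline
  orders loci most-informative-first and reports how many loci reach the
  0.01 cutoff used for panel qualification (the synthetic default panel
  reaches < 0.001 by 7 loci).
- Hardy-Weinberg: Monte-Carlo exact test. Tables are sampled conditional
  on allele counts by re-pairing the allele vector; the conditional
  probability (Guo–Thompson form) reduces to H log 2 − Σ log n_ij! up to
  constants; p is the fraction of tables no more probable than observed,
  run in batches (default 100 × 1000) for a Monte-Carlo SE. Checked
  against full enumeration on diallelic tables and for ~5% type-I error
  on equilibrium data. Monomorphic loci return p = 1 by convention.
  Dememorization-style burn-in is unnecessary because draws are exact and
  independent, not a Markov chain.
- Error rates from replicated individuals: dropout = homozygous
  observations of consensus-heterozygous loci over all observations of
  consensus-heterozygous loci; false alleles = observations carrying an
  allele absent from the consensus over all locus observations. With no
  replicated individual the rates are *undefined*, not zero.
- Queller–Goodnight relatedness: symmetrized over the two reference
  individuals, numerators and denominators summed over loci before
  dividing, frequencies estimated from all individuals including the
  focal pair. That choice reproduces the estimator's known centering:
  the all-pairs mean is ≈ −1/(n−1) (−0.0053 at n = 190). A lone
  diallelic heterozygous locus has denominator exactly 0 (undefined);
  pairs with no shared typed loci are excluded from matrices.
- ML kinship: per-locus pair likelihood k₀P(G₁)P(G₂) + k₁P(G₁)T(G₁→G₂) +
  k₂P(G₁)[G₁=G₂] under (k₀,k₁,k₂) = U(1,0,0), HS(.5,.5,0),
  FS(.25,.5,.25), PO(0,1,0); category by maximum summed log-likelihood,
  ties broken toward the less related class. PO/FS count as first-order,
  HS as second-order for network edge styling.

## Sociality

Two individuals are associated if any pair of their samples was collected
on the same day, within the chosen radius (75/100/250 m; Euclidean), and
in the same deposition-age class; samples flagged as differently aged are
excluded first. One qualifying co-deposition suffices — the field
assumption is that same-aged dung in close proximity marks a group
passing together — and repeated co-depositions do not inflate edge
weights: edges are binary presence, weighted by Queller–Goodnight r and
styled by kinship order. Isolated individuals are excluded. Components
are scored for size, sex composition, and the number of distinct female
haplotypes; a multi-female component containing an unhaplotyped female is
*unassessable* (reported separately) rather than dropped, and the
monomorphic proportion — the female-philopatry signal — is computed over
assessable components only. Edge sets are nested across radii by
construction (tested).

The Mantel test correlates the binary association matrix with the
relatedness matrix over off-diagonal entries, permuting the relatedness
matrix's labels (rows and columns simultaneously); p is one-sided upper
tail — the directional hypothesis is that associates are more related —
with the +1/(permutations+1) correction, default 999 permutations. NaN
relatedness entries follow their labels and are masked per permutation.
The statistic matches the vegan R implementation to 1e-8 on shared
fixtures, and the test holds its ~5% type-I error over 200 independent
null matrix pairs.

## The synthetic generator

What it emulates: a closed population whose size is Poisson(D × buffered
area); matrilineal groups seeded by a female founder carrying a haplotype
drawn from configured frequencies, every later member the offspring of a
group female (haplotype maternally inherited, one maternal and one
paternal allele per locus, one sire per mother so sibships are full);
female dispersal between groups with probability `female_dispersal_prob`
(dispersers keep their natal haplotype — the process that erodes
within-group haplotype monomorphism); activity centers scattered 300 m
(sd) around group centers inside a region buffered 2 km beyond the survey
hull; per-visit per-individual detection counts Poisson(λ0 e^{−d/σ});
dung placed near a per-(group, visit) anchor jittered 100 m (sd) around
the visited point, group members within a 50 m spread of each other;
dropout, false alleles (±2 repeat units, stutter-like), whole-locus
missingness, sex-marker failure ('+' statuses failing to '−', which the
sexing logic maps to unknown or, rarely, the wrong sex — a real failure
mode), and haplotype missingness.

Defaults: density 0.62/km², 10×10 grid at 3 km spacing visited twice,
λ0 = 0.2/visit, σ = 1500 m, mean group size 3, six haplotypes with
geometric frequencies, eight loci with 6–16 alleles and geometrically
decaying frequencies (He ≈ 0.82–0.91), dropout 0.05, false alleles 0.01,
missing locus 0.02, sex-marker failure 0.02, female share 0.55, dispersal
0.1. These produce surveys of a few hundred samples with ~1.2–1.3
captures per detected individual — the regime the analyses are built for.

What it does **not** emulate, hence what passing tests do not show about
real data: habitat heterogeneity and landscape covariates (centers are
uniform); temporal population turnover (closed by construction); actual
transect geometry (effort is a per-point-visit constant; the real
searched area per point is not modeled); correlated group movement
(detections are independent across individuals given distance, so
co-deposition is rarer than in real accumulated dung); and deposition-age
ambiguity — each group's passage gets a distinct, correctly judged
freshness cohort, so cross-group same-day collections are always
separable. Real freshness judgment is imperfect; the generator represents
the idealized field protocol, which is exactly what makes the
dispersal-to-monomorphism dose-response a clean test.

One global integer seed drives everything through named substreams
(population / genotypes / survey / haplotype sequences), so stages are
independently reproducible and a survey can be re-drawn over a fixed
population.

## Pipeline and reproducibility

Stages write independent artifacts (TSV tables, JSON summaries, GraphML
networks) into one output directory; the consolidated report embeds the
seed and every parameter, and a re-run with the same configuration is
byte-identical up to embedded paths. Configuration is one YAML/JSON file
with full defaulting; CLI flags override file values. Warnings that
matter scientifically — ambiguous clusters, boundary MLEs, unreliable
bootstrap intervals, non-convergence, degenerate mixtures — are logged
and carried in the outputs.

## Known limitations

- The two-stage TIRM α is an estimator choice forced by the
  non-identifiability of (N, α); different software lineages make
  slightly different choices here, so third-party point estimates may
  differ at the optimizer level (the worked-example spectrum reproduces
  to the integer).
- The TIRMpart bootstrap interval simulates from the reduced-data TIRM
  fit; it does not propagate partition-selection uncertainty.
- Wald intervals for density are symmetric on the log scale; profile or
  bootstrap intervals would be preferable near boundaries but are not
  implemented.
- The identification rule has no genotype-uncertainty model (no
  likelihood-based matching); it reproduces the rule-based field
  procedure, and its failure modes (sibling collision, split under heavy
  recapture with dropout) are quantified in the tests rather than
  modeled away.
- Mantel permutations treat individuals as exchangeable; spatial
  autocorrelation of sampling could inflate significance on real data.
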