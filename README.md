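# gencmr

Genetic capture-recapture analysis for populations sampled noninvasively —
abundance, density, and social structure estimated from georeferenced dung
(or hair, scat, feather) genotypes. The package was built around surveys of
African forest elephants, where individuals are identified from
microsatellite genotypes of dung collected on a systematic grid, but every
stage is generic to any diploid species surveyed this way.

## What it computes

Given a table of samples — each with a collection date, planar coordinates,
a diploid genotype at 8 STR loci, amplification statuses at three
sex-chromosome markers (SRY, AMELY, PLP1), and an mtDNA control-region
haplotype — the pipeline:

1. **Identifies individuals** (`identify`). Samples match when their
   genotypes differ at ≤ 1 of the loci typed in both (tolerating one
   genotyping error), sexes are compatible and haplotypes identical when
   known; clusters are connected components of the match graph. Same-day,
   same-place samples of one individual collapse to a single capture
   event, yielding the capture-class spectrum (how many individuals were
   captured 1×, 2×, ...).
2. **Qualifies the marker panel** (`popgen`). Per-locus Na, Ne, Ho, He,
   unbiased He, F_IS and a Monte-Carlo exact Hardy-Weinberg test with
   Bonferroni correction; cumulative P(ID) and sibling P(ID) — the
   probability two random individuals (or two siblings) share a
   multi-locus genotype; allelic-dropout and false-allele rates from
   replicated individuals; pairwise Queller–Goodnight relatedness and
   maximum-likelihood kinship classification (unrelated / half-sib /
   full-sib / parent–offspring).
3. **Estimates abundance** (`capwire` module). Capture events are modeled
   as multinomial draws over N individuals:
   - **ECM** (equal capture): logL(N) = log C(N, k) − s·log N, maximized
     over integer N ∈ [k, maxpop];
   - **TIRM** (two innate rates): individuals captured once form a
     low-rate class, repeats a high-rate class with weight ratio α ≥ 1,
     estimated by a two-stage moment/refit scheme;
   - **TIRMpart**: an extreme high-capture class is split off by a
     three-class likelihood, removed, TIRM refitted, and the removed
     individuals added back.
   Parametric-bootstrap CIs, bootstrap likelihood-ratio model comparison,
   and linear area extrapolation round out the stage.
4. **Estimates density** (`secr` module). Maximum-likelihood spatially
   explicit capture-recapture: Poisson activity centers on a habitat mask
   (survey grid buffered by 2 km), exponential detection
   λ(d) = λ0·exp(−d/σ), count-type proximity detectors, a null and a
   sex-mixture detection model, ranked by AICc.
5. **Maps social structure** (`sociality`). Individuals whose same-aged
   samples were collected on the same day within 75/100/250 m are
   associated; network components are scored for sex and mtDNA-haplotype
   composition (female philopatry predicts haplotype-monomorphic
   components), edges are weighted by relatedness, and a Mantel
   permutation test correlates association with relatedness.

A synthetic-population generator (`synthetic`) simulates all of it —
matrilineal groups with Mendelian STR inheritance, distance-decayed dung
detection, and a realistic genotyping-error channel — so every stage is
testable against known truth.

## Worked example

Fit the abundance models to a capture-class spectrum (here: 157
individuals captured once, 25 twice, 5 three times, 2 four times, 1 five
times — 190 individuals, 235 events):

```sh
echo '{"1":157,"2":25,"3":5,"4":2,"5":1}' > spectrum.json
gencmr abundance --spectrum spectrum.json -o out --seed 1
```

prints (abridged):

```json
{
 "fits": {
  "ECM":      {"n_hat": 530, "loglik": -1131.598, "ci": [428, 694]},
  "TIRM":     {"n_hat": 690, "alpha": 6.188, "loglik": -1088.083, "ci": [505, 759]},
  "TIRMpart": {"n_hat": 867, "alpha": 6.369, "loglik": -935.884, "ci": [670, 1254],
               "excluded": [8, 28]}
 },
 "lrt_ecm_vs_tirm": {"lr": 43.52, "p": 0.0198}
}
```

Reading it: under equal capture the population is ~530; allowing two
innate capture rates (strongly preferred — likelihood ratio 43.5) raises
the estimate to 690; partitioning off the 8 most-recaptured individuals
before refitting gives 867. CIs are 95% parametric-bootstrap percentile
intervals (100 replicates). `gencmr extrapolate 754` scales an estimate
from the 891 km² survey area to a 3,585 km² region (→ 3033).

A full synthetic run — simulate, identify, popgen, abundance, density,
sociality, consolidated report — is one command:

```sh
gencmr run --seed 1 -o out
gencmr report out/report.json
```

## Layout

- `src/gencmr/genotype_io.py` — sample table / FASTA / GenAlEx I/O, sexing,
  haplotype collapsing
- `src/gencmr/synthetic.py` — population, genotype and survey simulation
- `src/gencmr/popgen.py` — diversity, P(ID), HWE, error rates, relatedness,
  kinship
- `src/gencmr/identify.py` — individual identification, capture spectrum
- `src/gencmr/capwire.py` — capture-class abundance models
- `src/gencmr/secr.py` — spatially explicit density estimation
- `src/gencmr/sociality.py` — association networks, component composition,
  Mantel test
- `src/gencmr/pipeline.py`, `cli.py` — orchestration and the `gencmr`
  command

See `docs/methods.md` for the models, their assumptions, and the numerical
choices.
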