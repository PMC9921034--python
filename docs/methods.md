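# Methods

## Scope and data model

All computation runs on dosage matrices: samples × biallelic SNP loci with
alternate-allele counts 0/1/2 and NaN for missing calls, plus per-locus
metadata (sequenced-tag "clone" id, reproducibility score, call rate) of the
kind attached to DArTseq reports.  Family structure is a table of
(species, site, maternal line, mother id, progeny id) with per-site
coordinates in decimal degrees (WGS84 assumed; no datum metadata is consumed).

## Quality filters

Rules and defaults: marker reproducibility ≥ 0.98; marker missingness ≤ 0.10;
one SNP retained per clone; sample missingness ≤ 0.40.  The rules are applied
in the order reproducibility → locus missingness → clone thinning → sample
missingness, so that sample missingness is measured on the retained markers;
the order is configurable and recorded in the filter report.  Clone thinning
keeps the SNP with the highest observed call rate, breaking ties by lowest
locus id.  Missing-dosage symbols accepted on input: `-`, empty, `NA`.
Filtering is idempotent, and the report counts always sum to the change in
matrix dimensions (both are tested properties).

## Diversity and relatedness estimators

* **Ho** — per-locus fraction of heterozygous calls among non-missing calls,
  averaged over loci.  **He** — Nei gene diversity 2p̂q̂ with the small-sample
  factor 2n/(2n−1) (toggleable), averaged over loci; monomorphic loci
  contribute zero.
* **F_IS** = 1 − mean(Ho_l)/mean(He_l), a multilocus ratio of averages.  The
  alternative (averaging per-locus ratios) explodes at low-diversity loci;
  the ratio-of-averages form is the stable choice for SNP panels dominated by
  low-MAF markers.  An all-monomorphic population yields NaN with a warning,
  not an exception.
* **F_ST** — Weir & Cockerham (1984) θ, multilocus ratio-of-sums of the
  a/(a+b+c) variance components, with per-locus sample sizes reduced by
  missingness.  Negative estimates are kept as computed.  The vectorised
  implementation is tested to 1e-12 against an independent scalar
  transcription of the 1984 component formulas.
* **Isolation by distance** — least-squares slope and Spearman rank
  correlation of pairwise F_ST against great-circle (haversine) distance.
* **Kinship** — method-of-moments IBD coefficient
  φ̂ = mean_l (x−2p)(y−2p)/(4p(1−p)) using *supplied* allele frequencies
  (by design those estimated from the wild-sampled mothers of the pair's
  population, never from the subsample under test); loci fixed in the
  reference (p ∈ {0,1}) and pairwise-missing loci are excluded.  Expectations:
  0.25 for outbred parent–offspring, 0.125 for half-sibs, (1+F)/2 for
  self-pairs, and 0.5 for a mother and her selfed offspring — the last
  verified against a brute-force pedigree oracle that tracks labelled allele
  copies.
* **Isogenic lines** — single-linkage grouping of samples whose pairwise
  identity-in-state proportion (non-missing loci) is ≥ 0.99 (configurable);
  intended to expose clonal or repeatedly selfed site structure.
* **Genetic distance** — Euclidean distance on dosage vectors, pairwise-
  complete over the shared called loci C with rescaling √(L/|C| · Σ_C (x−y)²).

## Selfing-rate estimators

The error model throughout is an independent per-allele miscall with
probability ε (default 0.005): a true homozygote is observed non-homozygous
with probability 2ε−ε², a true heterozygote loses a given allele with
probability ε(1−ε).

**Method of moments (MME).**  At a locus where the mother's call is
homozygous, define X = 1 when the progeny call carries the allele the mother
could not have transmitted.  Under outcrossing, X = 1 with probability

    d = (1 − q') (2ε − ε²) + q' (1 − ε(1 − ε)),

where q' is the pollen-pool frequency of the non-maternal allele; under
selfing X = 1 only through error, e = 2ε − ε².  Heterozygous-mother loci have
X = d = e = 0 and drop out — the estimator deliberately avoids
genotype-specific heterozygous-transmission terms, trading a modest loss of
information for robustness (a documented limitation).  Since
E[X] = (1−s)d + s·e, summing over informative loci gives the linear solve
ŝ = (D−T)/(D−E), clamped to [0,1].  The standard error propagates
Var(T) ≈ Σ m(1−m) with m = (1−ŝ)d + ŝe through the solve.  When D ≤ E the
estimate is flagged `uninformative` rather than raised.  The d/e terms are
tested against exhaustive enumeration of all true-genotype × observed-call
outcomes for every mother dosage and ε ∈ {0, 0.01, 0.05}.

**Likelihood cross-check (ML).**  Per progeny, L(s) is the product over loci
of s·P(g_o|g_m, self, ε) + (1−s)·P(g_o|g_m, outcross, q, ε), with Mendelian
transmission and the 3×3 flip matrix on the progeny call.  Maximisation is a
dense grid (step 0.001) plus bounded local refinement; the exact grid
endpoint is kept when the bounded search cannot improve on it.  Data
impossible under both modes, or likelihoods flat in s (e.g. only
heterozygous-mother loci), yield flagged estimates.

**CNN.**  A per-site 1-D convolutional network maps a (loci × 4) image —
mother dosage/2, progeny dosage/2, population alternate-allele frequency,
call mask — to a selfing score.  Loci are sorted by population minor-allele
frequency, descending, and the top-L (default L = 2000) form the input; a
shortfall is zero-padded with mask 0.  The MAF ordering canonicalises the
unordered marker set so the network is invariant to marker permutation.
Architecture: two convolution blocks (16 then 32 filters, kernel 7, ReLU,
stride-2 average pooling), global average pooling, a 32-unit dense layer and
a single sigmoid output; squared-error loss, Adam (default 3e-3), implemented
directly in numpy (im2col products for forward and backward).  Training data
are progeny simulated from the site's observed mothers and allele
frequencies: for each example a selfing level s is drawn (Uniform(0,1) by
default), the progeny is wholly selfed with probability s, and the
**regression label is the realized selfing indicator**.  A sigmoid output
trained with squared error then estimates P(selfed | data), whose grid means
recover s; labelling with the parameter s instead would make the
squared-error optimum the posterior mean of s (≈ 2/3 for a clearly selfed
progeny under a uniform prior), which would be badly calibrated per progeny
and discordant with the other two estimators.  Uncertainty comes from a deep
ensemble of K = 5 members (independent initialisation and shuffling seeds);
training is fully deterministic given the seeds.

**Site screening.**  Sites whose mothers carry almost no variation cannot
support selfing inference: a site is flagged (and excluded from mating-system
summaries, with the flag logged in the output table) when mean mother He
< 0.01 or when all mothers fall into a single isogenic-line group.

**Comparisons.**  Species/group differences in ŝ use the two-sided
Mann–Whitney U test (asymptotic, tie-corrected); the relationship between ŝ
and the progeny-minus-mother difference in Ho uses Spearman's ρ (undefined
under complete ties, reported as missing).  Proportion contrasts (e.g.
germination success) use the 2×2 chi-square test with continuity correction.

## Synthetic data generator

The generator defines the conditions under which everything is validated.

* **Landscape**: hierarchical island model.  Ancestral alternate-allele
  frequencies are drawn per locus (default Uniform(0.1, 0.5)); each
  population draws its own frequency from Beta(a, b) with mean p and variance
  F_ST·p(1−p) (a+b = (1−F_ST)/F_ST), so the configured `fst_target` is the
  expected Wright F_ST.  Genotypes follow inbreeding-adjusted HWE:
  P(het) = 2pq(1−F); for negative F the class probabilities are clipped at
  zero and renormalised.  Defaults (6 adults per population, 10 mothers per
  collection site, 7 lines × 3 progeny + 3 lines × 10 progeny) mirror a
  realistic landscape-plus-progeny survey design.
* **Families**: each progeny is wholly selfed with its probability s (two
  independent Mendelian maternal gametes) or outcrossed (one maternal gamete
  plus one pollen allele ~ Bernoulli(q) from the population frequency).
  Selfing can be set per site or per progeny.  The truth table records both
  the assigned s and the realized selfing indicator.
* **Noise**: per-allele flips at rate ε (default 0.005, a typical
  reduced-representation figure) applied to progeny calls, random masking at
  a per-call rate (default 0.05), and injected per-locus metadata
  (reproducibility scores, a configurable fraction of two-SNP clones, call
  rates) so the QC filters have realistic work.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about field data: linkage and recombination maps, spatial
pollen-dispersal kernels, biparental inbreeding (outcrossing to relatives,
which in real arrays inflates ŝ), apomixis, and batch- or tag-correlated
genotyping artefacts.

## Validation experiments and problem sizes

The acceptance-style tests run, at sizes chosen to make Monte-Carlo noise
small relative to the tolerances while staying desk-scale:

* MME recovery: 200 progeny per s ∈ {0, 0.25, 0.5, 0.75, 1}, 5000 loci,
  ε = 0.005.  Because each simulated progeny is wholly selfed or outcrossed,
  recovery is judged on grid means: |mean(ŝ)−s| ≤ 0.03 per grid point and
  RMSE of the grid means ≤ 0.06.
* Concordance: mean |ŝ_MME − ŝ_ML| ≤ 0.05 and mean |ŝ_CNN − ŝ_MME| ≤ 0.10 on
  held-out simulations (1500-locus panel; CNN at L = 1000, 2000 training
  examples, K = 5, 20 epochs).
* Kinship: on 20 mothers (F = 0.2) × 10 progeny under mixed selfing at 2000
  loci, mean mother–progeny kinship ≥ 0.25 and within-line sib kinship
  ≥ 0.125 (`scripts/acceptance.py` recomputes exactly this experiment).
* Generator truth: realized F_IS within ±0.05 of configured F and mean
  pairwise Weir–Cockerham F_ST within 15% of `fst_target` at 10⁴ loci;
  allele capture monotone in number of sites and in MAF threshold.
* Landscape contrast: reaching 90% capture of ≥5%-frequency alleles needs
  strictly more collection sites on a high-F_ST selfing landscape
  (F_ST 0.7, F 0.6, s 0.9) than on a moderate mixed landscape
  (F_ST 0.25, F 0.1, s 0.3), 8 sites each, 1200 loci.

One further validation requires the original field DArTseq matrices, which
have no public accession; the corresponding test documents the expected
layout under `data/empirical/` and fails in their absence.

## Numerical choices and degenerate inputs

Ties in clone thinning break by locus id; MME estimates are clamped to [0,1]
(the clamp's truncation bias at the grid edges is well inside the stated
tolerances); the ML grid uses a 1e-300 likelihood floor; loci with reference
frequency 0 or 1 are excluded from kinship and selfing likelihoods; distance
computation raises on pairs with no shared called loci; populations of one
sample are rejected for F_ST.  All pipeline randomness derives from a single
seed via named `SeedSequence` substreams, and identical configs + seeds
produce byte-identical output tables.
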