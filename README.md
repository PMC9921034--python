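# progarray

Mating-system inference from SNP progeny arrays, population-genetic summary
statistics, and evaluation of seed-collection sampling designs — with a
synthetic-data generator so the whole pipeline is testable end to end without
any external download.

## The problem

Seed collections for conservation and restoration are usually gathered as
*progeny arrays*: seeds from a handful of known mother plants per site.  How
much genetic diversity such a collection captures depends on the species'
mating system — a predominantly selfing shrub packages far less diversity per
seed (and per site) than an outcrossing one.  Given biallelic SNP dosage
matrices (DArTseq-style, 0/1/2 + missing) for mothers and their seedlings,
this package:

1. applies the standard marker/sample quality filters (reproducibility ≥ 0.98,
   locus missingness ≤ 10%, one SNP per sequenced tag, sample missingness
   ≤ 40%);
2. computes Ho, He, multilocus F_IS, pairwise Weir–Cockerham F_ST, isolation
   by distance, method-of-moments IBD kinship, and isogenic-line detection;
3. estimates a per-progeny selfing rate ŝ ∈ [0,1] three ways:
   * **MME** — a Ritland-style single-locus method of moments.  At loci where
     the mother is homozygous, let X indicate that the progeny carries the
     non-maternal allele, d = P(X=1 | outcross, pollen frequency q, error ε)
     and e = P(X=1 | selfing, error only).  Then with T = ΣX, D = Σd, E = Σe
     over informative loci, **ŝ = (D − T)/(D − E)**, clamped to [0,1], with a
     binomial-variance standard error;
   * **ML** — per-progeny maximisation of the mixture likelihood
     L(s) = Π_l [s·P(g_o|g_m, self, ε) + (1−s)·P(g_o|g_m, outcross, q, ε)],
     used as an independent cross-check;
   * **CNN** — a 1-D convolutional network trained per site on progeny
     simulated from the site's observed mothers and allele frequencies; a
     deep ensemble of K=5 members gives the estimate and its uncertainty;
4. evaluates seed-sampling schemes: within-site splits of eight seeds among
   1/2/4/8 maternal lines scored by mean pairwise Euclidean distance, and
   among-site subsampling scored by capture of reference-panel alleles at
   minor-allele-frequency thresholds 0.5/1/2/5%.

The synthetic-data module simulates island-model landscapes with tunable
F_ST and inbreeding F, mothers-plus-progeny family designs (default 10
mothers per site: 7 × 3 progeny + 3 × 10 progeny), per-progeny selfing,
per-allele genotyping error and missingness — with the truth returned, so
every estimator is validated by parameter recovery.

## Worked example

```python
import numpy as np
import progarray as pa

# a panmictic site: 10 genotyped mothers, 2000 SNPs
cfg = pa.LandscapeConfig(n_populations=1, n_loci=2000, fst_target=0.0,
                         n_adults_per_pop=10, seed=1)
mothers, freqs, _ = pa.generate_landscape(cfg)

# simulate a progeny array with a true selfing rate of 0.6
matrix, fam, truth = pa.generate_families(
    mothers, pa.FamilyDesign(), 0.6, freqs,
    pa.NoiseModel(error_rate_epsilon=0.005), seed=2, site="P01")

q = freqs.alt_freqs("P01").to_numpy()
row = fam.entries.iloc[0]
est = pa.mme_selfing(matrix.genotypes.loc[row.mother_id].to_numpy(float),
                     matrix.genotypes.loc[row.progeny_id].to_numpy(float),
                     q, 0.005)
print(round(est.s_hat, 3), round(est.uncertainty, 3), est.n_informative_loci)
print(truth.iloc[0].selfed)
```

prints

```
0.994 0.01 1165
1.0
```

i.e. this first seedling was in fact selfed (`selfed = 1.0`) and the moment
estimator concludes the same (ŝ = 0.994 ± 0.010 from 1165 informative loci).
Averaged over all 51 progeny of the array, the mean ŝ is 0.648 against a
realized selfed fraction of 0.647 under the simulated site-level rate of 0.6.

A full synthetic study (simulate → filter → popgen → mating system →
resampling, with every table written as TSV plus a provenance JSON) runs
from a YAML config:

```bash
progarray run-all --config examples/demo.yaml --seed 1 --out demo_out
```

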