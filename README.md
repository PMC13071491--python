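# clinekit

Geographic cline analysis for contact zones along one-dimensional
population transects.

When two formerly separated lineages meet after range expansion — as
the southern and northern recolonization lineages of Norway spruce,
Scots pine and silver birch do across central Sweden — alleles that
differentiate the lineages change frequency across the contact zone.
Loci under divergent selection form *clines*: sharp sigmoid transitions
whose **centre** c marks the position of steepest change and whose
**width** w (the inverse of the maximum slope) reflects the balance of
dispersal and selection, w ∝ σ/√s. `clinekit` turns a VCF plus
population metadata into per-locus cline fits and the downstream
population-genetic quantities built on them. It is aimed at population
geneticists analysing transect-design resequencing data, and ships a
synthetic transect generator so every stage can be exercised and
validated without any external data.

## What it computes

* **Cline fitting** — four Szymura–Barton models per SNP (sigmoid with
  fixed or free end frequencies; stepped versions with exponential
  tails), by seeded multistart bounded maximum likelihood on the
  binomial count likelihood
  P(x) = pmin + (pmax − pmin)/(1 + exp(−4(x − c)/w)).
* **Model choice** — AICc (n = populations), Akaike weights, and the
  evidence ratio exp((AICc_null − AICc_best)/2) against a uniform-
  frequency null; residual standard errors as fit diagnostics; explicit
  exclusion of linear gradients that have no cline centre.
* **Clinal classification** — outlier rule: a locus is clinal when its
  evidence ratio exceeds the 99th percentile of the genome-wide
  distribution.
* **F_ST and isolation by distance** — Weir–Cockerham θ from allele
  counts (pairwise matrix, ratio-of-averages), OLS of F_ST/(1−F_ST) on
  ln(geodesic km), Mantel permutation test, and neighbourhood size
  N_S = 1/slope as a dispersal proxy.
* **Enrichment** — upper-tail hypergeometric test of externally derived
  candidate-SNP sets for clinal alleles, against a background matched on
  end-frequency difference, Bonferroni-adjusted.
* **Environmental clines** — the same model ladder fitted (Gaussian
  likelihood) to 19 min-max-normalized bioclimatic variables.
* **Selection strength** — s = N_S/w² per clinal candidate locus, from
  migration–selection balance.

See `docs/methods.md` for the models, estimators and numerical choices.

## Worked example

Simulate a 400-locus transect dataset (12 populations over 1,400 km,
15 diploids each, five true clinal loci among linear, flat and
spatially autocorrelated neutral loci), run the full pipeline, and
compare calls against the simulation truth:

```python
import pandas as pd
from clinekit import SimConfig, simulate_dataset
from clinekit.cli import RunConfig, run_pipeline

cfg = SimConfig(seed=42, n_clinal=5, n_linear=10, n_flat=135, n_ibd_neutral=250)
paths = simulate_dataset(cfg, "example")
rc = RunConfig(vcf=str(paths["vcf"]), popmap=str(paths["popmap"]),
               geometry=str(paths["geometry"]), env=str(paths["env"]),
               outdir="example_run", seed=7)
res = run_pipeline(rc)

ibd = res["ibd"]
print(f"IBD slope = {ibd.slope:.4f} per ln(km); N_S = {ibd.n_s:.1f}")
print(f"Mantel rho = {ibd.mantel_rho:.3f} (p = {ibd.mantel_p:.4f})")
```

prints

```
IBD slope = 0.0219 per ln(km); N_S = 45.7
Mantel rho = 0.948 (p = 0.0001)
```

— genetic and geographic distance are strongly correlated, and the
inverse regression slope gives the neighbourhood size used later for
selection estimates. The clinal calls and fitted parameters:

```
clinal calls: 4 of 400 loci; true classes: ['clinal']
fitted clinal loci (best model, centre km, width km):
  chr1:1000: I  c = 717  w = 369
  chr1:3000: I  c = 630  w = 344
  chr1:4000: I  c = 682  w = 169
  chr1:5000: I  c = 734  w = 377
selection coefficients: 3.35e-04, 3.87e-04, 1.61e-03, 3.22e-04
```

Four of the five true clines exceed the 99th-percentile evidence-ratio
threshold (the outlier rule caps the clinal set at ~1% of loci); every
call is a true cline, centres cluster around the simulated contact zone
(550–750 km), and the implied selection coefficients fall in the weak
range (10⁻⁴–10⁻³) expected for clines a few hundred km wide at this
neighbourhood size.

The same run is available from the shell:

```sh
clinekit simulate --outdir example --seed 42 --n-clinal 5 --n-linear 10 --n-flat 135 --n-ibd-neutral 250
clinekit run-all --vcf example/transect.vcf --popmap example/popmap.tsv \
    --geometry example/geometry.tsv --env example/environment.tsv \
    --outdir example_run --seed 7
```

Every stage writes flat TSVs (`counts.tsv`, `fst.tsv`, `ibd.tsv`,
`clines.tsv`, `clinal_calls.tsv`, `enrichment.tsv`, `env_clines.tsv`,
`selection.tsv`) plus a `manifest.txt` recording configuration and
seeds; each stage can also be rerun in isolation via the `counts`,
`fst`, `ibd`, `clines`, `classify`, `enrich`, `envclines` and
`selection` subcommands.

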