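# kelpshift

Did past climate-driven range shifts structure today's intraspecific genetic
diversity? `kelpshift` implements, end to end, the analysis pipeline used to
ask that question for giant kelp (*Macrocystis pyrifera*): a species
distribution model (SDM) hindcast from the present to the Last Glacial
Maximum (LGM, ~20 kyr ago) identifies glacial refugia and range shifts, and
microsatellite population genetics tests whether diversity is higher and
more endemic inside those refugia than along post-glacial expansion fronts.

It is written for molecular ecologists and biogeographers who want a tested,
scriptable version of this workflow — exercised on synthetic landscapes and
genotypes with planted ground truth, so every estimator can be validated
without downloading the original data.

## What it computes

**Distribution track** (`kelpshift.sdm`)

- Boosted regression trees (Bernoulli deviance, xgboost backend) of
  presence vs pseudo-absence with hard monotone constraints: responses
  non-increasing in maximum temperature and ice thickness, non-decreasing
  in nutrients, salinity and minimum temperature.
- Spatial thinning below the correlogram-derived autocorrelation distance
  (Moran's *I* per distance class, permutation significance).
- Tenfold cross-validation over independent latitudinal bands to select
  hyper-parameters (trees 50–1000, complexity 1–6, learning rate
  0.01/0.005/0.001), reporting AUC and sensitivity.
- Relative predictor contributions by deviance-explained increments,
  stepwise parsimony reduction, and physiological tolerance limits read off
  partial response curves at the max-sensitivity+specificity threshold τ.
- Binary present/LGM surfaces, per-region range-shift areas
  ((present − LGM)/present × 100, areas in 10³ km²), the refugium raster,
  and Schoener's D niche overlap.

**Genetics track** (`kelpshift.popgen`, `kelpshift.allele_network`,
`kelpshift.structure_summary`)

- Unbiased gene diversity He = n/(n−1)·(1 − Σp²); rarefied allelic richness
  Â and rarefied private alleles PÂ at a common gene-copy size *g*, by
  Monte-Carlo subsampling (default 10⁴ randomisations) with the closed-form
  hypergeometric expectation E[Â] = Σᵢ(1 − C(n−Nᵢ, g)/C(n, g)) as oracle.
- Jost's D between sites or clusters (Nei–Chesser-corrected Hs/Ht,
  k/(k−1) factor, arithmetic mean over loci).
- A shared-allele site network: per-locus Jaccard similarity, a percolation
  threshold scan maximising modularity Q under leading-eigenvector
  communities, a 10⁴-permutation significance test for Q, and eigenvector
  centrality with >95th-percentile hubs.
- Evanno ΔK = mean|L″(K)|/sd(L(K)) model choice for external Bayesian
  clustering runs, admixture flagging, and the two-step hierarchical
  clustering bookkeeping.
- The refugium join: great-circle distance from each site to the nearest
  predicted refugial cell, binned diversity summaries, and a Spearman
  monotone-trend test.

**Synthetic data** (`kelpshift.synthdata`) generates the whole study as a
planted-truth simulation: co-registered present/LGM predictor stacks on a
two-terrace shelf (glacial shoreline at the −120 m isobath), occurrences
from a known niche, hierarchically clustered Dirichlet-multinomial
microsatellite genotypes with refugial private alleles and a founder-effect
allele-pool truncation, and clustering-run log-probability tables.

## Worked example

```python
from kelpshift import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=7, outdir="runs/demo"))
for stage in manifest["stages"]:
    print(stage)
```

prints (timings machine-dependent):

```
{'stage': 'landscape', 'seconds': 0.006, 'cells': 5248}
{'stage': 'occurrences', 'seconds': 0.007, 'records': 800}
{'stage': 'pruning', 'seconds': 1.312, 'kept': 122, 'pruning_km': 55.66}
{'stage': 'pseudo_absences', 'seconds': 0.004, 'presences': 122, 'absences': 122}
{'stage': 'sdm_fit', 'seconds': 12.888, 'predictors': 4, 'cv_auc': 0.7633962684489}
{'stage': 'predict', 'seconds': 0.011, 'present_cells': 664, 'lgm_cells': 278}
{'stage': 'sites', 'seconds': 0.004, 'sites': 40}
{'stage': 'range_report', 'seconds': 0.004, 'refugium_cells': 278}
{'stage': 'genotypes', 'seconds': 0.265, 'individuals': 1200}
{'stage': 'popgen', 'seconds': 0.649, 'sites': 40}
{'stage': 'network', 'seconds': 2.337, 'communities': 7, 'modularity': 0.6433487147088524, 'p_value': 0.0004997501249375312}
{'stage': 'structure', 'seconds': 0.052, 'selected_k': 2}
{'stage': 'refugia_join', 'seconds': 0.051, 'rho_A_hat': -0.6844456118030181, 'rho_PA_hat': -0.7073865054442531}
```

Reading the output: the hindcast contracts the range toward low latitudes
(278 of 664 suitable cells remain at the LGM — those cells are the
refugia); the Evanno criterion recovers the two planted main clusters
(`selected_k: 2`); the site network is significantly modular
(p ≈ 5·10⁻⁴); and both rarefied allelic richness (ρ ≈ −0.68) and private
alleles (ρ ≈ −0.71) decline with distance to the nearest refugium — the
planted founder-effect signature, recovered by the full chain. Per-site
tables, rasters (plain-text ESRI ASCII grids), the range report and a
checksummed manifest land in `runs/demo/`.

The same pipeline is available from a shell:

```bash
kelp demo-config --out run.yaml --seed 7 --outdir runs/demo
kelp run --config run.yaml
kelp popgen --genotypes runs/demo/genotypes.csv --reps 10000 --out diversity.csv
kelp network --genotypes runs/demo/genotypes.csv --n-perm 10000 --seed 7 --out net.csv
kelp structure --runs runs/demo/structure_runs.csv
kelp validate runs/demo/genotypes.gen --kind genepop
```

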