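# Methods

This note documents the models implemented in `kelpshift`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that shape the results.

## 1. The scientific procedure

The package couples two independent lines of evidence about glacial range
dynamics:

1. **Hindcast distribution modelling.** A presence/pseudo-absence
   classifier fitted on present-day benthic predictors is projected onto
   Last Glacial Maximum (LGM) climatologies with a displaced shoreline
   (sea level −120 m). Cells predicted present at the LGM are *glacial
   refugia*; the per-region area difference between the two binary maps is
   the range shift.
2. **Population-genetic diversity.** Standardised (rarefied) allelic
   richness, private alleles, gene diversity, Jost's D and a shared-allele
   network are computed from diploid microsatellite genotypes. Under
   post-glacial expansion, serial founder effects predict lower and less
   endemic diversity with increasing distance from refugia; the package
   tests this with a Spearman monotone-trend statistic on the per-site
   distance to the nearest refugial cell.

## 2. Distribution model

**Learner.** Gradient-boosted regression trees on Bernoulli deviance
(xgboost). "Tree complexity" maps to maximum tree depth. Monotone response
constraints are hard model constraints, not post-hoc checks: non-increasing
in maximum temperature and ice thickness (disturbance/physiological upper
limits), non-decreasing in minimum temperature, nitrate, phosphate and
salinity (resources/physiological lower limits). A finite-difference scan
of every partial response is asserted in the tests all the same.

**Cross-validation.** Folds are ten equal-count latitude quantiles of the
combined presence/pseudo-absence records, so each held-out fold is a
spatially independent band; this deliberately measures transferability
rather than interpolation, and CV AUC is accordingly lower than a random
split would give (~0.7–0.8 on the demo landscape vs ≈1.0 in-band).
Hyper-parameter selection maximises mean held-out AUC; ties prefer fewer
trees, lower complexity, then higher learning rate. The full search grid
(trees 50–1000 step 50, complexity 1–6, learning rate 0.01/0.005/0.001;
`full_hyper_grid()`) is available; `default_hyper_grid()` scans a 6-point
sub-grid (trees {500, 1000} × depth {1, 2, 3} × rate 0.01) so a
cross-validated search stays interactive on one CPU. Folds in which one
class is absent are skipped (more than two such folds abort the fit).

**Thresholding.** τ is the score maximising sensitivity + specificity over
the unique candidate scores; ties resolve to higher sensitivity, then
lower τ. CV sensitivity uses each fold's own τ.

**Contributions, parsimony, tolerance limits.** A predictor's contribution
is the increase in training deviance explained (1 − D_model/D_null) when it
is added to the model of all remaining predictors, floored at 0 and
rescaled to 100%. The stepwise reduction removes the least-contributive
predictor while the reduced model's deviance explained stays within 1e-6 of
the full model's. Tolerance limits are read off 512-point partial response
curves (other predictors at their record means) where the response crosses
τ, with linear interpolation; the upper crossing is reported for
negative-monotone predictors (a tolerance maximum), the lower crossing for
positive-monotone ones. A curve that never crosses τ reports the range
boundary with a flag.

**Spatial thinning.** Moran's *I* of every predictor over record pairs is
evaluated per great-circle distance class (default width: twice the cell
size) with one-sided significance from 199 value permutations at α = 0.05,
uncorrected. The pruning distance is the upper bound of the first class in
which no predictor is significantly positively autocorrelated; if every
tested class is significant, the maximum tested distance is used and a
warning issued. Thinning then visits records in seeded random order and
keeps a record only if no kept record lies within the pruning distance.
Note that on a landscape dominated by a smooth monotone gradient the
fallback is the *expected* outcome — neighbour similarity relative to
global variance stays high at every tested lag — so the demo pipeline caps
the scanned range at two one-cell classes (~56 km) to bound the fallback
distance at a workable record density. Note also that the per-predictor
false-positive rate of 5% compounds across predictors (no multiplicity
correction), so null-calibration statements hold per predictor.

**Areas and overlap.** Cell area is (resolution · 111.32 km)² · cos(lat).
The range-change convention is (present − LGM)/present × 100, which
reproduces the published all-region (+40.12%) and per-region values from
the printed areas. Schoener's D normalises each suitability surface to sum
to one over the shared valid cells and reports 1 − ½Σ|p_a − p_b|.

## 3. Genetic statistics

**Gene diversity.** He = n/(n−1)·(1 − Σp²) per locus on gene copies
(n = 2 × typed individuals), averaged over typed loci.

**Rarefaction.** Â at gene-copy size *g* is the expected number of distinct
alleles in a size-*g* subsample without replacement, averaged over loci —
by multivariate-hypergeometric Monte Carlo (default 10⁴ randomisations) or
by the closed form E[Â] = Σᵢ(1 − C(n−Nᵢ, g)/C(n, g)), which the tests use
as an oracle (agreement within 0.05 at 10⁴ reps). PÂ counts only alleles
observed at no other site in the comparison set (global privacy; the
comparison set is configurable). The default *g* is the floor of the
minimum over sites of the mean usable gene copies per locus, where
site × locus cells with ≤ 10 copies are ignored as too small to inform the
standardisation, and cells with n < g are excluded with a warning.

**Jost's D.** Per locus, for two groups with gene-copy counts n₁, n₂ and
harmonic mean ñ: Hs = ñ/(ñ−1)·(1 − mean Σp²), Ht = 1 − Σp̄² + Hs/(2ñ),
D = (Ht − Hs)/(1 − Hs) · 2. Loci monomorphic for the same allele in both
groups are undefined and dropped from the mean; negative estimates are
clamped to zero (the identity case D = 0 therefore holds after clamping,
as the unbiased estimator is slightly negative on identical finite
samples). The multi-locus default is the arithmetic mean over loci; a
variant from loci-averaged (Ht − Hs) and (1 − Hs) components is exposed as
`multilocus="pooled"`.

**Shared-allele network.** Edge weight = mean over commonly typed loci of
the Jaccard index of allele sets (a frequency-weighted variant is a flag).
The percolation scan keeps edges with weight ≥ t for every unique weight t,
runs leading-eigenvector community detection, and retains the network with
maximal modularity Q (ties → lower threshold, i.e. more edges). Leading
eigenvector is recursive spectral bisection of the (generalised) modularity
matrix with single-node fine-tuning, splitting only while the leading
eigenvalue is positive and Q strictly increases; on graphs of ≤ 8 nodes it
is within 0.02 of the exhaustive partition optimum. The permutation test
shuffles node labels (preserving community sizes) and reports
p = (1 + #{Q_perm ≥ Q_obs})/(1 + n_perm). Eigenvector centrality is power
iteration (tolerance 1e-10, ≤ 10⁴ iterations) per connected component with
global max-normalisation; hubs are nodes strictly above the 95th
percentile, so an all-tied graph has no hubs.

*Known behaviour:* maximising Q over thresholds is degenerate on noisy
similarity matrices — fragmenting the graph into many small components
raises Q toward 1 − 1/k — so on realistic genotype data the selected
network can be fragmented (this is logged). Connectivity is deliberately
not enforced. The planted-cluster recovery guarantees hold for similarity
structures with near-tied within-cluster weights and clearly lower
between-cluster weights.

**Evanno ΔK.** ΔK = mean|L″(K)|/sd(L(K)) with L″ computed per replicate
(L(K+1) − 2L(K) + L(K−1)) when replicate ids align across K, else from the
per-K means; requires ≥ 3 consecutive K and ≥ 2 replicates. A zero
replicate sd yields an infinite sentinel with a warning; exactly linear
per-replicate tables give ΔK = 0 everywhere and an "ambiguous" flag. ΔK is
invariant under adding a constant to every lnP. Site assignment is the
argmax of mean membership; a site is admixed when its maximum mean
membership falls below 0.7 (not stated by the original workflow;
configurable). The two-step workflow writes per-group GenePop subsets with
admixed sites removed and joins the two levels into final labels.

## 4. The synthetic study system

The generator plants every signal the estimators are asked to recover and
is a pure function of configuration + seed.

- **Landscape.** A meridional coastline, 14–55° N × 8° of longitude at
  0.25° resolution. Bathymetry is a two-terrace shelf: a gentle present
  shelf (0 to −30 m over ~2°), a scarp to −120 m, a glacial terrace
  (−120 to −150 m, the habitat band once sea level drops 120 m), then deep
  ocean — so both periods have a ~2°-wide 30 m-depth habitat band.
  Maximum temperature falls linearly with latitude (34 − 0.5·lat °C),
  minimum temperature is 8 °C lower, nutrients increase poleward, salinity
  is nearly uniform, ice is absent below 58° N. Gaussian measurement noise
  (σ = 1 °C on temperatures, 0.01 on the others) provides within-band
  predictor variance.
- **Niche truth.** Suitable = max temperature ≤ 24 °C, min temperature
  ≥ 3 °C, phosphate and nitrate ≥ 0.01 mmol m⁻³, salinity 20–45,
  ice ≤ 0.16 m. Temperature binds at both range edges.
- **Glacial anomalies.** Additive offsets: −2 °C on maximum temperature
  (the tropical-anomaly scale), −6 °C on minimum temperature (steeper
  glacial meridional gradient at the poleward edge), +0.05 m ice. The
  resulting ~50% latitudinal contraction of the suitable band is the
  planted range shift; offsets are strictly additive (no clamping), so the
  identity "LGM = present + offsets" holds exactly.
- **Sites and genotypes.** Sites sit on the innermost habitat cell of
  evenly spaced suitable latitudes (a 1-D coastline embedded in the grid).
  A site is refugial when its latitude band stayed suitable at the LGM
  (cross-shore displacement of the glacial shoreline must not disqualify a
  persistent latitude). Allele frequencies follow a hierarchical Dirichlet
  model: level-1 clusters diverge from an ancestral vector with
  concentration 0.3·A (giving between-cluster Jost's D ≈ 0.6–0.7, the
  scale observed between hemispheric kelp clusters), level-2 clusters
  diverge from their parent with concentration 10·A. Refugial sites carry
  2 private alleles per locus (6% total mass); non-refugial sites keep the
  top max(2, round(A·e^(−0.003·d))) alleles by frequency for distance d km
  to the nearest refugial site — truncation, not rescaling, so private
  alleles are lost first and the distance decay of PÂ is guaranteed in
  expectation. Defaults: 40 sites × 30 diploids × 6 loci, pool A = 20,
  2% missing data coded "000".
- **Clustering runs.** Mean lnP rises by 50 per cluster up to the true K
  and by 1 beyond it, with i.i.d. Gaussian replicate noise (σ = 2); at
  these defaults ΔK recovers the true K in ≥ 95% of seeds.

**What the generator does not emulate** — and therefore what green tests do
not demonstrate about real data: coalescent genealogies (no mutation-model
fidelity, linkage, or drift dynamics), spatially autocorrelated *noise*
fields (noise is white), realistic coastline geometry or 2-D connectivity,
rafting dispersal, admixture gradients, and genotyping artefacts beyond
uniform missingness. The planted-truth tests validate the estimators, not
the biology.

## 5. Pipeline, scaling and determinism

`run_pipeline` executes landscape → occurrences → thinning →
pseudo-absences → CV fit (+ stepwise, contributions, limits) → present/LGM
prediction → range report and refugium raster → sites/genotypes →
diversity, Jost's D, network, ΔK → refugium join, writing every artifact
into a SHA-256-checksummed manifest with a JSON-lines log. The global seed expands into
per-stage seeds as SHA-256("seed:stage") mod 2³¹, so stages are
independently reproducible; reruns are bit-identical.

Demo problem sizes (800 occurrence records thinning to ~120, 40 sites × 30
individuals, 2 × 10³ rarefaction randomisations and network permutations, a
6-point hyper-grid) keep a full run under a minute on one CPU; the
statistics they feed are the same code paths as the full-size settings
(10⁴ randomisations, the complete hyper-grid), which remain available
through configuration.

Rasters are written as plain-text ESRI ASCII grids (north-up, cell-centre
registration, ocean mask as a 0/1 layer); genotypes as GenePop (3-digit
codes, "Pop" blocks, comma after the individual id) and a long-format CSV;
distances are great-circle (haversine) kilometres on WGS84 decimal degrees.

## 6. Limitations

- The hindcast refugium raster inherits all threshold-transfer brittleness
  of binary SDM projection; with few training records the LGM map can be
  sparse or empty, and the refugium–diversity trend correspondingly noisy.
  The demo sizes were chosen so this chain is stable across seeds, but
  individual stages (especially band-CV hyper-parameter selection) remain
  the dominant source of run-to-run variance.
- Percolation by Q-maximisation fragments noisy networks (see §3).
- The rarefied private-allele statistic uses global privacy; within-cluster
  privacy changes the numbers and is available via `comparison_sites`.
- Real-data reproduction (the deposited genotype/occurrence/climate bundle)
  is supported by the readers and statistics but is not exercised by the
  test suite, which is fully synthetic.
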