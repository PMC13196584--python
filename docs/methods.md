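# Methods note

This note records the statistical model behind `magcsr`, the exact
numerical conventions used, the scope of the synthetic-community
generator, and known limitations. Every quantitative statement here is
either a definition or a property exercised by the test suite /
`scripts/acceptance.py`.

## 1. Study design

A disturbance-frequency gradient with six levels (frequencies 0, 1/8,
1/6, 1/4, 1/2, 1 — the fraction of days a disturbance is applied), five
independent replicates per level, analysed at a fixed sampling day
(default 42). Levels map to three regimes:

| regime | levels | hypothesised strategy |
|---|---|---|
| undisturbed | 0 | C (competitor) |
| intermediate | 1–4 | R (ruderal) |
| press | 5 | S (stress-tolerant) |

`DisturbanceDesign` carries frequencies, the level→regime map,
replicate count, and day; `default_design()` gives the configuration
above (30 samples).

## 2. Feature classification (CSR assignment)

For each feature (genome relative abundance, or CAT trait value) and
each regime, the enrichment statistic is

T = mean(feature in regime) − mean(feature outside regime).

`regime_enrichment_test` recomputes T under `n_sim` random permutations
of the sample→regime labels (default 9999, vectorised) and reports the
one-sided enrichment p-value with the add-one convention

p = (#{T_perm ≥ T_obs} + 1) / (n_sim + 1),

ties counting as exceedances, so p is never 0 and the test is exact for
exchangeable nulls. An optional `backend="multinomial"` draws label
permutations with replacement instead; the default permutes labels.
All p-values in the feature × regime family are corrected together by
Benjamini-Hochberg FDR (`statsmodels.stats.multitest`, `q_enrich`).

`assign_strategy` labels each feature with the letters of every regime
whose q ≤ α (default α = 0.05): `C`, `R`, `S`, compound labels `CR`,
`CS`, `RS`, `CRS` for multiple significant regimes, `unassigned` for
none. Letters within a compound label are reported in canonical C-R-S
order.

Calibration properties (tested): with no planted effect the fraction of
features receiving any label at α = 0.05 is small (≤ 0.07 in the
acceptance run) and the enrichment p-values are uniform (KS test);
on a 3+3-sample toy the Monte-Carlo p matches exact enumeration of all
20 assignments.

## 3. Community-aggregated traits (CATs)

Per-genome trait profiles are gene counts in 19 COG single-letter
functional categories (C D E F G H I J K L M N O P Q T U V Z).
Multi-letter annotations are aggregated per gene either as one count
per letter (`full`, default) or 1/k per letter (`fractional`).
`normalize_traits` converts counts to per-genome fractions;
`quality_filter` keeps genomes with completeness ≥ 50% and
contamination ≤ 10%.

The CAT of sample s for trait t is the abundance-weighted community
mean

CAT(s, t) = Σ_g p(s, g) · f(g, t),

with p the relative abundance and f the genome's trait fraction. CATs
are linear in p, convex (bounded by the per-genome extremes), and rows
of the CAT matrix sum to 1. For display along the gradient,
`zscore_level_means` standardises level means by the across-sample mean
and standard deviation (ddof = 1); constant traits are flagged and
zeroed rather than divided by 0.

`genome_size_welch_anova` compares genome size across the C/R/S groups
with Welch's heteroscedastic one-way ANOVA (Satterthwaite denominator
degrees of freedom); it matches `pingouin.welch_anova` exactly in the
tests.

## 4. Distance-based multivariate statistics

All procedures operate on square-root Bray-Curtis dissimilarities:
counts → relative abundances → square root → Bray-Curtis
(`scipy.spatial.distance`). `DistanceMatrix` validates symmetry and a
zero diagonal.

- **PCoA** — Gower-centred matrix G = −½·C·D²·C eigendecomposed with
  `scipy.linalg.eigh`; negative eigenvalues are retained and their axes
  kept separately (no Lingoes/Cailliez correction).
- **PERMANOVA** — one-way fixed-factor pseudo-F on squared
  dissimilarities (SS_total = Σ d²/N; within-group SS per group divided
  by group size), p by unrestricted permutation of group labels with
  the add-one convention above. Matches scikit-bio's statistic to
  1e-10 and exact enumeration on small instances in the tests.
- **PERMDISP** — per-sample distance to its group centroid in PCoA
  space with the negative-eigenvalue correction (squared centroid
  distance = real-axis contribution − imaginary-axis contribution,
  floored at 0), one-way F on those distances, p by permuting the
  distances across groups. The F statistic matches vegan's
  `betadisper(type="centroid")` exactly, and per-dataset p-values match
  vegan's `permutest` within Monte-Carlo noise. Note a finite-sample
  property of the method itself (shared with vegan): because distances
  are taken to *estimated* centroids, the test is mildly liberal for
  very small groups (measured true level ≈ 0.056–0.06 at 10 samples
  per group) and reaches the nominal 0.05 from about 20 samples per
  group — the regime used by the calibration tests.
- **CAP** — canonical discriminant analysis (LDA) on the first m PCoA
  axes; when m is not given it is chosen to maximise leave-one-out
  allocation success (ties broken toward the smallest m). Returns
  canonical scores and the LOO success rate.
- **DistLM** — for a predictor subset X with intercept, the explained
  sum of squares is tr(H·G) with H the (pseudoinverse) hat matrix of X;
  R² = tr(HG)/tr(G). Model selection is bidirectional stepwise search
  minimising small-sample AICc in the form
  AICc = N·ln(SS_res/N) + 2v·N/(N − v − 1),
  with v = number of fitted predictors + intercept; only strict
  decreases are accepted, so the step trace is strictly decreasing and
  the search terminates. With Euclidean distances from a univariate
  response, R² equals the OLS R² to 1e-8 (tested each build).
- **dbRDA** — eigendecomposition of H·G·H for the selected predictors;
  axis variation is reported as a percent of fitted variation and of
  total variation (the percent-total sum equals the DistLM R²).
- **Vector overlays** — Pearson correlations of each variable with the
  first two ordination axes; a vector is drawn when the 2-axis vector
  norm √(r₁² + r₂²) ≥ r_min (default 0.20). Constant variables are
  excluded.
- **UPGMA similarity clusters** — average-linkage clustering of the
  dissimilarity matrix cut at similarity `threshold`% (default 85),
  i.e. distance 1 − threshold/100.

## 5. Co-occurrence network

`sparcc_correlations` estimates basis correlations from compositional
counts (SparCC): counts + 0.5 are resampled as Dirichlet fractions
(default 20 resamples), the log-ratio variation matrix
t_ij = var(log x_i/x_j) is inverted for basis variances under the
sparsity approximation, the strongest correlated pair is iteratively
excluded (threshold 0.1, up to 10 iterations), and the median over
resamples is returned with a unit diagonal. Requires ≥ 4 genomes, all
present in at least one sample. Estimates are invariant to per-sample
depth rescaling (tested) because only log-ratios enter.

`build_network` keeps edges with correlation ≥ r_min (default 0.20,
boundary inclusive; `positive_only=False` switches to |r|). Louvain
modules come from `networkx.community.louvain_communities` (seeded);
Newman's modularity Q is reported (two disconnected unit triangles give
Q = 0.5 exactly). `module_regime_association` maps each module to the
regime with the highest mean summed relative abundance of its members,
flagging exact ties (broken in regime order).

## 6. Synthetic-community generator

The generator plants known CSR structure so the full chain can be
validated against ground truth.

- **Genomes** — configurable counts per strategy (default 15 C / 15 R /
  15 S / 15 neutral). Trait profiles: per-genome gene totals uniform in
  1800–4200 distributed over the 19 categories from a uniform baseline;
  a strategy's linked categories (C: Q I V E M; R: K P E M;
  S: F D L T J V — so V is shared by C and S, E and M by C and R) are
  boosted by ×(1 + trait_effect), default trait_effect = 2, then
  renormalised. Genome sizes are log-normal per strategy with
  parameters calibrated so a Welch ANOVA on them is non-significant at
  defaults.
- **Abundances** — expected abundance of genome g in sample s is
  base_g · exp(fitness_effect · match(g, s)), where match is 1 when the
  sample's regime favours the genome's strategy; base_g is log-normal
  (σ = 0.5). Sample compositions are Dirichlet(concentration · p)
  draws (concentration 200) and counts are multinomial at log-normal
  depth (mean 2×10⁴, CV 0.3). fitness_effect = 0 gives a fully
  exchangeable null (tested: PERMANOVA non-significant, enrichment
  p-values uniform).
- **Function metrics** — regime-dependent Gaussian metrics
  (TKN_removal, neg_SVI, effluent_NO3, effluent_PO4, total_alkalinity,
  COD_removal) for overlay demonstrations.
- **Seeding** — every stage draws from a child of
  `numpy.random.SeedSequence(seed)` with a stage-specific spawn key, so
  a single integer seed reproduces the whole bundle bit-for-bit.

Scope: the generator emulates the *design* (6 × 5 gradient, 19-category
profiles, strategy-dependent fitness, compositional counts at variable
depth, regime-correlated metrics). It does not model taxonomy,
phylogenetic correlation among genomes, temporal dynamics within the
experiment, or sequencing error; planted effects are exchangeable
within regimes by construction.

## 7. Numerical conventions

- Permutation p-values always use the add-one convention and a 1e-12
  tie tolerance; they are never 0 and are reproducible bit-for-bit
  given seed and n_perm.
- Rarefaction subsamples without replacement via
  `numpy.random.Generator.multivariate_hypergeometric` (default depth
  5089 reads); samples below depth are dropped with a logged warning;
  samples exactly at depth are returned unchanged.
- Written tables are tab-separated with floats at 10 significant
  digits; pipeline reports contain no timestamps, so identical
  config + seed gives byte-identical output trees.
- Eigen-decompositions use `scipy.linalg.eigh` on symmetrised
  matrices; hat matrices use pseudoinverses, so collinear (e.g.
  duplicated) predictors are handled without error.

## 8. Limitations

- One-way fixed-factor designs only; no nested or multi-factor
  PERMANOVA, no repeated-measures structure across days.
- PERMDISP's finite-sample level is above nominal for very small
  groups (see §4); interpret dispersion p-values cautiously below
  ~20 samples per group.
- The enrichment test assumes samples are exchangeable within regimes
  under the null; replicate-level pseudoreplication is not modelled.
- SparCC's sparsity approximation degrades in strongly coupled
  communities (many true correlations); the planted-recovery test uses
  a single correlated pair among independent genomes.
- CAT analysis inherits the compositional nature of relative
  abundances; trait fractions per genome are treated as error-free.
- No NMDS and no plotting: ordinations, vectors, and network layouts
  are exported as coordinate tables only.
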