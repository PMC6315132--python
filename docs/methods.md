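# Methods

`phylocomm` infers community-assembly processes for plot-based vegetation
surveys along a stand-age chronosequence, combining phylogenetic-signal
estimation, abundance-weighted diversity metrics, randomization null models,
and a conservatism-aware decision matrix. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Phylogenetic signal: Blomberg's K

For a trait vector *x* over the *n* tips of a rooted, branch-lengthed tree
with Brownian variance–covariance matrix **V** (entries: shared root-to-MRCA
path length), the phylogenetically correct mean is the GLS estimate
â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x. K compares the mean squared error of the tips around
â in ordinary space, MSE₀ = (x−â)ᵀ(x−â)/(n−1), with the error under the
tree's covariance, MSE = (x−â)ᵀV⁻¹(x−â)/(n−1), and scales the ratio by its
Brownian-motion expectation:

    K = (MSE₀/MSE) / [(tr V − n/Σᵢⱼ(V⁻¹)ᵢⱼ) / (n−1)]

K ≈ 1 indicates Brownian evolution on the tree, K ≪ 1 convergent or
tree-independent traits, K > 1 stronger-than-Brownian similarity of close
relatives. K is invariant to affine trait transforms and to global branch
rescaling; on a star tree K = 1 identically (asserted to 1e−10 in the test
suite). Branch lengths are accepted in any nonnegative unit; K and MPD are
length-scale dependent in the sense that *relative* branch lengths matter,
so trees of different calibrations should not be mixed in one analysis.

Significance uses a tip-shuffle permutation test: trait values are permuted
across tips and the observed MSE is compared against the permuted MSEs
(small MSE = good fit to the tree), with the add-one rule
p = (1 + #{MSE_perm ≤ MSE_obs})/(1 + n_perm) so p is never 0. The number of
randomizations is a parameter (default 999, minimum 99); the seed is
required, never defaulted. Singular **V** (e.g. zero-length cherries) gets a
logged ridge of 1e−8 × mean diagonal.

Ancestral states are Brownian-motion ML point estimates: each internal node
u receives the GLS conditional expectation â + c_uᵀV⁻¹(x − â1), where
c_u[i] is the covariance between node u and tip i (depth of their MRCA),
with the GLS prediction variance (including uncertainty in â) reported
alongside. The root estimate equals â; on a star tree it reduces to the
arithmetic mean. No Pagel's λ or OU fitting is attempted.

## Diversity metrics

Within-plot relative covers pᵢ weight all metrics, so any common cover scale
(percent, proportion, raw score) is accepted. Per plot:

* MPD = Σ_{i≠j} pᵢpⱼ d(i,j) / Σ_{i≠j} pᵢpⱼ on patristic distances
  (abundance-weighted mean pairwise distance; self-pairs excluded and the
  weight denominator renormalized accordingly).
* MFD: the same statistic on cophenetic distances of a UPGMA dendrogram
  built from Euclidean distances in z-standardized trait space. Traits are
  standardized because raw units span four orders of magnitude (leaf area in
  mm² against nitrogen content in %); unscaled distances would be dominated
  by the largest-unit trait. A switch (`mfd_mode="euclidean"`) computes MFD
  on the raw Euclidean trait distances instead; the dendrogram-cophenetic
  mode is the default because it mirrors the tree-based MPD construction.
  UPGMA (average linkage) is the linkage default for the same reason: it is
  the ultrametric analogue of the phylogeny in trait space. Ties in the
  linkage order are resolved deterministically by scipy's implementation, so
  outputs are platform-stable.
* CWM = Σ pᵢxᵢ and CWV = Σ pᵢ(xᵢ − CWM)² per trait.

A single-species plot has no pairwise distances: MPD/MFD are reported as
missing (never 0, which would masquerade as extreme clustering), the plot is
excluded from SES summaries, and the exclusion is logged. Species with any
missing trait value are dropped from trait-space computations with a logged
warning, never imputed. Quadrat-level covers, when provided, are averaged
(not summed) per species within a plot to preserve the percent-cover scale.

## Null models, SES, and classification

1. **Taxa shuffle, phylogeny** — per run, one permutation of species labels
   across the tips of the phylogenetic distance matrix, shared by all plots
   (shuffling the labels of the one study-wide tree); MPD recomputed.
2. **Taxa shuffle, trait dendrogram** — the same scheme on
   dendrogram-cophenetic distances; MFD recomputed.
3. **Within-plot abundance shuffle** — per run, each plot's covers are
   permuted among its own present species, traits fixed; CWV recomputed per
   trait, one permutation per run shared across traits.

The species pool for models 1–2 defaults to every species occurring in the
community table (the sampled flora); a narrower pool can be passed
explicitly. SES = (observed − mean(null))/sd(null) with the sample (n−1)
standard deviation; the quantile rank is (#{null < obs} + 0.5·#{null = obs}
+ 1)/(runs + 1), so it lies strictly inside (0, 1). Classification demands
both the sign and the tail: rank < 0.05 with SES < 0 → clustering
(convergence for CWV); rank > 0.95 with SES > 0 → overdispersion
(divergence); everything else random. Records whose sign and tail disagree
therefore fall to random. With 999 runs the nominal one-tailed rates are
49/1000 (lower) and 50/1000 (upper); the test suite checks both against
exact binomial 99% bands over 500 neutrally assembled plots.

An ensemble whose spread is below 1e−10 of its own scale (all permutations
equivalent, e.g. equal abundances or equidistant species) leaves SES
undefined; such records are labelled `undefined`, excluded from averages,
and counted in the provenance record. Default runs = 999, exposed as a
parameter because the number of randomizations behind the study design this
package follows is an assumption, not a given.

## Chronosequence inference

Pattern summaries report, per stand age and metric, the percentage of
defined-SES plots in each pattern (they sum to 100 within rounding) plus the
mean SES. The early-vs-late shift test is a Pearson chi-squared without
continuity correction on the 2 × k table of pattern counts, early = {4, 14}
years and late = {98, 203} years by default (configurable); pattern columns
empty in both groups are dropped to avoid zero expected counts. Group
differences in SES across ages use the tie-corrected Kruskal–Wallis test —
standing in for rank-based one-way ANOVA regression variants, which are
numerically close but not identical — with Dunn's post-hoc z-tests on mean
ranks (tie-corrected variance), unadjusted by default and optionally
Bonferroni- or Benjamini–Hochberg-adjusted.

Process interpretation follows the conservatism-dependent decision matrix.
Each non-random component (phylogenetic pattern, functional pattern, trait
dispersion) votes for a process: with conserved traits, clustering /
convergence vote filtering and overdispersion / divergence vote exclusion;
with convergent traits the *phylogenetic* reading flips (phylogenetic
clustering → competitive exclusion, phylogenetic overdispersion →
filtering) while the functional and dispersion readings keep their sign.
Unanimous votes name the process, no votes is stochastic, disagreement is
ambiguous with the conflicting components listed — the mapping is total over
all label combinations. The trait set is called conserved when a majority of
traits have K ≥ 0.5 with permutation p < 0.05, else convergent; the 0.5 cut
separates the Brownian regime (K ≈ 1) from the convergent regime (K ≪ 1)
with a wide margin on both sides and is configurable. Per-plot CWV patterns
across traits collapse to one dispersion label: any convergence without
divergence → convergence, the reverse → divergence, both or neither →
random.

## Synthetic data

The generator supplies ground truth for every stage; it emulates a regional
understory flora, not any particular dataset.

* **Tree**: Yule (pure birth) with exponential waiting times, default 60
  species, rate 1; ultrametric by construction.
* **Traits**: six continuous traits, Brownian motion (conserved regime,
  K ≈ 1) or clade-crossing optima with attraction noise (convergent regime,
  K ≪ 1). Latent simulated values are mapped affinely onto realistic field
  scales (leaf area ≈ 1900 mm², leaf carbon ≈ 43%, …, with relative spread
  0.15 per latent unit) so generated tables satisfy the same unit-range
  validation as read-in data; the map is affine, hence invisible to K and to
  all z-standardized quantities.
* **Communities**: plots of 6–20 species drawn from the pool under one of
  three kernels — `neutral` (uniform), `filtering` (Gaussian weight on
  distance to a trait optimum; multivariate over the whole standardized
  phenotype by default, because a filter on one of six traits produces only
  a diluted functional-diversity signal; a single-trait mode is available),
  and `limiting_similarity` (sequential assembly rejecting candidates closer
  than a threshold to an accepted species in standardized trait space).
  Default bandwidth 0.5 and strength 1.5 give, respectively, strongly
  clustered and detectably overdispersed functional structure at this pool
  size; thresholds ≳ 1.8 are geometrically infeasible for 20 mutually
  spaced species from a 60-species pool, so oversized limiting-similarity
  draws fall back to the largest feasible richness (the low-level samplers
  raise instead, to keep infeasibility loud). Covers are lognormal(0, 1),
  the standard species-abundance stand-in for percent cover.
* **Chronosequence scenario**: seven age classes (4, 14, 27, 55, 76, 98,
  203 years), twelve plots each. Ages 4–27 are fully neutral; older plots
  are deterministic with probability 0.8, split 80/20 between filtering and
  limiting similarity. These mixture weights make the early→late shift in
  functional patterns detectable by the chi-squared test in ≥ 80% of
  replicate datasets, which is the scenario's design goal: a dataset with a
  known, recoverable shift. All randomness flows from one master seed
  through SeedSequence substreams (tree, traits, one per plot), so any
  single plot is reproducible in isolation.

What the generator does **not** emulate: spatial structure and dispersal
limitation, intraspecific trait variation, observation error in cover
estimates, correlated trait evolution, and richness–age trends. Passing
recovery tests therefore show that the inference chain detects its target
signals under clean conditions, not that field data of this shape will yield
equally clean answers.

## Calibration experiments and problem sizes

`phylocomm.experiments` packages the reproducibility workloads:
`bm_k_calibration` (500 Brownian replicates on a fixed 100-tip tree; mean K
expected in [0.95, 1.05]), `neutral_mpd_calibration` and
`neutral_cwv_calibration` (500 ten-species plots, 999 randomizations each;
significant-tail rates checked against exact binomial 99% bands around the
nominal rates), `kernel_recovery` (200 plots across four independent
tree/trait realizations per kernel; the filter optimum sits at the
trait-space centroid — one filter, one environment, at the canonical
reference point), and `shift_detection_power` (50 replicate default
scenarios). These sizes give stable estimates at interactive runtimes
(seconds to a few minutes on one core); all are parameters, not constants.

## Known limitations

* MFD's dendrogram construction discards within-cluster distance structure;
  the Euclidean mode is provided for sensitivity analysis.
* The taxa-shuffle nulls hold abundances fixed to plot positions, so they
  test species-identity randomness, not abundance structure; the abundance
  shuffle covers the latter for CWV only.
* Kruskal–Wallis is a stand-in for rank-based one-way ANOVA regression
  fits; p-values may differ slightly in small or tie-heavy samples.
* The conservatism call is binary; traits with genuinely mixed regimes are
  forced to the majority label.
* Branch-length units are taken as given; no calibration or rate smoothing
  is performed.
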