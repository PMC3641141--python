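# Methods

This note documents the models implemented in `canopyphy`, the
conventions chosen where the literature is silent, the synthetic data
the tests rely on, and the package's known limitations.

## Data model

A census plot is a rectangular window `(xmin, ymin, xmax, ymax)` in
meters plus a table of stems (`stem_id, species, x, y, dbh`).
Coordinates are continuous; duplicate coordinates for distinct stems are
legal (multi-stemmed recruits) and counted individually.  Two filters
reproduce the usual census analysis variants: a dbh threshold (1 cm for
all stems, 10 cm for the large-stem rerun) and a per-species abundance
threshold (70 individuals for the common-species subset).  The dbh
filter is applied before the abundance count.

A phylogeny is a rooted Newick tree with non-negative branch lengths and
unique tip labels matching species ids; polytomies are allowed.  The
tree is flattened to postorder arrays (parent pointers, edge lengths,
tip-to-root incidence) so diversity metrics and tip-label
randomizations reduce to boolean matrix algebra.

## ISAR and its spatial null

* **Neighborhoods.** Disc membership is closed (`d <= r`).  Richness
  counts heterospecific species only; the focal stem is never its own
  neighbor and conspecifics are excluded by default (`
  include_focal_species=True` reverses this).  Excluding the focal
  species keeps the accumulator/repeller contrast about the *other*
  species rather than conspecific clumping.
* **Edge handling.** The buffer (default 50 m, matching the largest
  radius) applies to focal stems only; neighbors may lie anywhere in the
  window.  No toroidal correction is offered.
* **Radius grids.** ISAR: 1–50 m in 1 m steps.  IPAR: 1–10, 15, 20, 30,
  40, 50 m.
* **Intensity estimate.** Bivariate Epanechnikov kernel
  `k(d) = (2/(π h²))(1 − d²/h²)` for `d < h`, bandwidth `h = 50` m,
  evaluated on a 1 m lattice.  Each point's kernel is renormalized by
  its mass inside the window (switchable), so the surface integrates to
  the stem count; tests check this to ±1%.
* **Null model.** Each of `n_sim` iterations (999 by default) redraws
  exactly the observed number of target-species stems from the fitted
  intensity (a binomial point process — conditioning on the count keeps
  the ensembles comparable), leaves every other stem untouched,
  recomputes eligibility of the relocated stems under the same buffer,
  and records the mean richness curve.  Simulated stems inherit the
  species' median dbh so downstream dbh filters stay consistent.
  Iterations in which no relocated stem is eligible are recorded as NaN
  and ignored (vanishingly rare in realistic plots; logged when an
  entire ensemble degenerates).
* **Designation.** Pointwise two-sided Monte-Carlo test at
  `alpha = 0.05` per radius, no correction across radii: with 999
  simulations, accumulator means the observed value has pooled rank
  ≥ 976 (upper tail p = (1+#{null ≥ obs})/(n_sim+1) ≤ α/2), repeller the
  mirror image.  Ties between observed and null values count against
  significance on both sides, i.e. break toward neutral.  The rank rule
  and the pointwise (rather than simultaneous-envelope) convention are
  package choices — the standard Monte-Carlo test — documented here
  because the designation procedure admits both readings.

The heterogeneous Poisson null is deliberately conservative for sparse
focal species: the kernel concentrates relocated stems near the
species' observed locations, so some of the very structure being tested
leaks into the null.  The power benchmark below quantifies what the
test can still detect.

## IPAR, S.E.S. PD, NRI/NTI

* **Faith's PD** is rooted by default: the minimal spanning subtree
  always connects to the root, so a singleton neighborhood scores its
  root-to-tip path.  `rooted=False` gives the tips-only subtree.  The
  choice only partially cancels in the standardized effect size, so it
  is an explicit, logged parameter.  Empty neighborhoods contribute
  PD 0 and singletons are kept; both situations are visible in the
  output (`obs_pd` of 0, small neighborhoods), since no published
  convention covers them.
* **Null.** Species names are shuffled across *all* tips of the plot
  phylogeny (999 shuffles by default), never across a pooled multi-plot
  tree.  The S.E.S. sign convention is
  `(obs − null mean)/null sd` so positive values mean more phylogenetic
  diversity than expected for the observed richness.
* **Averaging order.** Per-focal PD values are averaged over focals
  first and the average standardized (`average_first=True`).  The
  alternative — standardize each focal, then average the z-scores — is
  implemented and exposed, because "PD of an average individual" admits
  both readings.
* **Degenerate nulls** (sd = 0, e.g. every neighborhood contains all
  species) yield ses = NaN, status neutral, and a flag string.
* **NRI/NTI** use unweighted MPD/MNTD over the status assemblage with
  the same tip-shuffle null (equivalently, random same-sized tip
  subsets): `NRI = −(MPD_obs − mean)/sd`, positive = clustered.  A set
  spanning all tips has zero null variance and returns NaN.

## Phylogenetic signal of status

* **Sankoff parsimony** uses an exact postorder dynamic program under an
  arbitrary cost matrix (unit off-diagonal costs by default for the
  ternary accumulator/repeller/neutral trait, since no costs are
  published for it).  Unscored tips are treated as unconstrained, which
  gives the same minimum as pruning them with the induced subtree.
  Polytomies are handled natively by the recursion.  The permutation
  test re-arrays the observed states across scored tips;
  `p = (1 + #{score_perm ≤ score_obs})/(n_perm + 1)` (999 permutations
  by default).  Unit-cost binary scores are cross-checked against an
  independent Fitch implementation and against R phangorn.
* **Fritz–Purvis D** estimates nodal values by averaging daughter
  values from the tips toward the root and sums the absolute
  sister-clade differences (polytomy daughters folded
  pairwise-sequentially in child order, flagged in the docstring).  The
  observed sum is scaled between the means of 1,000 tip-shuffles
  (prevalence preserved) and 1,000 Brownian-threshold simulations:
  Brownian tip values take independent normal increments with variance
  equal to edge length, thresholded at the rank that reproduces the
  observed prevalence exactly, avoiding prevalence drift.  `p_random`
  is the fraction of shuffle-null sums ≤ the observed sum (evidence
  against D = 1); `p_brownian` the fraction of Brownian sums ≥ observed
  (against D = 0).  Correctness is enforced through the calibration
  anchors (mean D ≈ 1 for shuffled traits, ≈ 0 for Brownian-threshold
  traits, D < 0 for a pure clade) rather than any single printed
  formula.
* When the binary accumulator-vs-repeller trait is formed, neutral
  species are excluded and D runs on the induced subtree of the scored
  species — a documented package default, since the source procedure
  does not state how neutral species were handled.

## Cross-tabulation

The 3×3 contingency of richness status × phylogenetic status at a scale
is tested for independence with Fisher's exact test: the closed-form
two-tailed test when the trimmed table is 2×2, otherwise a seeded
Monte-Carlo exact test (19,999 tables from the null distribution with
fixed margins).  Empty margins skip the test but still emit the table.

## Synthetic data

The generator is first-class, tested code; its defaults define the
study conditions for every calibration result.

* **Forests.** Fixed per-species counts (uniform, default 100 stems, or
  log-series with p = 0.995 for the tropical rank-abundance shape,
  floored at one stem).  Placements: CSR; Thomas clusters (Poisson
  parents at κ = 5·10⁻⁴ /m², Gaussian dispersal σ = 5 m, offspring
  redrawn until inside the window); attraction/repulsion constructed by
  rejection sampling with intensity multiplied (or divided) by a factor
  inside discs of the effect radius around the target species' stems.
  dbh is `1 + lognormal(0.5, 0.7)` cm, so all stems pass the 1 cm
  census threshold with a realistic right-skewed size distribution.
  All samplers condition on exact counts, so tests are not confounded
  by count variance.
* **Canonical attraction benchmark** (`attraction_scenario`): 250×250 m,
  one CSR focal species with 40 stems, 14 species of 80 stems each with
  a 20-fold intensity boost within 10 m of focal stems.  The focal is
  kept sparse deliberately: with a dense focal the attraction discs
  tile most of the window and the engineered effect dilutes itself, and
  the heterogeneous Poisson null (which re-places the focal near its own
  observed pattern) absorbs much of the remaining signal.
* **Trees and traits.** Yule trees via dendropy's birth–death sampler
  (death rate 0, exact tip count, ultrametric).  Binary traits by exact-
  prevalence random permutation or Brownian-threshold simulation.

What the simulator does *not* emulate: environmental covariates and
habitat patchiness (first-order heterogeneity), demographic dynamics,
interspecific clustering beyond the single-target attract/repel
construction, and spatial autocorrelation of dbh.  Passing calibration
tests therefore shows the machinery is correct and calibrated under
known conditions, not that real forests satisfy the null model's
assumptions.

## Problem sizes used in the checks

The statistical checks run at sizes chosen to give stable Monte-Carlo
estimates while keeping the suite quick to iterate on: the D anchors use
100 replicate 64-tip trees with 1,000 permutations per null; the ISAR
type-I benchmark uses a 20-species × 100-stem CSR plot (200×200 m) with
199 null iterations per species; the power benchmark 20 replicates of
the attraction scenario, also at 199 iterations; S.E.S. PD calibration
200 replicates with 199 shuffles.  Production analyses default to the
conventional 999 iterations / 999 shuffles / 1,000 permutations.

## Numerical and implementation notes

* Reproducibility: every stochastic routine takes a seed or numpy
  Generator; the pipeline derives independent per-stage, per-species
  streams from one root seed via `SeedSequence.spawn`, so results are
  bit-identical across reruns and independent of species iteration
  order.  Fixed-seed determinism is asserted end to end in the tests.
* The intensity sampler draws lattice cells by inverse-CDF lookup and
  jitters uniformly within the cell; with 1 m cells the discretization
  is far below the 1 m radius resolution of the analysis.
* Neighborhood queries use a KD-tree per plot with per-species minimal
  neighbor distances, making the richness curve over all radii an
  O(neighbors log neighbors) sort per focal rather than a per-radius
  rescan; exactness against all-pairs scans is asserted in the tests.
* Census CSV parsing uses round-trip float precision so write/read
  cycles are bit-exact.

## Limitations

Rectangular windows only; no abundance-weighted ISAR or PD; no
simultaneous (multiple-testing corrected) envelopes by default — the
per-radius designations inherit the usual pointwise caveat that ~5% of
radii will be flagged for a neutral species; tree construction and
calibration are out of scope (the package consumes a ready Newick
phylogeny); the heterogeneous Poisson null's conservatism for sparse
species is inherent to fitting the intensity from the pattern under
test.
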