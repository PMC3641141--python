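# canopyphy

Spatial and phylogenetic neighborhood analysis of mapped forest census
plots: who accumulates diversity around themselves, who repels it, and
whether that behaviour runs in phylogenetic families.

In a fully mapped plot (every free-standing woody stem ≥ 1 cm dbh
identified and located), the **individual species-area relationship
(ISAR)** of a species is the expected number of *other* species inside
circles of radius *r* centered on an average conspecific individual:

    ISAR(r) = (1/F) Σ_f  S_f(r)

over the F focal stems at least 50 m from the plot edge, where S_f(r)
is the heterospecific richness within distance r of focal f.  Whether
that curve is unusually high or low is judged against a **heterogeneous
Poisson null**: only the focal species' stems are relocated, drawn from
an Epanechnikov-kernel (bandwidth 50 m) estimate of their own intensity,
so habitat structure coarser than 50 m is preserved while fine-scale
interactions are erased.  Per radius, a species whose observed richness
exceeds the upper 2.5% of 999 null curves is an **accumulator**, below
the lower 2.5% a **repeller**, otherwise **neutral**.

The phylogenetic analogue (**IPAR**) replaces richness with Faith's
phylogenetic diversity PD of the neighborhood and uses a compositional
null — shuffling species names across the tips of the plot phylogeny —
to form a standardized effect size:

    S.E.S. PD(r) = (PD_obs(r) − mean PD_null(r)) / sd PD_null(r)

positive when neighborhoods are more phylogenetically diverse than their
richness predicts.  Finally, the package asks whether accumulator /
repeller status itself carries phylogenetic signal, via the Sankoff
parsimony score with a permutation test, the Fritz–Purvis **D
statistic** for the binary accumulator-vs-repeller trait (D = 1 random,
D = 0 Brownian-like, D < 0 strongly conserved), NRI/NTI dispersion of
each status assemblage, and a Fisher cross-tabulation of richness status
against phylogenetic status.

No census data ship with the package; a simulator generates mapped
multispecies plots (CSR, Thomas clusters, engineered attraction or
repulsion with known ground truth), Yule phylogenies and binary tip
traits, so every stage is testable end to end.

## Worked example

```python
import canopyphy as cp

# a 250x250 m plot where 14 species are attracted (20x intensity) to
# within 10 m of the stems of the sparse focal species sp01
plot = cp.generate_forest(cp.attraction_scenario(seed=0))

est = cp.IsarClassifier(n_sim=199, random_state=0).fit(plot, species=["sp01"])
print(est.results_[est.results_.radius_m.isin([2, 5, 10, 20, 40])]
      [["radius_m", "n_focals", "obs_mean_richness", "null_q975", "status"]])
```

```
    radius_m  n_focals  obs_mean_richness  null_q975       status
1        2.0        16             0.8125   0.611325  accumulator
4        5.0        16             5.1875   2.214683  accumulator
9       10.0        16            11.5000   6.505556  accumulator
19      20.0        16            13.1875  12.538811  accumulator
39      40.0        16            14.0000  14.000000      neutral
```

The engineered accumulator is recovered exactly where it was built: the
mean number of heterospecific species around a focal stem (16 eligible
focals) sits far above the null envelope at radii within the 10 m
attraction range, remains slightly elevated at 20 m (discs of nearby
focals overlap), and by 40 m every neighborhood holds all 14 other
species, indistinguishable from the null.

The same estimator API covers the other stages — `IparAnalysis` for
S.E.S. PD, `SankoffSignal` / `DStatistic` for signal — and
`run_pipeline(AnalysisConfig(...))` executes everything (ISAR → IPAR →
NRI/NTI → Sankoff/D → cross-tabulation), writing tidy CSV tables plus a
JSON manifest.  A `canopyphy` CLI wraps simulation, the individual
stages and the full pipeline for shell use.

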