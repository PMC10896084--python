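# detritrace

Source attribution for coral-reef detritus, combining two complementary
lines of evidence:

1. **Stable-isotope mixing.** Detritus sampled from the epilithic algal
   matrix (EAM) is modelled as a convex mixture of candidate sources
   (algae, cyanobacterial mats, fish feces, sponge tissues, water-column
   particulates) in two-tracer (δ¹³C, δ¹⁵N) space, with a Bayesian
   mixing model and an iterative procedure that pools sources whose
   proportion posteriors are too correlated to distinguish.
2. **eDNA metabarcoding post-processing.** Multi-marker (COI, 18S, 16S)
   hit tables are turned into rank-thresholded taxonomic assignments,
   screened against negative controls and a contaminant blocklist,
   tabulated as frequency-of-occurrence per sample type, and compared
   across groups with Jaccard NMDS, PERMANOVA, pairwise PERMANOVA and
   SIMPER.

The package is aimed at trophic ecologists who have isotope measurement
tables and BLAST-style hit exports in hand and want a reproducible,
seeded pipeline from those inputs to posterior source contributions and
community statistics. A synthetic-data module generates both kinds of
input with known ground truth, so every stage is testable without any
sequencing archive or reference database.

## The models

**Mixing model.** For mixture sample *i* and tracer *j*,

    x_ij ~ Normal( Σ_k p_k (μ_jk + c_jk),  Σ_k p_k² (σ_jk² + τ_jk²) + σ_j² )

where *p* is the source-proportion vector on the K-simplex, (μ_jk, σ_jk)
are source means/SDs in ‰, (c_jk, τ_jk) are optional discrimination
offsets (default 0), and σ_j is a per-tracer residual SD. Priors are
p ~ Dirichlet(α = 1) and σ_j ~ half-normal(1‰); sampling is adaptive
random-walk Metropolis on a log-ratio transform (default 10,000
iterations, first 1,000 discarded, thinned by 10). When the largest
absolute posterior correlation between two proportions reaches a
threshold (default |r| ≥ 0.6), those sources are merged at the
raw-sample level and the model is refit, iterating until no pair
exceeds the threshold or only two sources remain.

**Assignment rule.** An ESV's similarity score for a hit is
`identity × coverage / 100`. Walking phylum → species with minimum
scores 85, 90, 90, 95, 98, 99, the top-scoring consistent name is
assigned iff it meets the rank's bar; a tie between distinct names, or a
failed bar, leaves that rank and everything below it undefined. ESVs
detected in a batch's negative control are removed from all samples of
that batch; blocklisted taxa (e.g. *Homo sapiens*) are dropped at any
rank.

**Community statistics.** Presence/absence at a chosen rank (default
order), Jaccard distances, PERMANOVA pseudo-F with whole-row label
permutation (p = (1 + #{F_perm ≥ F_obs}) / (1 + permutations)),
Bonferroni-adjusted pairwise tests, and SIMPER percentage contributions
to mean between-group Bray–Curtis dissimilarity.

## Worked example

```python
import detritrace as dt

scenario = dt.default_isotope_scenario()          # true p = (0.6, 0.2, 0.15, 0.05)
sources, mixtures, truth = dt.generate_isotope_dataset(scenario, seed=1)
summaries = dt.summarize_sources(sources, dt.source_grouping(sources))
spec = dt.spec_from_summaries(summaries, mixtures[["d13c", "d15n"]].to_numpy())
draws = dt.sample_posterior(spec, dt.McmcSettings(), seed=1)
print(dt.posterior_summary(draws)[["source", "mean", "sd"]].round(3))
```

prints

```
  source  mean    sd
   algae 0.575 0.029
  sponge 0.198 0.093
cyanomat 0.129 0.072
plankton 0.098 0.026
```

i.e. the posterior means recover the true shares (0.6, 0.2, 0.15, 0.05)
to within a few percent, with the widths reflecting what two tracers can
resolve among four sources. The scripts in `examples/` walk through each
capability the same way: mixing-model fitting, correlation pooling,
taxonomic assignment, decontamination + frequency tables, and the
community comparison (whose PERMANOVA on the study-shaped synthetic
bundle prints `PERMANOVA F_2,10 = 1.8909, p = 0.026`).

A CLI mirrors the stages for shell use:

```sh
detritrace simulate --seed 7 --out bundle/
detritrace all --bundle bundle/ --out results/ --seed 7
```

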