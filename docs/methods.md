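# Methods

## Isotope preparation

Delta notation is δ = 1000·(R_sample/R_standard − 1) in ‰; the inverse
transform is exact, and the pair round-trips to 1e-12 relative
tolerance. The acidification quality filter removes records whose δ¹³C
is *strictly greater* than the cutoff (default −10‰): incomplete
acidification leaves inorganic carbonate, which drags δ¹³C far above
organic-matter values. "Exceeds" is read literally, so the boundary
value −10.0 is kept; the cutoff is configurable. Records with missing
δ¹³C cannot be evaluated and are kept with a log line.

Source summaries are arithmetic means and sample SDs (n−1 denominator)
per tracer, computed only from QC-passing samples that carry both
tracers. A source with a single member has no sample SD; it receives a
configurable SD floor (default 0.1‰) so the mixing model's variance
stays positive — a real situation, since one field season contributed a
single spongivore-feces replicate. Pooling merges sources by
concatenating their raw member measurements and recomputing, never by
averaging summaries; this makes pooling exactly equivalent to
relabelling the dataset (a property the tests verify).

## Mixing model

Likelihood: x_ij ~ Normal(Σ_k p_k(μ_jk + c_jk), Σ_k p_k²(σ_jk² + τ_jk²)
+ σ_j²) over mixture samples i and tracers j. This is the standard
normal mixing-model family with fixed source moments: source
uncertainty enters through the p²-weighted variance term rather than
through latent per-source means, and discrimination (trophic
enrichment) offsets c, τ default to zero because no detritus-specific
enrichment factors are established — both are configurable.

Priors: p ~ Dirichlet(α), α = 1 by default (uniform on the simplex);
residual SDs σ_j ~ half-normal with scale 1‰, a weakly informative
choice given that tracer measurement and aggregation noise is well
under a permil in this kind of data.

Sampling: the simplex is mapped to K−1 unconstrained additive-log-ratio
coordinates (a softmax with the last coordinate pinned, keeping the
chain identifiable) and σ_j to log-scale; the Dirichlet and half-normal
densities are carried into transform space with their exact
log-Jacobians. The proposal is a joint Gaussian random-walk whose
covariance adapts to the empirical chain covariance (Haario-style,
scaled 2.38²/d) and whose global step size is tuned toward 30%
acceptance with a diminishing (1/(t+10)^0.6) schedule, so adaptation
vanishes asymptotically. Defaults are 10,000 iterations with the first
1,000 discarded *before* thinning by 10, retaining 900 draws. Because
the likelihood depends on the data only through per-tracer sums and
sums of squares, an iteration costs O(J) regardless of the number of
mixture samples. Effective sample sizes are estimated per parameter
(via arviz); a warning is raised below 100.

Degenerate inputs: zero total variance for any tracer is a domain
error; a non-finite posterior at initialization raises immediately with
a hint that data and spec disagree; with zero mixture rows the sampler
returns the prior, a property the tests exploit.

### Identifiability and the pooling loop

With K sources and J tracers the likelihood constrains only J
directions of the (K−1)-dimensional simplex, so for K > J+1 the
posterior spreads along a null direction of the source-mean matrix and
proportion posteriors become correlated. The pooling loop automates the
standard remedy: fit, compute the Pearson correlation matrix of the
proportion draws, and if the largest |r| reaches the threshold merge
that pair (raw-sample level) and refit with all other settings
unchanged. The default threshold is |r| = 0.6, between correlations
weak enough to tolerate and the 0.6–0.75 range at which pooling is
typically applied in practice; it is configurable, ties on |r| break
lexicographically by source name, and the loop stops when no pair
reaches the threshold or only two sources remain (at K = 2 the simplex
forces r = −1, so pooling further would always fire).

The bundled four-source test scenario places its sources so that the
true proportion vector sits at the midpoint of the feasible segment
along the null direction: with a uniform prior the posterior mean then
estimates the truth rather than an arbitrary point of the polytope.
This is the geometry in which "well-separated sources" is a meaningful
recovery claim for K = 4, J = 2; for source layouts without that
property the posterior mean is biased toward the feasible-region
centre, which is exactly the situation the pooling loop exists to
repair.

## Taxonomic assignment

Scores are identity × coverage / 100 on percent scales. Comparisons
use exact decimal arithmetic (`decimal.Decimal` on the two-decimal
inputs), so a hit sitting exactly on a threshold is never misclassified
by binary floating point. Both the e-value cutoff (≤ 0.001) and the
rank thresholds (score ≥ bar) are inclusive, following BLAST convention
and the reading of "minimum score". Assignment walks phylum → species;
at each rank only hits consistent with every shallower assignment are
candidates, the top-scoring name wins, a tie between distinct names
voids the rank, and the first failure truncates all deeper ranks — so
assignments are always lineage prefixes.

Cross-marker consolidation uses union semantics with provenance: a
taxon is detected in a sample if any marker's ESV there assigns to it,
and conflicting species under one genus are both retained as distinct
taxa (markers differ in resolution and reference coverage; a
best-marker-wins rule would hide that). Negative-control screening
interprets "associated samples" as same extraction/PCR batch, supplied
via metadata, matching standard decontamination practice. The taxon
blocklist removes a row when any rank matches a blocked name, so a
genus entry subsumes its species. Name verification runs against an
offline validated-name list only — no network calls — flagging rather
than dropping unless strict mode is requested.

## Community statistics

Presence/absence matrices are built at a stated rank (default order);
detections unassigned at that rank are excluded and counted. Jaccard
distances come from scipy's pdist. PERMANOVA uses the classical
partition of squared distances (SS_total = Σ_{i<j} d²/N within/among
groups), equivalent to the Gower-centred inner-product decomposition,
with whole-row label permutation and the (1 + count)/(1 + permutations)
estimator; 999 permutations by default, and an exact mode enumerates
all label orderings for small designs. F-comparisons in the permutation
count use a 1e-12 tolerance so the identity permutation always counts.
scikit-bio's PERMANOVA serves as an independent cross-check in the test
suite, never as the implementation. Pairwise tests run one PERMANOVA
per group pair on the distance sub-matrix with Bonferroni adjustment by
default (Holm and none are available).

SIMPER decomposes presence/absence Bray–Curtis (≡ Sørensen) between
cross-group sample pairs per taxon and averages; contributions are
reported as percentages of the mean dissimilarity and sum to 100%
within 1e-6. Because an order-level analysis is often summarized at
phylum level, contributions can optionally be rolled up to a higher
rank by summing member taxa using the matrix's lineage table. NMDS is
non-metric SMACOF (iterative majorization with isotonic regression, via
scikit-learn) reporting Kruskal stress-1, best of 4 random starts,
configuration centred at the origin; the all-equal-distance degenerate
case warns and returns the classical-scaling layout with stress 0,
since ties impose no monotonicity constraint. Group ellipses are
exported as centre and standard-error axes only — no rendering.

## Synthetic data

The isotope generator draws source samples from Normal(μ, σ) per tracer
and mixture samples from the model's own marginal (mean Σp*μ, variance
Σp*²σ² + σ_res²), so model fitting is a well-posed recovery problem
with recorded truth. The `near_collinear` switch appends a twin of the
first source with means offset by under 0.2‰ — the regime that drives
posterior correlation and exercises the pooling loop. An
`n_acid_fail` count marks that many source samples with
carbonate-contaminated δ¹³C (uniform in (−8, −2)‰) to exercise the QC
filter.

The eDNA generator works at the hit-table level rather than simulating
sequences: identity values are drawn inside per-depth bands (e.g. a
family-depth taxon gets identity in [95.05, 97.95] at full coverage),
chosen strictly inside the rank thresholds so each ESV is assignable
exactly to its taxon's intended depth and no assignment hinges on
boundary arithmetic; class-depth taxa additionally truncate their hit
lineage, since class and order share the 90 bar. Each taxon is
detectable by the markers that plausibly amplify it (COI for metazoans,
18S for eukaryotes, 16S for cyanobacteria); per-marker dropout,
group-structured occurrence probabilities, batch structure with one
negative control per batch, and contaminant ESVs (always present in
blanks, present in same-batch samples at the contamination rate) are
all controlled. Decoy hits (low-scoring, mangled lineages) are added by
default so the top-score rule is actually load-bearing. Every sample is
guaranteed at least one taxon so distance matrices stay defined.

What the generator does *not* emulate: read abundances and sequencing
depth (detection is binary), chimeras and index hopping, reference-
database gaps (every taxon's lineage is by construction resolvable to
its intended depth), and correlated taxon occurrence. Passing tests
therefore demonstrate correctness of the post-processing chain under
its stated rules, not robustness to upstream bioinformatic artefacts.

The study-shaped fixture bundle mirrors the field design it emulates:
5 sequenced EAM detritus samples in the summer season and 6 in spring,
2 tray samples, sediment-trap/feces replicate counts to match, a
single summer spongivore-feces isotope replicate, 8 spring samples lost
to incomplete acidification, and an isotope layout with sponge tissues
enriched in δ¹⁵N relative to algae and mats. Problem sizes throughout
the test suite and acceptance script use these field-scale designs
(tens of samples, 10,000-iteration chains, 500-replicate null
simulations), which keep all checks statistically meaningful.

## Reproducibility

One global integer seed; every stochastic stage derives an independent
substream via `SeedSequence([seed, stage])`. Identical seed and inputs
give byte-identical output tables, including the regeneration of
simulated bundles.
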