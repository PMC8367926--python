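# Methods

This note documents the models, numerical choices and limitations behind
`betascape`, in the order data flows through the package.

## Data model and variable transforms

All analyses are incidence-based: community tables are collapsed to
presence/absence at read time, because every index implemented here is a
function of shared/unique species counts or shared/unique branch lengths,
not abundances. Plots must be non-empty; species and plot identifiers
unique; community, environment and coordinate tables are aligned on plot
ids, and species absent from the phylogeny are dropped with a warning (or
rejected, `on_missing_tip="error"`), mirroring the routine exclusion of
unplaced morphospecies from plot inventories.

Environment tables carry a class per column — soil (pH, organic matter,
texture fractions, P/Ca/Mg/K), climate (bioclim-style summaries),
geomorphology (slope position, slope, elevation, land-cover index). The
pre-analysis transform square-roots the soil and climate columns (they
are non-negative measurements whose raw scale is not the scale organisms
respond to) and, for each geomorphology column, z-standardizes it and
appends the cube of the standardized value as an additional predictor.
The cubed-augmentation construction is one reading of a loosely specified
standard practice ("standardize, adding the cubed values"); it is
isolated in `apply_transforms` so an alternative reading only touches one
function. Transforms are recorded per column and can never be applied
twice.

Coordinates are planar km. A helper converts decimal degrees by local
equirectangular approximation — adequate over a few degrees, not a
geodesic projection.

## Beta diversity

Pairwise components: `a` shared species, `b`/`c` unique; total
(Sorensen) = `(b+c)/(2a+b+c)`; turnover = `min(b,c)/(a+min(b,c))`
(Simpson-based replacement); nestedness = total − turnover, non-negative
by construction. The phylogenetic family uses root-inclusive Faith's PD
(sum of branch lengths on the union of root-to-tip paths). Root
inclusion guarantees shared branch length `a_pd = PD_i + PD_j − PD_tot
≥ 0` and makes the pooled-pair identity exact, which the total-PBD
formula `(2·PD_tot − PD_i − PD_j)/(PD_i + PD_j)` relies on. A
multiple-site turnover summary (min/max sums over all pairs against the
pooled richness core) is exposed separately; the pairwise decomposition
is the workhorse because every downstream analysis consumes pairwise
matrices.

The matrix path is vectorized through an edge × tip membership matrix
(PD of any plot set is a masked sum over edges), and per-pair scalar
functions remain as the reference implementation; tests assert exact
agreement (1e-12) between the two and against independent set/edge
enumeration oracles.

## Null models and standardized effect sizes

Two randomizations:

- **Richness-preserving equiprobable draws** — each plot keeps its
  richness, members drawn uniformly without replacement from the pool
  (table species for taxonomic metrics; *all* phylogeny tips for
  phylogenetic ones). A stated variant that would also fix pairwise
  shared-species counts is not enforceable jointly with equiprobable
  colonization and is not implemented; richness alone is constrained.
- **Tip shuffling** — labels permuted across the tips; topology, branch
  lengths and community membership fixed. Note that shared species counts
  are invariant under this null (both plot sets are permuted by the same
  map), so SES is driven by the non-shared taxa.

SES = (obs − null mean)/null sd, so positive = evenness (observed
between-community distances exceed the null), negative = clustering —
the inverse of Webb's NRI/NTI orientation, which multiplies by −1.
beta NRI uses between-community mean pairwise distance (deep structure),
beta NTI mean nearest-taxon distance (terminal structure), the latter
symmetrized as the average of the two directional means. Null mean and
SD are estimated from `n_iter` draws (999 recommended for inference, 199
in tests); pairs with zero null SD are reported NaN and flagged. The
95% envelope is mean ± 1.96·SD.

## PCNM

Euclidean plot distances; truncation threshold t = the longest edge of
the minimum spanning tree (the smallest t keeping the neighbour graph
connected); distances > t replaced by 4t (the canonical constant,
configurable); Gower double-centering and eigendecomposition; positive
axes kept, unit-normed (they enter RDA as standardized predictors),
deterministic sign (largest-magnitude loading positive). With t = ∞ the
construction reduces to classical PCoA, a tested identity. On a regular
transect the implementation reproduces vegan's `pcnm` exactly
(eigenvalues and vectors); the leading eigenfunction there is a
*full-period* sinusoid over the extent — a property worth knowing when
intuition expects a half-period hump.

Scale classification estimates each axis's dominant wavelength by
Lomb–Scargle periodogram along a depth-first path through the MST
(cumulative along-path distance as the abscissa, tolerant of irregular
spacing), then bins by two cutoffs. The default cutoffs are geometric
midpoints between the square roots of reference scale areas 50, 5 and
0.5 km² (≈ 3.98 and 1.26 km); any field design with a different extent
should pass its own cutoffs, as the examples do. The area → wavelength
mapping is an explicit interpretation: nothing canonical links PCNM axes
to areas.

## Ordination

- **PCA** on the correlation matrix by default (heterogeneous units);
  zero-variance columns are rejected by name.
- **NMDS** wraps scikit-learn's non-metric MDS (Kruskal stress-1,
  isotonic regression, best of `n_starts` random starts — 1000 mirrors
  publication practice, 20 in tests), then centers and
  principal-axis-rotates the configuration with a deterministic sign.
- **RDA**: least-squares projection of the centered response on centered
  predictors, SVD of the fitted values; R² = SS_fit/SS_total, adjusted
  R² by Ezekiel's formula. Validated to 7+ digits against vegan's `rda`
  (R², adjusted R², eigenvalue proportions).
- **db-RDA**: PCoA of the dissimilarity, positive-eigenvalue axes only
  (no Lingoes/Cailliez correction by default), then RDA. On Euclidean
  input this equals direct RDA to 1e-8, a tested identity.
- **Permutation pseudo-F**: `F = (SS_exp/m)/(SS_res/(n−m−1))`, free
  permutation of response rows, `p = (1 + #{F* ≥ F})/(1 + n_perm)`;
  with a conditioning matrix, Freedman–Lane permutation of
  reduced-model residuals, which keeps partial tests type-I calibrated.
- **Forward selection** with the double stopping rule: best candidate by
  added explained variance, partial permutation test at α, and the
  cumulative adjusted R² may not exceed the all-candidate model's. A
  global pre-test of all candidates at α gates the whole procedure;
  without it the probability of selecting ≥1 pure-noise variable is far
  above α. One behavioural consequence of the cap, shared with vegan's
  `ordiR2step`: when a single real predictor carries the signal, its
  one-variable adjusted R² equals the all-variable cap in expectation,
  so roughly half of such runs legitimately select nothing.

## Variance partitioning

Explained variation is adjusted R² throughout — raw R² is not comparable
across predictor sets of different sizes. For k = 2–4 named sets, the
adjusted R² of every union of sets is computed and the 2^k − 1 Venn
atoms solve the linear system "R(S) = sum of atoms intersecting S";
residual = 1 − R(full). Atoms can be negative (adjusted R² is an
estimator) and are reported as computed, with a clamped view for
presentation. Unique fractions are tested by partial permutation
pseudo-F of the set given all others. Closure (atoms + residual = 1) is
asserted to 1e-10 on every run. The scale-stratified variant restricts
the spatial set to the PCNM axes of one scale class.

The compositional response for partitioning defaults in the pipeline to
NMDS axes 1–2 of the chosen turnover matrix; PCoA axes 1–2 are the
configurable (and faster, fully deterministic) alternative and are what
the acceptance experiments use.

## Synthetic metacommunities

The generator emulates a tropical plot-network study design: 41 one-ha
plots, a regional pool of 1,687 species with genus-level polytomies, a
~222 × 167 km extent (≈ 2° × 1.5°), 19 climate / 9 soil / 4
geomorphology variables, and correlated climate–soil gradients
(default latent correlation 0.3).

- **Phylogeny**: birth–death tree conditioned on the tip count
  (birth 1.0, death 0.5), stem edge dropped, depth normalized to 1
  before trait evolution so σ² is the expected tip-trait variance.
  Internal edges shorter than 3% of tree depth are collapsed into
  polytomies with tip depths preserved, mimicking genus-level
  unresolved clades.
- **Niche evolution**: Brownian motion per axis (climate, soil),
  default σ² = 1 per axis; σ² = 0 is perfect conservatism.
- **Landscape**: plots uniform over the extent (grid optional); one
  latent gradient per variable class as a sum of sinusoids — climate at
  444 km wavelength (the dominant west–east regional gradient, oriented
  along the long axis so its configured wavelength is the true
  along-gradient wavelength), geomorphology at 80 km, soil at 20 km —
  standardized across plots; observed variables load on their class
  latent with white noise (sd 0.3), soil/climate shifted non-negative.
- **Assembly**: plot richness fixed at the target (250 by default;
  comparable to a wet-Amazon 1-ha inventory at dbh ≥ 10 cm) by weighted
  sampling without replacement (Gumbel top-k), weight
  `exp(−w·Σ_axes(g − opt)²)·exp(−dist(plot, seed source)/δ)`, with
  per-species seed sources uniform over the extent. Defaults w = 1,
  δ = 100 km put the system between the neutral and strongly structured
  regimes. At w = 0, δ = ∞ the assembly distribution is exactly the
  richness-preserving null (tested by chi-square).

What the generator does *not* emulate: abundance structure, species
richness gradients (fixed per-plot richness is deliberate, for
null-model comparability; a variable-richness mode is out of scope),
phylogenetic signal in dispersal ability, habitat-specialization
speciation at the tips, and observational error in the environmental
variables. Passing tests therefore demonstrate the *statistical
machinery* — calibration, identities, monotone recovery of known
effects — not that real forest data will show any particular pattern.

One substantive consequence, verified at length: with Brownian
(conserved) niches, Gaussian filtering and the tip-shuffling null,
beta NTI *increases* with climatic distance between plots — communities
at different gradient positions hold taxa from opposite tails of a
conserved trait, farther apart phylogenetically than a random
relabeling. A declining beta NTI at large environmental distance, as
field studies sometimes report for terminal structure, requires
tip-level niche divergence (habitat specialization among close
relatives), a mechanism outside this generator's model. The acceptance
suite states the declining-slope expectation as given and fails it
honestly; the measured slope is reported by the acceptance script.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances —
hundreds of two-plot replicates for SES calibration (independent pairs,
since pairs sharing plots are correlated), 20–41 plots and 100–300
species for pipeline-level experiments, 199-iteration nulls and
199-permutation tests, 50 replicates per level for the monotone-response
checks — sizes at which every targeted effect is decisive while the
whole suite stays desk-scale. All randomness flows from explicit seeds
(numpy `default_rng`; dendropy gets a derived `random.Random`), and
identical seeds give bit-identical outputs, including the full pipeline
(a tested property). Numerical tolerances: exact identities at 1e-12
(metric oracles, star-tree reduction), linear-algebra identities at
1e-8–1e-10 (db-RDA equivalence, PCoA reduction, partition closure),
statistical checks at 3 binomial SDs of their nominal rates.
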