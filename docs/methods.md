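# Methods

## Scope and data model

fermflavor analyses staged fermentation experiments: an ordered set of
processing stages (default `HT1`…`HT9`, raw material through three years
of maturation) each sampled by a fixed number of parallel replicates
(default 3). Two measurement tracks share this design:

- an OTU count table (OTU × sample, non-negative integers) with a
  taxonomy map (OTU → kingdom…genus lineage, `unclassified` sentinel for
  unresolved ranks), and
- a GC-MS peak-area table (compound × sample) with a per-sample
  internal-standard area and the quantification constants.

All containers are thin wrappers over pandas DataFrames; every module
consumes and produces plain CSV/TSV.

## Quantification

Per sample, the absolute content of a compound with peak area A against
internal-standard area A₁ is

    C = unit_factor · C₁ · V · A / (A₁ · m)

with C₁ the standard's mass concentration (μg/μL), V its spiked volume
(μL) and m the sample mass (g). With these units the quotient is μg/g;
`unit_factor` (default 1000) expresses the result in μg/kg, the unit odor
thresholds are tabulated in. Per-stage content is the replicate mean by
default (median available); the aggregation choice matters only when
replicates disagree, and the mean matches the usual "mean ± sd"
reporting convention. A peak area of exactly 0 is stored as content 0
with a False detection mask rather than as missing, because class-level
summary tables treat not-detected cells as zero when summing; the mask
preserves the distinction for detection counts and for writing "-" cells
back out.

## OAV scoring

OAV = content / odor threshold, elementwise per stage. Compounds without
a threshold cannot be scored; they are excluded with a warning rather
than an error, since threshold coverage is always partial in practice.
The default key-compound rule keeps compounds whose maximum OAV over
stages is ≥ 1; a generic `max_ge(x)` cutoff and an explicit `listed` rule
are also provided, because published key-compound lists sometimes include
borderline members whose printed OAV maxima sit just below 1 — the
packaged 27-compound reference table contains exactly one such row
(1-Heptanol, max 0.95), and exposing both rules makes that discrepancy
visible and testable instead of silently resolving it. Ranking is by
descending max OAV with ties broken by compound name.

## Alpha diversity

Estimator dialects were chosen to match the conventional amplicon-survey
toolchain and are pinned exactly:

- **Shannon**: −Σ pᵢ log pᵢ, base 2 by default with base e first-class.
  Published index tables rarely state the base, and at realistic
  richness both are plausible, so neither is privileged beyond the
  default.
- **Simpson**: reported as 1 − dominance (Gini–Simpson), so larger =
  more diverse; plugin (1 − Σ pᵢ²) default, unbiased
  (1 − Σ nᵢ(nᵢ−1)/(N(N−1))) optional.
- **Chao1**: bias-corrected S_obs + F₁(F₁−1)/(2(F₂+1)) by default —
  finite for F₂ = 0; the classic F₁²/(2F₂) form falls back to
  bias-corrected when F₂ = 0.
- **ACE**: rare/abundant cutoff at count ≤ 10; when every rare OTU is a
  singleton the coverage estimate is 0 and the estimator is undefined, so
  it falls back to Chao1 with a warning. The CV term γ̂² is floored at 0.
- **Good's coverage**: 1 − F₁/N.
- **Rarefaction**: the analytic hypergeometric expectation
  E[S(n)] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)), with binomial coefficients in
  log space (gammaln) so curves at realistic depths (10⁴–10⁶ reads) do
  not overflow; a subsampling-without-replacement Monte-Carlo route is
  kept for cross-checks.

The implementations are the package's own (the dialects above, the ACE
fallback and the log-space rarefaction are not uniformly available in one
place); the test suite cross-checks every index against scikit-bio and
against brute-force loop evaluations on random vectors.

Stage summaries are mean ± sd (ddof = 1) over replicates. Richness
invariants (Chao1 ≥ S_obs, ACE ≥ S_obs, curve monotone and concave) are
enforced by property tests.

## Community structure

Presence of an OTU in a group follows the raw-tag-count rule: mean count
over the group's samples strictly greater than 1. The strictness matters
at the boundary — counts (3, 0, 0) have mean exactly 1 and are absent.
The rule operates on raw counts, not rarefied ones; whether a published
Venn used rarefied counts is usually unstated, and raw counts keep the
operation deterministic. Venn summaries report the core (intersection of
all groups), per-group unique counts, and for ≤ 6 groups the full
exclusive-region lattice (region sizes sum to the union by construction);
above 6 groups only pairwise overlaps are reported, as the lattice grows
as 2^k.

Taxonomy aggregation sums counts per label at a rank and normalises per
sample; OTUs unresolved at that rank pool into `unclassified`. The
stacked-composition preparation ranks known taxa by mean relative
abundance across all samples, keeps the top k (default 10), pools the
remaining known taxa into `Others`, and keeps `unclassified` as its own
band excluded from the ranking — so a highly abundant unresolved fraction
can never crowd a named taxon out of the legend. Column sums are
preserved exactly. Dominant-taxon extraction takes the argmax over
non-reserved labels with alphabetical tie-breaking and a warning.

## Ordination

PCA on samples. Counts are first transformed per sample — relative
abundance by default; Hellinger (square root of relative abundance) and
CLR with pseudocount 0.5 are available for compositional robustness —
then features are centered and decomposed by SVD (scikit-learn, full
solver). Component signs are made deterministic by forcing the
largest-magnitude loading of each component to be positive. Tests verify
scores and explained variance against an independent covariance
eigendecomposition, full-rank reconstruction, loading orthonormality, and
permutation equivariance.

## Taxa–flavor correlation

Pearson r with a two-sided p from t = r√(n−2)/√(1−r²) on n−2 df.
Default pairing is stage means (n = number of stages, typically 9):
flavor is quantified per stage while the microbiome has replicates, so
stage means are the finest shared axis; per-sample pairing is available
when both tracks have sample-level data. Because Pearson r is invariant
to positive per-compound rescaling, correlating contents or OAVs gives
identical r and p — the choice is immaterial for the grid. Constant
features yield an undefined-correlation flag (NaN, rendered blank), never
r = 0. Stars follow the conventional reading: * for p < 0.05, ** for
p < 0.01, configurable. No multiple-testing correction is applied by
default, matching how such heatmaps are conventionally drawn;
Benjamini–Hochberg adjustment is exposed as a flag because a 13 × 27 grid
invites it.

Feature construction stacks the top 3 phyla over the top 10 genera by
mean relative abundance (reserved labels excluded) against the key
compounds' stage values — the conventional heatmap layout.

## Synthetic experiments

The generator emulates the study layout the package targets, not any
particular dataset:

- **Stage profiles**: a log-space Gaussian random walk across stages
  (drift 0.6) produces smooth succession; users may supply explicit
  profiles. Planted dominants re-weight one taxon to a target share and
  rescale the rest, keeping the simplex constraint exact.
- **Replicates**: Dirichlet around the stage profile with concentration
  200 by default (≈2–3% compositional noise for mid-abundance taxa);
  concentration ∞ disables replicate noise.
- **Library sizes**: negative binomial with mean 20,000 (the order of
  per-sample effective sequences in amplicon surveys of this kind) and
  dispersion 5, floored at 1 — uneven depth without pathological zeros.
- **Taxonomy**: OTUs draw a phylum from a pool of 4 and a genus from a
  pool of 40; a configurable fraction (default 10%) is `unclassified` at
  genus rank.
- **Flavor**: per-compound baselines are lognormal around 150 μg/kg,
  constant across stages, plus Gaussian noise (sd 5 μg/kg). A linked
  (taxon, compound, target r) triple replaces the compound's row with an
  affine function of the taxon's stage-mean relative abundance plus
  Gaussian noise: with noise sd σ and target r, the slope is
  a = σ·r / (s_x·√(1−r²)) where s_x is the sd of the realized taxon
  trajectory, making the population correlation equal the target. |r| = 1
  requires σ = 0, and 0 < |r| < 1 requires σ > 0; other combinations are
  rejected as unreachable. The intercept is placed at least 6 combined
  standard deviations above zero so the non-negativity clip essentially
  never distorts the calibration.
- **Peak tables** are constructed by inverting the quantification
  equation with identical replicates per stage, so
  `compute_absolute_content` recovers the ground-truth content matrix to
  machine precision — a round-trip identity the tests rely on.
- Thresholds are set to each compound's median stage content (floored at
  10⁻³ μg/kg), so OAVs straddle 1.

One seeded `numpy` generator per call; no global state. Identical seeds
give byte-identical tables.

What the generator does **not** emulate: read-level artefacts (chimeras,
sequencing error), phylogenetic correlation among OTUs, compositional
coupling between the flavor track and more than the explicitly linked
taxa, stage-autocorrelated flavor baselines, and inter-batch effects.
Passing tests therefore demonstrate correctness of the estimators and
plumbing under the stated generative model, not robustness to real-data
artefacts upstream of an OTU table.

## Calibration properties

Under the null configuration (no linked pairs) compound trajectories are
iid Gaussian and independent of the community, so conditional on any
taxon trajectory the Pearson t-statistic is exactly t-distributed and
p-values are uniform on (0,1); the acceptance suite checks the observed
false-positive rate at p < 0.05 over >10,000 cells lies in [0.04, 0.06].
With a planted link at target r = 0.9 on n = 9 stages, the sampling mean
of recovered r over 500 replicate experiments must lie in [0.80, 0.95]
(the point estimate of r at n = 9 is slightly biased toward 0), and the
planted cell must attain its row's maximum |r| in a majority of
replicates.

## Numerical choices

- Binomial coefficients via gammaln; probabilities of "OTU missed at
  depth d" computed only where N − Nᵢ ≥ d, else 0.
- Ties in rankings (key compounds, stage profiles, top-k taxa,
  dominance) break by name, with a warning where dominance is reported.
- |r| within 1e-15 of 1 is snapped to ±1 with p = 0.
- Class/stage summary tables append marginal `Total` row and column; the
  grand total equals both marginal sums to 1e-9 on exact inputs.
- Pipeline outputs are written through pandas with default float
  formatting; determinism is verified by SHA-256 manifests.

## Packaged reference tables

Three small CSVs transcribed from a published nine-stage dry-cured-ham
study ship with the package: the class × stage absolute-content table,
the 27-compound OAV matrix with odor thresholds, and bacterial/fungal
alpha-diversity summaries. The first two are used by tests and the
acceptance script as printed-arithmetic references (the class table's
ketone row sums to 1761.88 from its printed cells versus a printed total
of 1761.95 — a rounding inconsistency in the source, accommodated with a
±0.1 tolerance). The diversity summaries are regression references only:
they derive from raw sequencing runs that this package deliberately does
not process (the pipeline starts from a finished OTU table), so no test
asserts numeric agreement with them.

## Problem sizes

Tests and the acceptance script use deliberately modest sizes — 15–150
OTUs, library sizes 800–8,000, 9 stages × 3 replicates, 500-replicate
Monte-Carlo loops — chosen so the whole suite runs in seconds while
keeping Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

- Estimator dialects in published index tables are rarely stated; exact
  numeric agreement with any given published table is out of scope.
- The presence rule and top-k ranking operate on raw counts and mean
  relative abundance respectively; alternatives (rarefied counts,
  per-stage ranking) are not implemented.
- Beta diversity (UniFrac, Bray–Curtis, PCoA/NMDS, PERMANOVA) and
  differential abundance are out of scope.
- The correlation module offers Pearson only; rank or partial
  correlations and network methods are not provided.
- Threshold sets are user-supplied inputs; the package does not estimate
  odor thresholds.
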