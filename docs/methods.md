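# Methods

## The measurement model

The pipeline treats a scan as a node-by-time matrix (network- or
parcel-averaged BOLD-like series, repetition time `tr` seconds). Dynamic
connectivity is the sliding-window Pearson correlation stack A_ijs with
negative correlations set to 0 and the diagonal zeroed; windows are
rectangular, length `round(window_seconds / tr)` samples, advancing by
`step` samples (default 1 TR, i.e. maximal overlap; a near-disjoint reading
of the window overlap is available by passing a larger `step`).

Community structure across windows is estimated by maximizing multilayer
modularity

    Q(γ, ω) = (1/2μ) Σ_ijs [A_ijs − γ_s k_is k_js/(2 m_s)] δ(M_is, M_js)
            + (1/2μ) Σ_{i, |r−s|=1} ω δ(M_is, M_ir)

where k_is is node strength in layer s, m_s half the layer's total strength,
and 2μ the total multilayer strength including the ordinal couplings
(2μ = Σ_is k_is + 2ωN(L−1)). Sums run over ordered supra-node pairs, so the
single-layer case reduces to the standard Newman–Girvan modularity
(verified against the two-disjoint-cliques value Q = 1/2). A layer with zero
strength contributes no null-model term (logged).

### Optimizer

The generalized ordinal Louvain operates on the dense supra-modularity
matrix: greedy node-move sweeps (a supra-node joins the community maximizing
the summed modularity weight to its members; ties break toward staying, then
toward the lowest label) followed by community aggregation, iterated to a
local maximum. Move order is a seeded random permutation per sweep, making
every run exactly reproducible; Q is non-decreasing across sweeps by
construction and the recorded `q_history` asserts it. On every enumerable
fixture (≤ 12 supra-nodes, where all set partitions can be scored
exhaustively), the best of 50 seeded restarts attains the global optimum.
Enumeration beyond 12 supra-nodes is intractable (Bell numbers), which
bounds the size of fixtures an exhaustive oracle can certify.

Label stability uses consensus clustering: `n_runs` (default 10) independent
optimizer runs, a per-layer node-pair co-assignment fraction matrix, and one
final optimizer run on that consensus stack. A pooled-over-layers consensus
is available behind a flag; per-layer is the default because the
co-assignment question is posed window by window.

### Derived measures

Per-node switching is the fraction of the L−1 adjacent-window transitions at
which the node's community label changes; global switching is the arithmetic
mean over nodes. Allegiance of a node pair is the fraction of windows they
share a label (1 on the diagonal by convention). All three are invariant
under community relabelling.

### Resolution and coupling

γ = 1 per layer and ω = 1 between adjacent layers are the package defaults —
conventional values, recorded in every output's provenance since the
quantities of interest (switching, allegiance) depend on them. The synthetic
validation studies bundled with the package pass ω = 0.5 explicitly: on
small, sparse, low-SNR toy stacks, unit coupling dominates the intra-layer
terms and freezes assignments across layers (every scan, including pure
white-noise surrogates, then reports switching exactly 0, which collapses
the rank-based group statistics into degenerate ties). ω = 0.5 keeps the
temporal prior active without silencing the data term at these problem
sizes.

## Arousal staging

Eye-based: samples before scan onset are dropped; zero runs shorter than 1 s
(blinks) are linearly interpolated between flanking valid samples; runs of
1 s or longer are closures and remain; eyes-open runs shorter than 100 ms
flanked by ≥ 1 s closures are zeroed. Thresholds are applied to the
post-preprocessing closure fraction (the ordering is not dictated by the
staging rules themselves; applying them after cleanup is the stricter and
more reproducible choice): alert [0, 0.05), intermediate [0.05, 0.50),
drowsy [0.50, 0.90], discard (0.90, 1]. The bin edges follow the first-listed
rule where the verbal ranges touch. Preprocessing is idempotent; a boundary
run at the very start or end of a trace lacks a flanking sample and is left
as closure.

EEG-based: the scan-mean vigilance rank (integers 2–6, one per second,
produced upstream) is thresholded at 3.5 — above is alert, below is drowsy,
and exactly 3.5 raises an explicit "unclassifiable" error because both rules
are strict inequalities. Scans whose first-quarter mean is ≥ 4 and
last-quarter mean is ≤ 3 are transition scans (the quarter fraction is
configurable; the staging description gives no window, so a simple
first/last-quarter contrast was chosen).

## Surrogate null models

Levels 1–4 are temporally white Gaussian constructions preserving,
cumulatively: per-node temporal means; per-node temporal variances; each
node's correlation with the global (across-node mean) signal; and the static
correlations among a designated node subset. "Mean/variance across nodes"
is implemented as per-node temporal statistics, which also fixes the
cross-node mean profile in expectation.

Construction: noise rows are empirically whitened (exact sample mean 0,
identity sample covariance) and colored by the symmetric square root of a
target correlation matrix, so the preserved statistics hold *exactly in
sample*, not merely in expectation. The level-3 target is the one-factor
matrix a aᵀ + diag(1 − a²); the loadings a are solved by damped fixed-point
iteration so that each node's correlation with the surrogate's own
across-node mean equals the empirical value — the naive choice a_i = ρ_i
overshoots by a self-term of order (1 − ρ²)/n, material at n = 14. The
level-4 target overwrites the designated block with the empirical static
correlations and re-solves the remaining loadings with the block held fixed;
indefiniteness is repaired by eigenvalue clipping, and a repair exceeding
0.1 in spectral norm is an error (the requested block is then incompatible
with the unit-diagonal/global-signal structure).

Empirical p-values use the add-one convention
p = (#{|r_null| ≥ |r_emp|} + 1)/(n + 1), two-sided on the rank-biserial
effect magnitude (sidedness is not dictated by the test's definition; the
magnitude comparison is the conservative symmetric choice). The default
ensemble size is 100 surrogates per scan; the bundled validation studies use
50 for runtime. The cohort-level test computes, for the empirical cohort and
for each index-matched surrogate cohort, the per-node (and global) rank-
biserial effect of drowsy vs. alert switching through the full
windows → consensus → switching pipeline. Switching values do not depend on
the arousal labels, so label-permutation analyses reuse one cached
scan-by-draw switching table.

## Group statistics

Mann–Whitney comparisons use midranks over the pooled sample. U is reported
as the number of drowsy-over-alert pairs (U = n_d n_a + n_a(n_a+1)/2 −
R_alert); z is the tie-corrected normal approximation without continuity
correction, positive when drowsy ranks higher; the effect size is
r = z/√N. These conventions reproduce the published 22-scan statistics
exactly (U = 102/90/97/86, z = 2.77/1.98/2.44/1.71, r = 0.59/0.42/0.52/0.37,
and U = 53 → z = −0.46, r = −0.10 for global switching). FDR control is
Benjamini–Hochberg per measure family (global switching; per-node switching;
static/global-signal correlations; allegiance pairs; moderation outcomes),
with family membership explicit in the pipeline configuration. The
moderation model is OLS of accuracy on {1, switching, drowsy,
switching × drowsy} with a two-sided t-test on the interaction; scans are
treated as independent observations even when subjects contribute several —
a deliberate replication of the source analysis design, noted as a caveat.

## The synthetic cohort generator

Each scan is piecewise-stationary: node community membership re-assigns at
exponentially distributed intervals (a Poisson process with total rate
n_nodes × rate/100 per sample, the rate expressed as expected
re-assignments per node per 100 windows at the default 1-sample window
advance). Each event moves one uniformly chosen node to a uniformly chosen
other occupied community, always keeping at least two communities alive.
Within an epoch, same-community nodes share a latent factor giving
correlation `within_community_corr` (0 across communities); a shared global
component — unit-variance AR(1) with coefficient 0.3, a smooth stand-in for
a global BOLD signal without any claim of hemodynamic realism — is mixed in
per-node via `global_loading`, and rows are scaled/shifted to the requested
node SDs/means. All randomness flows from one root seed through
`SeedSequence(root, spawn_key=...)`.

Defaults (chosen once for testability; empirical switching magnitudes per
arousal state are not characterized in the literature the design follows):
14 nodes, 300 samples at tr = 1 s, within-community correlation 0.6, global
loading 0.3, and re-assignment rates 0.5 (alert) vs. 2.0 (drowsy) per node
per 100 windows. The rate values matter jointly with the window length: a
re-assignment is only detectable when the surrounding epochs are long
relative to the correlation window, so the validation studies pair these
rates with 40-sample windows advancing 10 samples. Eye traces place the
closure budget in ≥ 1 s closures (shorter closures would be interpolated
away), add requested sub-second blinks, and, above 50% closure, include a
sub-100 ms open burst between two long closures to exercise the zeroing
rule; the post-preprocessing closure fraction is exact to within 1%.
Accuracy outcomes follow the planted linear model with coefficients recorded
alongside the data.

What the generator does **not** emulate: hemodynamic response shapes,
autocorrelated nodal noise, scanner drift/motion artifacts, volumetric
geometry, or realistic inter-subject variability. Passing validation
therefore demonstrates that the pipeline recovers the planted structure
under its own assumptions — it does not certify performance on empirical
fMRI, where window length, γ, and ω interact with autocorrelation and SNR in
ways the toy model does not reproduce.

## Validation study sizes

The bundled validation uses: a 20+20-scan cohort of 8-node, 300-sample scans
with 50 level-2 surrogates per scan for null-model power and shuffled-label
validity (200 label permutations, reusing the cached switching table);
exhaustive-enumeration certification of the optimizer on ≤ 12-supra-node
fixtures with 50 restarts; surrogate-ladder checks at n_time = 5000;
and 200/500–1000 replicate simulations at n = 100 for moderation sign
recovery and type-I error. These sizes were chosen as the smallest at which
each check is decisive.

## Numerical notes

- Window correlation matrices are symmetrized ((C + Cᵀ)/2) and clipped to
  [0, 1]; a zero-variance node inside a window gets zero weights there
  (logged), while zero variance over the full scan is an error for the
  static summaries.
- Louvain tie-breaks (stay, then lowest label) and the seeded sweep order
  make results bit-reproducible across runs and platforms.
- Community labels are canonicalized to 1..K in order of first appearance,
  so label-permutation invariance is by construction in stored outputs.
- The moderation design matrix is checked for full rank before fitting;
  constant switching within an arousal group is reported as a named
  collinearity error (and recorded, not fatal, in the demo pipeline).
- Dual regression includes an intercept in both stages; volumes are
  spatially demeaned by default (a no-op for the estimates given the
  intercept) and stage-1 variance normalization is off by default,
  both configurable.
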