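# Methods

`seronet` implements a complete serum-autoantibody screening analysis for
xMAP-style suspension bead arrays — background correction and
normalization of median fluorescence intensities (MFI), rank-correlation
screening of antigen reactivity against clinical parameters, distance-based
multivariate tests for categorical parameters, reactivity-tier patient
stratification, antigen co-reactivity clustering, and shortest-path
recurrence analysis on protein-interaction graphs. Because raw serum data
of this kind is rarely shareable, the package ships a first-class synthetic
cohort generator with planted, recorded ground truth; every downstream
stage is validated against what was planted.

## Preprocessing model

An MFI plate holds samples x analytes median fluorescence values, with
dedicated empty wells and control analytes (tag, blank, loading, positive).

1. **Background.** The assay noise floor is estimated as
   `mean + 1 * SD` of the pooled empty-well readings across non-control
   analytes (sample SD, n-1 denominator; a per-analyte variant is available
   but off by default, since pooling is the conventional reading of a
   single scalar background). On the default simulation
   (mean 120, SD 10 MFI) the estimate concentrates near 130 with a
   Monte-Carlo spread of about +/-2.
2. **Correction.** Each value becomes `max(MFI - background, 0) + 1`.
   The floor-then-offset guarantees a strictly positive matrix whose
   minimum value 1 means "no reactivity above background".
3. **Clinical join.** Plate samples without a clinical row (enrollment
   dropouts) are excluded; row order follows the clinical table; the
   exclusion report records both directions of mismatch.
4. **Robust spline normalization (RSN).** Between-sample intensity bias is
   removed on the log2 scale by mapping each patient onto a virtual
   reference (the per-antigen median profile) through a stiff robust
   monotone map. The normalization offsets `reference - patient` are
   centred on their median with up to three rounds of 2-MAD trimming, so
   differentially reactive antigens — biology, not technical bias — are
   excluded from the fit. The default map is the stiffest member of the
   family, a single median shift (`n_knots=1`); larger `n_knots` fits a
   monotone PCHIP spline through equal-count bin medians with unit-slope
   linear tails. Two deliberate choices deserve emphasis:
   * *Stiffness.* With ~10^2 analytes per sample, a flexible
     (near-interpolating) curve chases sampling noise and antigen-specific
     biology; in simulation it measurably attenuates planted clinical
     correlations (from 0.30 to ~0.20), whereas the stiff robust map
     preserves them (~0.27). The curve's job is sample-level bias only.
   * *Anchor.* Inputs exactly at the background floor map to the floor, so
     antigens that are background-flat within a patient subset remain
     exactly constant there and are later caught by the zero-variance
     filter. The rank-invariant-subset selection variant
     (`selection="rank"`) is retained for comparison but is not the
     default: rank invariance keeps antigens pinned at the intensity
     extremes, which in reactive sera are exactly the differential ones.
   A full quantile-normalization mode (`mode="quantile"`) is provided as a
   simpler audited alternative.
5. **Box-Cox.** Per antigen, lambda maximizes the profile log-likelihood
   over [-5, 5] (coarse grid + bounded refinement, tolerance 1e-4);
   |lambda| < 1e-3 falls back to the log transform; constant columns are
   flagged and passed through with lambda = 1. A global offset `1 - min`
   is applied first if any value is non-positive. Per-antigen lambdas mean
   the final columns are on incommensurable scales — any cross-antigen
   distance computation must standardize first (see stratification).
6. **Zero-variance filter.** Columns with variance below 1e-12 within a
   given patient scope are removed and reported; "zero variance" is taken
   literally up to floating-point noise.

## Association screening

Numeric clinical parameters are first transformed so larger always means
worse: visual field index becomes `VFI loss = 100 - VFI` and mean deviation
its absolute value. Each (antigen, parameter) pair is tested by Spearman
rank correlation (tie-aware, two-sided p via the t approximation with
n-2 degrees of freedom), with pairwise deletion of missing values and
`n_used` recorded. Benjamini-Hochberg control is applied over the global
antigen x parameter family by default (per-parameter families by option);
the step-up `q_(i) = min_{j>=i} m p_(j) / j` is implemented directly and
is cross-checked in the tests against statsmodels.

Categorical parameters are screened by PERMANOVA on the Euclidean distance
matrix of the full reactivity profiles: with `a` groups of sizes `n_g`
among `N` patients,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a))

with `p = (#{F_perm >= F_obs} + 1)/(n_perm + 1)` under label permutation
(default 1000 permutations). The distance metric is configurable
(Euclidean, Manhattan, correlation); Euclidean matches the clustering
metric used elsewhere. The screening wrapper z-scores antigen columns
before computing distances (per-antigen Box-Cox scales are
incommensurable; without standardization a few large-scale columns decide
the test). For significant categories, per-antigen two-sided
permutation tests of a Welch t statistic follow (default 10,000
permutations; method descriptions of this analysis vary between 1000 and
10,000 — the larger figure is the default), BH-adjusted across antigens.
Exact enumeration variants of both permutation tests (all distinct label
partitions, two groups) back the small-sample validation; the sampled
convention `(k+1)/(n+1)` cannot return zero and gives the tests exact size
at alpha when `alpha * (n_perm + 1)` is an integer.

## Patient stratification and subgroup screening

Reactivity tiers (high / intermediate / low) are a between-patient *level*
structure. Between-sample normalization deliberately suppresses sample-
level differences, so tiers are identified on the **background-corrected**
matrix (log2), before RSN — in simulation, clustering the post-RSN or
post-Box-Cox matrix drops tier recovery from an adjusted Rand index of
~0.97 to below 0.5, for exactly the reason RSN exists. Clustering is
complete-linkage agglomeration on Euclidean row distances cut at k=3, with
tiers named by descending mean reactivity. `cluster_patients` on arbitrary
matrices defaults to z-scoring columns first (mandatory after per-antigen
Box-Cox); the stratification entry point `stratify_patients` leaves the
log2-corrected columns unscaled so strongly reactive antigens carry their
natural weight.

Within the high and low tiers, the Spearman screen is re-run (tier-wise
zero-variance filtering first, BH within each tier's family). A structural
caveat the synthetic study makes measurable: when a latent factor spans
about half the antigens (the default 46-antigen block carrying the
high-tier clinical effect), no between-sample normalization can
distinguish it from a sample-level shift, and roughly half of the factor
is absorbed into the normalization. Post-normalization, the factor's
clinical association therefore appears as a *signed contrast* — the block
strongly negative, the remaining antigens mildly positive — rather than as
an absolute effect confined to the block. The subgroup validation tests
detect that contrast, and its absence in the low tier.

## Antigen co-reactivity clustering

Reactivity profiles are patient-scaled (row z-score; degenerate rows
flagged), antigen-antigen Spearman correlations computed across patients,
and BH applied over the C(m,2) unordered pairs. Complete-linkage
clustering on the correlation distance `1 - rho` is cut at the merge
height that maximizes the number of clusters with size in [3, 20]
(ties: fewest out-of-range clusters, then the lowest height) — a
deterministic restatement of choosing thresholds that avoid oversized and
undersized groupings. Clusters outside the size window are kept but
flagged ineligible for network seeding.

## Network recurrence analysis

Interaction graphs are read from STRING-style `protein1 protein2
combined_score` lists; the 0-1000 score dialect is auto-detected (any
score above 1) and rescaled, and only edges with strength strictly greater
than 0.15 are retained. Duplicate undirected edges keep the maximum
strength; self-loops are dropped.

For a seed set (top-10 antigens by correlation with a parameter, with
antigen fragments collapsed to their protein keeping the maximum rho, or
an eligible antigen cluster), every unordered seed pair (s, t) contributes
its unweighted shortest paths. With BFS distances and path counts sigma
from each seed, a node v interior to the pair accumulates
`sigma_sv * sigma_vt` when `d_sv + d_vt = d_st`, and an edge (u, v)
accumulates `sigma_su * sigma_vt` when `d_su + 1 + d_vt = d_st` (both
orientations). Counts are exact integers; the conservation identities
(interior-node counts sum to `sigma_st (d_st - 1)`, edge counts to
`sigma_st d_st`) are asserted on every run. Seeds do not accumulate
interior counts for their own pair but may for other pairs; pairs are
unordered (direction would only double all counts); a 1-strength weighted
mode is deliberately absent — hop count is the minimal reading of
"shortest". A DFS enumerator over the BFS predecessor DAG provides an
independent oracle (it errors, never truncates, beyond a path-count cap)
and the two routes are compared exactly on hundreds of random graphs.

## Synthetic study design

The generator emulates the full study: 125 recruited patients (9 later
excluded at the clinical join, leaving 116), 92 antigens plus 4 control
analytes, 4 empty wells, and an interaction graph. Defaults, with
rationale; all are configurable:

* **Signal.** log MFI = antigen baseline (Normal(6, 1); planted antigens
  at least 6.5 so their associations are not floored at background) + tier
  effect + latent factors + sex shift + antigen noise (sd 0.3; 0.45 for
  planted antigens, reflecting the broad dynamic range of short-listed
  reactive antigens) + per-sample technical gain (sd 0.05, the bias RSN
  removes). MFI = round(exp(signal) + Normal(120, 10)), floored at 0.
* **Tiers.** Retained patients split 35/45/36 into high/intermediate/low.
  Reactivity is sparse and epitope-specific: 25% of antigens respond, with
  amplitude `tier_scale ^ w_j`, `w_j ~ U(1.8, 2.8)` and tier scales
  (4, 2, 1). A uniform multiplicative tier factor would be exactly the
  sample-level shift normalization removes; sparse, antigen-specific
  amplitudes are both the immunologically realistic model and the only one
  under which tier structure survives a correctly working pipeline.
* **Planted clinical associations.** Three antigens (indices 5, 8, 20,
  kept out of the co-reactive blocks) are coupled to spherical equivalent
  at Spearman rho 0.30 each via a Gaussian copula on the realized rank
  scores of their tier-free reactivity: solve `R b = 2 sin(pi rho / 6)`
  against the empirical score correlation matrix and add noise projected
  orthogonal to the scores, so the realized coupled-scale correlation
  equals the target up to rank-grid error (about +/-0.03 at n=116).
* **High-tier clinical block.** A latent factor shared by antigens 46-91
  (46 antigens, factor sd 0.2 in log units) is coupled to central corneal
  thickness within the high tier only, at per-antigen rho -0.5 — the
  strength needed for a 46-antigen cluster of significant correlations at
  n~35. The factor also forms the dominant co-reactive block. Exact
  copula coupling is infeasible here (46 columns from ~35 patients give a
  singular score-correlation matrix), hence the factor construction.
* **Co-reactive blocks.** Four further blocks (sizes 5, 9, 13, 16) with
  within-block latent correlation 0.35.
* **Sex effect.** A 1.5-sd mean shift on 12 random antigens for one sex,
  concentrated rather than diffuse so the multivariate (PERMANOVA) sex
  difference is clearly detectable after normalization (pseudo-F around 4
  at n=116) while adding only a handful of sex-confounded columns to the
  per-antigen screens; sex is drawn at the study's 56/116 male fraction.
* **Zero-variance planting.** Antigens 86-91 are forced to 0 MFI within
  the low tier; after floor-anchored normalization they are exactly
  constant there and the subgroup filter must remove exactly those six.
* **Clinical marginals.** Gaussian (clipped) with the cohort's summary
  statistics: age 70.97 +/- 6.12 y, IOP 32.44 +/- 5.58 mmHg, CCT
  541.40 +/- 33.04 um, MD -6.51 +/- 4.89 dB, VFI 85.56 +/- 14.40%,
  follow-up MD -10.07 +/- 6.36 dB and VFI 74.92 +/- 19.04%, progression
  rate 2.89 +/- 2.43 %/y (encoded positive-is-worse), medications
  2.70 +/- 0.84; binary parameters at the cohort frequencies (e.g., laser
  trabeculoplasty 37/116, progression on guided analysis 68/116).
  Spherical equivalent, acuity, cup-to-disc and OCT use plausible clinical
  ranges (means 0.5 D, 0.7, 0.70, 70 um).
* **Graph.** 60 nodes in 3 dense communities (within-community edge
  probability 0.3 plus a spanning chain), community members named after
  antigen identifiers so association-derived seed sets resolve; 1 bridge
  protein attached to half of each community; all strong strengths in
  (0.2, 1.0]; 40 decoy inter-community edges with strengths in
  (0.01, 0.15] that only the threshold filter removes. Every
  inter-community shortest path in the filtered graph necessarily crosses
  the bridge.

Identical configurations (including the seed) yield byte-identical
outputs.

### What the generator does not emulate

Bead-count quality control, plate spatial effects, batch structure beyond
a scalar per-sample gain, longitudinal visits, non-Gaussian clinical
marginals, and missing clinical data. Passing tests therefore demonstrate
correctness of the algorithms and their calibration under a plausible
generative model — not robustness to every artefact of real bead-array
data.

## Validation summary (computed by the test suite and acceptance script)

* Recurrence counts equal exhaustive enumeration exactly on hundreds of
  random graphs; conservation identities hold on every pair.
* PERMANOVA and the permutation t-test reject at 5.0% +/- MC error under
  the null; small-sample p-values match exact enumeration.
* BH q-values match statsmodels and the closed-form definition to 1e-12.
* The best-ranked spherical-equivalent antigen is a planted one in >=80%
  of replicate cohorts end to end; planted tiers are recovered with mean
  adjusted Rand index >=0.8; the high-tier-only block effect appears as
  the expected contrast only in the high tier; the background estimator,
  Box-Cox lambdas (within +/-0.2 at n=500, averaged over 5 replicates)
  and the zero-variance filter recover their planted values; the planted
  bridge attains the maximal recurrence in >=95% of graphs.

Problem sizes in the default runs (e.g., 100 cohorts for association
recovery, 50 for stratification, 500 null simulations at 199 permutations,
200 random graphs) were chosen to give the binomial assertions comfortable
Monte-Carlo margins while keeping the suite quick to run.

## Known limitations

* The half-array factor/sample-shift confound discussed above is intrinsic
  to between-sample normalization, not fixable by this package; analyses
  of factors spanning a large fraction of the panel should interpret
  post-normalization signs as contrasts.
* The Box-Cox profile likelihood is nearly flat for weakly skewed columns;
  per-antigen lambdas are reported so downstream users can audit them.
* "Manual" cluster-threshold choice is replaced by a deterministic
  objective; on perfectly homogeneous synthetic blocks the
  maximize-eligible-count objective can legitimately subdivide large
  blocks, which real, unevenly structured dendrograms rarely reward.
* Permutation p-values are lower-bounded at 1/(n_perm+1); q-values close
  to that floor are resolution-limited.
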