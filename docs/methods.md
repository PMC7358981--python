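# Methods

## Networks from time series

Each subject contributes an ROI×time matrix in the fixed atlas order
(26 DMN regions; homologous pairs interleaved, left before right). The
edge weight between two ROIs is one minus their sample Pearson
correlation, computed as mean-centred cross products normalised by root
sums of squares — scale factors cancel, so there is no n vs n−1
ambiguity. Correlations are clipped to [−1, 1] before the subtraction
to absorb boundary rounding, giving weights in [0, 2]. Negative
correlations are kept as weights above 1: no absolute value,
thresholding or sparsification is applied anywhere. A zero-variance
series raises an error naming the ROI rather than imputing a value,
since a constant BOLD series indicates broken upstream preprocessing.
The matrix is assembled from per-pair dot products (not one blocked
matrix product) so that a hemisphere submatrix equals bit-for-bit the
matrix recomputed from the subset series.

Hemisphere scopes select the 13 left or right rows; the whole-brain
network is built once and sub-set, which is exactly equivalent to
recomputation because each entry depends only on its two rows.

`discard_initial_volumes` removes scanner-equilibration timepoints
(default 10 for raw 140-volume acquisitions, configurable; the CLI
default is 0 because synthetic cohorts are generated post-discard at
K = 130).

## Filtration and persistent features

Thresholding the complete weighted graph at λ (closed convention:
edges with weight ≤ λ) yields the nested graph family. The zeroth
Betti number β₀(λ) — the number of connected components — changes only
at minimum-spanning-tree weights, so the filtration values are 0
followed by the m−1 MST weights ascending, and β₀ is evaluated only
there. The MST uses Kruskal with union-find; ties are broken by
lexicographic node-position order, which fixes the reported tree while
leaving the total weight, the filtration values and the β₀ curve
tie-invariant. Tied MST weights are kept as a multiset (the λ list is
non-decreasing; a tied value merges several components at once); the
strictly-increasing generic case is the measure-one situation for
continuous data, but ties are exercised in tests. The merge history is
identical to single-linkage agglomerative clustering and is exported
as a dendrogram event list; group-level summaries use the element-wise
mean of member weight matrices (a documented choice — any group
aggregation rule could be substituted).

The integrated persistent feature at the i-th filtration value is

    IPF_i = (m − i) / (m (m − 1)) · Σ_{k = i+1}^{m−1} λ_k ,  IPF_{m−1} = 0,

a non-increasing, non-negative curve: each merge removes its cost from
the tail sum. Two per-subject scalars summarise convergence rate:

* SIP: OLS slope of IPF on λ over all m points, unweighted, raw λ scale.
* BNP slope: OLS slope of β₀ on λ over the same points. The Betti curve
  itself is the classic Betti number plot; the slope reduction was
  chosen symmetrically with SIP among the plausible scalar reductions
  (area under curve, endpoint λ, …) because both features are then the
  same functional of their respective curves.

Both are negative for any non-degenerate network. Two analytic facts
matter for interpretation and are enforced by tests: scaling all
weights by c > 0 scales λ and IPF equally, so **SIP is scale-invariant**
(it reacts only to the relative dispersion of MST weights), whereas the
BNP slope scales by 1/c. Consequently, a uniform downward shift of all
weights — the signature of a global coupling increase — steepens the
BNP slope but *flattens* SIP slightly (the shift increases the relative
spread of the MST weights). Both features separate shifted from
unshifted networks; they do so through different geometry.

## Graph-theoretic comparison measures

Path-based measures use W directly as edge lengths (it is already a
dissimilarity): all-pairs distances by dense vectorized
Floyd–Warshall (m = 26, so cubic cost is negligible; a zero-weight
edge is a genuine zero-length edge), CPL the mean off-diagonal
distance, GC the mean inverse distance, NR the minimum nodal
eccentricity. Modularity and eigenvector centrality need affinities,
not distances: they run on s = max(0, 1 − W), i.e. the Pearson
correlation with negatives zeroed — the standard conversion for
weighted functional networks, and required for the Perron–Frobenius
guarantee behind the centrality vector. Modularity is Newman's Q of
the best partition found by seeded Louvain, best of 10 restarts
(deterministic for a fixed seed); the restart count covers the
heuristic's variability at m = 26, and on every ≤ 8-node test graph
the result equals the exhaustively enumerated optimum. Eigenvector
centrality is computed by power iteration on s + I (the shift keeps
the spectrum positive so the iteration cannot oscillate; eigenvectors
are unchanged), normalised to unit Euclidean norm, reduced to a
per-subject scalar as the mean nodal centrality.

## Permutation inference

The group statistic is the absolute difference of group means
(two-sided; a pooled-variance t statistic is available as an option).
Monte-Carlo p-values use the add-one correction
p = (1 + hits)/(1 + n_perm), so p ∈ (0, 1] with resolution
1/(n_perm + 1); the exhaustive variant enumerates all C(n, n_a)
relabellings and divides the plain count (identity included) by the
total. Relabellings are drawn from the sorted pooled sample and split
at the smaller group size — the complement bijection makes this
equivalent to label shuffling while rendering the p-value exactly
invariant under swapping the two group labels. Each cell of the
scope×feature grid draws from an independent stream spawned
deterministically from the run seed. No multiple-testing correction is
applied across the grid; the p-values are raw, which is a deliberate
caveat.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: two
groups of 27 and 31 subjects, 26 ROIs, 130 timepoints. Signals are
i.i.d.-in-time multivariate normal draws from a block-structured
correlation matrix: same-hemisphere pairs at `within_block_rho` (0.4),
cross-hemisphere pairs at `between_block_rho` (0.15) — values in the
range typically reported for within/between-hemisphere DMN functional
connectivity. `noise_sd` scales amplitude only and cannot affect any
correlation-based quantity. The planted group effect is a uniform
`coupling_boost` (default 0.15) added to every off-diagonal carrier
correlation (clipped below 1, eigenvalue-floor PSD projection with
diagonal renormalisation when needed): higher correlation means smaller
weights, so carrier networks aggregate faster — a steeper Betti slope.

Each subject additionally receives one global coupling jitter,
N(0, `subject_sd`²) with `subject_sd` = 0.1, added to all off-diagonal
correlations. This between-subject variance component is essential
realism: without it every subject in a group is an i.i.d. draw from
one matrix, group tests saturate at any effect size, and power
comparisons between features become meaningless. 0.1 is of the order
of the between-subject spread of edgewise functional connectivity seen
in rs-fMRI cohorts. An AR(1) temporal-filter knob exists (off by
default — the Pearson weight is agnostic to autocorrelation, which the
tests confirm at the correlation-recovery level).

What the generator does *not* emulate: hemodynamic response shapes,
scanner noise spectra, motion artifacts, spatially heterogeneous
(edge-specific) group effects, and non-Gaussian marginals. Passing
tests therefore demonstrate correctness of the computational pipeline
and calibration/power of the inference under this idealised model —
not performance on real scanner data.

A consequence of the uniform-boost effect model worth stating plainly:
because the boost shifts every edge weight nearly uniformly, the mean
edge weight — and hence CPL, which averages ~325 edges — is an
extremely powerful detector of this particular planted effect,
saturating at the Monte-Carlo p floor alongside the Betti slope, while
scale-invariant SIP responds only through second-order dispersion. An
empirical ordering in which the persistent features dominate all
path-based measures would require a topology-specific effect (e.g.
within-hemisphere coupling up, cross-hemisphere down at constant mean
weight); the uniform model was kept because a single global knob with
a documented direction is the cleanest testbed for the pipeline
itself.

## Numerical choices and edge cases

* Correlations clipped to [−1, 1]; weight matrices validated to be
  symmetric with zero diagonal and entries in [0, 2].
* β₀ thresholding is closed (≤ λ) so drops occur exactly at MST
  weights; λ = 0 gives m components whenever all pairwise weights are
  strictly positive (a duplicate series produces a zero-weight edge and
  lowers the starting count — allowed, but flagged in the acceptance
  path as degenerate).
* OLS slopes via centred cross products; degenerate (all-identical) x
  raises rather than returning NaN.
* GC is +inf if any distance is exactly 0 (duplicate ROI series); such
  networks are considered degenerate input.
* Eigen-factorisation (not Cholesky) for simulation so PSD matrices
  with zero eigenvalues are accepted; eigenvalue floor 1e−10 in the
  nearest-PSD projection.
* All randomness flows from named integer seeds through
  `numpy.random.SeedSequence` spawns: cohort simulation, Louvain
  restarts and permutation draws are each reproducible bit-for-bit,
  and the full pipeline is byte-identical under a fixed seed.

## Problem sizes used in the validation suite

Oracle-equivalence checks run exhaustive enumeration where it is
feasible (spanning trees for m ≤ 6, set partitions for m ≤ 8) and
independent library references at the production size (m = 26). The
calibration study uses 200 null cohorts of 10 + 10 subjects with 500
permutations; the power study 100 cohorts of 27 + 31 subjects with
1,000 permutations — sizes chosen so the whole suite completes in a
few minutes on one core while keeping Monte-Carlo standard errors
small relative to the tested margins.

## Known limitations

* Zeroth homology only: cycles/holes (first homology and higher) are
  outside the scope of the filtration machinery.
* The BNP scalar reduction (OLS slope of the Betti curve) is one
  defensible choice among several; comparisons with other reductions
  are not implemented.
* Slopes are fitted over λ, not over the merge index; for networks
  with extreme MST-weight outliers the λ-scale fit is dominated by the
  largest weights.
* Raw p-values across 21 grid cells; users testing many features
  should apply their own multiplicity control.
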