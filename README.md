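# topodmn

Persistent-homology and graph-theoretic analysis of resting-state
functional brain networks, built around the default mode network (DMN):
a 26-node subgraph of the AAL90 parcellation (13 homologous region pairs,
one node per hemisphere). The package takes per-subject ROI×time BOLD
series, builds weighted dissimilarity networks, tracks how their
connected components aggregate under a graph filtration, reduces the
dynamics to scalar network statistics, and tests two groups of subjects
against each other with permutation inference. A synthetic cohort
generator makes the entire pipeline runnable and testable without
access-controlled scan data.

It is intended for researchers analysing two-group rs-fMRI designs
(e.g. genetic-risk carriers vs non-carriers) who want multiscale,
threshold-free network summaries next to the classical graph measures.

## The model

For ROIs *i*, *j* with BOLD series *Tᵢ*, *Tⱼ* (K timepoints), the edge
weight is the Pearson dissimilarity

```
W_ij = 1 − corr(T_i, T_j)   ∈ [0, 2]
```

Thresholding W at an increasing value λ gives a nested family of graphs.
For zeroth homology the topology changes only at the weights of the
minimum spanning tree: the filtration values are λ₀ = 0 followed by the
m−1 MST weights sorted ascending, and the zeroth Betti number β₀(λ)
(number of connected components) steps from m down to 1 across them —
the merge sequence is exactly single-linkage clustering.

Two persistent features summarise the aggregation speed per subject:

* **IPF** (integrated persistent feature) at the *i*-th filtration value:
  `IPF_i = (m−i)/(m(m−1)) · Σ_{k>i} λ_k`, a non-increasing curve ending
  at 0 once the network is one component.
* **SIP** — the OLS slope of IPF against λ; **BNP** — the OLS slope of
  β₀ against λ. Both are negative; steeper means faster aggregation.

For comparison, five classical weighted-graph measures are computed on
the same networks: characteristic path length (CPL), global efficiency
(GC), network radius (NR), modularity (Mod, Louvain on the
non-negative affinities max(0, 1−W)), and mean eigenvector centrality
(EC). Group differences per feature and scope (whole brain / left /
right hemisphere) are assessed with a two-sided permutation test of the
absolute group-mean difference (default 10,000 shuffles).

## Worked example

```python
from topodmn import (CohortConfig, simulate_cohort, build_network,
                     betti0_curve, compute_sip, compute_bnp, compare_groups)

cfg = CohortConfig(n_carrier=6, n_noncarrier=6, seed=7)   # planted effect on
cohort = simulate_cohort(cfg)                             # the carrier group
net = build_network(cohort.subjects[0].timeseries)        # 26x26, weights 1-r
prof = betti0_curve(net)
print("first filtration values:", [round(float(x), 3) for x in prof.lambdas[:4]])
print("beta0:", list(prof.betti0[:4]), "...", list(prof.betti0[-2:]))
print("SIP = %.3f  BNP slope = %.2f" % (compute_sip(net), compute_bnp(net)))
print(compare_groups(cohort, n_perm=1000, seed=7).pvalues.round(3))
```

prints

```
first filtration values: [0.0, 0.359, 0.362, 0.369]
beta0: [26, 25, 24, 23] ... [2, 1]
SIP = -1.008  BNP slope = -58.34
         sip    bnp    cpl     nr     ec    mod     gc
scope
both   0.483  0.008  0.004  0.005  0.010  0.003  0.008
left   0.408  0.006  0.007  0.005  0.096  0.278  0.006
right  0.056  0.006  0.018  0.009  0.044  0.856  0.006
```

The filtration starts with 26 singleton components at λ = 0 and ends in
a single component at the largest MST weight; both fitted slopes are
negative (the network aggregates as λ grows). In the p-value grid, rows
are scopes and columns features: with the generator's planted carrier
effect, most whole-brain features separate the groups in this (small)
cohort, while SIP — which is scale-invariant and reacts only to the
shape of the MST weight distribution — responds less to a uniform
coupling shift.

The same pipeline runs from the shell:

```
topodmn simulate --out cohort/ --seed 7
topodmn compare --manifest cohort/manifest.tsv --out results/ --n-perm 10000
```

Real data enter through the same manifest format: one TSV per subject
(26 rows in atlas order × K timepoints; `--n-discard 10` drops scanner
equilibration volumes from raw 140-volume series), or precomputed
dissimilarity matrices with `kind: network` entries.

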