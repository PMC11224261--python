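# Methods

This note documents the statistical model behind `coreactnet`, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when reproducing results.

## Reactivation statistics

The unit of analysis is one animal × region with counts (n_dapi, n_td,
n_cfos, n_double). Labeling fractions are percentages of DAPI+ cells. Chance
overlap assumes independence of the learning tag and the retrieval marker:
`chance% = td% · cfos% / 100`; the reactivation ratio is `double% / chance%`,
algebraically equal to `n_double · n_dapi / (n_td · n_cfos)`. Given the
realized Td+ and c-Fos+ counts this estimator is conditionally unbiased, but
at very low expected double counts (well under one cell per animal) its
per-animal distribution is a point mass at 0 with rare large values; group
summaries at small n are then dominated by zeros. For calibration checks the
pooled estimator `Σ n_double / Σ (n_td · n_cfos / n_dapi)` is preferable, and
the test suite uses it where marginal rates are homecage-small. Undefined
ratios (chance exactly 0) propagate as missing values and are excluded from
summaries with a logged count.

The ratio is computed per animal and then summarized, not from group-mean
percentages; the alternative (ratio of group means) weights animals by their
labeling rates and is not exposed.

Multiple testing uses the Benjamini–Hochberg step-up. The raw product
`p·m/rank` is reported alongside the monotone adjusted value because the
plain product can be non-monotone in p; the running-minimum step restores the
standard procedure. "Global" adjustment means one family per analysis run,
pooling every permutation test of that run; family membership is recorded on
each result.

Behavioral indices are the context discrimination index
`(threat − neutral)/(threat + neutral)` (undefined, and an error, when both
are zero — not silently 0) and the signed light ON − OFF freezing difference.

## Correlation matrices and networks

Per experimental group, Pearson correlations of `double%` across animals are
computed for all region pairs. Pairs with fewer than 3 complete observations,
and any region with zero variance across animals, are left missing with a
warning rather than set to 0 — fabricated zeros would bias strength means.
The diagonal is stored as 1 but excluded from all summaries.

Networks are built per sign mode: positive (edges r > 0 at weight r),
negative (r < 0 at weight |r|), combined (all non-zero signed weights). No
correlation-magnitude or significance threshold is applied by default; sign
is the only filter (a `threshold` option exists but defaults to 0).

Centrality conventions:

- **Str** — the node's summed correlation divided by the number of other
  regions (N−1). Absent or sign-filtered edges therefore contribute 0, so
  strength reflects both the magnitude and the number of a node's
  connections; with this convention a star center strictly dominates its
  leaves. In combined mode the positive and negative averages are merged as
  `s* = s⁺ − (s⁻/(s⁺+s⁻))·s⁻`, scaling the negative contribution by its
  share of total connectivity.
- **Eig** — principal eigenvector of the weighted adjacency by power
  iteration (tolerance 1e-10, ≤ 10,000 iterations), normalized to max 1. A
  diagonal spectral shift keeps the Perron eigenvalue strictly dominant so
  the iteration cannot oscillate on bipartite components; the shift leaves
  the eigenvector unchanged. Disconnected graphs: computed on the largest
  component with a warning, other nodes score 0.
- **Bet / Clo** — weighted shortest paths with edge length = 1/weight
  (stronger correlation = shorter functional distance), the common convention
  for correlation networks. Betweenness is reported as unnormalized pair
  counts. Closeness is the inverse of the mean shortest-path length so that
  higher = more central; the raw mean path is exposed as `mean_path`.
  Disconnected graphs are handled per component. Binarized variants are not
  the default; the weighted versions are.
- **CC** — unweighted triad density among a node's neighbors,
  `links / (k(k−1)/2)`, 0 for k < 2.
- In combined mode all path/spectral/clustering measures operate on |r|
  (an interpretation choice: a strong negative correlation is still a strong
  functional link); only Str keeps the sign information.

**Hubs**: per centrality the candidate set is the `ceil(0.25·N)` top-ranked
nodes with all ties at the cutoff included (N = 15 → 4 candidates); a node in
≥ 3 of the 4 candidate sets is a hub. A fully degenerate centrality (all
nodes equal) admits every node with a warning.

**Communities**: weighted Newman modularity
`Q = Σ_c [W_c/W − (S_c/2W)²]` is maximized by Louvain with 100 seeded
restarts plus one Clauset–Newman–Moore greedy candidate; the best partition
is polished by deterministic single-node-move hill climbing (Louvain can
stall one move short of the optimum on small graphs), and exact-Q ties break
on the lexicographically smallest partition signature, making the result a
pure function of network and seed. Edgeless networks return singletons with
Q = 0.

**Topology**: global efficiency is the mean over ordered node pairs of
1/d(i,j) with weighted shortest paths (unreachable pairs contribute 0); local
efficiency is the mean over nodes of the global efficiency of the
neighbor-induced subgraph; average clustering, degree, and weighted degree
complete the overview. Node-deletion analysis removes either the hub set or a
size-matched set of non-hubs; "matched" means the |hubs| least central
non-hub nodes by composite rank (sum of the four centrality ranks), which
makes the hub-vs-non-hub efficiency comparison a contrast between the top and
bottom of the centrality distribution. Note that deleting weak nodes can
*raise* mean efficiency (their poor pairs leave the average), so deltas are
signed.

## Permutation inference

All group comparisons shuffle animal group labels without replacement,
preserving group sizes exactly, and rebuild the statistic from the shuffled
labeling: both correlation matrices (and networks) are recomputed jointly
from one shuffled labeling per resample, which preserves exchangeability.
Statistics are absolute differences (edge |r₁ − r₂|, per-node centrality
difference, mean anatomical-group connectivity difference). The p-value is
the literal exceedance frequency `#(null > empirical)/B` with B = 1000 by
default; it can be exactly 0, so the bias-corrected `(k+1)/(B+1)` is always
reported alongside. Resamples where the statistic is undefined (a shuffled
group with zero variance in a region) are redrawn, with the redraw count
recorded; more than 100 consecutive failures abort with an error. Every
result carries its seed and is bit-reproducible.

The per-node centrality family is computed in one pass (`B` shuffled network
ensembles shared across all node × measure tests) so a whole-network family
costs the same as a handful of single tests.

## Synthetic-data generator

The generator emulates the design of a dual-epoch tagging study: groups
(default CFC n=7, CFC-5s n=6, homecage n=6), a 15-region panel in four
anatomical groups (mPFC, amygdala, hippocampus, PH), per-region marginal
labeling rates on the few-percent scale of such experiments, planted
reactivation ratios (1.8 in conditioned groups, 1.0 in homecage), and
group-specific inter-regional correlation targets (an amygdala–PH block in
the CFC-5s-like group, a hippocampus–PH block in the CFC-like group, at 0.75
over a 0.2 background).

Per animal, a latent field z ~ N(0, C) over regions (Gaussian copula)
modulates both marginal rates through the multiplier
`exp(σz − σ²/2)` (σ = `sigma_animal`, default 0.3 on the log scale — animal
CVs of ~30%, a realistic scale for immediate-early-gene counts). DAPI counts
are Poisson around `dapi_mean` (default 5,000, large enough that fraction
noise is dominated by the planted structure at conditioned-group rates);
Td+ and c-Fos+ counts are binomial at the modulated rates; double counts are
binomial at `ratio · f_td · f_cfos` clamped to feasibility
(min(f_td, f_cfos)). Clamps are counted per cell and a configuration that
clamps more than 1% of cells fails fast — silent clamping would corrupt the
ground truth.

Because the double-label rate is a lognormal transform of the latent field
and counts add binomial noise, the realized Pearson correlation of `double%`
is a distorted, attenuated image of C. The generator therefore pre-calibrates
the latent correlation analytically: the lognormal pairwise-correlation map
is inverted exactly, an attenuation factor per region is estimated from the
expected signal-to-noise variance ratio, and the resulting matrix is
projected to the nearest unit-diagonal PSD matrix (eigenvalue clipping).
Targets unreachable after attenuation are capped (latent rate-correlation
0.99) and the cap count is recorded in the ground truth. Copula-on-rates
(rather than on counts) keeps marginal binomial noise and inter-regional
correlation separately controllable.

What the generator does **not** emulate: per-image counting variability and
tiling artifacts (counts are generated directly at the animal × region
level), sex effects, behavioral coupling (freezing does not feed the count
model), spatial structure within regions, and any between-region correlation
in the DAPI denominators. Passing tests therefore demonstrate correctness of
the statistical machinery under a known generative model, not robustness to
every artifact of real imaging data.

`planted_hub_network` builds complete weighted graphs with background weights
uniform on (0.05, 0.25) and all hub-incident edges scaled ×3 (capped at
0.95) for hub-recovery and deletion experiments.

## Problem sizes and determinism

Simulation-based checks in the test suite and acceptance script use: 1,000
(suite) / 200 (script) null datasets at B = 1000 for type-I calibration; 100
(suite) / 50 (script) replicates at n = 20 animals/group for planted-block
power; 100 replicates for hub recovery; 500 animals for ratio recovery; 2,000
all-null 15-test families for the Monte-Carlo FDR of the BH step-up; 200
random weighted graphs of ≤ 6 nodes (≤ 8 for community detection) against
exhaustive brute-force oracles. One global seed fans out to named substreams
(simulation, each permutation family, community restarts) via SHA-256, so
every stage is independently reproducible and all stochastic outputs are
bit-identical for a given seed.

## Known limitations

- The literal p-formula has resolution 1/B and can return 0; use
  `p_corrected` when a strictly positive estimate is needed.
- Hub identification on near-degenerate profiles (many ties) can flag more
  than ceil(0.25·N) nodes per candidate set by design; with heavy ties the
  hub set loses selectivity.
- Calibration of the copula is analytic and approximate: at very low marginal
  rates (expected double counts ≪ 1 cell) attenuation estimates are rough and
  high correlation targets are unreachable (reported via `n_capped_pairs`).
- Community detection is exact only in the sense of matching exhaustive
  search on small graphs; at 15 nodes the restart + refinement scheme is a
  heuristic, deterministic given the seed.
- Negative-mode centralities use |r|; whether one should instead rank by raw
  negative weight is a modeling choice the API does not currently expose.
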