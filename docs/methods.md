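# Methods

## The measures

Every analysis in this package runs on a *connectome*: a pair of symmetric
N x N matrices over a cortical parcellation (N = 78 regions by default),
holding a connection-strength index `w_ij` — tract counts between regions i
and j divided by the mean surface extent of the two regions — and the mean
fiber length `l_ij` in mm. An edge exists iff `w_ij > 0`.

Communication efficiency between two nodes is the inverse of the shortest
*physical* path length between them: the smallest achievable sum of fiber
lengths over paths through the network, not a hop count and not a Euclidean
distance. The weighted variant uses the effective edge length `l_e / w_e`,
so a strong connection behaves like a short one:

    d^w(i, j) = min over paths P of  sum_{e in P} l_e / w_e .

Connection weights are first rescaled by the subject's maximum weight, so
`w in [0, 1]` and the strongest connection contributes its bare fiber
length. From the distances:

* **Nodal global efficiency** of node i:
  `E_glob(i) = (1/(N-1)) * sum_{j != i} 1 / d(i, j)`, with `1/inf := 0` for
  unreachable partners. Indexes integrated long-range communication.
* **Nodal local efficiency** of node i: the efficiency of the subgraph G_i
  of i's neighbors (edges among neighbors only, i excluded), with shortest
  paths confined to G_i. Unweighted:
  `(1/(k(k-1))) * sum_{j != k in G_i} 1 / d(j, k)`; weighted, each ordered
  pair contributes `(w_ij * w_ik / d^w(j, k))^(1/3)`. Nodes with fewer than
  two neighbors score 0. Indexes fault tolerance / local segregation.
* **Whole-network efficiency**: the mean of `1/d` over ordered pairs
  (global) and the mean over nodes of each neighborhood subgraph's
  efficiency (local).

**Normalization.** Raw efficiencies are divided by their value on the ideal
fully connected network: the complete graph on the same nodes with every
weight 1 (the post-rescaling maximum) and every length equal to the
subject's minimum observed edge length `l_min`. Its nodal global efficiency
is `1/l_min` and its weighted local pair term is `(1/l_min)^(1/3)`; since no
real distance can fall below `l_min` and no weight can exceed 1, normalized
values always lie in [0, 1], and the construction reduces to the classical
unweighted normalization when all weights are 1. The edgeless graph
normalizes to 0 by convention. Restricting local-efficiency paths to the
neighborhood subgraph (rather than the whole graph) is a deliberate choice;
the subgraph reading matches the definition of local efficiency as the
subgraph's own efficiency.

## Regional statistics

Normalized efficiencies are analyzed region by region with ordinary least
squares (mass-univariate, one model per region; the fits are vectorized over
regions because all regions share one design matrix):

| contrast      | model                                           | inference on |
|---------------|-------------------------------------------------|--------------|
| `icv`         | eff ~ ICV + age + TBV                           | ICV slope    |
| `group`       | eff ~ group + age                               | group        |
| `icv_x_group` | eff ~ ICV + group + ICV:group + age + TBV       | interaction  |

Group is coded control = 0, ASD = 1, so a negative t-statistic means lower
efficiency in ASD. The group model deliberately controls age only — group
differences mediated by ICV are part of the effect of interest, not a
confound to remove. The interaction model carries all main effects plus both
volume covariates for hierarchical well-formedness. Two-sided p-values use
the t distribution with residual degrees of freedom. Each map of 78 regions
is corrected with the Benjamini–Hochberg step-up at q = 0.05, separately per
contrast and per efficiency measure; `significant` means q <= 0.05. Spatial
agreement between two maps is the cosine similarity of their t vectors.

## The synthetic cohort generator

No imaging data accompany the package, so validation runs on simulated
cohorts embodying the premises under study: wiring cost makes connection
weight fall off with fiber length; larger brains (indexed by intra-cranial
volume, ICV, the maximum brain size attained during development) have
proportionally longer fibers and selectively weakened long-distance
connections; and the ASD group carries an extra long-range weight deficit
plus a developmental ICV surplus.

Per cohort: region centroids sit on two mirror-symmetric ellipsoidal shells
with brain-like semi-axes (65, 85, 60 mm) and a minimum inter-centroid
separation of 18 mm — parcellation units are sizeable cortical patches, and
without the separation floor the minimum edge length that anchors the ideal
network becomes a noise-dominated extreme value. Region sizes are
log-normal and mirrored across hemispheres.

Per subject, with `s = (ICV / icv_mean)^(1/3)` (linear dimension scales as
the cube root of volume):

* fiber length `l_ij = tortuosity * Euclid(i, j) * s + N(0, length_noise_sd)`,
  floored at 1 mm;
* expected log tract count `log(base_count) - l_ij / wiring_decay`;
* edges whose Euclidean distance exceeds the 75th percentile of all pairwise
  distances are *long-range*; their log counts shift by
  `icv_longrange_slope * (ICV - icv_mean)` and, in ASD, by
  `log(1 - group_weight_deficit)`;
* counts are drawn log-normal around the expected value with coefficient of
  variation `weight_noise_cv` and rounded to integers, as a tract counter
  reports them.

Counts and lengths then pass through the same symmetrization and
size-normalization as real matrices. Covariates: ICV ~ Normal(icv_mean
[+ icv_group_shift in ASD], icv_sd), age ~ Uniform(19, 51) years,
TBV = 0.85 * ICV + noise, clipped so ICV > TBV > 0. All randomness flows
from one master seed through spawned per-subject substreams.

### Defaults and why

| parameter            | default        | rationale |
|----------------------|----------------|-----------|
| n_per_group          | 22             | the study design being emulated (44 adult males) |
| n_regions            | 78             | cortical parcellation size |
| icv_mean, icv_sd     | 1.55e6, 1.2e5 mm^3 | adult male intra-cranial volume and its population spread |
| icv_group_shift      | +5e4 mm^3      | a ~3% ASD surplus, consistent with persistent effects of early overgrowth |
| wiring_decay         | 35 mm          | connection probability/strength decay scale of cortical wiring |
| tortuosity           | 1.3            | fiber paths exceed straight-line distance |
| length_noise_sd      | 0.3 mm         | a mean over thousands of streamlines is tight |
| weight_noise_cv      | 0.1            | compiled counts from 10,000 seeds/voxel are reliable; between-subject biology enters through the modeled effects |
| icv_longrange_slope  | -2e-6 /mm^3    | ~-0.24 on long-range log-weights per ICV standard deviation |
| group_weight_deficit | 0.2            | a 20% ASD long-range weight reduction |
| longrange percentile | 75             | "long-distance" = top quartile of pairwise distances |
| icv_length_exponent  | 1/3            | volume to linear dimension |

The effect sizes are illustrative — chosen so that a cohort of 44 subjects
is an informative validation instrument (effects recoverable, nulls null) —
not calibrated to any empirical dataset. The `null()` configuration zeroes
the group shift, the long-range slope, the group deficit *and* the
ICV-length exponent; the last matters because the cube-root length scaling
is itself a causal ICV pathway, and leaving it on would make the "null"
cohort non-null for the ICV contrast.

### What the generator does and does not emulate

It reproduces the pipeline-relevant structure of tractography matrices:
symmetric positive strengths with distance decay, sizes in the strength
denominator, integer counts, spatial embedding, ICV- and group-dependent
long-range weights. It does not emulate: streamline-level artifacts,
distance-bias correction residues, anatomical bundle structure (weights at a
given distance are exchangeable), hub topology, or measured-ICV error.
Passing tests therefore demonstrate that the estimator chain recovers known
effects from data with this covariance structure — not that the paper-scale
effects exist in any real population.

A structural property of this model family is worth recording: because
effective edge cost `l/w` with distance-decaying weights is superadditive in
length, shortest weighted paths chain through short edges and simply reroute
around weakened long edges, and the subject-ideal normalization cancels
uniform length scalings. Weighted nodal *global* efficiency is therefore
nearly invariant to the generator's long-range manipulations, and the
direction-recovery and map-similarity checks are asserted on nodal *local*
efficiency, which carries the long-range mechanism directly through its
`w_ij * w_ik` factors. The global maps are still required to produce no
spurious FDR-significant positive regions, and they do not.

## Numerical choices

* Shortest paths: scipy's Floyd–Warshall on dense matrices when all edge
  lengths are strictly positive (the common case; zero means "no edge" in
  dense form), otherwise sparse Dijkstra. Both are exact for nonnegative
  lengths. A numba-compiled kernel runs the per-neighborhood loop of local
  efficiency; a pure-scipy reference implementation is kept and tested for
  exact agreement.
* Equality tolerances: 1e-9 absolute for path sums and efficiencies over
  <= 78 nodes; matrix symmetry to 1e-10.
* Text output carries 12 significant digits, so write/read round-trips are
  inside 1e-10.
* Disconnection: `1/inf := 0` throughout; degenerate inputs (edgeless
  graphs, isolates, single-neighbor nodes) yield 0, never an error.
* OLS with a zero-residual fit reports t = +/-inf and p = 0 rather than
  failing; rank-deficient designs raise an error naming the collinear
  columns.

## Problem sizes

The validation suite runs 50 default-condition cohorts for effect-direction
recovery and 200 null-generator replicates for FDR calibration; the oracle
comparison covers 500 random graphs of up to 8 nodes against exhaustive
simple-path enumeration; the reproduction script uses 25 recovery seeds and
100 null replicates. These sizes give stable medians and Monte-Carlo
standard errors small enough for the stated bounds.

## Known limitations

* The weighted local-efficiency denominator is `N_G(N_G - 1)` as in the
  unweighted case; weight-dependent alternatives exist in the literature.
* The ideal-network construction for weighted graphs is a convention
  (complete, unit weights, minimum observed length); other choices rescale
  the normalized values monotonically.
* Mass-univariate OLS assumes exchangeable residuals per region; no spatial
  model, no robust errors.
* The generator's exchangeable-weights assumption understates the path
  heterogeneity of real connectomes (see the global-efficiency note above).
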