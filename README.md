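# conneff

Physical-distance efficiency analysis of structural brain networks.

`conneff` is for researchers who compile region-by-region structural
connectomes from diffusion tractography — a strength matrix (tract counts
normalized by region size) paired with a mean fiber-length matrix — and want
to ask how efficiently such a network can communicate, and how that
efficiency relates to subject-level variables such as intra-cranial volume
(ICV, an index of the maximum brain size attained during development) or a
clinical group label. The motivating application is the brain-overgrowth
hypothesis in autism spectrum disorder: early excessive brain growth
lengthens long-distance connections, raising their cost and plausibly
reducing the efficiency of the adult network.

## The measures

For nodes i, j the package takes the shortest *physical* path length — the
smallest sum of fiber lengths over all network paths — and its weighted
form, in which each edge contributes `l_e / w_e` so that strong connections
act short:

    d^w_ij = min over paths  sum_e  l_e / w_e,         w rescaled to max 1.

From these it computes, per region,

    E_glob(i) = (1/(N-1)) * sum_{j != i} 1 / d^w_ij                (nodal global)
    E_loc(i)  = (1/(k(k-1))) * sum_{j != k in G_i} (w_ij w_ik / d^w_jk)^(1/3)

where G_i is the subgraph of i's k neighbors (paths restricted to it), plus
whole-network global/local efficiency. All values are normalized by the
ideal fully connected network (every pair directly connected at maximal
weight and minimal observed length), so they lie in [0, 1].

Downstream, per-region ordinary least squares relates efficiency to ICV
(controlling age and total brain volume), to group (controlling age; coded
so negative t = lower efficiency in the clinical group), and to the
ICV x group interaction, with Benjamini–Hochberg FDR across the 78 regions
of each map and cosine similarity between t-statistic maps.

Because tractography datasets are rarely shareable, the package includes a
synthetic cohort generator: spatially embedded connectomes with
distance-decaying weights, cube-root ICV length scaling, an ICV-dependent
long-range weight reduction, and a group-specific long-range deficit — all
recorded in a ground-truth sidecar so every pipeline stage is testable.

## Worked example

```sh
conneff run --seed 5 --out results/demo
```

runs the default synthetic analysis (44 subjects: 22 ASD, 22 controls; 78
regions; weighted efficiency) and prints:

```
conneff run (seed 5): 44 subjects, 78 regions
  global/group: 0/78 significant negative, 0/78 significant positive
  global/icv: 0/78 significant negative, 0/78 significant positive
  global/icv_x_group: 0/78 significant negative, 0/78 significant positive
  local/group: 0/78 significant negative, 0/78 significant positive
  local/icv: 78/78 significant negative, 0/78 significant positive
  local/icv_x_group: 0/78 significant negative, 0/78 significant positive
  cosine(t_icv, t_group) [global]: -0.9422
  cosine(t_icv, t_group) [local]: 0.9164
```

Reading this: for nodal local efficiency, the inverse ICV relation reaches
FDR significance in all 78 regions and no region shows a significant
positive relation; the ICV and group t-maps point the same way almost
everywhere (cosine 0.92) because both effects act on the same long-range
connections; and the ICV x group interaction is null, as generated. Each
map is also written as CSV (`results/demo/stats_local_icv.csv` etc.) with
per-region beta, t, p, FDR-adjusted q and a significance flag, e.g.

```
region_id,name,beta,t,p,q,significant
1,L01,-6.72963334718e-08,-2.36490183427,0.0229739710059,0.0229739710059,True
```

The same library surface is available in Python:

```python
from conneff import GeneratorConfig, generate_cohort, compute_cohort_efficiency
from conneff import fit_region_models

cohort = generate_cohort(GeneratorConfig(seed=5))
eff = compute_cohort_efficiency(cohort.atlas, cohort.subjects, cohort.connectomes)
results = fit_region_models(eff, cohort.subjects, contrast="icv", measure="local")
```

Other subcommands: `conneff generate` (write a cohort to disk),
`conneff compute` (efficiencies from matrix files), `conneff fit` (one
contrast), `conneff calibrate` (false-discovery calibration under the null
generator). Real data are read from the same formats the generator writes:
TSV matrix pairs, a subject CSV and an atlas CSV (see `docs/methods.md`).

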