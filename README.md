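# fanet

Mixed-type association networks and hypergraph centrality analysis of food
addiction in pediatric cohorts.

## The problem

Food addiction (FA) in children — compulsive consumption of ultra-processed
food, operationalized as a Yale Food Addiction Scale for Children (YFAS-C)
diagnosis — co-occurs with sociodemographic, anthropometric and metabolic
risk factors in ways that pairwise regressions describe poorly. Network
analysis treats each variable as a node and each sufficiently strong
association as an edge, so the *position* of FA (central hub vs. peripheral
satellite) becomes a measurable quantity. `fanet` implements this analysis
end to end for epidemiologists working with small mixed-type cohort tables:

- **YFAS-C scoring**: 25 items → seven DSM-IV-style dependence symptoms plus
  impairment/distress; diagnosis = ≥ 3 symptoms *and* impairment.
- **Mixed-type association matrix**: Pearson *r* (continuous–continuous),
  Cramér's V (categorical–categorical), η² from one-way ANOVA
  (continuous–categorical), chosen automatically from declared variable
  kinds; pairwise complete-case handling, binary zero-fill, mean-imputation
  sensitivity checks; greedy removal of collinear variables at |ρ| ≥ 0.90.
- **Networks**: thresholded graphs (|association| ≥ 0.2 or 0.3 by domain)
  and hypergraphs whose hyperedges are the maximal cliques of that graph
  (an `ego` variant is available).
- **Centrality**: degree k/(n−1), Wasserman–Faust closeness, normalized
  betweenness, and the principal adjacency eigenvector (unit Euclidean
  norm), each banded weak (≤ 0.3) / moderate / strong (≥ 0.7).
- **Stability**: nonparametric bootstrap (default B = 500) resampling the
  rows/columns of the association matrix (or the subjects), recomputing the
  hypergraph centralities per replicate, and summarizing the Spearman
  stability index r_s between original and replicate rankings.
- **Cohort statistics**: KS-normality-branched descriptive tables,
  chi-square / t / Mann–Whitney group comparisons, Cronbach's α, the
  noncentral-t a priori sample-size computation, and the
  10-participants-per-node rule.
- **Synthetic cohorts**: a latent-Gaussian copula generator whose default
  marginals match the published descriptive table of the reference cohort
  (n = 93, FA prevalence 24/93) with a configurable latent correlation
  structure — raw study data are not public, so all machinery is exercised
  and tested on synthetic cohorts.

## Worked example

```python
from fanet import AssociationNetworkModel
from fanet.synthetic import (default_study_specs, default_study_dependence,
                             generate_cohort)

specs = default_study_specs()
cohort = generate_cohort(specs, default_study_dependence(specs), n=93, seed=1)
model = AssociationNetworkModel.from_cohort(
    cohort,
    ["weight", "height", "waist_circumference", "bmi", "bmi_for_age",
     "body_fat", "lean_mass", "fat_mass", "food_addiction"],
    threshold=0.2, name="nutritional status")
res = model.fit()
print(res.summary())
```

```
Association network: nutritional status
================================================================
Variables: 9 (removed for collinearity: none)
Threshold: 0.2   Hyperedge rule: maximal_clique
Edges: 16   Hyperedges: 3

Graph centrality
----------------------------------------------------------------
                     degree  betweenness  eigenvector  closeness
weight                0.875        0.381        0.477      0.875
height                0.250        0.000        0.134      0.510
waist_circumference   0.500        0.000        0.376      0.612
bmi                   0.625        0.024        0.429      0.681
bmi_for_age           0.375        0.000        0.293      0.557
body_fat              0.500        0.000        0.376      0.612
lean_mass             0.250        0.000        0.134      0.510
fat_mass              0.625        0.024        0.429      0.681
food_addiction        0.000        0.000        0.000        NaN
...
```

Weight is the hub of this synthetic anthropometric network (high degree,
only node with appreciable betweenness), while the FA node is isolated at
this threshold — its closeness is undefined (NaN) and everything else is 0.
The strength labels (`res.centrality["degree_strength"]` etc.) band these
values as weak/moderate/strong.

Bootstrap stability of the hypergraph centralities:

```python
print(res.bootstrap_stability(B=500, seed=1).round(2))
```

```
             mean_rs    sd  median   p25   p75   min  max     n
degree          0.92  0.13    0.95  0.91  0.99 -0.30  1.0   493
betweenness     0.92  0.12    1.00  0.79  1.00  0.67  1.0   431
eigenvector     0.93  0.13    0.97  0.92  0.99 -0.30  1.0   493
closeness       0.91  0.14    0.95  0.91  0.99  0.11  1.0   451
pooled          0.92  0.13    0.97  0.91  1.00 -0.30  1.0  1868
```

Mean r_s ≈ 0.9 says the node ranking of each centrality measure is largely
preserved under node resampling of this (strongly structured, synthetic)
matrix; `n` counts the replicates whose index was defined (replicates that
collapse to < 3 shared nodes, or to a constant ranking, are excluded and
reported separately).

A full run — synthetic cohort, three domain networks (sociodemographic,
nutritional, metabolic at thresholds 0.2/0.2/0.3), centralities, stability,
descriptive table, manifest — is one command:

```sh
fanet all --seed 1 --outdir run1        # or: fanet synth / score / network / stability
```

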