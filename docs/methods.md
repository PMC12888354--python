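# Methods

This note documents the statistical procedures `fanet` implements, the
choices made where the underlying methodology was open, and what the
synthetic-data tests do and do not establish.

## Mixed-type association

Association between two variables is measured on the scale suited to their
declared kinds (`continuous`, `binary`, `nominal`, `ordinal`):

| pair | statistic | range |
|---|---|---|
| continuous–continuous | Pearson r | [−1, 1] |
| categorical–categorical | Cramér's V = √(χ²/(N·min(r−1, c−1))) | [0, 1] |
| continuous–categorical | η² = SS_between/SS_total (one-way ANOVA) | [0, 1] |

Ordinal variables are treated as categorical (no polychoric/polyserial
machinery). The χ² is computed **without** Yates continuity correction;
this is deliberate, because only the uncorrected statistic reproduces the
reference cohort's published FA-by-sex p-value (0.176; the corrected value
would be ≈ 0.27), which pins down the dialect. η² is stored as printed
rather than as the correlation ratio √η²; a `sqrt_eta` switch restores
scale comparability with |r| and V when wanted. Thresholding downstream
always uses absolute values; the signed r is retained for reporting.

Missing data: continuous pairs use pairwise complete-case deletion by
default (each entry records `n_used`; listwise and mean-imputation are
config options), and missing binary cells can be zero-filled with the
declared reference category (the "absence of the condition" reading).
`pipeline.imputation_sensitivity` reports the per-node centrality delta
between complete-case and mean-imputed runs.

Collinearity control removes variables greedily until no off-diagonal
|association| ≥ 0.90 remains. From each violating pair the member with the
larger mean absolute association to all other variables is dropped (ties
break toward the later variable in declared order). Removing only one
member of each pair, rather than both, is the standard practice reading:
published centrality tables retain members of highly related pairs
(BMI and BMI-for-age, weight and fat mass), which both-removal would have
eliminated. The procedure is idempotent and logs
(removed, triggering partner).

## Networks and hypergraphs

The graph at threshold t has an edge wherever |association| ≥ t (undefined
entries never create edges; isolated nodes are retained). Domain presets:
sociodemographic 0.2, nutritional status 0.2, metabolic 0.3; visualization
exports use 0.5.

How hyperedges are derived from a correlation matrix is the single largest
under-specification in this methodology, and the published account does not
state its rule. Two dialects are implemented:

- **maximal_clique** (default): hyperedges are the maximal cliques of size
  ≥ 2 of the thresholded graph — every group of mutually associated
  variables forms one polyadic interaction. Its two-section (clique
  expansion) provably reconstructs the thresholded graph, which the test
  suite checks exhaustively on random matrices.
- **ego**: one hyperedge per non-isolated node (the node plus its
  neighbourhood), the star-like alternative found in applied work.

Note that under the maximal-clique reading, graph and two-section
hypergraph centralities coincide by construction; published tables that
differ between the two (as the reference tables do) must rest on some other
hyperedge rule, which is recorded here rather than guessed at.

## Centrality

All measures are on the unweighted thresholded graph (edges binary above
threshold; weighted-path variants are out of scope):

- **Degree** k_i/(n−1).
- **Closeness** with Wasserman–Faust component-size scaling,
  ((r_i)/(n−1))·((r_i)/Σd), where r_i is the node's reachable count;
  isolated nodes are undefined and rendered as missing — consistent with
  blank closeness cells in published tables.
- **Betweenness** with endpoints excluded, normalized by (n−1)(n−2)/2.
- **Eigenvector**: power iteration from a uniform start, tolerance 1e-10
  (max-abs change), cap 1000 iterations, unit Euclidean norm, nonnegative.
  The iteration runs on A + I — the identity shift leaves eigenvectors
  unchanged but makes the iteration converge on bipartite graphs, where
  plain power iteration oscillates between the ±λ eigenspaces. An edgeless
  graph yields the all-zero vector with a warning.

Hypergraph centralities run on the two-section graph by default; a
bipartite variant runs the measure on the node–hyperedge incidence graph
and restricts the output to the variable nodes.

Strength bands: ≤ 0.3 weak, ≥ 0.7 strong, [0.4, 0.6] moderate. The
published banding leaves (0.3, 0.4) and (0.6, 0.7) unassigned; these are
completed to the nearest band, i.e. moderate.

Published per-node centrality values for the reference cohort are **not**
reproducible: the raw data are unavailable, and the printed values are not
consistent with any single standard normalization (e.g. 4-node degree
values of 0.750/0.250/0.250/0.500 cannot all be k/3 of one simple graph).
The package therefore fixes the standard normalizations above and treats
the published tables as layout targets only.

## Bootstrap stability

The published procedure resamples "rows and columns of the association
matrix" with replacement — node resampling, which is unusual relative to
the case-resampling convention of network psychometrics. Both are
implemented:

- **matrix_nodes** (default, faithful to the source): draw p node indices
  with replacement, collapse to the unique set (a duplicated node adds no
  structure to an unweighted graph), rebuild hypergraph and centralities on
  the submatrix.
- **subjects**: resample subjects with replacement and rebuild the
  association matrix from scratch.

The stability index is the Spearman correlation between original and
replicate centralities over the intersection of defined nodes (pairwise
deletion of dropped/undefined nodes; ties mid-ranked). Small intersections
are exactly what makes strongly negative indices possible, matching
published minima near −0.9. Indices are undefined — and the replicate is
excluded with its count reported — when fewer than 3 shared nodes remain or
either restricted vector is constant. Summaries report mean, sample SD,
median, P25/P75 (linear interpolation), min, max and n per measure plus a
pooled row concatenating all measures' valid indices. (The reference
table's pooled n of 998 against 500 replicates per measure is not
arithmetically reconstructible; the pooled row here counts all valid
indices, 4 × 500 minus exclusions.) Replicate r draws from the r-th spawned
substream of the master seed, so runs are reproducible and replicate sets
are prefix-stable in B.

## Cohort statistics

Normality uses the Kolmogorov–Smirnov test against a normal with the sample
mean/SD (normal iff p > 0.05). KS with estimated parameters is
anti-conservative; it is kept as the primary method for fidelity to the
source workflow, with Lilliefors available behind `method="lilliefors"`.
Group comparisons: uncorrected χ² for categoricals; Student's t (equal
variances) vs. Mann–Whitney for continuous variables, branched on
normality; Mann–Whitney is exact for both groups ≤ 20, tie-corrected
asymptotic otherwise. The descriptive table uses the pooled normality
verdict to choose both the summary style (mean ± SD vs. median (min–max))
and the test, so the presentation and inference never disagree.

Cronbach's α = k/(k−1)·(1 − Σs²_i/s²_total) with sample variances. The a
priori sample size inverts the exact noncentral-t power function of the
two-sided two-sample t-test by integer search, returning the smallest total
n (equal groups) whose power reaches the target — d = 0.6, α = 0.05, power
0.8 gives 45/group = 90 total, matching the planned analysis; minimality is
asserted (power at n−1 per group falls below target).

## Synthetic cohorts

One latent multivariate normal Z ~ N(0, R) drives all variables:

- symmetric continuous (reported mean ± SD): X = μ + σZ;
- right-skewed (reported median (min–max)): shifted log-normal
  X = min + exp(ln(median − min) + σ_L·Z), with σ_L set so the printed
  maximum sits at the expected-sample-maximum quantile for n = 93
  ((n−0.5)/n ≈ the 99.46th percentile);
- categorical: Z thresholded at the normal quantiles of the cumulative
  target frequencies.

Monotone transforms preserve the latent rank dependence, so one correlation
matrix R covers every mixed-type pair. R is validated symmetric with unit
diagonal and PSD-repaired by eigenvalue clipping (rejected when any entry
would move by more than 0.1). `plant_block` sets a chosen block of latent
correlations to a common strength, creating a known hub for end-to-end
parameter-recovery tests (the planted 4-block at 0.7 occupies the top-4
degree ranks in ≥ 95/100 seeded runs at n = 5000).

Default marginals reproduce the published descriptive table of the
reference cohort. Pooling the sex-stratified summaries: mixture mean and
mixture SD for symmetric variables; size-weighted median with the combined
min/max for skewed ones; age uses the pooled 9.13 ± 1.0 reported directly.
The default *dependence* structure (`default_study_dependence`) is not
published anywhere — it encodes once-chosen, physiologically standard
correlations for school-age children (anthropometric variables strongly
intercorrelated but below the 0.90 pruning cutoff, TC–LDL 0.85, HDL–TG
negative, SBP–DBP 0.6, weak FA links to age, socioeconomic position and
adiposity) so that study-scale runs produce non-trivial networks.

What the generator does **not** emulate: the real joint distribution (only
printed marginals plus the configurable latent structure), measurement
error and digit preference, within-school clustering, or item-level YFAS-C
response processes (FA is synthesized directly as a binary variable; the
scoring module is exercised on constructed item tables). An optional lipid
coherence adjustment (TC ≈ LDL + HDL + TG/5) is off by default since the
LDL-derivation coefficients are not part of the reproduced material.
Passing tests therefore establish that the machinery is correct and stable
under known dependence — not that the reference cohort's empirical network
is recovered.

## YFAS-C configuration

The item→symptom mapping ({1,2,3}, {4,17,18,25}, {5,6,7}, {8,9,10,11},
{21}, {22,23}, {12,13,14}; impairment {15,16}; 19/20/24 unscored) and the
diagnosis rule (≥ 3 symptoms AND impairment) are fixed. Which five items
are dichotomous and the per-item Likert endorsement cut points are
instrument-manual configuration not restated in the reproduced material;
`EndorsementMap` defaults to cut ≥ 3 with dichotomous {15, 16, 19, 20, 24}
as a documented fixture, and every scoring result is invariant to this
choice at the endorsement level (the tests operate there). The
impairment/distress criterion is implemented as item 15 OR item 16
endorsed; an AND reading would be strictly stricter and is not asserted as
the instrument's intent.

## Numerical and degenerate-input conventions

Undefined association entries, closeness of isolated nodes, and undefined
stability indices are all NaN and excluded pairwise, never silently zeroed.
Identical centrality vectors short-circuit the Spearman index to exactly
1.0 (scipy returns 1 − ε). Thresholds compare with ≥, so an association
exactly at threshold forms an edge. Maximal cliques come from the
Bron–Kerbosch enumeration in networkx and are ordered deterministically by
sorted membership; all exports are byte-stable for a fixed config and seed.

## Problem sizes used in the shipped analyses

Bulk marginal-fidelity checks use n = 20 000; planted-block recovery uses
100 seeded cohorts of n = 5000; study-scale pipeline runs use n = 93 with
B = 500 bootstrap replicates; the stochastic subject-scheme comparison uses
10 seeds at n = 50 vs. 600 with B = 20. These sizes give stable verdicts
for the properties they test while keeping a full run in well under a
minute each.
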