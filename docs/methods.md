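# Methods

This note records the models, conventions and numerical choices behind
`restconn`, in the order the pipeline applies them.

## Connectome construction

Edges are Pearson correlations between parcel-averaged BOLD time series;
the diagonal is fixed at zero and constant (zero-variance) parcels raise an
error naming the parcel rather than propagating NaNs. Fisher's
z = arctanh(r) is used wherever correlations are averaged or entered into
linear models; |r| is clipped to 1 − 1e−7 first so z stays finite.

**Proportional thresholding.** At density d the k = round(d·N(N−1)/2)
strongest edges are kept (rounding half away from zero). Ranking uses the
signed correlation, not |r|: negative edges are the weakest candidates, and
any negative weight that survives the cut is set to zero so all graph
metrics operate on nonnegative weights. The literature is split on
negative-edge handling; this convention is the common one for proportional
thresholding of functional connectivity and at the 10–40% densities
analyzed here virtually all retained edges are positive anyway. Weight
ties are broken by lexicographic (i, j) node order, which makes edge sets
deterministic and exactly nested across the density grid. The default
analysis band is 0.10–0.40 in 0.01 steps; 10% is the floor that keeps
typical group-average networks in one connected component.

**Group-representative networks.** Subject matrices are averaged in
Fisher-z space (the variance-stabilized convention), back-transformed, and
thresholded at the top 10% of connections for hub detection.

## Graph metrics

Metrics default to weighted networks. Conventions, chosen to match the
standard weighted counterparts in the field's toolboxes:

* path-based metrics use edge length 1/w; unreachable pairs contribute 0
  to efficiency and are excluded from CPL, which then carries a
  `disconnected` flag instead of erroring (thresholded subject networks
  can fragment below 10% density);
* clustering is Watts–Strogatz for binary graphs and Onnela geometric-mean
  triangle intensity (weights rescaled by the network maximum) for
  weighted graphs; nodes with degree < 2 get 0;
* local efficiency of a node is the global efficiency of the subgraph
  induced on its neighbors;
* modularity is the weighted Newman–Girvan Q with a resolution parameter
  (default 1).

**Null models.** Maslov–Sneppen rewiring performs double-edge swaps
(rejecting self-loops and multi-edges) with 20 attempts per edge by
default; weights travel with their edges, so the degree sequence and the
weight multiset are preserved exactly while the strength sequence is not —
the convention of the cited rewiring routines. Swap-free graphs (e.g.
cliques) are returned unchanged with a warning flag. Small-worldness
σ = (CC/⟨CC_null⟩)/(CPL/⟨CPL_null⟩) uses 100 such nulls by default.

## Modules and hubs

**Consensus Louvain.** Louvain is implemented as the standard greedy
two-phase algorithm on the weight matrix, with the node sweep order
randomized per run and modularity asserted non-decreasing across passes.
Consensus follows the agreement-matrix scheme: R runs (default 1000) give
co-assignment frequencies; entries below τ = 0.5 are zeroed and the
agreement matrix is re-clustered with R runs, iterating until every run
returns the same partition (error after 50 iterations; in practice 2–3
suffice). τ and the resolution are configuration, since the upstream
literature does not fix them.

**WMZ.** Within-module strength standardized within each module using the
sample standard deviation (ddof = 1, the default of the MATLAB routines
this convention follows); zero-spread modules and singletons get WMZ = 0.

**PC and PC_norm.** PC_i = 1 − Σ_s (k_is/k_i)² with strengths k. Raw PC is
mechanically depressed for nodes with a large intra-modular degree share,
so PC differences can reflect within-module degree rather than genuine
inter-modular dispersion. The normalized variant compares each node
against nulls in which only between-module edges are randomized:
degree-preserving double-edge swaps restricted so that both proposed edges
still join different modules, leaving every node's within-module
neighborhood — and hence its within/between degree split — untouched.
With pc_null the per-node null distribution over 1000 such nulls,

    pc_norm_i = clip(pc_i − median(pc_null_i) + M_null, 0, 1),

where M_null is the grand median of the null PCs (restoring the
network-wide scale). Because own-module strength is identical in every
null, the (k_own/k)² term cancels in the subtraction, leaving the evenness
of the node's between-module allocation relative to chance. An early
variant of this normalization used unrestricted Maslov–Sneppen nulls; it
*increased* the correlation with within-module strength (destroying the
modular structure inflates null PC for high-degree nodes) and was
discarded — the test suite checks the reduction property explicitly.

**Hub roles.** Connector hub: WMZ > 1 and PC_norm > 0.5; provincial hub:
WMZ > 1 and PC_norm < 0.5; the same PC_norm split names the non-hub
quadrants. Inequalities are strict; boundary values fall conservatively to
non-hub/provincial. Group-level hub detection runs on the group-averaged
10%-density network with the consensus partition; per-subject nodal curves
for statistics can use either subject-specific consensus partitions at
every density (`partition_mode="subject"`, the default) or one shared
partition from the pooled group average (`"group"`), which is the cheap
and more stable choice for simulation studies.

## Group statistics

**Permutation GLM.** Nuisance covariates (age) are demeaned and regressed
out of the response by least squares; the observed statistic is the Welch
(unequal-variance) t between groups on those residuals, and the null
permutes subject rows of the residual matrix (Freedman–Lane style).
Two-tailed p = (1 + #{|t*| ≥ |t|})/(B + 1), so p ≥ 1/(B+1). All nodes and
measures within an analysis share one permutation schedule, which keeps
the joint FDR coherent; the schedule is a function of the seed only.
Permutation nulls are evaluated in vectorized batches (group sums via
matrix products over permutation masks), so B = 20,000 across hundreds of
columns takes well under a second.

**FDR.** Benjamini–Hochberg step-up over the pooled p-vector of all nodes
× measures (per-measure pooling available as configuration). Note the
discreteness interaction: with B permutations the smallest attainable p is
1/(B+1), and a family of m tests can only produce discoveries if
1/(B+1) ≤ q·r/m for some rank r — choose B accordingly (the defaults do).

**NBS.** Edgewise Welch t on Fisher-z edges with the same Freedman–Lane
covariate handling (Welch is used for consistency with the nodal tests;
the original NBS toolbox default is a pooled-variance t). Suprathreshold
graphs are formed separately for t > t_init and t < −t_init; connected
components are measured in edge count; the null records the maximal
component size over both directions per permutation, giving per-component
FWE p = (1 + #{max* ≥ size})/(B + 1). t_init is an explicit parameter
(default 3.9856, the value used in the study design this mirrors; the
nominal α it corresponds to is not documented upstream and is not
rationalized here).

**Partial correlations.** Both sides are residualized on the covariates
(with intercept); the statistic is the Pearson correlation of residuals
and the null permutes the behavior residual vector. Columns whose
residuals are constant (e.g. WMZ in a spread-free module) return r = 0,
p = 1 rather than erroring in the mass-univariate path.

**Summary-table tests.** Demographic comparisons use the pooled-variance
two-sample t (computable from printed mean ± SD and n) and the Pearson
chi-square without continuity correction (df = 1), matching how such
tables are conventionally produced.

## Synthetic cohorts

The generator draws each subject's T×N series from a zero-mean stationary
multivariate Gaussian. This is deliberate: every downstream statistic
operates on Pearson correlations, so hemodynamic convolution, temporal
autocorrelation, motion and physiological artifacts would add realism
without exercising any additional code path. Consequences: passing tests
demonstrate correctness of the graph/statistical machinery under the
planted covariance model, not robustness to fMRI artifacts, preprocessing
choices, or non-Gaussian signals.

**Correlation template.** Within-module correlations average `within_r`
(default 0.5) and taper linearly with in-module node distance by
±`within_spread` (default 0.08). The taper matters: with exactly uniform
within-module weights, proportional thresholding degenerates into
tie-breaking on sampling noise and single-node perturbations (PSD repair,
planted shifts) decide edge survival wholesale; graded weights emulate the
heavy-tailed edge distribution of real FC and make thresholding behave
smoothly. Between-module coupling is carried by a rank-one global factor
with loadings sqrt(`between_r`) (default 0.1), so the construction is PSD
by design; hub nodes get loadings sqrt(`between_r` + `hub_boost`)
(default boost 0.45), which elevates hub–hub edges to ≈ 0.55 — a
rich-club-like motif that keeps the 10%-density group network in one
component and plants high-strength, high-WMZ hub ground truth.

**Planted effects.** Group B ("apd_like", 28 subjects vs 29 controls by
default) has the between-module entries of three effect nodes shifted by
`effect_delta` = −0.15. Each subject's behavior-node between-module
loading is jittered (SD 0.06, comparable to the group effect at ±2 SD) and
the behavioral score mixes the standardized jitter with noise at
correlation `rho_behavior` = 0.6 — the planted correlation targets the
latent coupling parameter, so the measurable correlation with estimated PC
is attenuated by FC sampling noise, as it would be in real data. Ages are
Gaussian (10.9 ± 1.5 years) with the control mean shifted by +1.0 year,
reproducing the age confound of the emulated design. Covariances made
indefinite by planted shifts are repaired by eigenvalue clipping with
diagonal renormalization (tolerance 1e−8); entries outside (−1, 1) raise
an invalid-spec error instead.

**Default scale.** 90 nodes in 5 modules of 18, 250 timepoints. The
90-node scale keeps full simulation suites (50 replicate cohorts through
thresholding, consensus clustering and 5000-permutation testing) in the
tens of seconds; the generator scales to 333 nodes for single-cohort runs.

## Problem sizes used in tests and the acceptance script

Replicate simulations run at the default cohort scale with a coarsened
density grid {0.10, 0.175, 0.25, 0.325, 0.40}, consensus over 20–100
Louvain runs, the shared group partition for nodal curves, and 999–4999
permutations; detection of the pre-specified planted behavior node is
assessed at uncorrected p < 0.05 (a single planned comparison), while the
exploratory nodal suite is held to joint FDR q < 0.05. Calibration suites
use 500 null replicates (type-I error) and 200/100 null replicates (NBS
FWE, tests/acceptance script respectively).

## Known limitations

* The Gaussian generator does not model autocorrelation, so effective
  sample sizes per correlation are optimistic relative to real BOLD.
* PC_norm follows this package's documented null-median normalization;
  other published normalizations differ in detail, so absolute PC_norm
  values should not be compared across implementations (the 0.5 hub
  threshold retains its "above/below chance-level scale" reading).
* The weighted null model preserves the degree sequence and weight
  multiset but not the strength sequence.
* Louvain with resolution 1 has the usual resolution limit; very small
  planted modules may merge.
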