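# Methods

## The problem

A gene co-expression network (GCN) joins transcripts whose expression
profiles correlate across samples. When the sample compendium pools several
biological conditions (tumor subtypes, tissues, treatments), two failure
modes appear in pairwise scatters:

* **co-modality** — two separated clouds of samples (one per condition)
  produce a high Pearson/Spearman coefficient even when neither cloud is
  internally correlated, introducing false edges;
* **masking** — co-expression confined to one condition is diluted by the
  other conditions' samples and falls below any global threshold.

comodnet addresses both by decomposing every pairwise scatter into Gaussian
modes *before* correlating, correlating each mode separately, and recording
per-edge which samples produced the edge. Edges therefore carry their
condition context, and sample-level metadata can be tested for enrichment on
modules of edges.

## Pairwise mixture decomposition

For a transcript pair, the complete observations form an N x 2 cloud
modeled as a K-component bivariate Gaussian mixture

    f(x | theta) = sum_k p_k N(x | mu_k, Sigma_k),  sum_k p_k = 1.

Fitting is by EM. Initialization follows the random-start convention:
component means are K distinct randomly chosen data points, proportions are
uniform 1/K, covariances start at the pooled ML covariance. Runs stop when
the relative log-likelihood change falls below `tol` (default 1e-6) or at
`max_iter` (default 100). Per K the best of `restarts` (default 3) seeded
runs by log-likelihood is kept.

Model selection minimizes the Integrated Completed Likelihood

    ICL = BIC + 2 * ENT,   BIC = -2 log L + nu log N,
    ENT = -sum_ik t_ik log t_ik,

where `t_ik` are responsibilities and `nu` counts free parameters. ICL's
entropy term penalizes overlapping components, which suits mode discovery:
on unimodal data it prefers K = 1 where BIC alone would fragment. K ranges
over 1..min(K_max, N-1) with K_max defaulting to 5 (matching a compendium
of up to five conditions; the feasibility cap keeps at least one more
observation than components).

Two covariance families are provided: `free_full` (default; all Sigma_k
free, nu = 6K-1) and `free_volume_common_shape` (Sigma_k = L_k * C with one
shared unit-determinant shape/orientation matrix C, nu = 4K+1 — the
"ellipsoidal model with free proportions"). The free family is strictly
more expressive and simpler to fit; the constrained family is retained for
fidelity to mixture-library defaults.

Degenerate fits (collapsed components) get a small diagonal ridge
(1e-6 x pooled variance applied when a determinant falls below 1e-12); a
fit that stays singular is retried from a fresh seeded start up to 3 times
and then reported as a degenerate pair.

The EM inner loop for the free family is compiled with numba; the
constrained family runs the vectorized numpy path. Both record the
per-iteration log-likelihood so monotonicity is assertable.

## Sample strings and per-cluster correlation

Every edge candidate carries one digit per GEM sample:

| digit | meaning |
|-------|-------------------------------------------------|
| 1     | in this edge's cluster (used for correlation)   |
| 0     | observed, not in this cluster                   |
| 9     | missing expression in either gene               |
| 6     | removed as pre-clustering outlier               |
| 8     | removed as within-cluster outlier               |

Outlier removal is per-axis Tukey fencing at the quartiles, applied twice.
The pre-clustering pass uses the *far-out* fences (3 x IQR): before
clustering the cloud is intentionally multimodal, and classic 1.5 x IQR
fences computed from a majority mode would flag large parts of a minority
mode as outliers — truncating exactly the condition-specific signal the
method exists to find (on the default synthetic fixture, 1.5 x IQR removed
~40% of a 56-sample minority mode and attenuated its correlation from 0.86
to 0.45). Within a cluster, where unimodality is the model assumption, the
classic 1.5 x IQR fence applies. Clusters are then filtered:

* **size**: at least `min_cluster_size` surviving samples (default 30,
  derived live from the Fisher-z power bound
  n = ceil(((z_{1-alpha/2} + z_{1-beta}) / atanh(r))^2 + 3) at
  alpha = 0.05, beta = 0.2, r = 0.5);
* **range**: both genes must span at least `min_expression_range` log2
  units within the cluster (default 0.1) — near-constant expression
  produces rank artifacts up to spurious perfect correlations.

Surviving clusters are correlated with Spearman (default; average ranks on
ties) or Pearson over their `1`-digit samples. A pair with two qualifying
modes yields two edges between the same transcripts, each with its own
sample string (multigraph semantics).

A cluster's reported `size` is its surviving sample count, i.e. the number
of `1` digits, and the size filter applies to that count; the within-cluster
outliers (`8`) sit outside it. This keeps every network edge's `1`-count at
or above the power-analysis minimum.

Pairs are enumerated row-major over the upper triangle and processed in
pair-index windows. Per-pair seeds derive from the pair's transcript ids
only, so chunked runs merge to the unchunked result and gene order does not
affect the fit.

## Threshold selection by random-matrix statistics

The significance threshold is the correlation level at which the
thresholded similarity matrix stops looking like correlated noise. Per
pair the similarity entry is the maximum |rho| over non-skipped clusters
("is there any significant relationship"); entries below a candidate tau
are zeroed and transcripts without surviving entries dropped.

The nearest-neighbour spacing distribution (NNSD) of the matrix's unfolded
eigenvalues discriminates the two regimes: a noise-dominated matrix follows
the Gaussian Orthogonal Ensemble (Wigner-Dyson, level repulsion), while a
matrix reduced to modular blocks is a superposition of independent spectra
and follows Poisson statistics. Unfolding fits a cubic least-squares spline
(10 interior knots at quantiles) to the cumulative spectral density after
pruning near-duplicate eigenvalues (tolerance 1e-6, since exact
degeneracies break the NNSD), maps eigenvalues through it and rescales
spacings to mean 1. Spline unfolding is not constrained monotone; rare
negative spacings are clipped to zero before rescaling.

Goodness-of-fit to Poisson is a chi-square against exponential bin counts
N (exp(-a) - exp(-b)) on 60 bins over [0, 3] plus an overflow bin;
low-expectation tail cells are merged rightward to keep expected counts at
5 or more. The scan ascends tau from `tau_start` (default 0.5) in
`tau_step` (default 0.001) increments and stops at the first tau whose
statistic drops to the 0.999 chi-square critical value (~99.6 at 59 df);
first-crossing semantics tolerate small local non-monotonicity in the
trajectory. A minimum of 100 eigenvalues is required; scans that shrink the
matrix below that report a diagnostic instead of a threshold.

Desk-scale note: with a few hundred eigenvalues the chi-square has limited
power, so the calibration fixture uses ~600 genes; at compendium scale
(tens of thousands of transcripts) the statistic is far sharper.

## Network, modules, enrichment, evaluation

Edges are all (pair, cluster) records with |rho| at or above the chosen
threshold and strictly below 1.0 — perfect correlations are artifacts of
near-zero expression range and are excluded. Degree distributions and
clustering-coefficient profiles are computed on the simple-graph projection.

Modules are link communities: edges sharing a node are scored by the
Jaccard similarity of the inclusive neighborhoods of their non-shared
endpoints, single-linkage clustering runs on 1 - similarity, and the
dendrogram is cut at the merge height maximizing partition density

    D = (2/M) sum_c m_c (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)),

with n_c = 2 modules contributing zero. Candidate cuts are the merge
heights below 1 (edges with zero similarity never link; fully disconnected
edge sets fall back to per-component modules), and density ties keep the
lower height. Because edges, not nodes, are partitioned, a pleiotropic gene
can belong to several modules. Multigraph records inherit the module of
their transcript pair but keep their own sample strings. Similarity is
computed on the simple projection — neighborhoods are node-set concepts.

Clinical enrichment: a module's sample set is the set of samples with digit
`1` in at least ceil(0.95 m_c) of its m_c edges (ceiling, the stricter
reading); a one-sided Fisher's exact test asks whether an annotation
category is over-represented in that set against the samples annotated for
that attribute. Functional enrichment runs the same test per GMT term over
a genomic background. Raw, Bonferroni and Benjamini-Hochberg p-values are
always reported; the significance convention is raw p < 0.001. Samples
lacking a value for an attribute drop out of that attribute's background.

Guilt-by-association performance is neighbor voting with k-fold
cross-validation (default 3 folds, the evaluation convention in this
literature): per function, each fold's positives are hidden, genes score
(annotated neighbors)/degree on the binary simple-projection adjacency
(degree-0 genes score 0), and the AUROC ranks hidden positives against
never-annotated genes, with half credit for ties (the Mann-Whitney
identity). 0.5 is chance; 0.7 is good.

## The synthetic compendium generator

The generator emulates a mixed-condition compendium: conditions with fixed
sample counts, planted modules of genes that co-express only in their
active conditions, background genes of pure noise, and uniform missing
values. Module genes in active conditions follow

    x_gs = mu_g + shift + noise_sd (sqrt(r) z_ms + sqrt(1-r) eps_gs)

with one latent factor z per (module, sample), giving within-module pairwise
correlation r by construction — which is what makes quantitative recovery
tests possible. Inactive conditions and background genes are independent
noise at the baseline mean mu_g (drawn uniformly in 4..10 log2 units), so an
active module gene is bimodal across the compendium with the two modes
separated by `mean_shift`. An optional compendium-wide latent factor
(`background_correlation`) correlates *all* genes at a low level, emulating
global covariation; it is what makes the threshold-scan calibration fixture
possible (noise regime connected, modules detaching above the background
level).

Defaults: five conditions of 60 samples (mirroring a five-subtype
compendium), two single-condition 10-gene modules plus one module shared by
two conditions (the shared-etiology case), 200 background genes,
noise_sd 1.0, mean_shift 4.0 (clearly separated modes at realistic
log2-expression noise), latent correlation 0.9, missing rate 0.02,
background correlation 0.

What the generator does **not** emulate: count-based noise (negative
binomial mean-variance coupling), library-size and batch effects,
heavy-tailed expression, correlated missingness, overlapping module
membership. Passing recovery tests therefore demonstrates the machinery is
correct under its own model assumptions, not that real compendia will yield
equally clean modules.

## Numerical and design choices

* log2 of a non-positive value is missing, not log2(x+1): zeros carry no
  rank information and the missing-value digit exists precisely for this.
* KS screen: two-sample statistic of each sample against the pooled values
  of all other samples (leave-one-out); flagged samples are reported, not
  removed — removal is the caller's decision.
* Quantile normalization with missing values: values rank within their
  non-missing column and interpolate the reference (mean of order
  statistics on a proportional grid); exact ties receive the average of
  their mapped reference quantiles, making the result order-independent.
* Pair enumeration seeds are symmetric in gene order, so (i, j) and (j, i)
  give identical fits.
* Module ids are "M" + zero-padded rank by descending edge count.
* The end-to-end recovery check extracts at tau = 0.5, the midpoint
  between the fixture's background (~0) and planted (~0.9) correlation
  levels; the RMT scan is exercised separately on the
  background-correlated fixture because the default fixture's thresholded
  matrix is too small for spacing statistics.

## Problem sizes

Calibration and recovery runs use desk-scale sizes chosen to keep the full
suite fast while leaving the statistics well-powered: the default fixture
(230 genes x 300 samples, ~26k pairs) for end-to-end recovery, a 600-gene
fixture for the threshold scan, 100 seeded replicates for the model-selection
and NNSD calibrations, and 2000-spacing GOE spectra drawn through the
tridiagonal beta = 1 ensemble (identical eigenvalue law to dense GOE at a
fraction of the eigensolve cost).

## Known limitations

* Non-linear single-population relationships can be split into several
  adjacent modes; no cluster-merging post-processing is applied.
* The NNSD chi-square needs on the order of hundreds of eigenvalues;
  networks whose thresholded matrix is smaller report a diagnostic and need
  an explicit threshold.
* Spline unfolding is unconstrained; pathological spectra can produce
  locally non-monotone maps (clipped at zero spacing).
* Mutual-information similarity, d > 2 mixtures, SEM/CEM variants and
  workflow-manager integration are out of scope.
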