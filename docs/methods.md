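# Methods

`fcbiotype` implements a network-based patient-stratification analysis
for resting-state functional connectivity: select symptom-correlated
edges, cluster patients with multikernel similarity learning, validate
the cluster number and assignment stability by resampling, contrast
each biotype against controls edgewise with network-block FDR, and
correlate the resulting signed node-abnormality profiles with
parcellated neurotransmitter density maps. This note records the model,
the defaults and why, the synthetic-data assumptions, and the numerical
choices.

## Data model

Connectivity is a per-subject symmetric P x P matrix of Fisher-z
transformed correlations (z = arctanh r), diagonal fixed at 0. The
bundled default atlas has P = 246 regions labeled with eight
resting-state networks (visual, somatomotor, dorsal attention, ventral
attention, limbic, frontoparietal, default, subcortical); its
ROI-to-network assignment is a synthetic stand-in with realistic
per-network counts — real analyses should supply their own parcellation
table. Edges are the strict upper triangle in row-major order, so
P = 246 gives E = P(P-1)/2 = 30,135 edges. The clinical table carries
the 19 SIPS prodromal-symptom items (domains P/N/D/G), two GAF
functioning scores, demographics, and the eight MCCB cognitive tests.

## Edge selection

Within the patient group, every edge is Pearson-correlated with each of
the 21 clinical items (19 SIPS + 2 GAF); p-values use the exact
transform t = r sqrt((n-2)/(1-r^2)) on n-2 df, two-sided. An edge is
selected when p < alpha on at least `min_items` items (defaults
alpha = 0.005, min_items = 3; a Spearman option exists for robustness).
No multiplicity correction is applied at this stage — selection is a
screening step whose stability is assessed by resampling. Zero-variance
edges or items yield r = 0, p = 1 and are counted in a degeneracy
counter rather than raised.

With independent items the expected null selection count is
E * P[Bin(21, 0.005) >= 3] ~ 5 edges; in practice clinical items are
inter-correlated, which raises the false-selection count — at the
synthetic defaults the observed false fraction is ~0.10-0.15 of the
selected set.

## Multikernel similarity learning

The kernel bank holds 55 Gaussian kernels over a (k, sigma) grid,
k in {10, 12, ..., 30} neighbors and sigma in {1.0, 1.25, ..., 2.0}:
K(i,j) = exp(-d^2(i,j) / (2 eps_ij^2)) with local scaling
eps_ij = sigma (m_i + m_j)/2, where m_i is the mean distance of subject
i to its k nearest neighbors (features z-scored first; an epsilon floor
handles duplicate subjects). Kernels are symmetrized and have unit
diagonal.

The learner minimizes

    f(S, w, L) = -<K_w, S> + beta ||S||_F^2
                 + gamma tr(L' (I - S_sym) L) + rho sum_m w_m log w_m

over a row-stochastic similarity S, simplex kernel weights w
(K_w = sum w_m K_m) and an orthonormal N x C spectral factor L. Block
updates are exact minimizers — L: top-C eigenvectors of S_sym; w:
softmax of the kernel-similarity alignments <K_m, S>/rho; S: row-wise
Euclidean projection of (K_w + gamma L L')/(2 beta) onto the simplex —
so the objective is non-increasing by construction (the test suite
asserts this to 1e-9 relative slack). Defaults beta = 0.8, gamma = 1,
rho = 0.1 gamma, 30 outer iterations, relative tolerance 1e-6. An
optional nearest-neighbor diffusion smoothing of S is implemented but
off by default. Final labels come from k-means (20 restarts, seeded) on
the row-normalized top-k spectral embedding of S.

## Cluster-number estimation

`estimate_k` is the eigengap heuristic: eigenvalues of the normalized
Laplacian I - D^{-1/2} S_sym D^{-1/2} in ascending order, k chosen to
maximize lambda_{k+1} - lambda_k over k in 2..8, ties broken toward
smaller k (parsimony). On an exactly block-diagonal similarity with b
blocks the zero eigenvalue has multiplicity exactly b, so the estimator
is exact there.

What it is applied to matters. The dense averaged Gaussian kernel
behaves like a near-complete graph: its Laplacian spectrum is nearly
flat above the trivial eigenvalue and the difference-form eigengap
degenerates to k = 2 regardless of structure. The pipeline therefore
applies the eigengap to the sparse row-stochastic similarity obtained
by projecting each row of K_bar/(2 beta) onto the probability simplex —
exactly the learner's own initialization (its S-step at gamma = 0). The
projection zeroes weak entries, producing a neighbor graph whose
spectrum separates cleanly (on the default synthetic cohort the gap at
k = 3 exceeds the others in every tested seed). A rotation-cost
estimator remains a pluggable alternative.

## Resampling validation

The stability harness repeats, per iteration: draw 90% of patients
without replacement; rerun edge selection on that subset; estimate k;
learn the similarity and cluster. Per-iteration RNG substreams
(`numpy SeedSequence.spawn`) make the log exactly reproducible.
Iterations with an empty selection are logged as skipped. The modal k
across iterations fixes the final cluster number, and the final
clustering runs on the full patient sample.

Assignment stability is scored by normalized mutual information with
sqrt normalization, NMI = I(A;B)/sqrt(H(A)H(B)), natural logs, computed
from the joint contingency table. Conventions: partitions identical up
to relabeling return exactly 1; if exactly one partition is single-class
(zero entropy) the NMI is defined as 0. The default comparison is final
full-sample labels vs each iteration's labels on the shared subjects; a
pairwise iteration-vs-iteration variant is provided. The null reference
shuffles one labeling (default 500 permutations).

Classifier reproducibility uses a linear one-vs-one SVM (C = 1) under
repeated stratified 10-fold cross-validation, reporting mean train and
test accuracy overall and per class. The repetition count is
config-exposed (500 in a full run; the test suite and acceptance script
use 25, which stabilizes the mean to well under a percentage point on
separable data).

## Group contrasts and block-level inference

Each biotype is contrasted against controls with a per-edge linear
model z ~ group + sex + age + education (sex coded 0/1, covariates
mean-centered — this affects only the intercept). With no covariates the
group t is algebraically the pooled two-sample t (asserted numerically
at 1e-10). Edgewise tests are two-sided; suprathreshold edges
(p < 0.005 uncorrected) are binarized by sign into symmetric increase /
decrease matrices.

Cluster-level correction is an explicit network-pair cluster-mass
permutation test: edges are grouped into the 36 unordered network-pair
blocks; the block statistic is the sum of |t| over suprathreshold edges;
the null re-permutes group labels (covariates fixed) and recomputes the
whole edgewise model; block p = (1 + #{perm >= obs}) / (n_perm + 1);
BH-FDR across the 36 blocks at q < 0.05. This replaces an opaque
"cluster-based parametric multivariate" correction with a transparent,
assumption-light analog, and reports label it as such. Note an
arithmetic constraint: with 36 blocks in the family, a block can only
survive BH at rank 1 if p < 0.05/36, which requires at least 999
permutations; the default is 1000.

Summary-statistic utilities reproduce demographic-table columns from
printed values alone: pooled-variance two-sample t (df = n1+n2-2),
Pearson chi-square without continuity correction, and one-way ANOVA
reconstructed from group means, dispersions (SD or SE; SE converted via
sd = se sqrt(n)) and counts.

## Node abnormality and neurotransmitter maps

A contrast's signed binary matrices are summed along the ROI dimension,
separately for increases and decreases, giving two nonnegative degree
vectors per contrast (the handshake identity sum(degree) = 2 x edges
holds by construction). Each vector is Pearson-correlated (Spearman
optional) with each of the 39 parcellated receptor/transporter maps;
p-values use the exact t transform on P-2 df and are BH-FDR adjusted
over the entire (contrast x direction x map) table in one family.
Degenerate vectors (e.g. an empty abnormality map) are flagged and
excluded from the family rather than correlated. No
spatial-autocorrelation-preserving (spin/variogram) null is applied by
default — plain parametric p + FDR mirrors the target analysis; this is
a known limitation for smooth real maps. Bonferroni is available as an
alternative correction flag.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs:

* 151 patients + 88 controls; 246-region atlas; biotype proportions
  0.298 / 0.192 / 0.510 (largest-remainder apportionment).
* Baseline connectivity: edge means 0.45 (within-network) / 0.10
  (between-network) Fisher-z with 0.10 SD edge-specific jitter; subject
  noise SD 0.15 — magnitudes typical of Fisher-z resting-state edges.
* Biotype effects: signed shifts on network-pair blocks, |delta| in
  0.20-0.30 Fisher-z. Biotype 1: increased somatomotor-somatomotor,
  decreased visual-subcortical. Biotype 2: increased
  subcortical-subcortical and visual/dorsal-attention/somatomotor,
  decreased within-visual and somatomotor-subcortical. Biotype 3:
  diffuse decreases sparing visual and dorsal attention, with increased
  limbic-subcortical and limbic-somatomotor. Effect sizes are not
  claims about any cohort; they are set so that recovery is possible
  but not trivial, and are config-exposed.
* Clinical coupling: four latent severity axes, one per SIPS domain,
  each loading (0.12 Fisher-z) on its share of 600 coupled edges drawn
  from the affected blocks, aligned with each edge's planted direction
  and orthogonalized to biotype membership. Items mix their domain's
  axis with noise, with the mixing weight calibrated per item so the
  mean |r| between an item and its coupled edges hits the design target
  (default 0.4) — verified by Monte Carlo to within 0.01. GAF scores
  couple negatively to all domains. A single global severity axis
  fails in two directions: biotype variance leaks into all affected
  edges (selection balloons roughly 14-fold), or, at loadings strong
  enough to keep selection clean, the one-dimensional severity
  continuum stretches every cluster and destroys the spectral eigengap.
  Four domain axes keep the within-biotype geometry near-isotropic and
  satisfy both the selection and the clustering recovery properties.
  Control subjects' SIPS items are near-zero noise, mirroring healthy
  screening scores.
* Maps: 39 named receptor/transporter maps; three (5HTT, D2, MOR —
  matching the serotonergic/dopaminergic/opioid families the biotypes
  are discussed against) are planted as
  rho x standardized(signed node profile) + sqrt(1-rho^2) x noise with
  rho = 0.6; the rest are spatial noise. Recovered correlation is 0.6
  within Monte-Carlo error.
* RNG: a single seed spawns separate substreams for connectomes,
  clinical items, demographics and maps, so e.g. changing the map count
  never perturbs the connectome draw. Identical design + seed gives
  bitwise-identical outputs.

What the generator does **not** emulate: spatial autocorrelation within
maps and connectivity, site/scanner effects, symptom floor effects
(items are Gaussian, not ordinal), motion artifacts, and
positive-definiteness of the per-subject matrices (never needed — the
pipeline does not invert them). Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under its own assumptions,
not that a real cohort would yield three biotypes.

## Problem sizes and numerical choices

The default test/acceptance problem sizes: stability loop 100
iterations (full runs use 500); SVM 25 repetitions (full 500); block
permutation 1000 (contrasts) / 200 (20-seed null calibration at a
60-ROI, 100-subject scaled design — type-I control is size-independent);
NMI null 500 shuffles. Symmetry tolerance for input matrices 1e-10;
matrices serialized at 12 significant digits; simplex projection is the
exact O(n log n) algorithm; eigen-decompositions use LAPACK `eigh` on
symmetrized matrices. K-means tie-breaks are fixed by seeding; cluster
labels are renumbered 1..k by order of first appearance so identical
partitions are byte-identical.

## Known limitations

* The eigengap estimator needs a sparse similarity; on dense kernels it
  collapses to k = 2 (documented above, and the reason the pipeline
  estimates k on the simplex-projected similarity).
* Permutation of group labels assumes exchangeability under the null
  after covariate adjustment (labels are permuted, covariates kept); a
  Freedman-Lane scheme would be more exact with strong covariate
  effects.
* Printed-table reproduction is limited by the table's own rounding:
  at |t| ~ 28 the two-decimal rounding of the input means propagates to
  ~ +-0.01 in t.
* BH-FDR across 36 blocks with permutation p-values is granular in
  n_perm; use >= 999 permutations.
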