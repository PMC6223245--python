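# Methods

## Problem setting

The package predicts unobserved links in a bipartite microbe–disease
association network. The input is a curated pair list — typically a few
hundred literature-supported associations over hundreds of microbes and a few
dozen diseases — encoded as a binary adjacency matrix `Y` (rows = microbes,
columns = diseases, sorted unique labels). Only positive evidence exists:
a 0 means *unknown*, not *non-associated*, which motivates both the profile
preprocessing and the rank-based evaluation below.

Duplicate records (the same pair backed by different evidence strings) are
collapsed when the matrix is built; the collapse count is logged. The dedup
key is the (microbe, disease) pair alone — evidence identifiers distinguish
sources, not associations.

## Similarity construction

**GIP kernel.** Two entities are similar when their interaction profiles
(rows or columns of `Y`) are close: `S(i,j) = exp(−γ ‖y_i − y_j‖²)` with
`γ = γ′ / mean_i ‖y_i‖²`. The normalization adapts the bandwidth to catalogue
density. `γ′ = 1` by default on both axes, the convention of the kernel's
original formulation for interaction networks; both are configurable.
All-zero profiles are legal (they contribute 0 to the normalization sum and
have similarity `exp(−γ‖y_j‖²) > 0` to everything); only a fully zero matrix
is rejected, since the bandwidth is then undefined.

**Symptom-based disease similarity (SDM).** Recomputing a symptom-based
similarity from literature co-occurrence is out of scope; the matrix is
consumed as a precomputed input, aligned *by label* with the disease axis.
Diseases missing from the SDM get similarity 0 before averaging (with a
warning; a strict mode errors instead). File input is clipped to [0, 1] and
symmetrized by averaging with the transpose, logging when the change exceeds
1e-9. The integrated similarity is the elementwise mean `(S^{d′} + SDM)/2`;
without an SDM the GIP kernel passes through unchanged.

## WKNN preprocessing

For each entity `q`, the K most similar entities *with at least one known
association* (q itself excluded — otherwise cross-validation would leak the
held-out label back into its own profile) are sorted by descending
similarity, ties broken by label. The new profile is
`(1/Q) Σ_{i=1..K} α^{i−1} S(i,q) · profile(i)` with `Q = Σ_{i=1..K} S(i,q)`.
The decay `α` appears in the weights but not in `Q`; the asymmetry is
deliberate (it shrinks the contribution of lower-ranked neighbors below a
convex average, keeping imputed scores conservative) and matches the
antecedent WKNN formulation — `normalize_with_decay=True` selects the fully
normalized variant. If all K similarities are zero the profile is set to
zeros rather than NaN. Defaults `K = 5`, `α = 0.9`: a small neighborhood with
mild decay, the usual WKNN regime; both are recorded in run metadata.

Microbe-side and disease-side results are combined as
`Y_md = (a₁Y_m + a₂Y_d)/(a₁+a₂)` with `a₁ = a₂ = 1`, and the adjacency is
updated once by `Y ← max(Y, Y_md)`, so entries that were 1 stay exactly 1 and
all entries remain in [0, 1]. No iterative refinement is performed.

## Neighborhood graphs

The factor regularization uses, per axis, a masked similarity graph
`S* = X ∘ S` where `X(i,j)` is 1 when `i` and `j` are mutual p-nearest
neighbors *and* co-occur in at least one cluster, 0 when neither is a
neighbor of the other *and* they share no cluster, and 0.5 otherwise; the
diagonal is fixed at 1 (self-similarity is kept; the Laplacian's off-diagonal
structure is unaffected since the degree matrix absorbs it). `p = 5` by
default, independent of the WKNN K. Neighbor ties break by label.

Clusters come from a simplified ClusterONE: greedily grow a cluster from the
uncovered vertex of highest weighted degree, accepting the add/remove move
that most increases cohesiveness `w_in/(w_in + w_bound)` until no move
improves it; discard grown clusters whose internal density (mean pairwise
weight) falls below 0.5; merge cluster pairs with Jaccard overlap ≥ 0.8;
uncovered vertices become singletons. The published algorithm's penalty term
and overlap scoring are intentionally omitted — only the cohesive-greedy core
is needed to instantiate the weight matrix — and externally computed clusters
can be supplied as a file instead. The cluster condition is read as
*co-membership of the pair*, the only well-defined reading.

`L = D − S*` is symmetric, has zero row sums, and satisfies
`xᵀLx = ½ Σ S*_{ij}(x_i − x_j)²`, hence is positive semi-definite; the test
suite asserts all three.

## Solver

Objective:
`‖Y − WHᵀ‖²_F + λ_l(‖W‖²_F + ‖H‖²_F) + λ_m Tr(WᵀL_m W) + λ_d Tr(HᵀL_d H)`,
`W, H ≥ 0`, with `Y` the *preprocessed* matrix (the pipeline order puts WKNN
before factorization). Multiplicative updates derived from the KKT
conditions run sequentially — W first, then H with the updated W. Defaults:
`rank_k = 10` (set to the planted rank in fixture studies), all λ = 0.01,
`max_iter = 1000`, `tol = 1e-6` on the relative objective change, seeded
uniform(0, 1) initialization. None of these is canonical; a grid-search
helper is provided. Denominators are floored at `eps = 1e-12` instead of
smoothing the numerators, preserving the zero-locking property (a factor
entry that reaches 0 stays 0). The objective trace is recorded every
iteration and is non-increasing — the updates are
majorization-minimization steps — which the acceptance suite verifies
together with a KKT residual `max‖min(factor, |gradient|)‖ < 1e-3` at
convergence.

**Known limitation.** As an MM scheme the multiplicative updates descend
within the basin of their initialization. On dense inputs (the solver's
actual domain — WKNN preprocessing produces dense matrices) they match an
independent projected-gradient minimizer to well under 1%; on sparse binary
toy inputs the two methods can settle in different local minima from the
same start, with the multiplicative fixed point a few percent higher. This
is intrinsic to the update family, not a defect: the KKT residual at such
points is ~0.

## Evaluation

LOOCV holds out each known association in turn, rebuilds everything — GIP
similarities, WKNN profiles, graphs, factors — from the reduced matrix, and
ranks the held-out pair's score against the candidate (unknown) pairs:
all of them in global mode, those of the same disease in local mode. Per-fold
full recomputation is the default because the held-out label influences both
similarity and preprocessing; `fast_mode` reuses the similarities across
folds for exploratory runs and is logged as optimistic.

Ties get mid-ranks. Per fold, `u = (N + 1 − r)/N` is exactly the mid-rank
Mann–Whitney normalization (fraction of the fold's N candidates ranked below
the test pair); the reported AUC is the average of `u` over folds, and the
emitted ROC staircase (vertical jumps at tied thresholds) integrates to the
same value by the trapezoid rule. The test suite asserts the Mann–Whitney
identity to 1e-12 against an independent implementation. Local-mode folds
have per-disease candidate counts; their normalized ranks are pooled the same
way.

## Synthetic fixtures

The generator emulates a curated catalogue: entities are assigned to one of
`true_rank` contiguous latent groups; factor loadings are uniform(0.6, 1) on
the own group and uniform(0, 0.05) elsewhere, giving the block structure the
clustering stage is meant to find; the true score matrix `P = W₀H₀ᵀ`
(rescaled to max 1) has numerical rank ≤ `true_rank`. The binary adjacency
takes the top `density` fraction of `P`'s cells, then flips each cell with
probability `noise_flip_prob`; the SDM is the cosine similarity of the
disease factors plus Gaussian noise (sd `sdm_noise_sd`), clipped,
symmetrized, unit diagonal. Everything is deterministic per seed.

Defaults — 60×25, rank 4, density 0.08 (~120 planted pairs), flip noise 0.01,
SDM noise sd 0.05 — are sized so a full LOOCV sweep (one pipeline run per
fold) completes in seconds while leaving the problem non-trivial: flip noise
plants spurious associations whose held-out ranks are near-random, and the
SDM is informative but noisy. What passing on fixtures does *not* show:
real catalogues have strong ascertainment bias (well-studied diseases have
many associations), heavy-tailed microbe degrees, and disease similarities
whose noise is structured rather than Gaussian; absolute AUC values on
fixtures therefore do not transfer to real data, only the correctness of the
machinery is established.

## Numerical and design notes

- Labels are compared case-sensitively after whitespace trimming; matrix
  rows/columns are bound to sorted unique labels for run-to-run determinism.
- All tie-breaks (neighbor selection, prediction lists, cluster seeding) are
  lexicographic by label.
- Score matrices are written with 17 significant digits; read-back
  round-trips below 1e-12.
- One seed (`RunConfig.seed`) governs a pipeline run; the solver inherits it.
  Run metadata (resolved config + diagnostics) is written next to every
  output, and a rerun from the same metadata is byte-identical.
- `rank_predictions` excludes known pairs, so a "new disease" run (column
  zeroed before computation) ranks the full microbe list; the column scores
  are nonzero because the disease similarity (GIP on a zero profile is
  positive; SDM adds external signal) feeds the WKNN imputation.
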