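# Methods

## Problem

Drug–target interaction (DTI) prediction is cast as low-rank matrix
completion.  The known interactions form a binary adjacency matrix
Y ∈ {0,1}^{M×N} with drugs in rows and targets in columns; a sampling
operator P (the *mask*) marks which cells count as training
observations.  The estimator recovers a real-valued score matrix Z of
rank at most r minimizing

    J(Z) = ½‖P(Y) − P(Z)‖_F² + λ‖Z‖_*
           + α₁·Tr(Zᵀ L_d Z) + α₂·Tr(Z L_t Zᵀ),

where ‖·‖_* is the nuclear norm (sum of singular values, the convex
surrogate for rank) and L_d, L_t are graph Laplacians built from drug–drug
and target–target similarity.  Scores are ranking quantities — no
thresholding is applied — matching the AUC/AUPR evaluation.

Convention: the data term carries ½ and λ shrinks singular values by
exactly λ.  Formulations written with a data term ‖·‖² and a threshold λ/2
are the same problem with λ doubled; the code uses one convention
throughout.

## Nuclear norm ↔ bilinear factorization

The identity ‖Z‖_* = min_{ABᵀ=Z} ½(‖A‖_F² + ‖B‖_F²) unifies nuclear-norm
minimization with matrix factorization.  For a fully observed Y the
rank-capped proximal problem

    min_{rank(Z)≤r} ½‖Y − Z‖² + λ‖Z‖_*

has the closed form Z = U_r S_λ(D_r) V_rᵀ — truncated SVD followed by
soft-thresholding of the singular values (`svt_oracle`, the brute-force
reference).  The equivalent bilinear program in (A, B) is solved
iteratively by the rank-restricted soft SVD (`rank_restricted_soft_svd`):
alternating exact ridge updates

    B ← Yᵀ A (AᵀA + λI)⁻¹,   A ← Y B (BᵀB + λI)⁻¹,

with re-orthogonalization after each sweep (two thin QRs plus an r×r SVD)
restoring the (U, d, V) form.  Each half-step is an exact minimization and
the balanced re-split never increases the penalty, so the objective is
nonincreasing; at the fixed point the reconstruction equals the closed
form.  The oracle-equivalence test sweeps 100 random problems and requires
elementwise agreement to 1e-6.

**Convergence statistic.**  Progress is measured by the relative squared
Frobenius change between successive iterates, evaluated from the factors
alone via the trace identity

    ∇F = [tr(D⁴) + tr(D̃⁴) − 2 tr(D² Uᵀ Ũ D̃² Ṽᵀ V)] / tr(D⁴),

with D² the diagonal of singular values.  A zero old iterate yields +inf
(unless the new iterate is also zero, then 0).  Because the per-sweep
change underestimates the distance to the fixed point by roughly
ρ/(1−ρ) for a linear convergence rate ρ, the stopping rule additionally
estimates ρ from consecutive changes (Aitken-style) and stops only when
the projected remaining squared distance is below the tolerance; without
this safeguard the oracle agreement stalls near 3e-6.

**Initialization.**  The fully observed solver starts from a seeded random
orthonormal pair (U, V) with unit singular values, so the oracle
equivalence genuinely validates the iterative path.  The masked solver
instead starts from the thresholded SVD of the zero-filled P(Y) — the
classic warm start for iterative completion — which makes the whole
pipeline deterministic and equivariant under relabeling of drugs or
targets; a random initialization would break the symmetry property that
permuting inputs permutes outputs.

## Masked completion

`soft_impute_masked` handles a partial mask by iterative fill-in: each
iteration forms Y* = P(Y) + P⊥(ABᵀ) (observed entries from the data,
unobserved from the current reconstruction) and applies one warm-started
alternating sweep on Y*.  This is majorize–minimize — the surrogate
½‖Y* − Z‖² + λ‖Z‖_* touches the masked objective at the current iterate —
so the recorded objective ½‖P(Y−Z)‖² + λ‖Z‖_* is provably nonincreasing.

A property of tiny-λ completion worth knowing: spurious small singular
components decay at a rate very close to 1, so the convergence statistic
can floor near machine precision while the unobserved-entry error is still
shrinking.  The recovery tests therefore run with a generous iteration
budget (30 000 fills on a 30×25 problem, a few seconds) rather than
trusting an early plateau.  On the shipped noiseless rank-2 instance with
60% of cells observed (λ = 1e-3, r = 4) the solver reaches ~1e-4 relative
error on the hidden entries; a cross-check with an independent convex
solver (FISTA on the uncapped problem) confirms both converge to the same
optimum.

## Similarities and graph Laplacians

Each side combines five matrices: one provided externally (SIMCOMP-style
chemical similarity for drugs; normalized Smith–Waterman sequence
similarity for targets; a zero matrix when absent) and four computed from
interaction profiles (rows of Y for drugs, columns for targets):

* **cosine** — inner product over norms; all-zero profiles get similarity
  0 with everything (no evidence of similarity);
* **correlation** — Pearson on the binary profiles, negatives clipped to 0
  (graph regularization needs nonnegative edge weights), constant profiles
  get 0;
* **Hamming** — fraction of agreeing positions;
* **Jaccard** — |intersection| / |union|, 0 when both profiles are empty.

Each matrix is sparsified to its p nearest neighbors before summation
(symmetric OR rule; the diagonal is preserved).  Entries tied with the
p-th largest are all kept: binary profiles tie constantly, and index-based
tie-breaking would silently break relabeling equivariance.  A 1e-9 slack
on the threshold comparison absorbs float noise among mathematically tied
values.  Sparsify-then-sum (rather than sum-then-sparsify) is the
documented choice, and the provided similarity participates in
sparsification uniformly with the profile similarities.

The combined similarity S^com is the elementwise sum; D^com is its
diagonal degree matrix and L^com = D^com − S^com.  Because L is linear in
S, the Laplacian of the sum equals the sum of the per-matrix Laplacians —
tested explicitly.  L is positive semidefinite whenever S is nonnegative,
which keeps the graph terms of J nonnegative.

## The full model's outer loop

With auxiliaries W₁ (drug side) and W₂ (target side) coupled to Z by
quadratic penalties v₁, v₂, each outer iteration solves two Sylvester
equations and performs one nuclear-norm proximal step:

1. (α₁ L_d + (v₁/2) I) W₁ + W₁ ((v₁/2) I) = v₁ Z
2. ((v₂/2) I) W₂ + W₂ (α₂ L_t + (v₂/2) I) = v₂ Z
3. Z ← rank-restricted soft SVD of
   [P(Y) + P⊥(Z) + v₁W₁ + v₂W₂] / (1 + v₁ + v₂),
   with shrinkage λ/(1 + v₁ + v₂), warm-started from the previous factors.

The Sylvester solves use Bartels–Stewart (scipy); both pencils are
positive definite (PSD Laplacian terms plus strictly positive multiples of
the identity), and residuals are verified to 1e-8 relative.  The blend in
step 3 comes from completing the square over the masked data term (fill-in
majorization with the previous Z) and the two couplings.

Two design choices matter for monotonicity of J:

* **Initialization at the unregularized solution.**  The outer loop starts
  from the plain masked-NNM completion.  The splitting drives an augmented
  objective (graph terms on the auxiliaries), not J itself; from a
  near-zero start J would *rise* as the data term is fitted.  Starting
  from the unregularized completion turns the iterations into progressive
  graph smoothing, and J decreases from the first step.
* **Monotone safeguard.**  Near the splitting's own fixed point J can
  creep back up by ~1e-4 relative.  An iterate is accepted only while J
  decreases; the loop stops at objective stationarity and returns the
  objective-best iterate.  The recorded trace is therefore nonincreasing
  by construction, and the safeguard rarely engages before the Eq.-style
  relative-change criterion is met.

With α₁ = α₂ = 0 the model reduces exactly to plain masked nuclear-norm
completion and the implementation delegates to that solver; v₁, v₂ are
held constant across iterations (no annealing).

## Hyperparameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| λ (`lam`) | nuclear-norm weight | 0.1 | singular values shrink by exactly λ |
| α₁, α₂ | drug/target graph weights | 0.1, 0.01 | 0 disables graph terms |
| v₁, v₂ | penalty couplings | 0.1, 0.1 | must be > 0 |
| `p_nn` | nearest-neighbor sparsification | 2 | applied per similarity matrix |
| r | rank cap | 4 | latent dimension of the factors |
| `tol` | relative-change threshold | 1e-5 | squared relative Frobenius change |
| `max_outer` | outer iteration cap | 200 | warm-started inner solves |

The generic defaults are the benchmark-tuned values for the nuclear
receptor dataset under pairwise cross-validation; `default_params(scheme,
dataset)` exposes the full tuned table for the four public benchmarks (E,
IC, GPCR, NR) under all three CV settings.  Continuous parameters were
searched in (0,1), integer parameters in (1,10).

## Cross-validation protocols

* **CVS1** (pairs): only cells whose drug has ≥ 2 known targets *and*
  whose target has ≥ 2 known drugs are eligible; the eligible cells —
  interacting and non-interacting alike — are partitioned into 10 folds.
  Blinding a fold zeroes both mask and training values at those cells;
  evaluation uses exactly those cells against the true labels.
* **CVS2** (new drugs): whole drug rows partitioned into folds and blinded.
* **CVS3** (new targets): whole target columns, symmetrically.

Within every fold the four profile similarities are recomputed from the
*training-masked* matrix, never the full one — otherwise the test labels
leak through the similarity channel.  Metrics are pooled per fold (not
averaged per drug/target); reports give mean and sample (n−1) standard
deviation over repetition×fold values, formatted "0.8500 (0.0707)".
Repetition k uses fold seed `base_seed + k`, recorded in the report
header.  AUC uses midrank tie handling; AUPR is the average-precision step
rule Σ (R_n − R_{n−1}) P_n.  Both delegate to scikit-learn, with
hand-enumerated examples kept in the tests as an independent check.

## Synthetic data generator

The generator emulates the statistical shape of the public gold-standard
benchmarks, not their chemistry:

* latent factors G (M×rank), H (N×rank) i.i.d. standard normal; the true
  affinity matrix is G Hᵀ (numerical rank exactly `rank`);
* Y thresholds the affinities at the empirical quantile matching the
  requested density (so realized density is controlled directly, ±1
  percentage point; tie handling is strict ≥ at the quantile value);
* provided similarities are the row-cosines of G (resp. H) mapped to
  [0, 1], perturbed by symmetric Gaussian noise of scale `sim_noise`,
  clipped, diagonal pinned at 1 — correlated with the latent structure,
  as chemical/sequence similarity is correlated with binding;
* the mask holds exactly `mask_fraction` of the cells, drawn uniformly
  without replacement.

Defaults: 60 drugs × 50 targets, rank 4, density 0.05 (the real
benchmarks run 1–6% dense; 5% keeps profiles nonempty at this size),
sim_noise 0.1, mask_fraction 1.0 (cross-validation does the blinding).
Three independent sub-streams (latent, noise, mask) are spawned from one
seed sequence, so adding a field never shifts earlier draws.

What passing tests on this generator do **not** show: real interaction
matrices have heavy-tailed degree distributions, block structure from
protein families, and similarity matrices that are noisy in structured
(not i.i.d.) ways.  Results on synthetic instances demonstrate algorithmic
correctness and the recoverability pathway, not expected real-data
accuracy.  On the default instance the cross-validated AUC saturates
around 0.84 under CVS1 — the binarization to 5% density discards most of
the latent ordering, which bounds what any completion method can recover
there — while the graph terms contribute a consistent paired improvement
over the graph-free baseline on identical folds.

## Numerical choices and degenerate inputs

* Ties among equal singular values: any orthonormal basis is accepted;
  tests compare reconstructions, never factor matrices.
* Similarity tables with asymmetry ≤ 1e-8 are symmetrized silently as
  (S+Sᵀ)/2; larger asymmetry is an error.
* An all-unobserved mask, negative similarity entries reaching the
  Laplacian, non-binary interaction cells, and duplicate row/column labels
  are hard errors.
* Non-convergence at the iteration cap returns the result with
  `converged=False`, never an exception.
* Scores are written at 17 significant digits so write→read round-trips
  to ≤ 1e-12.

## Known limitations

* The outer splitting solves the quadratic-penalty relaxation; for very
  large α the returned Z smooths less than the exact minimizer of J
  would (the auxiliaries, not Z, carry the graph terms internally).
* Completion with very small λ converges slowly (see above); the
  implementation favors faithfulness of the iteration over acceleration
  tricks such as λ-continuation, which users can layer on via the `warm`
  argument.
* Dense linear algebra throughout: intended for the benchmark scale
  (hundreds × hundreds), not genome-wide matrices.
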