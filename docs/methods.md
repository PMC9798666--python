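# Methods

## Problem and model

Drug–target interaction (DTI) prediction is cast as completion of a binary
matrix `Z ∈ {0,1}^{n×m}` under side information: a drug–drug similarity
matrix `S^d` (e.g. chemical-structure similarity) and a target–target
similarity matrix `S^t` (e.g. normalized Smith–Waterman sequence
similarity, `SW(p,q)/√(SW(p,p)·SW(q,q))`). The model is a non-negative
low-rank factorization `Z ≈ XYᵀ` with three additions:

1. **Dual graph regularization.** Both similarity matrices are sparsified
   into `p`-nearest-neighbor graphs and converted to normalized Laplacians;
   the penalties `λ_d Tr(Xᵀ L̃_d X)` and `λ_t Tr(Yᵀ L̃_t Y)` make latent
   factors vary smoothly over each graph. This is the only channel through
   which a drug or target with no known interactions receives information.
2. **Hard consistency constraint.** `P_Ω(Z − M) = 0`, where `Ω` indexes the
   known interactions and `M` is the working prediction matrix: validated
   interactions are treated as ground truth, not as soft targets. The
   solver maintains `M_ij = 1` on `Ω` *bitwise* at every iterate.
3. **Variable splitting.** `X = U`, `Yᵀ = V` with `U, V ≥ 0` isolates the
   non-negativity constraints so every block update is closed-form.

The optimizer is block minimization of the augmented Lagrangian

```
L = ½‖M − XYᵀ‖² + λ_d Tr(Xᵀ L̃_d X) + λ_t Tr(Yᵀ L̃_t Y)
    + Λ•(X−U) + Π•(Yᵀ−V) + (α/2)‖X−U‖² + (β/2)‖Yᵀ−V‖²
```

with sweeps in the order X, Y, M, U, V followed by dual ascent
`Λ += γα(X−U)`, `Π += γβ(Yᵀ−V)`. The X and Y updates are single `k×k`
symmetric-positive-definite solves (Cholesky; no explicit inverse):

```
X⁺ (YᵀY + αI) = MY − λ_d L̃_d X + αU − Λ
Y⁺ (XᵀXₙ + βI) = MᵀX⁺ − λ_t L̃_t Y + βVᵀ − Πᵀ
```

where the Laplacian products use the *previous* iterate (prox-linearized
scheme): the smoothness term is treated as linear within each block solve,
which keeps the update closed-form at one matrix product plus one small
factorization per block. The M update writes `XYᵀ` everywhere and restores
`Z` on `Ω`; the U/V updates are `P₊(X + Λ/α)` and `P₊(Yᵀ + Π/β)`. The
reported non-negative factors are `U` and `Vᵀ`; the prediction scores are
the entries of `M`, which off `Ω` may be negative — they are ranking
scores, and all reported metrics are invariant to monotone transforms.

## Graph construction

For each entity `i`, `𝒩_p(i)` is the set of its `p` most similar other
entities (self excluded; ties broken toward the smaller index so the graph
is deterministic). Edge weights are 1 for mutual neighbors, 0.5 for
one-sided neighbors, 0 otherwise; the sparsified similarity is the
elementwise product `Ŝ = N ∘ S` with zero diagonal. The normalized
Laplacian is `L̃ = D^{−1/2}(D − Ŝ)D^{−1/2}` with `D` the degree matrix;
zero-degree vertices use the pseudo-inverse convention (their rows and
columns of `L̃` are zero). `L̃` is symmetric PSD with spectrum in `[0, 2]`.

`p` defaults to 5, the customary choice in graph-regularized matrix
factorization for these benchmarks; with the benchmark sizes (26–664
entities per side) it keeps the graphs sparse but connected enough for
information to propagate.

## Parameters

| parameter | default | role |
|---|---|---|
| `k` | 50 | latent rank; clamped to `min(n, m)` with a warning |
| `λ_d`, `λ_t` | 1e-3 | graph smoothness weights (0 disables a term) |
| `α` | 0.5 | penalty on `X = U` |
| `β` | 0.01 | penalty on `Yᵀ = V` |
| `γ` | 1.618 | dual step length, in `(0, (1+√5)/2]` |
| `ε` | 1e-6 | tolerance on relative Frobenius change of `M` |
| `max_iter` | 500 | sweep cap; exceeding it flags non-convergence |
| `p` | 5 | neighbor count for graph sparsification |

`α`, `β`, `γ` defaults are the values that performed best in the benchmark
experiments this design follows; `k ∈ {50, 100}` and
`λ ∈ {0, 1e-4, 1e-3, 1e-2, 1e-1}` form the default grid-search space.

**Stability bound and the λ default.** Because the Laplacian term is
prox-linearized, it enters the fixed-point iteration with an effective gain
of roughly `λ_d‖L̃_d‖ / σ_min(YᵀY + αI)` on the drug side and
`λ_t‖L̃_t‖ / σ_min(XᵀX + βI)` on the target side. When the configured rank
exceeds the effective rank, latent columns die out, `σ_min` approaches the
bare penalty (`α` or `β`), and with `‖L̃‖ ≤ 2` the iteration diverges once
`2λ_t ≳ β`. With `β = 0.01` this rules out `λ_t ≥ ~5e-3` as a safe default;
`λ_d = λ_t = 1e-3` (a grid value) keeps a margin on both sides and performs
well on synthetic cold-start benchmarks. Grid search may still visit
unstable points; a diverging fit raises a `NumericalError` naming the block
and iteration, and grid search / cross-validation simply drop that point or
fold with a logged warning.

**Convergence behavior.** The stopping metric is
`‖M⁺ − M‖_F / max(‖M‖_F, 1) < ε`. With `λ_d = λ_t = 0` (pure constrained
completion) the iteration reaches `ε = 1e-6` in well under 500 sweeps on
the synthetic instances, with primal residuals `‖X−U‖_F`, `‖Yᵀ−V‖_F` below
1e-3. With active graph terms the objective has long flat valleys — the
factors can keep drifting toward the Laplacian near-null space while the
fit stays exact — and the relative change decays sublinearly (~1/t),
typically stalling between 1e-4 and 1e-5. Such runs hit `max_iter` flagged
as non-converged, but the *ranking* of unknown pairs stabilizes orders of
magnitude earlier; cross-validation results at the cap are insensitive to
extending it. This is a property of the prox-linearized scheme and the
model's scale indeterminacy, not of the data; it is the reason
non-convergence is reported as a flag rather than an error.

## Initialization and determinism

`X₀, Y₀ ~ Uniform(0, √(mean(Z)/k))` from a seeded generator (scale chosen
so `X₀Y₀ᵀ` matches the mean of `Z`; a small floor guards the all-zero
matrix), `U₀ = X₀`, `V₀ = Y₀ᵀ`, `Λ₀ = Π₀ = 0`, `M₀ = Z` — so the
consistency constraint holds from the start. An `svd-based` scheme
(absolute truncated-SVD factors, with an 1e-8 jitter to avoid exact-zero
rank deficiency) is available as an alternative. All randomness — the
generator, fold assignment, initialization — flows from explicit integer
seeds, and identical configurations reproduce identical traces bit for bit.

## Synthetic data

The generator plants a non-negative rank-`k_true` model: every drug and
target gets one dominant latent component (`Uniform(0.5, 1)`) over a
low-intensity background (`Uniform(0, 0.2)`), giving the loose
family-vs-family block structure of real chemogenomic data. The top
`density` fraction of `ABᵀ` scores becomes `Z`'s 1-entries. Similarities
are cosine similarities of the planted factors plus symmetric Gaussian
noise of scale `noise_sd`, re-symmetrized, unit diagonal, clipped to
`[0, 1]`. Defaults (60×40, rank 4, density 0.08, noise 0.05) give every
10-fold split positives in each fold and solve in well under a second.

What the generator does *not* emulate: the extreme sparseness of the real
benchmarks (93–99%), hubness (promiscuous drugs, popular targets),
similarity measures whose relation to binding is weaker and more
heterogeneous than noisy latent cosine, and label noise from undiscovered
true interactions among the zeros. Passing tests on synthetic data
therefore demonstrate correctness of the machinery and the qualitative
value of the graph terms for cold-start prediction — not the AUC/AUPR
levels to expect on real benchmark data.

## Evaluation protocol

`CV_d` partitions *drugs* into folds and zeroes the full rows of the test
fold in the training matrix; `CV_t` does the same with targets and
columns. Test pairs are all pairs involving held-out entities; zeros among
them count as negatives (the standard convention; a known label-noise
caveat). AUC is the Mann–Whitney probability with ties at ½; AUPR is the
non-interpolated step-wise area (the convention matters — interpolated
variants report higher values). Folds with no positive test pair are
skipped with a warning, not scored as zero. Aggregates are reported across
all repeat×fold cells and, separately, the standard deviation across
repeat means, since published tables rarely state which is printed.

Grid search, when enabled, selects `(k, λ_d, λ_t)` by AUPR on an inner
hold-out of the *training* entities of each fold (same masking scenario,
ties toward smaller λ then smaller k), so the test fold never leaks into
model selection. Published benchmark results in this family did not
document their selection protocol precisely; inner-hold-out selection is
the conservative choice and may score slightly below selection on full
data.

## Known limitations

- The hard constraint makes every known interaction unquestionable; noisy
  or retracted annotations cannot be down-weighted.
- The prox-linearized updates impose the `λ/penalty` stability bound above;
  large graph weights require the exact (Sylvester) block solve, which this
  package deliberately omits to keep per-sweep cost at one small Cholesky
  per side.
- With active graph terms the `ε = 1e-6` relative-change tolerance is
  effectively unreachable; runs stop at `max_iter` with stable rankings.
- Similarity matrices must be dense, square, symmetric in `[0, 1]`; missing
  entries are not supported.
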