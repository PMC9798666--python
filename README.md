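# dtimf — drug–target interaction prediction by constrained graph-regularized NMF

`dtimf` predicts unknown drug–target interactions (DTIs) from a sparse
binary interaction matrix plus chemical-structure similarity between drugs
and sequence similarity between target proteins. It is aimed at
computational chemogenomics: given the handful of validated interactions a
benchmark or screening campaign provides, rank every untested drug–target
pair by how likely it is to interact — including *cold-start* drugs or
targets with no known interaction at all, which can only be reached through
the similarity information.

## The model

Let `Z ∈ {0,1}^{n×m}` record known interactions between `n` drugs and `m`
targets, and let `Ω = {(i,j) : Z_ij = 1}`. Drug and target similarity
matrices `S^d`, `S^t` are sparsified into `p`-nearest-neighbor graphs
(mutual neighbors weight 1, one-sided 0.5, otherwise 0) and turned into
normalized graph Laplacians `L̃_d`, `L̃_t`. The prediction matrix `M` and
non-negative latent factors `X ∈ R^{n×k}`, `Y ∈ R^{m×k}` solve

```
min   ½‖M − XYᵀ‖²_F + λ_d Tr(Xᵀ L̃_d X) + λ_t Tr(Yᵀ L̃_t Y)
s.t.  X = U, Yᵀ = V,  U ≥ 0, V ≥ 0,  P_Ω(Z − M) = 0
```

The equality constraint `P_Ω(Z − M) = 0` is *hard*: known interactions are
never explained away — `M` equals 1 on `Ω` exactly at every iterate. The
Laplacian traces pull the latent vectors of similar drugs (and similar
targets) together, which is what lets a drug with an empty row of `Z`
inherit a meaningful factor from its structural neighbors.

The solver is an alternating-direction method on the augmented Lagrangian:
closed-form updates for `X`, `Y` (one small SPD solve each, with the
Laplacian term prox-linearized at the previous iterate), an exact
projection update for `M`, non-negative projections for `U`, `V`, and dual
ascent with step `γ` for the multipliers `Λ`, `Π`. Iteration stops when the
relative Frobenius change of `M` drops below `ε`. Scores for unknown pairs
are the corresponding entries of `M` (ranking scores, not probabilities).

Evaluation follows the standard cold-start protocols: `CV_d` masks whole
drug rows, `CV_t` whole target columns, in repeated 10-fold
cross-validation scored by AUC and AUPR, with optional inner-hold-out grid
search over `(k, λ_d, λ_t)`.

## Worked example

Generate a synthetic benchmark with planted rank-4 structure, fit, and
cross-validate (the `interactions.txt` file uses the targets-in-rows layout
of the public benchmark distributions):

```
$ dtimf simulate --n-drugs 60 --n-targets 40 --rank 4 --density 0.08 --seed 0 --outdir demo
wrote synthetic triple (60 drugs x 40 targets, 192 interactions) to demo

$ dtimf fit demo/interactions.txt demo/drug_sim.txt demo/target_sim.txt \
      --lambda-d 0 --lambda-t 0 --rank 10 --outdir demo/fit
converged after 358 iterations; 2208 candidate pairs ranked in demo/fit

$ head -4 demo/fit/predictions.tsv
drug_id	target_id	score
D0038	T0007	1.8117303652579053
D0038	T0002	1.6303435324801563
D0038	T0020	1.6233368140061788
```

The top-ranked pairs are unobserved entries whose latent-factor product is
largest — here pairs that belong to the planted interaction blocks but were
below the density cutoff. Cold-start cross-validation, with and without the
drug graph term:

```
$ dtimf cv demo/interactions.txt demo/drug_sim.txt demo/target_sim.txt --scenario CV_t --n-repeats 1 --outdir demo/cv
CV_t: AUC 0.9178 (0.0886)  AUPR 0.6086 (0.2209)

$ dtimf cv demo/interactions.txt demo/drug_sim.txt demo/target_sim.txt --scenario CV_d --n-repeats 1 --outdir demo/cvd
CV_d: AUC 0.8653 (0.0780)  AUPR 0.4439 (0.1350)

$ dtimf cv demo/interactions.txt demo/drug_sim.txt demo/target_sim.txt --scenario CV_d --lambda-d 0 --n-repeats 1 --outdir demo/cvd0
CV_d: AUC 0.6897 (0.0930)  AUPR 0.1659 (0.0537)
```

Numbers in parentheses are standard deviations across folds. Dropping the
drug graph term (`--lambda-d 0`) collapses drug cold-start AUC from 0.87 to
0.69: with the row of `Z` fully masked, the similarity graph is the only
source of signal for those drugs.

The same pipeline runs on the public benchmark files (NR, GPCR, IC, E
triples in tab-delimited matrix format) by passing their paths instead.

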