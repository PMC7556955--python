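# Methods

This note documents the models implemented in `mccmf`, their assumptions,
the defaults and the reasoning behind them, what the synthetic benchmark
does and does not probe, and the numerical choices that matter.

## Data model and conventions

The association matrix MD is binary, rows are miRNAs and columns are
diseases throughout; a 1 means an experimentally supported association and
a 0 means *unknown*, not negative. All similarity matrices are square,
symmetric (enforced to 1e-8), with entries in [0, 1] and unit diagonal
after post-processing. Edge-list inputs are given a deterministic
lexicographic label order; dense inputs keep file order.

## Disease semantic similarity

Each disease D is a DAG of ontology ancestors: T(D) is D plus its
transitive ancestors, E(D) the induced parent edges. Two complementary
contribution models are averaged:

- **Layer decay.** The disease contributes 1 to itself; an ancestor t
  contributes Δ·max over t's children in the DAG, i.e. Δ^(shortest hop
  count). Δ = 0.5, the conventional value; Δ must lie in (0, 1).
- **Prevalence.** An ancestor contributes −log(fraction of disease DAGs
  containing it): ubiquitous ancestors are uninformative, rare ones
  specific. The log base cancels between numerator and denominator of the
  similarity, so it is configurable but irrelevant; natural log is the
  default. When every term of both semantic values is zero (all shared
  ancestors occur in every DAG) the similarity is defined as 0 — the limit
  of vanishing information — with a warning.

Similarity in both models is the shared-ancestor contribution sum divided
by the sum of the two semantic values, which lands in [0, 1] and is 1 on
the diagonal (layer-decay always; prevalence whenever the semantic value is
positive).

**MISIM** (miRNA functional similarity): the similarity of a disease to a
disease group is its best match within the group; two miRNAs score the
average of all such best matches across their two groups. A miRNA with no
associated disease is rejected rather than scored 0 — an empty group has no
best match.

## GIP kernels

The interaction profile of a miRNA is its row of MD (a disease's profile is
its column); the kernel is exp(−γ‖p_i − p_j‖²) with γ = δ / (mean squared
profile norm), δ = 1. The normalization makes the kernel invariant to
duplicating every association pattern, so density differences between
datasets do not change the kernel scale. Inside cross-validation the
kernels are always recomputed from the masked training matrix — computing
them from the full matrix would leak the held-out pairs into the features.

## Similarity denoising (low-rank representation)

The similarity matrices are modelled as self-expressive plus column-sparse
noise: D = DR + N with ‖R‖\* + ω‖N‖₂,₁ minimized. The inexact-ALM/ADM
solver alternates:

1. X ← SVT(R + Y₂/β, 1/β) — nuclear-norm proximal step on the splitting
   variable,
2. R ← (I + DᵀD)⁻¹(DᵀD − DᵀN + X + (DᵀY₁ − Y₂)/β) — a Cholesky solve; the
   system matrix is constant across iterations and factorized once,
3. N ← column-shrinkage(D − DR + Y₁/β, ω/β),
4. dual updates on Y₁, Y₂ and β ← min(ρβ, β_max).

Initialization is R = X = N = Y₁ = Y₂ = 0, standard for inexact ALM.
Defaults: ω = 0.1, β₀ = 1e-2, ρ = 1.1, β_max = 1e6, ε = 1e-8 (∞-norm on
both residuals), max 500 iterations. Hitting the cap returns a warning and
`converged=False`, never an exception. The completed matrix is D·R\*
(identical to D − N\* at exact feasibility, and low-rank even at loose
tolerance), then symmetrized, clipped to [0, 1], unit diagonal — the
downstream stages assume similarity semantics that the raw product need not
satisfy.

**Choosing ω.** N absorbs a corrupted column only while ω·‖column‖ is
cheaper than representing the column inside R (roughly cost 1 in nuclear
norm for a column independent of the rest). For [0, 1]-bounded similarity
matrices the default ω = 0.1 sits comfortably below that threshold. On
standard-normal benchmark fixtures with matched-scale corruption the
default is marginal — whether a given column lands in N or in R is
draw-dependent — so corruption-identification experiments there are
reported as averages over replicate draws. Note also that a fully replaced
column carries no clean information: reconstruction quality is only
meaningful on the uncorrupted columns, where the solver is exact to ~1e-11
on planted low-rank instances.

## Integration and WKNKN

Integration is entrywise: where the original similarity is 0 (no semantic
information) the completed and GIP values are averaged; elsewhere all three
are. When a stage is disabled the rule degrades to the two-source analogue,
and with both auxiliary sources off the original similarity passes through
— this is what makes the plain-CMF ablation baseline exact.

WKNKN estimates each unknown entry from the K most similar *other* entities
that have at least one known association (ties broken lexicographically for
determinism), weighting the t-th neighbor by η^(t−1)·similarity and
normalizing by the weight sum. Row- and column-side estimates are averaged
and combined with MD by an entrywise max, so known 1-entries always
survive. If fewer than K known neighbors exist, all available are used with
a warning; an all-zero weight vector yields estimate 0. Defaults K = 5,
η = 0.7, the convention of the method this step follows; both are exposed
as parameters since reported values for them do not exist.

## Collaborative matrix factorization

Objective:

    J(A, B) = ‖PMD − ABᵀ‖²_F + λ_l(‖A‖²_F + ‖B‖²_F)
              + λ_m‖IMS − AAᵀ‖²_F + λ_d‖IDS − BBᵀ‖²_F.

A and B are initialized from the top-k SVD (A = U√S_k, B = V√S_k, the best
rank-k approximation), then alternately updated with the exact stationarity
conditions, e.g.

    A ← (PMD·B + 2λ_m·IMS·A)(BᵀB + λ_l·I_k + 2λ_m·AᵀA)⁻¹,

using the previous sweep's A on the right-hand side. The factor 2 comes
from differentiating the quadratic similarity penalties; with it, a fixed
point of the update map is a genuine stationary point of J, which the test
suite verifies with an independently validated analytic gradient (checked
against central finite differences at random points). The k×k Gram system
is symmetric positive definite for λ_l > 0 and solved by Cholesky, never
inverted. With λ_m = λ_d = 0 the iteration is exact alternating least
squares and the objective is provably non-increasing; with similarity
penalties on, the update is a heuristic fixed-point step and monotonicity
is monitored, not guaranteed.

Numerical choices: the SVD sign ambiguity is fixed by making the
largest-magnitude entry of each left singular vector positive, so runs are
bit-reproducible; convergence is declared at relative objective change
< 1e-6 (max 200 sweeps); a non-finite objective aborts with the sweep
number.

Defaults: k = 50 clamped to min(nm, nd) — k is not a quantity with an
established value and is grid-searchable; λ_l = 0.25 and λ_m = λ_d = 0.125,
small values from the low end of the standard search grids
(λ_l ∈ {2⁻²…2¹}, λ_m/λ_d ∈ {2⁻³…2⁵}) that favour the data-fit term at desk
scale. `grid_search` selects (λ_l, λ_m=λ_d) by cross-validated AUC (tied by
default, full product grid optional; ties prefer smaller values).

## Evaluation

Pairs-mode CV masks positive *pairs*, never whole rows or columns: per
repeat, the positives are randomly partitioned into folds differing in size
by at most one. For each fold the entire MD-dependent pipeline is re-run on
the masked matrix; the completed similarities CM/CD depend only on MF/DS
and are shared across folds, which is leakage-free by construction. AUC is
the rank statistic (ties ½) of held-out pairs against all pairs that are 0
in the full matrix; per-fold AUCs are averaged within a repeat and
summarized across repeats. Classification metrics use a threshold that, by
default, maximizes f-measure over the training positives' scores versus the
negatives (any fixed threshold can be supplied instead); zero-denominator
ratios are reported as 0 and flagged. The f-measure is the standard
harmonic mean 2PR/(P+R).

## Synthetic benchmark

`make_problem` plants nonnegative rank-k_true factors with unit row norms
(homogeneous entity scales, so the global top-quantile cut leaves no row or
column empty), sets MD to 1 at the top density·nm·nd entries of the
ground-truth affinity T = PQᵀ (exact density, deterministic per seed), and
builds MF and DS as the factor cosine matrices plus symmetric noise.
Defaults nm = 150, nd = 100, k_true = 5, density = 0.10, noise 0.05,
seed 7 — desk-scale, and the planted signal is learnable by construction
(ranking masked positives by T itself gives AUC ≥ 0.99).

What the generator does *not* emulate: the long-tailed degree distributions
of real association databases, block structure of disease ontologies,
annotation bias (well-studied miRNAs have more recorded links), or
similarity matrices estimated from partially overlapping evidence. Passing
the benchmark therefore shows the pipeline recovers the structure it
assumes, at the stated sizes — not that it attains any particular
performance on curated human data.

The cross-validation experiments in the tests and the acceptance script run
the 150×100 default problem with 5 folds and 2 repeats; completion runs at
full default tolerance on 150×150/100×100 inputs. These sizes keep a full
run in the tens of seconds while leaving the fold sizes (≈300 held-out
pairs) large enough for stable AUCs.

## Known limitations

- The completion stage denoises *fully observed* similarity matrices; it is
  not masked-entry matrix completion.
- DS2-style prevalence similarity depends only on DAG membership counts,
  so two ontologies with identical T sets but different edge structure are
  indistinguishable to it.
- The ADM solver's objective can stall ~0.1% above the optimum on
  unstructured full-rank inputs (where the optimum is essentially the
  trivial point R = 0); its accuracy guarantees are for the low-rank
  regime it targets.
- The λ grids are searched with λ_m = λ_d tied by default; the untied
  product grid is 9× larger and correspondingly slower.
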