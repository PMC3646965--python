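# Methods

## Model

NetCBP treats target prediction as a graph query. Drugs and proteins
each live on their own similarity network; the known drug-target
interactions form a sparse bipartite graph between them. For a query
drug `d` the method asks: which candidate protein `p`, when both are
propagated through their networks, makes the known interactions connect
high-relevance drugs to high-relevance proteins?

Propagation uses the regularized Laplacian of the normalized similarity
network. With `W = Δ^{-1/2} S Δ^{-1/2}` (Δ = diag of row sums of `S`)
and a binary indicator `q`,

    f = (1 - α) (I - α W)^{-1} q

is the closed-form minimizer of
`α fᵀ(I - W)f + (1 - α) ||f - q||²` up to scaling: a smoothness penalty
that forces similar entities toward similar scores, balanced against
fidelity to the query. Because `W` is similar to a row-stochastic
matrix, its spectral radius is at most 1, so `(I - αW)` is invertible
for every α < 1 and the Neumann series keeps `f` non-negative.

The pair score is the Pearson correlation between one side's relevance
vector and the interaction image of the other side's:
`r(f_d, A f_p)` (drug side) or `r(f_p, Aᵀ f_d)` (protein side). Both
projections are implemented; `auto` selects the side with the higher
mean AUC in an internal drug-wise cross-validation on the training data,
ties going to the drug side. Proteins are ranked by score, ties broken
by ascending protein identifier so rankings are deterministic across
platforms.

Assumptions: similar drugs tend to target similar proteins; similarity
matrices are symmetric, in [0, 1], with unit self-similarity; unknown
pairs are unlabeled, not negative.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | drug-side diffusion weight, dimensionless in [0, 1) | 0.2 | best-performing value on the benchmark networks; 0 returns the raw query |
| β | protein-side diffusion weight | 0.2 | same role on the protein network |
| variant | projection side of the pair score | drug_side | `auto` selects by internal CV |
| normalization | similarity normalization | symmetric | `column` (column-stochastic) available; the two conventions differ only off-equilibrium |
| zero_diagonal | drop self-similarity before normalizing | false | sensitivity analysis only |
| folds / repeats | CV protocol | 5 / 5 | drug-wise splits of near-equal size |
| tol / max_iter | iterative propagation stopping rule | 1e-10 / 10000 | iteration is a verification oracle; production uses the dense solve |

The dense closed form is the production path because the benchmark
networks are small (at most ~700 entities); per-protein propagation is
computed as one factorized solve with m right-hand sides, whose column j
equals the propagation of protein j's indicator.

## Normalization choice

The symmetric normalization is the default because it guarantees a
symmetric operator with eigenvalues in [-1, 1], which makes the closed
form unconditionally well-posed. The column-stochastic reading is kept
behind a flag; which convention best reproduces published benchmark
AUCs is an empirical question that requires the external gold-standard
files, so it is surfaced as a reported configuration item rather than
decided here.

## Evaluation protocol

Drug-wise k-fold CV: drugs are randomly partitioned (seeded generator,
sizes differing by at most one); each fold's drugs have their
interaction rows zeroed in the working network - similarity matrices
are never masked, which is the semi-supervised premise - and are then
queried against all proteins. AUC is the Mann-Whitney statistic with
midrank tie handling, computed per test drug (its held-out targets vs
its non-targets), averaged over drugs, folds and repeats. Pooled-pair
AUC across all test pairs is also reported for sensitivity; per-drug
averaging is the headline number because the method is a per-drug
query. Drugs with no known target have undefined AUC and are excluded
from averages (they remain rankable through prediction). Top-k recovery
counts drugs whose best-ranked held-out true target lies within the top
k (k = 1, 5, 10); with repeated CV the count is averaged per repeat,
since each repeat covers every drug exactly once.

## Synthetic data

The generator plants matched cluster structure: entities are assigned
round-robin to clusters (so tiny fixtures populate every cluster),
similarity is `within_sim` inside a cluster and `between_sim` across,
with Gaussian noise added *before* symmetrization and clipping so the
loader's repair path is exercised; interactions are independent
Bernoulli draws at rate `p_in` for matched drug/protein clusters and
`p_out` otherwise. Defaults: 60 drugs, 30 proteins, 4 clusters,
similarities 0.8/0.2, noise sd 0.05, rates 0.5/0.02 - a clearly
recoverable but non-trivial signal that keeps the whole test suite and
the acceptance run at desk scale (seconds on one CPU).

What the generator does not emulate: the long-tailed score
distributions of real chemical/sequence similarity, hub drugs and
promiscuous targets, or correlated interaction noise. Passing the
synthetic tests therefore demonstrates correctness of the machinery and
recoverability of block-structured signal, not benchmark-level accuracy
on real pharmacology.

A note on the ceiling: with `p_in = 0.5`, whether a matched-cluster
pair interacts is an independent coin flip that no ranking can predict,
so even the Bayes-optimal ranking (true membership probabilities)
achieves only ~0.88 mean per-drug AUC under the default conditions; the
method's ~0.85-0.87 sits near that ceiling, and a shuffled-label null
sits at ~0.5.

## Numerical choices

- Linear systems are solved by LAPACK factorization, never explicit
  inversion; the iterative fixed point (geometric rate α) provides an
  independent cross-check to 1e-8.
- Pearson correlation with a zero-variance argument is defined as 0:
  an uninformative projection ranks below any informative one.
- Similarity repairs on load: average-symmetrization, clipping to
  [0, 1], diagonal reset to 1, each counted and logged; missing cells
  fail fast rather than being imputed.
- Cell parsing uses correctly-rounded `float()` so write/load round
  trips are exact at 17 significant digits.
- All randomness flows through seeded `numpy` generators; CV reports
  are bit-reproducible given (dataset, seed).

## Limitations

- Similarity computation (chemical graph alignment, Smith-Waterman) is
  out of scope; matrices are consumed as-is, and prediction quality is
  bounded by their quality.
- The interpretation of the two score variants as the two projection
  sides is this package's reading; rank-transformed alternatives are
  not implemented.
- Dense kernels scale as O(n³ + m³); networks beyond a few thousand
  entities would need the iterative path and sparse operators.
- No integration of pharmacological similarity, kernel learning, or
  heterogeneous random walks; those are different methods, referenced
  only as context.
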