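# Methods

## Model

`hypergraphmt` fits an assortative mixed-membership Poisson model to a
weighted hypergraph. The data are counts `A_e ≥ 1` on observed hyperedges
`e` (node subsets of size `d_e ≥ 2`); duplicate node sets are merged at load
time by summing counts, consistent with reading `A_e` as the number of times
the group interaction occurred. Latent parameters are a nonnegative `N × K`
membership matrix `u` and a nonnegative `(D−1) × K` affinity matrix `w`
indexed by hyperedge size `d ∈ {2..D}` and community; `D` is the maximum
observed size, and the space Ω of potential hyperedges is truncated to sizes
`2..D` (sizes never observed cannot be assigned positive affinity by the
updates, so they drop out of Ω automatically).

Every `e ∈ Ω` is an independent Poisson draw with rate
`λ_e = Σ_k w_{d_e k} Π_{i∈e} u_ik`. Assortativity — the rate only counts
community overlap shared by *all* members — is what makes the parameter
count linear in `D` and the inference tractable; interactions between
mismatched communities are not modelled. A single zero membership entry among
a hyperedge's members nulls that community's contribution.

Assumptions to keep in mind: conditional independence of hyperedges given
`(u, w)`; Poisson (equidispersed) counts; no degree correction — hubs are
absorbed into larger membership magnitudes; a hyperedge does not imply its
sub-hyperedges.

## Inference

Maximum likelihood by EM on
`L = − Σ_{e∈Ω} λ_e + Σ_{e obs} A_e log λ_e` (factorial term dropped).
The E-step sets responsibilities `ρ_ek = w_{d_e k} Π u_ik / λ_e` per observed
hyperedge; the M-step updates

- `u_ik = (Σ_{e∋i} A_e ρ_ek) / (Σ_{d} w_dk C_k^{(−i)}(d−1))`, then
- `w_dk = (Σ_{e obs, d_e=d} A_e ρ_ek) / C_k(d)`,

where `C_k(d)` is the order-`d` elementary symmetric polynomial (ESP) of
membership column `k` and `C_k^{(−i)}` its leave-one-out version. The ESPs
are built once per sweep by the standard one-node-at-a-time recurrence
(`O(NDK)`) and deflated/refolded per node in `O(DK)`, so the Ω sums are never
enumerated. Memberships update sequentially (Gauss–Seidel): each entry's
denominator excludes the entry itself, so every single update is an exact
coordinate maximization of the Jensen bound

    𝓛(ρ, u, w) = − Σ_{e∈Ω} λ_e + Σ_{e obs} A_e Σ_k ρ_ek log( w_{d_e k} Π u_ik / ρ_ek ),

which therefore never decreases across iterations — a property the test
suite asserts to `1e−9`.

Defaults: 10 random restarts (uniform `(0,1)` initialization of `u` and `w`;
restart `r` uses seed `base + r`), at most 500 iterations, log-likelihood
checked every 10 iterations, convergence when the relative change stays
below `1e−6` at two consecutive checks; the best restart by final
log-likelihood is returned, with a warning flag if it hit the iteration cap.
Observed hyperedges with `λ_e = 0` get a uniform ρ row (logged as
"degenerate") so the M-step stays defined.

### Numerical choices

- ESP deflation subtracts nearly equal numbers when one membership dominates
  a column: negative residues above `−1e−12` are clipped to zero, anything
  worse triggers a full rebuild; a full rebuild also opens every sweep.
- A size observed in exactly one hyperedge admits the degenerate optimum
  `w → ∞`, `u → 0` (the hyperedge explained by an enormous affinity on
  vanishing memberships — exactly the mechanism that keeps a lone noisy
  hyperedge from contaminating communities). Affinities are capped at
  `1e10` so the collapse remains finite.
- When evaluating the Jensen bound, responsibilities below `1e−15` are
  skipped: their terms are `≲ 1e−12` in magnitude, but their membership
  products can underflow to an exact floating-point 0 and fake a `−∞`.
- Ties in hard assignments (row argmax) break to the lowest community index.

### MAP variants

Two documented alternatives to plain ML, both realized as a constant in the
membership denominators: a sparsity mode with an exponential prior of rate
`γ` on `u` (MAP update adds `γ` to the denominator; default `γ = 1`), and a
normalized mode that projects each membership row to the probability simplex
by renormalizing after every sweep (zero rows become uniform). The
exponential prior is one admissible realization of "a constant in the
denominator", and renormalizing every sweep (rather than once at
convergence) is the package's choice; both are conventions, not claims.

## Projections, cores, summaries

- Clique expansion replaces each size-`d` hyperedge by its `d(d−1)/2` pairs,
  each inheriting the hyperedge weight; weights of a pair covered by several
  hyperedges are summed (preserving total pairwise interaction counts —
  an aggregation convention).
- The pairs-only projection keeps just the observed size-2 hyperedges.
- The c-core peels nodes of unweighted degree (number of distinct incident
  hyperedges) below `c`, shrinking hyperedges and dropping those that fall
  under size 2, to the unique fixpoint; hyperedges that collapse onto an
  identical node set merge by weight summation. Degree is the peeling
  quantity; the summary statistic `M` is the total weight `Σ_e A_e`.

## Synthetic benchmark generator

`planted_state` builds hard community blocks (contiguous, near-equal),
optionally letting a seeded fraction of nodes split their mass 1/2–1/2
between their block and the next, and assortative per-size affinities;
`sample_hypergraph` then draws every potential hyperedge's Poisson count by
explicit enumeration of Ω (guarded by a 10^6-subset budget — scalable
sampling is out of scope). The default configuration, used as the study
condition across the tests, is `N=100`, `K=2`, sizes `{2,3}`,
`w2 = 0.05`, `w3 = 0.005`, overlap 0: within-block rates give each node a
mean degree near 8 and roughly 300 hyperedges — strong but not saturated
assortative signal. Smaller experiments use `N=50` with `w = (0.1, 0.01)`
to keep comparable density.

What the generator does *not* emulate: heterogeneous (heavy-tailed) degrees
and hyperedge-size distributions, disassortative or overlapping-by-degree
structure, non-Poisson dispersion, and metadata that disagrees with
structure. Tests passing on these benchmarks certify the estimator's
correctness and its behaviour under the model's own assumptions, not
performance on arbitrary real data.

The noisy-hyperedge experiment follows the "event" construction: starting
from a two-block planted hypergraph, one hyperedge of size 20 is injected,
joining 10 fresh guest nodes with 10 random existing nodes (weight 1). Its
clique expansion adds `C(20,2) = 190` pairs to the projected graph. The
robustness metric is the guests' share of total membership mass,
`Σ_guests Σ_k u_gk / Σ_i Σ_k u_ik`, which is invariant to the overall
rescaling degeneracy `u → cu, w → w/c^d` and therefore comparable between
the hypergraph fit and the clique-expansion fit; the hypergraph fit should
give the guests the smaller share in a majority of seeds (a stochastic
check).

## Hyperedge prediction protocol

5-fold cross-validation: distinct hyperedges (weights count once) are
partitioned uniformly at random into folds differing by at most one in size;
each trial trains on four folds (80%) and scores the fifth. The existence
score of a candidate hyperedge is the Poisson positivity probability
`1 − exp(−λ_e)` — the only reading consistent with the count model, and any
strictly increasing transform of `λ_e` yields the same AUC. The
clique-expansion baseline scores a hyperedge as the product of its pairs'
existence probabilities (all pairs must exist). Test hyperedges larger than
the training maximum size receive score 0 (the fitted affinity has no row
for their size).

The AUC is estimated from 10^3 sampled comparisons: positives drawn
uniformly with replacement from the held-out fold, and for each positive of
size `d` a negative `d`-subset drawn by rejection among subsets observed
nowhere in the dataset (train *or* test — excluding all observed hyperedges
avoids labelling true positives as negatives), so the negatives match the
positives' size distribution exactly. Then
`AUC = (#(R1 > R0) + 0.5 #(R1 = R0)) / |R1|`. Reports carry per-fold values
and mean ± SD. The pairs-only baseline is evaluated on the size-2 subset of
the test fold, and the hypergraph/graph fits are additionally scored on that
same subset for a balanced comparison.

## Community evaluation

F1 against categorical metadata: hard-assign nodes by membership argmax,
match communities to categories by maximum-weight bipartite matching on the
contingency table (so the score is invariant to relabelling), and report
micro-averaged F1 — with one label per node this equals matched accuracy.
The matching protocol is the package's own convention. Cosine similarity
compares each (matching-aligned) membership row with the one-hot metadata
vector; zero rows score 0. The majority profile labels each hyperedge by the
strict majority category of its members ("tie" when the top categories draw
level) and reports, per node, the fraction of its incident hyperedges under
each label.

## Validation experiment sizes

`scripts/acceptance.py` (all randomness from `--seed`) uses: 100 random
instances with `N ≤ 12`, `D ≤ 4`, `K ≤ 3` for the enumeration oracle; 20
planted `N=50` fits for bound monotonicity; 20 seeds of the default `N=100`
benchmark with 10-restart fits for partition recovery; 100 repeats of 10^3
comparisons for AUC sanity; a 100-hyperedge fixture for the fold
bookkeeping; a 40-node pairs-only benchmark for the pairwise reduction; and
20 seeds of the injection experiment with 5-restart fits. These sizes keep
the whole script at a couple of minutes on one CPU while leaving each check
statistically meaningful.

## Known limitations

Assortative affinities only (no full tensors); no model selection over `K`
(`K` is a user input, typically the number of metadata classes); EM finds
local optima — restarts mitigate but do not guarantee the global optimum;
the sampler enumerates Ω and is deliberately budget-guarded; counts are
equidispersed Poisson; hyperedge lists carry no isolated nodes, so node sets
are defined by participation.
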