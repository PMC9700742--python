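"""Hyperedge prediction and community evaluation protocols.

Hyperedge prediction follows a 5-fold cross-validation design: the hyperedges
are partitioned uniformly at random into five folds, the model is trained on
four (80% of hyperedges) and scored on the held-out fold.  Because the space
of potential hyperedges is huge, the AUC is estimated from sampled paired
comparisons: n scores of held-out (positive) hyperedges go into R1, n scores
of never-observed node subsets — drawn to match R1's size distribution — go
into R0, and

    AUC = ( #(R1 > R0) + 0.5 #(R1 == R0) ) / n .

Existence scores: under the hypergraph model a hyperedge exists with the
Poisson positivity probability 1 - exp(-lambda_e); under a pairwise model fit
on a clique expansion, a hyperedge exists only if *all* its pairs do, i.e.
the product of the pair probabilities over its 2-combination set.

Community evaluation against categorical node metadata: hard-membership
F1 (argmax assignment, communities matched to categories by maximum-weight
bipartite matching, micro-averaged), per-node cosine similarity between the
membership row and the one-hot metadata vector, and per-node profiles of the
majority category of incident hyperedges.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hypergraph import Hypergraph, MetadataTable, clique_expand, pairs_only
from .model import HypergraphMT, LatentState, expected_rate

__all__ = [
    "CVPlan",
    "ScoreSets",
    "kfold_split",
    "existence_score_hyper",
    "existence_score_graph",
    "sample_score_sets",
    "auc",
    "match_communities",
    "f1_vs_metadata",
    "cosine_vs_metadata",
    "majority_profile",
    "cross_validate",
]


# -- cross-validation plumbing -------------------------------------------


@dataclass
class CVPlan:
    """Fold assignment of hyperedges: ``fold_of[e]`` in 0..folds-1."""

    fold_of: np.ndarray
    folds: int
    seed: int | None

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_of != fold)[0]

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_of == fold)[0]


def kfold_split(h: Hypergraph, folds: int = 5, seed: int | None = None) -> CVPlan:
    """Uniform random partition of hyperedges into equal-size folds.

    Fold sizes differ by at most one; each distinct hyperedge counts once
    regardless of its weight.
    """
    if h.E < folds:
        raise ValueError(f"cannot split E={h.E} hyperedges into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(h.E)
    fold_of = np.empty(h.E, dtype=np.int64)
    fold_of[order] = np.arange(h.E) % folds
    return CVPlan(fold_of, folds, seed)


# -- existence scores -----------------------------------------------------


def existence_score_hyper(state: LatentState, e) -> float:
    """P(hyperedge exists) = 1 - exp(-lambda_e) under the Poisson model."""
    return 1.0 - float(np.exp(-expected_rate(state, e)))


def existence_score_graph(state: LatentState, e) -> float:
    """Product of pair existence probabilities over the 2-combination set of e.

    ``state`` must come from a pairwise (D = 2) fit, e.g. on a clique
    expansion; every pair has to exist for the hyperedge to exist.
    """
    if state.D != 2:
        raise ValueError("graph scorer needs a pairwise (D=2) state")
    score = 1.0
    for i, j in itertools.combinations(sorted(e), 2):
        lam = float(state.w[0] @ (state.u[i] * state.u[j]))
        score *= 1.0 - float(np.exp(-lam))
        if score == 0.0:
            break
    return score


@dataclass
class ScoreSets:
    """Paired scores of sampled positives (R1) and matched negatives (R0)."""

    R1: np.ndarray
    R0: np.ndarray


def sample_score_sets(
    test_edges: list[tuple],
    observed: set,
    N: int,
    scorer,
    n_comparisons: int = 1000,
    seed: int | None = None,
    max_rejections: int = 1000,
) -> ScoreSets:
    """Sample balanced positive/negative score sets for the AUC estimator.

    Positives are drawn uniformly with replacement from ``test_edges``
    (node-id tuples).  For each positive of size d, a negative is drawn as a
    uniform random d-subset of the N nodes that appears nowhere in
    ``observed`` (rejection sampling), so the negatives match the positives'
    size distribution exactly.  Both sets are scored with ``scorer``.
    """
    if not test_edges:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(test_edges), size=n_comparisons)
    R1 = np.empty(n_comparisons)
    R0 = np.empty(n_comparisons)
    for t, p in enumerate(picks):
        pos = test_edges[p]
        R1[t] = scorer(pos)
        d = len(pos)
        for attempt in range(max_rejections):
            neg = tuple(sorted(rng.choice(N, size=d, replace=False).tolist()))
            if neg not in observed:
                break
        else:
            raise RuntimeError(
                f"could not draw an unobserved size-{d} subset in "
                f"{max_rejections} attempts; the hypergraph is too dense at this size"
            )
        R0[t] = scorer(neg)
    return ScoreSets(R1, R0)


def auc(sets: ScoreSets) -> float:
    """Sampled AUC from element-wise comparisons of R1 against R0."""
    R1, R0 = np.asarray(sets.R1), np.asarray(sets.R0)
    if R1.shape != R0.shape or R1.size == 0:
        raise ValueError("R1 and R0 must be non-empty and of equal length")
    return float((np.sum(R1 > R0) + 0.5 * np.sum(R1 == R0)) / R1.size)


# -- community evaluation against metadata --------------------------------


def match_communities(u: np.ndarray, cats: np.ndarray, K: int) -> np.ndarray:
    """Permutation mapping community index -> category index.

    Hard-assigns nodes by row argmax (ties to the lowest index) and solves
    maximum-weight bipartite matching on the K x K contingency table.
    """
    hard = np.argmax(u, axis=1)
    table = np.zeros((K, K))
    for com, cat in zip(hard, cats):
        table[com, cat] += 1
    rows, cols = linear_sum_assignment(-table)
    perm = np.empty(K, dtype=np.int64)
    perm[rows] = cols
    return perm


def f1_vs_metadata(u: np.ndarray, meta: MetadataTable, node_labels) -> float:
    """Micro-averaged F1 of the hard partition against node categories.

    Communities are matched to categories by maximum-weight matching, so the
    score is invariant to community relabelling.  With one label per node the
    micro-averaged F1 equals the matched accuracy.
    """
    K = u.shape[1]
    if meta.K != K:
        raise ValueError(f"u has {K} communities but metadata has {meta.K} categories")
    cats = meta.category_ids(node_labels)
    perm = match_communities(u, cats, K)
    predicted = perm[np.argmax(u, axis=1)]
    return float(np.mean(predicted == cats))


def cosine_vs_metadata(
    u: np.ndarray, meta: MetadataTable, node_labels
) -> tuple[np.ndarray, float]:
    """Per-node cosine similarity between memberships and one-hot metadata.

    Community columns are permuted by the same matching as the F1 score;
    zero membership rows get similarity 0.  Returns (per-node values, mean).
    """
    K = u.shape[1]
    if meta.K != K:
        raise ValueError(f"u has {K} communities but metadata has {meta.K} categories")
    cats = meta.category_ids(node_labels)
    perm = match_communities(u, cats, K)
    aligned = np.zeros_like(u)
    aligned[:, perm] = u
    norms = np.linalg.norm(aligned, axis=1)
    num = aligned[np.arange(len(cats)), cats]
    cs = np.divide(num, norms, out=np.zeros_like(num), where=norms > 0)
    return cs, float(cs.mean())


def majority_profile(h: Hypergraph, meta: MetadataTable) -> dict:
    """Per-node fractions of incident hyperedges by majority category.

    Each hyperedge is labelled with the category held by a strict majority of
    its members, or ``"tie"`` when the top categories draw level.  For every
    node, the fraction of its incident hyperedges carrying each label.
    """
    meta.validate(h)
    cats = meta.category_ids(h.node_labels)
    cat_names = meta.categories
    labels = cat_names + ["tie"]
    edge_label = []
    for e, _ in h.hyperedges:
        counts = Counter(cats[i] for i in e)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            edge_label.append("tie")
        else:
            edge_label.append(cat_names[top[0][0]])
    profile = {}
    tallies = [Counter() for _ in range(h.N)]
    deg = np.zeros(h.N)
    for (e, _), lab in zip(h.hyperedges, edge_label):
        for i in e:
            tallies[i][lab] += 1
            deg[i] += 1
    for i, lab in enumerate(h.node_labels):
        if deg[i] == 0:
            profile[lab] = {name: 0.0 for name in labels}
        else:
            profile[lab] = {name: tallies[i][name] / deg[i] for name in labels}
    return profile


# -- the full cross-validation experiment ---------------------------------


def _safe_hyper_scorer(state: LatentState):
    """Hypergraph scorer tolerating test sizes above the train maximum (score 0)."""

    def score(e):
        if len(e) > state.D:
            return 0.0
        return existence_score_hyper(state, e)

    return score


def cross_validate(
    h: Hypergraph,
    n_communities: int,
    folds: int = 5,
    seed: int = 0,
    n_comparisons: int = 1000,
    methods: tuple = ("hypergraph", "graph", "pairs"),
    **fit_kwargs,
) -> dict:
    """Run the k-fold hyperedge-prediction experiment.

    For every fold, trains the requested structures on the training
    hyperedges — the hypergraph itself ("hypergraph"), its clique expansion
    ("graph"), and its pairwise subset ("pairs") — and estimates the sampled
    AUC on the held-out fold.  The hypergraph and graph models are also
    scored on the pairs-only subset of the test fold ("*_pairs" entries) for
    a balanced comparison with the pairs-only baseline.  Negative samples
    exclude every hyperedge observed anywhere in the dataset.

    Returns a JSON-ready dict with per-fold and aggregate (mean, sd) AUCs.
    """
    fit_kwargs.setdefault("n_restarts", 3)
    plan = kfold_split(h, folds=folds, seed=seed)
    observed = {e for e, _ in h.hyperedges}
    per_fold: dict[str, list] = {}

    def record(name, value):
        per_fold.setdefault(name, []).append(value)

    for fold in range(folds):
        train = h.subset(plan.train_indices(fold))
        test_edges = [h.hyperedges[i][0] for i in plan.test_indices(fold)]
        test_pairs = [e for e in test_edges if len(e) == 2]
        fold_seed = seed + 1000 * (fold + 1)
        if "hypergraph" in methods:
            res = HypergraphMT(train, n_communities).fit(seed=fold_seed, **fit_kwargs)
            scorer = _safe_hyper_scorer(res.state)
            sets = sample_score_sets(test_edges, observed, h.N, scorer, n_comparisons, fold_seed)
            record("hypergraph", auc(sets))
            if test_pairs:
                sets = sample_score_sets(
                    test_pairs, observed, h.N, scorer, n_comparisons, fold_seed + 1
                )
                record("hypergraph_pairs", auc(sets))
        if "graph" in methods:
            g = clique_expand(train)
            res = HypergraphMT(g, n_communities).fit(seed=fold_seed, **fit_kwargs)
            scorer = lambda e, s=res.state: existence_score_graph(s, e)  # noqa: E731
            sets = sample_score_sets(test_edges, observed, h.N, scorer, n_comparisons, fold_seed)
            record("graph", auc(sets))
            if test_pairs:
                sets = sample_score_sets(
                    test_pairs, observed, h.N, scorer, n_comparisons, fold_seed + 1
                )
                record("graph_pairs", auc(sets))
        if "pairs" in methods:
            p = pairs_only(train)
            if p.E > 0 and test_pairs:
                res = HypergraphMT(p, n_communities).fit(seed=fold_seed, **fit_kwargs)
                scorer = _safe_hyper_scorer(res.state)
                sets = sample_score_sets(
                    test_pairs, observed, h.N, scorer, n_comparisons, fold_seed + 1
                )
                record("pairs", auc(sets))

    report = {
        "folds": folds,
        "seed": seed,
        "n_comparisons": n_comparisons,
        "fold_assignment": plan.fold_of.tolist(),
        "auc": {},
    }
    for name, values in per_fold.items():
        arr = np.asarray(values)
        report["auc"][name] = {
            "per_fold": arr.tolist(),
            "mean": float(arr.mean()),
            "sd": float(arr.std()),
        }
    return report
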