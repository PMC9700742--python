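"""Generative sampling of synthetic hypergraphs with planted communities.

The model is generative: given memberships u and affinities w, every potential
hyperedge e of size 2..D carries an independent Poisson count with rate
lambda_e = sum_k w_{d_e k} prod_{i in e} u_ik, and the hypergraph keeps the
hyperedges whose count is positive.  Sampling enumerates the potential space
explicitly, so it is meant for benchmark-scale instances (a budget guard
rejects anything beyond ~1e6 potential hyperedges; scalable sampling is out
of scope).

``planted_state`` builds the benchmark ground truth: K hard blocks of nodes,
optionally overlapping (overlapping nodes split their mass evenly between
their own block and the next one), with per-size assortative affinities.  The
default configuration is the study condition used throughout the tests: 100
nodes, two equal blocks, hyperedges of sizes 2 and 3 with strong within-block
affinities (w2 = 0.05, w3 = 0.005), giving a mean node degree around 8.

``inject_noisy_hyperedge`` reproduces the "event" perturbation: one large
hyperedge joining freshly added guest nodes with a random subset of existing
nodes, whose clique expansion floods the projected graph with new pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .hypergraph import Hypergraph
from .model import LatentState

__all__ = [
    "PlantedConfig",
    "planted_state",
    "sample_hypergraph",
    "expected_hyperedge_count",
    "inject_noisy_hyperedge",
]

#: potential hyperedges enumerable before sampling refuses
ENUMERATION_BUDGET = 10**6


@dataclass
class PlantedConfig:
    """Ground-truth configuration for planted-community benchmarks.

    Attributes
    ----------
    N, K : int
        Node count and number of blocks (nodes are split into K nearly
        equal contiguous blocks).
    D_max : int
        Largest hyperedge size to generate (sizes 2..D_max).
    w : tuple of float
        Assortative affinity per size, ``w[d - 2]`` for size d, shared by
        all communities.
    overlap : float
        Fraction of nodes with mixed membership (mass split 1/2 - 1/2
        between their own block and the cyclically next one).
    seed : int
        Seed for choosing the overlapping nodes.
    """

    N: int = 100
    K: int = 2
    D_max: int = 3
    w: tuple = (0.05, 0.005)
    overlap: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.N >= self.K >= 1):
            raise ValueError("need N >= K >= 1")
        if self.D_max < 2:
            raise ValueError("D_max must be >= 2")
        if len(self.w) != self.D_max - 1:
            raise ValueError(f"w must give one value per size 2..{self.D_max}")
        if any(x < 0 for x in self.w):
            raise ValueError("affinities must be >= 0")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")


def planted_state(cfg: PlantedConfig) -> LatentState:
    """Deterministic ground-truth (u, w) with hard blocks and optional overlap."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    block = np.repeat(np.arange(cfg.K), np.diff(np.linspace(0, cfg.N, cfg.K + 1).astype(int)))
    u = np.zeros((cfg.N, cfg.K))
    u[np.arange(cfg.N), block] = 1.0
    n_overlap = int(round(cfg.overlap * cfg.N))
    if n_overlap and cfg.K > 1:
        mixed = rng.choice(cfg.N, size=n_overlap, replace=False)
        u[mixed] = 0.0
        u[mixed, block[mixed]] = 0.5
        u[mixed, (block[mixed] + 1) % cfg.K] = 0.5
    w = np.tile(np.asarray(cfg.w, dtype=float)[:, None], (1, cfg.K))
    return LatentState(u, w)


def sample_hypergraph(
    state: LatentState, seed: int | None = None, node_labels=None
) -> Hypergraph:
    """Draw one hypergraph: A_e ~ Poisson(lambda_e) over all potential e.

    Enumerates every subset of sizes 2..D; subsets whose draw is positive
    become hyperedges with that weight.  Raises if the potential space
    exceeds the enumeration budget — this sampler is for benchmark scales.
    """
    N, D = state.N, state.D
    n_potential = sum(comb(N, d) for d in range(2, D + 1))
    if n_potential > ENUMERATION_BUDGET:
        raise ValueError(
            f"{n_potential} potential hyperedges exceed the enumeration budget "
            f"({ENUMERATION_BUDGET}); reduce N or D_max"
        )
    rng = np.random.default_rng(seed)
    if node_labels is None:
        node_labels = [f"n{i}" for i in range(N)]
    edges = []
    for d in range(2, D + 1):
        combos = np.array(list(itertools.combinations(range(N), d)), dtype=np.int64)
        lam = np.prod(state.u[combos], axis=1) @ state.w[d - 2]
        counts = rng.poisson(lam)
        for idx in np.nonzero(counts)[0]:
            edges.append((tuple(combos[idx]), int(counts[idx])))
    return Hypergraph(node_labels, edges)


def expected_hyperedge_count(state: LatentState) -> float:
    """Expected number of observed hyperedges, sum_e (1 - exp(-lambda_e))."""
    N, D = state.N, state.D
    total = 0.0
    for d in range(2, D + 1):
        combos = np.array(list(itertools.combinations(range(N), d)), dtype=np.int64)
        lam = np.prod(state.u[combos], axis=1) @ state.w[d - 2]
        total += float(np.sum(1.0 - np.exp(-lam)))
    return total


def inject_noisy_hyperedge(
    h: Hypergraph, size: int, n_new_nodes: int, seed: int | None = None
) -> Hypergraph:
    """Append one large "event" hyperedge of the given size and weight 1.

    The hyperedge joins ``n_new_nodes`` fresh guest nodes (labelled
    ``guest_0`` ...) with ``size - n_new_nodes`` existing nodes chosen
    uniformly at random.
    """
    if size < 2:
        raise ValueError("injected hyperedge must have size >= 2")
    n_existing = size - n_new_nodes
    if n_existing < 0 or n_existing > h.N:
        raise ValueError(
            f"need {n_existing} existing nodes for size {size} with {n_new_nodes} guests"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(h.N, size=n_existing, replace=False) if n_existing else np.array([], int)
    labels = list(h.node_labels) + [f"guest_{j}" for j in range(n_new_nodes)]
    guests = range(h.N, h.N + n_new_nodes)
    new_edge = tuple(sorted(chosen.tolist() + list(guests)))
    return Hypergraph(labels, list(h.hyperedges) + [(new_edge, 1)])
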