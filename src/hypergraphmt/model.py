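"""Mixed-membership Poisson model for weighted hypergraphs (Hypergraph-MT).

Each node i carries a nonnegative membership vector u_i over K communities;
each hyperedge size d and community k carries an affinity w_dk (the density of
size-d hyperedges inside community k).  A hyperedge e of size d_e is observed
with a Poisson count whose rate is assortative:

    lambda_e = sum_k  w_{d_e k}  prod_{i in e} u_ik

so a hyperedge is likely only when *all* its members share a community; a
single zero membership among the members nulls that community's contribution.
The log-likelihood over the space Omega of all potential hyperedges of sizes
2..D (D = maximum observed size) is

    L = - sum_{e in Omega} lambda_e  +  sum_{e observed} A_e log lambda_e

(dropping the parameter-free factorial term).  Inference is an EM algorithm:
the E-step computes per-hyperedge community responsibilities rho_ek, and the
M-step applies closed-form multiplicative updates for u and w.  The sums over
Omega collapse, community by community, into elementary symmetric polynomials
of the membership columns (see :mod:`hypergraphmt.sympoly`), giving O(N D K)
cost per sweep instead of enumerating Omega.

Estimation follows the statsmodels idiom: build a :class:`HypergraphMT` model
from a :class:`~hypergraphmt.hypergraph.Hypergraph`, call :meth:`fit`, and
inspect the returned :class:`HypergraphMTResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .hypergraph import Hypergraph
from .sympoly import SymPolyCache, build_esp

#: cap on affinity entries; bounds the single-hyperedge degeneracy w -> inf
W_MAX = 1e10

__all__ = [
    "LatentState",
    "HypergraphMT",
    "HypergraphMTResults",
    "expected_rate",
    "log_likelihood",
    "e_step",
    "update_u",
    "update_w",
]


@dataclass
class LatentState:
    """Model parameters: memberships ``u`` (N x K) and affinities ``w``.

    ``w`` has one row per hyperedge size d = 2..D, so ``w[d - 2, k]`` is the
    affinity of size-d hyperedges in community k.
    """

    u: np.ndarray
    w: np.ndarray

    @property
    def N(self) -> int:
        return self.u.shape[0]

    @property
    def K(self) -> int:
        return self.u.shape[1]

    @property
    def D(self) -> int:
        return self.w.shape[0] + 1

    def copy(self) -> "LatentState":
        return LatentState(self.u.copy(), self.w.copy())


def expected_rate(state: LatentState, e) -> float:
    """Poisson rate lambda_e = sum_k w_{|e| k} prod_{i in e} u_ik."""
    members = np.asarray(sorted(e), dtype=np.int64)
    d = members.size
    if d < 2 or d > state.D:
        raise ValueError(f"hyperedge size {d} outside the model range 2..{state.D}")
    if len(set(members.tolist())) != d:
        raise ValueError("hyperedge repeats a node")
    prod = np.prod(state.u[members], axis=0)
    return float(state.w[d - 2] @ prod)


def _size_groups(h: Hypergraph) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """size -> (positions in h.hyperedges, member ids (E_d, d), weights)."""
    groups: dict[int, tuple[list, list, list]] = {}
    for pos, (e, w) in enumerate(h.hyperedges):
        groups.setdefault(len(e), ([], [], []))[0].append(pos)
        groups[len(e)][1].append(e)
        groups[len(e)][2].append(w)
    return {
        d: (
            np.array(pos, dtype=np.int64),
            np.array(mem, dtype=np.int64),
            np.array(ws, dtype=np.float64),
        )
        for d, (pos, mem, ws) in sorted(groups.items())
    }


def _rates_by_size(state: LatentState, groups) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """size -> (per-edge per-community rate contributions (E_d, K), rates (E_d,))."""
    out = {}
    for d, (_, members, _) in groups.items():
        prod = np.prod(state.u[members], axis=1)  # (E_d, K)
        contrib = prod * state.w[d - 2]
        out[d] = (contrib, contrib.sum(axis=1))
    return out


def log_likelihood(state: LatentState, h: Hypergraph) -> float:
    """Poisson log-likelihood (factorial term dropped).

    The Omega term is evaluated through the symmetric-polynomial identity
    sum_{e in Omega} lambda_e = sum_d sum_k w_dk C_k(d).  Observed hyperedges
    with zero rate and positive weight yield ``-inf`` (returned, not raised).
    """
    if state.N != h.N:
        raise ValueError(f"state has N={state.N} but hypergraph has N={h.N}")
    if h.D > state.D:
        raise ValueError(f"hypergraph has size-{h.D} hyperedges but the state caps at {state.D}")
    C = build_esp(state.u, state.D)
    total = -float(np.sum(state.w * C[:, 2:].T))
    groups = _size_groups(h)
    rates = _rates_by_size(state, groups)
    for d, (_, _, weights) in groups.items():
        lam = rates[d][1]
        if np.any(lam == 0.0):
            return float("-inf")
        total += float(weights @ np.log(lam))
    return total


def e_step(state: LatentState, h: Hypergraph) -> tuple[np.ndarray, np.ndarray]:
    """Responsibilities rho_ek over communities for every observed hyperedge.

    Returns
    -------
    rho : (E, K) array, rows aligned with ``h.hyperedges``, each summing to 1.
    degenerate : (E,) bool array
        Marks hyperedges whose rate is identically zero; their rows are set
        uniform (1/K) by convention so the M-step stays defined.
    """
    rho = np.empty((h.E, state.K))
    degenerate = np.zeros(h.E, dtype=bool)
    groups = _size_groups(h)
    rates = _rates_by_size(state, groups)
    for d, (pos, _, _) in groups.items():
        contrib, lam = rates[d]
        bad = lam == 0.0
        safe = np.where(bad, 1.0, lam)
        r = contrib / safe[:, None]
        r[bad] = 1.0 / state.K
        rho[pos] = r
        degenerate[pos] = bad
    return rho, degenerate


@njit(cache=False)
def _sweep_u(u, w, C, num, gamma, normalize):  # pragma: no cover - jitted
    """Sequential coordinate update of every membership entry.

    For each node in turn: deflate the ESP cache to leave the node out, apply
    the multiplicative update u_ik = num_ik / (gamma + sum_d w_dk C^(-i)(d-1)),
    then refold the cache with the new row.  Returns the count of
    ill-conditioned entries (zero denominator with positive numerator, left
    unchanged) and whether cancellation demands a full rebuild.
    """
    N, K = u.shape
    Dp1 = C.shape[1]
    Cm = np.empty((K, Dp1))
    n_ill = 0
    need_rebuild = False
    for i in range(N):
        for k in range(K):
            Cm[k, 0] = 1.0
            for d in range(1, Dp1):
                v = C[k, d] - u[i, k] * Cm[k, d - 1]
                if v < 0.0:
                    if v < -1e-12:
                        need_rebuild = True
                    v = 0.0
                Cm[k, d] = v
        for k in range(K):
            den = gamma
            for d in range(2, Dp1):
                den += w[d - 2, k] * Cm[k, d - 1]
            nv = num[i, k]
            if nv == 0.0:
                u[i, k] = 0.0
            elif den == 0.0:
                n_ill += 1
            else:
                u[i, k] = nv / den
        if normalize:
            s = 0.0
            for k in range(K):
                s += u[i, k]
            if s == 0.0:
                for k in range(K):
                    u[i, k] = 1.0 / K
            else:
                for k in range(K):
                    u[i, k] = u[i, k] / s
        for k in range(K):
            for d in range(Dp1 - 1, 0, -1):
                C[k, d] = Cm[k, d] + u[i, k] * Cm[k, d - 1]
            C[k, 0] = 1.0
    return n_ill, need_rebuild


def _numerators(h: Hypergraph, rho: np.ndarray, groups=None) -> np.ndarray:
    """num[i, k] = sum over observed hyperedges containing i of B_ie rho_ek."""
    N = h.N
    num = np.zeros((N, rho.shape[1]))
    if groups is None:
        groups = _size_groups(h)
    for d, (pos, members, weights) in groups.items():
        contrib = weights[:, None] * rho[pos]
        for col in range(d):
            np.add.at(num, members[:, col], contrib)
    return num


def update_u(
    state: LatentState,
    h: Hypergraph,
    rho: np.ndarray,
    cache: SymPolyCache | None = None,
    *,
    gamma: float = 0.0,
    normalize: bool = False,
) -> tuple[LatentState, SymPolyCache, int]:
    """One full membership sweep (all nodes, sequentially).

    The numerator uses only observed incident hyperedges; the Omega-sum
    denominator comes from leave-one-out ESP deflation, and the cache is
    refolded after each node.  Returns the new state, a cache consistent with
    it, and the number of ill-conditioned (unchanged) entries.
    """
    new = state.copy()
    C = build_esp(new.u, new.D) if cache is None else cache.C.copy()
    num = _numerators(h, rho)
    n_ill, _ = _sweep_u(new.u, new.w, C, num, gamma, normalize)
    # a fresh rebuild each sweep guards against deflation drift
    return new, SymPolyCache(new.u, new.D), n_ill


def update_w(
    state: LatentState, h: Hypergraph, rho: np.ndarray, cache: SymPolyCache
) -> np.ndarray:
    """Affinity update w_dk = sum_{e observed, d_e=d} A_e rho_ek / C_k(d).

    Sizes with no observed hyperedge, or with a vanishing Omega denominator,
    get w_dk = 0 (removing them from the Omega term altogether).  A size
    observed in a single hyperedge admits the degenerate optimum w -> inf,
    u -> 0 (the hyperedge is explained by an arbitrarily large affinity on
    arbitrarily small memberships); the affinity is capped at ``W_MAX`` so
    the collapse stays finite.
    """
    w = np.zeros_like(state.w)
    groups = _size_groups(h)
    for d, (pos, _, weights) in groups.items():
        numer = (weights[:, None] * rho[pos]).sum(axis=0)
        denom = cache.C[:, d]
        nz = denom > 0.0
        with np.errstate(over="ignore"):
            w[d - 2, nz] = np.minimum(numer[nz] / denom[nz], W_MAX)
    return w


def _variational_bound(state: LatentState, h: Hypergraph, rho: np.ndarray) -> float:
    """Jensen lower bound on the log-likelihood at (rho, u, w).

    Terms with rho_ek = 0 contribute zero; a substantial responsibility on a
    zero-rate contribution yields -inf.  Responsibilities below 1e-15 are
    skipped: their terms are bounded by ~1e-12 in magnitude, but their
    membership products can underflow to an exact 0 and fake a -inf.
    """
    C = build_esp(state.u, state.D)
    total = -float(np.sum(state.w * C[:, 2:].T))
    groups = _size_groups(h)
    for d, (pos, members, weights) in groups.items():
        prod = np.prod(state.u[members], axis=1)
        contrib = prod * state.w[d - 2]
        r = rho[pos]
        active = r > 1e-15
        if np.any(active & (contrib == 0.0)):
            return float("-inf")
        ratio = np.ones_like(r)
        np.divide(contrib, r, out=ratio, where=active)
        ratio[~active] = 1.0  # contributes r*log(ratio) = 0
        total += float(np.sum(weights[:, None] * r * np.log(ratio)))
    return total


class HypergraphMT:
    """Assortative mixed-membership Poisson model of a weighted hypergraph.

    Parameters
    ----------
    hypergraph : Hypergraph
        Observed data; D is taken as the maximum observed hyperedge size.
    n_communities : int
        Number of communities K.
    prior : {"ml", "sparsity"}
        "ml" is plain maximum likelihood; "sparsity" places an exponential
        prior of rate ``gamma`` on the memberships, which adds the constant
        ``gamma`` to the denominator of every membership update (MAP).
    gamma : float
        Rate of the sparsity prior (used only when ``prior="sparsity"``).
    normalize_membership : bool
        Constrain each membership row to the probability simplex by
        renormalizing after every sweep; zero rows become uniform.
    """

    def __init__(
        self,
        hypergraph: Hypergraph,
        n_communities: int,
        *,
        prior: str = "ml",
        gamma: float = 1.0,
        normalize_membership: bool = False,
    ):
        if hypergraph.E == 0:
            raise ValueError("cannot fit an empty hypergraph")
        if n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if prior not in ("ml", "sparsity"):
            raise ValueError(f"unknown prior {prior!r}")
        if gamma < 0:
            raise ValueError("gamma must be >= 0")
        self.hypergraph = hypergraph
        self.K = int(n_communities)
        self.prior = prior
        self.gamma = float(gamma) if prior == "sparsity" else 0.0
        self.normalize_membership = bool(normalize_membership)

    @classmethod
    def from_file(cls, path, n_communities: int, **kwargs) -> "HypergraphMT":
        from .hypergraph import read_hyperedge_list

        return cls(read_hyperedge_list(path), n_communities, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 10,
        seed: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        check_interval: int = 10,
    ) -> "HypergraphMTResults":
        """Run EM from ``n_restarts`` random initializations, keep the best.

        Each restart alternates the E-step (responsibilities) with the
        multiplicative M-step updates, monitoring the log-likelihood every
        ``check_interval`` iterations; a run converges when its relative
        change stays below ``tol`` for two consecutive checks.  Restart r
        draws its initialization from seed ``seed + r``.  The restart with
        the highest final log-likelihood wins.
        """
        if max_iter < 1 or tol <= 0 or check_interval < 1 or n_restarts < 1:
            raise ValueError("invalid fit configuration")
        base_seed = (
            int(np.random.SeedSequence().entropy % (2**31)) if seed is None else int(seed)
        )
        traces = []
        best = None
        for r in range(n_restarts):
            run = self._run_em(base_seed + r, max_iter, tol, check_interval)
            traces.append(run)
            if best is None or run["loglik"] > traces[best]["loglik"]:
                best = r
        winner = traces[best]
        if not winner["converged"]:
            warnings.warn(
                f"best restart did not converge within {max_iter} iterations; "
                "returning best state so far",
                RuntimeWarning,
                stacklevel=2,
            )
        return HypergraphMTResults(self, winner, traces, best)

    def _run_em(self, run_seed: int, max_iter: int, tol: float, check_interval: int) -> dict:
        h = self.hypergraph
        rng = np.random.default_rng(run_seed)
        D = h.D
        u = rng.uniform(size=(h.N, self.K))
        w = rng.uniform(size=(D - 1, self.K))
        if self.normalize_membership:
            u /= u.sum(axis=1, keepdims=True)
        state = LatentState(u, w)
        groups = _size_groups(h)

        bound_trace: list[float] = []
        check_trace: list[float] = []
        converged = False
        last = None
        streak = 0
        n_degen = 0
        n_ill = 0
        rho = None
        it = 0
        for it in range(1, max_iter + 1):
            rho, degen = e_step(state, h)
            n_degen = int(degen.sum())
            num = _numerators(h, rho, groups)
            C = build_esp(state.u, D)
            ill, _ = _sweep_u(state.u, state.w, C, num, self.gamma, self.normalize_membership)
            n_ill += ill
            cache = SymPolyCache(state.u, D)
            state.w = update_w(state, h, rho, cache)
            bound_trace.append(_variational_bound(state, h, rho))
            if it % check_interval == 0:
                L = log_likelihood(state, h)
                check_trace.append(L)
                if last is not None and np.isfinite(L):
                    rel = abs(L - last) / max(abs(last), 1.0)
                    streak = streak + 1 if rel < tol else 0
                    if streak >= 2:
                        converged = True
                        break
                last = L
        final = log_likelihood(state, h)
        return {
            "seed": run_seed,
            "state": state,
            "rho": rho,
            "loglik": final,
            "loglik_trace": check_trace,
            "bound_trace": bound_trace,
            "converged": converged,
            "n_iter": it,
            "n_degenerate": n_degen,
            "n_ill_conditioned": n_ill,
        }


class HypergraphMTResults:
    """Fitted Hypergraph-MT parameters plus per-restart diagnostics.

    Attributes
    ----------
    state : LatentState
        Best-likelihood parameters (u, w).
    rho : (E, K) array
        Responsibilities at the final E-step of the winning restart.
    loglik : float
        Final log-likelihood of the winning restart.
    traces : list of dict
        One record per restart: seed, log-likelihood trace (checks), Jensen
        bound trace (per iteration), convergence flag, iteration count.
    """

    def __init__(self, model: HypergraphMT, winner: dict, traces: list[dict], best: int):
        self.model = model
        self.state: LatentState = winner["state"]
        self.rho: np.ndarray = winner["rho"]
        self.loglik: float = winner["loglik"]
        self.converged: bool = winner["converged"]
        self.n_iter: int = winner["n_iter"]
        self.n_degenerate: int = winner["n_degenerate"]
        self.best_restart: int = best
        self.best_seed: int = winner["seed"]
        self.traces = traces

    @property
    def u(self) -> np.ndarray:
        return self.state.u

    @property
    def w(self) -> np.ndarray:
        return self.state.w

    def hard_partition(self) -> np.ndarray:
        """Community of largest membership per node (ties -> lowest index)."""
        return np.argmax(self.u, axis=1)

    def normalized_memberships(self) -> np.ndarray:
        """Membership rows scaled to sum to 1 (zero rows stay zero)."""
        s = self.u.sum(axis=1, keepdims=True)
        return np.divide(self.u, s, out=np.zeros_like(self.u), where=s > 0)

    def expected_rate(self, e) -> float:
        return expected_rate(self.state, e)

    def existence_probability(self, e) -> float:
        """Probability the hyperedge exists: 1 - exp(-lambda_e)."""
        return 1.0 - float(np.exp(-expected_rate(self.state, e)))

    def sample(self, seed: int | None = None) -> Hypergraph:
        """Draw a synthetic hypergraph from the fitted parameters."""
        from .sampler import sample_hypergraph

        return sample_hypergraph(self.state, seed=seed, node_labels=self.model.hypergraph.node_labels)

    def summary(self) -> str:
        h = self.model.hypergraph
        mode = self.model.prior
        if self.model.normalize_membership:
            mode += "+normalized"
        sizes = np.bincount(self.hard_partition(), minlength=self.model.K)
        lines = [
            "Hypergraph-MT results",
            "=" * 54,
            f"{'Nodes (N)':<30}{h.N:>24}",
            f"{'Hyperedges (E)':<30}{h.E:>24}",
            f"{'Total weight (M)':<30}{h.M:>24}",
            f"{'Max hyperedge size (D)':<30}{h.D:>24}",
            f"{'Communities (K)':<30}{self.model.K:>24}",
            f"{'Estimation mode':<30}{mode:>24}",
            f"{'Restarts':<30}{len(self.traces):>24}",
            f"{'Best restart (seed)':<30}{f'{self.best_restart} ({self.best_seed})':>24}",
            f"{'Log-likelihood':<30}{self.loglik:>24.4f}",
            f"{'Converged':<30}{str(self.converged):>24}",
            f"{'EM iterations':<30}{self.n_iter:>24}",
            f"{'Degenerate hyperedges':<30}{self.n_degenerate:>24}",
            f"{'Hard partition sizes':<30}{str(sizes.tolist()):>24}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def save(self, outdir, extra: dict | None = None) -> None:
        """Write u.csv (rows = node labels), w.csv (rows = sizes 2..D) and
        report.json (seeds, traces, convergence flags, mode)."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = self.model.hypergraph
        cols = [f"community_{k}" for k in range(self.model.K)]
        pd.DataFrame(self.u, index=h.node_labels, columns=cols).to_csv(
            outdir / "u.csv", index_label="node"
        )
        pd.DataFrame(
            self.w, index=[d for d in range(2, h.D + 1)], columns=cols
        ).to_csv(outdir / "w.csv", index_label="size")
        report = {
            "mode": self.model.prior
            + ("+normalized" if self.model.normalize_membership else ""),
            "K": self.model.K,
            "N": h.N,
            "E": h.E,
            "M": h.M,
            "D": h.D,
            "best_restart": self.best_restart,
            "best_seed": self.best_seed,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "restarts": [
                {
                    "seed": t["seed"],
                    "loglik": t["loglik"],
                    "converged": t["converged"],
                    "n_iter": t["n_iter"],
                    "loglik_trace": [float(x) for x in t["loglik_trace"]],
                }
                for t in self.traces
            ],
        }
        if extra:
            report.update(extra)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
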