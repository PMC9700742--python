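"""Independent brute-force oracles for the EM quantities.

Everything here enumerates the latent hyperedge space Omega explicitly with
itertools, deliberately avoiding the package's symmetric-polynomial fast
path, so the two routes can be compared on small instances.
"""

import itertools

import numpy as np


def esp_brute(col, d):
    """Elementary symmetric polynomial of order d by subset enumeration."""
    n = len(col)
    if d == 0:
        return 1.0
    return float(sum(np.prod([col[j] for j in S]) for S in itertools.combinations(range(n), d)))


def omega_rate_sum_brute(u, w):
    """sum over all potential hyperedges (sizes 2..D) of lambda_e."""
    N, K = u.shape
    D = w.shape[0] + 1
    total = 0.0
    for d in range(2, D + 1):
        for S in itertools.combinations(range(N), d):
            prod = np.prod(u[list(S)], axis=0)
            total += float(w[d - 2] @ prod)
    return total


def u_denominator_brute(u, w, i):
    """Per-community sum over potential hyperedges containing node i of
    w_{d k} prod_{j in e, j != i} u_jk."""
    N, K = u.shape
    D = w.shape[0] + 1
    den = np.zeros(K)
    others = [j for j in range(N) if j != i]
    for d in range(2, D + 1):
        for S in itertools.combinations(others, d - 1):
            prod = np.prod(u[list(S)], axis=0) if S else np.ones(K)
            den += w[d - 2] * prod
    return den


def w_denominator_brute(u, d):
    """Per-community sum over potential size-d hyperedges of prod u_jk."""
    N, K = u.shape
    return np.array([esp_brute(u[:, k], d) for k in range(K)])


def log_likelihood_brute(u, w, hyperedges):
    """Poisson log-likelihood (factorial dropped) by enumerating Omega."""
    total = -omega_rate_sum_brute(u, w)
    for e, a in hyperedges:
        lam = float(w[len(e) - 2] @ np.prod(u[list(e)], axis=0))
        if lam == 0.0:
            return float("-inf")
        total += a * np.log(lam)
    return total


class PairwiseReference:
    """Directly coded assortative pairwise Poisson model (D = 2).

    Mirrors the EM updates for a plain graph without any hypergraph
    machinery: the Omega denominator for node i is w_k (S_k - u_ik) with
    S_k = sum_j u_jk, and the affinity denominator is the sum over all pairs
    of u_ik u_jk = (S_k^2 - sum_j u_jk^2) / 2.  Memberships are updated
    sequentially in node order, as in the package.
    """

    def __init__(self, n_nodes, pair_edges):
        self.N = n_nodes
        self.edges = [(tuple(e), float(a)) for e, a in pair_edges]

    def e_step(self, u, w):
        rho = np.empty((len(self.edges), u.shape[1]))
        for t, ((i, j), _) in enumerate(self.edges):
            contrib = w[0] * u[i] * u[j]
            lam = contrib.sum()
            rho[t] = contrib / lam if lam > 0 else 1.0 / u.shape[1]
        return rho

    def update_u(self, u, w, rho):
        u = u.copy()
        K = u.shape[1]
        num = np.zeros((self.N, K))
        for t, ((i, j), a) in enumerate(self.edges):
            num[i] += a * rho[t]
            num[j] += a * rho[t]
        S = u.sum(axis=0)
        for i in range(self.N):
            for k in range(K):
                den = w[0, k] * (S[k] - u[i, k])
                old = u[i, k]
                if num[i, k] == 0.0:
                    new = 0.0
                elif den == 0.0:
                    new = old
                else:
                    new = num[i, k] / den
                u[i, k] = new
                S[k] += new - old
        return u

    def update_w(self, u, rho):
        K = u.shape[1]
        num = np.zeros(K)
        for t, (_, a) in enumerate(self.edges):
            num += a * rho[t]
        S = u.sum(axis=0)
        den = (S**2 - (u**2).sum(axis=0)) / 2.0
        w = np.zeros((1, K))
        nz = den > 0
        w[0, nz] = num[nz] / den[nz]
        return w
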