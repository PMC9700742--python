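"""Weighted hypergraph container, I/O, projections and summaries.

A hypergraph is a collection of hyperedges, each an unordered set of two or
more distinct nodes carrying a positive integer weight (a count of how many
times that group interaction was observed).  Node sets are canonical keys:
duplicate hyperedges are merged at construction by summing weights.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Hypergraph",
    "MetadataTable",
    "read_hyperedge_list",
    "write_hyperedge_list",
    "read_metadata",
    "clique_expand",
    "pairs_only",
    "c_core",
    "summarize",
    "write_summary",
]


class Hypergraph:
    """A weighted hypergraph with labelled nodes.

    Parameters
    ----------
    node_labels : sequence of hashable
        External labels; internal ids are their 0-based positions.
    hyperedges : iterable of (members, weight)
        ``members`` is an iterable of internal node ids (distinct, >= 2 of
        them); ``weight`` a positive integer.  Hyperedges with identical node
        sets are merged by summing their weights.

    Attributes
    ----------
    N, E, M, D : int
        Node count, number of distinct hyperedges, total weight
        (sum of hyperedge weights) and maximum hyperedge size.
    """

    def __init__(self, node_labels: Sequence, hyperedges: Iterable[tuple]):
        self.node_labels = list(node_labels)
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be distinct")
        self._label_to_id = {lab: i for i, lab in enumerate(self.node_labels)}
        merged: dict[tuple, int] = {}
        for members, weight in hyperedges:
            key = tuple(sorted(members))
            if len(key) < 2:
                raise ValueError(f"hyperedge {key} has size < 2")
            if len(set(key)) != len(key):
                raise ValueError(f"hyperedge {key} repeats a node")
            if not (0 <= key[0] and key[-1] < self.N):
                raise ValueError(f"hyperedge {key} has out-of-range node ids")
            w = int(weight)
            if w < 1 or w != weight:
                raise ValueError(f"hyperedge {key} has non-positive or non-integer weight {weight!r}")
            merged[key] = merged.get(key, 0) + w
        self.hyperedges: list[tuple[tuple, int]] = sorted(merged.items())

    # -- basic properties -------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def E(self) -> int:
        return len(self.hyperedges)

    @property
    def M(self) -> int:
        return sum(w for _, w in self.hyperedges)

    @property
    def D(self) -> int:
        """Maximum observed hyperedge size (0 for an empty hypergraph)."""
        return max((len(e) for e, _ in self.hyperedges), default=0)

    def sizes(self) -> np.ndarray:
        return np.array([len(e) for e, _ in self.hyperedges], dtype=np.int64)

    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.hyperedges], dtype=np.float64)

    def degrees(self) -> np.ndarray:
        """Unweighted node degrees: number of distinct incident hyperedges."""
        deg = np.zeros(self.N, dtype=np.int64)
        for e, _ in self.hyperedges:
            for i in e:
                deg[i] += 1
        return deg

    def incidence(self) -> list[list[tuple[int, int]]]:
        """Per node, the list of (hyperedge index, weight B_ie) it belongs to."""
        inc: list[list[tuple[int, int]]] = [[] for _ in range(self.N)]
        for eidx, (e, w) in enumerate(self.hyperedges):
            for i in e:
                inc[i].append((eidx, w))
        return inc

    def edges_by_size(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Group hyperedges by size: size -> (member id array (E_d, d), weights (E_d,))."""
        groups: dict[int, tuple[list, list]] = {}
        for e, w in self.hyperedges:
            groups.setdefault(len(e), ([], []))[0].append(e)
            groups[len(e)][1].append(w)
        return {
            d: (np.array(mem, dtype=np.int64), np.array(ws, dtype=np.float64))
            for d, (mem, ws) in sorted(groups.items())
        }

    def subset(self, edge_indices: Iterable[int]) -> "Hypergraph":
        """New hypergraph keeping only the given hyperedges; node set preserved."""
        keep = [self.hyperedges[i] for i in edge_indices]
        return Hypergraph(self.node_labels, keep)

    def __repr__(self) -> str:
        return f"Hypergraph(N={self.N}, E={self.E}, M={self.M}, D={self.D})"


@dataclass
class MetadataTable:
    """Categorical node attribute (label -> category string)."""

    labels: dict = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v)
        return list(seen)

    @property
    def K(self) -> int:
        return len(self.categories)

    def category_ids(self, node_labels: Sequence) -> np.ndarray:
        """Category index per node label, in category-list order."""
        cat_id = {c: i for i, c in enumerate(self.categories)}
        missing = [lab for lab in node_labels if lab not in self.labels]
        if missing:
            raise ValueError(f"nodes without metadata: {missing[:5]}")
        return np.array([cat_id[self.labels[lab]] for lab in node_labels], dtype=np.int64)

    def validate(self, h: Hypergraph) -> None:
        unknown = [lab for lab in self.labels if lab not in h._label_to_id]
        if unknown:
            raise ValueError(f"metadata labels not in hypergraph: {unknown[:5]}")


# -- file I/O -------------------------------------------------------------


def read_hyperedge_list(path) -> Hypergraph:
    """Read a TSV hyperedge list.

    Each line is ``label1,label2,...,labeld<TAB>weight``; the weight column is
    optional (default 1); lines starting with ``#`` are ignored.  Duplicate
    hyperedges are merged by summing weights; node ids follow first appearance.
    """
    labels: list = []
    label_to_id: dict = {}
    edges: list[tuple[tuple, int]] = []
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_data_lines += 1
            parts = line.split("\t")
            if len(parts) > 2:
                raise ValueError(f"{path}:{lineno}: expected at most 2 tab-separated columns")
            names = parts[0].split(",")
            if len(names) < 2:
                raise ValueError(f"{path}:{lineno}: hyperedge has fewer than 2 nodes")
            if len(set(names)) != len(names):
                raise ValueError(f"{path}:{lineno}: duplicate node within hyperedge")
            if len(parts) == 2:
                try:
                    weight = int(parts[1])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer weight {parts[1]!r}") from None
                if weight < 1:
                    raise ValueError(f"{path}:{lineno}: non-positive weight {weight}")
            else:
                weight = 1
            ids = []
            for name in names:
                if name not in label_to_id:
                    label_to_id[name] = len(labels)
                    labels.append(name)
                ids.append(label_to_id[name])
            edges.append((tuple(ids), weight))
    if n_data_lines == 0:
        raise ValueError(f"{path}: no hyperedges found")
    return Hypergraph(labels, edges)


def write_hyperedge_list(h: Hypergraph, path, header: str | None = None) -> None:
    """Write the TSV hyperedge list read back by :func:`read_hyperedge_list`."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for e, w in h.hyperedges:
            names = ",".join(str(h.node_labels[i]) for i in e)
            fh.write(f"{names}\t{w}\n")


def read_metadata(path) -> MetadataTable:
    """Read a TSV node-metadata table (node label <TAB> category)."""
    labels: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'label<TAB>category'")
            labels[parts[0]] = parts[1]
    return MetadataTable(labels)


# -- projections ----------------------------------------------------------


def clique_expand(h: Hypergraph) -> Hypergraph:
    """Project to a graph: each size-d hyperedge becomes its d(d-1)/2 pairs.

    Each pair inherits the hyperedge weight; weights of a pair arising from
    several hyperedges are summed.  The node set is preserved.
    """
    pair_w: Counter = Counter()
    for e, w in h.hyperedges:
        for pair in itertools.combinations(e, 2):
            pair_w[pair] += w
    return Hypergraph(h.node_labels, pair_w.items())


def pairs_only(h: Hypergraph) -> Hypergraph:
    """Keep only the observed size-2 hyperedges, weights unchanged."""
    return Hypergraph(h.node_labels, [(e, w) for e, w in h.hyperedges if len(e) == 2])


def c_core(h: Hypergraph, c: int) -> Hypergraph:
    """Maximal subhypergraph in which every node has degree >= c.

    Obtained by iteratively peeling nodes of unweighted degree < c, removing
    them from their hyperedges and dropping hyperedges that fall below size 2,
    until stable.  Hyperedges that collapse onto an identical node set are
    merged by summing weights.  The result can be empty.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    edges = {e: w for e, w in h.hyperedges}
    alive = set(range(h.N))
    while True:
        deg = Counter()
        for e in edges:
            for i in e:
                deg[i] += 1
        drop = {i for i in alive if deg[i] < c}
        if not drop:
            break
        alive -= drop
        new_edges: dict[tuple, int] = {}
        for e, w in edges.items():
            e2 = tuple(i for i in e if i not in drop)
            if len(e2) >= 2:
                new_edges[e2] = new_edges.get(e2, 0) + w
        edges = new_edges
    keep = sorted(alive)
    remap = {old: new for new, old in enumerate(keep)}
    return Hypergraph(
        [h.node_labels[i] for i in keep],
        [(tuple(remap[i] for i in e), w) for e, w in edges.items()],
    )


# -- summaries ------------------------------------------------------------


def summarize(h: Hypergraph, g: Hypergraph | None = None) -> dict:
    """Descriptive statistics of a hypergraph and its clique expansion.

    Returns N, E, E_G (pairs in the expansion), M, M_G, mean/SD of node
    degree, mean/SD of hyperedge size, D, the percentage of hyperedges that
    are pairwise, and the percentage of 2-subsets of size>2 hyperedges that
    are already observed as pairwise hyperedges.
    """
    if g is None:
        g = clique_expand(h)
    deg = h.degrees()
    sizes = h.sizes().astype(float)
    observed_pairs = {e for e, _ in h.hyperedges if len(e) == 2}
    big_subpairs = set()
    for e, _ in h.hyperedges:
        if len(e) > 2:
            big_subpairs.update(itertools.combinations(e, 2))
    pct_big_in_g = (
        100.0 * len(big_subpairs & observed_pairs) / len(big_subpairs) if big_subpairs else 0.0
    )
    return {
        "N": h.N,
        "E": h.E,
        "E_G": g.E,
        "M": h.M,
        "M_G": g.M,
        "mean_degree": float(deg.mean()) if h.N else 0.0,
        "sd_degree": float(deg.std()) if h.N else 0.0,
        "mean_size": float(sizes.mean()) if h.E else 0.0,
        "sd_size": float(sizes.std()) if h.E else 0.0,
        "D": h.D,
        "pct_d2": 100.0 * len(observed_pairs) / h.E if h.E else 0.0,
        "pct_dgt2_in_G": pct_big_in_g,
    }


def write_summary(record: Mapping, path) -> None:
    """Serialize a summary record as a flat key<TAB>value text file."""
    with open(path, "w") as fh:
        for key, val in record.items():
            fh.write(f"{key}\t{val}\n")
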