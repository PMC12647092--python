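"""Network prioritization of adverse-reaction-related targets.

Pipeline stage mirroring the common network-toxicology workflow: filter a
STRING-style protein–protein interaction (PPI) edge list at a combined-score
threshold (default 0.700) and drop isolated nodes; screen hub nodes by
Maximal Clique Centrality (MCC — the cytoHubba score: for each node, the sum
of (|C|−1)! over maximal cliques C containing it); merge networks; and run
a Random Walk with Restart (RWR) from the screened seed nodes to rank the
remaining proteins by affinity to the seeds.

The walk iterates p_{t+1} = (1−r)·W·p_t + r·p0 with W the column-normalized
(degree-normalized) adjacency and p0 uniform over the seeds; the stationary
vector is a probability distribution whose mass measures proximity to the
seeds.  The restart probability defaults to r = 0.75 (the R dnet default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.700
DEFAULT_RESTART_PROB = 0.75
MCC_NODE_CAP = 2000


class NetworkError(Exception):
    """Malformed edge list, empty filtered network, or non-convergence."""


class ConvergenceError(NetworkError):
    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"random walk did not converge in {iterations} iterations "
            f"(last L1 residual {residual:.3e})"
        )
        self.residual = residual
        self.iterations = iterations


# ---------------------------------------------------------------------------
# loading / filtering / merging


def _drop_isolated(g: nx.Graph) -> nx.Graph:
    g.remove_nodes_from([n for n, deg in dict(g.degree()).items() if deg == 0])
    return g


def load_network(
    path: str | Path,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> nx.Graph:
    """Read a three-column (nodeA, nodeB, score) edge list and filter it.

    Scores may be on [0,1] or STRING-style 0–1000 (auto-detected from the
    maximum and rescaled, logged).  Edges under the threshold are dropped,
    then isolated nodes; an empty post-filter graph is fatal.  Duplicate
    edges keep the maximum score; self-loops are ignored.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 3:
                raise NetworkError(f"{path}:{lineno}: malformed edge line {line!r}")
            a, b, raw = parts[0], parts[1], parts[2]
            if lineno == 1 and not _is_number(raw):
                continue  # header line
            if not _is_number(raw):
                raise NetworkError(f"{path}:{lineno}: non-numeric score {raw!r}")
            edges.append((a, b, float(raw)))
    if not edges:
        raise NetworkError(f"{path}: no edges read")
    max_score = max(s for _, _, s in edges)
    if max_score > 1.0:
        logger.info("%s: scores look STRING-style (max %.0f); rescaling by 1/1000",
                    path, max_score)
        edges = [(a, b, s / 1000.0) for a, b, s in edges]
    g = nx.Graph()
    for a, b, s in edges:
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=s)
    g.remove_edges_from([
        (a, b) for a, b, d in g.edges(data=True) if d["score"] < score_threshold
    ])
    _drop_isolated(g)
    if g.number_of_nodes() == 0:
        raise NetworkError(
            f"{path}: no edges survive the {score_threshold} score threshold"
        )
    return g


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def merge(net1: nx.Graph, net2: nx.Graph) -> nx.Graph:
    """Node and edge union; duplicate edges keep the max score."""
    g = nx.Graph()
    for src in (net1, net2):
        for a, b, d in src.edges(data=True):
            s = d.get("score", 1.0)
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
    _drop_isolated(g)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
            fh.write(f"{a}\t{b}\t{g[a][b].get('score', 1.0):.3f}\n")


# ---------------------------------------------------------------------------
# maximal clique centrality


def mcc(network: nx.Graph, node_cap: int = MCC_NODE_CAP) -> dict[str, float]:
    """Maximal Clique Centrality via exact Bron–Kerbosch enumeration.

    score(v) = Σ over maximal cliques C ∋ v of (|C|−1)!.  In a triangle-free
    component every maximal clique is an edge, so the score equals the
    degree.  Exact enumeration is exponential in the worst case; intended
    for networks up to ~2,000 nodes, enforced by ``node_cap``.
    """
    n = network.number_of_nodes()
    if n == 0:
        raise NetworkError("MCC on an empty network")
    if n > node_cap:
        raise NetworkError(
            f"network has {n} nodes, above the MCC cap of {node_cap}; "
            "raise node_cap explicitly if you mean it"
        )
    scores: dict[str, float] = {v: 0.0 for v in network.nodes}
    for clique in nx.find_cliques(network):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def top_k(scores: Mapping[str, float], k: int = 10) -> list[str]:
    """The k best-scoring nodes; ties broken lexicographically by node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    if len(ranked) < k:
        logger.warning("only %d nodes available for top_%d", len(ranked), k)
    return ranked[:k]


# ---------------------------------------------------------------------------
# random walk with restart


@dataclass
class RWRState:
    restart_prob: float
    nodes: list[str]
    seed_vector: np.ndarray
    affinity: np.ndarray
    iterations: int
    residual: float
    seeds: frozenset

    def affinity_of(self, node: str) -> float:
        return float(self.affinity[self.nodes.index(node)])

    def as_dict(self) -> dict[str, float]:
        return {v: float(p) for v, p in zip(self.nodes, self.affinity)}


def _walk_matrix(network: nx.Graph, nodes: Sequence[str], weighted: bool) -> np.ndarray:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((n, n))
    for a, b, d in network.edges(data=True):
        s = d.get("score", 1.0) if weighted else 1.0
        w[idx[a], idx[b]] = s
        w[idx[b], idx[a]] = s
    col = w.sum(axis=0)
    if np.any(col == 0):
        raise NetworkError("isolated node in walk matrix; filter the network first")
    return w / col  # column-stochastic


def rwr(
    network: nx.Graph,
    seeds: Iterable[str],
    r: float = DEFAULT_RESTART_PROB,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    weighted: bool = False,
) -> RWRState:
    """Random walk with restart from a uniform seed distribution.

    Iterates p ← (1−r)·W·p + r·p0 on the column-normalized adjacency until
    the L1 change drops below ``tol``.  With r = 1 the walk returns p0
    exactly.  The converged vector is a probability distribution (sums to 1)
    satisfying the fixed-point equation to within the tolerance.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    seeds = frozenset(seeds)
    nodes = sorted(network.nodes)
    missing = seeds - set(nodes)
    if missing:
        raise NetworkError(f"seed nodes not in network: {sorted(missing)}")
    if not seeds:
        raise NetworkError("no seed nodes")
    w = _walk_matrix(network, nodes, weighted)
    p0 = np.zeros(len(nodes))
    for s in seeds:
        p0[nodes.index(s)] = 1.0 / len(seeds)
    p = p0.copy()
    residual = math.inf
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (w @ p) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return RWRState(r, nodes, p0, p, it, residual, seeds)
    raise ConvergenceError(residual, max_iter)


def rwr_direct(
    network: nx.Graph,
    seeds: Iterable[str],
    r: float = DEFAULT_RESTART_PROB,
    weighted: bool = False,
) -> dict[str, float]:
    """Closed-form stationary vector: solve (I − (1−r)W)p = r·p0.

    Exact alternative to the iteration, practical for small networks; used
    as the independent cross-check of :func:`rwr`.
    """
    seeds = frozenset(seeds)
    nodes = sorted(network.nodes)
    w = _walk_matrix(network, nodes, weighted)
    p0 = np.zeros(len(nodes))
    for s in seeds:
        p0[nodes.index(s)] = 1.0 / len(seeds)
    p = np.linalg.solve(np.eye(len(nodes)) - (1.0 - r) * w, r * p0)
    return {v: float(x) for v, x in zip(nodes, p)}


def rank_affinity(
    state: RWRState,
    k: int = 10,
    include_seeds: bool = False,
) -> list[tuple[str, float]]:
    """Top-k nodes by affinity, seeds excluded by default; ties lexicographic."""
    if k <= 0:
        return []
    items = [
        (v, float(p)) for v, p in zip(state.nodes, state.affinity)
        if include_seeds or v not in state.seeds
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    return items[:k]


def write_ranking(
    path: str | Path,
    mcc_scores: Mapping[str, float],
    state: RWRState,
    k: int = 10,
    include_seeds: bool = False,
) -> None:
    """Ranked-node TSV: node, mcc, affinity, rank."""
    ranked = rank_affinity(state, k=k, include_seeds=include_seeds)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tmcc\taffinity\trank\n")
        for rank, (node, aff) in enumerate(ranked, start=1):
            fh.write(f"{node}\t{mcc_scores.get(node, 0.0):.6g}\t{aff:.8g}\t{rank}\n")
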