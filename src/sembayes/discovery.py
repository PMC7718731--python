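"""Causal structure search from posterior residual covariances.

Three steps: (1) a multi-trait BayesC-pi chain yields posterior samples
of the residual covariance R; (2) for every trait pair (i, j) and every
conditioning subset h of the remaining traits, the residual partial
correlation is computed per sample and the pair is declared
conditionally independent given h when the highest-posterior-density
interval of chosen mass (0.9 by default) contains zero; (3) the
Pearl-Verma IC algorithm turns the independence table into a CPDAG,
whose acyclic, v-structure-preserving orientations are the candidate
causal structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import chain as _chain, combinations, product

import numpy as np

from .data import CausalStructure

logger = logging.getLogger(__name__)

__all__ = [
    "IndependenceDecision",
    "Cpdag",
    "partial_correlation",
    "hpd_interval",
    "independence_table",
    "ic_algorithm",
    "enumerate_orientations",
]


@dataclass
class IndependenceDecision:
    """Conditional-independence verdict for one pair and conditioning set."""

    i: int
    j: int
    h: tuple[int, ...]
    hpd_low: float
    hpd_high: float
    independent: bool

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("pair indices must differ")
        if self.i in self.h or self.j in self.h:
            raise ValueError("conditioning set must exclude the pair")


@dataclass
class Cpdag:
    """Partially directed graph: directed edges (a, b) mean a -> b."""

    n_nodes: int
    directed: set[tuple[int, int]] = field(default_factory=set)
    undirected: set[frozenset[int]] = field(default_factory=set)

    def has_edge(self, a: int, b: int) -> bool:
        return (a, b) in self.directed or (b, a) in self.directed or frozenset((a, b)) in self.undirected

    def neighbors(self, a: int) -> set[int]:
        out = {b for (x, b) in self.directed if x == a}
        out |= {x for (x, b) in self.directed if b == a}
        out |= {next(iter(e - {a})) for e in self.undirected if a in e}
        return out


def partial_correlation(R: np.ndarray, i: int, j: int, h: tuple[int, ...] = ()) -> float:
    """Partial correlation of traits i, j given the set h, from covariance R.

    Computed from the precision of the (i, j, h) submatrix as
    -omega_ij / sqrt(omega_ii omega_jj); with empty h this is the
    marginal correlation R_ij / sqrt(R_ii R_jj).
    """
    idx = [i, j, *h]
    sub = R[np.ix_(idx, idx)]
    omega = np.linalg.inv(sub)
    return float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))


def hpd_interval(samples: np.ndarray, mass: float) -> tuple[float, float]:
    """Empirical shortest interval containing ceil(mass * m) of m samples.

    Ties between equally short windows are broken toward the lower
    start, which makes the result deterministic.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=np.float64).ravel())
    m = x.size
    k = math.ceil(mass * m)
    if m < k or m < 2:
        raise ValueError(f"need at least {k} samples, got {m}")
    widths = x[k - 1 :] - x[: m - k + 1]
    start = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[start]), float(x[start + k - 1])


def independence_table(
    R_samples: np.ndarray,
    mass: float = 0.9,
    max_cond: int | None = None,
) -> list[IndependenceDecision]:
    """All pairwise conditional-independence decisions from R samples.

    For each unordered pair and each subset of the remaining traits (up
    to ``max_cond`` traits, all subsets by default), the HPD interval of
    the posterior partial correlations decides independence: the pair is
    independent given h iff the interval contains zero.
    """
    R_samples = np.asarray(R_samples, dtype=np.float64)
    t = R_samples.shape[1]
    decisions = []
    for i, j in combinations(range(t), 2):
        rest = [k for k in range(t) if k not in (i, j)]
        limit = len(rest) if max_cond is None else min(max_cond, len(rest))
        for size in range(limit + 1):
            for h in combinations(rest, size):
                pc = np.array([partial_correlation(R, i, j, h) for R in R_samples])
                low, high = hpd_interval(pc, mass)
                decisions.append(
                    IndependenceDecision(i, j, h, low, high, independent=low <= 0.0 <= high)
                )
    return decisions


def _sepsets(decisions: list[IndependenceDecision]) -> dict[frozenset[int], list[tuple[int, ...]]]:
    sep: dict[frozenset[int], list[tuple[int, ...]]] = {}
    for d in decisions:
        key = frozenset((d.i, d.j))
        sep.setdefault(key, [])
        if d.independent:
            sep[key].append(d.h)
    return sep


def ic_algorithm(decisions: list[IndependenceDecision]) -> Cpdag:
    """Pearl-Verma IC: skeleton, v-structures, then Meek orientation rules.

    Edges: i - j iff no conditioning set renders the pair independent.
    V-structures: for nonadjacent (i, j) with common neighbour k, orient
    i -> k <- j iff k lies in no separating set of (i, j).  Conflicting
    forced orientations are logged and the edge left undirected.
    """
    nodes = sorted({d.i for d in decisions} | {d.j for d in decisions})
    n = (max(nodes) + 1) if nodes else 0
    sep = _sepsets(decisions)

    undirected: set[frozenset[int]] = set()
    for key, seps in sep.items():
        if not seps:
            undirected.add(key)

    adj = {a: {b for e in undirected if a in e for b in e - {a}} for a in range(n)}
    directed: set[tuple[int, int]] = set()
    conflicted: set[frozenset[int]] = set()

    # v-structures
    for i, j in combinations(range(n), 2):
        if frozenset((i, j)) in undirected:
            continue
        seps = sep.get(frozenset((i, j)), [])
        for k in adj[i] & adj[j]:
            if all(k not in h for h in seps):
                for a in (i, j):
                    e = frozenset((a, k))
                    if (k, a) in directed:
                        logger.warning(
                            "conflicting orientation for edge %s-%s; left undirected", a, k
                        )
                        directed.discard((k, a))
                        conflicted.add(e)
                    elif e not in conflicted:
                        directed.add((a, k))
                        undirected.discard(e)

    _meek_closure(n, adj, directed, undirected, conflicted)
    return Cpdag(n_nodes=n, directed=directed, undirected=undirected)


def _meek_closure(n, adj, directed, undirected, conflicted):
    """Meek rules 1-3, applied to a fixed point."""

    def orient(a, b):
        e = frozenset((a, b))
        if e in conflicted or (a, b) in directed:
            return False
        if (b, a) in directed:
            logger.warning("conflicting orientation for edge %s-%s; left undirected", a, b)
            directed.discard((b, a))
            undirected.add(e)
            conflicted.add(e)
            return False
        directed.add((a, b))
        undirected.discard(e)
        return True

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, x - y, z and y nonadjacent  =>  x -> y
                if any((z, x) in directed and y not in adj[z] and z != y for z in adj[x]):
                    changed |= orient(x, y)
                    continue
                # R2: x -> z -> y and x - y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed for z in adj[x] & adj[y]):
                    changed |= orient(x, y)
                    continue
                # R3: x - z1 -> y, x - z2 -> y, z1 and z2 nonadjacent  =>  x -> y
                half = [
                    z
                    for z in adj[x] & adj[y]
                    if frozenset((x, z)) in undirected and (z, y) in directed
                ]
                if any(
                    z2 not in adj[z1] and z1 != z2
                    for z1, z2 in combinations(half, 2)
                ):
                    changed |= orient(x, y)


def _vstructures(directed: set[tuple[int, int]], skeleton: set[frozenset[int]]) -> set[tuple[int, int, int]]:
    out = set()
    parents: dict[int, set[int]] = {}
    for a, b in directed:
        parents.setdefault(b, set()).add(a)
    for k, ps in parents.items():
        for a, b in combinations(sorted(ps), 2):
            if frozenset((a, b)) not in skeleton:
                out.add((a, k, b))
    return out


def enumerate_orientations(cpdag: Cpdag, trait_names=None) -> list[CausalStructure]:
    """All members of the Markov equivalence class as Lambda supports.

    Each undirected edge is oriented both ways; orientations are kept
    when the result is acyclic and introduces no v-structure absent from
    the CPDAG.  Returned structures have 1.0 at each supported position
    (entry [k, l] nonzero for the edge l -> k).
    """
    skeleton = set(cpdag.undirected) | {frozenset(e) for e in cpdag.directed}
    base_v = _vstructures(cpdag.directed, skeleton)
    free = [tuple(e) for e in sorted(cpdag.undirected, key=sorted)]
    members = []
    for choice in product((0, 1), repeat=len(free)):
        directed = set(cpdag.directed)
        for (a, b), c in zip(free, choice):
            directed.add((a, b) if c == 0 else (b, a))
        if _has_cycle(cpdag.n_nodes, directed):
            continue
        if _vstructures(directed, skeleton) != base_v:
            continue
        lam = np.zeros((cpdag.n_nodes, cpdag.n_nodes))
        for a, b in directed:  # a -> b: trait a affects trait b
            lam[b, a] = 1.0
        members.append(CausalStructure(lam, trait_names))
    return members


def _has_cycle(n: int, directed: set[tuple[int, int]]) -> bool:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(directed)
    return not nx.is_directed_acyclic_graph(g)
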