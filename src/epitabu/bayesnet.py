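"""DAG individuals, acyclicity machinery and BIC scoring.

A network individual is an n x n 0/1 adjacency matrix over the SNP nodes
plus the phenotype (Class) node: ``C[i, j] = 1`` iff node i is a parent
of node j.  The class node sits at the last index by convention.

The score is the decomposable BIC of a discrete Bayesian network,

    BIC(G | D) = sum_i sum_j sum_k m_ijk log(m_ijk / m_ij*)
                 - sum_i q_i (r_i - 1) / 2 * log m

with m the sample count, r_i the node cardinality (3 for SNPs, 2 for
Class), q_i the number of parent-value combinations and m_ijk the count
of samples where node i takes value k under parent combination j.  Zero
counts contribute zero to the likelihood sum.  Parent combinations are
indexed in mixed radix with the lowest parent index as the
fastest-varying digit; only combinations observed in the data are
materialized, while q_i enters the penalty exactly, so heavily
over-parented nodes score (very poorly) instead of blowing up memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import GenotypeTable

__all__ = [
    "DagIndividual",
    "SufficientStats",
    "ScoreCache",
    "EditRejectedError",
    "OverparameterizedError",
    "is_acyclic",
    "topological_order",
    "would_create_cycle",
    "sufficient_stats",
    "bic_score",
    "apply_edit",
    "write_edge_list",
    "to_dot",
]

DEFAULT_Q_CAP = 3**25


class EditRejectedError(ValueError):
    """The requested edge edit is inapplicable or would create a cycle."""


class OverparameterizedError(ValueError):
    """A node's parent-combination count q_i exceeds the configured cap."""


class DagIndividual:
    """One search individual: an acyclic 0/1 adjacency matrix plus node names."""

    __slots__ = ("adjacency", "node_names", "cached_score")

    def __init__(self, adjacency, node_names, cached_score: float | None = None):
        adjacency = np.asarray(adjacency, dtype=np.int8)
        if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if np.any((adjacency != 0) & (adjacency != 1)):
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if len(node_names) != adjacency.shape[0]:
            raise ValueError("node_names length must match adjacency size")
        self.adjacency = adjacency
        self.node_names = list(node_names)
        self.cached_score = cached_score

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def class_index(self) -> int:
        return self.n_nodes - 1

    def parents(self, node: int) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.adjacency[:, node]))

    def copy(self) -> "DagIndividual":
        return DagIndividual(
            self.adjacency.copy(), self.node_names, cached_score=self.cached_score
        )

    def fingerprint(self) -> bytes:
        """Exact-identity key for tabu membership."""
        return self.adjacency.tobytes()

    def __eq__(self, other) -> bool:
        return isinstance(other, DagIndividual) and np.array_equal(
            self.adjacency, other.adjacency
        )

    def __hash__(self) -> int:
        return hash(self.fingerprint())

    def __repr__(self) -> str:
        n_edges = int(self.adjacency.sum())
        return f"DagIndividual(n_nodes={self.n_nodes}, n_edges={n_edges})"


def _matrix_topological_order(adj: np.ndarray) -> list[int] | None:
    # Kahn's algorithm; returns None when a cycle blocks completion.
    n = adj.shape[0]
    indegree = adj.sum(axis=0).astype(int)
    stack = [i for i in range(n) if indegree[i] == 0]
    order: list[int] = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in np.flatnonzero(adj[u]):
            indegree[v] -= 1
            if indegree[v] == 0:
                stack.append(int(v))
    return order if len(order) == n else None


def topological_order(ind: DagIndividual) -> list[int] | None:
    """A topological node order, or None if the graph is cyclic."""
    return _matrix_topological_order(ind.adjacency)


def is_acyclic(ind) -> bool:
    """True iff a topological order exists."""
    adj = ind.adjacency if isinstance(ind, DagIndividual) else np.asarray(ind)
    return _matrix_topological_order(adj) is not None


def _reaches(adj: np.ndarray, src: int, dst: int) -> bool:
    # Depth-first reachability src -> dst along directed edges.
    if src == dst:
        return True
    seen = np.zeros(adj.shape[0], dtype=bool)
    stack = [src]
    seen[src] = True
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(adj[u]):
            if v == dst:
                return True
            if not seen[v]:
                seen[v] = True
                stack.append(int(v))
    return False


def would_create_cycle(ind: DagIndividual, frm: int, to: int) -> bool:
    """True iff adding edge frm->to closes a directed cycle.

    A self-loop (frm == to) counts as a cycle by convention.
    """
    if frm == to:
        return True
    return _reaches(ind.adjacency, to, frm)


def apply_edit(ind: DagIndividual, edit: str, frm: int, to: int) -> DagIndividual:
    """Return a new individual with an edge added, dropped or reversed.

    Raises :class:`EditRejectedError` when the edit is inapplicable or
    would create a cycle, leaving the input untouched — the caller picks
    another edit.
    """
    n = ind.n_nodes
    if not (0 <= frm < n and 0 <= to < n) or frm == to:
        raise EditRejectedError(f"invalid edge ({frm}, {to})")
    present = bool(ind.adjacency[frm, to])
    if edit == "add":
        if present:
            raise EditRejectedError(f"edge ({frm}, {to}) already present")
        if would_create_cycle(ind, frm, to):
            raise EditRejectedError(f"adding ({frm}, {to}) would create a cycle")
        out = ind.adjacency.copy()
        out[frm, to] = 1
    elif edit == "drop":
        if not present:
            raise EditRejectedError(f"edge ({frm}, {to}) absent")
        out = ind.adjacency.copy()
        out[frm, to] = 0
    elif edit == "reverse":
        if not present:
            raise EditRejectedError(f"edge ({frm}, {to}) absent")
        out = ind.adjacency.copy()
        out[frm, to] = 0
        # reversal is legal iff `frm` is unreachable from `to` without the edge
        if _reaches(out, frm, to):
            raise EditRejectedError(f"reversing ({frm}, {to}) would create a cycle")
        out[to, frm] = 1
    else:
        raise EditRejectedError(f"unknown edit {edit!r}")
    return DagIndividual(out, ind.node_names)


@dataclass
class SufficientStats:
    """Sparse per-node counts backing one BIC term.

    ``configs`` holds the observed parent-combination indices j (mixed
    radix, lowest parent index fastest-varying); ``counts[c, k]`` is
    m_ijk for configuration ``configs[c]`` and node value k.  Unobserved
    combinations carry zero counts and are omitted.
    """

    node: int
    r: int
    q: int
    parents: tuple[int, ...]
    configs: np.ndarray
    counts: np.ndarray
    m: int

    @property
    def margins(self) -> np.ndarray:
        """m_ij* = sum_k m_ijk per observed configuration."""
        return self.counts.sum(axis=1)


def _node_values_and_cards(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    values = np.column_stack([table.genotypes, table.phenotype]).astype(np.int64)
    cards = np.full(table.n_snps + 1, 3, dtype=np.int64)
    cards[-1] = 2
    return values, cards


def sufficient_stats(
    ind: DagIndividual,
    table: GenotypeTable,
    node: int,
    q_cap: int = DEFAULT_Q_CAP,
) -> SufficientStats:
    """Counts m_ijk / m_ij* for one node under its current parent set."""
    values, cards = _node_values_and_cards(table)
    if not 0 <= node < ind.n_nodes:
        raise ValueError(f"node index {node} out of range")
    return _stats_for_parents(values, cards, node, ind.parents(node), q_cap)


def _stats_for_parents(
    values: np.ndarray,
    cards: np.ndarray,
    node: int,
    parents: tuple[int, ...],
    q_cap: int,
) -> SufficientStats:
    m = values.shape[0]
    r = int(cards[node])
    q = 1
    for p in parents:
        q *= int(cards[p])
    if q > q_cap:
        raise OverparameterizedError(
            f"node {node}: q_i = {q} parent combinations exceed cap {q_cap}"
        )
    j = np.zeros(m, dtype=np.int64)
    weight = 1
    for p in sorted(parents):  # lowest parent index = fastest-varying digit
        j += values[:, p] * weight
        weight *= int(cards[p])
    code = j * r + values[:, node]
    uniq, cnt = np.unique(code, return_counts=True)
    js = uniq // r
    ks = uniq % r
    configs, inverse = np.unique(js, return_inverse=True)
    counts = np.zeros((configs.size, r), dtype=np.int64)
    counts[inverse, ks] = cnt
    return SufficientStats(
        node=node, r=r, q=q, parents=tuple(sorted(parents)),
        configs=configs, counts=counts, m=m,
    )


def _bic_node_term(stats: SufficientStats, base: float | None) -> float:
    counts = stats.counts
    margins = stats.margins[:, None]
    nz = counts > 0
    ll = float(np.sum(counts[nz] * np.log(counts[nz] / np.broadcast_to(margins, counts.shape)[nz])))
    log_m = math.log(stats.m)
    if base is not None:
        ll /= math.log(base)
        log_m /= math.log(base)
    penalty = float(stats.q) * (stats.r - 1) / 2.0 * log_m
    return ll - penalty


class ScoreCache:
    """Memoized decomposable BIC scorer for one dataset.

    Node terms depend only on (node, parent set), so a search that edits
    few columns per step re-scores only the touched families.
    """

    def __init__(
        self,
        table: GenotypeTable,
        base: float | None = None,
        q_cap: int = DEFAULT_Q_CAP,
    ):
        self._values, self._cards = _node_values_and_cards(table)
        self.base = base
        self.q_cap = q_cap
        self._terms: dict[tuple[int, tuple[int, ...]], float] = {}
        self.n_nodes = table.n_snps + 1

    def node_term(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        term = self._terms.get(key)
        if term is None:
            stats = _stats_for_parents(
                self._values, self._cards, node, key[1], self.q_cap
            )
            term = _bic_node_term(stats, self.base)
            self._terms[key] = term
        return term

    def score(self, ind: DagIndividual) -> float:
        if ind.cached_score is None:
            ind.cached_score = sum(
                self.node_term(i, ind.parents(i)) for i in range(ind.n_nodes)
            )
        return ind.cached_score


def bic_score(
    ind: DagIndividual,
    table: GenotypeTable,
    base: float | None = None,
    q_cap: int = DEFAULT_Q_CAP,
) -> float:
    """BIC of a network against a table (caches the score on the individual)."""
    if not is_acyclic(ind):
        raise ValueError("cannot score a cyclic network")
    score = 0.0
    for node in range(ind.n_nodes):
        stats = sufficient_stats(ind, table, node, q_cap=q_cap)
        score += _bic_node_term(stats, base)
    ind.cached_score = score
    return score


def write_edge_list(ind: DagIndividual, path) -> None:
    """Serialize the DAG as one ``parent<TAB>child`` line per edge."""
    with open(path, "wt", encoding="utf-8") as fh:
        for frm, to in zip(*np.nonzero(ind.adjacency)):
            fh.write(f"{ind.node_names[frm]}\t{ind.node_names[to]}\n")


def to_dot(ind: DagIndividual) -> str:
    """GraphViz DOT text for visual inspection."""
    lines = ["digraph network {"]
    for name in ind.node_names:
        lines.append(f'  "{name}";')
    for frm, to in zip(*np.nonzero(ind.adjacency)):
        lines.append(f'  "{ind.node_names[frm]}" -> "{ind.node_names[to]}";')
    lines.append("}")
    return "\n".join(lines)
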