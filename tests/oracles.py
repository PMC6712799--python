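"""Independent brute-force oracles the fast implementations are checked against.

Everything here works by direct row scanning over the genotype matrix,
deliberately sharing no code with the bitwise or sparse-count paths.
"""

import math
from itertools import product

import numpy as np

from epitabu.io import GenotypeTable


def count_matching_rows(table: GenotypeTable, assignment, class_value=None) -> int:
    n = 0
    for i in range(table.n_samples):
        if any(table.genotypes[i, s] != v for s, v in assignment):
            continue
        if class_value is not None and table.phenotype[i] != class_value:
            continue
        n += 1
    return n


def _entropy(counts, n, base=None):
    h = 0.0
    for c in counts:
        if c:
            p = c / n
            h -= p * (math.log(p) if base is None else math.log(p, base))
    return h


def contingency_entropy(table: GenotypeTable, snp_indices, include_class, base=None):
    counts = []
    class_values = (0, 1) if include_class else (None,)
    for values in product((0, 1, 2), repeat=len(snp_indices)):
        assignment = list(zip(snp_indices, values))
        for c in class_values:
            counts.append(count_matching_rows(table, assignment, c))
    return _entropy(counts, table.n_samples, base)


def contingency_mi(table: GenotypeTable, snp_indices, base=None) -> float:
    h_class = _entropy(
        [int(np.sum(table.phenotype == c)) for c in (0, 1)], table.n_samples, base
    )
    return (
        h_class
        + contingency_entropy(table, snp_indices, include_class=False, base=base)
        - contingency_entropy(table, snp_indices, include_class=True, base=base)
    )


def node_counts_by_row_scan(table: GenotypeTable, node: int, parents):
    """m_ijk by explicit row filtering; keys are parent value tuples in
    ascending parent-index order."""
    values = np.column_stack([table.genotypes, table.phenotype])
    r = 2 if node == table.n_snps else 3
    parents = sorted(parents)
    counts: dict[tuple, list[int]] = {}
    for i in range(table.n_samples):
        key = tuple(int(values[i, p]) for p in parents)
        counts.setdefault(key, [0] * r)[int(values[i, node])] += 1
    return counts


def bic_by_row_scan(table: GenotypeTable, adjacency, base=None) -> float:
    """Decomposable BIC computed entirely by row scanning."""
    n_nodes = table.n_snps + 1
    m = table.n_samples
    log = math.log if base is None else (lambda x: math.log(x, base))
    score = 0.0
    for node in range(n_nodes):
        parents = [p for p in range(n_nodes) if adjacency[p, node]]
        r = 2 if node == table.n_snps else 3
        q = 1
        for p in parents:
            q *= 2 if p == table.n_snps else 3
        counts = node_counts_by_row_scan(table, node, parents)
        for row in counts.values():
            total = sum(row)
            for c in row:
                if c:
                    score += c * log(c / total)
        score -= q * (r - 1) / 2 * log(m)
    return score


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.3):
    """DAG built constructively: edges only along a random topological order."""
    order = rng.permutation(n_nodes)
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                adj[order[i], order[j]] = 1
    return adj
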