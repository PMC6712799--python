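import math

import networkx as nx
import numpy as np
import pytest

from epitabu.bayesnet import (
    DagIndividual,
    EditRejectedError,
    OverparameterizedError,
    ScoreCache,
    apply_edit,
    bic_score,
    is_acyclic,
    sufficient_stats,
    to_dot,
    topological_order,
    would_create_cycle,
    write_edge_list,
)
from epitabu.io import GenotypeTable

from oracles import bic_by_row_scan, node_counts_by_row_scan, random_dag


def _ind(adj, names=None):
    adj = np.asarray(adj, dtype=np.int8)
    names = names or [f"N{i}" for i in range(adj.shape[0])]
    return DagIndividual(adj, names)


CHAIN3 = [[0, 1, 0], [0, 0, 1], [0, 0, 0]]  # A->B->C


class TestDagIndividual:
    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            _ind([[1, 0], [0, 0]])

    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError, match="0 or 1"):
            _ind([[0, 2], [0, 0]])

    def test_fingerprint_is_exact_identity(self):
        a, b = _ind(CHAIN3), _ind(CHAIN3)
        assert a.fingerprint() == b.fingerprint() and a == b
        c = apply_edit(a, "drop", 0, 1)
        assert c.fingerprint() != a.fingerprint()


class TestAcyclicity:
    def test_empty_graph_is_acyclic(self):
        assert is_acyclic(_ind(np.zeros((4, 4))))

    def test_two_cycle_is_not(self):
        assert not is_acyclic(np.array([[0, 1], [1, 0]]))
        assert topological_order(_ind(CHAIN3)) == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(10))
    def test_constructed_dags_and_back_edges_against_networkx(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_dag(rng, 8)
        assert is_acyclic(adj)
        g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
        assert nx.is_directed_acyclic_graph(g)
        edges = np.argwhere(adj)
        if edges.size:
            frm, to = edges[rng.integers(len(edges))]
            adj2 = adj.copy()
            adj2[to, frm] = 1  # back edge closes a cycle unless it is a 2-cycle skip
            g2 = nx.from_numpy_array(adj2, create_using=nx.DiGraph)
            assert is_acyclic(adj2) == nx.is_directed_acyclic_graph(g2)
            assert not is_acyclic(adj2)


class TestWouldCreateCycle:
    def test_closing_a_chain(self):
        ind = _ind(CHAIN3)
        assert would_create_cycle(ind, 2, 0)
        assert not would_create_cycle(ind, 0, 2)

    def test_self_loop_by_convention(self):
        assert would_create_cycle(_ind(np.zeros((3, 3))), 1, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_add_and_check(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_dag(rng, 7)
        ind = _ind(adj)
        absent = np.argwhere((adj == 0) & ~np.eye(7, dtype=bool))
        for frm, to in absent[rng.permutation(len(absent))[:10]]:
            trial = adj.copy()
            trial[frm, to] = 1
            assert would_create_cycle(ind, int(frm), int(to)) == (not is_acyclic(trial))


class TestApplyEdit:
    def test_add_to_empty(self):
        out = apply_edit(_ind(np.zeros((3, 3))), "add", 0, 1)
        assert out.adjacency[0, 1] == 1 and out.adjacency.sum() == 1

    def test_reverse_middle_edge_accepted(self):
        out = apply_edit(_ind(CHAIN3), "reverse", 1, 2)
        assert out.adjacency[2, 1] == 1 and out.adjacency[1, 2] == 0
        assert is_acyclic(out)

    def test_reverse_rejected_when_alternative_path_exists(self):
        # A->B with extra path A->C->B: reversing (A,B) creates a cycle
        adj = [[0, 1, 1], [0, 0, 0], [0, 1, 0]]
        with pytest.raises(EditRejectedError):
            apply_edit(_ind(adj), "reverse", 0, 1)

    def test_add_existing_and_drop_absent_rejected(self):
        ind = _ind(CHAIN3)
        with pytest.raises(EditRejectedError):
            apply_edit(ind, "add", 0, 1)
        with pytest.raises(EditRejectedError):
            apply_edit(ind, "drop", 2, 0)

    def test_cycle_creating_add_rejected(self):
        with pytest.raises(EditRejectedError):
            apply_edit(_ind(CHAIN3), "add", 2, 0)


@pytest.fixture
def counts_table():
    rng = np.random.default_rng(42)
    genotypes = rng.integers(0, 3, size=(146, 3))
    phenotype = np.array([1] * 96 + [0] * 50)
    return GenotypeTable(["A", "B", "C"], genotypes, phenotype)


class TestSufficientStats:
    def test_parentless_class_node_margins(self, counts_table):
        n = counts_table.n_snps + 1
        ind = _ind(np.zeros((n, n)), [*counts_table.snp_names, "Class"])
        stats = sufficient_stats(ind, counts_table, node=n - 1)
        assert stats.q == 1 and stats.r == 2
        assert stats.margins.tolist() == [146]
        assert stats.counts.tolist() == [[50, 96]]  # value order 0, 1

    def test_single_ternary_parent_conserves_total(self, counts_table):
        n = counts_table.n_snps + 1
        adj = np.zeros((n, n), dtype=np.int8)
        adj[0, n - 1] = 1
        stats = sufficient_stats(_ind(adj, [*counts_table.snp_names, "Class"]),
                                 counts_table, node=n - 1)
        assert stats.q == 3
        assert stats.counts.sum() == 146

    def test_q_cap_enforced(self, counts_table):
        n = counts_table.n_snps + 1
        adj = np.zeros((n, n), dtype=np.int8)
        adj[0, 3], adj[1, 3], adj[2, 3] = 1, 1, 1
        ind = _ind(adj, [*counts_table.snp_names, "Class"])
        with pytest.raises(OverparameterizedError):
            sufficient_stats(ind, counts_table, node=3, q_cap=9)

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_row_scan(self, seed, make_random_table):
        rng = np.random.default_rng(seed)
        table = make_random_table(rng, 50, 4)
        n = 5
        adj = random_dag(rng, n)
        ind = _ind(adj, [*table.snp_names, "Class"])
        for node in range(n):
            stats = sufficient_stats(ind, table, node)
            oracle = node_counts_by_row_scan(table, node, stats.parents)
            assert stats.counts.sum() == 50
            got = {tuple(c): row.tolist() for c, row in zip(
                _configs_to_tuples(stats), stats.counts)}
            assert got == oracle


def _configs_to_tuples(stats, class_index=4):
    """Decode mixed-radix config indices back to parent value tuples
    (ascending parent order, lowest index as the fastest-varying digit)."""
    out = []
    for j in stats.configs:
        j = int(j)
        values = []
        for p in stats.parents:
            r = 2 if p == class_index else 3
            values.append(j % r)
            j //= r
        out.append(tuple(values))
    return out


class TestBicScore:
    def test_edgeless_closed_form(self, counts_table):
        n = counts_table.n_snps + 1
        ind = _ind(np.zeros((n, n)), [*counts_table.snp_names, "Class"])
        score = bic_score(ind, counts_table)
        expected = 0.0
        m = counts_table.n_samples
        for col in range(counts_table.n_snps):
            counts = [int(np.sum(counts_table.genotypes[:, col] == v)) for v in range(3)]
            expected += sum(c * math.log(c / m) for c in counts if c)
            expected -= (3 - 1) / 2 * math.log(m)
        expected += 50 * math.log(50 / m) + 96 * math.log(96 / m)
        expected -= (2 - 1) / 2 * math.log(m)
        assert score == pytest.approx(expected, abs=1e-10)

    def test_hand_derived_four_sample_score(self, worked_table):
        # edgeless network: B counts (1,3,0), C counts (2,2,0), class (2,2)
        ind = _ind(np.zeros((3, 3)), ["SNPB", "SNPC", "Class"])
        expected = (
            (1 * math.log(1 / 4) + 3 * math.log(3 / 4)) - math.log(4)
            + (2 * math.log(2 / 4) + 2 * math.log(2 / 4)) - math.log(4)
            + (2 * math.log(2 / 4) + 2 * math.log(2 / 4)) - 0.5 * math.log(4)
        )
        assert bic_score(ind, worked_table) == pytest.approx(expected, abs=1e-12)

    def test_independent_edge_decreases_score_in_expectation(self):
        rng = np.random.default_rng(0)
        deltas = []
        for _ in range(10):
            genotypes = rng.integers(0, 3, size=(200, 2))
            phenotype = rng.integers(0, 2, size=200)
            phenotype[:2] = [0, 1]
            table = GenotypeTable(["A", "B"], genotypes, phenotype)
            empty = _ind(np.zeros((3, 3)), ["A", "B", "Class"])
            adj = np.zeros((3, 3), dtype=np.int8)
            adj[0, 2] = 1
            with_edge = _ind(adj, ["A", "B", "Class"])
            deltas.append(bic_score(with_edge, table) - bic_score(empty, table))
        assert np.mean(deltas) < 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_row_scan_oracle(self, seed, make_random_table):
        rng = np.random.default_rng(seed)
        table = make_random_table(rng, 40, 4)
        adj = random_dag(rng, 5)
        ind = _ind(adj, [*table.snp_names, "Class"])
        assert bic_score(ind, table) == pytest.approx(
            bic_by_row_scan(table, adj), abs=1e-9
        )

    def test_decomposability_delta(self, make_random_table):
        rng = np.random.default_rng(3)
        table = make_random_table(rng, 60, 4)
        cache = ScoreCache(table)
        adj = random_dag(rng, 5)
        ind = _ind(adj, [*table.snp_names, "Class"])
        full = cache.score(ind)
        # change node 2's parents only: full-score delta equals the term delta
        edges2 = np.flatnonzero(adj[:, 2])
        adj2 = adj.copy()
        if edges2.size:
            adj2[edges2[0], 2] = 0
        else:
            candidates = [p for p in range(5) if p != 2 and not would_create_cycle(ind, p, 2)]
            adj2[candidates[0], 2] = 1
        ind2 = _ind(adj2, ind.node_names)
        full2 = cache.score(ind2)
        delta_term = cache.node_term(2, ind2.parents(2)) - cache.node_term(2, ind.parents(2))
        assert full2 - full == pytest.approx(delta_term, abs=1e-9)

    def test_relabel_invariance(self, make_random_table):
        rng = np.random.default_rng(5)
        table = make_random_table(rng, 50, 4)
        adj = random_dag(rng, 5)
        ind = _ind(adj, [*table.snp_names, "Class"])
        base = bic_score(ind, table)
        perm = np.array([2, 0, 3, 1])  # permute SNP nodes, class stays last
        table2 = GenotypeTable(
            [table.snp_names[i] for i in perm], table.genotypes[:, perm], table.phenotype
        )
        full_perm = np.concatenate([perm, [4]])
        adj2 = adj[np.ix_(full_perm, full_perm)]
        ind2 = _ind(adj2, [*table2.snp_names, "Class"])
        assert bic_score(ind2, table2) == pytest.approx(base, abs=1e-9)

    def test_base_rescales_uniformly(self, counts_table):
        n = counts_table.n_snps + 1
        ind = _ind(np.zeros((n, n)), [*counts_table.snp_names, "Class"])
        nat = bic_score(ind, counts_table)
        ind.cached_score = None
        b10 = bic_score(ind, counts_table, base=10)
        assert b10 == pytest.approx(nat / math.log(10), rel=1e-12)


class TestSerialization:
    def test_edge_list_and_dot(self, tmp_path):
        ind = _ind(CHAIN3, ["A", "B", "C"])
        path = tmp_path / "net.tsv"
        write_edge_list(ind, path)
        assert path.read_text().splitlines() == ["A\tB", "B\tC"]
        dot = to_dot(ind)
        assert '"A" -> "B";' in dot and dot.startswith("digraph")
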