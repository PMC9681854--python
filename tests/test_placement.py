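"""Pruning likelihood and simplified evolutionary placement."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plankshift.oracles import enumeration_loglik
from plankshift.placement import (
    BackboneTree,
    GTRModel,
    Placement,
    discrete_gamma_rates,
    place_all,
    place_query,
    placements_per_clade,
    read_jplace,
    tree_loglik,
    write_jplace,
)
from plankshift.simulate import gen_tree_and_alignment
from plankshift.types import FormatError

JC = GTRModel(gamma_shape=100.0, n_rate_categories=1)


def _random_model(rng) -> GTRModel:
    freqs = rng.uniform(0.5, 2.0, 4)
    return GTRModel(
        exchangeabilities=tuple(rng.uniform(0.3, 3.0, 6)),
        base_frequencies=tuple(freqs / freqs.sum()),
        gamma_shape=float(rng.uniform(0.3, 3.0)),
        n_rate_categories=int(rng.integers(1, 5)),
        p_invariant=float(rng.choice([0.0, 0.25])),
    )


class TestModel:
    def test_rate_matrix_rows_sum_to_zero_mean_one(self, rng):
        m = _random_model(rng)
        Q = m.rate_matrix()
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        rates, weights = m.category_rates_weights()
        mean = -np.dot(m.base_frequencies, np.diag(Q)) * np.dot(rates, weights)
        assert mean == pytest.approx(1.0, abs=1e-10)

    def test_gamma_category_means_average_to_one(self):
        for shape in (0.2, 1.0, 5.0):
            rates = discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(rates) > 0)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            GTRModel(exchangeabilities=(0, 0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            GTRModel(base_frequencies=(0.5, 0.5, 0.2, 0.2))


class TestTreeLoglik:
    def test_single_leaf_equilibrium(self):
        tree = BackboneTree.from_newick("A;")
        assert tree_loglik(tree, {"A": "A"}, JC) == pytest.approx(np.log(0.25))

    def test_identical_leaves_zero_path(self):
        tree = BackboneTree.from_newick("(A:0.0,B:0.0);")
        ll = tree_loglik(tree, {"A": "AC", "B": "AC"}, JC)
        assert ll == pytest.approx(2 * np.log(0.25))

    def test_missing_leaf_sequence_rejected(self):
        tree = BackboneTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(FormatError, match="B"):
            tree_loglik(tree, {"A": "AC"}, JC)

    def test_zero_length_alignment_rejected(self):
        tree = BackboneTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(FormatError):
            tree_loglik(tree, {"A": "", "B": ""}, JC)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pruning_matches_enumeration(self, seed):
        """Property: on random 3-5-leaf trees with random GTR+Gamma models
        and 1-10 sites, pruning equals brute-force state enumeration."""
        rng = np.random.default_rng(seed)
        model = _random_model(rng)
        tree, aln, _ = gen_tree_and_alignment(
            int(rng.integers(3, 6)), int(rng.integers(1, 11)), model,
            seed=seed + 1,
        )
        a = tree_loglik(tree, aln, model)
        b = enumeration_loglik(tree, aln, model)
        assert abs(a - b) <= 1e-10 * abs(b)

    def test_rerooting_invariance(self, rng):
        """A reversible model's likelihood does not depend on root
        placement (checked by re-rooting at several edge midpoints)."""
        model = _random_model(rng)
        tree, aln, _ = gen_tree_and_alignment(8, 120, model, seed=77)
        base = tree_loglik(tree, aln, model)
        for k in range(3):
            rerooted = BackboneTree.from_newick(_reroot_newick(tree, k))
            assert tree_loglik(rerooted, aln, model) == pytest.approx(base, abs=1e-8)


def _reroot_newick(tree: BackboneTree, edge_index: int) -> str:
    """Newick of ``tree`` re-rooted at the midpoint of one undirected edge.

    The original degree-2 root is dissolved (its two child edges merge), so
    branch lengths and the induced unrooted topology are conserved exactly.
    """
    root = tree.root
    adj: dict[int, list[tuple[int, float]]] = {v: [] for v in range(tree.n_nodes)}

    def connect(a, b, ln):
        adj[a].append((b, ln))
        adj[b].append((a, ln))

    a, b = tree.children[root]
    connect(a, b, tree.blen[a] + tree.blen[b])
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and p != root:
            connect(v, p, tree.blen[v])
    edges = sorted(
        {(min(u, v), max(u, v)) for u in adj for v, _ in adj[u]}
    )
    x, y = edges[edge_index % len(edges)]
    (ln,) = [l for v, l in adj[x] if v == y][:1]

    def subtree(v: int, parent: int) -> str:
        kids = [(w, l) for w, l in adj[v] if w != parent]
        if not kids:
            return tree.names[v]
        return "(" + ",".join(f"{subtree(w, v)}:{l:.10g}" for w, l in kids) + ")"

    return f"({subtree(x, y)}:{ln / 2:.10g},{subtree(y, x)}:{ln / 2:.10g});"


@pytest.fixture(scope="module")
def world():
    model = GTRModel(gamma_shape=0.8)
    tree, aln, truth = gen_tree_and_alignment(12, 300, model, seed=42, n_queries=6)
    refs = {k: v for k, v in aln.items() if not k.startswith("Q")}
    queries = {k: v for k, v in aln.items() if k.startswith("Q")}
    return model, tree, refs, queries, truth


class TestPlacement:

    def test_self_placement_on_own_pendant_edge(self, world):
        model, tree, refs, _, _ = world
        for v in tree.leaves[:6]:
            name = tree.names[v]
            placements = place_query(tree, refs, model, refs[name], query_id=name)
            assert placements[0].edge_id == tree.edge_num[v]

    def test_like_weight_ratios_normalize(self, world):
        model, tree, refs, queries, _ = world
        qid, seq = next(iter(queries.items()))
        placements = place_query(tree, refs, model, seq, query_id=qid)
        assert sum(p.like_weight_ratio for p in placements) == pytest.approx(1.0, abs=1e-9)
        lls = [p.log_likelihood for p in placements]
        assert lls == sorted(lls, reverse=True)

    def test_simulated_queries_recover_true_edge(self, world):
        model, tree, refs, queries, truth = world
        hits = 0
        for qid, seq in queries.items():
            placements = place_query(tree, refs, model, seq, query_id=qid)
            if truth[qid] in [p.edge_id for p in placements[:2]]:
                hits += 1
        assert hits >= 0.8 * len(queries)

    def test_boundary_pendant_lengths_flagged(self, world):
        model, tree, refs, _, _ = world
        name = tree.names[tree.leaves[0]]
        placements = place_query(tree, refs, model, refs[name], query_id=name)
        lo, hi = 1e-8, 2.0
        for p in placements:
            if p.pendant_length <= lo or p.pendant_length >= hi:
                assert p.at_bound

    def test_all_gap_query_unplaceable(self, world):
        model, tree, refs, _, _ = world
        width = len(next(iter(refs.values())))
        with pytest.raises(FormatError, match="unplaceable"):
            place_query(tree, refs, model, "-" * width)

    def test_wrong_length_query_rejected(self, world):
        model, tree, refs, _, _ = world
        with pytest.raises(FormatError, match="length"):
            place_query(tree, refs, model, "ACGT")

    def test_placement_deterministic(self, world):
        model, tree, refs, queries, _ = world
        qid, seq = next(iter(queries.items()))
        p1 = place_query(tree, refs, model, seq, query_id=qid)
        p2 = place_query(tree, refs, model, seq, query_id=qid)
        assert p1 == p2


class TestCladeCounts:
    def _placements(self, edges):
        return {
            f"Q{i}": [Placement(f"Q{i}", e, 0.01, -10.0, 1.0)]
            for i, e in enumerate(edges)
        }

    def test_single_clade_gets_all_counts(self):
        pls = self._placements([1, 1, 2])
        df = placements_per_clade(pls, {1: "Rotaliida", 2: "Rotaliida"})
        assert df["n_motus"].sum() == 3
        assert set(df["clade"]) == {"Rotaliida"}

    def test_counts_conserve_and_unmapped_edges_flagged(self):
        pls = self._placements([1, 2, 9])
        labels = {"Q0": "putative_planktonic", "Q1": "benthic", "Q2": "benthic"}
        df = placements_per_clade(pls, {1: "A", 2: "B"}, labels=labels)
        assert df["n_motus"].sum() == 3
        assert "unassigned" in set(df["clade"])


class TestJplace:
    def test_round_trip(self, tmp_path):
        model = GTRModel(gamma_shape=1.0)
        tree, aln, _ = gen_tree_and_alignment(6, 80, model, seed=9, n_queries=2)
        refs = {k: v for k, v in aln.items() if not k.startswith("Q")}
        queries = {k: v for k, v in aln.items() if k.startswith("Q")}
        placements = place_all(tree, refs, model, queries)
        path = tmp_path / "p.jplace"
        write_jplace(placements, tree, path)
        back = read_jplace(path)
        assert back == {
            q: [
                Placement(p.query_id, p.edge_id, p.pendant_length,
                          p.log_likelihood, p.like_weight_ratio)
                for p in plist
            ]
            for q, plist in placements.items()
        }

    def test_empty_placements_valid(self, tmp_path):
        tree = BackboneTree.from_newick("(A:0.1,B:0.2);")
        path = tmp_path / "empty.jplace"
        write_jplace({}, tree, path)
        doc = json.loads(path.read_text())
        assert doc["placements"] == []

    def test_required_fields_present(self, tmp_path):
        tree = BackboneTree.from_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        path = tmp_path / "p.jplace"
        write_jplace({"Q": [Placement("Q", 0, 0.01, -5.0, 1.0)]}, tree, path)
        doc = json.loads(path.read_text())
        assert doc["version"] == 3
        assert doc["fields"][:3] == ["edge_num", "likelihood", "like_weight_ratio"]
        assert "{0}" in doc["tree"]
        entry = doc["placements"][0]
        assert set(entry) >= {"p", "n"}
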