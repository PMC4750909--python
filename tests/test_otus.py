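"""K2P distances, neighbor joining and OTU delineation."""

from __future__ import annotations

import itertools
import math
from collections import defaultdict, deque

import numpy as np
import pytest

from oligocoi import (
    DistanceMatrix,
    K2PSaturationError,
    community_table,
    count_reads_per_otu,
    delineate_otus,
    distance_matrix,
    end_reference,
    k2p_distance,
    mean_reads,
    neighbor_joining,
    tree_distances,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def k2p_oracle(a: str, b: str) -> float:
    """Direct per-site evaluation of Kimura's closed form."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if {x, y} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
    p, q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))


def random_additive_matrix(n_leaves: int, rng) -> tuple[list[str], np.ndarray]:
    """Leaf distance matrix of a random binary tree with positive branch
    lengths (additive by construction; the generating tree is the oracle)."""
    adj: dict[int, dict[int, float]] = defaultdict(dict)
    w = rng.uniform(0.2, 1.0)
    adj[0][1] = adj[1][0] = w
    next_id = n_leaves  # internal node ids
    for leaf in range(2, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        m = next_id
        next_id += 1
        t = rng.uniform(0.2, 0.8)
        adj[u][m] = adj[m][u] = w * t
        adj[v][m] = adj[m][v] = w * (1 - t)
        adj[leaf][m] = adj[m][leaf] = rng.uniform(0.2, 1.0)
    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        queue = deque([src])
        while queue:
            cur = queue.popleft()
            for nb, wt in adj[cur].items():
                if nb not in dist:
                    dist[nb] = dist[cur] + wt
                    queue.append(nb)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]
    return [f"L{i}" for i in range(n_leaves)], d


def enumerate_5taxon_topologies() -> list[list[tuple[int, int]]]:
    """All 15 unrooted binary topologies on leaves 0..4 as edge lists
    (internal nodes numbered from 5)."""
    base = [(0, 5), (1, 5), (2, 5)]  # star on 3 leaves

    def add_leaf(edges: list[tuple[int, int]], leaf: int) -> list[list[tuple[int, int]]]:
        out = []
        new_internal = max(max(e) for e in edges) + 1
        for i, (u, v) in enumerate(edges):
            rest = edges[:i] + edges[i + 1 :]
            out.append(
                rest + [(u, new_internal), (new_internal, v), (leaf, new_internal)]
            )
        return out

    trees3 = [base]
    trees4 = [t for tr in trees3 for t in add_leaf(tr, 3)]
    return [t for tr in trees4 for t in add_leaf(tr, 4)]


def topology_splits(edges: list[tuple[int, int]], n_leaves: int = 5) -> set:
    adj = defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    splits = set()
    for u, v in edges:
        # leaves reachable from u without crossing (u, v)
        seen = {u}
        stack = [u]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if (cur, nb) in ((u, v), (v, u)) or nb in seen:
                    continue
                seen.add(nb)
                stack.append(nb)
        side = frozenset(x for x in seen if x < n_leaves)
        other = frozenset(range(n_leaves)) - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def nj_tree_splits(tree) -> set:
    all_leaves = frozenset(l.name for l in tree.leaves())
    out = set()

    def walk(node):
        names = frozenset(l.name for l in node.leaves())
        if 2 <= len(names) <= len(all_leaves) - 2:
            out.add(frozenset({names, all_leaves - names}))
        for child, _ in node.children:
            walk(child)

    walk(tree)
    return out


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # hand evaluations of -1/2 ln((1-2P-Q) sqrt(1-2Q)):
            ("AAAA", "GAAA", -0.5 * math.log(0.5)),  # P=1/4, Q=0
            ("AAAA", "CAAA", -0.5 * math.log(0.75 * math.sqrt(0.5))),  # P=0, Q=1/4
        ],
    )
    def test_closed_form_spot_values(self, a, b, expected):
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert k2p_distance(a, b) == pytest.approx(k2p_oracle(a, b), abs=1e-12)

    def test_transition_vs_transversion_classification(self):
        # A<->G and C<->T are transitions; everything else transversions
        assert k2p_distance("AAAA", "GAAA") == pytest.approx(
            k2p_distance("CCCC", "TCCC"), abs=1e-12
        )
        assert k2p_distance("AAAA", "TAAA") == pytest.approx(
            k2p_distance("AAAA", "CAAA"), abs=1e-12
        )

    def test_reduces_to_jukes_cantor_for_uniform_substitutions(self):
        # one third of the differing sites are transitions => K2P == JC
        L, diffs = 600, 90
        a = "A" * L
        b = "G" * (diffs // 3) + "C" * (2 * diffs // 3) + "A" * (L - diffs)
        p = diffs / L
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert k2p_distance(a, b) == pytest.approx(jc, abs=1e-9)

    def test_pairwise_deletion_of_ambiguous_sites(self):
        # the N-bearing site is dropped: effectively AAA vs GAA (P=1/3)
        d = k2p_distance("AAAN", "GAAT")
        assert d == pytest.approx(k2p_oracle("AAAN", "GAAT"), abs=1e-12)
        assert d == pytest.approx(k2p_distance("AAA", "GAA"), abs=1e-12)

    def test_saturation_raises_or_returns_inf(self):
        a, b = "ACAC" * 10, "CACA" * 10  # all transversions, Q=1
        with pytest.raises(K2PSaturationError):
            k2p_distance(a, b)
        assert k2p_distance(a, b, on_saturation="inf") == math.inf

    def test_length_mismatch_and_no_comparable_sites(self):
        with pytest.raises(ValueError):
            k2p_distance("AAAA", "AAA")
        with pytest.raises(ValueError):
            k2p_distance("NNNN", "AAAA")

    def test_matrix_matches_per_pair_oracle(self):
        rng = np.random.default_rng(42)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=120)) for _ in range(10)
        ]
        # keep pairs comparable: mutate from the first sequence instead
        base = seqs[0]
        seqs = [base] + [
            "".join(
                c if rng.random() > 0.15 else rng.choice(list("ACGT"))
                for c in base
            )
            for _ in range(9)
        ]
        dm = distance_matrix(seqs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        for i, j in itertools.combinations(range(len(seqs)), 2):
            assert dm.values[i, j] == pytest.approx(
                k2p_oracle(seqs[i], seqs[j]), abs=1e-12
            )

    def test_matrix_error_names_the_offending_pair(self):
        with pytest.raises(ValueError, match="seq1"):
            distance_matrix(["AAAA", "AAA", "AAAA"])


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 2, 4, 4],
                [2, 0, 4, 4],
                [4, 4, 0, 2],
                [4, 4, 2, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        td = tree_distances(tree)
        for i, j in itertools.combinations(range(4), 2):
            assert td[frozenset((labels[i], labels[j]))] == pytest.approx(
                d[i, j], abs=1e-9
            )
        # topology ((A,B),(C,D)): the only nontrivial split is AB|CD
        assert nj_tree_splits(tree) == {
            frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        }

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        td = tree_distances(tree)
        # pendant branches (dAB+dAC-dBC)/2 = 1 etc. reproduce all distances
        assert td[frozenset(("A", "B"))] == pytest.approx(3, abs=1e-9)
        assert td[frozenset(("A", "C"))] == pytest.approx(4, abs=1e-9)
        assert td[frozenset(("B", "C"))] == pytest.approx(5, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))

    def test_infinite_entries_rejected(self):
        d = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="saturated"):
            neighbor_joining(DistanceMatrix(["A", "B", "C"], d))

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_recovers_additive_matrices_exactly(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(5):
            labels, d = random_additive_matrix(n_leaves, rng)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            td = tree_distances(tree)
            for i, j in itertools.combinations(range(n_leaves), 2):
                assert td[frozenset((labels[i], labels[j]))] == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_topology_agrees_with_exhaustive_enumeration_at_5_taxa(self):
        """NJ recovers the unique 5-taxon topology whose path-length system
        fits the additive matrix exactly (checked over all 15 topologies)."""
        rng = np.random.default_rng(7)
        topologies = enumerate_5taxon_topologies()
        assert len(topologies) == 15
        pair_index = list(itertools.combinations(range(5), 2))
        for _ in range(5):
            labels, d = random_additive_matrix(5, rng)
            y = np.array([d[i, j] for i, j in pair_index])
            exact = []
            for edges in topologies:
                # design matrix: which edges lie on each leaf-pair path
                adj = defaultdict(set)
                for u, v in edges:
                    adj[u].add(v)
                    adj[v].add(u)

                def path_edges(src, dst):
                    prev = {src: None}
                    queue = deque([src])
                    while queue:
                        cur = queue.popleft()
                        for nb in adj[cur]:
                            if nb not in prev:
                                prev[nb] = cur
                                queue.append(nb)
                    out, cur = [], dst
                    while prev[cur] is not None:
                        out.append(tuple(sorted((cur, prev[cur]))))
                        cur = prev[cur]
                    return out

                cols = sorted({tuple(sorted(e)) for e in edges})
                a_mat = np.zeros((len(pair_index), len(cols)))
                for r, (i, j) in enumerate(pair_index):
                    for e in path_edges(i, j):
                        a_mat[r, cols.index(e)] = 1.0
                sol, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
                if np.abs(a_mat @ sol - y).max() < 1e-9:
                    exact.append(edges)
            assert len(exact) == 1
            want = {
                frozenset(
                    {
                        frozenset(f"L{i}" for i in side)
                        for side in pair
                    }
                )
                for pair in topology_splits(exact[0])
            }
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert nj_tree_splits(tree) == want


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------


def _mutated(seq: str, frac: float, rng) -> str:
    pos = rng.choice(len(seq), size=int(frac * len(seq)), replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestDelineation:
    @pytest.fixture
    def refs(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=400))
        other = _mutated(base, 0.30, rng)
        return {"T9": base, "R1": other}, rng

    def test_identical_query_assigned_to_reference(self, refs):
        ref_map, _ = refs
        res = delineate_otus({"q1": ref_map["T9"]}, ref_map)
        assert res.otu_of("q1") == "T9"
        assert res.table["nearest_ref_distance"].iloc[0] == 0.0

    def test_query_below_threshold_joins_nearest_reference(self, refs):
        ref_map, rng = refs
        q = _mutated(ref_map["T9"], 0.03, rng)
        res = delineate_otus({"q1": q}, ref_map)
        assert res.otu_of("q1") == "T9"
        assert 0 < res.table["nearest_ref_distance"].iloc[0] < 0.10

    def test_distant_query_becomes_new_otu(self, refs):
        ref_map, rng = refs
        far = _mutated(ref_map["T9"], 0.25, rng)  # >= 15% from everything
        res = delineate_otus({"q1": far}, ref_map)
        assert res.otu_of("q1") == "(1)"
        assert res.new_otus == ["(1)"]

    def test_close_novel_queries_share_one_new_otu(self, refs):
        ref_map, rng = refs
        anc = _mutated(ref_map["T9"], 0.25, rng)
        q1 = _mutated(anc, 0.015, rng)
        q2 = _mutated(anc, 0.015, rng)  # ~3% apart via the shared ancestor
        res = delineate_otus({"q1": q1, "q2": q2}, ref_map)
        assert res.otu_of("q1") == res.otu_of("q2") == "(1)"
        assert res.new_otus == ["(1)"]

    def test_two_distant_novel_queries_get_distinct_labels_in_order(self, refs):
        ref_map, rng = refs
        n1 = _mutated(ref_map["T9"], 0.25, rng)
        n2 = _mutated(n1, 0.25, rng)
        res = delineate_otus({"a": n1, "b": n2}, ref_map)
        assert res.otu_of("a") == "(1)"
        assert res.otu_of("b") == "(2)"

    def test_idempotent_on_cluster_representatives(self, refs):
        ref_map, rng = refs
        anc = _mutated(ref_map["T9"], 0.25, rng)
        queries = {
            "q1": _mutated(ref_map["T9"], 0.02, rng),
            "q2": _mutated(anc, 0.01, rng),
            "q3": _mutated(anc, 0.01, rng),
        }
        first = delineate_otus(queries, ref_map)
        reps = {}
        for otu in first.table["otu_id"].unique():
            member = first.table.loc[first.table["otu_id"] == otu, "query"].iloc[0]
            reps[member] = queries[member]
        second = delineate_otus(reps, ref_map)
        assert set(second.table["otu_id"]) == set(first.table["otu_id"])

    def test_no_input_rejected(self):
        with pytest.raises(ValueError):
            delineate_otus({}, {})

    def test_end_reference_orientation(self):
        seq = "AACCGGTTAC"
        assert end_reference(seq, "LCO", 4) == "AACC"
        assert end_reference(seq, "HCO", 4) == "GTAA"  # revcomp prefix
        with pytest.raises(ValueError):
            end_reference(seq, "XYZ", 4)


# ---------------------------------------------------------------------------
# Count aggregation and tables
# ---------------------------------------------------------------------------


class TestCounts:
    def test_counts_sum_member_sequences(self):
        datasets = {("LCO", 1): {"AAA": 10, "AAT": 5}}
        assignments = {"LCO": {"AAA": "T9", "AAT": "T9"}}
        counts, unassigned = count_reads_per_otu(datasets, assignments)
        assert counts.loc["T9", ("LCO", 1)] == 15
        # absent datasets recorded as explicit zeros, not missing
        assert counts.loc["T9", ("HCO", 2)] == 0
        assert all(v == 0 for v in unassigned.values())

    def test_totals_conserved_per_dataset(self):
        rng = np.random.default_rng(3)
        seqs = [f"S{i}" for i in range(20)]
        assignments = {"LCO": {s: f"T{i % 4}" for i, s in enumerate(seqs)}}
        derep = {s: int(rng.integers(1, 50)) for s in seqs}
        counts, _ = count_reads_per_otu({("LCO", 1): derep}, assignments)
        assert counts[("LCO", 1)].sum() == sum(derep.values())

    def test_missing_assignment_is_an_error(self):
        with pytest.raises(KeyError):
            count_reads_per_otu({("LCO", 1): {"AAA": 1}}, {"LCO": {}})

    @pytest.mark.parametrize(
        "reads,expected", [((10, 20, 0, 30), 15.0), ((0, 0, 0, 0), 0.0), ((7, 7, 7, 7), 7.0)]
    )
    def test_mean_reads_includes_zeros(self, reads, expected):
        assert mean_reads(reads) == expected

    def test_mean_reads_requires_four_values(self):
        with pytest.raises(ValueError):
            mean_reads((1, 2, 3))

    def test_community_table_proportions_sum_to_100(self):
        table = community_table(
            {"A": 3, "B": 1},
            {("LCO", 1): {"A": 50, "B": 150}},
            sample_id="S1",
        )
        assert table["pct_specimens"].sum() == pytest.approx(100.0)
        assert table["pct_reads"].sum() == pytest.approx(100.0)
        a = table.set_index("otu_id")
        assert a.loc["A", "pct_specimens"] == pytest.approx(75.0)
        assert a.loc["B", "pct_specimens"] == pytest.approx(25.0)
        # mean reads averages over all four datasets, zeros included
        assert a.loc["B", "mean_reads"] == pytest.approx(150 / 4)
        assert a.loc["B", "pct_reads"] == pytest.approx(75.0)
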