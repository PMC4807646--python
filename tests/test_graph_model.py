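"""Regression-graph structure, anterior sets, and m-separation."""

import itertools

import numpy as np
import pytest
from conftest import naive_m_separated, random_block_graph

from seqreg.errors import IdentificationError, ValidityError
from seqreg.graph_model import (
    BlockOrdering,
    RegressionGraph,
    VariableSpec,
    anterior_set,
    edges_from_dot,
    implied_independencies,
    m_separated,
    to_dot,
    to_graphml,
    validate_graph,
)


def ordering_of(*boxes, context_last=False):
    out = []
    for i, box in enumerate(boxes):
        kind = "context" if (context_last and i == len(boxes) - 1) else "response"
        out.append([VariableSpec(n, i, kind) for n in box])
    return BlockOrdering(out)


@pytest.fixture
def chain():
    """A <- B <- C over three boxes."""
    o = ordering_of(["A"], ["B"], ["C"])
    return o, RegressionGraph.from_ordering(o, arrows={("B", "A"), ("C", "B")})


class TestOrderingInvariants:
    def test_duplicate_name_rejected(self):
        with pytest.raises(ValidityError, match="duplicate"):
            ordering_of(["A"], ["A"])

    def test_context_must_trail(self):
        boxes = [
            [VariableSpec("a", 0, "context")],
            [VariableSpec("b", 1, "response")],
        ]
        with pytest.raises(ValidityError):
            BlockOrdering(boxes)

    def test_log_requires_positivity(self):
        with pytest.raises(ValidityError):
            VariableSpec("x", 0, log_transform=True, positive_required=False)

    def test_yaml_round_trip(self, tmp_path):
        o = ordering_of(["A", "B"], ["C"], context_last=True)
        p = tmp_path / "ordering.yaml"
        o.to_yaml(p)
        o2 = BlockOrdering.from_yaml(p)
        assert o2.to_dict() == o.to_dict()


class TestValidateGraph:
    def test_empty_graph_no_violations(self):
        o = ordering_of(["A"], ["B"])
        g = RegressionGraph.from_ordering(o)
        assert validate_graph(g, o) == []

    def test_edge_rule_violations(self):
        o = ordering_of(["A", "B"], ["C", "D"], context_last=True)
        g = RegressionGraph.from_ordering(
            o,
            arrows={("A", "C")},      # wrong direction: box 0 -> box 1
            dashed={("A", "C")},      # spans boxes
            full={("A", "B")},        # full line in a response box
        )
        rules = sorted(v.rule for v in validate_graph(g, o))
        assert rules == ["arrow direction", "dashed cross-box",
                         "full line outside context box"]

    def test_unknown_node_raises(self):
        o = ordering_of(["A"], ["B"])
        g = RegressionGraph(nodes={"Z": 0})
        with pytest.raises(IdentificationError):
            validate_graph(g, o)


class TestAnteriorSet:
    def test_chain_ancestry(self, chain):
        _, g = chain
        assert anterior_set(g, {"A"}) == {"A", "B", "C"}
        assert anterior_set(g, {"C"}) == {"C"}

    def test_full_line_closure(self):
        o = ordering_of(["A"], ["B", "C"], context_last=True)
        g = RegressionGraph.from_ordering(o, arrows={("B", "A")},
                                          full={("B", "C")})
        assert anterior_set(g, {"A"}) == {"A", "B", "C"}

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_block_graph(rng)
            names = sorted(g.nodes)
            small = set(rng.choice(names, size=1))
            big = small | set(rng.choice(names, size=2))
            a_small = anterior_set(g, small)
            assert anterior_set(g, a_small) == a_small
            assert a_small <= anterior_set(g, big)


class TestMSeparation:
    def test_chain_blocked_by_middle(self, chain):
        _, g = chain
        assert m_separated(g, "A", "C", {"B"})
        assert not m_separated(g, "A", "C", set())

    def test_collider_logic(self):
        o = ordering_of(["C"], ["A", "B"])
        g = RegressionGraph.from_ordering(o, arrows={("A", "C"), ("B", "C")})
        assert m_separated(g, "A", "B", set())
        assert not m_separated(g, "A", "B", {"C"})

    def test_dashed_edge_acts_as_double_mark(self):
        # A <- B ~~ C (dashed): B is a collider on the path A..C
        o = ordering_of(["A"], ["B", "C"])
        g = RegressionGraph.from_ordering(o, arrows={("B", "A")},
                                          dashed={("B", "C")})
        assert not m_separated(g, "A", "C", set())  # B non-collider? A<-B~~C:
        # path edges: B->A has mark at A only; at B the arrow tail is unmarked
        # while the dashed end is marked, so B is NOT a collider: open given {}
        assert m_separated(g, "A", "C", {"B"})

    def test_conditioning_set_validation(self, chain):
        _, g = chain
        with pytest.raises(ValueError):
            m_separated(g, "A", "C", {"A"})
        with pytest.raises(IdentificationError):
            m_separated(g, "A", "Z", set())

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_block_graph(rng)
            names = sorted(g.nodes)
            for x, y in itertools.combinations(names, 2):
                rest = [n for n in names if n not in (x, y)]
                cond = set(rng.choice(rest, size=min(2, len(rest)),
                                      replace=False)) if rest else set()
                assert m_separated(g, x, y, cond) == m_separated(g, y, x, cond)

    def test_edge_addition_never_creates_separation(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            g = random_block_graph(rng, p_arrow=0.25)
            before = set(implied_independencies(g, max_cond=2))
            # add one admissible arrow not present
            candidates = [
                (u, v) for u in g.nodes for v in g.nodes
                if g.nodes[u] > g.nodes[v] and (u, v) not in g.arrows
            ]
            if not candidates:
                continue
            u, v = candidates[int(rng.integers(len(candidates)))]
            g2 = g.copy()
            g2.arrows.add((u, v))
            after = set(implied_independencies(g2, max_cond=2))
            assert after <= before

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            g = random_block_graph(rng, max_nodes=6)
            names = sorted(g.nodes)
            for x, y in itertools.combinations(names, 2):
                rest = [n for n in names if n not in (x, y)]
                for k in range(min(2, len(rest)) + 1):
                    for cond in itertools.combinations(rest, k):
                        assert m_separated(g, x, y, cond) == \
                            naive_m_separated(g, x, y, cond), (g, x, y, cond)


class TestImpliedIndependencies:
    def test_complete_box_has_no_separations(self):
        o = ordering_of(["A", "B", "C"])
        g = RegressionGraph.from_ordering(
            o, dashed={("A", "B"), ("B", "C"), ("A", "C")})
        assert implied_independencies(g, max_cond=2) == []

    def test_isolated_node_separated_from_all(self):
        o = ordering_of(["A", "Z"], ["B"])
        g = RegressionGraph.from_ordering(o, arrows={("B", "A")})
        out = implied_independencies(g, max_cond=0)
        assert ("A", "Z", frozenset()) in out
        assert ("B", "Z", frozenset()) in out

    def test_matches_bruteforce_over_naive_oracle(self):
        rng = np.random.default_rng(23)
        g = random_block_graph(rng, max_nodes=6)
        names = sorted(g.nodes)
        expected = []
        for x, y in itertools.combinations(names, 2):
            rest = [n for n in names if n not in (x, y)]
            for k in range(min(2, len(rest)) + 1):
                for cond in itertools.combinations(rest, k):
                    if naive_m_separated(g, x, y, cond):
                        expected.append((x, y, frozenset(cond)))
        assert implied_independencies(g, max_cond=2) == expected


class TestSerialization:
    def test_empty_graph_dot_has_clusters_no_edges(self):
        o = ordering_of(["A"], ["B"])
        text = to_dot(RegressionGraph.from_ordering(o))
        assert "cluster_box0" in text and "cluster_box1" in text
        arrows, dashed, full = edges_from_dot(text)
        assert not arrows and not dashed and not full

    def test_edge_label_appears_verbatim(self):
        o = ordering_of(["csa_dis"], ["lean_mass"])
        g = RegressionGraph.from_ordering(o, arrows={("lean_mass", "csa_dis")})
        text = to_dot(g, {("lean_mass", "csa_dis"): "0.46 (0.17, 0.76)"})
        assert "0.46 (0.17, 0.76)" in text

    def test_dot_round_trip(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            g = random_block_graph(rng)
            arrows, dashed, full = edges_from_dot(to_dot(g))
            assert arrows == g.arrows
            assert dashed == g.dashed
            assert full == g.full

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        o = ordering_of(["A"], ["B", "C"])
        g = RegressionGraph.from_ordering(o, arrows={("B", "A")},
                                          dashed={("B", "C")})
        p = tmp_path / "g.graphml"
        to_graphml(g, p, {("B", "A"): {"beta": 0.5, "p": 0.01}})
        G = nx.read_graphml(p)
        kinds = sorted(d["kind"] for _, _, d in G.edges(data=True))
        assert kinds == ["arrow", "dashed"]


def test_fitted_graph_lean_ucoc_separated_given_osteocalcin():
    """The lean-mass-UCOC link runs entirely through osteocalcin."""
    o = ordering_of(["csa_dis", "vbmd_dis"],
                    ["lean_mass", "fm_pct", "height"],
                    ["leptin", "adiponectin", "osteocalcin", "ucoc",
                     "phylloquinone"],
                    ["age"], context_last=True)
    g = RegressionGraph.from_ordering(
        o,
        arrows={("lean_mass", "csa_dis"), ("height", "csa_dis"),
                ("adiponectin", "csa_dis"), ("ucoc", "csa_dis"),
                ("adiponectin", "vbmd_dis"), ("phylloquinone", "vbmd_dis"),
                ("leptin", "fm_pct"), ("osteocalcin", "lean_mass")},
        dashed={("csa_dis", "vbmd_dis"), ("leptin", "adiponectin"),
                ("osteocalcin", "ucoc")},
    )
    assert validate_graph(g, o) == []
    assert not m_separated(g, "lean_mass", "ucoc", set())
    assert m_separated(g, "lean_mass", "ucoc", {"osteocalcin"})
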