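"""Shared fixtures and independent test oracles.

The path-enumeration m-separation oracle and the random block-ordered graph
generator here are deliberately naive: they re-derive separation statements
by exhaustive simple-path search so the walk-based production implementation
can be checked against something with no shared code.
"""

import itertools

import numpy as np
import pytest

from seqreg.graph_model import (
    BlockOrdering,
    RegressionGraph,
    VariableSpec,
    anterior_set,
)


# -- naive m-separation oracle ------------------------------------------------


def _edge_list(g: RegressionGraph):
    """Edges as (u, v, mark_at_u, mark_at_v), both directions."""
    edges = []
    for tail, head in g.arrows:
        edges.append((tail, head, False, True))
        edges.append((head, tail, True, False))
    for a, b in g.dashed:
        edges.append((a, b, True, True))
        edges.append((b, a, True, True))
    for a, b in g.full:
        edges.append((a, b, False, False))
        edges.append((b, a, False, False))
    return edges


def naive_m_separated(g: RegressionGraph, x, y, given) -> bool:
    """Exhaustive simple-path search for an m-connecting path."""
    given = frozenset(given)
    ant = anterior_set(g, given) if given else frozenset()
    edges_from = {}
    for u, v, mu, mv in _edge_list(g):
        edges_from.setdefault(u, []).append((v, mu, mv))

    def connects(path_edges):
        # path_edges: list of (u, v, mark_u, mark_v); check inner nodes
        for k in range(len(path_edges) - 1):
            node = path_edges[k][1]
            mark_in = path_edges[k][3]
            mark_out = path_edges[k + 1][2]
            if mark_in and mark_out:  # collider
                if node not in ant:
                    return False
            elif node in given:
                return False
        return True

    def dfs(node, visited, path_edges):
        if node == y:
            return connects(path_edges)
        for v, mu, mv in edges_from.get(node, []):
            if v in visited:
                continue
            if dfs(v, visited | {v}, path_edges + [(node, v, mu, mv)]):
                return True
        return False

    return not dfs(x, {x}, [])


# -- random block-ordered graphs ---------------------------------------------


def random_block_graph(rng, max_nodes=7, p_arrow=0.35, p_dashed=0.3,
                       p_full=0.5, p_context=0.5) -> RegressionGraph:
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    nb = int(rng.integers(2, min(4, n) + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=nb - 1, replace=False))
    boxes, prev = [], 0
    for c in list(cuts) + [n]:
        boxes.append(names[prev:c])
        prev = c
    has_context = rng.random() < p_context
    ordering = BlockOrdering([
        [
            VariableSpec(m, i,
                         "context" if (has_context and i == len(boxes) - 1)
                         else "response")
            for m in box
        ]
        for i, box in enumerate(boxes)
    ])
    arrows, dashed, full = set(), set(), set()
    for i, box in enumerate(boxes):
        for j in range(i + 1, len(boxes)):
            for u in boxes[j]:
                for v in box:
                    if rng.random() < p_arrow:
                        arrows.add((u, v))
        is_context = has_context and i == len(boxes) - 1
        for a, b in itertools.combinations(box, 2):
            if not is_context and rng.random() < p_dashed:
                dashed.add((a, b))
            if is_context and rng.random() < p_full:
                full.add((a, b))
    return RegressionGraph.from_ordering(ordering, arrows, dashed, full)


# -- expensive shared fixtures ------------------------------------------------


@pytest.fixture(scope="session")
def calibrated_spec():
    from seqreg.synthetic_data import default_spec

    return default_spec()


@pytest.fixture(scope="session")
def recovery_500(calibrated_spec):
    """500 simulate-fit replicates at the study's n = 70 (shared, ~minutes)."""
    from seqreg.synthetic_data import recovery_experiment

    return recovery_experiment(calibrated_spec, n=70, reps=500, seed=101)
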