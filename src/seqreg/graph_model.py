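"""Regression graphs over block-ordered variables.

A regression graph arranges variables in ordered boxes: box 0 holds the
ultimate responses, higher indices hold intermediate responses and, last,
context (background) variables.  Three edge kinds occur:

* **arrows** point from an explanatory variable in a later box to a response
  in an earlier box (a significant partial association);
* **dashed** lines join two joint responses within the same response box
  (residual association after controlling for both variables' regressors);
* **full** lines join context variables within a context box (a concentration
  -graph edge among background variables).

The global Markov property of such a graph is read off with *m-separation*:
on a path, a node is a collider when both incident edges carry an edge-mark
at it (arrowheads mark their head node; dashed edges mark both ends; full
lines mark neither).  A path connects x and y given C when every
non-collider on it avoids C and every collider lies in the anterior set of C.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import networkx as nx
import yaml

from .errors import IdentificationError, SchemaError, ValidityError

RESPONSE = "response"
CONTEXT = "context"


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one analysis variable.

    box_index counts from 0 (ultimate-response box) toward the background;
    context boxes carry the highest indices.  Variables flagged for the
    natural-log transform must be strictly positive on the original scale.
    """

    name: str
    box_index: int
    box_kind: str = RESPONSE
    log_transform: bool = True
    units: str = ""
    positive_required: bool | None = None

    def __post_init__(self):
        if self.box_kind not in (RESPONSE, CONTEXT):
            raise ValidityError(f"unknown box kind {self.box_kind!r}")
        if self.box_index < 0:
            raise ValidityError("box_index must be non-negative")
        if self.positive_required is None:
            object.__setattr__(self, "positive_required", self.log_transform)
        if self.log_transform and not self.positive_required:
            raise ValidityError(
                f"{self.name}: log_transform requires positive_required"
            )


@dataclass
class BlockOrdering:
    """A-priori ordered boxes of variables defining admissible regressors.

    ``boxes[i]`` is the list of VariableSpec with box_index i.  Admissible
    explanatory variables for a response in box i are exactly the variables
    in boxes with index > i.
    """

    boxes: list[list[VariableSpec]]

    def __post_init__(self):
        if not self.boxes or any(len(b) == 0 for b in self.boxes):
            raise ValidityError("boxes must be non-empty")
        seen = {}
        kinds = []
        for i, box in enumerate(self.boxes):
            box_kinds = {v.box_kind for v in box}
            if len(box_kinds) != 1:
                raise ValidityError(f"box {i} mixes response and context variables")
            kinds.append(box_kinds.pop())
            for v in box:
                if v.name in seen:
                    raise ValidityError(f"duplicate variable {v.name!r}")
                if v.box_index != i:
                    raise ValidityError(
                        f"{v.name}: box_index {v.box_index} != position {i}"
                    )
                seen[v.name] = v
        # context boxes must trail every response box
        first_context = next((i for i, k in enumerate(kinds) if k == CONTEXT), None)
        if first_context is not None and any(
            k == RESPONSE for k in kinds[first_context:]
        ):
            raise ValidityError("context boxes must follow all response boxes")
        if kinds[0] != RESPONSE:
            raise ValidityError("the first box must be a response box")
        self._by_name = seen

    @property
    def variables(self) -> dict[str, VariableSpec]:
        return dict(self._by_name)

    def names(self) -> list[str]:
        return [v.name for box in self.boxes for v in box]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise IdentificationError(f"unknown variable {name!r}") from None

    def box_index(self, name: str) -> int:
        return self[name].box_index

    def subset(self, drop: set[str]) -> "BlockOrdering":
        """Ordering with the named variables removed (boxes must stay non-empty)."""
        boxes = []
        for box in self.boxes:
            kept = [v for v in box if v.name not in drop]
            if kept:
                idx = len(boxes)
                boxes.append(
                    [
                        VariableSpec(v.name, idx, v.box_kind, v.log_transform,
                                     v.units, v.positive_required)
                        for v in kept
                    ]
                )
        return BlockOrdering(boxes)

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "boxes": [
                {
                    "kind": box[0].box_kind,
                    "variables": [
                        {"name": v.name, "log": v.log_transform, "units": v.units}
                        for v in box
                    ],
                }
                for box in self.boxes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockOrdering":
        try:
            raw_boxes = d["boxes"]
        except (KeyError, TypeError):
            raise SchemaError("ordering config must have a 'boxes' key") from None
        boxes = []
        for i, raw in enumerate(raw_boxes):
            kind = raw.get("kind", RESPONSE)
            boxes.append(
                [
                    VariableSpec(
                        name=rv["name"],
                        box_index=i,
                        box_kind=kind,
                        log_transform=bool(rv.get("log", True)),
                        units=rv.get("units", ""),
                    )
                    for rv in raw["variables"]
                ]
            )
        return cls(boxes)

    @classmethod
    def from_yaml(cls, path) -> "BlockOrdering":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class RegressionGraph:
    """Nodes with box assignments plus arrow / dashed / full edge sets.

    Arrows are stored (explanatory, response); the arrowhead sits at the
    response.  Dashed and full edges are unordered pairs.
    """

    nodes: dict[str, int]
    box_kinds: dict[str, str] = field(default_factory=dict)
    arrows: set = field(default_factory=set)
    dashed: set = field(default_factory=set)
    full: set = field(default_factory=set)

    def __post_init__(self):
        self.arrows = set(self.arrows)
        self.dashed = {_pair(*e) for e in self.dashed}
        self.full = {_pair(*e) for e in self.full}
        for n in self.nodes:
            self.box_kinds.setdefault(n, RESPONSE)

    @classmethod
    def from_ordering(cls, ordering: BlockOrdering, arrows=(), dashed=(), full=()):
        nodes = {v.name: v.box_index for box in ordering.boxes for v in box}
        kinds = {v.name: v.box_kind for box in ordering.boxes for v in box}
        return cls(nodes=nodes, box_kinds=kinds, arrows=set(arrows),
                   dashed=set(dashed), full=set(full))

    def _check_node(self, n: str) -> None:
        if n not in self.nodes:
            raise IdentificationError(f"unknown node {n!r}")

    # Each edge is (u, v, mark_at_u, mark_at_v).
    def _half_edges(self):
        adj: dict[str, list[tuple[str, bool, bool]]] = {n: [] for n in self.nodes}
        for tail, head in self.arrows:
            adj[tail].append((head, False, True))   # leave tail (no mark), hit head
            adj[head].append((tail, True, False))
        for a, b in self.dashed:
            adj[a].append((b, True, True))
            adj[b].append((a, True, True))
        for a, b in self.full:
            adj[a].append((b, False, False))
            adj[b].append((a, False, False))
        return adj

    def copy(self) -> "RegressionGraph":
        return RegressionGraph(dict(self.nodes), dict(self.box_kinds),
                               set(self.arrows), set(self.dashed), set(self.full))


@dataclass(frozen=True)
class Violation:
    rule: str
    detail: str

    def __str__(self):
        return f"{self.rule}: {self.detail}"


def validate_graph(g: RegressionGraph, ordering: BlockOrdering) -> list[Violation]:
    """Check every structural invariant of a regression graph.

    Returns an empty list iff the graph is valid for the ordering; each
    violation names the offending edge and the rule it breaks.
    """
    out = []
    for n in g.nodes:
        if n not in ordering:
            raise IdentificationError(f"node {n!r} not declared in the ordering")
        if g.nodes[n] != ordering.box_index(n):
            out.append(Violation("box assignment",
                                 f"{n} stored in box {g.nodes[n]}, "
                                 f"ordering says {ordering.box_index(n)}"))
    for tail, head in g.arrows:
        if tail == head:
            out.append(Violation("self edge", f"{tail} -> {head}"))
            continue
        if g.nodes[tail] <= g.nodes[head]:
            out.append(Violation(
                "arrow direction",
                f"{tail} (box {g.nodes[tail]}) -> {head} (box {g.nodes[head]}): "
                "explanatory box index must exceed the response's"))
    for a, b in g.dashed:
        if a == b:
            out.append(Violation("self edge", f"{a} -- {b}"))
            continue
        if g.nodes[a] != g.nodes[b]:
            out.append(Violation("dashed cross-box",
                                 f"{a} (box {g.nodes[a]}) -- {b} (box {g.nodes[b]})"))
        elif g.box_kinds[a] != RESPONSE or g.box_kinds[b] != RESPONSE:
            out.append(Violation("dashed in context box", f"{a} -- {b}"))
    for a, b in g.full:
        if a == b:
            out.append(Violation("self edge", f"{a} -- {b}"))
            continue
        if g.nodes[a] != g.nodes[b]:
            out.append(Violation("full cross-box",
                                 f"{a} (box {g.nodes[a]}) -- {b} (box {g.nodes[b]})"))
        elif g.box_kinds[a] != CONTEXT or g.box_kinds[b] != CONTEXT:
            out.append(Violation("full line outside context box", f"{a} -- {b}"))
    return out


def anterior_set(g: RegressionGraph, seeds) -> frozenset:
    """Seeds closed under directed ancestry and full-line connectivity.

    Adds every node with a directed path into a member, then closes under
    full lines, repeating until stable.  Idempotent and monotone in seeds.
    """
    for s in seeds:
        g._check_node(s)
    parents: dict[str, set] = {n: set() for n in g.nodes}
    for tail, head in g.arrows:
        parents[head].add(tail)
    full_nbrs: dict[str, set] = {n: set() for n in g.nodes}
    for a, b in g.full:
        full_nbrs[a].add(b)
        full_nbrs[b].add(a)
    out = set(seeds)
    frontier = list(out)
    while frontier:
        n = frontier.pop()
        for m in parents[n] | full_nbrs[n]:
            if m not in out:
                out.add(m)
                frontier.append(m)
    return frozenset(out)


def m_separated(g: RegressionGraph, x: str, y: str, given) -> bool:
    """True iff no m-connecting walk joins x and y given the conditioning set.

    Walk-based reachability over half-edge states (node, incoming-mark); a
    node passed with marks on both incident edges is a collider and must lie
    in the anterior set of the conditioning set, every other node passed must
    avoid the conditioning set.  Complete for m-separation because an
    m-connecting path exists iff an m-connecting walk does.
    """
    g._check_node(x)
    g._check_node(y)
    given = frozenset(given)
    for c in given:
        g._check_node(c)
    if x == y:
        raise ValueError("x and y must differ")
    if x in given or y in given:
        raise ValueError("conditioning set must not contain x or y")
    ant = anterior_set(g, given) if given else frozenset()
    adj = g._half_edges()
    # state: (node, arrived-with-mark-at-node)
    stack = [(nbr, mark_v) for nbr, _mark_u, mark_v in adj[x]]
    seen = set()
    while stack:
        node, in_mark = stack.pop()
        if node == y:
            return False
        if (node, in_mark) in seen:
            continue
        seen.add((node, in_mark))
        for nbr, mark_here, mark_there in adj[node]:
            collider = in_mark and mark_here
            if collider:
                if node not in ant:
                    continue
            elif node in given:
                continue
            stack.append((nbr, mark_there))
    return True


def implied_independencies(g: RegressionGraph, max_cond: int) -> list[tuple]:
    """All (x, y, C) with |C| <= max_cond for which m_separated holds.

    Deterministic: pairs lexicographic, conditioning sets by size then
    lexicographically.
    """
    if max_cond < 0:
        raise ValueError("max_cond must be >= 0")
    names = sorted(g.nodes)
    out = []
    for x, y in itertools.combinations(names, 2):
        rest = [n for n in names if n not in (x, y)]
        for k in range(min(max_cond, len(rest)) + 1):
            for cond in itertools.combinations(rest, k):
                if m_separated(g, x, y, cond):
                    out.append((x, y, frozenset(cond)))
    return out


# -- serialization ------------------------------------------------------------


def to_dot(g: RegressionGraph, fit_annotations: dict | None = None) -> str:
    """Render the graph as DOT with boxes as clusters, response box rightmost.

    ``fit_annotations`` maps an edge (tail, head) or unordered pair to a label
    string, e.g. ``"0.46 (0.17, 0.76)"``.
    """
    fit_annotations = fit_annotations or {}

    def label_for(key):
        if key in fit_annotations:
            return fit_annotations[key]
        if isinstance(key, tuple):
            return fit_annotations.get(_pair(*key))
        return None

    lines = ["digraph regression_graph {", "  rankdir=RL;", "  node [shape=box];"]
    by_box: dict[int, list[str]] = {}
    for n, b in sorted(g.nodes.items()):
        by_box.setdefault(b, []).append(n)
    for b in sorted(by_box):
        kind = g.box_kinds[by_box[b][0]]
        lines.append(f"  subgraph cluster_box{b} {{")
        lines.append(f'    label="box {b} ({kind})";')
        for n in by_box[b]:
            lines.append(f'    "{n}";')
        lines.append("  }")
    for tail, head in sorted(g.arrows):
        lab = label_for((tail, head))
        attr = f' [label="{lab}"]' if lab else ""
        lines.append(f'  "{tail}" -> "{head}"{attr};')
    for a, b in sorted(g.dashed):
        lab = label_for((a, b))
        attr = ' [dir=none, style=dashed' + (f', label="{lab}"' if lab else "") + "]"
        lines.append(f'  "{a}" -> "{b}"{attr};')
    for a, b in sorted(g.full):
        lines.append(f'  "{a}" -> "{b}" [dir=none];')
    lines.append("}")
    return "\n".join(lines)


_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"(?:\s*\[([^\]]*)\])?;')


def edges_from_dot(text: str):
    """Parse the edge list back out of DOT text emitted by :func:`to_dot`.

    Returns (arrows, dashed, full) as sets; used for round-trip checks.
    """
    arrows, dashed, full = set(), set(), set()
    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if not m:
            continue
        a, b, attrs = m.group(1), m.group(2), m.group(3) or ""
        if "style=dashed" in attrs:
            dashed.add(_pair(a, b))
        elif "dir=none" in attrs:
            full.add(_pair(a, b))
        else:
            arrows.add((a, b))
    return arrows, dashed, full


def to_graphml(g: RegressionGraph, path, fit_annotations: dict | None = None) -> None:
    """Write the graph as GraphML with edge kind/beta/ci/p attributes."""
    fit_annotations = fit_annotations or {}
    G = nx.MultiDiGraph()
    for n, b in g.nodes.items():
        G.add_node(n, box_index=b, box_kind=g.box_kinds[n])

    def attrs(key):
        ann = fit_annotations.get(key) or (
            fit_annotations.get(_pair(*key)) if isinstance(key, tuple) else None
        )
        if isinstance(ann, dict):
            return {k: ann[k] for k in ("beta", "ci_low", "ci_high", "p") if k in ann}
        return {}

    for tail, head in sorted(g.arrows):
        G.add_edge(tail, head, kind="arrow", **attrs((tail, head)))
    for a, b in sorted(g.dashed):
        G.add_edge(a, b, kind="dashed", **attrs((a, b)))
    for a, b in sorted(g.full):
        G.add_edge(a, b, kind="full")
    nx.write_graphml(G, path)
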