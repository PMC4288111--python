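"""Nested-set indexing of subsumption hierarchies.

Subsumption (subclass-of / subproperty-of) trees are labeled with a
(left, right) integer interval per node so that transitive queries become
interval-containment tests instead of recursive traversals: the descendants
of a node are exactly the nodes whose left label lies strictly inside its
interval.

Multiple inheritance is handled by node duplication: a resource with k
parents is placed once under each parent, and each placement carries a full
(recursively duplicated) copy of the resource's subtree.  Query results
collapse duplicate placements back to canonical resource ids.

The index is built in one batch pass over the whole edge set; incremental
single-resource insertion is supported either by local relabeling or by
marking the index stale until the next batch rebuild.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

from .exceptions import (
    HierarchyCycleError,
    OrphanNodeError,
    StaleIndexError,
    UnknownResourceError,
)


@dataclass(frozen=True)
class SubsumptionEdge:
    """One child-subsumed-by-parent edge between resource ids."""

    child: int
    parent: int

    def __post_init__(self):
        if self.child == self.parent:
            raise HierarchyCycleError([self.child, self.parent])


@dataclass
class Placement:
    """One placed node: a (possibly duplicated) occurrence of a resource."""

    node_id: int
    resource: int
    left: int = 0
    right: int = 0


class NestedSetIndex:
    """Interval labeling of a (duplicated-to-tree) subsumption forest."""

    def __init__(self):
        self.nodes: list[Placement] = []
        self.duplicate_map: dict[int, int] = {}  # node_id -> canonical resource
        self.node_parent: dict[int, int | None] = {}
        self.stale: bool = False
        self._by_resource: dict[int, list[Placement]] | None = None
        self._by_left: list[Placement] | None = None
        self._next_node_id: int = 1

    # -- caches ------------------------------------------------------------

    def _invalidate(self):
        self._by_resource = None
        self._by_left = None

    def _resource_map(self):
        if self._by_resource is None:
            m = defaultdict(list)
            for p in self.nodes:
                m[p.resource].append(p)
            self._by_resource = dict(m)
        return self._by_resource

    def _left_sorted(self):
        if self._by_left is None:
            self._by_left = sorted(self.nodes, key=lambda p: p.left)
        return self._by_left

    def _check_fresh(self):
        if self.stale:
            raise StaleIndexError(
                "index marked stale by an incremental insert; rebuild required"
            )

    # -- accessors ---------------------------------------------------------

    def placements(self, resource: int) -> list[Placement]:
        """Debug accessor: raw placements (duplicates) of one resource."""
        m = self._resource_map()
        if resource not in m:
            raise UnknownResourceError(f"resource {resource} is not placed")
        return list(m[resource])

    def resources(self):
        return set(self._resource_map())

    def labels(self):
        """All left/right labels, as a sorted list."""
        out = []
        for p in self.nodes:
            out.append(p.left)
            out.append(p.right)
        return sorted(out)

    # -- queries -----------------------------------------------------------

    def descendants(self, resource: int) -> set[int]:
        """Canonical resources strictly inside any placement of ``resource``.

        Answered purely by interval comparison on the left-sorted placement
        list (no recursion).
        """
        self._check_fresh()
        by_left = self._left_sorted()
        lefts = [p.left for p in by_left]
        out = set()
        for p in self.placements(resource):
            lo = bisect_right(lefts, p.left)
            hi = bisect_left(lefts, p.right)
            for q in by_left[lo:hi]:
                out.add(q.resource)
        out.discard(resource)
        return out

    def ancestors(self, resource: int) -> set[int]:
        """Canonical resources whose interval strictly contains a placement."""
        self._check_fresh()
        out = set()
        for p in self.placements(resource):
            for q in self.nodes:
                if q.left < p.left and q.right > p.right:
                    out.add(q.resource)
        out.discard(resource)
        return out

    # -- incremental insertion ---------------------------------------------

    def insert_resource(
        self, parent: int, new: int, policy: str = "relabel_incremental"
    ) -> "NestedSetIndex":
        """Place ``new`` under every placement of ``parent``.

        ``relabel_incremental`` shifts labels at or above each insertion
        point by 2, keeping the labeling identical to what a batch rebuild
        over the extended edge set would produce (children are kept in
        ascending resource-id order).  ``mark_stale`` defers the work to the
        next batch rebuild and makes queries refuse to answer.
        """
        if policy == "mark_stale":
            self.stale = True
            return self
        if policy != "relabel_incremental":
            raise ValueError(f"unknown insertion policy {policy!r}")
        m = self._resource_map()
        if parent not in m:
            raise UnknownResourceError(
                f"cannot insert under unplaced resource {parent}"
            )
        parent_placements = sorted(m[parent], key=lambda p: -p.left)
        children_of = defaultdict(list)
        for nid, pid in self.node_parent.items():
            if pid is not None:
                children_of[pid].append(nid)
        placement_of_node = {p.node_id: p for p in self.nodes}
        for pp in parent_placements:
            point = pp.right
            for cid in children_of.get(pp.node_id, ()):  # keep id order
                cp = placement_of_node[cid]
                if cp.resource > new and cp.left < point:
                    point = cp.left
            for q in self.nodes:
                if q.left >= point:
                    q.left += 2
                if q.right >= point:
                    q.right += 2
            nid = self._next_node_id
            self._next_node_id += 1
            np = Placement(nid, new, point, point + 1)
            self.nodes.append(np)
            self.duplicate_map[nid] = new
            self.node_parent[nid] = pp.node_id
            placement_of_node[nid] = np
            children_of[pp.node_id].append(nid)
        self._invalidate()
        return self


# ---------------------------------------------------------------------------
# construction


def _adjacency(edges):
    children = defaultdict(set)
    parents = defaultdict(set)
    resources = set()
    for e in edges:
        children[e.parent].add(e.child)
        parents[e.child].add(e.parent)
        resources.add(e.child)
        resources.add(e.parent)
    return children, parents, resources


def _check_acyclic(children, resources):
    WHITE, GREY, BLACK = 0, 1, 2
    color = dict.fromkeys(resources, WHITE)
    for start in sorted(resources):
        if color[start] != WHITE:
            continue
        stack = [(start, iter(sorted(children.get(start, ()))))]
        color[start] = GREY
        trail = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GREY:
                    raise HierarchyCycleError(trail[trail.index(nxt):] + [nxt])
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    trail.append(nxt)
                    stack.append((nxt, iter(sorted(children.get(nxt, ())))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                trail.pop()
                stack.pop()


def resolve_multiparent(edges, roots=None):
    """Expand a multi-parent DAG into a placement tree.

    Every resource with k parents becomes k node placements, one per parent
    placement, each carrying a recursively duplicated copy of the resource's
    subtree.  Returns ``(tree_edges, duplicate_map)`` where ``tree_edges``
    is a set of (child_node_id, parent_node_id) pairs and ``duplicate_map``
    maps every node id to its canonical resource id.
    """
    index = _build(edges, roots, label=False)
    tree_edges = {
        (nid, pid)
        for nid, pid in index.node_parent.items()
        if pid is not None
    }
    return tree_edges, dict(index.duplicate_map)


def build_nested_set(edges, roots=None) -> NestedSetIndex:
    """Batch-build the nested-set index for an acyclic subsumption edge set.

    ``roots`` defaults to the resources with no parents.  The labeling is a
    single depth-first pass with children visited in ascending resource-id
    order, so identical edge sets always produce identical labels; a pure
    tree of N placements uses exactly the labels 1..2N.  Cycles and
    root-unreachable resources are rejected.
    """
    return _build(edges, roots, label=True)


def _build(edges, roots, label):
    children, parents, resources = _adjacency(edges)
    if roots is None:
        roots = {r for r in resources if not parents.get(r)}
    else:
        roots = set(roots)
        resources |= roots
    _check_acyclic(children, resources)
    if resources and not roots:
        raise OrphanNodeError("no roots given and every resource has a parent")

    reachable = set(roots)
    frontier = list(roots)
    while frontier:
        nxt = []
        for r in frontier:
            for c in children.get(r, ()):
                if c not in reachable:
                    reachable.add(c)
                    nxt.append(c)
        frontier = nxt
    orphans = resources - reachable
    if orphans:
        raise OrphanNodeError(
            f"resources with no parent path to a root: {sorted(orphans)[:10]}"
        )

    index = NestedSetIndex()
    counter = 1
    for root in sorted(roots):
        # iterative DFS with explicit enter/exit events
        stack = [("enter", root, None, None)]
        while stack:
            event, resource, parent_node, placement = stack.pop()
            if event == "exit":
                if label:
                    placement.right = counter
                    counter += 1
                continue
            nid = index._next_node_id
            index._next_node_id += 1
            p = Placement(nid, resource)
            if label:
                p.left = counter
                counter += 1
            index.nodes.append(p)
            index.duplicate_map[nid] = resource
            index.node_parent[nid] = parent_node
            stack.append(("exit", resource, parent_node, p))
            for child in sorted(children.get(resource, ()), reverse=True):
                stack.append(("enter", child, nid, None))
    index._invalidate()
    return index


def descendants(index: NestedSetIndex, resource: int) -> set[int]:
    return index.descendants(resource)


def ancestors(index: NestedSetIndex, resource: int) -> set[int]:
    return index.ancestors(resource)


def insert_resource(
    index: NestedSetIndex, parent: int, new: int, policy: str = "relabel_incremental"
) -> NestedSetIndex:
    return index.insert_resource(parent, new, policy)
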