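"""Lineage (phylogeny) tracking for branching processes.

A :class:`LineageTracker` holds a tree of clones.  Each node carries a
live-population counter maintained through ``record_birth`` /
``record_death``; new mutant clones branch off a living parent.  Pruning
removes extinct leaves — nodes with zero live population and no living
descendants — and the surviving tree can be exported as a Newick string
(node ids quoted, branch lengths in generations since the parent clone
arose, included when generation stamps are provided).
"""

from __future__ import annotations


class LineageNode:
    """One clone in the lineage tree."""

    __slots__ = ("id", "parent", "children", "livePopulation", "generation", "attrs")

    def __init__(self, id: int, parent: "LineageNode | None" = None,
                 generation: float = 0.0, **attrs):
        self.id = id
        self.parent = parent
        self.children: list = []
        self.livePopulation = 0
        self.generation = generation
        self.attrs = attrs

    def has_living_descendant(self) -> bool:
        return any(c.livePopulation > 0 or c.has_living_descendant()
                   for c in self.children)


class LineageTracker:
    """Searchable tree of clones with live-population bookkeeping."""

    def __init__(self):
        self.root: LineageNode | None = None
        self._next_id = 0
        self._nodes: dict = {}

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, node_id: int) -> LineageNode:
        return self._nodes[node_id]

    def new_root(self, generation: float = 0.0, **attrs) -> LineageNode:
        if self.root is not None:
            raise RuntimeError("tree already has a root")
        node = LineageNode(self._next_id, None, generation, **attrs)
        self._next_id += 1
        self.root = node
        self._nodes[node.id] = node
        return node

    def add_mutant(self, parent: LineageNode, generation: float = 0.0,
                   **attrs) -> LineageNode:
        """Branch a new clone off a parent that is still in the tree."""
        if self._nodes.get(parent.id) is not parent:
            raise ValueError("parent is not part of this tree")
        node = LineageNode(self._next_id, parent, generation, **attrs)
        self._next_id += 1
        parent.children.append(node)
        self._nodes[node.id] = node
        return node

    def record_birth(self, node: LineageNode) -> None:
        node.livePopulation += 1

    def record_death(self, node: LineageNode) -> None:
        if node.livePopulation <= 0:
            raise ValueError("clone has no living members to kill")
        node.livePopulation -= 1

    def total_live(self) -> int:
        return sum(n.livePopulation for n in self._nodes.values())

    def prune(self) -> int:
        """Drop extinct nodes with no living descendants; return count."""
        removed = 0
        changed = True
        while changed:
            changed = False
            for node in list(self._nodes.values()):
                if node.livePopulation == 0 and not node.children and node.parent is not None:
                    node.parent.children.remove(node)
                    del self._nodes[node.id]
                    removed += 1
                    changed = True
        return removed

    def to_newick(self, branch_lengths: bool = True) -> str:
        """Newick export of the unpruned tree, ids quoted."""
        if self.root is None:
            return ";"

        def fmt(node: LineageNode, parent_gen: float) -> str:
            label = f"'{node.id}'"
            if branch_lengths:
                label += f":{node.generation - parent_gen:g}"
            if not node.children:
                return label
            inner = ",".join(fmt(c, node.generation) for c in node.children)
            return f"({inner}){label}"

        return fmt(self.root, self.root.generation) + ";"
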