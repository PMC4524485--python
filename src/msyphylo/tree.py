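"""Rooted mutation trees.

The central container of the package: a rooted tree whose tips are sampled
chromosomes and whose branches each carry the set of biallelic mutations
assigned to them.  Under the infinite-sites assumption every mutation lives
on exactly one branch, so branch length (in mutations) is simply the size of
that set.  Nodes may additionally carry an age in years (set by the dating
module or by the simulator).
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    """A node of a :class:`MutationTree`.

    ``mutations`` is the set of site names assigned to the branch *above*
    this node (empty for the root).  ``age`` is the node's age in years
    before present, when known.
    """

    __slots__ = ("label", "children", "parent", "mutations", "age")

    def __init__(
        self,
        label: Optional[str] = None,
        mutations: Optional[set[str]] = None,
        age: Optional[float] = None,
    ) -> None:
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.mutations: set[str] = set(mutations or ())
        self.age = age

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"node/{len(self.children)}ch"
        return f"<TreeNode {self.label!r} {kind} +{len(self.mutations)}mut>"


class MutationTree:
    """A rooted tree with per-branch mutation sets and labelled tips."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    def find(self, label: str) -> TreeNode:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r} in tree")

    def tips_below(self, node: TreeNode) -> frozenset[str]:
        return frozenset(
            n.label for n in self._subtree(node) if n.is_tip
        )

    @staticmethod
    def _subtree(node: TreeNode) -> Iterator[TreeNode]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    def branch_mutation_counts(self) -> dict[str, int]:
        """Mutation count of the branch above each (labelled) node."""
        counts: dict[str, int] = {}
        for i, node in enumerate(self.preorder()):
            key = node.label if node.label is not None else f"_node{i}"
            counts[key] = len(node.mutations)
        return counts

    def total_mutations(self) -> int:
        return sum(len(n.mutations) for n in self.preorder())

    def duration(self, node: TreeNode) -> float:
        """Branch duration in years (parent age minus node age)."""
        if node.parent is None or node.parent.age is None or node.age is None:
            raise ValueError("branch duration requires ages on both ends")
        return node.parent.age - node.age

    # ------------------------------------------------------------------
    # canonical form
    # ------------------------------------------------------------------
    def canonicalize(self) -> "MutationTree":
        """Order children by (descendant tip count, smallest tip label).

        Makes the in-memory form independent of construction order, so the
        same matrix always yields byte-identical output.
        """

        def key(node: TreeNode) -> tuple[int, str]:
            tips = sorted(
                n.label or "" for n in self._subtree(node) if n.is_tip
            )
            return (len(tips), tips[0] if tips else "")

        for node in self.preorder():
            node.children.sort(key=key)
        return self

    def copy(self) -> "MutationTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, set(node.mutations), node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return MutationTree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<MutationTree {len(self.tips())} tips, "
            f"{self.total_mutations()} mutations>"
        )
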