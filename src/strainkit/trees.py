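"""Minimal phylogenetic tree container: Newick round-trip, bipartitions,
Robinson–Foulds distance.

Trees are stored rooted (a node has children and a branch length to its
parent) but compared as unrooted: bipartitions are computed over the leaf
set, and the trivial splits as well as the duplicate split created by a
degree-2 root are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterator, List, Optional, Set, Tuple


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class Tree:
    root: TreeNode

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.root.leaves()]

    def edges(self) -> Iterator[Tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs, preorder."""
        for node in self.root.walk():
            for child in node.children:
                yield node, child

    # -- Newick ---------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode, with_length: bool) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c, True) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if with_length:
                s += f":{node.length:g}"
            return s

        return fmt(self.root, False) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        pos = 0
        s = text[:-1]

        def parse_node() -> TreeNode:
            nonlocal pos
            node = TreeNode()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                node.children.append(parse_node())
                while pos < len(s) and s[pos] == ",":
                    pos += 1
                    node.children.append(parse_node())
                if pos >= len(s) or s[pos] != ")":
                    raise ValueError("unbalanced parentheses in Newick")
                pos += 1
            # label
            start = pos
            while pos < len(s) and s[pos] not in ":,()":
                pos += 1
            label = s[start:pos].strip()
            if label:
                node.name = label
            # branch length
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",()":
                    pos += 1
                node.length = float(s[start:pos])
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in Newick: {s[pos:]!r}")
        return cls(root)

    # -- unrooted comparison -------------------------------------------

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial splits of the leaf set, one canonical side each.

        The side not containing the lexicographically first leaf is used as
        the canonical representative, so rootings of the same unrooted tree
        yield identical sets.
        """
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) != len(self.leaf_names()):
            raise ValueError("duplicate leaf names")
        anchor = min(all_leaves)
        splits: Set[FrozenSet[str]] = set()

        def collect(node: TreeNode) -> FrozenSet[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(collect(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if anchor in below else below
                splits.add(side)
            return below

        collect(self.root)
        return splits


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Number of bipartitions present in exactly one of the two trees.

    Both trees must have identical leaf sets.
    """
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())
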