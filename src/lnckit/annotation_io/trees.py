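"""Rooted species trees with branch lengths, in pruning-ready form.

A tree is stored as a postorder node list; each non-root node carries the
length of the branch to its parent (substitutions/site).  Leaf names must
match the species names used in MAF files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

from Bio import Phylo


@dataclass
class TreeNode:
    index: int
    name: str | None
    branch_length: float  # to parent; 0.0 for the root
    children: list[int]

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted tree; ``nodes`` is in postorder (root last)."""

    def __init__(self, nodes: list[TreeNode]):
        self.nodes = nodes
        self.root = len(nodes) - 1
        self.leaf_names = [n.name for n in nodes if n.is_leaf]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf names in tree")
        for n in nodes:
            if n.branch_length < 0:
                raise ValueError(f"negative branch length on node {n.index}")
        self._leaf_index = {n.name: n.index for n in nodes if n.is_leaf}

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def leaf_index(self, name: str) -> int:
        return self._leaf_index[name]

    def scaled(self, factor: float) -> "SpeciesTree":
        """New tree with all branch lengths multiplied by ``factor``."""
        nodes = [
            TreeNode(n.index, n.name, n.branch_length * factor, list(n.children))
            for n in self.nodes
        ]
        return SpeciesTree(nodes)

    def total_branch_length(self) -> float:
        return sum(n.branch_length for n in self.nodes)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            n = self.nodes[i]
            if n.is_leaf:
                return f"{n.name}:{n.branch_length:g}"
            inner = ",".join(fmt(c) for c in n.children)
            if i == self.root:
                return f"({inner});"
            return f"({inner}):{n.branch_length:g}"

        return fmt(self.root)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = Phylo.read(io.StringIO(newick), "newick")
        nodes: list[TreeNode] = []

        def visit(clade) -> int:
            child_idx = [visit(c) for c in clade.clades]
            idx = len(nodes)
            bl = clade.branch_length if clade.branch_length is not None else 0.0
            nodes.append(TreeNode(idx, clade.name, float(bl), child_idx))
            return idx

        visit(tree.root)
        return cls(nodes)

    @classmethod
    def read(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")
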