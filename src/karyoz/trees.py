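"""Rooted-tree plumbing shared by the simulator and the parsimony stage.

Trees come in as newick (parsed with dendropy) and are converted to a tiny
immutable structure: every node has a stable label, every branch is named
after its child node. That keeps branch assignment of rearrangement events
serialisable without carrying dendropy objects around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class Node:
    label: str
    parent: "Node | None" = None
    children: list["Node"] = field(default_factory=list)
    edge_length: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RootedTree:
    """A rooted (multifurcations allowed, typically binary) labelled tree."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self.nodes: dict[str, Node] = {}
        for node in self.preorder():
            if node.label in self.nodes:
                raise ValueError(f"duplicate node label {node.label!r}")
            self.nodes[node.label] = node

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        counter = [0]

        def build(dnode, parent):
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            else:
                counter[0] += 1
                label = f"n{counter[0]}"
            node = Node(
                label=label,
                parent=parent,
                edge_length=dnode.edge.length if dnode.edge.length is not None else 1.0,
            )
            for child in dnode.child_nodes():
                node.children.append(build(child, node))
            return node

        return cls(build(dt.seed_node, None))

    # -- traversals ------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def branches(self) -> list[str]:
        """Branch ids: every non-root node names the branch above it."""
        return [n.label for n in self.preorder() if n.parent is not None]

    def path_to(self, leaf_label: str) -> list[str]:
        """Branch ids on the root-to-leaf path, in root-to-tip order."""
        node = self.nodes[leaf_label]
        path = []
        while node.parent is not None:
            path.append(node.label)
            node = node.parent
        return path[::-1]

    def clade_leaves(self, label: str) -> set[str]:
        node = self.nodes[label]
        stack, out = [node], set()
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.label)
            stack.extend(n.children)
        return out
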