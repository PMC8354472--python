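"""Rooted trees for species phylogenies and reconciled gene trees.

Two tree flavours share one light container:

* a species tree — binary, rooted, branch lengths in substitutions/site,
  leaves named after species; branch lengths double as the time proxy for
  all per-branch rate estimates downstream;
* a reconciled gene tree — every internal node is labelled either as a
  speciation event (mapped onto a species-tree node) or a duplication
  event; leaves carry the species they were sampled from.

Newick I/O goes through dendropy; the reconciliation labels travel as
NHX-style comments (``[&&NHX:D=Y]``, ``[&&NHX:D=N:S=3]``), the dialect
emitted by reconciliation programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

SPECIATION = "speciation"
DUPLICATION = "duplication"
LEAF = "leaf"


@dataclass
class Node:
    id: int
    parent: Optional[int]
    children: list[int] = field(default_factory=list)
    length: float = 0.0          # branch length to the parent (subs/site)
    name: Optional[str] = None   # leaf name (species, or gene id)
    event: Optional[str] = None  # speciation | duplication | leaf (gene trees)
    species: Optional[int] = None  # species-tree node id (S tag)


class Tree:
    """Rooted tree addressed by integer node ids (root id 0 by convention)."""

    def __init__(self) -> None:
        self.nodes: dict[int, Node] = {}
        self.root: int = 0

    # -- construction -------------------------------------------------

    def add_node(self, parent: Optional[int], length: float = 0.0,
                 name: Optional[str] = None, event: Optional[str] = None,
                 species: Optional[int] = None) -> int:
        nid = len(self.nodes)
        self.nodes[nid] = Node(nid, parent, [], length, name, event, species)
        if parent is not None:
            self.nodes[parent].children.append(nid)
        else:
            self.root = nid
        return nid

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[int]:
        stack, out = [self.root], []
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    def leaves(self) -> list[int]:
        return [n for n in self.postorder() if not self.nodes[n].children]

    def n_nodes(self) -> int:
        return len(self.nodes)

    def is_leaf(self, nid: int) -> bool:
        return not self.nodes[nid].children

    def parent(self, nid: int) -> Optional[int]:
        return self.nodes[nid].parent

    def ancestors(self, nid: int) -> list[int]:
        """Path of ancestor ids from ``nid``'s parent up to the root."""
        out = []
        p = self.nodes[nid].parent
        while p is not None:
            out.append(p)
            p = self.nodes[p].parent
        return out

    def mrca(self, node_ids: list[int]) -> int:
        if not node_ids:
            raise ValueError("mrca of an empty node set")
        paths = []
        for nid in node_ids:
            anc = [nid] + self.ancestors(nid)
            paths.append(anc[::-1])  # root ... node
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            col = {p[depth] for p in paths}
            if len(col) == 1:
                mrca = col.pop()
            else:
                break
        return mrca

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is ``b`` or an ancestor of ``b``."""
        return a == b or a in self.ancestors(b)

    def subtree_leaves(self, nid: int) -> list[int]:
        stack, out = [nid], []
        while stack:
            x = stack.pop()
            if self.is_leaf(x):
                out.append(x)
            stack.extend(self.nodes[x].children)
        return out

    def branches(self) -> list[tuple[int, int]]:
        """All (parent, child) pairs."""
        return [(self.nodes[n].parent, n) for n in self.nodes
                if self.nodes[n].parent is not None]

    def validate(self) -> None:
        seen = set()
        for nid in self.postorder():
            node = self.nodes[nid]
            if nid in seen:
                raise ValueError(f"node {nid} reached twice; not a tree")
            seen.add(nid)
            if node.parent is not None and node.length <= 0:
                raise ValueError(f"non-positive branch length at node {nid}")
        if len(seen) != len(self.nodes):
            raise ValueError("disconnected nodes present")

    # -- Newick I/O ---------------------------------------------------

    def to_newick(self, nhx: bool = False) -> str:
        def fmt(nid: int) -> str:
            node = self.nodes[nid]
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                s = f"({inner})"
                if node.name:
                    s += node.name
            else:
                s = node.name or f"n{nid}"
            if node.parent is not None:
                s += f":{node.length:.10g}"
            if nhx and node.event in (SPECIATION, DUPLICATION):
                d = "Y" if node.event == DUPLICATION else "N"
                tag = f"[&&NHX:D={d}"
                if node.species is not None:
                    tag += f":S={node.species}"
                tag += "]"
                s += tag
            elif nhx and node.event == LEAF and node.species is not None:
                s += f"[&&NHX:S={node.species}]"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  extract_comment_metadata=False)
        tree = cls()

        def walk(dnode, parent):
            name = dnode.taxon.label if dnode.taxon else dnode.label
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            event = None
            species = None
            for comment in dnode.comments or []:
                if not comment.startswith("&&NHX"):
                    continue
                for fieldtxt in comment.split(":")[1:]:
                    if "=" not in fieldtxt:
                        continue
                    key, val = fieldtxt.split("=", 1)
                    if key == "D":
                        event = DUPLICATION if val == "Y" else SPECIATION
                    elif key == "S":
                        species = int(val)
            if not dnode.child_nodes():
                event = LEAF if (event or species is not None) else event
            nid = tree.add_node(parent, float(length), name, event, species)
            for child in dnode.child_nodes():
                walk(child, nid)

        walk(dtree.seed_node, None)
        return tree

    def copy(self) -> "Tree":
        other = Tree()
        for nid in self.preorder():
            n = self.nodes[nid]
            other.nodes[nid] = Node(nid, n.parent, list(n.children),
                                    n.length, n.name, n.event, n.species)
        other.root = self.root
        return other


# ----------------------------------------------------------------------
# The nine-species Paramecium fixture

#: Subclade membership of the aurelia complex: subclade B holds
#: P. sonneborni and P. sexaurelia; subclade A the six remaining aurelias;
#: P. caudatum is the outgroup.
SUBCLADE_A = ("ptredecaurelia", "pbiaurelia", "ptetraurelia",
              "poctaurelia", "pprimaurelia", "ppentaurelia")
SUBCLADE_B = ("psonneborni", "psexaurelia")
OUTGROUP = "pcaudatum"

_SPECIES_NEWICK = (
    "(pcaudatum:0.90,((psonneborni:0.24,psexaurelia:0.22):0.14,"
    "(ptredecaurelia:0.20,(pbiaurelia:0.16,((ptetraurelia:0.08,"
    "poctaurelia:0.08):0.05,(pprimaurelia:0.07,ppentaurelia:0.07):0.05)"
    ":0.04):0.03):0.06):0.30);"
)


def paramecium_species_tree() -> Tree:
    """Nine-species fixture tree: eight *P. aurelia* species in two
    subclades plus the *P. caudatum* outgroup, branch lengths in
    substitutions/site on a scale where the A/B subclade split is deep."""
    tree = Tree.from_newick(_SPECIES_NEWICK)
    tree.validate()
    return tree


def species_name_map(tree: Tree) -> dict[str, int]:
    return {tree.nodes[l].name: l for l in tree.leaves()}
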