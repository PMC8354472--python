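"""Per-branch gain/loss rate estimators on the species tree.

Ancestral posteriors live on gene trees; a species-tree branch i -> j is
represented in a gene family by every path that connects a speciation node
mapped to i with a speciation node mapped to j, passing only through
duplication nodes (a duplication above j doubles the paths, S8-style).
Summed positive (negative) per-edge changes in the probability of presence
along those paths, normalised by path count, alignment length and branch
length, give the gain rate G_ij (per kb per unit time) and loss rate L_ij
(per IES per unit time):

    G_ij = sum_g p+_gij / (sum_g n_g k_gij * b_ij)
    L_ij = sum_g p-_gij / (sum_g I_g k_gij * b_ij)

where n_g is the well-aligned alignment length of family g in kb, I_g its
number of IES loci, k_gij its path count and b_ij the species branch
length (substitutions/site, the time proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import DUPLICATION, LEAF, SPECIATION, Tree


@dataclass
class PathSet:
    branch: tuple[int, int]          # (i, j) species-tree node ids
    paths: list[list[int]]           # ordered gene-tree node ids, i-end first

    @property
    def k(self) -> int:
        return len(self.paths)


class ReconciliationError(ValueError):
    pass


def _species_end_nodes(gene_tree: Tree, species_node: int,
                       species_tree: Tree) -> list[int]:
    """Gene-tree nodes that realise ``species_node``: speciation nodes with
    that S label, or leaves of that species when it is a species-tree leaf."""
    out = []
    for nid in gene_tree.nodes:
        node = gene_tree.nodes[nid]
        if node.event == SPECIATION and node.species == species_node:
            out.append(nid)
        elif (node.event == LEAF or gene_tree.is_leaf(nid)) \
                and node.species == species_node:
            out.append(nid)
    return out


def validate_reconciliation(gene_tree: Tree, species_tree: Tree) -> None:
    """Every speciation child must map within the species subtree of its
    parent's species label."""
    for nid in gene_tree.nodes:
        node = gene_tree.nodes[nid]
        if node.event != SPECIATION:
            continue
        for child in node.children:
            cs = gene_tree.nodes[child].species
            if cs is None:
                continue
            if not species_tree.is_ancestor(node.species, cs):
                raise ReconciliationError(
                    f"gene node {child} maps to species {cs}, not a "
                    f"descendant of parent's species {node.species}")


def enumerate_paths(gene_tree: Tree, species_tree: Tree,
                    branch: tuple[int, int]) -> PathSet:
    """All speciation(i) -> speciation(j) paths through duplication nodes.

    Paths whose upward walk from a j-node meets a speciation node mapped to
    a different species (the i-speciation was elided by gene loss) are not
    counted.
    """
    i, j = branch
    if species_tree.parent(j) != i:
        raise ValueError(f"({i}, {j}) is not a parent-child species branch")
    validate_reconciliation(gene_tree, species_tree)
    paths = []
    for end in _species_end_nodes(gene_tree, j, species_tree):
        walk = [end]
        cur = gene_tree.parent(end)
        while cur is not None:
            walk.append(cur)
            node = gene_tree.nodes[cur]
            if node.event == SPECIATION:
                if node.species == i:
                    paths.append(walk[::-1])
                break
            if node.event != DUPLICATION:
                break
            cur = gene_tree.parent(cur)
    return PathSet((i, j), paths)


def accumulate_deltas(posterior: dict[int, float | np.ndarray],
                      path: list[int]) -> tuple[float, float]:
    """Summed per-edge increases (p+) and decreases (p-) of the probability
    of presence along an ancestor-to-descendant path."""
    p_plus = p_minus = 0.0
    for parent, child in zip(path[:-1], path[1:]):
        if parent not in posterior or child not in posterior:
            raise KeyError(f"posterior missing on path edge {parent}->{child}")
        delta = np.asarray(posterior[child], dtype=float) \
            - np.asarray(posterior[parent], dtype=float)
        p_plus += float(np.sum(np.maximum(delta, 0.0)))
        p_minus += float(np.sum(np.maximum(-delta, 0.0)))
    return p_plus, p_minus


@dataclass
class FamilyData:
    """Per-family inputs to the branch-rate accumulators."""
    gene_tree: Tree
    posteriors: dict[int, np.ndarray]   # node -> per-locus P(present)
    n_kb: float                          # well-aligned alignment length, kb
    n_loci: int


@dataclass
class BranchRateTable:
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def branch_rate_table(families: list[FamilyData],
                      species_tree: Tree) -> BranchRateTable:
    records = []
    for i, j in species_tree.branches():
        sum_plus = sum_minus = 0.0
        sum_nk = sum_ik = 0.0
        b = species_tree.nodes[j].length
        for fam in families:
            ps = enumerate_paths(fam.gene_tree, species_tree, (i, j))
            for path in ps.paths:
                plus, minus = accumulate_deltas(fam.posteriors, path)
                sum_plus += plus
                sum_minus += minus
            sum_nk += fam.n_kb * ps.k
            sum_ik += fam.n_loci * ps.k
        G = sum_plus / (sum_nk * b) if sum_nk > 0 and b > 0 else np.nan
        L = sum_minus / (sum_ik * b) if sum_ik > 0 and b > 0 else np.nan
        records.append({"parent": i, "child": j, "p_plus": sum_plus,
                        "p_minus": sum_minus, "nk_paths": sum_nk,
                        "loci_paths": sum_ik, "b": b,
                        "gain_rate": G, "loss_rate": L})
    return BranchRateTable(pd.DataFrame.from_records(records))


def gain_rate(families: list[FamilyData], species_tree: Tree,
              branch: tuple[int, int]) -> float:
    table = branch_rate_table(families, species_tree).rows
    row = table[(table.parent == branch[0]) & (table.child == branch[1])]
    return float(row.gain_rate.iloc[0])


def loss_rate(families: list[FamilyData], species_tree: Tree,
              branch: tuple[int, int]) -> float:
    table = branch_rate_table(families, species_tree).rows
    row = table[(table.parent == branch[0]) & (table.child == branch[1])]
    return float(row.loss_rate.iloc[0])


# ----------------------------------------------------------------------
# Insertion dating

def _gene_node_species(gene_tree: Tree, nid: int) -> int | None:
    node = gene_tree.nodes[nid]
    if node.species is not None and node.event != DUPLICATION:
        return node.species
    return None


def date_insertion(gene_tree: Tree, locus_posterior: dict[int, float],
                   species_tree: Tree, threshold: float = 0.99,
                   aurelia_root: int | None = None) -> dict:
    """Age of a locus: the species-tree node to which the MRCA of all
    gene-tree nodes carrying the IES with P > ``threshold`` maps.

    Classes: "New" when confined to a single species (the MRCA maps to a
    species-tree leaf), "Node <n>" for an internal species node, and "Old"
    when the MRCA predates the aurelia/caudatum split (i.e. maps to the
    species root, ``aurelia_root``'s parent side).
    """
    carriers = [nid for nid, p in locus_posterior.items() if p > threshold]
    if not carriers:
        return {"age_node": None, "age_class": "undatable"}
    species = set()
    for nid in carriers:
        s = _gene_node_species(gene_tree, nid)
        if s is not None:
            species.add(s)
    if not species:
        return {"age_node": None, "age_class": "undatable"}
    mrca = species_tree.mrca(sorted(species))
    if species_tree.is_leaf(mrca):
        cls = "New"
    elif mrca == species_tree.root or (
            aurelia_root is not None
            and not species_tree.is_ancestor(aurelia_root, mrca)):
        cls = "Old"
    else:
        cls = f"Node {mrca}"
    return {"age_node": mrca, "age_class": cls}
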