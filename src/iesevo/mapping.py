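"""Gene families, conserved blocks, and co-orthologous IES loci.

An IES insertion site spans the two nucleotides of its TA; projected into
a gapped codon alignment the locus can widen (T--A).  Two IES loci in the
same gene family are co-orthologous when they share at least one
alignment column, floating alternatives included; groups touching
poorly aligned regions are discarded wholesale because presence/absence
cannot be assessed there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)


class UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self) -> list[set]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return list(out.values())


# ----------------------------------------------------------------------
# Families

def cluster_families(pairwise_hits, min_members: int = 3,
                     min_identity: float = 0.50,
                     identities: Optional[dict] = None) -> list[set]:
    """Single-linkage gene families from pairwise homology hits.

    ``pairwise_hits``: iterable of (gene_a, gene_b); the relation is
    symmetrized.  Families with fewer than ``min_members`` genes are
    dropped; when ``identities`` supplies mean pairwise protein identities
    per frozenset of members, families below ``min_identity`` are dropped
    too.
    """
    uf = UnionFind()
    for a, b in pairwise_hits:
        uf.union(a, b)
    families = [g for g in uf.groups() if len(g) >= min_members]
    if identities is not None:
        families = [g for g in families
                    if identities.get(frozenset(g), 1.0) >= min_identity]
    return sorted(families, key=lambda g: sorted(g)[0])


def mean_pairwise_identity(aligned: dict[str, str]) -> float:
    """Mean over pairs of matches / alignment length (gaps included)."""
    names = sorted(aligned)
    if len(names) < 2:
        return 1.0
    vals = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = aligned[a], aligned[b]
            matches = sum(1 for x, y in zip(sa, sb)
                          if x == y and x != "-")
            vals.append(matches / max(len(sa), 1))
    return float(np.mean(vals))


def backtranslate(protein_alignment: dict[str, str],
                  cds_sequences: dict[str, str]) -> dict[str, str]:
    """Codon alignment from a protein alignment and unaligned CDSs.

    Each residue column expands to its codon, each gap to ``---``.  A
    gene whose CDS length is not 3x its ungapped protein length (a
    trailing stop codon is tolerated) is a per-gene failure: it is
    dropped from the output and logged.
    """
    out: dict[str, str] = {}
    for name, prot in protein_alignment.items():
        cds = cds_sequences.get(name)
        if cds is None:
            continue
        ungapped = prot.replace("-", "")
        if len(cds) == 3 * len(ungapped) + 3 and cds[-3:] in ("TAA", "TAG", "TGA"):
            cds = cds[:-3]  # tolerate a trailing stop codon
        if len(cds) != 3 * len(ungapped):
            logger.warning("backtranslate: %s CDS length %d != 3 x %d "
                           "residues; gene excluded", name, len(cds),
                           len(ungapped))
            continue
        codons = iter(cds[i:i + 3] for i in range(0, len(cds), 3))
        out[name] = "".join("---" if aa == "-" else next(codons)
                            for aa in prot)
    return out


def conserved_blocks(protein_alignment: dict[str, str], min_block: int = 10,
                     max_gap_fraction: float = 0.2,
                     min_column_identity: float = 0.5) -> np.ndarray:
    """Boolean mask over protein columns: maximal runs of at least
    ``min_block`` columns that are gap-poor and composition-coherent
    (majority residue fraction >= ``min_column_identity``)."""
    seqs = list(protein_alignment.values())
    if not seqs:
        raise ValueError("empty alignment")
    n_col = len(seqs[0])
    n_seq = len(seqs)
    good = np.zeros(n_col, dtype=bool)
    for c in range(n_col):
        col = [s[c] for s in seqs]
        gaps = col.count("-")
        if gaps / n_seq > max_gap_fraction:
            continue
        residues = [x for x in col if x != "-"]
        top = max(residues.count(r) for r in set(residues))
        if top / len(residues) >= min_column_identity:
            good[c] = True
    mask = np.zeros(n_col, dtype=bool)
    run = 0
    for c in range(n_col + 1):
        if c < n_col and good[c]:
            run += 1
        else:
            if run >= min_block:
                mask[c - run:c] = True
            run = 0
    return mask


# ----------------------------------------------------------------------
# IES -> alignment projection

@dataclass
class MappedLocus:
    ies_id: str
    family: str
    gene: str
    species: Optional[str]
    intervals: list[tuple[int, int]]   # codon-alignment columns, half-open;
                                       # one interval per floating alternative


def cds_position_to_alignment_column(codon_row: str, cds_index: int) -> int:
    """Alignment column of the ``cds_index``-th (0-based) coding nucleotide
    in a gapped codon-alignment row."""
    count = -1
    for col, ch in enumerate(codon_row):
        if ch != "-":
            count += 1
            if count == cds_index:
                return col
    raise IndexError(f"CDS index {cds_index} beyond the aligned sequence")


def map_ies_to_alignment(ies, gene, codon_alignment: dict[str, str],
                         cds_offset_of_position) -> Optional[MappedLocus]:
    """Project an IES's retained TA (plus floating alternatives) into
    codon-alignment column intervals.

    ``cds_offset_of_position(mac_position) -> int | None`` maps a MAC
    coordinate to a 0-based CDS nucleotide index for this gene (None when
    the position is not coding — intronic or intergenic path).
    """
    row = codon_alignment[gene.id if hasattr(gene, "id") else gene]
    intervals = []
    for d in sorted(ies.floating_offsets):
        cds_i = cds_offset_of_position(ies.mac_position + d)
        if cds_i is None:
            return None
        c1 = cds_position_to_alignment_column(row, cds_i)
        c2 = cds_position_to_alignment_column(row, cds_i + 1)
        intervals.append((c1, c2 + 1))  # includes gap columns between T and A
    gene_id = gene.id if hasattr(gene, "id") else gene
    return MappedLocus(ies.id, getattr(ies, "family", ""), gene_id,
                       getattr(ies, "species", None), intervals)


def group_co_orthologs(mapped_loci: list[MappedLocus],
                       block_mask_nt: np.ndarray) -> list[list[MappedLocus]]:
    """Connected components of the shares-a-column relation.

    ``block_mask_nt`` is the conserved-block mask expanded to codon-
    alignment (nucleotide) columns.  Loci whose primary interval lies
    outside the mask are excluded beforehand; any group containing a
    floating member with *any* alternative interval outside the mask is
    discarded entirely (presence elsewhere cannot be assessed).
    """
    def inside(iv):
        return bool(np.all(block_mask_nt[iv[0]:iv[1]]))

    usable = [m for m in mapped_loci if inside(m.intervals[0])]
    uf = UnionFind()
    for m in usable:
        uf.find(m.ies_id)
    columns = {m.ies_id: set() for m in usable}
    by_id = {m.ies_id: m for m in usable}
    for m in usable:
        for iv in m.intervals:
            columns[m.ies_id].update(range(iv[0], iv[1]))
    ids = sorted(columns)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if by_id[a].family == by_id[b].family \
                    and columns[a] & columns[b]:
                uf.union(a, b)
    groups = []
    for members in uf.groups():
        locs = [by_id[m] for m in members]
        if any(not inside(iv) for loc in locs for iv in loc.intervals):
            continue  # discard rule: off-block floating alternative
        groups.append(sorted(locs, key=lambda m: m.ies_id))
    return sorted(groups, key=lambda g: g[0].ies_id)


# ----------------------------------------------------------------------
# Highly conserved IESs

def pairwise_global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (all gap
    columns included)."""
    from Bio import Align
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-0.5)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / len(sa)


def find_conserved_ies(groups, ies_sequences: dict[str, str],
                       species_of: dict[str, str],
                       subclade_map: dict[str, str],
                       min_species: int = 5,
                       min_cross_identity: float = 0.70) -> list[dict]:
    """Deeply conserved co-ortholog groups: at least ``min_species``
    distinct aurelia species and best cross-subclade pairwise identity at
    or above ``min_cross_identity``.  Reports best and mean cross-subclade
    identities; groups lacking members in one subclade are not eligible."""
    out = []
    for group in groups:
        ids = [m.ies_id if hasattr(m, "ies_id") else m for m in group]
        species = {species_of[i] for i in ids if species_of.get(i)}
        aurelia = {s for s in species if subclade_map.get(s) in ("A", "B")}
        if len(aurelia) < min_species:
            continue
        a_ids = [i for i in ids if subclade_map.get(species_of.get(i)) == "A"]
        b_ids = [i for i in ids if subclade_map.get(species_of.get(i)) == "B"]
        if not a_ids or not b_ids:
            continue
        idents = [pairwise_global_identity(ies_sequences[x],
                                           ies_sequences[y])
                  for x in a_ids for y in b_ids]
        best = max(idents)
        if best >= min_cross_identity:
            out.append({"members": ids, "n_species": len(aurelia),
                        "best_cross_identity": best,
                        "mean_cross_identity": float(np.mean(idents))})
    return out
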