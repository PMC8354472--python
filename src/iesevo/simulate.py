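"""Synthetic data with the statistical structure the analysis assumes.

The generators produce every input the pipeline consumes:

* reconciled gene trees — birth-death expansions of a fixed species tree,
  every internal node labelled speciation (with its species-tree node) or
  duplication;
* IES gain/loss histories on those gene trees — gains as a Poisson
  process per kb of well-aligned sequence, losses per existing locus,
  with full ground truth (event lists, true ancestral states, per-branch
  tallies);
* MIC/MAC genome pairs — AT-rich TA-bounded IESs with the ~10-bp periodic
  length distribution, engineered tandem-repeat boundaries for floating
  IESs, and interspersed mobile-element families with conserved terminal
  inverted repeats and nested insertions;
* read sets — MIC sequencing contaminated by MAC DNA at a controlled
  read-mass fraction, with the true per-IES retention counts.

Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .catalog import Gene, GeneAnnotation, IESRecord, insert_all
from .trees import DUPLICATION, LEAF, SPECIATION, Tree

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ----------------------------------------------------------------------
# Random sequence helpers

def random_sequence(rng: np.random.Generator, length: int,
                    at_content: float = 0.5) -> str:
    probs = np.array([at_content / 2, (1 - at_content) / 2,
                      (1 - at_content) / 2, at_content / 2])
    codes = rng.choice(4, size=length, p=probs)
    return BASES[codes].tobytes().decode()


def mutate_sequence(rng: np.random.Generator, seq: str, rate: float,
                    frozen_prefix: int = 0, frozen_suffix: int = 0) -> str:
    """Substitution-only divergence; ends can be held fixed (terminal
    inverted repeats of a mobile element, or the TA bound of an IES)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    lo, hi = frozen_prefix, n - frozen_suffix
    hit = np.where(rng.random(n) < rate)[0]
    hit = hit[(hit >= lo) & (hit < hi)]
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


# ----------------------------------------------------------------------
# Gene families (reconciled gene trees + codon alignments)

@dataclass
class GeneFamilySim:
    id: str
    tree: Tree                       # reconciled gene tree
    cds: dict[str, str]              # gene (leaf) name -> CDS
    protein_alignment: dict[str, str]
    codon_alignment: dict[str, str]
    block_mask: np.ndarray           # boolean, per protein column


_SAFE_CODONS = None


def _safe_codons() -> list[str]:
    """Sense codons only (stops excluded)."""
    global _SAFE_CODONS
    if _SAFE_CODONS is None:
        from Bio.Seq import Seq
        _SAFE_CODONS = [a + b + c
                        for a in "ACGT" for b in "ACGT" for c in "ACGT"
                        if str(Seq(a + b + c).translate()) != "*"]
    return _SAFE_CODONS


def _evolve_cds(rng: np.random.Generator, seq: str, branch_length: float) -> str:
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    p = 1.0 - np.exp(-branch_length)
    safe = _safe_codons()
    for ci, codon in enumerate(codons):
        new = list(codon)
        for j in range(3):
            if rng.random() < p:
                choices = [b for b in "ACGT" if b != new[j]]
                new[j] = choices[rng.integers(3)]
        cand = "".join(new)
        if cand not in safe:
            cand = codon  # reject substitutions creating a stop
        codons[ci] = cand
    return "".join(codons)


def simulate_gene_tree(species_tree: Tree, dup_rate: float,
                       loss_rate_genes: float,
                       rng: np.random.Generator) -> Tree:
    """One birth-death expansion of the species tree.

    Lineages duplicate at ``dup_rate`` and die at ``loss_rate_genes`` per
    unit species-tree branch length; speciation nodes with a single
    surviving side are spliced out (their branch lengths merge), as in
    reconciled trees inferred from extant genes.  Gene-tree nodes carry
    the species node (S) they map to; duplication nodes carry the species
    node at the lower end of the species branch they sit on.
    """
    gene = Tree()
    counter = [0]

    def grow(species_node: int, remaining: float, accrued: float):
        """Return a subtree spec (recursive dicts) or None if extinct."""
        total = dup_rate + loss_rate_genes
        tau = rng.exponential(1.0 / total) if total > 0 else np.inf
        if tau < remaining:
            if rng.random() < (dup_rate / total):
                left = grow(species_node, remaining - tau, 0.0)
                right = grow(species_node, remaining - tau, 0.0)
                kids = [k for k in (left, right) if k is not None]
                if len(kids) == 2:
                    return {"event": DUPLICATION, "species": species_node,
                            "length": accrued + tau, "children": kids}
                if len(kids) == 1:  # splice the dead side
                    kids[0]["length"] += accrued + tau
                    return kids[0]
                return None
            return None  # gene loss
        # reached the species node at the end of this branch
        snode = species_tree.nodes[species_node]
        if not snode.children:
            counter[0] += 1
            name = f"{snode.name}_g{counter[0]}"
            return {"event": LEAF, "species": species_node,
                    "length": accrued + remaining, "name": name}
        kids = []
        for child in snode.children:
            sub = grow(child, species_tree.nodes[child].length, 0.0)
            if sub is not None:
                kids.append(sub)
        if len(kids) == 2:
            return {"event": SPECIATION, "species": species_node,
                    "length": accrued + remaining, "children": kids}
        if len(kids) == 1:
            kids[0]["length"] += accrued + remaining
            return kids[0]
        return None

    sroot = species_tree.root
    spec = {"event": SPECIATION, "species": sroot, "length": 0.0,
            "children": []}
    kids = []
    for child in species_tree.nodes[sroot].children:
        sub = grow(child, species_tree.nodes[child].length, 0.0)
        if sub is not None:
            kids.append(sub)
    if len(kids) < 2:
        if not kids:
            raise RuntimeError("family extinct")
        spec = kids[0]  # root speciation elided
    else:
        spec["children"] = kids

    def build(node_spec, parent):
        nid = gene.add_node(parent, node_spec["length"],
                            node_spec.get("name"), node_spec["event"],
                            node_spec["species"])
        for child in node_spec.get("children", []):
            build(child, nid)

    build(spec, None)
    return gene


def simulate_gene_families(species_tree: Tree, n_families: int,
                           dup_rate: float, loss_rate_genes: float,
                           seed: int, n_codons: int = 150,
                           with_sequences: bool = True,
                           min_genes: int = 3,
                           max_attempts: int = 200) -> list[GeneFamilySim]:
    """Reconciled gene trees plus (optionally) codon alignments.

    Families with fewer than ``min_genes`` surviving genes are rejected
    and resimulated, mirroring the downstream family-size filter.
    """
    if dup_rate < 0 or loss_rate_genes < 0:
        raise ValueError("rates must be non-negative")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    families = []
    for fi in range(n_families):
        for _ in range(max_attempts):
            try:
                tree = simulate_gene_tree(species_tree, dup_rate,
                                          loss_rate_genes, rng)
            except RuntimeError:
                continue
            if len(tree.leaves()) >= min_genes:
                break
        else:
            raise RuntimeError(f"family {fi}: no viable tree after "
                               f"{max_attempts} attempts")
        fam = GeneFamilySim(id=f"fam{fi:04d}", tree=tree, cds={},
                            protein_alignment={}, codon_alignment={},
                            block_mask=np.ones(n_codons, dtype=bool))
        if with_sequences:
            safe = _safe_codons()
            root_seq = "".join(safe[i] for i in
                               rng.integers(len(safe), size=n_codons))
            seqs: dict[int, str] = {tree.root: root_seq}
            for nid in tree.preorder():
                if nid == tree.root:
                    continue
                parent_seq = seqs[tree.parent(nid)]
                seqs[nid] = _evolve_cds(rng, parent_seq,
                                        tree.nodes[nid].length)
            from Bio.Seq import Seq
            for leaf in tree.leaves():
                name = tree.nodes[leaf].name
                fam.cds[name] = seqs[leaf]
                fam.codon_alignment[name] = seqs[leaf]
                fam.protein_alignment[name] = str(Seq(seqs[leaf]).translate())
        families.append(fam)
    return families


# ----------------------------------------------------------------------
# IES gain/loss histories

@dataclass
class PresenceMatrix:
    """Per-locus tip states: 0 absent, 1 present, -1 uncertain."""
    tips: list[str]
    data: np.ndarray   # (n_loci, n_tips) int8
    locus_ids: list[str] = field(default_factory=list)

    def as_tip_states(self) -> dict[str, np.ndarray]:
        return {t: self.data[:, i] for i, t in enumerate(self.tips)}

    @property
    def n_loci(self) -> int:
        return self.data.shape[0]

    def to_tsv(self, path) -> None:
        import pandas as pd
        frame = pd.DataFrame(self.data, columns=self.tips,
                             index=self.locus_ids or None)
        frame = frame.replace(-1, "?")
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        import pandas as pd
        frame = pd.read_csv(path, sep="\t", index_col=0)
        data = frame.replace("?", -1).astype(np.int8).to_numpy()
        return cls(list(frame.columns), data, [str(i) for i in frame.index])


@dataclass
class SimulatedHistory:
    events: list[dict]                         # branch/locus/type/time
    node_states: dict[str, dict[int, int]]     # locus -> node -> 0/1
    branch_counts: dict[int, dict[str, int]]   # gene edge (child id) tallies
    species_branch_counts: dict[tuple[int, int], dict[str, int]]
    observable: dict[str, bool]

    def tally_check(self) -> bool:
        from collections import Counter
        tally: dict[int, Counter] = {}
        for ev in self.events:
            tally.setdefault(ev["branch"], Counter())[ev["type"]] += 1
        for child, counts in self.branch_counts.items():
            for etype in ("gain", "loss"):
                if counts.get(etype, 0) != tally.get(child, {}).get(etype, 0):
                    return False
        return True


def _gene_edge_species_branch(gene_tree: Tree, species_tree: Tree,
                              child: int) -> Optional[tuple[int, int]]:
    """Species branch a gene edge lies on (None when gene loss merged
    segments across more than one species branch)."""
    cs = gene_tree.nodes[child].species
    parent = gene_tree.parent(child)
    if parent is None or cs is None:
        return None
    ps = gene_tree.nodes[parent].species
    sp_parent = species_tree.parent(cs)
    if ps == cs:  # duplication-to-something on the same species branch
        sp = species_tree.parent(cs)
        return (sp, cs) if sp is not None else None
    if sp_parent == ps:
        return (ps, cs)
    return None


def simulate_ies_history(gene_tree: Tree, gain_rate_per_kb: float,
                         loss_rate_per_ies: float, n_kb: float, seed: int,
                         root_density_per_kb: float = 0.0,
                         uncertain_fraction: float = 0.0,
                         species_tree: Optional[Tree] = None
                         ) -> tuple[PresenceMatrix, SimulatedHistory]:
    """Poisson gain / exponential loss of IES loci along a gene tree.

    Gains arise at ``gain_rate_per_kb * n_kb`` per unit branch length and
    create new loci (a lost locus is never re-gained: fresh insertion
    sites are effectively unlimited); each existing locus is lost at
    ``loss_rate_per_ies``.  Loci present in no tip are recorded in the
    history but excluded from the presence matrix (they are unobservable).
    """
    if gain_rate_per_kb < 0 or loss_rate_per_ies < 0:
        raise ValueError("rates must be non-negative")
    if n_kb <= 0:
        raise ValueError("n_kb must be positive")
    rng = np.random.default_rng(seed)
    gain_intensity = gain_rate_per_kb * n_kb

    events: list[dict] = []
    node_states: dict[str, dict[int, int]] = {}
    branch_counts: dict[int, dict[str, int]] = {
        c: {"gain": 0, "loss": 0} for _, c in gene_tree.branches()}
    locus_counter = [0]

    def new_locus() -> str:
        locus_counter[0] += 1
        return f"L{locus_counter[0]:05d}"

    n_root = rng.poisson(root_density_per_kb * n_kb)
    root_loci = [new_locus() for _ in range(n_root)]
    for loc in root_loci:
        node_states[loc] = {gene_tree.root: 1}

    order = [n for n in gene_tree.preorder() if n != gene_tree.root]
    # states propagate down; carry the set of present loci per node
    present: dict[int, list[str]] = {gene_tree.root: list(root_loci)}
    for child in order:
        t = gene_tree.nodes[child].length
        parent = gene_tree.parent(child)
        surviving = []
        for loc in present[parent]:
            if loss_rate_per_ies > 0 and rng.exponential(1.0 / loss_rate_per_ies) < t:
                tau = float(rng.uniform(0, t))
                events.append({"branch": child, "locus": loc,
                               "type": "loss", "time": tau})
                branch_counts[child]["loss"] += 1
                node_states[loc][child] = 0
            else:
                node_states[loc][child] = 1
                surviving.append(loc)
        n_gain = rng.poisson(gain_intensity * t)
        for _ in range(n_gain):
            tau = float(rng.uniform(0, t))
            loc = new_locus()
            node_states[loc] = {child: 1}
            events.append({"branch": child, "locus": loc,
                           "type": "gain", "time": tau})
            branch_counts[child]["gain"] += 1
            # the fresh locus can still be lost on the remainder of the edge
            if loss_rate_per_ies > 0 and \
                    rng.exponential(1.0 / loss_rate_per_ies) < (t - tau):
                tl = float(rng.uniform(tau, t))
                events.append({"branch": child, "locus": loc,
                               "type": "loss", "time": tl})
                branch_counts[child]["loss"] += 1
                node_states[loc][child] = 0
            else:
                surviving.append(loc)
        present[child] = surviving

    # complete state maps: a locus is absent anywhere it has no entry
    all_nodes = list(gene_tree.nodes)
    for loc, states in node_states.items():
        for nid in all_nodes:
            states.setdefault(nid, 0)
    # loci gained below a node keep absent states above: fix by re-walking
    # (the defaultdict fill above already yields 0 there, which is correct:
    # before the gain the site carries no IES)

    leaves = gene_tree.leaves()
    tip_names = [gene_tree.nodes[l].name for l in leaves]
    loci = sorted(node_states)
    observable = {}
    rows, kept_ids = [], []
    for loc in loci:
        tips = np.array([node_states[loc][l] for l in leaves], dtype=np.int8)
        obs = bool(tips.any())
        observable[loc] = obs
        if obs:
            rows.append(tips)
            kept_ids.append(loc)
    data = (np.stack(rows) if rows
            else np.zeros((0, len(leaves)), dtype=np.int8))
    if uncertain_fraction > 0 and data.size:
        mask = rng.random(data.shape) < uncertain_fraction
        data = data.copy()
        data[mask] = -1

    species_branch_counts: dict[tuple[int, int], dict[str, int]] = {}
    if species_tree is not None:
        for child, counts in branch_counts.items():
            sb = _gene_edge_species_branch(gene_tree, species_tree, child)
            if sb is None:
                continue
            agg = species_branch_counts.setdefault(sb, {"gain": 0, "loss": 0})
            agg["gain"] += counts["gain"]
            agg["loss"] += counts["loss"]

    matrix = PresenceMatrix(tip_names, data, kept_ids)
    history = SimulatedHistory(events, node_states, branch_counts,
                               species_branch_counts, observable)
    return matrix, history


# ----------------------------------------------------------------------
# Genome pairs

@dataclass
class MobileFamilyConfig:
    name: str
    length: int = 233
    n_copies: int = 0            # whole-IES (extremity-matched) insertions
    n_nested: int = 0            # copies nested inside longer IESs
    identity: float = 0.72       # target within-family pairwise identity
    tir_length: int = 12         # conserved terminal inverted repeat


@dataclass
class GenomeConfig:
    n_scaffolds: int = 1
    scaffold_length: int = 50_000
    ies_per_kb: float = 0.5
    at_content: float = 0.72
    ies_at_content: float = 0.80
    length_peak_weights: tuple = (0.45, 0.22, 0.12, 0.08, 0.05, 0.04, 0.04)
    long_fraction: float = 0.03      # >100 bp component
    floating_fraction: float = 0.07
    min_spacing: int = 60
    edge_margin: int = 150
    gene_length: int = 1200
    intergenic_length: int = 300
    intron_length: int = 25
    mobile_families: tuple = ()
    species: str = "ptetraurelia"


@dataclass
class GenomePair:
    mic: dict[str, str]
    mac: dict[str, str]
    catalog: list[IESRecord]
    annotation: GeneAnnotation
    mic_positions: dict[str, int]    # IES id -> fragment start on the MIC

    def check_round_trip(self) -> bool:
        by_scaffold: dict[str, list[IESRecord]] = {}
        for rec in self.catalog:
            by_scaffold.setdefault(rec.scaffold, []).append(rec)
        for name, mac_seq in self.mac.items():
            rebuilt = insert_all(mac_seq, by_scaffold.get(name, []))
            if rebuilt != self.mic[name]:
                return False
        return True


def _draw_ies_length(rng: np.random.Generator, cfg: GenomeConfig) -> int:
    if rng.random() < cfg.long_fraction:
        return int(rng.integers(105, 351))
    w = np.asarray(cfg.length_peak_weights, dtype=float)
    k = int(rng.choice(len(w), p=w / w.sum())) + 1
    lo = 25 + 10 * (k - 1)
    return int(rng.integers(lo, lo + 10))


def _annotate_genes(cfg: GenomeConfig, scaffold: str,
                    length: int, start_index: int) -> list[Gene]:
    genes = []
    pos = cfg.intergenic_length
    gi = start_index
    half = (cfg.gene_length - cfg.intron_length) // 2
    while pos + cfg.gene_length + cfg.intergenic_length < length:
        features = [("CDS", pos, pos + half),
                    ("intron", pos + half, pos + half + cfg.intron_length),
                    ("CDS", pos + half + cfg.intron_length,
                     pos + cfg.gene_length)]
        genes.append(Gene(f"g{gi:05d}", scaffold, pos,
                          pos + cfg.gene_length, "+", features))
        pos += cfg.gene_length + cfg.intergenic_length
        gi += 1
    return genes


def make_family_consensus(rng: np.random.Generator,
                          cfg: MobileFamilyConfig,
                          at_content: float = 0.8) -> str:
    inner = random_sequence(rng, cfg.length - 2, at_content)
    return "TA" + inner


def family_copy(rng: np.random.Generator, consensus: str,
                cfg: MobileFamilyConfig) -> str:
    # pairwise identity between two copies each at distance d from the
    # consensus is roughly (1-d)^2 + d^2/3; solve for d
    target = cfg.identity
    d = 0.75 * (1.0 - np.sqrt(max(1.0 - 4.0 * (1.0 - target) / 3.0, 0.0)))
    return mutate_sequence(rng, consensus, d,
                           frozen_prefix=max(cfg.tir_length, 2),
                           frozen_suffix=cfg.tir_length)


def build_genome_pair(config: GenomeConfig, seed: int) -> GenomePair:
    """MAC backbone + IES insertions -> MIC; exact round-trip guaranteed."""
    rng = np.random.default_rng(seed)
    mic, mac = {}, {}
    catalog: list[IESRecord] = []
    genes: list[Gene] = []
    mic_positions: dict[str, int] = {}
    ies_counter = 0
    gene_counter = 0

    consensi = {f.name: make_family_consensus(rng, f, config.ies_at_content)
                for f in config.mobile_families}

    for si in range(config.n_scaffolds):
        scaffold = f"scaffold_{si + 1}"
        mac_seq = random_sequence(rng, config.scaffold_length,
                                  config.at_content)
        genes_here = _annotate_genes(config, scaffold,
                                     config.scaffold_length, gene_counter)
        gene_counter += len(genes_here)
        genes.extend(genes_here)

        n_ies = round(config.ies_per_kb * config.scaffold_length / 1000)
        n_mobile = sum(f.n_copies for f in config.mobile_families) \
            if si == 0 else 0
        n_nested = sum(f.n_nested for f in config.mobile_families) \
            if si == 0 else 0
        n_total = n_ies + n_mobile + n_nested

        ta_sites = _spaced_ta_sites(mac_seq, n_total, config, rng)
        if len(ta_sites) < n_total:
            raise ValueError(
                f"{scaffold}: requested {n_total} IESs but only "
                f"{len(ta_sites)} usable TA sites at spacing "
                f"{config.min_spacing}")

        plan = (["plain"] * n_ies
                + [("mobile", f.name) for f in config.mobile_families
                   for _ in range(f.n_copies if si == 0 else 0)]
                + [("nested", f.name) for f in config.mobile_families
                   for _ in range(f.n_nested if si == 0 else 0)])
        rng.shuffle(ta_sites)
        records_here: list[IESRecord] = []
        mac_list = list(mac_seq)
        for kind, p in zip(plan, ta_sites):
            ies_counter += 1
            rid = f"ies_{ies_counter:05d}"
            meta = {}
            if kind == "plain":
                if rng.random() < config.floating_fraction:
                    motif_len = int(rng.choice([2, 2, 2, 3, 4, 5]))
                    motif = "TA" + random_sequence(rng, motif_len - 2,
                                                   config.ies_at_content)
                    reps = max(1, round(28 / motif_len))
                    seq = motif * reps
                    # engineer the MAC junction: one extra motif then TA
                    engineered = motif + "TA"
                    mac_list[p:p + len(engineered)] = list(engineered)
                    meta["engineered_floating"] = True
                    meta["motif_len"] = motif_len
                else:
                    L = _draw_ies_length(rng, config)
                    seq = "TA" + random_sequence(rng, L - 2,
                                                 config.ies_at_content)
            else:
                role, fname = kind
                fam_cfg = next(f for f in config.mobile_families
                               if f.name == fname)
                copy = family_copy(rng, consensi[fname], fam_cfg)
                if role == "mobile":
                    seq = copy
                    meta = {"family": fname, "role": "mobile"}
                else:
                    pad_l = "TA" + random_sequence(rng, int(rng.integers(6, 20)),
                                                   config.ies_at_content)
                    pad_r = random_sequence(rng, int(rng.integers(6, 20)),
                                            config.ies_at_content)
                    seq = pad_l + copy + pad_r
                    meta = {"family": fname, "role": "nested_host",
                            "copy_offset": len(pad_l),
                            "copy_length": len(copy)}
            records_here.append(IESRecord(
                id=rid, scaffold=scaffold, mac_position=p,
                excised_sequence=seq, species=config.species, meta=meta))

        mac_seq = "".join(mac_list)
        # build the MIC by right-to-left insertion, recording MIC coords
        records_here.sort(key=lambda r: r.mac_position)
        mic_seq = mac_seq
        for rec in reversed(records_here):
            mic_seq = mic_seq[:rec.mac_position] + rec.excised_sequence \
                + mic_seq[rec.mac_position:]
        shift = 0
        for rec in records_here:
            mic_positions[rec.id] = rec.mac_position + shift
            shift += rec.length

        mac[scaffold] = mac_seq
        mic[scaffold] = mic_seq
        catalog.extend(records_here)

    pair = GenomePair(mic, mac, catalog, GeneAnnotation(genes),
                      mic_positions)
    assert pair.check_round_trip()
    return pair


def _spaced_ta_sites(mac_seq: str, n_wanted: int, config: GenomeConfig,
                     rng: np.random.Generator) -> list[int]:
    arr = np.frombuffer(mac_seq.encode(), dtype=np.uint8)
    ta = np.where((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))[0]
    ta = ta[(ta >= config.edge_margin)
            & (ta < len(mac_seq) - config.edge_margin)]
    ta = rng.permutation(ta)
    chosen: list[int] = []
    taken = np.zeros(0, dtype=int)
    for p in ta:
        if len(chosen) >= n_wanted:
            break
        if chosen and np.any(np.abs(np.asarray(chosen) - p)
                             < config.min_spacing):
            continue
        chosen.append(int(p))
    return chosen


# ----------------------------------------------------------------------
# Read simulation

@dataclass
class ReadSet:
    reads: np.ndarray            # (n_reads, read_len) uint8 ASCII codes
    origin: np.ndarray           # 0 = MIC, 1 = MAC
    scaffold: np.ndarray         # scaffold index
    start: np.ndarray            # 0-based start on the source scaffold
    scaffold_names: list[str]

    def sequences(self):
        for row in self.reads:
            yield row.tobytes().decode()

    def __len__(self) -> int:
        return self.reads.shape[0]

    def write_fastq(self, path) -> None:
        qual = "I" * self.reads.shape[1]
        with open(path, "w") as fh:
            for i, row in enumerate(self.reads):
                fh.write(f"@read_{i}\n{row.tobytes().decode()}\n+\n{qual}\n")


def simulate_reads(pair: GenomePair, depth: float, error_rate: float,
                   mac_contamination_fraction: float, read_len: int,
                   seed: int):
    """MIC reads at ``depth`` plus MAC reads making up a fraction
    ``mac_contamination_fraction`` of total read mass.

    Returns (ReadSet, irs_truth DataFrame) where the truth table counts,
    per IES, simulated MIC reads spanning the retained fragment
    (retention support) and MAC reads spanning the excised junction.
    """
    f = mac_contamination_fraction
    if not 0 <= f < 1:
        raise ValueError("mac_contamination_fraction must be in [0, 1)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    mic_len = sum(len(s) for s in pair.mic.values())
    if mic_len == 0:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)

    names = sorted(pair.mic)
    mic_seqs = [pair.mic[n] for n in names]
    mac_seqs = [pair.mac[n] for n in names]
    total_mass = depth * mic_len / (1.0 - f)
    n_mic = int(round((1.0 - f) * total_mass / read_len))
    n_mac = int(round(f * total_mass / read_len))

    def sample(seqs, n):
        lens = np.array([max(len(s) - read_len + 1, 0) for s in seqs])
        if lens.sum() == 0:
            raise ValueError("scaffolds shorter than the read length")
        sc = rng.choice(len(seqs), size=n, p=lens / lens.sum())
        st = (rng.random(n) * lens[sc]).astype(np.int64)
        return sc, st

    mic_sc, mic_st = sample(mic_seqs, n_mic)
    mac_sc, mac_st = sample(mac_seqs, n_mac)

    arrs = {0: [np.frombuffer(s.encode(), dtype=np.uint8) for s in mic_seqs],
            1: [np.frombuffer(s.encode(), dtype=np.uint8) for s in mac_seqs]}
    reads = np.empty((n_mic + n_mac, read_len), dtype=np.uint8)
    idx = np.arange(read_len)
    for row, (org, sc, st) in enumerate(
            [(0, s, t) for s, t in zip(mic_sc, mic_st)]
            + [(1, s, t) for s, t in zip(mac_sc, mac_st)]):
        reads[row] = arrs[org][sc][st:st + read_len]
    del idx

    if error_rate > 0:
        mask = rng.random(reads.shape) < error_rate
        subs = BASES[rng.integers(0, 4, size=int(mask.sum()))]
        flat = reads.reshape(-1)
        pos = np.flatnonzero(mask.reshape(-1))
        flat[pos] = subs

    origin = np.concatenate([np.zeros(n_mic, dtype=np.int8),
                             np.ones(n_mac, dtype=np.int8)])
    scaffold = np.concatenate([mic_sc, mac_sc]).astype(np.int32)
    start = np.concatenate([mic_st, mac_st])
    readset = ReadSet(reads, origin, scaffold, start, names)

    irs_truth = _true_irs_table(pair, names, mic_sc, mic_st, mac_sc, mac_st,
                                read_len)
    return readset, irs_truth


def _true_irs_table(pair: GenomePair, names, mic_sc, mic_st, mac_sc, mac_st,
                    read_len, margin: int = 4):
    import pandas as pd
    rows = []
    mic_by = {i: np.sort(mic_st[mic_sc == i]) for i in range(len(names))}
    mac_by = {i: np.sort(mac_st[mac_sc == i]) for i in range(len(names))}
    for rec in pair.catalog:
        si = names.index(rec.scaffold)
        mic_p = pair.mic_positions[rec.id]
        # retention support: MIC reads spanning [mic_p - margin, mic_p + margin)
        starts = mic_by[si]
        lo = np.searchsorted(starts, mic_p + margin - read_len, side="left")
        hi = np.searchsorted(starts, mic_p - margin, side="right")
        retained = max(int(hi - lo), 0)
        starts = mac_by[si]
        p = rec.mac_position
        lo = np.searchsorted(starts, p + margin - read_len, side="left")
        hi = np.searchsorted(starts, p - margin, side="right")
        excised = max(int(hi - lo), 0)
        irs = retained / (retained + excised) if retained + excised else np.nan
        rows.append({"ies_id": rec.id, "retained": retained,
                     "excised": excised, "irs": irs})
    return pd.DataFrame(rows)
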