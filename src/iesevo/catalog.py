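"""IES data model and per-record classifications.

An internal eliminated sequence (IES) is stored as the excised fragment,
which by convention starts with the ``TA`` dinucleotide; the germline
(MIC) sequence around an insertion site reads

    MIC = prefix + excised_sequence + "TA" + suffix
    MAC = prefix + "TA" + suffix

so that excision leaves exactly one TA at the somatic (MAC) junction.
``mac_position`` is the 0-based index of that retained TA on the MAC
scaffold.  All coordinates are 0-based half-open internally; GFF3 output
is 1-based inclusive per the standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

EXON, INTRON, INTERGENIC = "exon", "intron", "intergenic"


class ExcisionError(ValueError):
    """Boundary mismatch: the recorded IES is not TA-bounded in its context."""


@dataclass
class IESRecord:
    id: str
    scaffold: str
    mac_position: int                  # 0-based index of the retained TA
    excised_sequence: str              # starts with "TA"
    floating_offsets: list[int] = field(default_factory=lambda: [0])
    compartment: Optional[str] = None  # exon | intron | intergenic
    irs: Optional[float] = None
    weak: Optional[bool] = None
    uncertain: bool = False
    species: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.excised_sequence.startswith("TA"):
            raise ValueError(f"{self.id}: excised sequence must start with TA")
        if 0 not in self.floating_offsets:
            raise ValueError(f"{self.id}: offset 0 missing from alternatives")

    @property
    def length(self) -> int:
        return len(self.excised_sequence)


@dataclass
class Gene:
    id: str
    scaffold: str
    start: int            # 0-based half-open, on the MAC
    end: int
    strand: str = "+"
    # (type, start, end) with type in {"CDS", "intron"}; non-overlapping
    features: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class GeneAnnotation:
    genes: list[Gene] = field(default_factory=list)

    def by_scaffold(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.scaffold, []).append(g)
        return out


# ----------------------------------------------------------------------
# Excision geometry

def excise(mic_scaffold: str, ies: IESRecord, mic_position: int) -> str:
    """Remove one IES from a MIC scaffold; ``mic_position`` is the 0-based
    start of the excised fragment on the MIC."""
    L = ies.length
    frag = mic_scaffold[mic_position:mic_position + L]
    if frag != ies.excised_sequence:
        raise ExcisionError(f"{ies.id}: sequence mismatch at {mic_position}")
    if mic_scaffold[mic_position + L:mic_position + L + 2] != "TA":
        raise ExcisionError(f"{ies.id}: no TA junction after the fragment")
    return mic_scaffold[:mic_position] + mic_scaffold[mic_position + L:]


def insert(mac_scaffold: str, ies: IESRecord) -> str:
    """Reinsert one IES into a MAC scaffold at its retained-TA position."""
    p = ies.mac_position
    if mac_scaffold[p:p + 2] != "TA":
        raise ExcisionError(f"{ies.id}: MAC junction at {p} is not TA")
    return mac_scaffold[:p] + ies.excised_sequence + mac_scaffold[p:]


def excise_all(mic_scaffold: str, records: list[tuple[IESRecord, int]]) -> str:
    """Excise many IESs given (record, mic_position) pairs; positions are
    MIC coordinates of each fragment start, processed right to left."""
    out = mic_scaffold
    for rec, pos in sorted(records, key=lambda x: -x[1]):
        out = excise(out, rec, pos)
    return out


def insert_all(mac_scaffold: str, records: Iterable[IESRecord]) -> str:
    """Reinsert IESs into a MAC scaffold (right to left by mac_position)."""
    out = mac_scaffold
    for rec in sorted(records, key=lambda r: -r.mac_position):
        out = insert(out, rec)
    return out


# ----------------------------------------------------------------------
# Floating IESs

def detect_floating(mic_context: str, ies: IESRecord, mic_position: int,
                    window: int = 10) -> list[int]:
    """Signed offsets d in [-window, +window] at which excising the
    equally-long TA-bounded fragment yields the identical MAC sequence.

    ``mic_context`` must cover ``mic_position`` +/- (window + length + 2).
    Offset 0 is always included (it is the annotated location itself).
    """
    L = ies.length
    lo = mic_position - window
    hi = mic_position + window + L + 2
    if lo < 0 or hi > len(mic_context):
        raise ValueError(f"{ies.id}: context too short for window {window}")
    reference = excise(mic_context, ies, mic_position)
    offsets = []
    for d in range(-window, window + 1):
        p = mic_position + d
        frag = mic_context[p:p + L]
        if not frag.startswith("TA"):
            continue
        if mic_context[p + L:p + L + 2] != "TA":
            continue
        if mic_context[:p] + mic_context[p + L:] == reference:
            offsets.append(d)
    assert 0 in offsets
    return offsets


def canonical_offset(offsets: list[int]) -> int:
    """Deterministic representative: the leftmost valid offset."""
    return min(offsets)


# ----------------------------------------------------------------------
# Per-record classifications

def assign_compartment(ies: IESRecord, annotation: GeneAnnotation,
                       scaffold_length: Optional[int] = None) -> str:
    """Compartment of the retained-TA base: exon, intron or intergenic."""
    p = ies.mac_position
    if p < 0 or (scaffold_length is not None and p >= scaffold_length):
        raise ValueError(f"{ies.id}: position {p} beyond scaffold")
    for gene in annotation.by_scaffold().get(ies.scaffold, []):
        if not (gene.start <= p < gene.end):
            continue
        for ftype, start, end in gene.features:
            if start <= p < end:
                return EXON if ftype == "CDS" else INTRON
        return INTERGENIC  # inside gene span but outside features: UTR-less model
    return INTERGENIC


def classify_length(length: int) -> tuple[Optional[int], str]:
    """Peak index under the ~10-bp periodic length model and a coarse
    class: short (<35 bp), long (>100 bp), mid otherwise.

    Peak k covers [25 + 10(k-1), 34 + 10(k-1)] bp; lengths between peaks
    get no peak index.
    """
    if length < 2:
        raise ValueError("IES length below the TA bound")
    peak = None
    if length >= 25:
        k = (length - 25) // 10 + 1
        lo = 25 + 10 * (k - 1)
        if lo <= length <= lo + 9:
            peak = int(k)
    if length < 35:
        cls = "short"
    elif length > 100:
        cls = "long"
    else:
        cls = "mid"
    return peak, cls


def call_weak(irs: Optional[float]) -> Optional[bool]:
    """Weak IES: more than 10% retention in wild-type cells (strict >)."""
    if irs is None or (isinstance(irs, float) and np.isnan(irs)):
        return None
    if not 0.0 <= irs <= 1.0:
        raise ValueError(f"IRS {irs} outside [0, 1]")
    return irs > 0.10


# ----------------------------------------------------------------------
# Reliability filters

@dataclass
class CoverageProfile:
    gene_depth: dict[str, float]         # gene id -> mean mapped-read depth
    scaffold_length: dict[str, int]


def apply_reliability_filters(catalog: list[IESRecord],
                              annotation: GeneAnnotation,
                              coverage: CoverageProfile,
                              min_scaffold_kb: float = 10.0,
                              min_gene_reads: float = 15.0,
                              pct_low: float = 10.0,
                              pct_high: float = 90.0) -> dict:
    """Remove IESs on small scaffolds and flag those in unreliably covered
    genes as uncertain.

    Genes below the ``pct_low`` or above the ``pct_high`` coverage
    percentile (over all genes), or with depth below ``min_gene_reads``,
    are flagged; their IESs become uncertain, and flagged genes with no
    annotated IES are reported as potentially containing IESs.
    Idempotent: re-applying to its own output changes nothing.
    """
    depths = np.array([coverage.gene_depth[g.id] for g in annotation.genes])
    if len(depths):
        lo = np.percentile(depths, pct_low)
        hi = np.percentile(depths, pct_high)
    else:
        lo = hi = 0.0
    flagged_genes = {
        g.id for g in annotation.genes
        if coverage.gene_depth[g.id] < max(lo, min_gene_reads)
        or coverage.gene_depth[g.id] > hi
    }
    by_scaffold = annotation.by_scaffold()

    def containing_gene(rec: IESRecord) -> Optional[Gene]:
        for gene in by_scaffold.get(rec.scaffold, []):
            if gene.start <= rec.mac_position < gene.end:
                return gene
        return None

    kept: list[IESRecord] = []
    genes_with_ies = set()
    for rec in catalog:
        length = coverage.scaffold_length.get(rec.scaffold)
        if length is not None and length < min_scaffold_kb * 1000:
            continue
        gene = containing_gene(rec)
        if gene is not None:
            genes_with_ies.add(gene.id)
        uncertain = rec.uncertain or (gene is not None and gene.id in flagged_genes)
        kept.append(replace(rec, uncertain=uncertain))
    potentially_containing = sorted(
        gid for gid in flagged_genes if gid not in genes_with_ies)
    return {"catalog": kept,
            "flagged_genes": sorted(flagged_genes),
            "potentially_containing_ies": potentially_containing}


def call_mac_variable_regions(depth: np.ndarray, min_expected_depth: float,
                              window: int = 2000,
                              min_region: int = 4000) -> list[tuple[int, int]]:
    """MAC-variable candidate regions at scaffold extremities.

    From each extremity, advance inward in ``window``-sized steps until the
    first window whose mean depth reaches ``min_expected_depth``; keep the
    extremity region if it spans at least ``min_region`` bp.
    """
    depth = np.asarray(depth, dtype=float)
    n = len(depth)

    def scan(from_left: bool) -> int:
        extent = 0
        while extent < n:
            if from_left:
                chunk = depth[extent:extent + window]
            else:
                chunk = depth[max(0, n - extent - window):n - extent]
            if len(chunk) == 0 or chunk.mean() >= min_expected_depth:
                break
            extent += len(chunk)
        return extent

    regions = []
    left = scan(True)
    right = scan(False)
    if left >= n:  # whole scaffold low: one region, not two
        return [(0, n)] if n >= min_region else []
    if left >= min_region:
        regions.append((0, left))
    if right >= min_region and n - right >= left:
        regions.append((n - right, n))
    return regions


# ----------------------------------------------------------------------
# Tabular / GFF3 round trips

def catalog_to_frame(catalog: list[IESRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "scaffold": r.scaffold, "mac_position": r.mac_position,
        "length": r.length, "compartment": r.compartment, "irs": r.irs,
        "weak": r.weak, "uncertain": r.uncertain, "species": r.species,
        "floating_offsets": ",".join(map(str, r.floating_offsets)),
    } for r in catalog])


def write_gff3(catalog: list[IESRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in catalog:
            attrs = f"ID={r.id};floating_offsets=" \
                    f"{','.join(map(str, r.floating_offsets))}"
            fh.write("\t".join([
                r.scaffold, "iesevo", "internal_eliminated_sequence",
                str(r.mac_position + 1), str(r.mac_position + 2), ".", "+",
                ".", attrs]) + "\n")


def read_gff3(path, sequences: dict[str, str]) -> list[IESRecord]:
    """Read an IES GFF3 plus an id -> excised-sequence FASTA mapping."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[2] != "internal_eliminated_sequence":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            offsets = [int(x) for x in
                       attrs.get("floating_offsets", "0").split(",")]
            out.append(IESRecord(
                id=attrs["ID"], scaffold=cols[0],
                mac_position=int(cols[3]) - 1,
                excised_sequence=sequences[attrs["ID"]],
                floating_offsets=offsets))
    return out
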