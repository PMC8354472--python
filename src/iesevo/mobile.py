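"""Interspersed (mobile) IES families.

Homology between IES sequences is established with in-package local
alignment (edlib global distance as a cheap prefilter, then a gapped
Smith-Waterman via Bio.Align) whose expectation scores are calibrated
empirically on dinucleotide-shuffled decoys of matched composition — the
honest way to score alignments of sequences this AT-rich.  A pair of
homologous IESs whose alignment reaches both extremities of both copies
(the 20-nt boundary rule) is either in-situ homology (same locus: flanks
also align) or evidence of mobility (different loci).  Candidate-mobile
pairs are clustered single-linkage; families with enough members get a
per-column log-odds profile (against the empirical IES background) that
re-scans the full catalog, splitting hits into ``mobile`` (profile match
reaches the IES extremities within a small tolerance) and ``nested``
(element inserted inside a pre-existing IES).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mapping import UnionFind

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimilarityHit:
    query: str
    subject: str
    query_interval: tuple[int, int]     # 0-based half-open
    subject_interval: tuple[int, int]
    identity: float                      # percent, 0..100
    length: int                          # alignment length (columns)
    score: float
    evalue: float
    strand: str = "+"


@dataclass
class RepeatFamily:
    id: str
    members: list[str]
    seed_alignment: dict[str, str] = field(default_factory=dict)
    consensus: str = ""
    profile: Optional[np.ndarray] = None        # (L, 4) log-odds
    background: Optional[np.ndarray] = None
    composition_suspect: bool = False
    score_null: Optional[tuple] = None          # (K, lam) decoy tail fit
    per_species_counts: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# Alignment + empirical E-values

def _aligner(mode="local"):
    from Bio import Align
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -5
    al.extend_gap_score = -2
    return al


def _best_local(a: str, b: str):
    """Best gapped local alignment of b (+/-) against a.

    Returns (score, a_interval, b_interval, identity_fraction,
    aln_length, strand)."""
    al = _aligner()
    best = None
    for strand, bb in (("+", b), ("-", revcomp(b))):
        score = al.score(a, bb)
        if best is None or score > best[0]:
            best = (score, bb, strand)
    score, bb, strand = best
    if score <= 0:
        return 0.0, (0, 0), (0, 0), 0.0, 0, strand
    aln = al.align(a, bb)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # Bio.Align pads local alignments with the full sequences: trim to the
    # aligned region using the coordinate table
    a_lo, a_hi = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    b_lo, b_hi = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    matches = aln.counts().identities
    length = aln.length
    ident = matches / length if length else 0.0
    if strand == "-":
        b_lo, b_hi = len(b) - b_hi, len(b) - b_lo
    return float(score), (a_lo, a_hi), (b_lo, b_hi), ident, length, strand


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Euler-path style walk
    on the transition multigraph; falls back to a plain shuffle on
    degenerate inputs)."""
    if len(seq) < 4:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    # keep the last edge of each vertex pointing along a path to the end
    out = [seq[0]]
    stack = [seq[0]]
    walk = []
    local = {a: list(bs) for a, bs in edges.items()}
    while stack:
        v = stack[-1]
        if local.get(v):
            stack.append(local[v].pop())
        else:
            walk.append(stack.pop())
    walk.reverse()
    if len(walk) != len(seq):  # disconnected graph: plain shuffle
        arr = list(seq)
        rng.shuffle(arr)
        return "".join(arr)
    return "".join(walk)


def calibrate_score_null(sequences: list[str], rng: np.random.Generator,
                         n_pairs: int = 400) -> tuple[float, float]:
    """Fit P(S >= s) ~ K exp(-lam s) on local-alignment scores of
    dinucleotide-shuffled decoy pairs (matched length and composition)."""
    if len(sequences) < 2:
        return 1.0, 0.1
    scores = []
    for _ in range(n_pairs):
        i, j = rng.integers(len(sequences)), rng.integers(len(sequences))
        a = dinucleotide_shuffle(sequences[i], rng)
        b = dinucleotide_shuffle(sequences[j], rng)
        al = _aligner()
        s = max(al.score(a, b), al.score(a, revcomp(b)))
        scores.append(float(s))
    scores = np.sort(scores)
    # exponential tail fit on the top half of the decoy score distribution
    tail = scores[len(scores) // 2:]
    surv = 1.0 - (np.arange(len(scores)) / len(scores))
    surv_tail = surv[len(scores) // 2:]
    keep = surv_tail > 0
    x, y = tail[keep], np.log(surv_tail[keep])
    if len(x) < 3 or np.ptp(x) == 0:
        return 1.0, 0.05
    lam, logk = np.polyfit(x, y, 1)
    lam = -lam
    if lam <= 0:
        lam = 0.05
    return float(np.exp(logk)), float(lam)


def empirical_evalue(score: float, null: tuple[float, float],
                     n_comparisons: int) -> float:
    K, lam = null
    p = min(K * np.exp(-lam * score), 1.0)
    return float(p * n_comparisons)


def all_vs_all(ies_sequences: dict[str, str], max_evalue: float = 1e-8,
               prefilter_identity: float = 0.50, seed: int = 0,
               min_length: int = 20,
               max_targets: int = 80) -> list[SimilarityHit]:
    """All-against-all gapped local alignment of IES sequences, both
    strands, self-hits excluded, E-values calibrated on shuffled decoys.

    A cheap edit-distance prefilter (edlib, both strands) gates the
    quadratic pair space; ``max_targets`` caps retained hits per sequence
    (the clustering downstream is single-linkage, so the cap does not
    change family membership).
    """
    import edlib

    ids = [i for i, s in sorted(ies_sequences.items())
           if len(s) >= min_length]
    seqs = {i: ies_sequences[i] for i in ids}
    rng = np.random.default_rng(seed)
    sample = [seqs[i] for i in
              rng.choice(ids, size=min(len(ids), 60), replace=False)]
    null = calibrate_score_null(sample, rng)
    n_comp = len(ids) * (len(ids) - 1) // 2
    al = _aligner()
    n_hits: dict[str, int] = {i: 0 for i in ids}
    rcs = {i: revcomp(seqs[i]) for i in ids}

    hits = []
    for i, qa in enumerate(ids):
        a = seqs[qa]
        for qb in ids[i + 1:]:
            if n_hits[qa] >= max_targets and n_hits[qb] >= max_targets:
                continue
            b = seqs[qb]
            span = max(len(a), len(b))
            d1 = edlib.align(a, b, task="distance")["editDistance"]
            d2 = edlib.align(a, rcs[qb], task="distance")["editDistance"]
            if 1.0 - min(d1, d2) / span < prefilter_identity:
                continue
            strand = "+" if d1 <= d2 else "-"
            bb = b if strand == "+" else rcs[qb]
            score = float(al.score(a, bb))
            ev = empirical_evalue(score, null, n_comp)
            if ev > max_evalue or score <= 0:
                continue
            aln = al.align(a, bb)[0]
            a_lo, a_hi = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
            b_lo, b_hi = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
            if strand == "-":
                b_lo, b_hi = len(b) - b_hi, len(b) - b_lo
            length = aln.length
            ident = aln.counts().identities / length if length else 0.0
            hits.append(SimilarityHit(qa, qb, (a_lo, a_hi), (b_lo, b_hi),
                                      100.0 * ident, length, score, ev,
                                      strand))
            n_hits[qa] += 1
            n_hits[qb] += 1
    return hits


# ----------------------------------------------------------------------
# Classification rules

def boundary_rule(hit: SimilarityHit, query_len: int, subject_len: int,
                  margin: int = 20) -> bool:
    """True when the alignment encompasses the first and last ``margin``
    nt of both sequences — i.e. the aligned interval contains [0, margin)
    and [len - margin, len) on query and subject alike, so the homology
    includes the IES boundaries.  Sequences shorter than 2x margin
    degenerate to a full-length coverage requirement."""
    return (_covers(hit.query_interval, query_len, margin)
            and _covers(hit.subject_interval, subject_len, margin))


def _covers(iv: tuple[int, int], n: int, margin: int) -> bool:
    # containing both terminal windows forces a full-span alignment; the
    # short-sequence degenerate case coincides with the same condition
    return iv[0] <= 0 and iv[1] >= n


def locus_class(hit: SimilarityHit, flank_a: Optional[str],
                flank_b: Optional[str], min_identity: float = 0.75,
                min_length: int = 150) -> dict:
    """Homologous-locus vs candidate-mobile call for one passing pair.

    Flanks are the concatenated 100-nt MAC-side contexts (left + right) of
    each IES.  A strong flank-vs-flank alignment (identity >=
    ``min_identity`` over >= ``min_length`` columns) means the two IESs
    sit at homologous loci; otherwise the pair is candidate mobile.
    Missing flanks (scaffold edge) are classified on what is available and
    flagged partial.
    """
    partial = flank_a is None or flank_b is None
    if flank_a and flank_b:
        score, iva, ivb, ident, length, _ = _best_local(flank_a, flank_b)
        if ident >= min_identity and length >= min_length:
            return {"class": "homologous_locus", "partial": partial,
                    "flank_identity": ident, "flank_length": length}
    return {"class": "candidate_mobile", "partial": partial}


def cluster_candidates(pairs: list[tuple[str, str]],
                       min_profile_members: int = 10) -> list[dict]:
    """Single-linkage families of candidate-mobile pairs; families with at
    least ``min_profile_members`` interspersed copies are flagged for
    profile building."""
    uf = UnionFind()
    for a, b in pairs:
        uf.union(a, b)
    fams = []
    for i, members in enumerate(sorted(uf.groups(),
                                       key=lambda g: -len(g))):
        fams.append({"id": f"FAM_{i + 1}", "members": sorted(members),
                     "profiled": len(members) >= min_profile_members})
    return fams


# ----------------------------------------------------------------------
# Profiles

def _merge_center_star(center: str, others: dict[str, str]) -> dict[str, str]:
    """Progressive center-star multiple alignment (global alignments to
    the center merged by union of center-relative gap patterns)."""
    al = _aligner(mode="global")
    pairwise = {}
    for name, seq in others.items():
        aln = al.align(center, seq)[0]
        pairwise[name] = (str(aln[0]), str(aln[1]))
    # number of insertion columns after each center position
    L = len(center)
    ins = np.zeros(L + 1, dtype=int)
    for ca, _ in pairwise.values():
        pos = 0
        run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[L] = max(ins[L], run)

    def expand(ca: str, cb: str) -> str:
        out = []
        pos = 0
        run = []
        for x, y in zip(ca, cb):
            if x == "-":
                run.append(y)
            else:
                out.append("-" * (ins[pos] - len(run)) + "".join(run))
                run = []
                out.append(y)
                pos += 1
        out.append("-" * (ins[L] - len(run)) + "".join(run))
        return "".join(out)

    merged = {"__center__": expand(center, center)}
    for name, (ca, cb) in pairwise.items():
        merged[name] = expand(ca, cb)
    width = len(merged["__center__"])
    assert all(len(v) == width for v in merged.values())
    return merged


def build_profile(member_sequences: dict[str, str],
                  background: Optional[np.ndarray] = None,
                  family_id: str = "FAM",
                  at_suspect_threshold: float = 0.92,
                  min_mean_identity: float = 0.40,
                  edge_gap_fraction: float = 0.5,
                  pseudocount: float = 0.5) -> RepeatFamily:
    """Seed alignment, consensus and per-column log-odds profile.

    The profile scores each column's residue frequencies against the
    background composition of the IES catalog (AT-rich), so that matches
    are informative *relative to* that composition.  Families whose
    consensus exceeds ``at_suspect_threshold`` A+T are flagged
    composition-suspect rather than silently dropped.  Edge columns with
    more than ``edge_gap_fraction`` gaps are trimmed (automatic stand-in
    for manual full-length delineation).
    """
    if len(member_sequences) < 2:
        raise ValueError("need at least 2 members")
    names = sorted(member_sequences)
    # center = member with the smallest total edlib distance to the others
    import edlib
    sample = names[:min(len(names), 25)]
    dist = {n: 0 for n in sample}
    for i, a in enumerate(sample):
        for b in sample[i + 1:]:
            d = edlib.align(member_sequences[a], member_sequences[b],
                            task="distance")["editDistance"]
            dist[a] += d
            dist[b] += d
    center_name = min(sample, key=dist.get)
    center = member_sequences[center_name]
    merged = _merge_center_star(
        center, {n: s for n, s in member_sequences.items()
                 if n != center_name})
    merged[center_name] = merged.pop("__center__")

    mean_ident = _alignment_mean_identity(merged)
    if mean_ident < min_mean_identity:
        logger.warning("%s: mean pairwise identity %.2f below %.2f; "
                       "family should be re-clustered at higher stringency",
                       family_id, mean_ident, min_mean_identity)

    cols = np.array([list(s) for s in merged.values()])
    gap_frac = (cols == "-").mean(axis=0)
    # match columns: majority-occupied; this trims ragged family edges and
    # drops the sparse insertion columns center-star merging creates, so
    # the profile length tracks the element length
    cols = cols[:, gap_frac <= edge_gap_fraction]

    if background is None:
        background = np.array([0.4, 0.1, 0.1, 0.4])
    counts = np.zeros((cols.shape[1], 4))
    for bi, base in enumerate("ACGT"):
        counts[:, bi] = (cols == base).sum(axis=0)
    freqs = (counts + pseudocount) / \
        (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    profile = np.log(freqs / background)
    consensus = "".join("ACGT"[i] for i in counts.argmax(axis=1))
    at = (consensus.count("A") + consensus.count("T")) / max(len(consensus), 1)

    fam = RepeatFamily(
        id=family_id, members=names,
        seed_alignment={n: "".join(row) for n, row in
                        zip(merged.keys(), cols)},
        consensus=consensus, profile=profile,
        background=np.asarray(background),
        composition_suspect=bool(at > at_suspect_threshold))
    return fam


def _alignment_mean_identity(aligned: dict[str, str]) -> float:
    names = sorted(aligned)
    if len(names) < 2:
        return 1.0
    vals = []
    sample = names[:20]
    for i, a in enumerate(sample):
        for b in sample[i + 1:]:
            sa, sb = aligned[a], aligned[b]
            m = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
            vals.append(m / len(sa))
    return float(np.mean(vals))


# ----------------------------------------------------------------------
# Profile scanning

def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_one(profile: np.ndarray, seq: str) -> tuple[float, int]:
    """Best gapless log-odds window score and its start offset (both
    strands are the caller's concern)."""
    codes = _encode(seq)
    L = profile.shape[0]
    n = len(codes)
    ok = codes >= 0
    safe = np.where(ok, codes, 0)
    if n < L:
        # slide the sequence inside the profile; negative pos = overhang
        per_off = [
            float(profile[off:off + n][np.arange(n)[ok], safe[ok]].sum())
            for off in range(L - n + 1)]
        best_off = int(np.argmax(per_off))
        return per_off[best_off], -best_off
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(safe, L)              # (n-L+1, L)
    win_ok = sliding_window_view(ok, L)
    rows = np.arange(L)
    scores = np.where(win_ok, profile[rows, win], 0.0).sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), best


def calibrate_profile_null(profile: np.ndarray, sequences: list[str],
                           rng: np.random.Generator,
                           n_decoys: int = 150) -> tuple[float, float]:
    scores = []
    for _ in range(n_decoys):
        seq = sequences[rng.integers(len(sequences))]
        decoy = dinucleotide_shuffle(seq, rng)
        s1, _ = _scan_one(profile, decoy)
        s2, _ = _scan_one(profile, revcomp(decoy))
        scores.append(max(s1, s2))
    scores = np.sort(np.asarray(scores, dtype=float))
    tail = scores[len(scores) // 2:]
    surv = 1.0 - np.arange(len(scores)) / len(scores)
    x, y = tail, np.log(np.maximum(surv[len(scores) // 2:], 1e-9))
    if np.ptp(x) == 0:
        return 1.0, 0.05
    lam, logk = np.polyfit(x, y, 1)
    lam = max(-lam, 1e-3)
    return float(np.exp(logk)), float(lam)


def scan_profiles(families: list[RepeatFamily],
                  ies_sequences: dict[str, str],
                  max_evalue: float = 1e-3, extremity_tol: int = 3,
                  seed: int = 0) -> list[dict]:
    """Scan every IES with every family profile; classify hits.

    A hit is ``mobile`` when the profile match starts within
    ``extremity_tol`` bp of the IES start AND ends within the tolerance
    of the IES end; anything interior is ``nested``.
    """
    rng = np.random.default_rng(seed)
    seq_list = list(ies_sequences.values())
    out = []
    for fam in families:
        if fam.profile is None:
            continue
        null = calibrate_profile_null(fam.profile, seq_list, rng)
        L = fam.profile.shape[0]
        n_comp = len(ies_sequences)
        for iid, seq in sorted(ies_sequences.items()):
            s1, p1 = _scan_one(fam.profile, seq)
            s2, p2 = _scan_one(fam.profile, revcomp(seq))
            if s2 > s1:
                score, pos, strand = s2, p2, "-"
            else:
                score, pos, strand = s1, p1, "+"
            ev = empirical_evalue(score, null, n_comp)
            if ev > max_evalue:
                continue
            if pos < 0:   # profile overhangs a shorter IES
                start, end = 0, len(seq)
            else:
                start, end = pos, min(pos + L, len(seq))
            if strand == "-":
                start, end = len(seq) - end, len(seq) - start
            mobile = start <= extremity_tol and end >= len(seq) - extremity_tol
            out.append({"family": fam.id, "ies_id": iid, "score": score,
                        "evalue": ev, "start": start, "end": end,
                        "strand": strand,
                        "class": "mobile" if mobile else "nested"})
    return out


def summarize(families: list[RepeatFamily], hits: list[dict],
              species_of: dict[str, str],
              min_mobile_copies: int = 10):
    """Per-family x species mobile/nested counts, Table-2 style: keep
    families with at least ``min_mobile_copies`` mobile copies in at
    least one species; totals row appended."""
    import pandas as pd
    rows = []
    by_family: dict[str, list[dict]] = {}
    for h in hits:
        by_family.setdefault(h["family"], []).append(h)
    lengths = {f.id: len(f.consensus) for f in families}
    species = sorted(set(species_of.values()))
    for fid, fhits in sorted(by_family.items()):
        counts = {(s, c): 0 for s in species for c in ("mobile", "nested")}
        for h in fhits:
            sp = species_of.get(h["ies_id"], "?")
            counts[(sp, h["class"])] = counts.get((sp, h["class"]), 0) + 1
        if max(counts[(s, "mobile")] for s in species) < min_mobile_copies:
            continue
        row = {"family": fid, "length": lengths.get(fid)}
        for s in species:
            row[f"{s}_mobile"] = counts[(s, "mobile")]
            row[f"{s}_nested"] = counts[(s, "nested")]
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        total = {"family": "TOTAL", "length": None}
        for col in frame.columns[2:]:
            total[col] = int(frame[col].sum())
        frame = pd.concat([frame, pd.DataFrame([total])],
                          ignore_index=True)
    return frame
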