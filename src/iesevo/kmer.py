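"""Assembly-free genome-size estimation from k-mer histograms.

The estimator is the classic depth-peak method: count canonical k-mers
(k = 17 by default) in the reads, locate the sequencing-depth peak of the
multiplicity histogram, and divide the total k-mer mass above the
error-induced peak near the origin by that depth.  For germline (MIC)
read sets contaminated by somatic (MAC) DNA, MAC-destined k-mers pile up
in a second, higher-depth peak; the proportion of that second-peak mass
contributed by contaminating reads — measured independently from the
IES-retention-score distribution — is subtracted before dividing by the
MIC depth.  K-mers deeper than ``mac_attribution_max_depth`` (default
500) are treated as high-copy repeats of pure MIC origin and kept whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

_CODE = np.full(256, -1, dtype=np.int8)   # -1: non-ACGT (N etc.)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_CODE[0] = -2                             # NUL: read separator, not biology


class NoPeakError(ValueError):
    """The histogram has no genomic depth peak beyond the origin."""


@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int]          # multiplicity -> number of distinct k-mers
    canonical: bool = True
    n_skipped: int = 0              # k-mers dropped for non-ACGT symbols

    def __post_init__(self):
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 3")
        if self.k < 11:
            warnings.warn("k below 11 is unreliable for genome sizing")
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    def total_mass(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def mass(self, lo: int, hi: int) -> int:
        """Sigma m*count(m) over lo < m <= hi."""
        return sum(m * c for m, c in self.counts.items() if lo < m <= hi)

    def as_array(self) -> np.ndarray:
        top = max(self.counts)
        arr = np.zeros(top + 1, dtype=np.int64)
        for m, c in self.counts.items():
            arr[m] = c
        return arr

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int = 17) -> "KmerHistogram":
        counts = {}
        with open(path) as fh:
            for line in fh:
                m, c = line.split()
                counts[int(m)] = int(c)
        return cls(k, counts)


@dataclass
class SizeEstimate:
    depth: float
    error_cutoff: int
    raw_size_bp: float
    corrected_size_bp: Optional[float] = None
    mac_fraction: float = 0.0
    notes: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# Counting

def _encode_kmers(codes: np.ndarray, k: int):
    """(canonical k-mer codes, count of N-containing windows skipped).

    ``codes``: 0..3 for ACGT, -1 for non-ACGT symbols, -2 for read
    separators.  Windows crossing a separator are dropped silently;
    windows containing a -1 are dropped and tallied.
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), 0
    valid = codes >= 0
    has_n = codes == -1
    c = np.where(valid, codes, 0).astype(np.int64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    skip_n = np.zeros(m, dtype=bool)
    for j in range(k):
        fwd = fwd * 4 + c[j:j + m]
        rev = rev + ((3 - c[j:j + m]) << (2 * j))
        ok &= valid[j:j + m]
        skip_n |= has_n[j:j + m]
    canon = np.minimum(fwd, rev)
    return canon[ok], int(skip_n.sum())


def count_kmers(reads, k: int = 17) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over a read set.

    ``reads`` is an iterable of sequence strings (or a ``ReadSet``,
    counted array-wise).  A k-mer and its reverse complement are the same
    species (lexicographic minimum kept).  K-mers containing non-ACGT
    symbols are skipped and tallied in ``n_skipped``.
    """
    chunks: list[np.ndarray] = []
    skipped = 0
    if hasattr(reads, "reads"):  # ReadSet fast path: one 2D uint8 array
        mat = reads.reads
        rows_per_chunk = max(1, 4_000_000 // max(mat.shape[1], 1))
        for lo in range(0, mat.shape[0], rows_per_chunk):
            block = _CODE[mat[lo:lo + rows_per_chunk]]
            sep = np.full((block.shape[0], 1), -2, dtype=np.int8)
            km, sk = _encode_kmers(np.hstack([block, sep]).reshape(-1), k)
            chunks.append(km)
            skipped += sk
    else:
        buf: list[str] = []
        buflen = 0
        for seq in reads:
            buf.append(seq)
            buf.append("\x00")
            buflen += len(seq) + 1
            if buflen > 8_000_000:
                km, sk = _flush(buf, k)
                chunks.append(km)
                skipped += sk
                buf, buflen = [], 0
        if buf:
            km, sk = _flush(buf, k)
            chunks.append(km)
            skipped += sk
    kmers = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    if kmers.size == 0:
        return KmerHistogram(k, {}, True, skipped)
    _, counts = np.unique(kmers, return_counts=True)
    mult, nkinds = np.unique(counts, return_counts=True)
    hist = {int(m): int(c) for m, c in zip(mult, nkinds)}
    return KmerHistogram(k, hist, True, skipped)


def _flush(buf: list[str], k: int):
    text = "".join(buf)
    codes = _CODE[np.frombuffer(text.encode(), dtype=np.uint8)]
    return _encode_kmers(codes, k)


# ----------------------------------------------------------------------
# Peaks and size

def find_depth_peak(hist: KmerHistogram) -> tuple[int, int]:
    """(depth, error_cutoff): the error cutoff is the first local minimum
    after multiplicity 1; the depth is the multiplicity with the largest
    count beyond the cutoff."""
    if not hist.counts:
        raise NoPeakError("empty histogram")
    arr = hist.as_array().astype(float)
    if arr[1] == 0:
        cutoff = 0  # no error peak at the origin at all
    else:
        for m in range(2, len(arr)):
            if arr[m] > arr[m - 1]:
                cutoff = m - 1
                break
        else:
            raise NoPeakError("histogram decreases monotonically: no "
                              "genomic peak beyond the origin")
    search = arr.copy()
    search[:cutoff + 1] = 0
    if search.max() == 0:
        raise NoPeakError("no peak beyond the error cutoff")
    depth = int(np.argmax(search))
    return depth, cutoff


def find_depth_peaks(hist: KmerHistogram, smooth: int = 5,
                     min_prominence_frac: float = 0.05) -> list[int]:
    """All depth peaks beyond the error cutoff, ascending (first = the
    lowest-depth genomic peak, typically the MIC-specific depth)."""
    _, cutoff = find_depth_peak(hist)
    arr = hist.as_array().astype(float)
    arr[:cutoff + 1] = 0.0
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        arr = np.convolve(arr, kernel, mode="same")
    peaks, _ = find_peaks(arr, prominence=arr.max() * min_prominence_frac)
    return [int(p) for p in peaks]


def refined_depth(hist: KmerHistogram, peak: int, cutoff: int = 0,
                  upper: Optional[int] = None) -> float:
    """Sub-bin depth: count-weighted mean multiplicity over the
    single-copy band (above the error cutoff, up to 1.5x the peak by
    default, so a 2x repeat peak stays out).  The true k-mer depth is
    rarely an integer — read-edge effects scale it by (L - k + 1)/L and
    the per-k-mer counts are overdispersed — so the integer argmax alone
    is off by up to half a bin, a several-percent size error."""
    if upper is None:
        upper = round(1.5 * peak)
    num = den = 0.0
    for m, c in hist.counts.items():
        if cutoff < m <= upper:
            num += m * c
            den += c
    return num / den if den else float(peak)


def estimate_genome_size(hist: KmerHistogram) -> SizeEstimate:
    """Raw size: total k-mer mass above the error cutoff divided by the
    (centroid-refined) depth of the largest peak."""
    depth, cutoff = find_depth_peak(hist)
    mass = hist.mass(cutoff, max(hist.counts))
    d = refined_depth(hist, depth, cutoff)
    return SizeEstimate(depth=depth, error_cutoff=cutoff,
                        raw_size_bp=mass / d,
                        notes={"refined_depth": d})


# ----------------------------------------------------------------------
# IRS and the MAC-contamination correction

def compute_irs(retained_reads, excised_reads):
    """IES retention score: retained / (retained + excised), elementwise.

    Both-zero entries are undefined and returned as NaN (flagged missing).
    """
    r = np.asarray(retained_reads, dtype=float)
    e = np.asarray(excised_reads, dtype=float)
    if np.any(r < 0) or np.any(e < 0):
        raise ValueError("read counts must be non-negative")
    total = r + e
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, r / np.where(total > 0, total, 1), np.nan)
    return out if out.ndim else float(out)


def estimate_mac_fraction(irs_values, bin_width: float = 0.05) -> float:
    """MAC DNA fraction of the sample: 1 - mode of the IRS distribution.

    The mode is located on a histogram with bins centred on multiples of
    ``bin_width`` (pure MIC peaks at IRS 1, pure MAC at 0).  When two
    near-equal modes compete, the larger-IRS one is taken with a warning.
    The distribution mean is reported separately by callers that want it.
    """
    irs = np.asarray(irs_values, dtype=float)
    irs = irs[~np.isnan(irs)]
    if irs.size < 100:
        raise ValueError("need at least 100 IRS values")
    if irs.min() < 0 or irs.max() > 1:
        raise ValueError("IRS values must lie in [0, 1]")
    edges = np.arange(-bin_width / 2, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(irs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    near = np.flatnonzero(counts >= 0.9 * counts.max())
    if near.max() - near.min() > 1:  # competing non-adjacent modes
        warnings.warn("near-bimodal IRS distribution; taking the "
                      "larger-IRS mode")
        mode_bin = int(near.max())
    else:
        mode_bin = int(np.argmax(counts))
    mode = float(np.clip(centers[mode_bin], 0.0, 1.0))
    return 1.0 - mode


def correct_for_mac_contamination(hist: KmerHistogram, mac_fraction: float,
                                  mic_depth: Optional[int] = None,
                                  mac_attribution_max_depth: int = 500
                                  ) -> SizeEstimate:
    """Subtract contaminating-MAC k-mer mass and re-estimate genome size.

    The first depth peak is the MIC-specific sequencing depth d; MAC-
    destined k-mers form a second peak at depth D2 = d + (contaminating
    MAC depth).  A fraction ``mac_fraction`` of the k-mer mass in the
    second-peak band (delimited below by the inter-peak minimum, above by
    ``mac_attribution_max_depth``) was contributed by contaminating MAC
    reads and is removed; deeper k-mers are high-copy repeats of MIC
    origin and are kept whole.  The corrected size is the remaining mass
    divided by the MIC depth.  Note 1 - mac_fraction = d / D2 under the
    model, which is reported as a consistency diagnostic.
    """
    if not 0 <= mac_fraction < 1:
        raise ValueError("mac_fraction must be in [0, 1)")
    _, cutoff = find_depth_peak(hist)
    peaks = find_depth_peaks(hist)
    if not peaks:
        raise NoPeakError("MIC depth not resolvable: no peak beyond the "
                          "error cutoff")
    if mic_depth is None:
        mic_depth = peaks[0]
    top = max(hist.counts)
    total = hist.mass(cutoff, top)
    raw = estimate_genome_size(hist)

    if mac_fraction == 0.0:
        return SizeEstimate(raw.depth, cutoff, raw.raw_size_bp,
                            raw.raw_size_bp, 0.0, {"mic_depth": mic_depth})

    second = [p for p in peaks if p > mic_depth * 1.25]
    notes = {"mic_depth": mic_depth,
             "phi_definition": "mac_fraction x second-peak band mass"}
    if second:
        d2 = second[0]
        arr = hist.as_array()
        lo = mic_depth + int(np.argmin(arr[mic_depth:d2 + 1])) \
            if d2 > mic_depth else mic_depth
        notes["second_peak_depth"] = d2
        notes["irs_consistency_depth_ratio"] = (d2 - mic_depth) / d2
    else:
        # no resolvable second peak: attribute within the whole band
        lo = cutoff
        notes["second_peak_depth"] = None
    band = hist.mass(lo, mac_attribution_max_depth)
    removed = min(mac_fraction * band if second else mac_fraction * total,
                  band)
    upper = min(round(1.5 * mic_depth), lo)
    d = refined_depth(hist, mic_depth, cutoff, upper)
    notes["refined_mic_depth"] = d
    corrected = (total - removed) / d
    return SizeEstimate(mic_depth, cutoff, raw.raw_size_bp, corrected,
                        mac_fraction, notes)
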