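"""Independent brute-force reference implementations used to verify the
package's vectorized operations.  Everything here is deliberately naive
(O(n*m) double loops, exhaustive enumeration) and shares no code with the
implementation under test."""

from __future__ import annotations

import math

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def five_prime(iv) -> int:
    return iv.start if iv.strand != "-" else iv.end - 1


def brute_count_reads(reads, peaks) -> np.ndarray:
    """Exhaustive containment count of read 5' positions in peaks."""
    counts = np.zeros(len(peaks))
    for i, peak in enumerate(peaks):
        for read in reads:
            if read.chrom == peak.chrom and peak.start <= five_prime(read) < peak.end:
                counts[i] += 1
    return counts


def brute_background_regions(peaks, width: int):
    """All flank candidates that touch no peak, as (chrom, start, end) tuples."""
    out = []
    for peak in peaks:
        for lo, hi in ((peak.start - width, peak.start), (peak.end, peak.end + width)):
            if lo < 0:
                continue
            clash = any(
                p.chrom == peak.chrom and lo < p.end and p.start < hi for p in peaks
            )
            if not clash:
                out.append((peak.chrom, lo, hi))
    return sorted(out)


def brute_tss_proximal(peaks, tss, window: int):
    """All-pairs gap computation; returns {peak_name: (gap, tss_name)} kept."""
    kept = {}
    for peak in peaks:
        best = None
        for t in tss:
            if t.chrom != peak.chrom:
                continue
            p = t.start
            if p < peak.start:
                gap = peak.start - p
            elif p >= peak.end:
                gap = p - (peak.end - 1)
            else:
                gap = 0
            if best is None or gap < best[0] or (gap == best[0] and p < best[2]):
                best = (gap, t.name, p)
        if best is not None and best[0] <= window:
            kept[peak.name] = (best[0], best[1])
    return kept


def brute_best_site(probs: np.ndarray, background: np.ndarray, seq: str):
    """Enumerate every offset and both strands; skip windows containing N."""
    L = len(probs)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    best = (float("-inf"), -1, "+")
    for strand in ("+", "-"):
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            if strand == "-":
                window = "".join(COMPLEMENT[b] for b in reversed(window))
            if "N" in window:
                continue
            score = sum(
                math.log2(probs[i][idx[b]] / background[idx[b]])
                for i, b in enumerate(window)
            )
            better = score > best[0] + 1e-12
            if better:
                best = (score, off, strand)
    return best


def two_pass_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def brute_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Naive UPGMA; returns the cophenetic distance matrix.

    Inter-cluster distance is the unweighted mean of all cross-pair leaf
    distances; ties merge the lowest-index pair first.
    """
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, i, j)
        dist, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dist
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


def brute_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n), by direct summation."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total
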