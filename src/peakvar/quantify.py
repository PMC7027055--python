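"""From read positions to a normalized peak x sample intensity matrix.

Reads are counted by their 5' tag position (single-end model): a read is
assigned to every peak whose interval contains that position.  Peak counts
are background-corrected by subtracting a width-scaled count of reads in
peak-free flanking windows, then normalized between samples so that every
sample's total over peaks equals the cross-sample mean total.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CountMatrix, PeakSet

logger = logging.getLogger(__name__)


def _count_positions(
    positions: dict[str, np.ndarray], starts_ends: PeakSet
) -> np.ndarray:
    """Count sorted tag positions falling inside each interval of a PeakSet."""
    counts = np.zeros(len(starts_ends), dtype=float)
    for chrom, (starts, ends, idx) in starts_ends.by_chrom().items():
        pos = positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        counts[idx] = hi - lo
    return counts


def count_reads_in_peaks(
    reads: PeakSet, peaks: PeakSet, sample_id: str = "sample"
) -> CountMatrix:
    """Count reads per peak (one raw-stage column).

    Each read contributes to every peak containing its 5' position; reads
    outside all peaks are ignored.  Overlapping peaks may both count the same
    read.
    """
    counts = _count_positions(reads.five_prime_by_chrom(), peaks)
    df = pd.DataFrame({sample_id: counts}, index=pd.Index(peaks.names, name="peak_id"))
    return CountMatrix(df, stage="raw")


def count_reads_matrix(
    reads_by_sample: Mapping[str, PeakSet], peaks: PeakSet
) -> CountMatrix:
    """Stack :func:`count_reads_in_peaks` columns for several samples."""
    cols = {
        sample: count_reads_in_peaks(r, peaks, sample).df[sample]
        for sample, r in reads_by_sample.items()
    }
    return CountMatrix(pd.DataFrame(cols), stage="raw")


def _usable_flanks(
    peak_start: int, peak_end: int, half: int, merged: tuple[np.ndarray, np.ndarray]
) -> list[tuple[int, int]]:
    """Flank windows of ``half`` bp each side minus peak-covered bases."""
    ms, me = merged
    pieces: list[tuple[int, int]] = []
    for lo, hi in ((max(peak_start - half, 0), peak_start), (peak_end, peak_end + half)):
        if hi <= lo:
            continue
        cur = lo
        # merged blocks intersecting [lo, hi)
        j = np.searchsorted(me, lo, side="right")
        while j < len(ms) and ms[j] < hi:
            if ms[j] > cur:
                pieces.append((cur, int(ms[j])))
            cur = max(cur, int(me[j]))
            j += 1
        if cur < hi:
            pieces.append((cur, hi))
    return pieces


def background_correct(
    raw: CountMatrix,
    peaks: PeakSet,
    reads: Mapping[str, PeakSet] | PeakSet,
    flank_bp: int = 1000,
) -> CountMatrix:
    """Subtract a local-background estimate from each peak count.

    For each peak, reads are counted in flanks of ``flank_bp / 2`` bp on each
    side, clipped at position 0 and excluding bases covered by any peak.  The
    flank count is scaled by ``peak_width / usable_flank_width`` and
    subtracted from the peak count; negatives are clipped to 0.  A peak whose
    flanks are entirely covered by other peaks keeps its raw count (logged).
    """
    if raw.stage != "raw":
        raise ValueError(f"background_correct expects a raw matrix, got {raw.stage!r}")
    if isinstance(reads, PeakSet):
        if len(raw.sample_ids) != 1:
            raise ValueError("a single read set requires a single-sample matrix")
        reads = {raw.sample_ids[0]: reads}
    missing = set(raw.sample_ids) - set(reads)
    if missing:
        raise ValueError(f"no reads supplied for samples {sorted(missing)}")
    if list(raw.peak_ids) != list(peaks.names):
        raise ValueError("matrix peak ids do not match the peak set")

    half = flank_bp // 2
    merged = peaks.merged_by_chrom()
    flank_pieces = [
        _usable_flanks(iv.start, iv.end, half, merged[iv.chrom]) for iv in peaks
    ]
    usable = np.array([sum(e - s for s, e in p) for p in flank_pieces], dtype=float)
    n_degenerate = int((usable == 0).sum())
    if n_degenerate:
        logger.warning(
            "%d peaks have no usable flank sequence; background set to 0 for them",
            n_degenerate,
        )

    widths = np.array([iv.width for iv in peaks], dtype=float)
    corrected = {}
    for sample in raw.sample_ids:
        pos = reads[sample].five_prime_by_chrom()
        flank_counts = np.zeros(len(peaks))
        for i, (iv, pieces) in enumerate(zip(peaks, flank_pieces)):
            p = pos.get(iv.chrom)
            if p is None or not pieces:
                continue
            for s, e in pieces:
                flank_counts[i] += np.searchsorted(p, e) - np.searchsorted(p, s)
        with np.errstate(divide="ignore", invalid="ignore"):
            bg = np.where(usable > 0, flank_counts * widths / np.where(usable > 0, usable, 1.0), 0.0)
        corrected[sample] = np.maximum(raw.df[sample].to_numpy() - bg, 0.0)
    df = pd.DataFrame(corrected, index=raw.df.index)
    return raw.advanced(df, "corrected")


def normalize_between_samples(m: CountMatrix) -> CountMatrix:
    """Scale each sample to the cross-sample mean total.

    Every column is multiplied by ``mean(column totals) / column total`` so
    that all column totals equal the mean total; the grand total of the
    matrix is conserved.
    """
    if m.stage == "raw":
        logger.warning("normalizing a raw (uncorrected) matrix")
    elif m.stage != "corrected":
        raise ValueError(f"cannot normalize a matrix at stage {m.stage!r}")
    totals = m.df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total signal: {list(zero.index)}")
    factors = totals.mean() / totals
    return m.advanced(m.df * factors, "normalized")


def filter_min_signal(
    m: CountMatrix, min_normalized: float = 2.0
) -> tuple[CountMatrix, list[str]]:
    """Drop peaks with less than ``min_normalized`` counts in every sample.

    A peak is kept when its maximum across samples reaches the threshold, so
    peaks supported by even a single sample survive.  Returns the filtered
    matrix and the removed peak ids.
    """
    if m.stage != "normalized":
        raise ValueError("filter_min_signal expects a normalized matrix")
    keep = m.df.max(axis=1) >= min_normalized
    removed = list(m.df.index[~keep])
    if removed:
        logger.info("discarded %d peaks below %g normalized counts", len(removed), min_normalized)
    return CountMatrix(m.df.loc[keep], stage=m.stage), removed


def presence_matrix(
    m: CountMatrix, min_normalized: float = 4.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Peak presence calls per sample at a strict intensity threshold.

    An entry is True iff the normalized count strictly exceeds
    ``min_normalized``; the per-sample fraction is the column mean of the
    calls.
    """
    if m.stage != "normalized":
        raise ValueError("presence_matrix expects a normalized matrix")
    present = m.df > min_normalized
    return present, present.mean(axis=0)


def relative_intensity(m: CountMatrix) -> CountMatrix:
    """Divide each peak row by its own cross-sample mean (row mean becomes 1)."""
    if m.stage != "normalized":
        raise ValueError("relative_intensity expects a normalized matrix")
    means = m.df.mean(axis=1)
    zero = means[means == 0]
    if len(zero):
        raise ValueError(f"peak(s) with zero mean intensity: {list(zero.index)[:5]}")
    return m.advanced(m.df.div(means, axis=0), "relative")
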