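"""Separating counting noise from genuine cross-sample binding variability.

For each peak the mean and coefficient of variation (CV) of its normalized
intensity across samples are computed.  Pure counting (shot) noise predicts
CV^2 ~ 1/mean, so the expected CV at a given mean is modelled by the trend

    CV^2(m) = a / m + b

where ``a`` captures shot noise and ``b`` the asymptotic multiplicative
variability floor.  Peaks whose observed CV exceeds a fold multiple of the
expected CV at their mean are flagged as highly variable, i.e. candidate
cell-line-specific binding sites.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import CountMatrix, CVTrendFit, GenomicInterval, PeakSet

logger = logging.getLogger(__name__)

MEANCV_COLUMNS = ["mean", "cv", "expected_cv", "residual", "flag"]


def mean_cv(m: CountMatrix) -> pd.DataFrame:
    """Per-peak mean and CV of normalized intensity across samples.

    CV uses the unbiased (n-1) standard deviation.  Peaks with mean 0 get
    CV 0 (they carry no usable dispersion information and are excluded from
    trend fitting).  Returns a frame with columns ``mean, cv, expected_cv,
    residual, flag``; the last three are filled by
    :func:`flag_variable_peaks`.
    """
    if m.stage != "normalized":
        raise ValueError("mean_cv expects a normalized matrix")
    if len(m.sample_ids) < 2:
        raise ValueError("CV requires at least 2 samples")
    values = m.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / np.where(means > 0, means, 1.0), 0.0)
    df = pd.DataFrame(
        {
            "mean": means,
            "cv": cv,
            "expected_cv": np.nan,
            "residual": np.nan,
            "flag": False,
        },
        index=m.df.index.copy(),
    )
    return df


def fit_cv_trend(table: pd.DataFrame) -> CVTrendFit:
    """Least-squares fit of ``CV^2 = a/mean + b`` over peaks with mean > 0.

    The fit is linear in (1/mean, CV^2); negative coefficient estimates are
    clipped to 0 (both terms are variances and cannot be negative).
    """
    sub = table[table["mean"] > 0]
    if len(sub) < 20:
        raise ValueError(f"need >=20 peaks with positive mean to fit a trend, got {len(sub)}")
    x = 1.0 / sub["mean"].to_numpy()
    y = sub["cv"].to_numpy() ** 2
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all peak means are equal")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    rss = float(((design @ np.array([a, b]) - y) ** 2).sum())
    return CVTrendFit(a=a, b=b, rss=rss, n=len(sub))


def flag_variable_peaks(
    table: pd.DataFrame,
    fit: CVTrendFit,
    fold: float = 1.5,
    min_mean: float = 2.0,
) -> tuple[pd.DataFrame, int]:
    """Flag peaks whose CV exceeds ``fold`` times the expected CV.

    A peak is flagged iff its mean is at least ``min_mean`` and its CV is
    strictly greater than ``fold * expected_cv(mean)``.  Returns the
    completed table (expected_cv, residual and flag columns filled) and the
    flagged count.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    out = table.copy()
    means = out["mean"].to_numpy()
    cv = out["cv"].to_numpy()
    expected = np.asarray(fit.expected_cv(means), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        residual = np.where(
            (cv > 0) & (expected > 0), np.log2(cv / np.where(expected > 0, expected, 1.0)), np.nan
        )
    flags = (means >= min_mean) & (cv > fold * np.where(np.isnan(expected), np.inf, expected))
    out["expected_cv"] = expected
    out["residual"] = residual
    out["flag"] = flags
    return out, int(flags.sum())


def tss_proximal(
    peaks: PeakSet, tss: PeakSet, window_bp: int = 10000
) -> tuple[PeakSet, dict[str, str]]:
    """Peaks within ``window_bp`` of a transcription start site.

    ``tss`` must hold width-1 intervals (a TSS is a point).  The gap between
    a peak [s, e) and a TSS at position p is 0 when the TSS lies inside the
    peak, ``s - p`` when the TSS is upstream and ``p - (e - 1)`` when
    downstream.  Retains peaks with minimal gap <= ``window_bp`` and maps
    each to its nearest TSS name (ties broken by the smaller TSS
    coordinate).
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    for iv in tss:
        if iv.width != 1:
            raise ValueError(f"TSS intervals must be width 1, got {iv.name} width {iv.width}")
    if not set(p.chrom for p in peaks) & set(t.chrom for t in tss):
        logger.warning("peaks and TSS share no chromosome names")

    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, (starts, _, idx) in tss.by_chrom().items():
        tss_by_chrom[chrom] = (starts, [tss[i].name for i in idx])

    kept: list[GenomicInterval] = []
    nearest: dict[str, str] = {}
    for iv in peaks:
        entry = tss_by_chrom.get(iv.chrom)
        if entry is None:
            continue
        pos, names = entry
        # candidate nearest points around the peak ends
        j = np.searchsorted(pos, iv.start)
        cand = [c for c in (j - 1, j, np.searchsorted(pos, iv.end - 1, side="right") - 1,
                            np.searchsorted(pos, iv.end - 1, side="right")) if 0 <= c < len(pos)]
        best_gap, best_i = None, None
        for c in cand:
            p = int(pos[c])
            if p < iv.start:
                gap = iv.start - p
            elif p >= iv.end:
                gap = p - (iv.end - 1)
            else:
                gap = 0
            if best_gap is None or gap < best_gap or (gap == best_gap and p < pos[best_i]):
                best_gap, best_i = gap, c
        if best_gap is not None and best_gap <= window_bp:
            kept.append(iv)
            nearest[iv.name] = names[best_i]
    return PeakSet(kept), nearest


def write_meancv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "peak_id"
    out.to_csv(path, sep="\t")
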