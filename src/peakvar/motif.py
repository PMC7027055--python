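"""Position-weight-matrix scoring of peak sequences.

A motif is modelled as an L x 4 matrix of per-position nucleotide
probabilities over (A, C, G, T).  Before scanning, a probability floor is
applied (every cell raised to at least ``floor`` and rows renormalized) so
that log-odds scores stay finite even for positions where the training data
never showed a nucleotide.  A sequence is scored by the best site: the
maximum over all offsets and both strands of

    sum_i log2( p[i, base_i] / background[base_i] )

in bits, with a uniform background by default.  Windows containing N are
skipped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, PeakSet, SequenceSet

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMatrix:
    """Per-position nucleotide probabilities with an optional floor.

    ``floor`` records the minimum per-cell probability already applied;
    a freshly read matrix has ``floor == 0``.
    """

    probs: np.ndarray
    floor: float = 0.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be an L x 4 matrix")
        if (self.probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        # after flooring, row renormalization can shrink cells to at worst
        # floor / (1 + 4*floor); enforce that effective lower bound
        if self.floor > 0 and (
            self.probs < self.floor / (1 + 4 * self.floor) - 1e-12
        ).any():
            raise ValueError("cell below the declared probability floor")
        if self.background.shape != (4,) or not math.isclose(
            float(self.background.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background must be 4 frequencies summing to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2 odds vs background (may contain -inf when floor is 0)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(np.max(self.log_odds, axis=1).sum())


def apply_probability_floor(pwm: PWMatrix, floor: float = 0.01) -> PWMatrix:
    """Raise every cell to at least ``floor`` and renormalize each row.

    ``floor`` must be below 0.25; at 0.25 every row would be forced uniform
    and above it rows could not sum to 1.
    """
    if not (0 <= floor < 0.25):
        raise ValueError(f"floor must be in [0, 0.25), got {floor}")
    probs = np.maximum(pwm.probs, floor)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWMatrix(probs=probs, floor=floor, background=pwm.background.copy())


def score_best_site(pwm: PWMatrix, seq: str) -> tuple[float, int, str]:
    """Best-site log-odds score of ``seq`` under ``pwm``.

    Returns ``(score, offset, strand)`` where ``offset`` is the 0-based start
    of the best window within ``seq`` and ``strand`` is ``+`` or ``-`` (the
    reverse-complement match).  Windows containing N are skipped; if every
    window is skipped the score is ``-inf`` with offset -1.  Ties prefer the
    forward strand, then the smaller offset.
    """
    L = len(pwm)
    seq = seq.upper()
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} shorter than motif length {L}")
    codes = np.fromiter((_CODE.get(b, 4) for b in seq), dtype=np.int8, count=len(seq))
    # the reverse strand is scored by forward-scanning the reverse
    # complement; reusing the identical summation makes strand symmetry an
    # exact floating-point identity
    rc_codes = np.where(codes == 4, 4, 3 - codes)[::-1]
    lo = pwm.log_odds

    def scan(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        windows = np.lib.stride_tricks.sliding_window_view(c, L)
        valid = ~(windows == 4).any(axis=1)
        scores = np.full(len(windows), float("-inf"))
        if valid.any():
            scores[valid] = lo[np.arange(L), windows[valid]].sum(axis=1)
        return scores, valid

    fwd, fwd_valid = scan(codes)
    rev, rev_valid = scan(rc_codes)
    if not fwd_valid.any() and not rev_valid.any():
        return float("-inf"), -1, "+"
    best_f = int(np.argmax(fwd))
    best_r = int(np.argmax(rev))
    if fwd[best_f] >= rev[best_r]:
        return float(fwd[best_f]), best_f, "+"
    # map the rc offset back onto the input sequence
    return float(rev[best_r]), len(seq) - L - best_r, "-"


def score_sequences(pwm: PWMatrix, seqs: SequenceSet) -> pd.DataFrame:
    """Score every record; returns a frame with columns score/position/strand."""
    rows = {}
    for name, seq in seqs.items():
        score, pos, strand = score_best_site(pwm, seq)
        rows[name] = (score, pos, strand)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["score", "position", "strand"]
    )
    df.index.name = "peak_id"
    n_skipped = int(np.isneginf(df["score"]).sum())
    if n_skipped:
        logger.warning("%d sequences had no N-free window and scored -inf", n_skipped)
    return df


def p53_consensus_pwm() -> PWMatrix:
    """A synthetic p53-style consensus PWM (two RRRCWWGYYY half-sites).

    Built programmatically from the canonical degenerate consensus rather
    than from any trained model: strongly conserved C/G core positions and
    degenerate R/W/Y positions.  Intended as a ready-made 20-bp motif for
    simulations and examples; real analyses should supply their own PWM.
    """
    profiles = {
        # A     C     G     T
        "R": (0.45, 0.04, 0.47, 0.04),
        "Y": (0.04, 0.47, 0.04, 0.45),
        "W": (0.46, 0.04, 0.04, 0.46),
        "C": (0.04, 0.88, 0.04, 0.04),
        "G": (0.04, 0.04, 0.88, 0.04),
    }
    half_site = "RRRCWWGYYY"
    probs = np.array([profiles[ch] for ch in half_site * 2])
    return PWMatrix(probs=probs, floor=0.0)


def make_background_regions(peaks: PeakSet, width_bp: int = 500) -> PeakSet:
    """Peak-flanking background regions for motif-score comparison.

    For each peak, the candidates ``[start - width, start)`` and
    ``[end, end + width)`` are kept only when they lie fully within the genome
    (non-negative start) and overlap no peak in the set.  Names get the
    suffixes ``_bgL`` / ``_bgR``.
    """
    merged = peaks.merged_by_chrom()
    out: list[GenomicInterval] = []
    for iv in peaks:
        ms, me = merged[iv.chrom]
        for lo, hi, suffix in (
            (iv.start - width_bp, iv.start, "_bgL"),
            (iv.end, iv.end + width_bp, "_bgR"),
        ):
            if lo < 0:
                continue
            # overlap against the merged peak blocks
            j = np.searchsorted(ms, hi)
            if j > 0 and me[j - 1] > lo:
                continue
            out.append(GenomicInterval(iv.chrom, lo, hi, f"{iv.name}{suffix}"))
    return PeakSet(out)


def subset_average_correlation(
    scores: pd.Series,
    m: CountMatrix,
    k: int,
    max_combos: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Motif-score vs binding correlation after averaging over k samples.

    For every k-subset of the samples (all of them when C(n, k) does not
    exceed ``max_combos``, otherwise ``max_combos`` distinct subsets sampled
    with ``seed``), computes the Pearson correlation between the per-peak
    motif score and the subset-mean intensity.  Returns the array of r
    values; subsets where either vector has zero variance yield NaN with a
    warning.
    """
    n = len(m.sample_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    scores = scores.reindex(m.peak_ids)
    if scores.isna().any():
        raise ValueError("scores missing for some peaks in the matrix")
    x = scores.to_numpy(dtype=float)

    n_combos = math.comb(n, k)
    if n_combos <= max_combos:
        combos = list(itertools.combinations(range(n), k))
    else:
        rng = np.random.default_rng(seed)
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < max_combos:
            chosen.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
        combos = sorted(chosen)

    values = m.values
    means = np.stack([values[:, list(c)].mean(axis=1) for c in combos], axis=1)

    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())
    yc = means - means.mean(axis=0)
    ynorm = np.sqrt((yc**2).sum(axis=0))
    r = np.full(len(combos), np.nan)
    ok = (xnorm > 0) & (ynorm > 0)
    if xnorm > 0:
        r[ok] = (xc @ yc[:, ok]) / (xnorm * ynorm[ok])
    if (~ok).any():
        logger.warning("%d subsets had a zero-variance vector; reported NaN", int((~ok).sum()))
    return r
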