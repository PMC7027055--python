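"""Synthetic multi-cell-line binding datasets with known ground truth.

The generator emulates the statistical structure of a cross-cell-line
transcription-factor ChIP-seq experiment: a consensus set of peaks measured
in several samples (cell lines), where

* most peaks are *shared* -- bound everywhere with a peak-specific latent
  affinity drawn log-normally;
* a small planted fraction are *variable* (cell-line specific) -- boosted by
  ``effect_fold`` in a few active lines;
* per-line chromatin accessibility multiplies expected intensity through a
  power-law coupling, and is itself elevated in the active lines of variable
  peaks;
* optional lineage pairs share a multiplicative noise factor (tissue-of-
  origin correlation), and independent per-line log-normal noise models
  line-to-line biological/technical variability;
* observed counts are Poisson around the expected intensity (shot noise),
  optionally overdispersed via a gamma mixture.

Every stage is deterministic given the config seed, and per-stage seeds are
derived so truth, counts, sequences and expression can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, PeakSet, SequenceSet
from .motif import PWMatrix, reverse_complement

CHROM = "chrS"
READ_LENGTH = 75


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the study design the pipeline targets: 12 cell lines,
    a consensus universe of 8742 peaks of which ~5% are cell-line specific
    with a 4-fold single-line effect, and Poisson counting noise around a
    mean depth of ~50 reads per peak.
    """

    n_peaks: int = 8742
    n_samples: int = 12
    frac_variable: float = 0.05
    affinity_sd: float = 0.5
    effect_fold: float = 4.0
    n_active_lines: int = 1
    acc_coupling: float = 0.5
    acc_sd: float = 0.5
    acc_sample_sd: float = 0.1
    lineage_pairs: Sequence[tuple[int, int]] = field(default_factory=tuple)
    lineage_sd: float = 0.3
    line_noise_sd: float = 0.3
    depth: float = 50.0
    background_rate: float = 0.005
    nb_dispersion: float | None = None
    peak_width: int = 500
    gap_bp: int = 2500
    seq_len: int = 60
    site_temperature: float = 1.0
    temp_affinity_coupling: float = 0.7
    expr_acc_coupling: float = 1.0
    expr_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_variable <= 1):
            raise ValueError("frac_variable must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if not (1 <= self.n_active_lines <= self.n_samples):
            raise ValueError("n_active_lines must be in [1, n_samples]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.gap_bp < 2000:
            raise ValueError("peaks must be separated by >= 2 kb gaps")
        if self.site_temperature < 0 or self.seq_len <= 0:
            raise ValueError("invalid sequence parameters")
        flat = [s for pair in self.lineage_pairs for s in pair]
        if len(flat) != len(set(flat)) or any(
            not (0 <= s < self.n_samples) for s in flat
        ):
            raise ValueError("lineage_pairs must be disjoint valid sample indices")

    @property
    def sample_ids(self) -> list[str]:
        return [f"line_{i + 1:02d}" for i in range(self.n_samples)]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    peaks: PeakSet
    sample_ids: list[str]
    is_variable: np.ndarray  # (P,) bool
    latent_affinity: np.ndarray  # (P,) positive
    active_lines: list[np.ndarray]  # per peak, empty for shared peaks
    accessibility: np.ndarray  # (P, S) positive
    expected_intensity: np.ndarray  # (P, S) positive

    @property
    def classes(self) -> np.ndarray:
        return np.where(self.is_variable, "variable", "shared")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "class": self.classes,
                "latent_affinity": self.latent_affinity,
                "active_lines": [
                    ",".join(self.sample_ids[s] for s in lines)
                    for lines in self.active_lines
                ],
            },
            index=pd.Index(self.peaks.names, name="peak_id"),
        )
        return df


def generate_truth(cfg: SyntheticConfig) -> tuple[SyntheticTruth, PeakSet]:
    """Plant peak classes, affinities, accessibility and expected intensity."""
    rng = cfg.rng(0)
    P, S = cfg.n_peaks, cfg.n_samples

    starts = 1000 + np.arange(P) * (cfg.peak_width + cfg.gap_bp)
    peaks = PeakSet(
        GenomicInterval(CHROM, int(s), int(s) + cfg.peak_width, f"peak_{i + 1:05d}")
        for i, s in enumerate(starts)
    )

    n_var = int(round(P * cfg.frac_variable))
    var_idx = np.sort(rng.choice(P, size=n_var, replace=False))
    is_variable = np.zeros(P, dtype=bool)
    is_variable[var_idx] = True

    affinity = np.exp(rng.normal(0.0, cfg.affinity_sd, size=P))
    active_lines: list[np.ndarray] = [np.empty(0, dtype=int)] * P
    for i in var_idx:
        active_lines[i] = np.sort(rng.choice(S, size=cfg.n_active_lines, replace=False))

    # accessibility splits into a per-peak level (chromatin context of the
    # locus, shared by all lines) and a smaller per-line fluctuation; the
    # active lines of a variable peak additionally sit in opened chromatin
    acc_peak = np.exp(rng.normal(0.0, cfg.acc_sd, size=P))
    acc_line = np.exp(rng.normal(0.0, cfg.acc_sample_sd, size=(P, S)))
    active_mask = np.zeros((P, S), dtype=bool)
    for i in var_idx:
        active_mask[i, active_lines[i]] = True
    accessibility = (
        acc_peak[:, None] * acc_line * np.where(active_mask, cfg.effect_fold, 1.0)
    )

    expected = (
        cfg.depth
        * affinity[:, None]
        * np.where(active_mask, cfg.effect_fold, 1.0)
        * accessibility**cfg.acc_coupling
    )
    for a, b in cfg.lineage_pairs:
        factor = np.exp(rng.normal(0.0, cfg.lineage_sd, size=P))
        expected[:, a] = expected[:, a] * factor
        expected[:, b] = expected[:, b] * factor
    if cfg.line_noise_sd > 0:
        expected = expected * np.exp(rng.normal(0.0, cfg.line_noise_sd, size=(P, S)))

    truth = SyntheticTruth(
        peaks=peaks,
        sample_ids=cfg.sample_ids,
        is_variable=is_variable,
        latent_affinity=affinity,
        active_lines=active_lines,
        accessibility=accessibility,
        expected_intensity=expected,
    )
    return truth, peaks


def generate_counts(
    truth: SyntheticTruth, cfg: SyntheticConfig, with_reads: bool = False
) -> tuple[CountMatrix, dict[str, PeakSet] | None]:
    """Draw Poisson counts around the expected intensities.

    With ``with_reads`` the same counts are realized as read intervals: each
    peak/sample count places that many 5' positions uniformly inside the
    peak, plus background reads at ``background_rate`` per base of inter-peak
    gap; re-counting the reads reproduces the matrix exactly.
    """
    rng = cfg.rng(1)
    lam = truth.expected_intensity
    if cfg.nb_dispersion:
        # gamma-Poisson mixture: var = mean + mean^2 / dispersion
        lam = rng.gamma(cfg.nb_dispersion, lam / cfg.nb_dispersion)
    counts = rng.poisson(lam).astype(float)
    df = pd.DataFrame(
        counts,
        index=pd.Index(truth.peaks.names, name="peak_id"),
        columns=truth.sample_ids,
    )
    matrix = CountMatrix(df, stage="raw")
    if not with_reads:
        return matrix, None

    gaps: list[tuple[int, int]] = []
    prev = 0
    for iv in truth.peaks:
        if iv.start > prev:
            gaps.append((prev, iv.start))
        prev = iv.end
    gaps.append((prev, prev + cfg.gap_bp))
    gap_lens = np.array([e - s for s, e in gaps], dtype=float)

    reads: dict[str, PeakSet] = {}
    for j, sample in enumerate(truth.sample_ids):
        positions: list[int] = []
        for i, iv in enumerate(truth.peaks):
            c = int(counts[i, j])
            if c:
                positions.extend(rng.integers(iv.start, iv.end, size=c).tolist())
        n_bg = rng.poisson(cfg.background_rate * gap_lens)
        for (s, e), nb in zip(gaps, n_bg):
            if nb:
                positions.extend(rng.integers(s, e, size=int(nb)).tolist())
        reads[sample] = PeakSet(
            GenomicInterval(CHROM, p, p + READ_LENGTH, f"{sample}_read_{i}")
            for i, p in enumerate(positions)
        )
    return matrix, reads


def generate_sequences(
    truth: SyntheticTruth, pwm: PWMatrix, cfg: SyntheticConfig
) -> SequenceSet:
    """Peak sequences carrying one planted motif site each.

    The site is sampled position-wise from the PWM sharpened by a per-peak
    temperature ``T = site_temperature * exp(-temp_affinity_coupling * z)``
    with z the standardized log affinity, so high-affinity peaks carry
    near-consensus sites.  At temperature 0 every site is the consensus.
    """
    rng = cfg.rng(2)
    L = len(pwm)
    if cfg.seq_len < L:
        raise ValueError("seq_len shorter than the motif")
    z = np.log(truth.latent_affinity)
    z = (z - z.mean()) / (z.std() or 1.0)
    records: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for i, iv in enumerate(truth.peaks):
        seq = rng.choice(bases, size=cfg.seq_len)
        T = cfg.site_temperature * float(np.exp(-cfg.temp_affinity_coupling * z[i]))
        if T <= 1e-9:
            site = pwm.consensus
        else:
            sharpened = pwm.probs ** (1.0 / T)
            sharpened = sharpened / sharpened.sum(axis=1, keepdims=True)
            site = "".join(
                bases[rng.choice(4, p=sharpened[pos])] for pos in range(L)
            )
        if rng.random() < 0.5:
            site = reverse_complement(site)
        offset = int(rng.integers(0, cfg.seq_len - L + 1))
        seq[offset : offset + L] = list(site)
        records[iv.name] = "".join(seq)
    return SequenceSet(records)


def generate_expression(
    truth: SyntheticTruth, cfg: SyntheticConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """One gene per peak whose expression tracks local accessibility.

    ``expression = base * accessibility^expr_acc_coupling * noise``; with the
    coupling at 0 expression is independent of binding.  Returns the
    gene x sample matrix and the peak -> gene mapping.
    """
    rng = cfg.rng(3)
    P, S = cfg.n_peaks, cfg.n_samples
    base = np.exp(rng.normal(2.0, 0.5, size=P))
    noise = np.exp(rng.normal(0.0, cfg.expr_noise_sd, size=(P, S)))
    expr = base[:, None] * truth.accessibility**cfg.expr_acc_coupling * noise
    genes = [f"gene_{name}" for name in truth.peaks.names]
    df = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"), columns=truth.sample_ids
    )
    mapping = dict(zip(truth.peaks.names, genes))
    return df, mapping


def generate_tss(truth: SyntheticTruth, cfg: SyntheticConfig, offset_bp: int = 800) -> PeakSet:
    """A width-1 TSS for each peak's gene, ``offset_bp`` downstream of the peak."""
    intervals = []
    for iv in truth.peaks:
        pos = iv.end + offset_bp
        intervals.append(GenomicInterval(CHROM, pos, pos + 1, f"gene_{iv.name}"))
    return PeakSet(intervals)


def config_from_mapping(data: Mapping) -> SyntheticConfig:
    """Build a config from a flat mapping (e.g. parsed JSON)."""
    kwargs = dict(data)
    if "lineage_pairs" in kwargs and kwargs["lineage_pairs"] is not None:
        kwargs["lineage_pairs"] = tuple(tuple(p) for p in kwargs["lineage_pairs"])
    known = {f.name for f in fields(SyntheticConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticConfig(**kwargs)


def config_to_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["lineage_pairs"] = [list(p) for p in cfg.lineage_pairs]
    return d
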