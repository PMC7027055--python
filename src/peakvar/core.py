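"""Core data containers shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  Two intervals on the same
chromosome overlap iff ``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: ordered processing stages of a count matrix
STAGE_ORDER = ("raw", "corrected", "normalized", "relative")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5' position of the interval read as a sequencing tag.

        ``start`` on the forward (or unspecified) strand, ``end - 1`` on the
        reverse strand.
        """
        return self.start if self.strand != "-" else self.end - 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered, sorted collection of :class:`GenomicInterval`.

    Sorted by ``(chrom, start, end)`` on construction; interval names must be
    unique when present.  Used for peaks, read 5' tags, background regions and
    TSS locations alike.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        names = [iv.name for iv in ivs if iv.name is not None]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            for n in names:
                if n in seen:
                    raise ValueError(f"duplicate interval name {n!r}")
                seen.add(n)
        self._intervals: list[GenomicInterval] = ivs
        self.id_index: dict[str, int] = {
            iv.name: i for i, iv in enumerate(ivs) if iv.name is not None
        }
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] | None = None
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals, {len(self.chroms)} chromosomes)"

    # -- derived views -------------------------------------------------------
    @property
    def names(self) -> list[str | None]:
        return [iv.name for iv in self._intervals]

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        """Per-chromosome ``(starts, ends, original indices)`` arrays."""
        if self._by_chrom is None:
            out: dict[str, tuple[list[int], list[int], list[int]]] = {}
            for i, iv in enumerate(self._intervals):
                out.setdefault(iv.chrom, ([], [], []))
                s, e, idx = out[iv.chrom]
                s.append(iv.start)
                e.append(iv.end)
                idx.append(i)
            self._by_chrom = {
                c: (np.asarray(s), np.asarray(e), idx) for c, (s, e, idx) in out.items()
            }
        return self._by_chrom

    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Union of the intervals per chromosome as sorted disjoint blocks."""
        if self._merged is None:
            merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, (starts, ends, _) in self.by_chrom().items():
                ms: list[int] = []
                me: list[int] = []
                for s, e in zip(starts, ends):
                    if ms and s <= me[-1]:
                        me[-1] = max(me[-1], int(e))
                    else:
                        ms.append(int(s))
                        me.append(int(e))
                merged[chrom] = (np.asarray(ms), np.asarray(me))
            self._merged = merged
        return self._merged

    def five_prime_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted 5' tag positions per chromosome."""
        out: dict[str, list[int]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv.five_prime)
        return {c: np.sort(np.asarray(p)) for c, p in out.items()}


class CountMatrix:
    """A peak x sample matrix of non-negative signal values.

    Carries a processing-stage tag that advances monotonically through
    ``raw -> corrected -> normalized -> relative``; stages may be skipped
    (e.g. normalizing an uncorrected matrix) but never revisited.
    """

    def __init__(self, df: pd.DataFrame, stage: str = "raw"):
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGE_ORDER}")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("count matrix contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at peak {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if df.index.has_duplicates:
            raise ValueError("duplicate peak ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self._df = df.astype(float)
        self._stage = stage

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def stage(self) -> str:
        return self._stage

    @property
    def peak_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def advanced(self, df: pd.DataFrame, stage: str) -> "CountMatrix":
        """Return a new matrix at a strictly later processing stage."""
        if STAGE_ORDER.index(stage) <= STAGE_ORDER.index(self._stage):
            raise ValueError(
                f"illegal stage transition {self._stage!r} -> {stage!r}; "
                f"stages advance through {STAGE_ORDER}"
            )
        return CountMatrix(df, stage=stage)

    def subset_peaks(self, peak_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self._df.loc[list(peak_ids)], stage=self._stage)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"CountMatrix({n} peaks x {m} samples, stage={self._stage!r})"


class SequenceSet(Mapping):
    """A named collection of DNA sequences over the alphabet {A,C,G,T,N}.

    Sequences are stored uppercase; names are unique and sequences non-empty.
    Behaves as a read-only mapping from record name to sequence.
    """

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, records: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = dict(records)
        clean: dict[str, str] = {}
        for name, seq in items.items():
            s = str(seq).upper()
            if not s:
                raise ValueError(f"empty sequence for record {name!r}")
            bad = set(s) - self._ALPHABET
            if bad:
                raise ValueError(
                    f"record {name!r} contains non-DNA characters {sorted(bad)}"
                )
            clean[name] = s
        self._records = clean

    def __getitem__(self, name: str) -> str:
        return self._records[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __repr__(self) -> str:
        return f"SequenceSet({len(self)} records)"


@dataclass
class CVTrendFit:
    """Fitted mean-CV trend ``CV^2(m) = a/m + b``.

    ``a`` is the shot-noise coefficient (intensity units) and ``b`` the
    asymptotic CV^2 floor absorbing multiplicative variability.
    """

    a: float
    b: float
    rss: float
    n: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("trend coefficients must be non-negative")

    def expected_cv(self, mean: np.ndarray | float) -> np.ndarray | float:
        m = np.asarray(mean, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(m > 0, self.a / np.where(m > 0, m, 1.0) + self.b, np.nan)
        return np.sqrt(cv2)


@dataclass
class LinearFit:
    """OLS fit of log2 binding signal on motif score (and accessibility)."""

    coefficients: dict[str, float]
    r_squared: float
    adj_r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


@dataclass
class CorrelationSummary:
    """Pearson correlation with its two-tailed t-distribution p-value."""

    r: float
    p: float
    n: int


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges`` lists ``(node_a, node_b, height)`` in merge order, where leaves
    are numbered ``0..n-1`` and the i-th merge creates node ``n + i``
    (SciPy linkage convention). ``linkage`` keeps the full (n-1) x 4 matrix
    for interoperability with :mod:`scipy.cluster.hierarchy`.
    """

    merges: list[tuple[int, int, float]]
    labels: list[str]
    linkage: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-9 for h1, h2 in zip(heights, heights[1:])):
            logger.warning("non-monotone merge heights in dendrogram")
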