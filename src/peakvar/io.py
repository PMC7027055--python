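"""Readers and writers for the plain-text formats the pipeline consumes.

Supported formats: BED3/BED4/BED6 (0-based half-open), FASTA, TSV count
matrices with a ``peak_id`` header column, and tab-separated position
probability matrices with an ``A C G T`` header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import CountMatrix, GenomicInterval, PeakSet, SequenceSet
from .motif import PWMatrix

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input file; the message names the offending location."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3/4/6 file into a :class:`PeakSet`.

    Intervals are taken verbatim as 0-based half-open.  When the name column
    is absent, names ``peak_1..peak_n`` are assigned in file order.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if len(fields) >= 4 and fields[3] not in ("", "."):
                name = fields[3]
            else:
                auto += 1
                name = f"peak_{auto}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    try:
        return PeakSet(intervals)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix with header ``peak_id<TAB>sample...``.

    An optional leading comment line ``#stage=<stage>`` declares the
    processing stage; the default is ``raw``.
    """
    path = Path(path)
    stage = "raw"
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if line.strip().startswith("#stage="):
                    stage = line.strip().split("=", 1)[1]
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype={0: str})
    if df.index.name != "peak_id":
        raise ParseError(f"{path}: first header field must be 'peak_id'")
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing/ragged value at peak {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{path}: non-numeric value at peak {bad!r}, sample {col!r}"
            )
    try:
        return CountMatrix(df, stage=stage)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#stage={m.stage}\n")
        df = m.df.copy()
        df.index.name = "peak_id"
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceSet:
    """Read FASTA records into a :class:`SequenceSet` (uppercased)."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        records[rec.id] = seq
    try:
        return SequenceSet(records)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path) -> PWMatrix:
    """Read a tab-separated probability matrix with header ``A C G T``.

    Rows whose sum is within 1e-6 of 1 are renormalized exactly to 1; larger
    deviations are rejected.  No probability floor is applied on read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["A", "C", "G", "T"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: PWM header must be {expected}, got {list(df.columns)}")
    probs = df.to_numpy(dtype=float)
    if (probs < 0).any():
        row = int(np.flatnonzero((probs < 0).any(axis=1))[0])
        raise ParseError(f"{path}: negative probability in row {row + 1}")
    sums = probs.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-6
    if bad.any():
        row = int(np.argmax(bad))
        raise ParseError(
            f"{path}: row {row + 1} probabilities sum to {sums[row]:.6g}, expected 1"
        )
    probs = probs / sums[:, None]
    return PWMatrix(probs=probs, floor=0.0)


def write_pwm(pwm: PWMatrix, path: str | Path) -> None:
    df = pd.DataFrame(pwm.probs, columns=["A", "C", "G", "T"])
    df.to_csv(path, sep="\t", index=False)
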