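"""End-to-end orchestration: quantify -> variability -> motif -> integrate -> cluster.

A run is configured by a flat JSON mapping of input paths and stage
parameters, writes every intermediate table to the output directory, and
finishes with a manifest of SHA-256 checksums so that reruns with the same
inputs and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__, cluster, integrate, io, motif, quantify, variability
from .core import PeakSet

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "flank_bp": 1000,
    "min_signal": 2.0,
    "presence_min": 4.0,
    "fold": 1.5,
    "min_mean": 2.0,
    "floor": 0.01,
    "tss_window": 10000,
    "pseudocount": 1.0,
    "seed": 0,
}

_INPUT_KEYS = ("peaks", "counts", "pwm", "fasta", "tss", "expression", "atac")


def _load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return json.load(fh)
    return dict(config)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: Mapping | str | Path) -> list[dict]:
    """Pre-flight checks; returns one pass/fail record per check."""
    cfg = _load_config(config)
    checks: list[dict] = []

    def record(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(passed), "detail": detail})

    for key in _INPUT_KEYS:
        if key in cfg:
            exists = Path(cfg[key]).exists()
            record(f"file:{key}", exists, cfg[key])
    reads = cfg.get("reads", {})
    for sample, path in reads.items():
        record(f"file:reads:{sample}", Path(path).exists(), path)

    if "counts" not in cfg and not reads:
        record("inputs:counts_or_reads", False, "neither 'counts' nor 'reads' given")
    if reads and "peaks" not in cfg:
        record("inputs:peaks_for_reads", False, "'reads' given without 'peaks'")

    peaks = None
    if cfg.get("peaks") and Path(cfg["peaks"]).exists():
        peaks = io.read_bed(cfg["peaks"])
    m = None
    if cfg.get("counts") and Path(cfg["counts"]).exists():
        m = io.read_count_matrix(cfg["counts"])
        if peaks is not None:
            record(
                "labels:peaks_vs_counts",
                set(m.peak_ids) == set(peaks.names),
                f"{len(set(m.peak_ids) ^ set(peaks.names))} mismatched peak ids",
            )
    if cfg.get("tss") and Path(cfg["tss"]).exists() and peaks is not None:
        tss = io.read_bed(cfg["tss"])
        shared = set(peaks.chroms) & set(tss.chroms)
        record(
            "chroms:peaks_vs_tss",
            bool(shared),
            "no shared chromosome names" if not shared else f"shared: {sorted(shared)}",
        )
    if cfg.get("expression") and Path(cfg["expression"]).exists() and m is not None:
        expr = pd.read_csv(cfg["expression"], sep="\t", index_col=0, comment="#")
        shared = set(m.sample_ids) & set(expr.columns)
        record(
            "labels:binding_vs_expression_samples",
            len(shared) >= 3,
            f"binding samples {sorted(m.sample_ids)[:3]}... vs "
            f"expression samples {sorted(expr.columns)[:3]}...; shared={len(shared)}",
        )
    if cfg.get("pwm") and Path(cfg["pwm"]).exists():
        try:
            io.read_pwm(cfg["pwm"])
            record("pwm:valid", True)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            record("pwm:valid", False, str(exc))
    return checks


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> dict:
    """Execute all applicable stages; returns the manifest dictionary.

    Raises before any stage runs when a named input file is missing.
    """
    cfg = _load_config(config)
    params = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    outdir = Path(outdir)

    # fail fast on missing inputs
    paths = {k: cfg[k] for k in _INPUT_KEYS if k in cfg}
    paths.update({f"reads:{s}": p for s, p in cfg.get("reads", {}).items()})
    missing = {k: p for k, p in paths.items() if not Path(p).exists()}
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    if "counts" not in cfg and "reads" not in cfg:
        raise ValueError("config must provide either 'counts' or 'reads'")

    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(name: str) -> Path:
        p = outdir / name
        outputs.append(p)
        return p

    peaks = io.read_bed(cfg["peaks"]) if "peaks" in cfg else None

    # --- quantify ---------------------------------------------------------
    if "reads" in cfg:
        if peaks is None:
            raise ValueError("'reads' input requires a 'peaks' BED file")
        reads = {s: io.read_bed(p) for s, p in cfg["reads"].items()}
        raw = quantify.count_reads_matrix(reads, peaks)
        corrected = quantify.background_correct(
            raw, peaks, reads, flank_bp=int(params["flank_bp"])
        )
        norm = quantify.normalize_between_samples(corrected)
    else:
        m = io.read_count_matrix(cfg["counts"])
        norm = m if m.stage == "normalized" else quantify.normalize_between_samples(m)
    norm, removed = quantify.filter_min_signal(norm, float(params["min_signal"]))
    io.write_count_matrix(norm, emit("normalized.tsv"))
    _, fractions = quantify.presence_matrix(norm, float(params["presence_min"]))
    fractions.rename("fraction_present").to_csv(emit("presence_fractions.tsv"), sep="\t")

    # --- variability ------------------------------------------------------
    table = variability.mean_cv(norm)
    fit = variability.fit_cv_trend(table)
    table, n_flagged = variability.flag_variable_peaks(
        table, fit, fold=float(params["fold"]), min_mean=float(params["min_mean"])
    )
    variability.write_meancv(table, emit("meancv.tsv"))
    logger.info("flagged %d / %d peaks as highly variable", n_flagged, len(table))

    results: dict[str, Any] = {
        "n_peaks": int(len(table)),
        "n_removed_low_signal": len(removed),
        "n_flagged": n_flagged,
        "cv_trend": {"a": fit.a, "b": fit.b, "n": fit.n},
    }

    # --- TSS subsetting ---------------------------------------------------
    if "tss" in cfg and peaks is not None:
        tss = io.read_bed(cfg["tss"])
        kept_names = [n for n in table.index[table["flag"]]]
        flagged_peaks = (
            PeakSet([iv for iv in peaks if iv.name in set(kept_names)])
            if kept_names
            else None
        )
        if flagged_peaks is not None and len(flagged_peaks):
            prox, nearest = variability.tss_proximal(
                flagged_peaks, tss, window_bp=int(params["tss_window"])
            )
            io.write_bed(prox, emit("variable_tss_proximal.bed"))
            results["n_variable_tss_proximal"] = len(prox)

    # --- motif + integrate ------------------------------------------------
    if "pwm" in cfg and "fasta" in cfg:
        pwm = motif.apply_probability_floor(io.read_pwm(cfg["pwm"]), float(params["floor"]))
        seqs = io.read_fasta(cfg["fasta"])
        scores = motif.score_sequences(pwm, seqs)
        scores.to_csv(emit("motif_scores.tsv"), sep="\t")

        common = [p for p in norm.peak_ids if p in scores.index]
        y = integrate.log2_signal(
            norm.df.loc[common].mean(axis=1), float(params["pseudocount"])
        )
        x = scores.loc[common, "score"].to_numpy()
        acc = None
        if "atac" in cfg:
            atac = io.read_count_matrix(cfg["atac"])
            acc = integrate.log2_signal(
                atac.df.reindex(common).mean(axis=1), float(params["pseudocount"])
            )
        fit_motif = integrate.fit_binding_model(y, x)
        results["binding_model"] = {
            "motif_only": {
                "r_squared": fit_motif.r_squared,
                "coefficients": fit_motif.coefficients,
                "n": fit_motif.n,
            }
        }
        if acc is not None:
            fit_both = integrate.fit_binding_model(y, x, acc)
            results["binding_model"]["motif_plus_accessibility"] = {
                "r_squared": fit_both.r_squared,
                "coefficients": fit_both.coefficients,
                "n": fit_both.n,
            }

    # --- clustering -------------------------------------------------------
    if len(norm.sample_ids) >= 3:
        logm = pd.DataFrame(
            integrate.log2_signal(norm.values, float(params["pseudocount"])),
            index=norm.df.index,
            columns=norm.df.columns,
        )
        d, labels = cluster.correlation_distance(logm, axis="samples")
        dend = cluster.average_linkage(d, labels)
        with open(emit("dendrogram.json"), "w") as fh:
            json.dump(
                {"labels": dend.labels, "merges": dend.merges}, fh, indent=1
            )

    with open(emit("results.json"), "w") as fh:
        json.dump(results, fh, indent=1, default=float)

    manifest = {
        "peakvar_version": __version__,
        "params": params,
        "inputs": {k: str(v) for k, v in paths.items()},
        "checksums": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
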