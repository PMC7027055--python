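"""Relating binding strength to motif score, accessibility and expression.

The central model is an ordinary least-squares fit of log2 binding signal on
motif score and (optionally) log2 chromatin accessibility; the fraction of
binding variance each model explains (R^2) quantifies how much sequence
versus chromatin state predicts occupancy.  Companion routines compare
binding changes to accessibility changes between two conditions, correlate
binding with gene expression across samples, test gene-set enrichment with
the hypergeometric distribution, and summarize binding within bins of a
covariate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CorrelationSummary, CountMatrix, LinearFit

logger = logging.getLogger(__name__)


def log2_signal(values: np.ndarray | pd.Series, pseudocount: float = 1.0) -> np.ndarray:
    """log2(x + pseudocount); the pseudocount keeps zero-count peaks finite."""
    x = np.asarray(values, dtype=float)
    if (x + pseudocount <= 0).any():
        raise ValueError("values + pseudocount must be positive before log2")
    return np.log2(x + pseudocount)


def fit_binding_model(
    log2_signal: np.ndarray,
    motif_score: np.ndarray,
    accessibility: np.ndarray | None = None,
) -> LinearFit:
    """OLS of log2 binding signal on motif score (and log accessibility).

    With ``accessibility`` omitted this is the motif-only model.  Raises on
    near-collinear predictors (design condition number above 1e10).
    """
    y = np.asarray(log2_signal, dtype=float)
    predictors = {"motif": np.asarray(motif_score, dtype=float)}
    if accessibility is not None:
        predictors["accessibility"] = np.asarray(accessibility, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need >=10 observations, got {n}")
    for name, v in predictors.items():
        if len(v) != n:
            raise ValueError(f"predictor {name!r} length {len(v)} != {n}")
    X = sm.add_constant(np.column_stack(list(predictors.values())))
    if np.linalg.cond(X) > 1e10:
        raise ValueError("collinear predictors (design condition number > 1e10)")
    res = sm.OLS(y, X).fit()
    names = ["intercept", *predictors.keys()]
    return LinearFit(
        coefficients=dict(zip(names, map(float, res.params))),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        n=n,
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> CorrelationSummary:
    """Pearson r with a two-tailed p-value from the t-distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector in correlation")
    r, p = stats.pearsonr(x, y)
    return CorrelationSummary(r=float(r), p=float(p), n=len(x))


def delta_delta_correlation(
    bind_a: np.ndarray,
    bind_b: np.ndarray,
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    pseudocount: float = 1.0,
) -> tuple[CorrelationSummary, float]:
    """Correlate the binding change with the accessibility change.

    Computes ``dbind = log2(bind_b + pc) - log2(bind_a + pc)`` and the same
    for accessibility, then the Pearson correlation between the two deltas.
    Returns the correlation summary and the R^2 of dbind on dacc.
    """
    dbind = log2_signal(bind_b, pseudocount) - log2_signal(bind_a, pseudocount)
    dacc = log2_signal(acc_b, pseudocount) - log2_signal(acc_a, pseudocount)
    if dbind.std() == 0 or dacc.std() == 0:
        raise ValueError("zero variance in a delta vector")
    summary = pearson_with_p(dbind, dacc)
    return summary, float(summary.r**2)


def binding_expression_association(
    binding: CountMatrix,
    expression: pd.DataFrame,
    peak_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Per-peak correlation of binding with its gene's expression.

    For every peak, the Pearson correlation across the shared samples
    between the peak's binding intensity and the mapped gene's expression.
    Peaks with a constant binding or expression row get NaN.
    """
    shared = [s for s in binding.sample_ids if s in expression.columns]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared samples, got {len(shared)}")
    missing = [p for p in binding.peak_ids if p not in peak_to_gene]
    if missing:
        raise ValueError(f"no gene mapped for peaks {missing[:5]}")
    rows = []
    for peak in binding.peak_ids:
        gene = peak_to_gene[peak]
        if gene not in expression.index:
            raise ValueError(f"gene {gene!r} absent from expression matrix")
        b = binding.df.loc[peak, shared].to_numpy(dtype=float)
        e = expression.loc[gene, shared].to_numpy(dtype=float)
        if b.std() == 0 or e.std() == 0:
            rows.append((peak, gene, np.nan, np.nan))
            continue
        s = pearson_with_p(b, e)
        rows.append((peak, gene, s.r, s.p))
    out = pd.DataFrame(rows, columns=["peak_id", "gene", "r", "p"]).set_index("peak_id")
    n_nan = int(out["r"].isna().sum())
    if n_nan:
        logger.warning("%d peaks had a constant row; correlation undefined", n_nan)
    return out


def group_correlation_test(
    r_a: Iterable[float], r_b: Iterable[float], fisher_z: bool = False
) -> tuple[float, float, float]:
    """Welch t-test between two sets of correlation coefficients.

    Compares e.g. variable-peak vs canonical-target correlation
    distributions.  Returns ``(t, df, p)``.  With ``fisher_z`` the r values
    are arctanh-transformed first (variance-stabilized).
    """
    a = np.asarray([v for v in r_a if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in r_b if np.isfinite(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 finite correlations")
    if fisher_z:
        a, b = np.arctanh(np.clip(a, -0.999999, 0.999999)), np.arctanh(
            np.clip(b, -0.999999, 0.999999)
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def hypergeometric_enrichment(
    query: set[str],
    terms: Mapping[str, set[str]],
    universe: set[str],
    correction: str = "BH",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    For each term, ``p = P(X >= k)`` with k query hits among the term's K
    universe genes, drawing n = |query| from N = |universe|.  Multiple-test
    correction across terms is Benjamini-Hochberg (``BH``) or
    ``bonferroni``.  Results are sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in terms.items():
        members = set(genes) & set(universe)
        K = len(members)
        k = len(set(query) & members)
        # P(X >= k); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]).set_index("term")
    method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}")
    df["p_adj"] = multipletests(df["p"].to_numpy(), method=method)[1] if len(df) else []
    return df.sort_values("p")


def bin_summary(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 5,
    scheme: str = "quantile",
) -> pd.DataFrame:
    """Five-number summaries of y within bins of x (box-plot style).

    ``scheme='quantile'`` uses equal-count bins (ties may merge bins, with a
    warning); ``'fixed'`` uses equal-width bins over the range of x.
    Whiskers use the 1.5 IQR rule clipped to the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be aligned")
    if len(x) < n_bins:
        raise ValueError("need at least n_bins observations")
    if scheme == "quantile":
        binned = pd.qcut(x, n_bins, duplicates="drop")
        if len(binned.categories) < n_bins:
            logger.warning(
                "ties reduced %d requested quantile bins to %d",
                n_bins,
                len(binned.categories),
            )
    elif scheme == "fixed":
        binned = pd.cut(x, n_bins, include_lowest=True)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    for i, cat in enumerate(binned.categories):
        vals = y[np.asarray(binned == cat)]
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = float(vals[vals >= q1 - 1.5 * iqr].min())
        hi = float(vals[vals <= q3 + 1.5 * iqr].max())
        rows.append((i, str(cat), len(vals), lo, q1, med, q3, hi))
    return pd.DataFrame(
        rows,
        columns=["bin", "interval", "count", "whisker_lo", "q1", "median", "q3", "whisker_hi"],
    ).set_index("bin")
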