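"""Bulk-RNA-seq plumbing: log-CPM with optional TMM, a simple internal
differential-expression test, BH adjustment and pseudobulk aggregation.

The internal DE test is a per-gene Welch t-test on log2-CPM values.  It
is deliberately NOT a reimplementation of the LIMMA-Voom moderated model
the original workflow uses; it exists so the signature machinery can be
exercised end-to-end on synthetic data, and externally produced DE tables
are accepted as first-class inputs everywhere downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def tmm_factors(
    counts: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values library-size correction factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each sample, gene-wise
    log-ratios (M) against the reference are trimmed two-sided by
    ``m_trim`` on M and ``a_trim`` on average log intensity (A), then
    combined as a precision-weighted mean.  Factors are normalized to have
    geometric mean 1; identical libraries therefore get factor 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    frac = mat / lib
    uq = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75) if (frac[:, j] > 0).any() else 0.0
                   for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        ok = (mat[:, j] > 0) & (mat[:, ref] > 0)
        if not ok.any():
            continue
        obs, r = mat[ok, j], mat[ok, ref]
        m = np.log2((obs / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((obs / lib[j]) * (r / lib[ref]))
        # asymptotic variance of M (delta method)
        w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref] - r) / (lib[ref] * r)
        keep = np.ones(m.size, dtype=bool)
        for vals, trim in ((m, m_trim), (a, a_trim)):
            lo, hi = np.quantile(vals, [trim, 1 - trim])
            keep &= (vals >= lo) & (vals <= hi)
        if not keep.any():
            continue
        factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, method: str = "cpm") -> pd.DataFrame:
    """log2 counts-per-million: log2((count + 0.5) / (libsize + 1) * 1e6).

    ``method="tmm-cpm"`` multiplies library sizes by TMM factors first.
    """
    if method not in ("cpm", "tmm-cpm"):
        raise ValueError(f"unknown method {method!r}")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    if method == "tmm-cpm":
        lib = lib * tmm_factors(counts).to_numpy()
    out = np.log2((mat + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def simple_de(
    log_expr: pd.DataFrame,
    group_labels,
    treated_label: str = "treated",
) -> pd.DataFrame:
    """Per-gene Welch t-test between two groups of log-expression columns.

    Returns a DE table with columns gene_id, log2_fc (treated minus
    control mean), p_value and adj_p (BH).  Genes with zero variance in
    both groups get p = 1 by convention.
    """
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    treated = labels == treated_label
    if treated_label not in groups:
        raise ValueError(f"no samples labelled {treated_label!r}")
    if treated.sum() < 2 or (~treated).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    a = log_expr.loc[:, treated].to_numpy(dtype=float)
    b = log_expr.loc[:, ~treated].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame({
        "gene_id": log_expr.index,
        "log2_fc": lfc,
        "p_value": p,
        "adj_p": bh_adjust(p),
    })


def pseudobulk_aggregate(
    cell_counts: pd.DataFrame, cell_to_sample: dict | pd.Series
) -> pd.DataFrame:
    """Sum per-cell counts (genes x cells) into per-sample counts.

    Every cell must map to exactly one sample; total counts are conserved.
    """
    mapping = pd.Series(cell_to_sample)
    missing = [c for c in cell_counts.columns if c not in mapping.index]
    if missing:
        raise ValueError(f"{len(missing)} cells unmapped (e.g. {missing[0]!r})")
    return cell_counts.T.groupby(mapping.loc[cell_counts.columns].to_numpy()).sum().T
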