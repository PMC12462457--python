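"""Derivation and scoring of directional senescence gene signatures.

A therapy-induced-senescence (TIS) signature is the intersection, across
every cell line x drug contrast supplied, of genes that are significantly
up- (or down-) regulated with consistent sign.  Per-drug variants
(CP_TIS, CX_TIS) come from restricting the contrast list to one drug;
the cross-drug intersection is the core HGSOC_TIS signature.

Samples are scored by the mean z-scored expression of the up genes minus
that of the down genes, and called signature-high when their score
exceeds the cohort median by more than k (default 2) raw median absolute
deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_DE_COLUMNS = ("gene_id", "log2_fc", "p_value", "adj_p")


@dataclass
class DETable:
    """One differential-expression contrast (treated vs control)."""

    table: pd.DataFrame
    cell_line: str = ""
    drug: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        if self.table.gene_id.duplicated().any():
            raise ValueError("duplicate gene_id in DE table")


@dataclass
class SignatureSet:
    """Directional gene signature with provenance."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    alpha: float
    contrasts_used: tuple[str, ...] = ()
    name: str = "TIS"

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets overlap")


def derive_signature(
    tables: list[DETable],
    alpha: float = 0.01,
    require_all: bool = True,
    name: str = "TIS",
) -> SignatureSet:
    """Intersect significant, sign-consistent genes across contrasts.

    up = genes with adj_p < alpha and log2_fc > 0 in EVERY table (down
    analogously).  A gene absent from any table fails that table.  With
    ``require_all=False`` a gene need only pass in at least one table and
    must never reach significance with the opposite sign in another.
    """
    if not tables:
        raise ValueError("at least one DE table required")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    up_sets, down_sets = [], []
    for t in tables:
        sig = t.table[t.table.adj_p < alpha]
        up_sets.append(set(sig.loc[sig.log2_fc > 0, "gene_id"]))
        down_sets.append(set(sig.loc[sig.log2_fc < 0, "gene_id"]))
    if require_all:
        up = set.intersection(*up_sets)
        down = set.intersection(*down_sets)
    else:
        up = set.union(*up_sets) - set.union(*down_sets)
        down = set.union(*down_sets) - set.union(*up_sets)
    contrasts = tuple(f"{t.cell_line}:{t.drug}" for t in tables)
    return SignatureSet(
        up=tuple(sorted(up)), down=tuple(sorted(down)),
        alpha=alpha, contrasts_used=contrasts, name=name,
    )


def recurrent_features(
    tables: list[DETable],
    fc_threshold: float = 1.5,
    require_significant: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank features by how many contrasts show a strong fold change.

    A contrast counts toward up-recurrence when its linear fold change
    exceeds ``fc_threshold`` (i.e. log2_fc > log2(threshold)) and toward
    down-recurrence when below -threshold (log2_fc < -log2(threshold)).
    With ``require_significant`` the contrast must also pass
    ``adj_p < alpha`` (the proteomics convention: |FC| > 1.5 and adjusted
    p < 0.05).  Returns a frame with n_up, n_down, n_total sorted by
    n_total (descending), ties broken by feature id.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    cut = np.log2(fc_threshold)
    counts: dict[str, list[int]] = {}
    for t in tables:
        tab = t.table
        if require_significant:
            tab = tab[tab.adj_p < alpha]
        for g, lfc in zip(tab.gene_id, tab.log2_fc):
            rec = counts.setdefault(g, [0, 0])
            if lfc > cut:
                rec[0] += 1
            elif lfc < -cut:
                rec[1] += 1
    df = pd.DataFrame(
        [(g, u, d, u + d) for g, (u, d) in counts.items()],
        columns=["feature_id", "n_up", "n_down", "n_total"],
    )
    return df.sort_values(
        ["n_total", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)


def score_signature(
    expr: pd.DataFrame, signature: SignatureSet
) -> pd.Series:
    """Per-sample signature scores from a genes x samples matrix.

    Each gene is z-scored across samples; the score is the mean over up
    genes minus the mean over down genes.  Genes absent from the matrix
    are skipped (and logged); zero-variance genes contribute 0.  Raises if
    no signature gene is present at all.
    """
    present_up = [g for g in signature.up if g in expr.index]
    present_down = [g for g in signature.down if g in expr.index]
    skipped = (set(signature.up) - set(present_up)) | (
        set(signature.down) - set(present_down)
    )
    if skipped:
        logger.warning("%d signature genes absent from matrix: %s",
                       len(skipped), sorted(skipped)[:5])
    if not present_up and not present_down:
        raise ValueError("no signature gene present in the matrix")

    def mean_z(genes: list[str]) -> np.ndarray:
        if not genes:
            return np.zeros(expr.shape[1])
        sub = expr.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        z = np.divide(sub - mu, sd, out=np.zeros_like(sub), where=sd > 0)
        return z.mean(axis=0)

    score = mean_z(present_up) - mean_z(present_down)
    return pd.Series(score, index=expr.columns, name=f"{signature.name}_score")


def classify_high(scores, k: float = 2.0) -> pd.Series:
    """Label samples 'high' when score > median + k * MAD (raw MAD).

    Raises for fewer than 3 scores or MAD = 0 (degenerate distribution).
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 scores")
    med = s.median()
    mad = (s - med).abs().median()
    if mad == 0:
        raise ValueError("MAD of scores is zero: classification degenerate")
    return pd.Series(
        np.where(s > med + k * mad, "high", "other"), index=s.index, name="class"
    )


def correlate_lfc(
    table_a: DETable | pd.DataFrame,
    table_b: DETable | pd.DataFrame,
    gene_subset=None,
) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes over shared genes.

    Returns (r, two-sided p from the t transform with n-2 df, n shared
    genes).  Requires at least 3 shared genes.
    """
    a = table_a.table if isinstance(table_a, DETable) else table_a
    b = table_b.table if isinstance(table_b, DETable) else table_b
    sa = a.set_index("gene_id").log2_fc
    sb = b.set_index("gene_id").log2_fc
    shared = sa.index.intersection(sb.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(gene_subset))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    r, p = stats.pearsonr(sa.loc[shared], sb.loc[shared])
    return float(r), float(p), int(len(shared))
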