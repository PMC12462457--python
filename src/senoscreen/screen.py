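"""Hit calling for the senolytic high-content screen.

Per-well viable-cell counts are fold-changed to the median of the DMSO
vehicle wells on the same plate (removing plate-level batch effects),
averaged across replicate plates, and converted to robust Z-scores

    Z = (value - median of all sample values) / MAD of all sample values

computed per condition x concentration stratum over compound (sample)
wells only.  A compound is a hit when Z <= -3 (default) in BOTH senescent
conditions at either tested concentration.  The MAD is the raw median
absolute deviation (no 1.4826 normal-consistency factor) unless
``scaled=True`` is requested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PlateNormalizationError(ValueError):
    """DMSO wells missing or degenerate on a plate."""


class DegenerateDistributionError(ValueError):
    """Robust statistics undefined (MAD = 0 or too few values)."""


def robust_z(values, scaled: bool = False) -> np.ndarray:
    """Robust Z-scores: (x - median) / MAD.

    Parameters
    ----------
    values : array-like, length >= 3
    scaled : multiply the MAD by 1.4826 (normal consistency) if True; the
        default follows the raw-MAD convention.

    Raises
    ------
    DegenerateDistributionError
        For fewer than 3 values or MAD = 0; no silent fallback.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDistributionError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateDistributionError("MAD is zero")
    if scaled:
        mad *= 1.4826
    return (x - med) / mad


def normalize_to_vehicle(counts: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    """Fold-change every well to the same-plate DMSO median count.

    ``counts`` needs columns plate_id, well_id, count; ``platemap`` the
    layout columns (plate_id, well_id, role, compound_id,
    concentration_uM, condition, replicate).  Returns the merged frame
    with a ``fold_change`` column.  DMSO wells are fold-changed to their
    own plate median too.
    """
    merged = platemap.merge(counts, on=["plate_id", "well_id"], how="left")
    if merged["count"].isna().any():
        missing = merged[merged["count"].isna()]
        logger.warning("%d wells missing counts; dropped", len(missing))
        merged = merged.dropna(subset=["count"])
    out = []
    for plate, grp in merged.groupby("plate_id", sort=False):
        dmso = grp.loc[grp.role == "dmso", "count"]
        if dmso.empty:
            raise PlateNormalizationError(f"plate {plate} has no DMSO wells")
        med = dmso.median()
        if med <= 0:
            raise PlateNormalizationError(f"plate {plate}: DMSO median is {med}")
        g = grp.copy()
        g["fold_change"] = g["count"] / med
        out.append(g)
    return pd.concat(out, ignore_index=True)


def summarize_replicates(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Mean fold change per compound x concentration x condition.

    Averages across replicate plates; a missing replicate produces a mean
    over the available ones with a logged warning.  Only sample wells are
    summarized.
    """
    samples = fold_changes[fold_changes.role == "sample"]
    grouped = samples.groupby(
        ["compound_id", "concentration_uM", "condition"], sort=False
    )
    summary = grouped.agg(
        mean_fold_change=("fold_change", "mean"),
        n_replicates=("fold_change", "size"),
    ).reset_index()
    expected = samples.replicate.nunique()
    short = summary[summary.n_replicates < expected]
    if not short.empty:
        logger.warning(
            "%d compound/concentration/condition groups have fewer than %d replicates",
            len(short), expected,
        )
    return summary


def score_screen(summary: pd.DataFrame, scaled: bool = False) -> pd.DataFrame:
    """Attach robust Z-scores, stratified per condition x concentration.

    The Z distribution is formed from compound (sample) mean fold changes
    only; controls never enter it.
    """
    out = summary.copy()
    out["robust_z"] = np.nan
    for (_, _), idx in out.groupby(["condition", "concentration_uM"], sort=False).groups.items():
        out.loc[idx, "robust_z"] = robust_z(
            out.loc[idx, "mean_fold_change"].to_numpy(), scaled=scaled
        )
    return out


def call_hits(
    scored: pd.DataFrame,
    z_threshold: float = -3.0,
    required_conditions: tuple[str, ...] = ("CP", "CX"),
) -> set[str]:
    """Compounds with Z <= threshold in every required condition at >= 1
    concentration ("either concentration tested").

    Compounds absent from a required condition are excluded with a
    warning.
    """
    best = scored.groupby(["compound_id", "condition"], sort=False).robust_z.min()
    hits: set[str] = set()
    for comp, sub in best.groupby(level="compound_id", sort=False):
        present = set(sub.index.get_level_values("condition"))
        if not set(required_conditions) <= present:
            logger.warning("compound %s missing from a required condition; excluded", comp)
            continue
        if all(sub[(comp, cond)] <= z_threshold for cond in required_conditions):
            hits.add(comp)
    return hits


def intersect_hits(hits_a: set[str], hits_b: set[str]) -> set[str]:
    """Compounds called in both screens."""
    return set(hits_a) & set(hits_b)


def analyze_screen(
    counts: pd.DataFrame,
    platemap: pd.DataFrame,
    z_threshold: float = -3.0,
    required_conditions: tuple[str, ...] = ("CP", "CX"),
    scaled: bool = False,
) -> tuple[pd.DataFrame, set[str]]:
    """counts + layout -> scored screen-result table and the hit set.

    The returned table has one row per compound x concentration x
    condition with mean_fold_change, n_replicates, robust_z and is_hit
    (the compound-level call, repeated on each of its rows).
    """
    fc = normalize_to_vehicle(counts, platemap)
    summary = summarize_replicates(fc)
    scored = score_screen(summary, scaled=scaled)
    hits = call_hits(scored, z_threshold, required_conditions)
    scored["is_hit"] = scored.compound_id.isin(hits)
    return scored, hits
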