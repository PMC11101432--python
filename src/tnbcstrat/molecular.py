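"""Centroid-correlation molecular subtype caller.

Expression profiles are normalized (quantile normalization across samples,
log2 transform of raw intensities, per-gene median centering) and each
sample is assigned the subtype whose centroid it correlates with best,
provided that correlation is significant; otherwise the sample is
unclassified (UNC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# argmax tie-break order
SUBTYPE_ORDER = ("LAR", "IM", "BL1", "M")

MIN_SHARED_GENES = 10


@dataclass(frozen=True)
class MolecularCall:
    """Per-sample call with its correlation evidence."""

    label: str
    correlations: dict[str, float]
    p_values: dict[str, float]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization across samples (columns).

    Each column is replaced by the mean of the sorted columns at its ranks;
    ties within a column receive the average of the tied rank means.
    """
    arr = matrix.to_numpy(dtype=float)
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        # average ranks for ties, then interpolate into the rank means
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), rank_means)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_expression(raw: pd.DataFrame, pre_logged: bool = False) -> pd.DataFrame:
    """Quantile-normalize, log2-transform (unless pre-logged) and median-center.

    ``raw`` is genes x samples.  Raw intensities must be strictly positive
    unless ``pre_logged`` is set.  Centering is per gene, so every gene's
    median across samples is 0 afterwards.
    """
    if raw.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if not pre_logged and (raw.to_numpy() <= 0).any():
        raise ValueError("raw intensities must be strictly positive for log2")
    norm = quantile_normalize(raw)
    if not pre_logged:
        norm = np.log2(norm)
    return norm.sub(norm.median(axis=1), axis=0)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def call_molecular_subtype(
    profile: pd.Series,
    centroids: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
) -> MolecularCall:
    """Call one sample against a genes x subtypes centroid matrix.

    The call is the subtype with the maximal correlation if its two-sided
    p-value is below ``alpha``; if no subtype reaches significance the call
    is UNC.  Profile and centroids are matched on gene id (inner join,
    at least 10 shared genes).
    """
    shared = profile.index.intersection(centroids.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between profile and centroids; "
            f"need >= {MIN_SHARED_GENES}"
        )
    x = profile.loc[shared].to_numpy(dtype=float)
    subtypes = [s for s in SUBTYPE_ORDER if s in centroids.columns]
    if not subtypes:
        raise ValueError("centroid matrix has no recognized subtype columns")
    if np.std(x) == 0:
        logger.warning("zero-variance profile %s: calling UNC", profile.name)
        nan = {s: float("nan") for s in subtypes}
        return MolecularCall("UNC", nan, {s: 1.0 for s in subtypes})
    correlations: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for s in subtypes:
        r, p = _correlate(x, centroids.loc[shared, s].to_numpy(dtype=float), method)
        correlations[s] = r
        p_values[s] = p
    best = max(subtypes, key=lambda s: (correlations[s], -subtypes.index(s)))
    label = best if p_values[best] < alpha else "UNC"
    return MolecularCall(label, correlations, p_values)


def call_cohort(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Call every sample (column) of a normalized genes x samples matrix.

    Returns one row per sample with the label and per-subtype correlation
    and p-value columns; logs the UNC fraction.
    """
    subtypes = [s for s in SUBTYPE_ORDER if s in centroids.columns]
    rows = []
    for sample in matrix.columns:
        call = call_molecular_subtype(matrix[sample], centroids, alpha, method)
        row: dict[str, object] = {"sample_id": sample, "label": call.label}
        for s in subtypes:
            row[f"r_{s}"] = call.correlations[s]
            row[f"p_{s}"] = call.p_values[s]
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "label"]
        + [f"r_{s}" for s in subtypes]
        + [f"p_{s}" for s in subtypes],
    )
    if len(out):
        unc = float((out["label"] == "UNC").mean())
        logger.info("molecular calls: %d samples, UNC fraction %.3f", len(out), unc)
    return out
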