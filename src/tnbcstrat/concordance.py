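"""Agreement between classifier calls and molecular truth.

The confusion table keeps the five molecular truth labels (including UNC)
as rows and the four classified groups as columns.  Percentage reports
include the UNC row in column denominators, but accuracy, kappa and the
per-class metrics exclude UNC-truth cases and score each classified group
against its corresponding molecular subtype (LAR-LAR, LP-IM, LI-BL1,
LD-M).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from tnbcstrat.labels import CLASSIFIED_LABELS, CORRESPONDENCE, MOLECULAR_LABELS

logger = logging.getLogger(__name__)


@dataclass
class ConfusionTable:
    """5 truth rows x 4 classified columns of counts."""

    counts: pd.DataFrame  # index MOLECULAR_LABELS, columns CLASSIFIED_LABELS

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def matched(self) -> pd.DataFrame:
        """4x4 truth x classified table after dropping the UNC truth row."""
        return self.counts.drop(index="UNC")


def crosstab(calls: pd.Series, truths: pd.Series) -> ConfusionTable:
    """Count cases by (molecular truth, classified label)."""
    calls = pd.Series(calls).reset_index(drop=True)
    truths = pd.Series(truths).reset_index(drop=True)
    if len(calls) != len(truths):
        raise ValueError("calls and truths must be the same length")
    bad_calls = set(calls) - set(CLASSIFIED_LABELS)
    bad_truths = set(truths) - set(MOLECULAR_LABELS)
    if bad_calls or bad_truths:
        raise ValueError(
            f"unknown labels: calls {sorted(bad_calls)}, truths {sorted(bad_truths)}"
        )
    table = (
        pd.crosstab(truths, calls)
        .reindex(index=MOLECULAR_LABELS, columns=CLASSIFIED_LABELS, fill_value=0)
        .astype(int)
    )
    table.index.name = "molecular_truth"
    table.columns.name = "classified"
    return ConfusionTable(table)


def _round_half_up(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    scale = 10.0**decimals
    # nextafter guards against values like 52.05 sitting a hair below the tie
    return np.floor(np.nextafter(x * scale, np.inf) + 0.5) / scale


def column_percentages(ct: ConfusionTable, decimals: int = 1) -> pd.DataFrame:
    """Within-column percentages (UNC row included in denominators), rounded half-up."""
    counts = ct.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, counts / totals * 100.0, np.nan)
    return pd.DataFrame(
        _round_half_up(pct, decimals), index=ct.counts.index, columns=ct.counts.columns
    )


def _matched_diagonal(ct: ConfusionTable) -> int:
    m = ct.matched()
    return int(sum(m.loc[CORRESPONDENCE[c], c] for c in CLASSIFIED_LABELS))


def overall_accuracy(
    ct: ConfusionTable, exclude_unc: bool = True, ci_method: str = "wilson"
) -> tuple[float, tuple[float, float]]:
    """Accuracy under the correspondence mapping, with a 95% binomial CI.

    ``ci_method`` is ``wilson`` (default) or ``clopper-pearson``.
    """
    table = ct.matched() if exclude_unc else ct.counts
    n = int(table.to_numpy().sum())
    if n == 0:
        raise ValueError("no cases left after UNC exclusion")
    hits = _matched_diagonal(ct)
    method = {"wilson": "wilson", "clopper-pearson": "beta"}[ci_method]
    lo, hi = proportion_confint(hits, n, alpha=0.05, method=method)
    return hits / n, (float(lo), float(hi))


def cohen_kappa(ct: ConfusionTable, exclude_unc: bool = True) -> float:
    """Unweighted Cohen's kappa on the 4x4 matched table.

    Classified labels are mapped to their corresponding molecular labels so
    both raters share the four molecular categories.  Returns NaN when the
    expected agreement is 1 (degenerate marginals).
    """
    m = (ct.matched() if exclude_unc else ct.counts).to_numpy(dtype=float)
    # reorder columns so column j corresponds to truth row j
    order = [MOLECULAR_LABELS.index(CORRESPONDENCE[c]) for c in CLASSIFIED_LABELS]
    sq = np.zeros((len(order), len(order)))
    for j, col in enumerate(m.T):
        sq[: len(col), order[j]] += col[: len(order)]
    n = sq.sum()
    if n == 0:
        raise ValueError("empty table")
    po = np.trace(sq) / n
    pe = float((sq.sum(axis=1) / n) @ (sq.sum(axis=0) / n))
    if pe == 1.0:
        logger.warning("degenerate marginals: kappa undefined")
        return float("nan")
    return (po - pe) / (1.0 - pe)


def per_class_metrics(ct: ConfusionTable, exclude_unc: bool = True) -> pd.DataFrame:
    """One-vs-rest precision, recall, F1 and balanced accuracy per classified group."""
    m = (ct.matched() if exclude_unc else ct.counts).astype(float)
    n = m.to_numpy().sum()
    rows = []
    for c in CLASSIFIED_LABELS:
        truth = CORRESPONDENCE[c]
        tp = m.loc[truth, c] if truth in m.index else 0.0
        col_total = m[c].sum()
        row_total = m.loc[truth].sum() if truth in m.index else 0.0
        fp = col_total - tp
        fn = row_total - tp
        tn = n - tp - fp - fn
        precision = tp / col_total if col_total > 0 else float("nan")
        recall = tp / row_total if row_total > 0 else float("nan")
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = float("nan")
        else:
            f1 = 2 * precision * recall / (precision + recall)
        specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        balanced = (recall + specificity) / 2.0
        if np.isnan(precision) or np.isnan(recall):
            logger.info("class %s: zero denominator, metric reported as NA", c)
        rows.append(
            {
                "classified": c,
                "molecular": truth,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "balanced_accuracy": balanced,
            }
        )
    return pd.DataFrame(rows).set_index("classified")
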