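"""The shipped LAR/LP/LI/LD decision rule and its table application."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tnbcstrat import scoring
from tnbcstrat.scoring import TIL_HIGH_CUT, TIL_LOW_CUT

logger = logging.getLogger(__name__)

ALLRED_CUTOFF = 6


def classify(
    allred_total: int,
    til_percent: float,
    allred_cutoff: int = ALLRED_CUTOFF,
    til_cutoffs: tuple[float, float] = (TIL_LOW_CUT, TIL_HIGH_CUT),
) -> str:
    """Classify one case: Allred total >= cutoff -> LAR, else by TIL stratum.

    With the default cut-offs, non-LAR cases map TIL >= 60 -> LP,
    20 <= TIL < 60 -> LI and TIL < 20 -> LD.
    """
    low, high = til_cutoffs
    if not low < high:
        raise ValueError(f"til_cutoffs must be increasing, got {til_cutoffs!r}")
    if not 0 <= allred_total <= 8:
        raise ValueError(f"allred_total must be in 0..8, got {allred_total!r}")
    if not 0.0 <= til_percent <= 100.0:
        raise ValueError(f"til_percent must be in [0, 100], got {til_percent!r}")
    if allred_total >= allred_cutoff:
        return "LAR"
    if til_percent >= high:
        return "LP"
    if til_percent >= low:
        return "LI"
    return "LD"


def classify_table(
    cases: pd.DataFrame,
    allred_cutoff: int = ALLRED_CUTOFF,
    til_cutoffs: tuple[float, float] = (TIL_LOW_CUT, TIL_HIGH_CUT),
) -> pd.DataFrame:
    """Apply the decision rule to a case table.

    Scores AR/TIL columns first if needed (adding ``allred_total`` and
    ``til_range``) and appends a ``classified`` column.  Rows with missing
    AR or TIL readings are excluded from the output, one log entry each.
    """
    if len(cases) == 0:
        out = cases.copy()
        out["classified"] = pd.Series(dtype="object")
        return out
    scored = cases if "allred_total" in cases.columns else scoring.score_table(cases)
    til = pd.to_numeric(scored["til_percent"], errors="coerce")
    missing = scored["allred_total"].isna() | til.isna()
    for case_id in scored.index[missing]:
        ident = scored.loc[case_id].get("case_id", case_id)
        logger.warning("excluding case %s: missing AR or TIL reading", ident)
    kept = scored.loc[~missing].copy()
    low, high = til_cutoffs
    til = til.loc[kept.index].to_numpy(dtype=float)
    is_lar = kept["allred_total"].astype(int).to_numpy() >= allred_cutoff
    kept["classified"] = np.select(
        [is_lar, til >= high, til >= low], ["LAR", "LP", "LI"], default="LD"
    )
    return kept
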