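"""Allred scoring of AR immunohistochemistry and stromal-TIL binning.

The Allred score is the sum of a proportion score (0-5, from the percentage
of positive tumor nuclei) and an intensity score (0-3, from the nuclear
staining intensity), giving a total of 0-8.  Stromal TIL percentages are
binned into three strata with cut-offs at 20% and 60%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tnbcstrat.labels import INTENSITY_LEVELS

# Proportion-score bin upper edges: 0 -> 0, (0,1] -> 1, (1,10] -> 2,
# (10,33] -> 3, (33,66] -> 4, (66,100] -> 5.  Half-open on the left so the
# whole continuum [0,100] is covered.
_PROPORTION_EDGES = (0.0, 1.0, 10.0, 33.0, 66.0)

_INTENSITY_POINTS = {level: i for i, level in enumerate(INTENSITY_LEVELS)}

TIL_LOW_CUT = 20.0
TIL_HIGH_CUT = 60.0


@dataclass(frozen=True)
class AllredScore:
    """Composite AR immunohistochemistry score."""

    proportion_score: int
    intensity_score: int

    @property
    def total(self) -> int:
        return self.proportion_score + self.intensity_score


def proportion_score(ar_percent: float) -> int:
    """Score the percentage of AR-positive nuclei on the 0-5 scale."""
    if not 0.0 <= ar_percent <= 100.0:
        raise ValueError(f"ar_percent must be in [0, 100], got {ar_percent!r}")
    score = 0
    for edge in _PROPORTION_EDGES:
        if ar_percent > edge:
            score += 1
    return score


def intensity_score(level: str) -> int:
    """Score nuclear staining intensity: negative/weak/intermediate/strong -> 0-3."""
    try:
        return _INTENSITY_POINTS[level]
    except KeyError:
        raise ValueError(
            f"unknown intensity level {level!r}; expected one of {INTENSITY_LEVELS}"
        ) from None


def allred_total(ar_percent: float, level: str) -> AllredScore:
    """Combine proportion and intensity scores into the 0-8 Allred score."""
    return AllredScore(proportion_score(ar_percent), intensity_score(level))


def til_group(til_percent: float) -> str:
    """Bin a stromal TIL percentage: >=60 LP_range, [20,60) LI_range, <20 LD_range."""
    if not 0.0 <= til_percent <= 100.0:
        raise ValueError(f"til_percent must be in [0, 100], got {til_percent!r}")
    if til_percent >= TIL_HIGH_CUT:
        return "LP_range"
    if til_percent >= TIL_LOW_CUT:
        return "LI_range"
    return "LD_range"


def score_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring over a case table.

    Requires columns ``ar_percent``, ``ar_intensity`` and ``til_percent``;
    returns a copy with ``allred_proportion``, ``allred_intensity``,
    ``allred_total`` and ``til_range`` columns appended.  Rows with missing
    inputs get NA scores (downstream classification excludes them).
    """
    out = cases.copy()
    ar = pd.to_numeric(out["ar_percent"], errors="coerce")
    til = pd.to_numeric(out["til_percent"], errors="coerce")

    bad_ar = ar.notna() & ((ar < 0) | (ar > 100))
    bad_til = til.notna() & ((til < 0) | (til > 100))
    if bad_ar.any() or bad_til.any():
        raise ValueError(
            "out-of-range readings in rows "
            f"{sorted(out.index[bad_ar | bad_til].tolist())}"
        )

    prop = np.searchsorted(_PROPORTION_EDGES, ar.to_numpy(dtype=float), side="left")
    prop = pd.Series(prop, index=out.index, dtype="float").where(ar.notna())
    inten = out["ar_intensity"].map(_INTENSITY_POINTS)

    out["allred_proportion"] = prop.astype("Int64")
    out["allred_intensity"] = inten.astype("Int64")
    out["allred_total"] = (out["allred_proportion"] + out["allred_intensity"]).astype(
        "Int64"
    )
    out["til_range"] = pd.Series(
        np.select(
            [til >= TIL_HIGH_CUT, til >= TIL_LOW_CUT, til >= 0],
            ["LP_range", "LI_range", "LD_range"],
            default=None,
        ),
        index=out.index,
        dtype="object",
    )
    return out
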