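"""Kaplan-Meier estimation, log-rank tests and Cox proportional-hazards fits.

Thin, contract-enforcing wrappers around lifelines.  The Cox model uses
Efron tie handling and encodes the subtype with LP as the reference level
so subtype contrasts read as LAR-vs-LP, LI-vs-LP and LD-vs-LP hazard
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from tnbcstrat.labels import CLASSIFIED_LABELS

REFERENCE_GROUP = "LP"


@dataclass
class CoxResult:
    """Per-term hazard ratios with Wald 95% CIs and p-values."""

    terms: pd.DataFrame  # index term, columns hr, ci_low, ci_high, p
    reference: str


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event/censoring time with columns ``time``,
    ``survival`` and ``at_risk``.  Survival starts at 1 and is a
    nonincreasing right-continuous step function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one sample")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    distinct = np.unique(times)
    out = pd.DataFrame(
        {
            "time": distinct,
            "survival": kmf.survival_function_at_times(distinct).to_numpy(dtype=float),
            "at_risk": [(times >= t).sum() for t in distinct],
        }
    )
    return out.reset_index(drop=True)


def logrank(times, events, groups) -> tuple[float, int, float]:
    """Unweighted K-group log-rank test: (chi-square, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def cox_fit(
    samples: pd.DataFrame,
    duration_col: str,
    event_col: str,
    group_col: str = "classified",
    covariates: list[str] | None = None,
    reference: str = REFERENCE_GROUP,
) -> CoxResult:
    """Multivariable Cox PH fit with Efron ties and a categorical group term.

    The group column is dummy-encoded against ``reference``; optional numeric
    covariate columns are entered as-is.  Warns when the number of events is
    below the number of terms.
    """
    covariates = covariates or []
    df = samples[[duration_col, event_col, group_col, *covariates]].dropna().copy()
    levels = [g for g in CLASSIFIED_LABELS if g in set(df[group_col])]
    if reference not in levels:
        levels = sorted(set(df[group_col]))
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from data")
    design = df[[duration_col, event_col, *covariates]].copy()
    term_names = []
    for level in levels:
        if level == reference:
            continue
        name = f"{group_col}[{level}]"
        design[name] = (df[group_col] == level).astype(float)
        term_names.append(name)
    term_names.extend(covariates)
    for term in term_names:
        if design[term].std() == 0:
            raise ValueError(f"term {term!r} has zero variance")
    n_events = int(design[event_col].sum())
    if n_events < len(term_names):
        import warnings

        warnings.warn(
            f"only {n_events} events for {len(term_names)} terms; "
            "estimates may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    cph.fit(design, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    terms = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    terms.index.name = "term"
    return CoxResult(terms=terms, reference=reference)
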