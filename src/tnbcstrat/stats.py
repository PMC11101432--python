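"""Signature scoring and group comparisons across classified subtypes.

Covers per-sample gene-set scores (ssGSEA-style rank enrichment or mean
z-score), one-way ANOVA with Benjamini-Hochberg adjustment, pairwise
post-hoc t-tests, exact tests of alteration frequencies (Fisher with the
Freeman-Halton extension for more than two groups) and Kruskal-Wallis /
rank-sum comparisons of continuous scores such as HRD.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# signature scoring


def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float = 0.25) -> float:
    """Rank-weighted running-sum enrichment for one sample.

    Genes are ordered by decreasing expression; the score is the summed
    difference between the weighted in-set ECDF (weights = rank^alpha) and
    the unweighted out-of-set ECDF, normalized by the number of genes.
    """
    n = len(expr)
    order = np.argsort(-expr, kind="stable")
    in_sorted = in_set[order]
    # descending rank weights: the top-expressed gene carries rank n
    weights = np.arange(n, 0, -1, dtype=float) ** alpha
    w_in = np.where(in_sorted, weights, 0.0)
    denom_in = w_in.sum()
    n_out = n - in_set.sum()
    if denom_in == 0 or n_out == 0:
        return float("nan")
    ecdf_in = np.cumsum(w_in) / denom_in
    ecdf_out = np.cumsum(~in_sorted) / n_out
    return float((ecdf_in - ecdf_out).sum() / n)


def signature_scores(
    expr: pd.DataFrame, genesets: dict[str, list[str]], method: str = "ssgsea"
) -> pd.DataFrame:
    """Score gene sets per sample on a genes x samples matrix.

    ``method`` is ``ssgsea`` (rank enrichment, exponent 0.25) or ``mean_z``
    (mean of per-gene z-scores across samples).  Sets with no genes in the
    matrix yield an all-NA row with a warning.
    """
    if method not in ("ssgsea", "mean_z"):
        raise ValueError(f"unknown scoring method {method!r}")
    values = expr.to_numpy(dtype=float)
    if method == "mean_z":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = pd.DataFrame((values - mu) / sd, index=expr.index, columns=expr.columns)
    rows = {}
    usable = 0
    for name, genes in genesets.items():
        members = expr.index.intersection(pd.Index(genes).unique())
        if len(members) == 0:
            logger.warning("gene set %s has no overlap with the matrix", name)
            rows[name] = np.full(expr.shape[1], np.nan)
            continue
        usable += 1
        if method == "mean_z":
            rows[name] = z.loc[members].mean(axis=0).to_numpy()
        else:
            in_set = expr.index.isin(members)
            rows[name] = np.array(
                [_ssgsea_sample(values[:, j], in_set) for j in range(values.shape[1])]
            )
    if usable == 0:
        raise ValueError("no gene set overlaps the expression matrix")
    out = pd.DataFrame(rows, index=expr.columns).T
    out.index.name = "signature"
    out.attrs["method"] = method
    return out


# ---------------------------------------------------------------------------
# group tests on scores


def group_anova_fdr(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way ANOVA per signature with BH adjustment across signatures."""
    groups = pd.Series(groups, index=scores.columns)
    labels = pd.unique(groups)
    if len(labels) < 2 or any((groups == g).sum() < 2 for g in labels):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    raw = []
    for _, row in scores.iterrows():
        arrays = [row[groups == g].dropna().to_numpy(dtype=float) for g in labels]
        if any(len(a) < 2 for a in arrays) or np.ptp(np.concatenate(arrays)) == 0:
            raw.append(np.nan)
            continue
        stat, p = stats.f_oneway(*arrays)
        raw.append(p if np.isfinite(p) else np.nan)
    raw = np.asarray(raw, dtype=float)
    adjusted = np.full_like(raw, np.nan)
    ok = np.isfinite(raw)
    if ok.any():
        adjusted[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"p_raw": raw, "p_adjusted": adjusted, "significant": adjusted < 0.05},
        index=scores.index,
    )


def posthoc_pairwise_t(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """All pairwise two-sided Student t-tests per signature.

    Returns long format: signature, group_a, group_b, p.  Pairs with a
    group of fewer than two samples are skipped with a warning.
    """
    groups = pd.Series(groups, index=scores.columns)
    labels = list(pd.unique(groups))
    records = []
    for name, row in scores.iterrows():
        for a, b in itertools.combinations(labels, 2):
            xa = row[groups == a].dropna().to_numpy(dtype=float)
            xb = row[groups == b].dropna().to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                logger.warning("skipping %s %s-vs-%s: group too small", name, a, b)
                continue
            _, p = stats.ttest_ind(xa, xb)
            records.append(
                {"signature": name, "group_a": a, "group_b": b, "p": float(p)}
            )
    return pd.DataFrame(records, columns=["signature", "group_a", "group_b", "p"])


# ---------------------------------------------------------------------------
# exact tests of alteration frequencies


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_rx2(
    altered: np.ndarray,
    totals: np.ndarray,
    max_tables: int = 2_000_000,
    mc_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """Exact (Freeman-Halton) p for an R x 2 table of altered/total counts.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more likely than the observed table.  When the
    enumeration would exceed ``max_tables`` the p-value is estimated by
    Monte Carlo from the multivariate hypergeometric null.
    """
    altered = np.asarray(altered, dtype=int)
    totals = np.asarray(totals, dtype=int)
    if (altered < 0).any() or (altered > totals).any():
        raise ValueError("altered counts must satisfy 0 <= altered <= total")
    c1 = int(altered.sum())
    n = int(totals.sum())
    if c1 == 0 or c1 == n:
        return 1.0
    log_denom = _log_binom(np.array(n), np.array(c1))
    logp_obs = float(_log_binom(totals, altered).sum() - log_denom)

    # enumeration size estimate
    size = 1.0
    for t in totals[:-1]:
        size *= min(t, c1) + 1
    if size > max_tables:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(totals, c1, size=mc_draws)
        logp = _log_binom(totals[None, :], draws).sum(axis=1) - log_denom
        return float(np.mean(logp <= logp_obs + 1e-9))

    total_p = 0.0
    tol = 1e-9

    def _enumerate(i: int, remaining: int, logp: float) -> None:
        nonlocal total_p
        if i == len(totals) - 1:
            if 0 <= remaining <= totals[i]:
                lp = logp + float(_log_binom(totals[i], np.array(remaining)))
                if lp - log_denom <= logp_obs + tol:
                    total_p += np.exp(lp - log_denom)
            return
        upper = min(totals[i], remaining)
        lower = max(0, remaining - int(totals[i + 1 :].sum()))
        for a in range(lower, upper + 1):
            _enumerate(
                i + 1, remaining - a, logp + float(_log_binom(totals[i], np.array(a)))
            )

    _enumerate(0, c1, 0.0)
    return float(min(total_p, 1.0))


def alteration_tests(alterations: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-event exact test of frequency differences across groups.

    ``alterations`` is an events x samples binary matrix; ``groups`` maps
    sample id to classified subtype.  Events absent from every sample are
    skipped with a log entry.  Returns per-event raw and BH-adjusted p plus
    per-group frequencies.
    """
    groups = pd.Series(groups, index=alterations.columns)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    totals = np.array([(groups == g).sum() for g in labels], dtype=int)
    records = []
    for event, row in alterations.iterrows():
        vals = row.to_numpy(dtype=int)
        if vals.sum() == 0:
            logger.info("event %s absent in all samples; skipped", event)
            continue
        altered = np.array(
            [int(vals[(groups == g).to_numpy()].sum()) for g in labels], dtype=int
        )
        p = fisher_exact_rx2(altered, totals)
        rec = {"event": event, "p_raw": p}
        for g, a, t in zip(labels, altered, totals):
            rec[f"freq_{g}"] = a / t if t else float("nan")
        records.append(rec)
    out = pd.DataFrame(records)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < 0.05
        out = out.set_index("event")
    return out


# ---------------------------------------------------------------------------
# continuous-score comparisons (e.g. HRD)


def hrd_compare(
    scores: pd.Series, groups: pd.Series, paired: bool = False
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across groups plus BH-adjusted pairwise rank tests.

    Returns (KW statistic, KW p, pairwise table).  The pairwise test is the
    two-sample rank-sum (Mann-Whitney) test; ``paired=True`` switches to the
    signed-rank test and requires equal-size, aligned groups.
    """
    groups = pd.Series(groups, index=scores.index)
    labels = list(pd.unique(groups))
    arrays = {g: scores[groups == g].dropna().to_numpy(dtype=float) for g in labels}
    if len(labels) < 2 or any(len(a) < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:
        logger.warning("all scores tied: KW p undefined")
        return float("nan"), float("nan"), pd.DataFrame()
    kw_stat, kw_p = stats.kruskal(*arrays.values())
    records = []
    for a, b in itertools.combinations(labels, 2):
        if paired:
            if len(arrays[a]) != len(arrays[b]):
                raise ValueError("paired test requires equal-size groups")
            _, p = stats.wilcoxon(arrays[a], arrays[b])
        else:
            _, p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        records.append({"group_a": a, "group_b": b, "p_raw": float(p)})
    pairwise = pd.DataFrame(records)
    pairwise["p_adjusted"] = multipletests(pairwise["p_raw"].to_numpy(), method="fdr_bh")[1]
    return float(kw_stat), float(kw_p), pairwise
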