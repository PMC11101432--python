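"""Synthetic cohorts with the statistical structure the pipeline assumes.

Provides a deterministic 317-case fixture that reproduces the published
classifier-vs-molecular cross-tabulation cell for cell, plus seeded
generators for case tables (AR/TIL readings, molecular truth, exponential
proportional-hazards survival), centroid-plus-noise expression matrices and
Bernoulli alteration matrices with HRD-like continuous scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from tnbcstrat.classifier import classify
from tnbcstrat.labels import CLASSIFIED_LABELS, MOLECULAR_LABELS
from tnbcstrat.molecular import SUBTYPE_ORDER
from tnbcstrat.scoring import allred_total

ENDPOINTS = ("os", "rfs", "dfs")

# canonical per-column readings for the deterministic fixture
_FIXTURE_READINGS = {
    "LAR": {"ar_percent": 80.0, "ar_intensity": "strong", "til_percent": 10.0},
    "LP": {"ar_percent": 0.0, "ar_intensity": "negative", "til_percent": 70.0},
    "LI": {"ar_percent": 0.0, "ar_intensity": "negative", "til_percent": 40.0},
    "LD": {"ar_percent": 0.0, "ar_intensity": "negative", "til_percent": 10.0},
}

CASE_COLUMNS = [
    "case_id",
    "ar_percent",
    "ar_intensity",
    "til_percent",
    "p16_pattern",
    "molecular_truth",
    "time_os",
    "event_os",
    "time_rfs",
    "event_rfs",
    "time_dfs",
    "event_dfs",
]


def _load_calibration() -> dict:
    text = resources.files("tnbcstrat").joinpath("data/default_cohort.yaml").read_text()
    return yaml.safe_load(text)


def reference_crosstab() -> pd.DataFrame:
    """The published 5x4 cross-tabulation (molecular rows x classified columns)."""
    cal = _load_calibration()["crosstab"]
    table = pd.DataFrame(
        {row: cal["counts"][row] for row in cal["rows"]},
        index=cal["columns"],
    ).T
    table.index.name = "molecular_truth"
    table.columns.name = "classified"
    return table


def reference_cohort() -> pd.DataFrame:
    """Deterministic 317-case fixture realizing the reference cross-tabulation.

    AR/TIL readings take fixed canonical values per classified column, so the
    decision rule routes each case to its intended column and repeated calls
    return byte-identical tables.  Survival fields are filled with a fixed
    formula (they carry no information; cohort generators produce model-based
    survival).
    """
    table = reference_crosstab()
    rows = []
    i = 0
    for truth in table.index:
        for column in table.columns:
            for _ in range(int(table.loc[truth, column])):
                readings = _FIXTURE_READINGS[column]
                time = 24.0 + (i % 60)
                rows.append(
                    {
                        "case_id": f"case{i:03d}",
                        **readings,
                        "p16_pattern": "negative",
                        "molecular_truth": truth,
                        "time_os": time,
                        "event_os": i % 2,
                        "time_rfs": time * 0.75,
                        "event_rfs": (i + 1) % 2,
                        "time_dfs": time * 0.8,
                        "event_dfs": i % 2,
                    }
                )
                i += 1
    return pd.DataFrame(rows, columns=CASE_COLUMNS)


@dataclass
class CohortConfig:
    """Sampling configuration for :func:`generate_cohort`.

    ``ar_conditionals`` maps molecular truth to a list of
    ``(probability, ar_percent, ar_intensity)`` triples; ``til_conditionals``
    maps truth to a ``{til_percent: probability}`` distribution.  ``hr_map``
    holds per-endpoint hazard ratios keyed by classified subtype relative to
    LP.
    """

    n_cases: int
    subtype_priors: dict[str, float]
    ar_conditionals: dict[str, list[tuple[float, float, str]]]
    til_conditionals: dict[str, dict[float, float]]
    hr_map: dict[str, dict[str, float]]
    baseline_hazard: float
    censor_rate: float
    til_increments: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be nonnegative")
        total = sum(self.subtype_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_priors must sum to 1, got {total}")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be positive")
        for endpoint, hrs in self.hr_map.items():
            for subtype, hr in hrs.items():
                if hr <= 0:
                    raise ValueError(f"hazard ratio {endpoint}/{subtype} must be > 0")
        for truth in self.subtype_priors:
            if truth not in MOLECULAR_LABELS:
                raise ValueError(f"unknown molecular label {truth!r}")


def default_cohort_config(n_cases: int = 500, seed: int = 0) -> CohortConfig:
    """Config calibrated to the reference cross-tabulation and reported HRs.

    Priors are the molecular row totals; the probability of an AR-high
    reading given truth equals the LAR-column share of that row, and TIL
    values spread the remaining column shares uniformly within each TIL
    stratum, so P(classified | truth) matches the reference table.
    """
    cal = _load_calibration()
    table = reference_crosstab()
    row_totals = table.sum(axis=1)
    grand = float(row_totals.sum())
    priors = {t: float(row_totals[t]) / grand for t in table.index}

    ar_high = [tuple(v) for v in cal["ar_high_values"]]
    ar_low = tuple(cal["ar_low_value"])
    til_values = {k: list(v) for k, v in cal["til_values"].items()}
    range_for_column = {"LP": "LP_range", "LI": "LI_range", "LD": "LD_range"}

    ar_conditionals = {}
    til_conditionals = {}
    for truth in table.index:
        p_high = float(table.loc[truth, "LAR"]) / float(row_totals[truth])
        cond = [(p_high / len(ar_high), float(p), inten) for p, inten in ar_high]
        cond.append((1.0 - p_high, float(ar_low[0]), ar_low[1]))
        ar_conditionals[truth] = cond
        non_lar = float(row_totals[truth] - table.loc[truth, "LAR"])
        dist: dict[float, float] = {}
        for column, range_name in range_for_column.items():
            share = float(table.loc[truth, column]) / non_lar if non_lar else 0.0
            values = til_values[range_name]
            for v in values:
                dist[float(v)] = dist.get(float(v), 0.0) + share / len(values)
        til_conditionals[truth] = dist

    return CohortConfig(
        n_cases=n_cases,
        subtype_priors=priors,
        ar_conditionals=ar_conditionals,
        til_conditionals=til_conditionals,
        hr_map={e: dict(cal["hazard_ratios"][e]) for e in ENDPOINTS},
        baseline_hazard=float(cal["baseline_hazard"]),
        censor_rate=float(cal["censor_rate"]),
        seed=seed,
    )


def _draw_categorical(rng: np.random.Generator, items: list, probs: list[float]):
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    return items[int(rng.choice(len(items), p=probs))]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample a case table under the configured joint distribution.

    Molecular truth comes from the priors, AR/TIL readings from the
    truth-conditional distributions (TIL snapped to 10% increments by
    default), and survival from an exponential proportional-hazards model
    driven by the *classified* subtype, with independent exponential
    censoring.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = list(config.subtype_priors)
    prior = [config.subtype_priors[t] for t in truths]
    rows = []
    for i in range(config.n_cases):
        truth = _draw_categorical(rng, truths, prior)
        ar_opts = config.ar_conditionals[truth]
        _, ar_percent, intensity = _draw_categorical(
            rng, ar_opts, [p for p, _, _ in ar_opts]
        )
        til_dist = config.til_conditionals[truth]
        til = float(
            _draw_categorical(rng, list(til_dist), list(til_dist.values()))
        )
        if config.til_increments:
            til = float(np.round(til / 10.0) * 10.0)
        label = classify(allred_total(ar_percent, intensity).total, til)
        row = {
            "case_id": f"sim{i:05d}",
            "ar_percent": float(ar_percent),
            "ar_intensity": intensity,
            "til_percent": til,
            "p16_pattern": _draw_categorical(
                rng,
                ["negative", "weak_mosaic", "diffuse_strong"],
                [0.5, 0.3, 0.2],
            ),
            "molecular_truth": truth,
        }
        for endpoint in ENDPOINTS:
            rate = config.baseline_hazard * config.hr_map[endpoint].get(label, 1.0)
            event_time = rng.exponential(1.0 / rate)
            censor_time = rng.exponential(1.0 / config.censor_rate)
            row[f"time_{endpoint}"] = float(min(event_time, censor_time))
            row[f"event_{endpoint}"] = int(event_time <= censor_time)
        rows.append(row)
    return pd.DataFrame(rows, columns=CASE_COLUMNS)


def generate_expression(
    cases: pd.DataFrame,
    n_genes: int = 200,
    centroid_sep: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centroid-plus-noise expression profiles for a case table.

    Four near-orthogonal block centroids (one per molecular subtype, block
    height ``centroid_sep``) define the means; each non-UNC sample is its
    truth centroid plus N(0, noise_sd) noise, and UNC-truth samples are pure
    noise.  Returns (genes x samples matrix, genes x 4 centroid matrix).
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes to distinguish four centroids")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    centroids = pd.DataFrame(0.0, index=genes, columns=list(SUBTYPE_ORDER))
    block = n_genes // 4
    for k, subtype in enumerate(SUBTYPE_ORDER):
        start = k * block
        stop = (k + 1) * block if k < 3 else n_genes
        centroids.iloc[start:stop, k] = centroid_sep
    noise_scale = noise_sd if noise_sd > 0 else 1.0
    profiles = {}
    for _, case in cases.iterrows():
        truth = case["molecular_truth"]
        if truth == "UNC":
            profile = rng.normal(0.0, noise_scale, n_genes)
        else:
            profile = centroids[truth].to_numpy() + rng.normal(0.0, noise_sd, n_genes)
        profiles[case["case_id"]] = profile
    expr = pd.DataFrame(profiles, index=genes)
    return expr, centroids


DEFAULT_ALTERATION_FREQS = pd.DataFrame(
    [
        # gene, event_type, then per-subtype Bernoulli frequency
        ("PIK3CA", "mutation", {"LAR": 0.55, "LP": 0.15, "LI": 0.15, "LD": 0.15}),
        ("CD274", "deletion", {"LAR": 0.30, "LP": 0.05, "LI": 0.05, "LD": 0.05}),
        ("PDCD1LG2", "deletion", {"LAR": 0.30, "LP": 0.05, "LI": 0.05, "LD": 0.05}),
        ("B2M", "deletion", {"LAR": 0.05, "LP": 0.25, "LI": 0.05, "LD": 0.05}),
        ("NOTCH2", "amplification", {"LAR": 0.05, "LP": 0.05, "LI": 0.05, "LD": 0.30}),
        ("MYC", "amplification", {"LAR": 0.15, "LP": 0.15, "LI": 0.20, "LD": 0.50}),
        ("TP53", "mutation", {"LAR": 0.60, "LP": 0.80, "LI": 0.80, "LD": 0.80}),
    ],
    columns=["gene", "event_type", "freqs"],
)

# HRD-like score distributions (mean, sd) per classified subtype;
# LAR low, LD high by default.
DEFAULT_HRD_PARAMS = {
    "LAR": (10.0, 8.0),
    "LP": (25.0, 10.0),
    "LI": (30.0, 10.0),
    "LD": (45.0, 12.0),
}


def generate_alterations(
    cases: pd.DataFrame,
    freq_table: pd.DataFrame | None = None,
    hrd_params: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Bernoulli alteration matrix plus HRD-like scores per case.

    ``cases`` must carry a ``classified`` column; frequencies and HRD normal
    parameters are keyed by that label.  The alteration matrix is events
    (``gene:event_type``) x samples, binary.
    """
    if "classified" not in cases.columns:
        raise ValueError("cases must carry a 'classified' column")
    freq_table = DEFAULT_ALTERATION_FREQS if freq_table is None else freq_table
    hrd_params = DEFAULT_HRD_PARAMS if hrd_params is None else hrd_params
    labels = cases["classified"].tolist()
    unknown = set(labels) - set(CLASSIFIED_LABELS)
    if unknown:
        raise ValueError(f"unknown subtype keys {sorted(unknown)}")
    for row in freq_table.itertuples():
        bad = [f for f in row.freqs.values() if not 0.0 <= f <= 1.0]
        if bad:
            raise ValueError(f"frequencies outside [0,1]: {bad}")
        missing = set(labels) - set(row.freqs)
        if missing:
            raise ValueError(f"{row.gene}:{row.event_type} lacks keys {sorted(missing)}")
    missing_hrd = set(labels) - set(hrd_params)
    if missing_hrd:
        raise ValueError(f"hrd_params lacks keys {sorted(missing_hrd)}")

    rng = np.random.default_rng(seed)
    sample_ids = cases["case_id"].tolist()
    data = {}
    for row in freq_table.itertuples():
        if all(f == 0.0 for f in row.freqs.values()):
            continue  # impossible event: leave it out of the matrix
        probs = np.array([row.freqs[lab] for lab in labels])
        data[f"{row.gene}:{row.event_type}"] = (
            rng.random(len(labels)) < probs
        ).astype(int)
    alterations = pd.DataFrame(data, index=sample_ids, dtype=int).T
    means = np.array([hrd_params[lab][0] for lab in labels])
    sds = np.array([hrd_params[lab][1] for lab in labels])
    hrd = pd.Series(rng.normal(means, sds), index=sample_ids, name="hrd_score")
    return alterations, hrd
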