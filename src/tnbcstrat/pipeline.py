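"""End-to-end orchestration: simulate/ingest, score, classify, call, compare.

A single YAML-serializable :class:`RunConfig` drives every stage; each run
writes its artifacts plus a manifest (config echo, seed, package version and
a checksum per output file) so deterministic stages re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tnbcstrat
from tnbcstrat import concordance as conc
from tnbcstrat import io as tio
from tnbcstrat import stats as tstats
from tnbcstrat import survival as tsurv
from tnbcstrat.classifier import classify_table
from tnbcstrat.molecular import call_cohort, normalize_expression
from tnbcstrat.synthetic import (
    default_cohort_config,
    generate_alterations,
    generate_cohort,
    generate_expression,
    reference_cohort,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "input",
    "thresholds",
    "stages",
    "molecular",
}
_KNOWN_INPUT = {"kind", "n_cases", "cases_path"}
_KNOWN_THRESHOLDS = {"allred_cutoff", "til_cutoffs", "alpha", "fdr_q"}
_KNOWN_STAGES = {"molecular", "survival", "downstream"}
_KNOWN_MOLECULAR = {"n_genes", "centroid_sep", "noise_sd", "expression_path", "centroids_path"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "runs/out"
    input_kind: str = "fixture"  # fixture | simulate | file
    n_cases: int = 500
    cases_path: str | None = None
    allred_cutoff: int = 6
    til_cutoffs: tuple[float, float] = (20.0, 60.0)
    alpha: float = 0.05
    fdr_q: float = 0.05
    run_molecular: bool = False
    run_survival: bool = True
    run_downstream: bool = False
    n_genes: int = 200
    centroid_sep: float = 2.0
    noise_sd: float = 0.3
    expression_path: str | None = None
    centroids_path: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
        inp = raw.get("input", {})
        if unknown := set(inp) - _KNOWN_INPUT:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        cfg.input_kind = inp.get("kind", cfg.input_kind)
        if cfg.input_kind not in ("fixture", "simulate", "file"):
            raise ValueError(f"unknown input kind {cfg.input_kind!r}")
        cfg.n_cases = int(inp.get("n_cases", cfg.n_cases))
        cfg.cases_path = inp.get("cases_path", cfg.cases_path)
        thr = raw.get("thresholds", {})
        if unknown := set(thr) - _KNOWN_THRESHOLDS:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        cfg.allred_cutoff = int(thr.get("allred_cutoff", cfg.allred_cutoff))
        cfg.til_cutoffs = tuple(thr.get("til_cutoffs", cfg.til_cutoffs))
        cfg.alpha = float(thr.get("alpha", cfg.alpha))
        cfg.fdr_q = float(thr.get("fdr_q", cfg.fdr_q))
        stages = raw.get("stages", {})
        if unknown := set(stages) - _KNOWN_STAGES:
            raise ValueError(f"unknown stage keys: {sorted(unknown)}")
        cfg.run_molecular = bool(stages.get("molecular", cfg.run_molecular))
        cfg.run_survival = bool(stages.get("survival", cfg.run_survival))
        cfg.run_downstream = bool(stages.get("downstream", cfg.run_downstream))
        mol = raw.get("molecular", {})
        if unknown := set(mol) - _KNOWN_MOLECULAR:
            raise ValueError(f"unknown molecular keys: {sorted(unknown)}")
        cfg.n_genes = int(mol.get("n_genes", cfg.n_genes))
        cfg.centroid_sep = float(mol.get("centroid_sep", cfg.centroid_sep))
        cfg.noise_sd = float(mol.get("noise_sd", cfg.noise_sd))
        cfg.expression_path = mol.get("expression_path", cfg.expression_path)
        cfg.centroids_path = mol.get("centroids_path", cfg.centroids_path)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "input": {
                "kind": self.input_kind,
                "n_cases": self.n_cases,
                "cases_path": self.cases_path,
            },
            "thresholds": {
                "allred_cutoff": self.allred_cutoff,
                "til_cutoffs": list(self.til_cutoffs),
                "alpha": self.alpha,
                "fdr_q": self.fdr_q,
            },
            "stages": {
                "molecular": self.run_molecular,
                "survival": self.run_survival,
                "downstream": self.run_downstream,
            },
            "molecular": {
                "n_genes": self.n_genes,
                "centroid_sep": self.centroid_sep,
                "noise_sd": self.noise_sd,
                "expression_path": self.expression_path,
                "centroids_path": self.centroids_path,
            },
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input(config: RunConfig) -> pd.DataFrame:
    if config.input_kind == "fixture":
        return reference_cohort()
    if config.input_kind == "simulate":
        return generate_cohort(default_cohort_config(config.n_cases, config.seed))
    if not config.cases_path:
        raise ValueError("input kind 'file' requires cases_path")
    return tio.read_cases(config.cases_path)


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    report: dict = {"stages": []}

    def _emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / name
        tio.write_table(df, path, index=index)
        artifacts.append(path)

    cases = _load_input(config)
    _emit(cases, "cases.tsv")
    report["stages"].append({"name": "input", "n_cases": len(cases)})

    classified = classify_table(
        cases, allred_cutoff=config.allred_cutoff, til_cutoffs=config.til_cutoffs
    )
    _emit(classified, "classified.tsv")
    excluded = len(cases) - len(classified)
    report["stages"].append(
        {"name": "classify", "n_classified": len(classified), "n_excluded": excluded}
    )

    truth_col = "molecular_truth"
    if config.run_molecular:
        if config.expression_path and config.centroids_path:
            expr = tio.read_matrix(config.expression_path)
            centroids = tio.read_matrix(config.centroids_path)
            expr = normalize_expression(expr, pre_logged=True)
        else:
            expr, centroids = generate_expression(
                classified,
                n_genes=config.n_genes,
                centroid_sep=config.centroid_sep,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
        calls = call_cohort(expr, centroids, alpha=config.alpha)
        _emit(calls, "molecular_calls.tsv")
        merged = classified.merge(
            calls[["sample_id", "label"]],
            left_on="case_id",
            right_on="sample_id",
            how="inner",
        )
        classified = merged
        truth_col = "label"
        report["stages"].append(
            {
                "name": "molecular",
                "n_called": len(calls),
                "unc_fraction": float((calls["label"] == "UNC").mean()),
            }
        )

    ct = conc.crosstab(classified["classified"], classified[truth_col])
    accuracy, ci = conc.overall_accuracy(ct)
    kappa = conc.cohen_kappa(ct)
    metrics = conc.per_class_metrics(ct)
    pct = conc.column_percentages(ct)
    _emit(ct.counts, "crosstab.tsv", index=True)
    _emit(pct, "crosstab_percent.tsv", index=True)
    _emit(metrics.reset_index(), "per_class_metrics.tsv")
    concordance_report = {
        "name": "concordance",
        "accuracy": accuracy,
        "accuracy_ci95": list(ci),
        "kappa": kappa,
        "crosstab": {
            row: ct.counts.loc[row].tolist() for row in ct.counts.index
        },
    }
    report["stages"].append(concordance_report)

    if config.run_survival:
        surv_report = {"name": "survival", "endpoints": {}}
        for endpoint in ("os", "rfs", "dfs"):
            tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
            if tcol not in classified.columns:
                continue
            groups = classified["classified"]
            entry: dict = {}
            if groups.nunique() >= 2:
                stat, df_, p = tsurv.logrank(
                    classified[tcol], classified[ecol], groups
                )
                entry["logrank"] = {"statistic": stat, "df": df_, "p": p}
                if classified[ecol].sum() >= 5 and "LP" in set(groups):
                    try:
                        cox = tsurv.cox_fit(classified, tcol, ecol, "classified")
                        entry["cox"] = {
                            term: {
                                "hr": float(row["hr"]),
                                "ci": [float(row["ci_low"]), float(row["ci_high"])],
                                "p": float(row["p"]),
                            }
                            for term, row in cox.terms.iterrows()
                        }
                    except Exception as exc:  # noqa: BLE001 - report, don't abort
                        entry["cox_error"] = str(exc)
            surv_report["endpoints"][endpoint] = entry
        report["stages"].append(surv_report)

    if config.run_downstream:
        alts, hrd = generate_alterations(classified, seed=config.seed)
        _emit(tio.alterations_to_long(alts), "alterations.tsv")
        groups = pd.Series(
            classified["classified"].to_numpy(), index=classified["case_id"]
        )
        alt_tests = tstats.alteration_tests(alts, groups)
        _emit(alt_tests.reset_index(), "alteration_tests.tsv")
        hrd_groups = groups.loc[hrd.index]
        kw_stat, kw_p, pairwise = tstats.hrd_compare(hrd, hrd_groups)
        _emit(pairwise, "hrd_pairwise.tsv")
        report["stages"].append(
            {
                "name": "downstream",
                "n_events": len(alts),
                "kw_statistic": kw_stat,
                "kw_p": kw_p,
            }
        )

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    artifacts.append(report_path)

    manifest = {
        "package_version": tnbcstrat.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
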