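# tnbcstrat

An end-to-end, tested pipeline for an immunohistochemistry/TIL-based
triple-negative breast cancer (TNBC) subtyping scheme and its evaluation
against an expression-based molecular subclassification.

The classifier assigns each tumor to one of four groups from two routine
pathology readings:

* **LAR** — AR Allred score ≥ 6;
* otherwise, by stromal TIL percentage: **LP** (≥ 60%), **LI** (20–60%),
  **LD** (< 20%).

Around that rule the package provides:

| module | what it does |
| --- | --- |
| `tnbcstrat.scoring` | Allred proportion/intensity scoring (0–8) and TIL binning |
| `tnbcstrat.classifier` | the decision rule, scalar and vectorized over case tables |
| `tnbcstrat.cart` | in-house greedy Gini CART used to re-derive the 6 / 20 / 60 cut-offs, with a controlled threshold-reporting convention |
| `tnbcstrat.molecular` | quantile normalization + correlation-to-centroid molecular calls (LAR/IM/BL1/M, UNC when no correlation reaches p < 0.05) |
| `tnbcstrat.concordance` | classifier-vs-molecular cross-tabulation, column percentages, accuracy with Wilson/Clopper–Pearson CI, Cohen's kappa, per-class precision/recall/F1/balanced accuracy |
| `tnbcstrat.survival` | Kaplan–Meier curves, K-group log-rank, multivariable Cox PH (Efron ties, LP reference) via lifelines |
| `tnbcstrat.stats` | ssGSEA-style / mean-z signature scores, ANOVA + BH FDR, pairwise t post-hocs, Freeman–Halton exact alteration tests, Kruskal–Wallis + rank-sum HRD comparisons |
| `tnbcstrat.synthetic` | deterministic 317-case reference fixture reproducing the published cross-tabulation, plus seeded generators for cohorts, expression matrices and alteration/HRD data |
| `tnbcstrat.pipeline` / `tnbcstrat.cli` | YAML-configured orchestration with checksummed manifests |

## CLI

All stages are exposed under a single `tnbcstrat` entry point:

```sh
tnbcstrat simulate --n 500 --seed 1 --out-dir runs/sim      # synthetic cohort
tnbcstrat classify --in cases.tsv --out calls.tsv           # score + classify
tnbcstrat derive-tree --in calls.tsv --out tree.json        # CART cut-offs
tnbcstrat call-subtype --expression expr.tsv --centroids c.tsv --out mol.tsv
tnbcstrat concordance --calls calls.tsv --truth truth.tsv --out report
tnbcstrat survival --in calls.tsv --endpoint rfs --out fits.json
tnbcstrat stats --scores scores.tsv --groups calls.tsv --out stats
tnbcstrat run-all --config config.yaml                      # whole pipeline
```

A minimal `run-all` config:

```yaml
seed: 1
out_dir: runs/demo
input: {kind: simulate, n_cases: 300}     # or kind: fixture / kind: file
thresholds: {allred_cutoff: 6, til_cutoffs: [20, 60], alpha: 0.05}
stages: {molecular: true, survival: true, downstream: true}
```

Every run writes a `manifest.json` with the config hash and a SHA-256 per
artifact; rerunning the same config reproduces identical artifacts.

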