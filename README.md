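# synrank

Synergy-network spectral feature ranking and embedded cross-validation
biomarker selection for case-control data.

Many risk factors matter for a disease outcome only through pairwise
interactions, which single-variable screening cannot see. `synrank` builds a
*synergy network* over the candidate features of a case-control dataset:

- **node weights** — individual predictive power, `-log p` of the slope in a
  single-feature logistic model of the outcome;
- **edge weights** — synergistic power of each unordered feature pair,
  `-log p` of the product-term coefficient in a two-feature logistic model
  with interaction.

Selecting the best bounded-size subnetwork (sum of internal node plus
`λ`-weighted edge weights) is a maximum-weighted-clique problem. `synrank`
solves it exactly on small instances and, in general, through a spectral
relaxation: features are scored by the absolute entries of the leading
eigenvector of the matrix `M` with node weights on the diagonal and
`λ`-scaled edge weights off it. The resulting ranking feeds a forward
feature selection wrapped in an *embedded* 10-fold cross-validation protocol
(ranking and selection are redone inside every outer training fold; a
quadratic discriminant classifier and an inner 10-fold CV score each
candidate), yielding leakage-free accuracy/AUC estimates, per-feature
selection frequencies and a consensus biomarker set. A case-control
simulator with sparse pairwise logistic interactions (mixture-of-Gaussian
features) is included for validation, along with an exhaustive-search
baseline over all feature subsets.

## Test

```sh
python -m pytest -q tests/
```

The test extras (`pip install -e .[test]`) add `statsmodels` and
`scikit-learn`, used only as independent oracles.

## Command line

Datasets are CSV/TSV files with a header; one column (default `outcome`)
holds the 0/1 outcome, all other numeric columns are features.

```sh
# simulate 20 case-control datasets (30 features, 200 samples, 10 synergy pairs)
synrank simulate --out sim/ --n-datasets 20 --seed 1

# build + export the synergy network (averaged if several inputs are given)
synrank network --data sim/dataset_000.csv --out net --graphml

# spectral feature ranking
synrank rank --data sim/dataset_000.csv --lambda 1.0 --out ranking

# forward selection on the full dataset
synrank select --data sim/dataset_000.csv --metric auc --seed 1 --out sel.json

# embedded 10x10 CV comparison of network vs individual ranking
synrank evaluate --data sim/dataset_000.csv --ranking both --metric auc \
    --repeats 100 --seed 1 --out eval.json
```

All runs are pure functions of their inputs and `--seed`; every JSON report
embeds the configuration that produced it.

## Python API

```python
import synrank as sr

ds = sr.read_dataset("data.csv", outcome_column="outcome")
net = sr.build_network(ds, lam=1.0)
ranking = sr.rank_features(net)                 # spectral scores + order
report = sr.embedded_cv(ds, "network", "auc",
                        n_repeats=100, seed=1)  # leakage-free evaluation
markers = sr.consensus_biomarkers(report, 0.40)
```

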