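"""Forward feature selection, the embedded cross-validation protocol,
consensus biomarker extraction and the exhaustive-search baseline.

All stochastic routines derive every fold assignment from named seed paths
(master seed plus repeat/fold/method/metric indices), so results are pure
functions of (inputs, seed) and identical folds are reused wherever a fair
paired comparison requires it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data import CaseControlDataset
from .errors import ComplexityGuardError, InputError
from .network import build_network, node_weight_vector
from .qda import auc_score, qda_fold_posterior
from .spectral import rank_features

__all__ = [
    "SelectionResult",
    "FoldRecord",
    "EvaluationReport",
    "individual_ranking",
    "forward_select",
    "embedded_cv",
    "embedded_cv_compare",
    "consensus_biomarkers",
    "evaluate_subset",
    "exhaustive_search",
    "paired_comparison",
]

METRICS = ("accuracy", "auc")
METHODS = ("network", "individual")
_METHOD_CODE = {"network": 0, "individual": 1}
_METRIC_CODE = {"accuracy": 0, "auc": 1}
EPS_IMPROVE = 1e-12


# ---------------------------------------------------------------------------
# fold machinery


def stratified_fold_indices(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random stratified k-fold split: list of (train_idx, test_idx)."""
    buckets: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            buckets[pos % k].append(int(i))
    folds = []
    all_idx = np.arange(y.shape[0])
    for b in buckets:
        te = np.asarray(sorted(b), dtype=int)
        tr = np.setdiff1d(all_idx, te, assume_unique=True)
        folds.append((tr, te))
    return folds


def _seeded_rng(*path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(p) for p in path]))


def _fold_metrics(X, y, cols, tr, te, shrinkage, auc_mode="posterior"):
    """(accuracy, auc) of QDA trained on rows tr, scored on rows te.

    ``auc_mode`` picks the score fed to the ROC: the class-1 posterior
    (default) or the hard 0/1 prediction (with balanced data, label-based
    AUC coincides with accuracy up to class-imbalance effects).
    """
    p1 = qda_fold_posterior(X[np.ix_(tr, cols)], y[tr], X[np.ix_(te, cols)], shrinkage)
    yte = y[te]
    labels = p1 >= 0.5
    acc = float(np.mean(yte == labels))
    if 0 < yte.sum() < yte.size:
        auc = auc_score(yte, p1 if auc_mode == "posterior" else labels.astype(float))
    else:
        auc = np.nan
    return acc, auc


def _score_subset(X, y, cols, folds, metric, shrinkage, auc_mode) -> float:
    """Mean inner-CV metric of a feature subset; NaN if no fold is usable."""
    vals = []
    for tr, te in folds:
        ytr = y[tr]
        if ytr.min() == ytr.max():
            warnings.warn("inner CV fold with a single training class skipped")
            continue
        if metric == "auc" and not 0 < y[te].sum() < y[te].size:
            continue
        acc, auc = _fold_metrics(X, y, cols, tr, te, shrinkage, auc_mode)
        vals.append(acc if metric == "accuracy" else auc)
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# rankings


def _order_by_weights(weights: np.ndarray) -> np.ndarray:
    w = np.round(np.asarray(weights, dtype=float), 10)
    return np.lexsort((np.arange(w.shape[0]), -w))


def individual_ranking(dataset: CaseControlDataset, test: str = "wald") -> np.ndarray:
    """Features ordered by individual power (-log p) descending."""
    weights, _, _ = node_weight_vector(dataset, test=test)
    return _order_by_weights(weights)


# ---------------------------------------------------------------------------
# forward selection


@dataclass
class CandidateDecision:
    feature: int
    score_with: float
    best_before: float
    accepted: bool


@dataclass
class SelectionResult:
    selected: list[int]
    inner_cv_trace: list[CandidateDecision]
    metric_name: str


def _majority_baseline(y, folds, metric) -> float:
    """Inner-CV score of the empty set under a majority-class classifier."""
    vals = []
    for tr, te in folds:
        if y[tr].min() == y[tr].max():
            continue
        if metric == "accuracy":
            maj = 1 if y[tr].mean() >= 0.5 else 0
            vals.append(float(np.mean(y[te] == maj)))
        else:
            vals.append(0.5)
    return float(np.mean(vals)) if vals else 0.0


def forward_select(
    ranked,
    train: CaseControlDataset,
    metric: str,
    inner_folds: int = 10,
    seed=0,
    shrinkage: float = 1e-4,
    baseline: str = "zero",
    auc_mode: str = "posterior",
) -> SelectionResult:
    """Single pass down a ranked feature list with inner-CV acceptance.

    A candidate is appended iff the inner stratified ``inner_folds``-fold CV
    metric of the current set plus the candidate strictly exceeds the best
    score so far. Folds are fixed once per call from ``seed`` so every
    candidate is scored on identical splits.

    ``baseline`` sets the score of the empty starting set: ``"zero"``
    (default) admits the first usable candidate unconditionally, so ranking
    quality drives what the classifier gets to see; ``"majority"`` starts
    from the majority-class score, a conservative variant that can return an
    empty selection.
    """
    if metric not in METRICS:
        raise InputError(f"metric must be one of {METRICS}")
    if baseline not in ("zero", "majority"):
        raise InputError("baseline must be 'zero' or 'majority'")
    if auc_mode not in ("posterior", "label"):
        raise InputError("auc_mode must be 'posterior' or 'label'")
    ranked = [int(i) for i in ranked]
    if sorted(ranked) != list(range(train.n_features)):
        raise InputError("ranked must be a permutation of all feature indices")
    rng = (
        np.random.default_rng(seed)
        if isinstance(seed, (np.random.SeedSequence, np.random.Generator))
        else _seeded_rng(1, int(seed))
    )
    folds = stratified_fold_indices(train.outcome, inner_folds, rng)
    X, y = train.features, train.outcome
    selected: list[int] = []
    trace: list[CandidateDecision] = []
    best = 0.0 if baseline == "zero" else _majority_baseline(y, folds, metric)
    for feat in ranked:
        score = _score_subset(X, y, selected + [feat], folds, metric, shrinkage, auc_mode)
        accepted = np.isfinite(score) and score > best + EPS_IMPROVE
        trace.append(CandidateDecision(feat, score, best, bool(accepted)))
        if accepted:
            selected.append(feat)
            best = score
    return SelectionResult(selected=selected, inner_cv_trace=trace, metric_name=metric)


# ---------------------------------------------------------------------------
# embedded cross-validation


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    selected: tuple[int, ...]
    test_accuracy: float
    test_auc: float


@dataclass
class EvaluationReport:
    method: str
    metric: str
    lam: float
    n_repeats: int
    n_folds: int
    inner_folds: int
    threshold: float
    seed: int
    feature_names: list[str]
    records: list[FoldRecord]
    auc_mode: str = "posterior"
    accuracy_mean: float = 0.0
    accuracy_sd: float = 0.0
    auc_mean: float = 0.0
    auc_sd: float = 0.0
    selection_frequency: np.ndarray = field(default_factory=lambda: np.zeros(0))
    consensus: tuple[int, ...] = ()

    def finalize(self) -> "EvaluationReport":
        accs = np.array([r.test_accuracy for r in self.records])
        aucs = np.array([r.test_auc for r in self.records])
        self.accuracy_mean = float(np.nanmean(accs))
        self.accuracy_sd = float(np.nanstd(accs, ddof=1))
        self.auc_mean = float(np.nanmean(aucs))
        self.auc_sd = float(np.nanstd(aucs, ddof=1))
        counts = np.zeros(len(self.feature_names))
        for r in self.records:
            for i in r.selected:
                counts[i] += 1
        self.selection_frequency = counts / max(len(self.records), 1)
        self.consensus = consensus_biomarkers(self, self.threshold)
        return self

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "method": self.method,
            "metric": self.metric,
            "lambda": self.lam,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "inner_folds": self.inner_folds,
            "threshold": self.threshold,
            "seed": self.seed,
            "auc_mode": self.auc_mode,
            "feature_names": list(self.feature_names),
            "records": [
                {
                    "repeat": r.repeat,
                    "fold": r.fold,
                    "selected": list(r.selected),
                    "test_accuracy": r.test_accuracy,
                    "test_auc": r.test_auc,
                }
                for r in self.records
            ],
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "selection_frequency": self.selection_frequency.tolist(),
            "consensus": list(self.consensus),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        rep = cls(
            method=d["method"],
            metric=d["metric"],
            lam=d["lambda"],
            n_repeats=d["n_repeats"],
            n_folds=d["n_folds"],
            inner_folds=d["inner_folds"],
            threshold=d["threshold"],
            seed=d["seed"],
            auc_mode=d.get("auc_mode", "posterior"),
            feature_names=list(d["feature_names"]),
            records=[
                FoldRecord(
                    r["repeat"],
                    r["fold"],
                    tuple(r["selected"]),
                    r["test_accuracy"],
                    r["test_auc"],
                )
                for r in d["records"]
            ],
        )
        rep.accuracy_mean = d["accuracy_mean"]
        rep.accuracy_sd = d["accuracy_sd"]
        rep.auc_mean = d["auc_mean"]
        rep.auc_sd = d["auc_sd"]
        rep.selection_frequency = np.asarray(d["selection_frequency"])
        rep.consensus = tuple(d["consensus"])
        return rep


def _check_cv_feasible(dataset: CaseControlDataset, n_folds: int) -> None:
    if dataset.n_samples < 20:
        raise InputError("embedded CV requires at least 20 samples")
    counts = np.bincount(dataset.outcome, minlength=2)
    if counts.min() < n_folds:
        raise InputError(
            f"each class needs at least n_folds={n_folds} samples "
            f"(class counts: {counts.tolist()})"
        )


def embedded_cv_compare(
    dataset: CaseControlDataset,
    methods=METHODS,
    metrics=METRICS,
    lam: float = 1.0,
    n_folds: int = 10,
    n_repeats: int = 100,
    inner_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.40,
    test: str = "wald",
    shrinkage: float = 1e-4,
    auc_mode: str = "posterior",
) -> dict[tuple[str, str], EvaluationReport]:
    """Run the embedded CV protocol for several (ranking, metric) combos.

    The synergy network for each outer training fold is built once and
    shared across every requested combination; outer folds depend only on
    (seed, repeat) so all combinations are evaluated on identical splits.
    Feature ranking, forward selection and classifier training only ever see
    the outer training portion.
    """
    methods = tuple(methods)
    metrics = tuple(metrics)
    for m in methods:
        if m not in METHODS:
            raise InputError(f"unknown ranking method {m!r}")
    for m in metrics:
        if m not in METRICS:
            raise InputError(f"unknown metric {m!r}")
    _check_cv_feasible(dataset, n_folds)
    X, y = dataset.features, dataset.outcome
    records: dict[tuple[str, str], list[FoldRecord]] = {
        (m, mt): [] for m in methods for mt in metrics
    }
    for rep in range(n_repeats):
        folds = stratified_fold_indices(y, n_folds, _seeded_rng(0, seed, rep))
        for fold_i, (tr, te) in enumerate(folds):
            sub = dataset.subset_rows(tr)
            orders: dict[str, np.ndarray] = {}
            if "network" in methods:
                net = build_network(sub, lam, test=test)
                orders["network"] = rank_features(net).order
                node_w = net.node_weights
            else:
                node_w, _, _ = node_weight_vector(sub, test=test)
            if "individual" in methods:
                orders["individual"] = _order_by_weights(node_w)
            for method in methods:
                for metric in metrics:
                    fs_seed = np.random.SeedSequence(
                        [1, seed, rep, fold_i, _METHOD_CODE[method], _METRIC_CODE[metric]]
                    )
                    sel = forward_select(
                        orders[method], sub, metric, inner_folds, fs_seed,
                        shrinkage, auc_mode=auc_mode,
                    ).selected
                    if sel:
                        acc, auc = _fold_metrics(X, y, sel, tr, te, shrinkage, auc_mode)
                    else:
                        maj = 1 if y[tr].mean() >= 0.5 else 0
                        acc, auc = float(np.mean(y[te] == maj)), 0.5
                        warnings.warn(
                            f"empty selection in repeat {rep} fold {fold_i}; "
                            "majority-class fallback used"
                        )
                    records[(method, metric)].append(
                        FoldRecord(rep, fold_i, tuple(sel), float(acc), float(auc))
                    )
    reports = {}
    for key, recs in records.items():
        method, metric = key
        reports[key] = EvaluationReport(
            method=method,
            metric=metric,
            lam=lam,
            n_repeats=n_repeats,
            n_folds=n_folds,
            inner_folds=inner_folds,
            threshold=threshold,
            seed=seed,
            auc_mode=auc_mode,
            feature_names=list(dataset.feature_names),
            records=recs,
        ).finalize()
    return reports


def embedded_cv(
    dataset: CaseControlDataset,
    ranking_method: str = "network",
    metric: str = "accuracy",
    lam: float = 1.0,
    n_folds: int = 10,
    n_repeats: int = 100,
    inner_folds: int = 10,
    seed: int = 0,
    threshold: float = 0.40,
    test: str = "wald",
    shrinkage: float = 1e-4,
    auc_mode: str = "posterior",
) -> EvaluationReport:
    """Embedded CV for one ranking method and one selection metric."""
    reports = embedded_cv_compare(
        dataset,
        methods=(ranking_method,),
        metrics=(metric,),
        lam=lam,
        n_folds=n_folds,
        n_repeats=n_repeats,
        inner_folds=inner_folds,
        seed=seed,
        threshold=threshold,
        test=test,
        shrinkage=shrinkage,
        auc_mode=auc_mode,
    )
    return reports[(ranking_method, metric)]


def consensus_biomarkers(
    report: EvaluationReport, threshold: float = 0.40
) -> tuple[int, ...]:
    """Features selected in at least ``threshold`` of all recorded subsets."""
    counts = np.zeros(len(report.feature_names))
    for r in report.records:
        for i in r.selected:
            counts[i] += 1
    freq = counts / max(len(report.records), 1)
    return tuple(int(i) for i in np.flatnonzero((freq >= threshold) & (freq > 0)))


# ---------------------------------------------------------------------------
# fixed-subset evaluation and exhaustive search


def _fixed_subset_cv(X, y, cols, n_repeats, n_folds, seed, shrinkage, auc_mode):
    accs, aucs = [], []
    for rep in range(n_repeats):
        folds = stratified_fold_indices(y, n_folds, _seeded_rng(2, seed, rep))
        for tr, te in folds:
            if y[tr].min() == y[tr].max():
                warnings.warn("CV fold with single-class training portion skipped")
                continue
            acc, auc = _fold_metrics(X, y, cols, tr, te, shrinkage, auc_mode)
            accs.append(acc)
            aucs.append(auc)
    return float(np.nanmean(accs)), float(np.nanmean(aucs))


def evaluate_subset(
    dataset: CaseControlDataset,
    subset,
    n_repeats: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    shrinkage: float = 1e-4,
    auc_mode: str = "posterior",
) -> tuple[float, float]:
    """(mean accuracy, mean AUC) of QDA on a fixed feature subset under
    repeated stratified k-fold CV — no selection happens inside."""
    cols = sorted(set(int(i) for i in subset))
    if not cols:
        raise InputError("subset must be non-empty")
    if cols[0] < 0 or cols[-1] >= dataset.n_features:
        raise InputError("subset contains out-of-range indices")
    return _fixed_subset_cv(
        dataset.features, dataset.outcome, cols, n_repeats, n_folds, seed,
        shrinkage, auc_mode,
    )


def exhaustive_search(
    dataset: CaseControlDataset,
    metric: str = "auc",
    max_features: int = 16,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    override: bool = False,
    shrinkage: float = 1e-4,
    auc_mode: str = "posterior",
) -> tuple[tuple[int, ...], float]:
    """Best subset over all 2^d - 1 non-empty subsets by repeated-CV score.

    Uses the same fold scheme as :func:`evaluate_subset`, so the returned
    score dominates ``evaluate_subset`` of any subset at the same seed.
    """
    if metric not in METRICS:
        raise InputError(f"metric must be one of {METRICS}")
    d = dataset.n_features
    if d > max_features and not override:
        raise ComplexityGuardError(
            f"{d} features would require {2 ** d - 1} subset evaluations; "
            "pass override=True to force"
        )
    X, y = dataset.features, dataset.outcome
    # precompute folds shared by every subset
    folds_all = [
        stratified_fold_indices(y, n_folds, _seeded_rng(2, seed, rep))
        for rep in range(n_repeats)
    ]
    best_subset: tuple[int, ...] = ()
    best_score = -np.inf
    which = 0 if metric == "accuracy" else 1
    for size in range(1, d + 1):
        for subset in combinations(range(d), size):
            vals = []
            for folds in folds_all:
                for tr, te in folds:
                    if y[tr].min() == y[tr].max():
                        continue
                    vals.append(
                        _fold_metrics(X, y, list(subset), tr, te, shrinkage, auc_mode)[which]
                    )
            score = float(np.nanmean(vals))
            if score > best_score:
                best_score, best_subset = score, subset
    return best_subset, best_score


# ---------------------------------------------------------------------------
# paired comparison across repeats


def paired_comparison(
    report_a: EvaluationReport, report_b: EvaluationReport
) -> dict:
    """Per-repeat paired deltas (a minus b) with a two-sided Wilcoxon test."""
    from scipy.stats import wilcoxon

    if report_a.n_repeats != report_b.n_repeats:
        raise InputError("reports must have the same number of repeats")

    def per_repeat(report, attr):
        out = np.zeros(report.n_repeats)
        cnt = np.zeros(report.n_repeats)
        for r in report.records:
            out[r.repeat] += getattr(r, attr)
            cnt[r.repeat] += 1
        return out / np.maximum(cnt, 1)

    result = {}
    for attr, name in (("test_accuracy", "accuracy"), ("test_auc", "auc")):
        a = per_repeat(report_a, attr)
        b = per_repeat(report_b, attr)
        delta = a - b
        try:
            p = float(wilcoxon(a, b, zero_method="wilcox").pvalue)
        except ValueError:
            p = float("nan")
        result[name] = {
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "mean_delta": float(delta.mean()),
            "wilcoxon_p": p,
        }
    return result
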