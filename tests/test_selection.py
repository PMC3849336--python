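"""Forward selection, embedded CV, consensus and exhaustive search."""

import numpy as np
import pytest

import synrank.selection as sel
from synrank import (
    CaseControlDataset,
    ComplexityGuardError,
    InputError,
    consensus_biomarkers,
    embedded_cv,
    embedded_cv_compare,
    evaluate_subset,
    exhaustive_search,
    forward_select,
    individual_ranking,
    rank_features,
)
from synrank.selection import EvaluationReport, FoldRecord, _order_by_weights

from conftest import make_interaction_dataset, make_noise_dataset


def _perfect_dataset(n=120, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (X[:, 0] > 0).astype(int)
    return CaseControlDataset(X, y)


# --- individual ranking ----------------------------------------------------

def test_order_by_weights_example():
    assert np.array_equal(_order_by_weights(np.array([0.1, 5.0, 2.0])), [1, 2, 0])


def test_individual_ranking_matches_lambda_zero_spectral(noise_dataset):
    from synrank import build_network

    net = build_network(noise_dataset, lam=0.0)
    assert np.array_equal(individual_ranking(noise_dataset), rank_features(net).order)


def test_individual_ranking_finds_strong_main_effect():
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        X = rng.normal(size=(300, 5))
        y = (rng.random(300) < 1 / (1 + np.exp(-2.0 * X[:, 0]))).astype(int)
        if y.min() == y.max():
            continue
        ds = CaseControlDataset(X, y)
        hits += individual_ranking(ds)[0] == 0
    assert hits >= 95


# --- forward selection -----------------------------------------------------

def test_forward_select_noise_stays_small():
    # null-simulation oracle: with the default baseline the first candidate
    # is always admitted and chance-level strict improvements add ~2 more on
    # average; the conservative majority baseline stays near-empty
    sizes_default, sizes_majority = [], []
    for rep in range(50):
        ds = make_noise_dataset(n=100, d=8, seed=2000 + rep)
        res = forward_select(np.arange(8), ds, "accuracy", seed=rep)
        sizes_default.append(len(res.selected))
        res_m = forward_select(
            np.arange(8), ds, "accuracy", seed=rep, baseline="majority"
        )
        sizes_majority.append(len(res_m.selected))
    # oracle-computed reference levels: 3.0 and 2.16 at this configuration
    assert np.mean(sizes_default) <= 3.5
    assert np.mean(sizes_majority) <= 2.5
    assert np.mean(sizes_majority) < np.mean(sizes_default)


def test_forward_select_perfect_feature_accepted():
    ds = _perfect_dataset()
    res = forward_select(np.arange(4), ds, "accuracy", seed=1)
    assert res.selected[0] == 0
    accepted = [t for t in res.inner_cv_trace if t.accepted]
    assert accepted[0].score_with >= 0.95


def test_forward_select_trace_strictly_increasing():
    ds = make_interaction_dataset(seed=3)
    res = forward_select(np.arange(ds.n_features), ds, "auc", seed=4)
    scores = [t.score_with for t in res.inner_cv_trace if t.accepted]
    assert all(b > a for a, b in zip(scores, scores[1:]))
    assert len(set(res.selected)) == len(res.selected)


def test_forward_select_requires_permutation(noise_dataset):
    with pytest.raises(InputError):
        forward_select([0, 1, 2], noise_dataset, "accuracy")
    with pytest.raises(InputError):
        forward_select(
            np.arange(noise_dataset.n_features), noise_dataset, "f1"
        )


def test_forward_select_deterministic(noise_dataset):
    a = forward_select(np.arange(8), noise_dataset, "auc", seed=9)
    b = forward_select(np.arange(8), noise_dataset, "auc", seed=9)
    assert a.selected == b.selected
    assert [t.score_with for t in a.inner_cv_trace] == [
        t.score_with for t in b.inner_cv_trace
    ]


# --- embedded CV -----------------------------------------------------------

def test_embedded_cv_subset_count():
    ds = make_interaction_dataset(n=120, d=5, seed=5)
    rep = embedded_cv(ds, "network", "accuracy", n_repeats=2, n_folds=10, seed=3)
    assert len(rep.records) == 2 * 10
    assert rep.n_repeats * rep.n_folds == 20
    assert np.all((rep.selection_frequency >= 0) & (rep.selection_frequency <= 1))


def test_embedded_cv_deterministic():
    ds = make_interaction_dataset(n=100, d=5, seed=6)
    a = embedded_cv(ds, "network", "auc", n_repeats=2, seed=11)
    b = embedded_cv(ds, "network", "auc", n_repeats=2, seed=11)
    assert a.to_dict() == b.to_dict()


def test_embedded_cv_single_matches_compare():
    ds = make_interaction_dataset(n=100, d=5, seed=13)
    single = embedded_cv(ds, "network", "auc", n_repeats=2, seed=7)
    combo = embedded_cv_compare(
        ds, methods=("network", "individual"), metrics=("accuracy", "auc"),
        n_repeats=2, seed=7,
    )[("network", "auc")]
    assert single.to_dict() == combo.to_dict()


def test_embedded_cv_permuted_outcome_near_chance():
    rng = np.random.default_rng(17)
    ds = make_interaction_dataset(n=100, d=6, seed=8)
    y_perm = rng.permutation(ds.outcome)
    perm = CaseControlDataset(ds.features, y_perm)
    rep = embedded_cv(perm, "network", "auc", n_repeats=20, seed=21)
    assert 0.45 <= rep.auc_mean <= 0.55


def test_embedded_cv_rejects_tiny_data():
    ds = make_noise_dataset(n=18, d=3, seed=1)
    with pytest.raises(InputError):
        embedded_cv(ds, "network", "auc", n_repeats=1)


def test_embedded_cv_no_test_rows_reach_network_construction(monkeypatch):
    ds = make_interaction_dataset(n=100, d=5, seed=9)
    seen = []
    orig = sel.build_network

    def spy(sub, lam, **kw):
        seen.append(sub.features.copy())
        return orig(sub, lam, **kw)

    monkeypatch.setattr(sel, "build_network", spy)
    sel.embedded_cv_compare(
        ds, methods=("network",), metrics=("accuracy",), n_repeats=1, seed=5
    )
    folds = sel.stratified_fold_indices(ds.outcome, 10, sel._seeded_rng(0, 5, 0))
    assert len(seen) == len(folds)
    for (tr, te), feats in zip(folds, seen):
        train_rows = {r.tobytes() for r in feats}
        assert len(train_rows) == len(tr)
        for i in te:
            assert ds.features[i].tobytes() not in train_rows


# --- consensus -------------------------------------------------------------

def _report_with_frequencies(counts, total, n_features=4):
    records = []
    for t in range(total):
        selected = tuple(i for i, c in enumerate(counts) if t < c)
        records.append(FoldRecord(0, t, selected, 0.5, 0.5))
    return EvaluationReport(
        method="network", metric="auc", lam=1.0, n_repeats=1, n_folds=total,
        inner_folds=10, threshold=0.4, seed=0,
        feature_names=[f"v{i}" for i in range(n_features)], records=records,
    )


def test_consensus_threshold_inclusive_at_40_percent():
    rep = _report_with_frequencies([400, 399, 1000, 0], total=1000)
    assert consensus_biomarkers(rep, 0.40) == (0, 2)


def test_consensus_threshold_zero_returns_ever_selected():
    rep = _report_with_frequencies([3, 0, 10, 1], total=10)
    assert consensus_biomarkers(rep, 0.0) == (0, 2, 3)


def test_consensus_threshold_one_boundary():
    rep = _report_with_frequencies([10, 9, 0, 0], total=10)
    assert consensus_biomarkers(rep, 1.0) == (0,)


# --- fixed-subset evaluation and exhaustive search -------------------------

def test_evaluate_subset_perfect_feature():
    ds = _perfect_dataset()
    acc, auc = evaluate_subset(ds, [0], n_repeats=5, n_folds=5, seed=0)
    assert acc >= 0.95
    assert auc >= 0.95


def test_evaluate_subset_noise_near_chance():
    ds = make_noise_dataset(n=200, d=4, seed=31)
    acc, auc = evaluate_subset(ds, [1, 2], n_repeats=20, n_folds=10, seed=2)
    assert 0.45 <= auc <= 0.55


def test_evaluate_subset_deterministic_and_validated(noise_dataset):
    r1 = evaluate_subset(noise_dataset, [0, 3], n_repeats=3, seed=5)
    r2 = evaluate_subset(noise_dataset, [0, 3], n_repeats=3, seed=5)
    assert r1 == r2
    with pytest.raises(InputError):
        evaluate_subset(noise_dataset, [])


def test_exhaustive_search_matches_enumeration_of_evaluate_subset():
    from itertools import chain, combinations

    ds = make_interaction_dataset(n=80, d=3, pair=(0, 1), seed=12)
    best, score = exhaustive_search(ds, "auc", n_repeats=3, n_folds=5, seed=4)
    subsets = list(
        chain.from_iterable(combinations(range(3), k) for k in (1, 2, 3))
    )
    assert len(subsets) == 7
    scores = {
        s: evaluate_subset(ds, s, n_repeats=3, n_folds=5, seed=4)[1] for s in subsets
    }
    assert score == pytest.approx(max(scores.values()))
    assert scores[best] == pytest.approx(score)
    # dominance over every other subset on identical folds/seed
    assert all(score >= v - 1e-12 for v in scores.values())


def test_exhaustive_search_guard_and_override():
    ds = make_noise_dataset(n=60, d=5, seed=3)
    with pytest.raises(ComplexityGuardError):
        exhaustive_search(ds, "auc", max_features=4)
    best, _ = exhaustive_search(
        ds, "auc", max_features=4, override=True, n_repeats=2, n_folds=5, seed=1
    )
    assert 1 <= len(best) <= 5


def test_exhaustive_search_recovers_planted_pair():
    hits = 0
    for rep in range(100):
        ds = make_interaction_dataset(n=150, d=6, pair=(1, 3), beta=3.0, seed=5000 + rep)
        best, _ = exhaustive_search(ds, "auc", n_repeats=2, n_folds=5, seed=rep)
        hits += {1, 3} <= set(best)
    assert hits >= 90
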