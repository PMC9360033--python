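"""Dirichlet-process clustering: recovery, merging, two-step fit, grid
search and rule-based post-processing."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from amlclass import (
    ClusteringResult,
    DpHyperParams,
    fit_dp_mixture,
    grid_search,
    merge_components,
    postprocess_assignments,
    two_step_fit,
)

FAST = DpHyperParams(n_mcmc_iterations=120, burn_in=60, seed=0)


def planted(K, n, f=None, signal=0.9, background=0.02, seed=0,
            features_per_class=3):
    """Block-structured binary matrix: each class owns `features_per_class`
    private high-rate features over a low background."""
    rng = np.random.default_rng(seed)
    f = f or K * features_per_class + 6
    truth = rng.integers(0, K, n)
    X = (rng.random((n, f)) < background).astype(float)
    for k in range(K):
        rows = np.where(truth == k)[0]
        cols = slice(k * features_per_class, (k + 1) * features_per_class)
        X[rows, cols] = (rng.random((len(rows), features_per_class)) < signal)
    return X, truth


def test_two_disjoint_blocks_recovered_exactly():
    rng = np.random.default_rng(1)
    X = np.zeros((100, 8))
    truth = np.repeat([0, 1], 50)
    X[:50, :3] = 1.0
    X[50:, 3:6] = 1.0
    res = merge_components(fit_dp_mixture(X, FAST))
    assert res.n_components == 2
    assert adjusted_rand_score(truth, res.labels) == 1.0


def test_identical_rows_collapse_to_one_component():
    X = np.tile([1, 0, 1, 0, 0], (40, 1)).astype(float)
    res = merge_components(fit_dp_mixture(X, FAST))
    assert res.n_components == 1


def test_all_zero_matrix_gives_single_component():
    X = np.zeros((30, 6))
    res = merge_components(fit_dp_mixture(X, FAST))
    assert res.n_components == 1


def test_assignment_probabilities_sum_to_one():
    X, _ = planted(3, 90, seed=2)
    res = fit_dp_mixture(X, FAST)
    np.testing.assert_allclose(res.probs.sum(axis=1), 1.0, atol=1e-9)
    assert res.labels.shape == (90,)


def test_seeded_determinism():
    X, _ = planted(3, 90, seed=3)
    a = fit_dp_mixture(X, FAST)
    b = fit_dp_mixture(X, FAST)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_allclose(a.components, b.components)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DpHyperParams(cosine_merge_threshold=1.5)
    with pytest.raises(ValueError):
        DpHyperParams(alpha_shape=-1.0)
    with pytest.raises(ValueError):
        DpHyperParams(base_distribution="poisson")
    res = fit_dp_mixture(planted(2, 40, seed=0)[0], FAST)
    with pytest.raises(ValueError):
        merge_components(res, threshold=2.0)
    X = np.array([[0.5]])
    with pytest.raises(ValueError):
        fit_dp_mixture(X, FAST)


def test_merge_identical_and_orthogonal_components():
    base = ClusteringResult(
        components=np.array([[0.9, 0.1, 0.0], [0.9, 0.1, 0.0],
                             [0.0, 0.0, 0.9]]),
        sizes=np.array([10, 10, 10]),
        probs=np.full((5, 3), 1 / 3),
        labels=np.zeros(5, dtype=int),
        feature_names=("a", "b", "c"),
    )
    merged = merge_components(base, threshold=0.99)
    assert merged.n_components == 2
    np.testing.assert_allclose(merged.probs.sum(axis=1), 1.0)
    untouched = merge_components(base, threshold=1.01 - 1e-9) \
        if False else merge_components(base, threshold=1.0)
    assert untouched.n_components == 2  # only the exact duplicates merge


def test_component_count_non_increasing_as_threshold_decreases():
    X, _ = planted(3, 120, seed=4)
    res = fit_dp_mixture(X, FAST)
    counts = [
        merge_components(res, thr).n_components
        for thr in (1.0, 0.9, 0.7, 0.5, 0.3, 0.0)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[-1] == 1


def test_gaussian_base_also_recovers_blocks():
    X, truth = planted(2, 80, seed=5)
    params = DpHyperParams(base_distribution="gaussian",
                           n_mcmc_iterations=120, burn_in=60, seed=5)
    res = merge_components(fit_dp_mixture(X, params))
    assert adjusted_rand_score(truth, res.labels) >= 0.9


def test_two_step_noop_when_all_confident():
    X = np.zeros((60, 8))
    X[:30, :3] = 1.0
    X[30:, 4:7] = 1.0
    one = merge_components(fit_dp_mixture(X, FAST))
    two = two_step_fit(X, FAST)
    assert two.n_components == one.n_components
    np.testing.assert_array_equal(two.labels, one.labels)


def test_two_step_improves_confidence_of_noisy_rows():
    rng = np.random.default_rng(6)
    X, truth = planted(3, 150, seed=6)
    noisy = rng.choice(150, size=15, replace=False)
    X[noisy] = (rng.random((15, X.shape[1])) < 0.5).astype(float)
    one = merge_components(fit_dp_mixture(X, FAST, confidence_threshold=0.9))
    two = two_step_fit(X, FAST, confidence_threshold=0.9)
    low = ~one.high_confidence
    if low.sum() >= 2:
        assert two.top_prob[low].mean() >= one.top_prob[low].mean() - 1e-9


def test_grid_search_single_point_and_ranking():
    X, truth = planted(2, 80, seed=7)
    single = grid_search(X, [FAST])
    assert len(single) == 1 and single.loc[0, "grid_index"] == 0
    grid = [
        DpHyperParams(n_mcmc_iterations=120, burn_in=60, seed=8,
                      cosine_merge_threshold=0.95),
        DpHyperParams(n_mcmc_iterations=120, burn_in=60, seed=8,
                      cosine_merge_threshold=0.0),  # merges everything
    ]
    ranked = grid_search(X, grid)
    top = ranked.iloc[0]
    assert top["n_components"] == 2  # true K ranks first
    with pytest.raises(ValueError):
        grid_search(X, [])


def test_grid_search_deterministic_tie_break():
    X, _ = planted(2, 60, seed=9)
    grid = [FAST, FAST]  # identical configs: tie broken by grid order
    ranked = grid_search(X, grid)
    assert list(ranked["grid_index"]) == [0, 1]


# -- post-processing ---------------------------------------------------------

def _toy_result():
    # component 0 "NPM1-like", component 1 "APL/KMT2A mixed"
    probs = np.array([
        [0.9, 0.1],
        [0.8, 0.2],
        [0.2, 0.8],
        [0.3, 0.7],
        [0.6, 0.4],
    ])
    return ClusteringResult(
        components=np.array([[0.9, 0.0, 0.0], [0.0, 0.8, 0.8]]),
        sizes=np.array([3, 2]),
        probs=probs,
        labels=probs.argmax(axis=1),
        feature_names=("NPM1", "t(15;17)", "t(11;x)"),
    )


def test_postprocess_demotes_patients_lacking_defining_lesion():
    res = _toy_result()
    X = np.array([
        [1, 0, 0],
        [0, 0, 0],  # top prob for NPM1 component but no NPM1 mutation
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 0],
    ], dtype=float)
    labels = postprocess_assignments(
        res, X, {0: ["NPM1"], 1: ["t(15;17)", "t(11;x)"]}
    )
    assert labels[0] == 0
    assert labels[1] == -1  # unassigned, feeds mNOS downstream
    assert labels[4] == 0


def test_postprocess_manual_split_separates_mixed_component():
    res = _toy_result()
    X = np.array([
        [1, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 0],
    ], dtype=float)
    labels = postprocess_assignments(
        res, X, {0: ["NPM1"], 1: ["t(15;17)", "t(11;x)"]},
        manual_splits=[(1, "t(15;17)")],
    )
    # the t(15;17) carrier is split out of the mixed component
    assert labels[2] == 2
    assert labels[3] == 1


def test_postprocess_warns_on_unconstrained_component():
    res = _toy_result()
    X = np.ones((5, 3))
    with pytest.warns(UserWarning, match="no class-defining"):
        labels = postprocess_assignments(res, X, {0: ["NPM1"]})
    assert (labels >= 0).all()


def test_postprocess_never_assigns_without_defining_lesion_exhaustive():
    """Small exhaustive check: every patient pattern x every probability
    ordering respects the defining-lesion constraint."""
    import itertools

    feature_names = ("A", "B")
    for bits in itertools.product([0, 1], repeat=2):
        x = np.array([bits], dtype=float)
        for p0 in (0.2, 0.8):
            res = ClusteringResult(
                components=np.array([[0.9, 0.1], [0.1, 0.9]]),
                sizes=np.array([1, 1]),
                probs=np.array([[p0, 1 - p0]]),
                labels=np.array([0 if p0 >= 0.5 else 1]),
                feature_names=feature_names,
            )
            lab = postprocess_assignments(res, x, {0: ["A"], 1: ["B"]})[0]
            if lab == 0:
                assert bits[0] == 1
            elif lab == 1:
                assert bits[1] == 1
            else:
                assert bits == (0, 0)
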