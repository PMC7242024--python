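"""Shrinkage LDA, AUC, temporal decoding, time generalization and the
memory-strength proxy against closed forms and independent oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.metrics import roc_auc_score

import oscmem as om
from oscmem import decode


def brute_force_auc(scores, labels):
    """Concordant-pair count with ties worth 1/2 — the rank definition."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


# -- LDA ----------------------------------------------------------------------

def test_lda_recovers_closed_form_direction(rng):
    """w = Sigma^-1 (mu1 - mu0); with Sigma = I and mu-diff along x the
    discriminant aligns with (1, 0)."""
    n = 500
    X = rng.standard_normal((n, 2))
    y = np.arange(n) % 2 == 0
    X[y, 0] += 2.0
    model = decode.fit_lda(X, y)
    cos = model.weights[0] / np.linalg.norm(model.weights)
    assert cos > 0.99


def test_lda_anisotropic_closed_form(rng):
    """Known anisotropic covariance: w proportional to Sigma^-1 d mu."""
    n = 4000
    cov = np.array([[2.0, 0.8], [0.8, 1.0]])
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, 2)) @ L.T
    y = np.arange(n) % 2 == 0
    dmu = np.array([1.0, 0.5])
    X[y] += dmu
    model = decode.fit_lda(X, y, shrinkage=0.0)
    expected = np.linalg.solve(cov, dmu)
    cos = (model.weights @ expected) / (
        np.linalg.norm(model.weights) * np.linalg.norm(expected))
    assert cos > 0.995


def test_lda_full_shrinkage_is_mean_difference(rng):
    X = rng.standard_normal((40, 5))
    y = np.arange(40) % 2 == 0
    X[y] += np.array([1.0, -2.0, 0.0, 0.5, 3.0])
    model = decode.fit_lda(X, y, shrinkage=1.0)
    mu_diff = X[y].mean(0) - X[~y].mean(0)
    # proportional: lambda=1 shrinks to a scaled identity
    cos = (model.weights @ mu_diff) / (
        np.linalg.norm(model.weights) * np.linalg.norm(mu_diff))
    assert cos == pytest.approx(1.0, abs=1e-12)


def test_lda_equal_means_gives_chance(rng):
    X = rng.standard_normal((200, 6))
    y = np.arange(200) % 2 == 0
    model = decode.fit_lda(X, y)
    assert np.linalg.norm(model.weights) < 1.0
    # cross-validated AUC near 0.5
    scores = model.score(rng.standard_normal((200, 6)))
    assert 0.4 < decode.auc(scores, y) < 0.6


def test_lda_shrinkage_matches_sklearn(rng):
    """The analytic shrinkage intensity equals scikit-learn's Ledoit-Wolf
    estimate on the class-centered data."""
    X = rng.standard_normal((60, 8)) @ rng.standard_normal((8, 8))
    y = np.arange(60) % 2 == 0
    Xc = X.copy()
    Xc[y] -= X[y].mean(0)
    Xc[~y] -= X[~y].mean(0)
    lam = decode._ledoit_wolf_shrinkage(Xc)
    expected = ledoit_wolf_shrinkage(Xc, assume_centered=True)
    assert lam == pytest.approx(expected, abs=1e-12)


def test_lda_errors(rng):
    X = rng.standard_normal((10, 3))
    with pytest.raises(ValueError):
        decode.fit_lda(X, np.zeros(10))
    X[0, 0] = np.nan
    with pytest.raises(ValueError):
        decode.fit_lda(X, np.arange(10) % 2)


# -- AUC ----------------------------------------------------------------------

def test_auc_worked_examples():
    assert decode.auc([0.1, 0.4, 0.4, 0.9], [0, 0, 1, 1]) == pytest.approx(0.875)
    assert decode.auc([0, 1, 2, 10], [0, 0, 1, 1]) == 1.0
    assert decode.auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5


def test_auc_matches_brute_force_and_sklearn(rng):
    scores = rng.integers(0, 8, 40).astype(float)   # ties included
    labels = rng.integers(0, 2, 40).astype(bool)
    if labels.all() or not labels.any():
        labels[:2] = [True, False]
    ours = decode.auc(scores, labels)
    assert ours == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
    assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=-5, max_value=5), min_size=4,
                max_size=30))
def test_auc_label_flip_symmetry(score_ints):
    """Flipping all labels maps AUC exactly to 1 - AUC (midrank ties)."""
    scores = np.array(score_ints, dtype=float)
    labels = np.arange(scores.size) % 2 == 0
    a = decode.auc(scores, labels)
    b = decode.auc(scores, ~labels)
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_map_agrees_with_scalar_auc(rng):
    scores = rng.standard_normal((30, 4, 5))
    labels = rng.integers(0, 2, 30).astype(bool)
    labels[:2] = [True, False]
    amap = decode.auc_map(scores, labels)
    for i in range(4):
        for j in range(5):
            assert amap[i, j] == pytest.approx(
                decode.auc(scores[:, i, j], labels), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        decode.auc([1.0, 2.0], [1, 1])


# -- temporal decoding ---------------------------------------------------------

def test_temporal_decoding_grid_91_points(tiny_subject):
    _, ep, _ = tiny_subject
    res = om.temporal_decoding(ep, ep.trials["probe_in_set"].to_numpy(),
                               (1.8, 2.7), cv=om.CVSpec(n_repeats=1))
    assert res.times.size == 91
    assert np.allclose(np.diff(res.times), 0.01)


def test_temporal_decoding_shuffled_labels_at_chance(tiny_subject, rng):
    _, ep, _ = tiny_subject
    labels = rng.permutation(ep.trials["probe_in_set"].to_numpy())
    res = om.temporal_decoding(ep, labels, (2.3, 2.7),
                               cv=om.CVSpec(n_repeats=2, seed=3))
    assert 0.45 <= res.auc.mean() <= 0.55


def test_temporal_decoding_planted_window_contrast(default_subject):
    """The pattern lives 0.3-0.7 s post-probe: decoding in the trained
    window clearly exceeds the pre-probe baseline."""
    _, ep, _ = default_subject
    res = om.temporal_decoding(ep, ep.trials["probe_in_set"].to_numpy(),
                               (1.8, 2.7))
    assert res.mean_auc((2.4, 2.7)) - res.mean_auc((1.8, 2.0)) > 0.2


def test_cv_reproducibility(tiny_subject):
    _, ep, _ = tiny_subject
    labels = ep.trials["probe_in_set"].to_numpy()
    r1 = om.temporal_decoding(ep, labels, (2.4, 2.6), cv=om.CVSpec(seed=9))
    r2 = om.temporal_decoding(ep, labels, (2.4, 2.6), cv=om.CVSpec(seed=9))
    assert np.array_equal(r1.fold_auc, r2.fold_auc)


def test_temporal_decoding_fewer_trials_than_folds_errors(tiny_subject):
    _, ep, _ = tiny_subject
    sub = om.EpochSet(data=ep.data[:4], times=ep.times, sfreq=ep.sfreq,
                      trials=ep.trials.iloc[:4].reset_index(drop=True))
    with pytest.raises(ValueError):
        om.temporal_decoding(sub, np.array([0, 1, 0, 1]), (2.4, 2.5))


# -- time generalization -------------------------------------------------------

def test_timegen_resubstitution_optimism(tiny_subject):
    """Training-data AUC on the diagonal is at least the cross-validated
    AUC at the same time points."""
    _, ep, _ = tiny_subject
    labels = ep.trials["probe_in_set"].to_numpy()
    window = (2.4, 2.6)
    cvres = om.temporal_decoding(ep, labels, window)
    tg = om.time_generalization(ep, labels, window, window)["all"]
    diag = np.diag(tg.auc)
    assert np.all(diag >= cvres.auc - 0.02)
    assert diag.mean() >= cvres.auc.mean()


def test_timegen_positive_and_inverted_retention_block():
    """A positive retention gain yields block AUC > 0.5; sign-inverting the
    gain yields the mirrored block below 0.5 (label-flip symmetry)."""
    base = dict(n_subjects=1, n_trials=96, n_blocks=4, n_channels=12,
                n_sources=27, seed=21)
    pos = om.SimulationConfig(
        reactivation_gain={"strong": 2.0, "weak": 2.0}, **base)
    neg = om.SimulationConfig(
        reactivation_gain={"strong": -2.0, "weak": -2.0}, **base)
    vals = {}
    for name, cfg in (("pos", pos), ("neg", neg)):
        ep, _ = om.Simulator(cfg).subject(0)
        labels = ep.trials["probe_in_set"].to_numpy()
        tg = om.time_generalization(ep, labels, (2.4, 2.7), (0.5, 1.0))["all"]
        vals[name] = om.memory_strength(tg, (2.4, 2.7), (0.5, 1.0))
    assert vals["pos"] > 0.55
    assert vals["neg"] < 0.45


def test_timegen_single_class_group_errors(tiny_subject):
    _, ep, _ = tiny_subject
    labels = ep.trials["probe_in_set"].to_numpy()
    groups = {"bad": labels}           # group with only probe-in trials
    with pytest.raises(ValueError):
        om.time_generalization(ep, labels, (2.4, 2.5), (0.5, 0.6),
                               groups=groups)


# -- memory strength -----------------------------------------------------------

def make_tg(auc_matrix, train_times, test_times):
    return decode.TimeGenResult(train_times=np.asarray(train_times),
                                test_times=np.asarray(test_times),
                                auc=np.asarray(auc_matrix))


def test_memory_strength_constant_matrix():
    tg = make_tg(np.full((5, 7), 0.5), np.linspace(2.4, 2.7, 5),
                 np.linspace(0.5, 1.0, 7))
    assert om.memory_strength(tg, (2.4, 2.7), (0.5, 1.0)) == 0.5


def test_memory_strength_block_selection():
    train = np.linspace(2.0, 2.7, 8)
    test = np.linspace(0.0, 1.0, 11)
    mat = np.full((8, 11), 0.5)
    trm = (train >= 2.4) & (train <= 2.7)
    tem = (test >= 0.5) & (test <= 1.0)
    mat[np.ix_(trm, tem)] = 0.6
    tg = make_tg(mat, train, test)
    assert om.memory_strength(tg, (2.4, 2.7), (0.5, 1.0)) == pytest.approx(0.6)
    with pytest.raises(ValueError):
        om.memory_strength(tg, (3.0, 3.5), (0.5, 1.0))


# -- band-filtered decoding ----------------------------------------------------

def test_band_decoding_white_noise_is_chance(rng):
    import pandas as pd
    data = rng.standard_normal((60, 8, 512))
    times = -1.0 + np.arange(512) / 256.0
    trials = pd.DataFrame({"subject": 0, "trial": np.arange(60), "block": 0,
                           "condition": "weak", "probe_in_set": False,
                           "response_correct": True, "rt_ms": 500.0})
    ep = om.EpochSet(data=data, times=times, sfreq=256.0, trials=trials)
    labels = np.arange(60) % 2 == 0
    specs = [decode.BandDecodingSpec("theta", (1.0, 7.0), "real"),
             decode.BandDecodingSpec("alpha", (9.0, 17.0), "real")]
    res = decode.band_filtered_decoding(ep, labels, (-0.3, 0.3), specs=specs,
                                        cv=om.CVSpec(n_repeats=1, seed=2))
    for r in res.values():
        assert 0.4 <= r.auc.mean() <= 0.6
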