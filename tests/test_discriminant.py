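import numpy as np
import pytest

from tcwt import (RunConfig, backproject_ldf, classify, cwt_transform,
                  detect_outliers, accumulate_ss, find_extrema,
                  fit_discriminant, fit_ldf, fit_pca, generate_dataset,
                  hotelling_t2, ldf_value, mahalanobis_sq, prepare_transforms,
                  project_filtered, step_down_select, t_scalogram, to_frequency,
                  window_and_baseline)
from helpers import make_small_spec, small_config


def two_class(rng, n=40, d=3, delta=0.0):
    X = rng.standard_normal((2 * n, d))
    X[:n, 0] += delta
    labels = np.asarray(["A"] * n + ["B"] * n, dtype=object)
    return X, labels


# ---------------------------------------------------------------------------
# step-down selection

def test_step_down_keeps_separable_component(rng):
    n = 30
    Wp = rng.standard_normal((2 * n, 2))
    Wp[:n, 0] += 4.0                     # component 0 separates strongly
    labels = np.asarray(["A"] * n + ["B"] * n, dtype=object)
    # make component 1 exactly null: B mirrors A
    Wp[n:, 1] = Wp[:n, 1]
    assert list(step_down_select(Wp, labels, alpha_sd=0.3)) == [0]


def test_step_down_pure_noise_keeps_first():
    # every component identical across conditions: all p-values are 1
    A = np.arange(12, dtype=float).reshape(6, 2)
    Wp = np.vstack([A, A])
    labels = np.asarray(["A"] * 6 + ["B"] * 6, dtype=object)
    assert list(step_down_select(Wp, labels, alpha_sd=0.3)) == [0]


def test_step_down_alpha_one_keeps_all(rng):
    Wp, labels = two_class(rng, n=10, d=4)
    assert list(step_down_select(Wp, labels, alpha_sd=1.0)) == [0, 1, 2, 3]


def test_step_down_selects_mid_rank_components(rng):
    n = 50
    Wp = rng.standard_normal((2 * n, 5))
    Wp[:n, 3] += 3.0                     # effect hidden in component 3
    labels = np.asarray(["A"] * n + ["B"] * n, dtype=object)
    assert 3 in step_down_select(Wp, labels, alpha_sd=0.05)


# ---------------------------------------------------------------------------
# LDA

def test_equal_priors_midpoint_on_plane(rng):
    X, labels = two_class(rng, delta=3.0)
    m = fit_ldf(X, labels)
    mid = 0.5 * (X[:40].mean(axis=0) + X[40:].mean(axis=0))
    assert ldf_value(mid, m) == pytest.approx(m.threshold, rel=1e-10)
    assert classify(X[:40].mean(axis=0), m) == "A"


def test_one_dimensional_reduction(rng):
    x = np.concatenate([rng.normal(2.0, 1.0, 50), rng.normal(-1.0, 1.0, 50)])
    labels = np.asarray(["A"] * 50 + ["B"] * 50, dtype=object)
    m = fit_ldf(x[:, None], labels)
    mu_a, mu_b = x[:50].mean(), x[50:].mean()
    s2 = (np.sum((x[:50] - mu_a) ** 2) + np.sum((x[50:] - mu_b) ** 2)) / 98
    assert m.ldf[0] == pytest.approx((mu_a - mu_b) / s2, rel=1e-10)


def test_spherical_classes_nearest_mean(rng):
    """With spherical covariance the LDF is parallel to the mean difference
    and classification reduces to the nearest class mean."""
    n, d = 400, 4
    A = rng.standard_normal((n, d)) + np.array([2.0, 0, 0, 0])
    B = rng.standard_normal((n, d))
    X = np.vstack([A, B])
    labels = np.asarray(["A"] * n + ["B"] * n, dtype=object)
    m = fit_ldf(X, labels)
    diff = A.mean(axis=0) - B.mean(axis=0)
    cos = m.ldf @ diff / np.linalg.norm(m.ldf) / np.linalg.norm(diff)
    assert cos > 0.99
    test = rng.standard_normal((200, d)) + np.array([1.0, 0, 0, 0])
    nearest = np.where(
        np.linalg.norm(test - A.mean(axis=0), axis=1)
        < np.linalg.norm(test - B.mean(axis=0), axis=1), "A", "B")
    agree = np.mean(classify(test, m) == nearest)
    assert agree > 0.97


def test_prior_shift_monotonicity(rng):
    X, labels = two_class(rng, delta=2.0)
    probe = rng.standard_normal((500, 3))
    n_a = []
    for pb in (0.2, 0.5, 0.8):
        m = fit_ldf(X, labels, priors=(1 - pb, pb))
        n_a.append(int(np.sum(classify(probe, m) == "A")))
    assert n_a[0] >= n_a[1] >= n_a[2]


def test_well_separated_error_below_one_percent():
    rng = np.random.default_rng(99)
    train = np.concatenate([rng.normal(6.0, 1.0, 200), rng.normal(0.0, 1.0, 200)])
    labels = np.asarray(["A"] * 200 + ["B"] * 200, dtype=object)
    m = fit_ldf(train[:, None], labels)
    test = np.concatenate([rng.normal(6.0, 1.0, 500), rng.normal(0.0, 1.0, 500)])
    truth = np.asarray(["A"] * 500 + ["B"] * 500, dtype=object)
    err = np.mean(classify(test[:, None], m) != truth)
    assert err < 0.01


def test_mean_difference_ldf_value_is_mahalanobis(rng):
    X, labels = two_class(rng, n=60, d=3, delta=1.5)
    m = fit_ldf(X, labels)
    mu_a, mu_b = X[:60].mean(axis=0), X[60:].mean(axis=0)
    A, B = X[:60] - mu_a, X[60:] - mu_b
    S = (A.T @ A + B.T @ B) / 118
    oracle = (mu_a - mu_b) @ np.linalg.inv(S) @ (mu_a - mu_b)
    assert (mu_a - mu_b) @ m.ldf == pytest.approx(oracle, rel=1e-10)


def test_ldf_optimal_direction(rng):
    """After sphering, the mean difference projects onto the LDF direction at
    least as strongly as onto random directions."""
    X, labels = two_class(rng, n=100, d=5, delta=1.0)
    m = fit_ldf(X, labels)
    pca = fit_pca(X, criterion=100.0)
    sphere = pca.loadings / np.sqrt(pca.eigvals)
    diff = X[:100].mean(axis=0) - X[100:].mean(axis=0)
    dz = diff @ sphere
    # LDF direction in the sphered space
    ldf_z = np.linalg.pinv(sphere) @ m.ldf
    best = abs(dz @ ldf_z / np.linalg.norm(ldf_z))
    for _ in range(200):
        u = rng.standard_normal(5)
        assert abs(dz @ u / np.linalg.norm(u)) <= best + 1e-9


def test_singular_covariance_rejected(rng):
    X = np.tile(rng.standard_normal((1, 3)), (10, 1))   # zero variance
    labels = np.asarray(["A"] * 5 + ["B"] * 5, dtype=object)
    with pytest.raises(np.linalg.LinAlgError):
        fit_ldf(X, labels)


# ---------------------------------------------------------------------------
# representation chain

def test_decision_value_chain_agreement():
    """SPC-space, frequency-domain and time-domain LDF products agree."""
    spec = make_small_spec(seed=31)
    cfg = small_config()
    e = window_and_baseline(generate_dataset(spec), 0.0, 0.3, (-0.1, 0.0))
    basis, grid, cb, F = prepare_transforms(e, cfg)
    rep, pca = detect_outliers(F, 2.7, cfg.pca_criterion)
    F0 = F.select(~rep.excluded)
    Fp = project_filtered(F0, pca)
    W = cwt_transform(Fp, cb)
    ts = t_scalogram(accumulate_ss(W, F0.labels), F0.n_channels)
    fb = find_extrema(ts, grid)
    model = fit_discriminant(W[:, fb.columns()], F0.labels,
                             cfg.pca_criterion, cfg.alpha_sd)
    backproject_ldf(model, pca, fb, cb, basis, e.n_channels)

    scores_feat = model.decision_values(W[:, fb.columns()])
    scores_freq = F0.data @ model.d_f
    scores_time = e.select(~rep.excluded).data @ model.d_time
    np.testing.assert_allclose(scores_feat, scores_freq, atol=1e-8)
    np.testing.assert_allclose(scores_feat, scores_time, atol=1e-8)


# ---------------------------------------------------------------------------
# Hotelling's T^2

def test_hotelling_identical_samples(rng):
    X = rng.standard_normal((20, 4))
    t2, f, p = hotelling_t2(X, X.copy(), features_independent=True)
    assert t2 == pytest.approx(0.0, abs=1e-20)
    assert p == pytest.approx(1.0)


def test_hotelling_univariate_equals_t_squared(rng):
    from scipy import stats
    a = rng.normal(0.5, 1.0, 14)
    b = rng.normal(0.0, 1.2, 19)
    t2, f, p = hotelling_t2(a, b, features_independent=True)
    t = stats.ttest_ind(a, b, equal_var=True).statistic
    assert t2 == pytest.approx(t * t, rel=1e-10)
    assert f == pytest.approx(t * t, rel=1e-10)   # p=1: F = T^2


def test_hotelling_warns_without_independence_flag(rng):
    with pytest.warns(UserWarning, match="independent"):
        hotelling_t2(rng.standard_normal((10, 2)),
                     rng.standard_normal((10, 2)))


def test_hotelling_insufficient_df(rng):
    with pytest.raises(ValueError, match="degrees of freedom"):
        hotelling_t2(rng.standard_normal((3, 5)),
                     rng.standard_normal((3, 5)),
                     features_independent=True)
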