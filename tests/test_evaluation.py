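import numpy as np
import pytest

from tcwt import (RunConfig, binomial_pvalue, biased_error, cwt_transform,
                  detect_outliers, estimate_demands, generate_dataset,
                  group_holdout, holdout_individual, pool_datasets,
                  prepare_transforms, project_filtered, split_half,
                  window_and_baseline)
from tcwt.evaluation import fit_fold
from helpers import make_small_spec, small_config


def windowed(spec):
    return window_and_baseline(generate_dataset(spec), 0.0, 0.3, (-0.1, 0.0))


# ---------------------------------------------------------------------------
# binomial test and resource estimates

def test_binomial_closed_forms():
    assert binomial_pvalue(0, 10, 0.5) == pytest.approx(2.0 ** -10, rel=1e-12)
    assert binomial_pvalue(10, 10, 0.5) == pytest.approx(1.0)


def test_binomial_matches_bruteforce_sum():
    from math import comb
    n, k, p = 37, 9, 0.136
    oracle = sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1))
    assert binomial_pvalue(k, n, p) == pytest.approx(oracle, rel=1e-12)
    with pytest.raises(ValueError):
        binomial_pvalue(5, 4, 0.5)
    with pytest.raises(ValueError):
        binomial_pvalue(1, 4, 0.0)


def test_resource_estimates_identities():
    r = estimate_demands(64, 1.0, 0.05, 15)
    assert r.n_f == 81
    assert r.n_p == 2 * 64**2 * 81**2 == 53_747_712
    assert r.n_w == 64 * r.n_f * r.n_g
    # closed-form approximation sits within a few percent of the exact count
    assert abs(r.n_p_approx - r.n_p) / r.n_p < 0.03
    rng = np.random.default_rng(5)
    for _ in range(10):
        K = int(rng.integers(1, 64))
        T = float(rng.uniform(0.3, 1.2))
        s_c = float(rng.uniform(0.03, 0.3))
        R = int(rng.integers(5, 20))
        r = estimate_demands(K, T, s_c, R)
        assert r.n_p == 2 * K * K * r.n_f**2
        assert r.n_w == K * r.n_f * r.n_g


def test_doubling_r_quadruples_approximate_nw():
    a = estimate_demands(9, 0.6, 0.04, 10)
    b = estimate_demands(9, 0.6, 0.04, 20)
    assert b.n_w_approx == pytest.approx(4.0 * a.n_w_approx)


# ---------------------------------------------------------------------------
# pooling

def test_pool_datasets():
    e1 = windowed(make_small_spec(seed=1))
    e2 = windowed(make_small_spec(seed=2))
    e2.dataset_ids[:] = "S02"
    pooled = pool_datasets([e1, e2])
    assert pooled.n_trials == e1.n_trials + e2.n_trials
    assert set(pooled.dataset_ids) == {"S01", "S02"}
    one = pool_datasets([e1])
    np.testing.assert_array_equal(one.data, e1.data)

    bad = windowed(make_small_spec(seed=3, channels=["a", "b", "c", "d"],
                                   components=[]))
    with pytest.raises(ValueError, match="disagree"):
        pool_datasets([e1, bad])


# ---------------------------------------------------------------------------
# protocols on separable synthetic data

@pytest.fixture(scope="module")
def strong_epochs():
    # crank the planted difference so classes separate nearly perfectly
    spec = make_small_spec(seed=17, white_sd=0.3, pink_sd=0.8)
    return windowed(spec)


def test_holdout_separable_low_error(strong_epochs):
    cfg = small_config(holdout_stride=2)
    rep = holdout_individual(strong_epochs, cfg)
    assert rep.total_error < 5.0
    assert rep.table["p_binomial"].iloc[0] < 1e-6
    assert rep.table["n_tested"].iloc[0] == 40


def test_split_half_deterministic_and_low_error(strong_epochs):
    rep = split_half(strong_epochs, small_config())
    # the chronological second half is tested: floor(80/2) trials
    assert rep.table["n_tested"].iloc[0] == 40
    assert rep.total_error < 15.0


def test_biased_flagged_and_zero_on_separable(strong_epochs):
    rep = biased_error(strong_epochs, small_config())
    assert rep.biased
    assert rep.total_error <= 2.0


def test_biased_not_worse_than_holdout_in_expectation():
    """Training-set error is an optimistic estimate: over seeds its mean
    cannot exceed the hold-out mean."""
    cfg = small_config(holdout_stride=4)
    b, h = [], []
    for seed in range(20):
        e = windowed(make_small_spec(seed=200 + seed))
        b.append(biased_error(e, cfg).total_error)
        h.append(holdout_individual(e, cfg).total_error)
    assert np.mean(b) <= np.mean(h) + 1.0


# ---------------------------------------------------------------------------
# leakage

def test_holdout_fold_ignores_held_out_trial():
    """Poisoning the held-out trial leaves the fold's fitted model bitwise
    unchanged (nothing downstream of the whole-sample stage sees it)."""
    e = windowed(make_small_spec(seed=55))
    cfg = small_config()
    basis, grid, cb, F = prepare_transforms(e, cfg)
    rep, pca = detect_outliers(F, cfg.c_individual, cfg.pca_criterion)
    F0 = F.select(~rep.excluded)
    Fp = project_filtered(F0, pca)
    W = cwt_transform(Fp, cb)
    i = 11
    mask = np.ones(F0.n_trials, dtype=bool)
    mask[i] = False

    m1, fb1 = fit_fold(F0.select(mask), pca, cb, grid, cfg, 2.7, W_train=W[mask])

    F_poison = F0.select(np.arange(F0.n_trials))
    F_poison.data[i] = 1e12
    W_poison = W.copy()
    W_poison[i] = 1e12
    m2, fb2 = fit_fold(F_poison.select(mask), pca, cb, grid, cfg, 2.7,
                       W_train=W_poison[mask])
    np.testing.assert_array_equal(fb1.vertices, fb2.vertices)
    np.testing.assert_array_equal(m1.ldf, m2.ldf)
    assert m1.threshold == m2.threshold


def test_group_holdout_shared_effect_and_leakage():
    spec = make_small_spec(seed=77, n_datasets=3, n_standard=50, n_deviant=18,
                           white_sd=0.5, pink_sd=1.5)
    pooled = windowed(spec)
    cfg = small_config()
    rep = group_holdout(pooled, cfg)
    assert len(rep.table) == 3
    assert (rep.table["err_total"] < 40.0).all()

    # leakage: the held-out dataset's trials never enter its own fold's
    # fitted model -- poisoning them leaves that model bitwise unchanged
    basis, grid, cb, F = prepare_transforms(pooled, cfg)
    test_mask = np.asarray(pooled.dataset_ids == "S01")

    def fold_model(Fin):
        r, pca = detect_outliers(Fin.select(~test_mask), cfg.c_group,
                                 cfg.group_pca_criterion)
        return fit_fold(Fin.select(~test_mask).select(~r.excluded),
                        pca, cb, grid, cfg, cfg.c_group)

    m1, fb1 = fold_model(F)
    F_poison = F.select(np.arange(F.n_trials))
    F_poison.data[test_mask] = 1e12
    m2, fb2 = fold_model(F_poison)
    np.testing.assert_array_equal(fb1.vertices, fb2.vertices)
    np.testing.assert_array_equal(m1.ldf, m2.ldf)
    assert m1.threshold == m2.threshold


def test_group_holdout_needs_three_datasets():
    pooled = windowed(make_small_spec(seed=5, n_datasets=2))
    with pytest.raises(ValueError, match="3 datasets"):
        group_holdout(pooled, small_config())


def test_group_holdout_inverted_dataset_misclassified():
    """A subject whose planted effect is sign-flipped relative to the group is
    classified near-perfectly wrongly on deviants."""
    from tcwt import Component
    spec = make_small_spec(seed=88, n_datasets=3, n_standard=50, n_deviant=18,
                           white_sd=0.4, pink_sd=1.0)
    good = windowed(spec)
    inv_comps = [Component(c.latency, c.scale, c.amplitude, -c.contrast,
                           c.topography) for c in spec.components]
    bad_spec = make_small_spec(seed=89, n_standard=50, n_deviant=18,
                               white_sd=0.4, pink_sd=1.0,
                               components=inv_comps)
    bad = windowed(bad_spec)
    bad.dataset_ids[:] = "S99"
    pooled = pool_datasets([good, bad])
    rep = group_holdout(pooled, small_config())
    assert rep.table.loc["S99", "err_deviant"] > 60.0
    assert (rep.table.drop("S99")["err_deviant"] < 40.0).all()
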