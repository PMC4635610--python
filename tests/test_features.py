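import numpy as np
import pytest

from tcwt import (ErpEpochs, RunConfig, accumulate_ss, build_cwt_basis,
                  build_log_grid, build_spectral_basis, cwt_transform,
                  extract_features, find_extrema, generate_dataset,
                  prepare_transforms, t_scalogram, to_frequency,
                  window_and_baseline)
from tcwt.features import TScalogram
from helpers import make_small_spec, small_config


# ---------------------------------------------------------------------------
# streaming sums of squares

def test_merge_equals_full_batch(rng):
    W = rng.standard_normal((30, 15))
    labels = np.asarray(["A"] * 14 + ["B"] * 16, dtype=object)
    full = accumulate_ss(W, labels)
    merged = accumulate_ss(W[:11], labels[:11], "A", "B").merge(
        accumulate_ss(W[11:], labels[11:], "A", "B")
    )
    for attr in ("n_a", "n_b"):
        assert getattr(full, attr) == getattr(merged, attr)
    for attr in ("sum_a", "sum_b", "sumsq_a", "sumsq_b"):
        np.testing.assert_allclose(getattr(full, attr), getattr(merged, attr),
                                   rtol=1e-12)


def test_constant_coefficients():
    W = np.full((8, 3), 2.5)
    labels = np.asarray(["A"] * 4 + ["B"] * 4, dtype=object)
    ss = accumulate_ss(W, labels)
    np.testing.assert_allclose(ss.sum_a, 4 * 2.5)
    # centered sum of squares vanishes
    np.testing.assert_allclose(ss.sumsq_a - ss.sum_a**2 / ss.n_a, 0.0,
                               atol=1e-10)


def test_mean_sd_match_two_pass_oracle(rng):
    W = rng.standard_normal((25, 9)) * 3.0 + 1.0
    labels = np.asarray(["A"] * 12 + ["B"] * 13, dtype=object)
    ss = accumulate_ss(W, labels)
    A = W[:12]
    np.testing.assert_allclose(ss.sum_a / ss.n_a, A.mean(axis=0), rtol=1e-12)
    css = ss.sumsq_a - ss.sum_a**2 / ss.n_a
    np.testing.assert_allclose(css / (ss.n_a - 1), A.var(axis=0, ddof=1),
                               rtol=1e-10)


def test_missing_condition_rejected(rng):
    # inferring conditions from a single label fails outright ...
    with pytest.raises(ValueError):
        accumulate_ss(rng.standard_normal((4, 2)), ["A", "A", "A", "A"])
    # ... and an explicit one-sided partial batch cannot yield t values
    ss = accumulate_ss(rng.standard_normal((4, 2)),
                       ["A", "A", "A", "A"], "A", "B")
    with pytest.raises(ValueError, match="at least 2 trials"):
        t_scalogram(ss, 1)


# ---------------------------------------------------------------------------
# t scalogram

def test_equal_means_give_zero_t(rng):
    A = rng.standard_normal((10, 6))
    W = np.vstack([A, A])          # both conditions see the same sample
    labels = np.asarray(["A"] * 10 + ["B"] * 10, dtype=object)
    ts = t_scalogram(accumulate_ss(W, labels), n_channels=2)
    np.testing.assert_allclose(ts.values, 0.0, atol=1e-10)
    assert ts.df == 18


def test_condition_swap_negates_t(rng):
    W = rng.standard_normal((20, 6))
    labels = np.asarray(["A"] * 8 + ["B"] * 12, dtype=object)
    t_ab = t_scalogram(accumulate_ss(W, labels, "A", "B"), 2)
    t_ba = t_scalogram(accumulate_ss(W, labels, "B", "A"), 2)
    np.testing.assert_allclose(t_ab.values, -t_ba.values, rtol=1e-12)


def test_hand_computed_pooled_t():
    W = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
    labels = np.asarray(["A"] * 3 + ["B"] * 3, dtype=object)
    ts = t_scalogram(accumulate_ss(W, labels), 1)
    # pooled SD = 1, t = sqrt(9/6) * (2 - 3) = -1.2247...
    assert ts.values[0, 0] == pytest.approx(-np.sqrt(1.5), rel=1e-12)


def test_degenerate_vertices_flagged():
    W = np.column_stack([np.array([1.0, 2, 3, 2, 3, 4]), np.full(6, 5.0)])
    labels = np.asarray(["A"] * 3 + ["B"] * 3, dtype=object)
    ts = t_scalogram(accumulate_ss(W, labels), 1)
    assert ts.values[0, 1] == 0.0 and ts.degenerate[0, 1]
    with pytest.raises(ValueError, match="degenerate"):
        t_scalogram(accumulate_ss(np.full((6, 2), 1.0), labels), 1)


# ---------------------------------------------------------------------------
# extrema

def make_ts(values, grid):
    values = np.atleast_2d(values)
    return TScalogram(values=values, df=10, condition_a="A", condition_b="B",
                      degenerate=np.zeros_like(values, dtype=bool))


def test_single_bump_single_extremum():
    # single scale line (S_c/2 = 4T); bump at h=3 dominates a strictly
    # monotone falloff, so exactly one maximum exists, at the peak
    T, R = 0.25, 40
    grid = build_log_grid(8 * T, T, R)
    assert grid.n_lines == 1
    v = 5.0 - 0.1 * np.abs(np.arange(grid.n_vertices) - 3)
    fb = find_extrema(make_ts(v, grid), grid)
    maxima = fb.vertices[fb.signs == 1]
    assert list(maxima) == [3]
    assert fb.t_values[fb.signs == 1][0] == 5.0


def bruteforce_extrema(values, grid, sign):
    """Exhaustive scan with an independently-derived neighbor set."""
    out = []
    for i in range(grid.n_vertices):
        g, h = grid.line[i], grid.h[i]
        nbrs = []
        if h > 0:
            nbrs.append(i - 1)
        if h < grid.line_counts[g] - 1:
            nbrs.append(i + 1)
        for gp in (g - 1, g + 1):
            if 0 <= gp < grid.n_lines:
                hp = int(round(grid.time[i] * grid.R / grid.line_scales[gp]))
                hp = min(max(hp, 0), grid.line_counts[gp] - 1)
                nbrs.append(grid.line_starts[gp] + hp)
        ok = True
        for j in nbrs:
            if sign * values[j] > sign * values[i]:
                ok = False
            elif values[j] == values[i] and j < i:
                ok = False
        if ok:
            out.append(i)
    return out


def test_extrema_match_exhaustive_oracle(rng):
    grid = build_log_grid(0.15, 0.4, 5)
    values = rng.standard_normal((2, grid.n_vertices))
    values[1, :10] = values[1, 0]          # include ties
    fb = find_extrema(make_ts(values, grid), grid)
    for ch in (0, 1):
        for sign in (1, -1):
            got = sorted(fb.vertices[(fb.channels == ch) & (fb.signs == sign)])
            assert got == bruteforce_extrema(values[ch], grid, sign)


def test_flat_scalogram_warns_empty():
    grid = build_log_grid(0.2, 0.4, 4)
    with pytest.warns(RuntimeWarning, match="flat"):
        fb = find_extrema(make_ts(np.zeros(grid.n_vertices), grid), grid)
    assert fb.n_features == 0


# ---------------------------------------------------------------------------
# feature extraction

@pytest.fixture(scope="module")
def small_pipeline():
    spec = make_small_spec(seed=21)
    cfg = small_config()
    e = window_and_baseline(generate_dataset(spec), 0.0, 0.3, (-0.1, 0.0))
    basis, grid, cb, F = prepare_transforms(e, cfg)
    W = cwt_transform(F, cb)
    ts = t_scalogram(accumulate_ss(W, F.labels), F.n_channels)
    fb = find_extrema(ts, grid)
    return spec, cfg, e, basis, grid, cb, F, W, ts, fb


def test_features_equal_scalogram_columns(small_pipeline):
    _, _, _, _, grid, cb, F, W, _, fb = small_pipeline
    W_star = extract_features(F, fb, cb)
    np.testing.assert_allclose(W_star, W[:, fb.columns()], atol=1e-12)


def test_extremum_t_values_consistent(small_pipeline):
    """t recomputed from the extracted features equals the scalogram values."""
    _, _, _, _, _, cb, F, W, ts, fb = small_pipeline
    W_star = extract_features(F, fb, cb)
    ss = accumulate_ss(W_star, F.labels, ts.condition_a, ts.condition_b)
    t_feat = t_scalogram(ss, 1).values[0]
    np.testing.assert_allclose(t_feat, fb.t_values, rtol=1e-8)


def test_planted_difference_recovered(small_pipeline):
    """The planted deviant-minus-standard component yields a strong extremum
    of the right sign near its latency in its peak-topography channel."""
    spec, _, _, _, grid, _, F, _, _, fb = small_pipeline
    comp = spec.components[1]     # contrast +3 at 180 ms, peak in channel 1
    m = (fb.channels == 1) & (fb.signs == 1)
    tt = grid.time[fb.vertices[m]]
    strong = np.abs(fb.t_values[m]) > 4.0
    assert np.any(strong & (np.abs(tt - comp.latency) < 0.05))


def test_label_permutation_destroys_extrema(small_pipeline):
    _, _, _, _, _, _, F, W, ts, _ = small_pipeline
    observed = np.abs(ts.values).max()
    rng = np.random.default_rng(8)
    beaten = 0
    for _ in range(20):
        perm = rng.permutation(len(F.labels))
        ts_p = t_scalogram(accumulate_ss(W, F.labels[perm]), F.n_channels)
        if np.abs(ts_p.values).max() < observed:
            beaten += 1
    assert beaten >= 19
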