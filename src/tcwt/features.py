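"""t-value scalograms and wavelet-domain feature extraction.

For a two-condition design the two-sample t statistic is computed at every
log-grid vertex and channel from streaming sums and sums of squares of the
CWT coefficients.  The features are the CWT coefficients at the local
extrema of the per-channel t surfaces; extracting them is a projection onto
the corresponding columns of the CWT matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import ErpEpochs
from .wavelet import CwtBasis, LogGrid

__all__ = [
    "ScalogramSS",
    "accumulate_ss",
    "TScalogram",
    "t_scalogram",
    "FeatureBasis",
    "find_extrema",
    "extract_features",
]


@dataclass
class ScalogramSS:
    """Streaming per-column count/sum/sum-of-squares for two conditions.

    Associative under :meth:`merge`, so trial blocks can be accumulated in
    any grouping.
    """

    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    sum_a: np.ndarray
    sum_b: np.ndarray
    sumsq_a: np.ndarray
    sumsq_b: np.ndarray

    def merge(self, other: "ScalogramSS") -> "ScalogramSS":
        if (self.condition_a, self.condition_b) != (other.condition_a, other.condition_b):
            raise ValueError("cannot merge accumulators over different conditions")
        return ScalogramSS(
            self.condition_a, self.condition_b,
            self.n_a + other.n_a, self.n_b + other.n_b,
            self.sum_a + other.sum_a, self.sum_b + other.sum_b,
            self.sumsq_a + other.sumsq_a, self.sumsq_b + other.sumsq_b,
        )


def accumulate_ss(
    W: np.ndarray,
    labels,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> ScalogramSS:
    """Accumulate counts, sums and sums of squares per condition.

    Conditions default to the two distinct labels in sorted order.
    """
    labels = np.asarray([str(x) for x in labels], dtype=object)
    tags = sorted(set(labels))
    if condition_a is None and condition_b is None:
        if len(tags) != 2:
            raise ValueError(f"expected two condition labels, found {tags}")
        condition_a, condition_b = tags
    ma = labels == condition_a
    mb = labels == condition_b
    if not ma.any() and not mb.any():
        raise ValueError(
            f"conditions {condition_a!r}/{condition_b!r} not present in {tags}"
        )
    # weighted BLAS reductions avoid copying the (large) row blocks
    wa = ma.astype(float)
    wb = mb.astype(float)
    W = np.asarray(W, dtype=float)
    W2 = np.square(W)
    return ScalogramSS(
        condition_a, condition_b,
        int(ma.sum()), int(mb.sum()),
        wa @ W, wb @ W,
        wa @ W2, wb @ W2,
    )


@dataclass
class TScalogram:
    """Per-channel two-sample t values on the log-grid.

    ``values`` has shape (K, N_G); ``degenerate`` marks vertices where the
    pooled variance vanished (t forced to zero there).
    """

    values: np.ndarray
    df: int
    condition_a: str
    condition_b: str
    degenerate: np.ndarray


def t_scalogram(ss: ScalogramSS, n_channels: int) -> TScalogram:
    """Pooled-variance two-sample t at every vertex and channel.

    t = sqrt(M*N/(M+N)) * (mean_A - mean_B) / sigma_AB with sigma_AB from the
    within-condition sums of squares over df = M + N - 2.
    """
    m, n = ss.n_a, ss.n_b
    if m < 2 or n < 2:
        raise ValueError("each condition needs at least 2 trials")
    mean_a = ss.sum_a / m
    mean_b = ss.sum_b / n
    css = (ss.sumsq_a - ss.sum_a**2 / m) + (ss.sumsq_b - ss.sum_b**2 / n)
    np.clip(css, 0.0, None, out=css)
    df = m + n - 2
    sigma = np.sqrt(css / df)
    degenerate = sigma <= 0
    if degenerate.all():
        raise ValueError("pooled variance is zero everywhere: degenerate data")
    t = np.zeros_like(sigma)
    np.divide(mean_a - mean_b, sigma, out=t, where=~degenerate)
    t *= np.sqrt(m * n / (m + n))
    k = n_channels
    return TScalogram(
        values=t.reshape(k, -1),
        df=df,
        condition_a=ss.condition_a,
        condition_b=ss.condition_b,
        degenerate=degenerate.reshape(k, -1),
    )


@dataclass
class FeatureBasis:
    """Local extrema of the t scalograms: the wavelet-domain feature set.

    Extrema are ordered by (channel, vertex index); ``signs`` is +1 for a
    local maximum and -1 for a minimum.
    """

    channels: np.ndarray   # (N_X,)
    vertices: np.ndarray   # (N_X,) flat vertex index into the grid
    t_values: np.ndarray   # (N_X,)
    signs: np.ndarray      # (N_X,)
    grid: LogGrid

    @property
    def n_features(self) -> int:
        return len(self.vertices)

    def columns(self, n_vertices: int | None = None) -> np.ndarray:
        """Column indices into a flat (trials, K*N_G) scalogram matrix."""
        n_g = self.grid.n_vertices if n_vertices is None else n_vertices
        return self.channels * n_g + self.vertices

    def restricted_block(self, cb: CwtBasis) -> np.ndarray:
        """T_star_w as a dense (K*N_F, N_X) matrix (block structure expanded)."""
        n_f = cb.block.shape[0]
        k = int(self.channels.max()) + 1 if self.n_features else 1
        out = np.zeros((k * n_f, self.n_features))
        for j, (ch, v) in enumerate(zip(self.channels, self.vertices)):
            out[ch * n_f : (ch + 1) * n_f, j] = cb.block[:, v]
        return out


def _extremum_mask(v: np.ndarray, nbr: np.ndarray, sign: int) -> np.ndarray:
    """Strict local extrema with lexicographic tie-breaking.

    A vertex wins against an equal-valued neighbor iff its (scale-major)
    index is smaller, so exactly one vertex per flat plateau survives.
    """
    idx = np.arange(len(v))
    ok = np.ones(len(v), dtype=bool)
    for col in range(nbr.shape[1]):
        j = nbr[:, col]
        valid = j >= 0
        vj = v[j[valid]]
        vi = v[valid]
        if sign > 0:
            win = (vi > vj) | ((vi == vj) & (idx[valid] < j[valid]))
        else:
            win = (vi < vj) | ((vi == vj) & (idx[valid] < j[valid]))
        ok[valid] &= win
    return ok


def find_extrema(ts: TScalogram, grid: LogGrid) -> FeatureBasis:
    """Detect per-channel local extrema of the t surfaces on the log-grid.

    The neighborhood of a vertex is its two within-line neighbors plus the
    nearest-in-time vertex on each adjacent scale line; rectangle edges use
    one-sided comparison.  A channel whose surface is constant contributes no
    extrema (with a warning).
    """
    if ts.values.shape[1] != grid.n_vertices:
        raise ValueError("scalogram layout does not match the grid")
    nbr = grid.neighbors()
    chans, verts, vals, signs = [], [], [], []
    for k in range(ts.values.shape[0]):
        v = ts.values[k]
        if np.all(v == v[0]):
            warnings.warn(
                f"flat t scalogram in channel {k}: no features", RuntimeWarning
            )
            continue
        for sign in (1, -1):
            m = _extremum_mask(v, nbr, sign)
            w = np.flatnonzero(m)
            chans.append(np.full(len(w), k, dtype=np.int64))
            verts.append(w)
            vals.append(v[w])
            signs.append(np.full(len(w), sign, dtype=np.int64))
    if chans:
        channels = np.concatenate(chans)
        vertices = np.concatenate(verts)
        t_values = np.concatenate(vals)
        sgn = np.concatenate(signs)
        order = np.lexsort((vertices, channels))
        channels, vertices, t_values, sgn = (
            channels[order], vertices[order], t_values[order], sgn[order]
        )
    else:
        channels = vertices = sgn = np.zeros(0, dtype=np.int64)
        t_values = np.zeros(0)
    return FeatureBasis(
        channels=channels, vertices=vertices, t_values=t_values,
        signs=sgn, grid=grid,
    )


def extract_features(F: ErpEpochs, fb: FeatureBasis, cb: CwtBasis) -> np.ndarray:
    """Feature matrix W*: each trial's CWT coefficient at every extremum.

    Equivalent to the full scalogram transform restricted to the extremum
    columns, computed channel by channel.
    """
    if F.domain != "frequency":
        raise ValueError("feature extraction expects frequency-domain epochs")
    n_f = cb.block.shape[0]
    if F.samples_per_channel != n_f:
        raise ValueError("epochs and CWT basis disagree on N_F")
    out = np.empty((F.n_trials, fb.n_features))
    for ch in np.unique(fb.channels):
        cols = np.flatnonzero(fb.channels == ch)
        src = F.data[:, ch * n_f : (ch + 1) * n_f]
        out[:, cols] = src @ cb.block[:, fb.vertices[cols]]
    return out
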