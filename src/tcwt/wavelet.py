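"""Mexican-Hat wavelet, scale-invariant log-grid, and the frequency-domain
continuous wavelet transform (CWT) matrix.

The CWT of a channel curve v(t) on the window [0, T) is

    w(s, t0) = (1/sqrt(s)) * integral_0^T v(tau) * psi((tau - t0)/s) dtau,

discretized as a left-endpoint Riemann sum at the original sampling rate.
The mother wavelet is the Mexican Hat psi(t) = (1 - 16 t^2) exp(-8 t^2),
whose unit scale is four times the textbook one so that a scale value
matches the duration of the ERP wave it responds to.

The (s, t0) plane is sampled on a logarithmic grid with R lines per scale
octave and R points per time interval of one scale length, confined to the
rectangle S_c/2 <= s <= 4T, 0 <= t0 <= T.  Because the CWT is linear, its
matrix restricted to the retained DFT basis functions (one N_F x N_G block,
reused for every channel) maps frequency-domain epochs straight to scalogram
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .epochs import ErpEpochs
from .spectral import SpectralBasis

__all__ = [
    "mexican_hat",
    "LogGrid",
    "build_log_grid",
    "grid_vertex_count",
    "CwtBasis",
    "build_cwt_basis",
    "cwt_transform",
]


def mexican_hat(t):
    """Mexican Hat mother wavelet, psi(t) = (1 - 16 t^2) exp(-8 t^2)."""
    t = np.asarray(t, dtype=float)
    out = (1.0 - 16.0 * t * t) * np.exp(-8.0 * t * t)
    return float(out) if out.ndim == 0 else out


def _scale_lines(s_c: float, T: float, R: int):
    """Scales S0 * 2^(g/R), anchored at S0 = S_c/2, up to 4T inclusive."""
    s0 = s_c / 2.0
    lines = []
    g = 0
    while True:
        s = s0 * 2.0 ** (g / R)
        if s > 4.0 * T * (1.0 + 1e-12):
            break
        lines.append(s)
        g += 1
    return s0, lines


def grid_vertex_count(s_c: float, T: float, R: int) -> int:
    """Closed-form vertex count sum_g (floor(R*T/s^g) + 1), no grid built."""
    _, lines = _scale_lines(s_c, T, R)
    return sum(int(math.floor(R * T / s + 1e-9)) + 1 for s in lines)


@dataclass
class LogGrid:
    """Scale-invariant sampling lattice in the (time-shift, scale) plane.

    Vertices are enumerated scale-major: line g holds the times
    t = s^g * h / R, h = 0..floor(R*T/s^g).
    """

    R: int
    S0: float
    T: float
    s_c: float
    scale: np.ndarray        # (N_G,) scale of each vertex, s
    time: np.ndarray         # (N_G,) time shift of each vertex, s
    line: np.ndarray         # (N_G,) scale-line index g
    h: np.ndarray            # (N_G,) within-line index
    line_scales: np.ndarray  # (G,) scale per line
    line_starts: np.ndarray  # (G,) first vertex index per line
    line_counts: np.ndarray  # (G,) vertices per line
    _neighbors: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.scale)

    @property
    def n_lines(self) -> int:
        return len(self.line_scales)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(s_min, s_max, t_min, t_max) of the confining rectangle."""
        return (self.s_c / 2.0, 4.0 * self.T, 0.0, self.T)

    def neighbors(self) -> np.ndarray:
        """(N_G, 4) neighbor indices (-1 where absent).

        Columns: previous/next vertex on the same scale line, then the
        nearest-in-time vertex on the scale lines below and above.
        """
        if self._neighbors is None:
            n = self.n_vertices
            nbr = np.full((n, 4), -1, dtype=np.int64)
            idx = np.arange(n)
            first = self.h == 0
            last = self.h == self.line_counts[self.line] - 1
            nbr[~first, 0] = idx[~first] - 1
            nbr[~last, 1] = idx[~last] + 1
            for col, dg in ((2, -1), (3, 1)):
                gp = self.line + dg
                ok = (gp >= 0) & (gp < self.n_lines)
                hp = np.rint(
                    self.time[ok] * self.R / self.line_scales[gp[ok]]
                ).astype(np.int64)
                hp = np.clip(hp, 0, self.line_counts[gp[ok]] - 1)
                nbr[ok, col] = self.line_starts[gp[ok]] + hp
            self._neighbors = nbr
        return self._neighbors


def build_log_grid(s_c: float, T: float, R: int) -> LogGrid:
    """Enumerate the log-grid confined to S_c/2 <= s <= 4T, 0 <= t <= T."""
    if R < 1 or int(R) != R:
        raise ValueError("scale-invariant sampling rate R must be a positive integer")
    R = int(R)
    if s_c <= 0 or s_c / 2.0 > 4.0 * T * (1.0 + 1e-12):
        raise ValueError("empty grid: require 0 < S_c/2 <= 4T")
    s0, lines = _scale_lines(s_c, T, R)
    scales, times, gs, hs = [], [], [], []
    starts, counts = [], []
    pos = 0
    for g, s in enumerate(lines):
        n_h = int(math.floor(R * T / s + 1e-9)) + 1
        starts.append(pos)
        counts.append(n_h)
        pos += n_h
        h = np.arange(n_h)
        scales.append(np.full(n_h, s))
        times.append(s * h / R)
        gs.append(np.full(n_h, g, dtype=np.int64))
        hs.append(h)
    return LogGrid(
        R=R, S0=s0, T=T, s_c=s_c,
        scale=np.concatenate(scales),
        time=np.concatenate(times),
        line=np.concatenate(gs),
        h=np.concatenate(hs),
        line_scales=np.asarray(lines),
        line_starts=np.asarray(starts, dtype=np.int64),
        line_counts=np.asarray(counts, dtype=np.int64),
    )


@dataclass
class CwtBasis:
    """Frequency-domain CWT matrix: one (N_F, N_G) block shared by all channels.

    Column (g, h) holds the CWT at vertex (s^g, t^{g,h}) of every retained
    DFT basis function, so a frequency-domain channel block right-multiplied
    by ``block`` yields that channel's scalogram sample.
    """

    block: np.ndarray
    grid: LogGrid
    rate: float
    wavelet: str = "mexican_hat"


def build_cwt_basis(
    grid: LogGrid,
    basis: SpectralBasis,
    chunk: int = 4096,
) -> CwtBasis:
    """CWT of each retained DFT basis function at every grid vertex.

    The convolution integral is a left-endpoint Riemann sum over [0, T) at
    the original sampling rate:  (1/sqrt(s)) * sum_l b(t_l) psi((t_l - t0)/s) / R0.
    """
    if abs(grid.T - basis.T) > 1e-9:
        raise ValueError("grid and spectral basis cover different windows")
    L = basis.n_samples
    t = np.arange(L) / basis.rate
    n_g = grid.n_vertices
    block = np.empty((basis.n_frequencies, n_g))
    for lo in range(0, n_g, chunk):
        hi = min(lo + chunk, n_g)
        s = grid.scale[lo:hi]
        arg = (t[:, None] - grid.time[lo:hi][None, :]) / s[None, :]
        psi = mexican_hat(arg) / (np.sqrt(s)[None, :] * basis.rate)
        block[:, lo:hi] = basis.T_hat_f.T @ psi
    return CwtBasis(block=block, grid=grid, rate=basis.rate)


def cwt_transform(
    F: ErpEpochs,
    cb: CwtBasis,
    block_size: int = 64,
) -> np.ndarray:
    """Scalogram samples of frequency-domain epochs.

    Returns a (n_trials, K * N_G) matrix; channel k's scalogram occupies
    columns [k*N_G, (k+1)*N_G).  Channels are processed one at a time and
    trials in blocks of ``block_size``, bounding the peak extra memory by one
    channel block times the trial block.
    """
    if F.domain != "frequency":
        raise ValueError("CWT input must be frequency-domain epochs")
    n_f = cb.block.shape[0]
    if F.samples_per_channel != n_f:
        raise ValueError(
            f"epochs carry {F.samples_per_channel} coefficients per channel, "
            f"CWT basis expects {n_f}"
        )
    n, k = F.n_trials, F.n_channels
    n_g = cb.grid.n_vertices
    out = np.empty((n, k * n_g))
    for ch in range(k):
        src = F.data[:, ch * n_f : (ch + 1) * n_f]
        dst = out[:, ch * n_g : (ch + 1) * n_g]
        for lo in range(0, n, block_size):
            hi = min(lo + block_size, n)
            dst[lo:hi] = src[lo:hi] @ cb.block
    return out
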