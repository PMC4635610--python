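"""Real-DFT frequency representation with low-pass and time-window envelopes.

The time-domain epoch of length T (L = rate*T samples) is rotated into an
orthonormal real discrete Fourier basis and reduced to the frequencies
f_j = j/T with f_j <= 2*f_c, where f_c = 1/S_c is the cutoff frequency of the
cutoff scale S_c.  Frequencies in the last retained octave (f_c, 2*f_c] are
attenuated linearly, and a Tukey-type fade-in/fade-out envelope may be applied
in the time domain.  The forward transform of an epoch row v is

    v_f = v @ T_tilde_f,      T_tilde_f = diag(R_t) @ T_hat_f @ diag(R_f),

and the (filtering) return to the time domain uses the orthonormal block
alone: v_filtered = v_f @ T_hat_f.T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .epochs import ErpEpochs

__all__ = ["SpectralBasis", "build_spectral_basis", "to_frequency", "to_time"]


@dataclass
class SpectralBasis:
    T: float                 # window length, s
    rate: float              # sampling frequency R0, Hz
    s_c: float               # cutoff scale, s
    t_in: float              # fade-in time, s
    t_out: float             # fade-out start time, s
    freqs: np.ndarray        # retained frequency of every column, Hz
    T_hat_f: np.ndarray      # (L, N_F) orthonormal reduced real-DFT block
    R_f: np.ndarray          # (N_F,) frequency attenuation envelope
    R_t: np.ndarray          # (L,) time-window envelope
    T_tilde_f: np.ndarray    # (L, N_F) combined per-channel transform

    @property
    def f_c(self) -> float:
        return 1.0 / self.s_c

    @property
    def n_frequencies(self) -> int:
        """N_F: DC plus a cos/sin pair per retained nonzero frequency."""
        return self.T_hat_f.shape[1]

    @property
    def n_samples(self) -> int:
        return self.T_hat_f.shape[0]


def tukey_envelope(t: np.ndarray, T: float, t_in: float, t_out: float) -> np.ndarray:
    """Tukey window rising over [0, t_in), flat, falling over [t_out, T)."""
    env = np.ones_like(t)
    if t_in > 0:
        m = t < t_in
        env[m] = 0.5 * (1.0 - np.cos(np.pi * t[m] / t_in))
    if t_out < T:
        m = t >= t_out
        env[m] = 0.5 * (1.0 - np.cos(np.pi * (T - t[m]) / (T - t_out)))
    return env


def build_spectral_basis(
    T: float,
    rate: float,
    s_c: float,
    t_in: float = 0.0,
    t_out: float | None = None,
) -> SpectralBasis:
    """Construct the reduced, enveloped real-DFT basis for one channel.

    Parameters
    ----------
    T:
        Analysis window length in seconds; ``rate * T`` must be integral.
    rate:
        Sampling frequency R0 in Hz.
    s_c:
        Cutoff scale in seconds; the cutoff frequency is f_c = 1/s_c and
        frequencies up to 2*f_c are retained.
    t_in, t_out:
        Fade-in duration and fade-out start time of the time-window envelope.
        ``t_out=None`` disables the fade-out (t_out = T).
    """
    if s_c <= 0:
        raise ValueError("cutoff scale must be positive")
    Lf = rate * T
    L = int(round(Lf))
    if abs(Lf - L) > 1e-6 or L < 2:
        raise ValueError(f"rate*T = {Lf} is not a positive integer sample count")
    if t_out is None:
        t_out = T
    if not (0.0 <= t_in <= t_out <= T):
        raise ValueError("require 0 <= t_in <= t_out <= T")

    f_c = 1.0 / s_c
    j_max = int(math.floor(2.0 * f_c * T + 1e-9))
    if j_max >= L / 2:
        raise ValueError(
            f"cutoff 2*f_c = {2 * f_c} Hz needs j_max < L/2 = {L / 2}; "
            "increase the sampling rate or the cutoff scale"
        )

    t = np.arange(L) / rate
    cols = [np.full(L, 1.0 / math.sqrt(L))]
    freqs = [0.0]
    for j in range(1, j_max + 1):
        f = j / T
        phase = 2.0 * np.pi * f * t
        for w in (np.cos(phase), np.sin(phase)):
            cols.append(w / np.linalg.norm(w))
            freqs.append(f)
    T_hat = np.column_stack(cols)
    freqs = np.asarray(freqs)

    R_f = np.where(freqs <= f_c + 1e-12, 1.0, 2.0 - freqs / f_c)
    R_t = tukey_envelope(t, T, t_in, t_out)
    T_tilde = (R_t[:, None] * T_hat) * R_f[None, :]
    return SpectralBasis(
        T=T, rate=rate, s_c=s_c, t_in=t_in, t_out=t_out,
        freqs=freqs, T_hat_f=T_hat, R_f=R_f, R_t=R_t, T_tilde_f=T_tilde,
    )


def _check_channels(e: ErpEpochs, b: SpectralBasis, per_channel: int) -> None:
    if e.samples_per_channel != per_channel:
        raise ValueError(
            f"epoch channel block has {e.samples_per_channel} columns, "
            f"basis expects {per_channel}"
        )


def to_frequency(e: ErpEpochs, b: SpectralBasis) -> ErpEpochs:
    """Filtered frequency representation: each channel block times T_tilde_f."""
    if e.domain != "time":
        raise ValueError("input must be time-domain epochs")
    _check_channels(e, b, b.n_samples)
    out = e.blocks() @ b.T_tilde_f
    return e.with_data(out.reshape(e.n_trials, -1), domain="frequency")


def to_time(f: ErpEpochs, b: SpectralBasis) -> ErpEpochs:
    """Rotate frequency-domain epochs back: each block times T_hat_f.T.

    Because the reduced basis is rectangular this returns the *filtered*
    time-domain signal, not the original one.
    """
    if f.domain != "frequency":
        raise ValueError("input must be frequency-domain epochs")
    _check_channels(f, b, b.n_frequencies)
    out = f.blocks() @ b.T_hat_f.T
    return f.with_data(out.reshape(f.n_trials, -1), domain="time")
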