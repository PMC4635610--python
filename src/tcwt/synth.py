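"""Synthetic multi-subject oddball ERP datasets with known ground truth.

The generator emulates a passive auditory oddball recording: 9 scalp
channels at 500 Hz, 700 ms epochs starting 100 ms before the trigger,
242 frequent "standard" and 38 rare "deviant" trials per dataset.  The
deviant-minus-standard response is a sum of Mexican-Hat-shaped components -
by default a mismatch negativity near 200 ms, a P3 near 300 ms and a
negative slow wave near 400 ms, each with its own scalp topography.  Noise
is 1/f-dominated with a white floor, spatially correlated through a shared
source, and a few trials are scaled up wholesale to mimic high-amplitude
artifacts.  Every draw is reproducible from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import ErpEpochs
from .wavelet import mexican_hat

__all__ = ["Component", "SynthSpec", "generate_dataset", "DEFAULT_CHANNELS"]

DEFAULT_CHANNELS = ["Fz", "Cz", "Pz", "F3", "F4", "C3", "C4", "P3", "P4"]


@dataclass
class Component:
    """One ERP component: a Mexican-Hat deflection at a latency and scale.

    A standard trial receives ``amplitude`` (µV) times the topography; a
    deviant trial receives ``amplitude + contrast``, so ``contrast`` is the
    planted deviant-minus-standard difference.
    """

    latency: float            # s, relative to the trigger
    scale: float              # s, duration parameter of the deflection
    amplitude: float          # µV in the standard condition
    contrast: float           # µV added in the deviant condition
    topography: np.ndarray    # per-channel weights

    def waveform(self, t: np.ndarray, deviant: bool) -> np.ndarray:
        amp = self.amplitude + (self.contrast if deviant else 0.0)
        return amp * mexican_hat((t - self.latency) / self.scale)


def _default_components() -> list[Component]:
    mk = np.asarray
    return [
        # obligatory auditory response, identical in both conditions
        Component(0.10, 0.08, -3.0, 0.0,
                  mk([1.0, 1.0, 0.6, 0.8, 0.8, 0.8, 0.8, 0.5, 0.5])),
        # mismatch negativity, fronto-central, ~200 ms
        Component(0.20, 0.12, 0.0, -3.0,
                  mk([1.0, 0.8, 0.4, 0.9, 0.9, 0.7, 0.7, 0.3, 0.3])),
        # P3, parietal maximum, ~300 ms
        Component(0.30, 0.16, 0.0, 5.0,
                  mk([0.4, 0.8, 1.0, 0.3, 0.3, 0.6, 0.6, 0.9, 0.9])),
        # negative slow wave, ~400 ms
        Component(0.40, 0.20, 0.0, -2.5,
                  mk([0.6, 1.0, 0.8, 0.5, 0.5, 0.8, 0.8, 0.7, 0.7])),
    ]


@dataclass
class SynthSpec:
    """Generation parameters; defaults reproduce the emulated study layout."""

    seed: int
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    rate: float = 500.0
    t0: float = -0.1
    duration: float = 0.7            # epoch length incl. 100 ms baseline, s
    n_standard: int = 242
    n_deviant: int = 38
    components: list[Component] = field(default_factory=_default_components)
    white_sd: float = 2.0            # µV per sample
    pink_sd: float = 8.0             # µV RMS of the 1/f noise
    noise_correlation: float = 0.5   # variance fraction from the shared source
    n_outliers: int = 3              # trials scaled wholesale per dataset
    outlier_gain: float = 10.0
    n_datasets: int = 1
    inter_subject_sd: float = 0.2    # SD of the per-subject gain around 1
    standard_label: str = "standard"
    deviant_label: str = "deviant"

    def validate(self) -> "SynthSpec":
        L = self.rate * self.duration
        if abs(L - round(L)) > 1e-9 or L < 2:
            raise ValueError("rate*duration must be a positive integer")
        for c in self.components:
            rel = c.latency - self.t0
            if not (0.0 < rel < self.duration):
                raise ValueError(f"component latency {c.latency} outside epoch")
            if len(np.asarray(c.topography)) != len(self.channels):
                raise ValueError("topography length must match channel count")
            if not np.isfinite([c.amplitude, c.contrast]).all():
                raise ValueError("component amplitudes must be finite")
        if self.n_standard < 1 or self.n_deviant < 1 or self.n_datasets < 1:
            raise ValueError("trial and dataset counts must be positive")
        if not (0.0 <= self.noise_correlation <= 1.0):
            raise ValueError("noise_correlation must lie in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_standard:
            raise ValueError("invalid outlier count")
        return self


def _pink_noise(rng: np.random.Generator, n_rows: int, L: int,
                rate: float, sd: float) -> np.ndarray:
    """Rows of 1/f noise via spectral synthesis with random phases."""
    if sd == 0.0:
        return np.zeros((n_rows, L))
    freqs = np.fft.rfftfreq(L, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / freqs[1:]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_rows, len(freqs)))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=L, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return sd * x


def generate_dataset(spec: SynthSpec, return_truth: bool = False):
    """Draw a synthetic oddball sample (optionally with its ground truth).

    Returns the epochs, or ``(epochs, truth)`` where ``truth`` records the
    planted outlier rows, per-subject gains, and the noiseless
    deviant-minus-standard difference curves per channel.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K = len(spec.channels)
    L = int(round(spec.rate * spec.duration))
    t = spec.t0 + np.arange(L) / spec.rate
    n = spec.n_standard + spec.n_deviant
    if spec.components:
        topo = np.stack([np.asarray(c.topography, dtype=float)
                         for c in spec.components])
    else:
        topo = np.zeros((1, K))

    datasets = []
    truth = {"outlier_rows": [], "subject_gains": [], "difference": None}
    row_offset = 0
    for d in range(spec.n_datasets):
        gain = 1.0 + spec.inter_subject_sd * rng.standard_normal()
        labels = np.array(
            [spec.standard_label] * spec.n_standard
            + [spec.deviant_label] * spec.n_deviant, dtype=object
        )
        rng.shuffle(labels)
        deviant = labels == spec.deviant_label

        if spec.components:
            wf_std = np.stack([c.waveform(t, False) for c in spec.components])
            wf_dev = np.stack([c.waveform(t, True) for c in spec.components])
        else:
            wf_std = wf_dev = np.zeros((1, L))
        sig_std = gain * (topo.T @ wf_std)   # (K, L)
        sig_dev = gain * (topo.T @ wf_dev)

        data = np.empty((n, K * L))
        shared_w = np.sqrt(spec.noise_correlation)
        indep_w = np.sqrt(1.0 - spec.noise_correlation)
        for i in range(n):
            sig = sig_dev if deviant[i] else sig_std
            shared = (
                shared_w
                * (_pink_noise(rng, 1, L, spec.rate, spec.pink_sd)[0]
                   + spec.white_sd * rng.standard_normal(L))
            )
            indep = indep_w * (
                _pink_noise(rng, K, L, spec.rate, spec.pink_sd)
                + spec.white_sd * rng.standard_normal((K, L))
            )
            data[i] = (sig + shared[None, :] + indep).reshape(-1)

        out_rows = rng.choice(n, size=spec.n_outliers, replace=False) \
            if spec.n_outliers else np.zeros(0, dtype=int)
        data[out_rows] *= spec.outlier_gain

        ds_id = f"S{d + 1:02d}"
        datasets.append(ErpEpochs(
            data=data,
            channels=list(spec.channels),
            rate=spec.rate,
            t0=spec.t0,
            labels=labels,
            dataset_ids=np.array([ds_id] * n, dtype=object),
            trial_index=np.arange(n),
        ))
        truth["outlier_rows"].append(np.sort(out_rows) + row_offset)
        truth["subject_gains"].append(gain)
        row_offset += n

    if spec.components:
        truth["difference"] = topo.T @ np.stack(
            [c.contrast * mexican_hat((t - c.latency) / c.scale)
             for c in spec.components]
        )
    else:
        truth["difference"] = np.zeros((K, L))
    if len(datasets) == 1:
        epochs = datasets[0]
    else:
        from .evaluation import pool_datasets
        epochs = pool_datasets(datasets)
    return (epochs, truth) if return_truth else epochs
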