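"""Shared builders for reduced-size test problems."""

import numpy as np

from tcwt import Component, ErpEpochs, RunConfig, SynthSpec


def make_small_spec(seed: int, **overrides) -> SynthSpec:
    """A reduced oddball spec (3 channels, 200 Hz, short window) for fast tests."""
    base = dict(
        seed=seed,
        channels=["a", "b", "c"],
        rate=200.0,
        t0=-0.1,
        duration=0.4,
        n_standard=60,
        n_deviant=20,
        components=[
            Component(0.10, 0.08, -1.0, 0.0, np.array([1.0, 0.5, 0.2])),
            Component(0.18, 0.10, 0.0, 3.0, np.array([0.3, 1.0, 0.6])),
        ],
        white_sd=1.0,
        pink_sd=3.0,
        n_outliers=0,
        inter_subject_sd=0.1,
    )
    base.update(overrides)
    return SynthSpec(**base)


def small_config(**overrides) -> RunConfig:
    base = dict(s_c=0.08, grid_rate=6, t_in=0.0, t_out=None)
    base.update(overrides)
    return RunConfig(**base)


def toy_epochs(n_trials=4, n_channels=2, n_samples=8, rate=100.0, t0=0.0,
               labels=None, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_channels * n_samples))
    return ErpEpochs(
        data=data,
        channels=[f"ch{k}" for k in range(n_channels)],
        rate=rate,
        t0=t0,
        labels=np.asarray(labels, dtype=object) if labels is not None else None,
    )
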