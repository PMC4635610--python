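"""Single-trial ERP epoch container and pre-processing.

An epoch sample of N trials from K channels, each L samples long, is stored
as an N-by-(K*L) matrix of voltages (microvolts).  Trials are rows; within a
row the K channel curves are concatenated channel-major, so channel k
(0-based) occupies columns [k*L, (k+1)*L).  Sample l (0-based) of a channel
corresponds to time t0 + l/rate relative to the trigger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ErpEpochs",
    "AsciiDialect",
    "AsciiParseError",
    "load_ascii_epochs",
    "save_ascii_epochs",
    "window_and_baseline",
    "prune_oddball_sequence",
]


class AsciiParseError(ValueError):
    """Raised when a plain-text epoch file does not parse under its dialect."""


@dataclass
class ErpEpochs:
    """Multi-channel single-trial ERP sample.

    Parameters
    ----------
    data:
        (n_trials, n_channels * samples_per_channel) voltage matrix, µV.
        For frequency-domain epochs the per-channel block holds spectral
        coefficients instead of time samples (``domain == "frequency"``).
    channels:
        Ordered channel labels.
    rate:
        Sampling frequency R0 in Hz (of the underlying time representation).
    t0:
        Time of the first sample relative to the trigger, seconds.
    labels:
        Per-trial condition tag (e.g. ``"standard"``/``"deviant"``).
    dataset_ids:
        Per-trial subject/dataset tag.
    trial_index:
        Original presentation ordinal of each trial within its dataset.
    """

    data: np.ndarray
    channels: list[str]
    rate: float
    t0: float = 0.0
    labels: np.ndarray = None
    dataset_ids: np.ndarray = None
    trial_index: np.ndarray = None
    domain: str = "time"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be a 2-D (trials x K*L) matrix")
        n = self.data.shape[0]
        k = len(self.channels)
        if k == 0 or self.data.shape[1] % k != 0:
            raise ValueError(
                f"column count {self.data.shape[1]} is not a multiple of the "
                f"{k} declared channels"
            )
        if self.labels is None:
            self.labels = np.array(["A"] * n, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.dataset_ids is None:
            self.dataset_ids = np.array(["0"] * n, dtype=object)
        self.dataset_ids = np.asarray(self.dataset_ids, dtype=object)
        if self.trial_index is None:
            self.trial_index = np.arange(n)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        for name, arr in (
            ("labels", self.labels),
            ("dataset_ids", self.dataset_ids),
            ("trial_index", self.trial_index),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per trial")

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def samples_per_channel(self) -> int:
        return self.data.shape[1] // self.n_channels

    @property
    def duration(self) -> float:
        """Window length T = L / rate (time domain only)."""
        if self.domain != "time":
            raise ValueError("duration is defined for time-domain epochs")
        return self.samples_per_channel / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to the trigger (time domain only)."""
        if self.domain != "time":
            raise ValueError("times are defined for time-domain epochs")
        return self.t0 + np.arange(self.samples_per_channel) / self.rate

    def channel(self, k: int) -> np.ndarray:
        """View of channel k's (n_trials, L) block."""
        L = self.samples_per_channel
        return self.data[:, k * L : (k + 1) * L]

    def blocks(self) -> np.ndarray:
        """(n_trials, K, L) view of the channel-major layout."""
        return self.data.reshape(self.n_trials, self.n_channels, -1)

    def select(self, rows) -> "ErpEpochs":
        """New container restricted to the given trial rows (mask or index)."""
        rows = np.asarray(rows)
        return replace(
            self,
            data=self.data[rows],
            labels=self.labels[rows],
            dataset_ids=self.dataset_ids[rows],
            trial_index=self.trial_index[rows],
        )

    def with_data(self, data: np.ndarray, *, domain: str | None = None,
                  t0: float | None = None) -> "ErpEpochs":
        return replace(
            self,
            data=data,
            domain=self.domain if domain is None else domain,
            t0=self.t0 if t0 is None else t0,
        )


@dataclass
class AsciiDialect:
    """Declared layout of a plain-text epoch file.

    The default dialect is whitespace-delimited, one sample-row per line with
    channels as columns, and trials separated by blank lines.  The layout is
    declared, never sniffed.
    """

    delimiter: str | None = None  # None = any whitespace
    comment: str = "#"
    channels: Sequence[str] | None = None
    rate: float | None = None
    t0: float = 0.0


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def load_ascii_epochs(path, dialect: AsciiDialect | None = None) -> ErpEpochs:
    """Read single-trial epochs from a plain-text matrix file.

    Trials are blocks of L lines with K columns each, separated by blank
    lines.  Metadata (channels, rate, t0, labels, dataset ids) is taken from
    a JSON sidecar ``<file>.json`` when present, falling back to the dialect.
    """
    path = Path(path)
    dialect = dialect or AsciiDialect()
    trials: list[list[list[float]]] = []
    block: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith(dialect.comment):
                continue
            if not line:
                if block:
                    trials.append(block)
                    block = []
                continue
            parts = line.split(dialect.delimiter)
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise AsciiParseError(
                    f"{path.name}: malformed row at line {lineno}: {line!r}"
                ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise AsciiParseError(
                    f"{path.name}: line {lineno} has {len(row)} columns, "
                    f"expected {width}"
                )
            block.append(row)
    if block:
        trials.append(block)
    if not trials:
        raise AsciiParseError(f"{path.name}: no trials found")

    lengths = {len(t) for t in trials}
    if len(lengths) != 1:
        raise ValueError(
            f"{path.name}: inconsistent trial lengths {sorted(lengths)}"
        )

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    channels = meta.get("channels") or (
        list(dialect.channels) if dialect.channels else None
    )
    if channels is None:
        channels = [f"ch{k}" for k in range(width)]
    if len(channels) != width:
        raise ValueError(
            f"{path.name}: {width} columns but {len(channels)} declared channels"
        )
    rate = meta.get("rate", dialect.rate)
    if rate is None:
        raise ValueError("sampling rate not declared (dialect or sidecar)")

    # (trials, L, K) -> channel-major rows
    arr = np.asarray(trials, dtype=float)
    data = arr.transpose(0, 2, 1).reshape(arr.shape[0], -1)
    return ErpEpochs(
        data=data,
        channels=list(channels),
        rate=float(rate),
        t0=float(meta.get("t0", dialect.t0)),
        labels=np.asarray(meta["labels"], dtype=object) if "labels" in meta else None,
        dataset_ids=(
            np.asarray(meta["dataset_ids"], dtype=object)
            if "dataset_ids" in meta else None
        ),
        trial_index=(
            np.asarray(meta["trial_index"], dtype=int)
            if "trial_index" in meta else None
        ),
    )


def save_ascii_epochs(e: ErpEpochs, path) -> Path:
    """Write epochs in the default plain-text dialect plus a JSON sidecar.

    Values are printed with 17 significant digits so a round trip reproduces
    the data exactly.
    """
    path = Path(path)
    L = e.samples_per_channel
    with open(path, "w") as fh:
        for n in range(e.n_trials):
            trial = e.data[n].reshape(e.n_channels, L).T  # rows=samples
            for row in trial:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")
    meta = {
        "channels": list(e.channels),
        "rate": e.rate,
        "t0": e.t0,
        "labels": list(map(str, e.labels)),
        "dataset_ids": list(map(str, e.dataset_ids)),
        "trial_index": [int(i) for i in e.trial_index],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def window_and_baseline(
    e: ErpEpochs,
    start: float,
    length: float,
    baseline: tuple[float, float],
) -> ErpEpochs:
    """Crop to [start, start+length) and subtract the per-channel baseline mean.

    ``baseline`` is a half-open interval (b0, b1) in seconds relative to the
    trigger; its per-trial, per-channel mean is subtracted from the whole
    trial before cropping.
    """
    if e.domain != "time":
        raise ValueError("windowing applies to time-domain epochs")
    L = e.samples_per_channel
    r = e.rate

    def idx(t: float) -> int:
        return int(round((t - e.t0) * r))

    i0, n = idx(start), int(round(length * r))
    b0, b1 = idx(baseline[0]), idx(baseline[1])
    if not (0 <= i0 and i0 + n <= L):
        raise ValueError(
            f"window [{start}, {start + length}) lies outside the stored epoch"
        )
    if not (0 <= b0 < b1 <= L):
        raise ValueError(f"baseline interval {baseline} lies outside the epoch")

    blocks = e.blocks()
    base = blocks[:, :, b0:b1].mean(axis=2, keepdims=True)
    out = (blocks - base)[:, :, i0 : i0 + n]
    return e.with_data(out.reshape(e.n_trials, -1), t0=start)


def prune_oddball_sequence(
    e: ErpEpochs,
    n_initial: int = 10,
    standard: str | None = None,
    deviant: str | None = None,
) -> ErpEpochs:
    """Prune an oddball sequence per dataset.

    Per dataset (in presentation order): the first ``n_initial`` trials are
    dropped; within every maximal run of two or more consecutive deviants only
    the first deviant is kept, the rest are dropped together with the single
    standard immediately following the run.
    """
    tags = sorted(set(map(str, e.labels)))
    if len(tags) != 2:
        raise ValueError(f"expected exactly two condition tags, found {tags}")
    if deviant is None or standard is None:
        counts = {t: int(np.sum(e.labels == t)) for t in tags}
        if counts[tags[0]] == counts[tags[1]]:
            raise ValueError(
                "equal condition counts: pass standard=/deviant= explicitly"
            )
        deviant = min(counts, key=counts.get) if deviant is None else deviant
        standard = next(t for t in tags if t != deviant) if standard is None else standard
    if {standard, deviant} != set(tags):
        raise ValueError(
            f"labels {tags} do not match standard={standard!r}, deviant={deviant!r}"
        )

    keep = np.zeros(e.n_trials, dtype=bool)
    for ds in np.unique(e.dataset_ids):
        rows = np.flatnonzero(e.dataset_ids == ds)
        rows = rows[np.argsort(e.trial_index[rows], kind="stable")]
        rows = rows[n_initial:]
        labels = [str(e.labels[r]) for r in rows]
        retained = np.ones(len(rows), dtype=bool)
        i = 0
        while i < len(rows):
            if labels[i] == deviant:
                j = i
                while j + 1 < len(rows) and labels[j + 1] == deviant:
                    j += 1
                if j > i:  # run of >= 2 deviants
                    retained[i + 1 : j + 1] = False
                    if j + 1 < len(rows) and labels[j + 1] == standard:
                        retained[j + 1] = False
                i = j + 1
            else:
                i += 1
        keep[rows[retained]] = True
    return e.select(keep)
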