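"""Classification error-rate estimators, binomial significance tests, dataset
pooling, and the computational-resource estimator.

Four error-rate protocols are provided, mirroring the standard practice for
single-trial ERP classifiers:

* individual hold-out - leave one trial out, refit everything downstream of
  the whole-sample outlier stage, classify the left-out trial;
* individual split-half - train on the chronological first half, test on the
  second half;
* individual biased - train and test on the same trials (optimistic bound);
* group hold-out - pool datasets, leave one whole dataset out, classify its
  trials with the group model.

Error counts are tested against chance with the lower-tail binomial
probability; with unequal priors the chance error rate is the minority-class
prior (the misclassify-all-minority baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .discriminant import DiscriminantModel, classify, fit_discriminant
from .epochs import ErpEpochs
from .features import (FeatureBasis, accumulate_ss, extract_features,
                       find_extrema, t_scalogram)
from .outliers import (PcaModel, detect_outliers, per_condition_outliers,
                       project_filtered)
from .spectral import build_spectral_basis, to_frequency
from .wavelet import (CwtBasis, LogGrid, build_cwt_basis, build_log_grid,
                      cwt_transform, grid_vertex_count)

__all__ = [
    "ErrorReport",
    "ResourceEstimate",
    "prepare_transforms",
    "fit_fold",
    "holdout_individual",
    "split_half",
    "biased_error",
    "group_holdout",
    "binomial_pvalue",
    "estimate_demands",
    "pool_datasets",
]


# ---------------------------------------------------------------------------
# shared machinery

def _conditions(labels, cfg: RunConfig) -> tuple[str, str]:
    tags = sorted(set(str(x) for x in labels))
    if cfg.condition_a is not None and cfg.condition_b is not None:
        if {cfg.condition_a, cfg.condition_b} != set(tags):
            raise ValueError(
                f"configured conditions do not match labels {tags}"
            )
        return cfg.condition_a, cfg.condition_b
    if len(tags) != 2:
        raise ValueError(f"expected two condition labels, found {tags}")
    return tags[0], tags[1]


def prepare_transforms(e: ErpEpochs, cfg: RunConfig):
    """Spectral basis, log-grid, CWT basis and the frequency representation."""
    cfg.validate()
    basis = build_spectral_basis(e.duration, e.rate, cfg.s_c, cfg.t_in, cfg.t_out)
    grid = build_log_grid(cfg.s_c, e.duration, cfg.grid_rate)
    cb = build_cwt_basis(grid, basis)
    return basis, grid, cb, to_frequency(e, basis)


def fit_fold(
    F_train: ErpEpochs,
    pca: PcaModel,
    cb: CwtBasis,
    grid: LogGrid,
    cfg: RunConfig,
    C: float,
    W_train: np.ndarray | None = None,
) -> tuple[DiscriminantModel, FeatureBasis]:
    """Everything downstream of the whole-sample outlier stage, on one fold.

    Runs the per-condition outlier pass (with the frozen PCT ``pca``),
    accumulates the scalogram sums of squares over the accepted trials,
    detects the t-scalogram extrema, and fits the feature-space discriminant.
    ``W_train`` may supply pre-computed scalogram samples of exactly the rows
    of ``F_train`` (they must already be PCA-projected).
    """
    cond_a, cond_b = _conditions(F_train.labels, cfg)
    rep = per_condition_outliers(F_train, pca, C, cfg.max_iter)
    keep = ~rep.trial_flags
    labels = F_train.labels[keep]
    if W_train is not None:
        W = W_train if keep.all() else W_train[keep]
    else:
        Fp = project_filtered(F_train.select(keep), pca)
        W = cwt_transform(Fp, cb, cfg.block_size)
    ss = accumulate_ss(W, labels, cond_a, cond_b)
    ts = t_scalogram(ss, F_train.n_channels)
    fb = find_extrema(ts, grid)
    if fb.n_features == 0:
        raise ValueError("no t-scalogram extrema found: degenerate fold")
    W_star = W[:, fb.columns()]
    model = fit_discriminant(
        W_star, labels, cfg.pca_criterion, cfg.alpha_sd, cfg.priors,
        cond_a, cond_b,
    )
    return model, fb


def _classify_rows(F_rows, model, fb, cb, pca) -> np.ndarray:
    Fp = project_filtered(F_rows, pca)
    W_star = extract_features(Fp, fb, cb)
    return classify(W_star, model)


@dataclass
class ErrorReport:
    """Per-dataset classification error rates with binomial significance."""

    method: str
    condition_a: str
    condition_b: str
    priors: tuple[float, float]
    chance: float
    table: pd.DataFrame
    biased: bool = False

    @property
    def total_error(self) -> float:
        """Pooled total error rate (%) over all tested trials."""
        return 100.0 * self.table["errors"].sum() / self.table["n_tested"].sum()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"{self.method} error rates (chance {self.chance * 100:.1f}%"
            + (", optimistically biased)" if self.biased else ")")
        )
        return head + "\n" + self.table.to_string()


def _build_report(method, rows, cond_a, cond_b, priors, biased=False):
    priors = priors or (0.5, 0.5)
    chance = min(priors)
    table = pd.DataFrame(rows).set_index("dataset")
    return ErrorReport(
        method=method, condition_a=cond_a, condition_b=cond_b,
        priors=priors, chance=chance, table=table, biased=biased,
    )


def _error_row(ds, true_labels, predicted, cond_a, cond_b, chance):
    true_labels = np.asarray([str(x) for x in true_labels], dtype=object)
    predicted = np.asarray([str(x) for x in predicted], dtype=object)
    wrong = predicted != true_labels
    ma, mb = true_labels == cond_a, true_labels == cond_b
    n = len(true_labels)
    row = {
        "dataset": ds,
        "n_tested": n,
        f"n_{cond_a}": int(ma.sum()),
        f"n_{cond_b}": int(mb.sum()),
        f"err_{cond_a}": 100.0 * wrong[ma].mean() if ma.any() else np.nan,
        f"err_{cond_b}": 100.0 * wrong[mb].mean() if mb.any() else np.nan,
        "err_total": 100.0 * wrong.mean(),
        "errors": int(wrong.sum()),
    }
    row["p_binomial"] = binomial_pvalue(int(wrong.sum()), n, chance)
    return row


def _dataset_order(e: ErpEpochs):
    return list(dict.fromkeys(e.dataset_ids))


# ---------------------------------------------------------------------------
# protocols

def holdout_individual(e: ErpEpochs, cfg: RunConfig) -> ErrorReport:
    """Leave-one-trial-out error rates per dataset.

    The whole-sample outlier stage (outlier flags and the PCA projection) is
    fitted once per dataset; every other step - per-condition outlier pass,
    scalogram statistics, extremum detection, feature PCA, step-down, LDF -
    is refitted per fold without the held-out trial.  ``cfg.holdout_stride``
    classifies every n-th retained trial to trade precision for time.
    """
    cfg.validate()
    rows = []
    cond_a = cond_b = None
    for ds in _dataset_order(e):
        ed = e.select(np.asarray(e.dataset_ids == ds))
        cond_a, cond_b = _conditions(ed.labels, cfg)
        for tag in (cond_a, cond_b):
            if (ed.labels == tag).sum() < 3:
                raise ValueError(f"dataset {ds}: condition {tag!r} has <3 trials")
        basis, grid, cb, F = prepare_transforms(ed, cfg)
        rep, pca = detect_outliers(
            F, cfg.c_individual, cfg.pca_criterion, cfg.max_iter, cfg.dataset_limit
        )
        F0 = F.select(~rep.excluded)
        Fp = project_filtered(F0, pca)
        W = cwt_transform(Fp, cb, cfg.block_size)
        tested_idx = np.arange(F0.n_trials)[:: cfg.holdout_stride]
        preds = []
        for i in tested_idx:
            mask = np.ones(F0.n_trials, dtype=bool)
            mask[i] = False
            model, fb = fit_fold(
                F0.select(mask), pca, cb, grid, cfg, cfg.c_individual,
                W_train=W[mask],
            )
            preds.append(classify(W[i, fb.columns()], model))
        chance = min(cfg.priors) if cfg.priors else 0.5
        rows.append(_error_row(ds, F0.labels[tested_idx], preds, cond_a, cond_b, chance))
    return _build_report("individual hold-out", rows, cond_a, cond_b, cfg.priors)


def split_half(e: ErpEpochs, cfg: RunConfig) -> ErrorReport:
    """Train on the chronological first half of each dataset, test the second.

    The first ceil(N/2) trials (by original presentation order) form the
    training set; the full pipeline, including whole-sample outlier
    rejection, runs on that half only, and the fitted chain is applied
    unchanged to the untouched second half.
    """
    cfg.validate()
    rows = []
    cond_a = cond_b = None
    for ds in _dataset_order(e):
        ed = e.select(np.asarray(e.dataset_ids == ds))
        cond_a, cond_b = _conditions(ed.labels, cfg)
        order = np.argsort(ed.trial_index, kind="stable")
        n_train = math.ceil(len(order) / 2)
        train, test = ed.select(order[:n_train]), ed.select(order[n_train:])
        basis, grid, cb, F_train = prepare_transforms(train, cfg)
        rep, pca = detect_outliers(
            F_train, cfg.c_individual, cfg.pca_criterion, cfg.max_iter,
            cfg.dataset_limit,
        )
        model, fb = fit_fold(
            F_train.select(~rep.excluded), pca, cb, grid, cfg, cfg.c_individual
        )
        preds = _classify_rows(to_frequency(test, basis), model, fb, cb, pca)
        chance = min(cfg.priors) if cfg.priors else 0.5
        rows.append(_error_row(ds, test.labels, preds, cond_a, cond_b, chance))
    return _build_report("individual split-half", rows, cond_a, cond_b, cfg.priors)


def biased_error(e: ErpEpochs, cfg: RunConfig) -> ErrorReport:
    """Train and test on the same trials; optimistically biased by design."""
    cfg.validate()
    rows = []
    cond_a = cond_b = None
    for ds in _dataset_order(e):
        ed = e.select(np.asarray(e.dataset_ids == ds))
        cond_a, cond_b = _conditions(ed.labels, cfg)
        basis, grid, cb, F = prepare_transforms(ed, cfg)
        rep, pca = detect_outliers(
            F, cfg.c_individual, cfg.pca_criterion, cfg.max_iter, cfg.dataset_limit
        )
        F0 = F.select(~rep.excluded)
        model, fb = fit_fold(F0, pca, cb, grid, cfg, cfg.c_individual)
        preds = _classify_rows(F0, model, fb, cb, pca)
        chance = min(cfg.priors) if cfg.priors else 0.5
        rows.append(_error_row(ds, F0.labels, preds, cond_a, cond_b, chance))
    return _build_report(
        "individual biased", rows, cond_a, cond_b, cfg.priors, biased=True
    )


def group_holdout(datasets, cfg: RunConfig) -> ErrorReport:
    """Leave-one-dataset-out error rates on the pooled group sample.

    For every dataset, the remaining datasets are pooled and the full
    pipeline (whole-sample outlier rejection with the group PCA criterion,
    per-condition pass, t-CWT, feature discriminant) is fitted on them alone;
    every trial of the held-out dataset is then classified.  The held-out
    trials influence no fitted statistic.
    """
    cfg.validate()
    pooled = pool_datasets(datasets) if isinstance(datasets, (list, tuple)) else datasets
    ids = pooled.dataset_ids
    names = _dataset_order(pooled)
    if len(names) < 3:
        raise ValueError("group hold-out needs at least 3 datasets")
    cond_a, cond_b = _conditions(pooled.labels, cfg)
    basis, grid, cb, F = prepare_transforms(pooled, cfg)
    rows = []
    for ds in names:
        test_mask = np.asarray(ids == ds)
        F_train = F.select(~test_mask)
        rep, pca = detect_outliers(
            F_train, cfg.c_group, cfg.group_pca_criterion, cfg.max_iter,
            cfg.dataset_limit,
        )
        model, fb = fit_fold(
            F_train.select(~rep.excluded), pca, cb, grid, cfg, cfg.c_group
        )
        preds = _classify_rows(F.select(test_mask), model, fb, cb, pca)
        chance = min(cfg.priors) if cfg.priors else 0.5
        rows.append(
            _error_row(ds, pooled.labels[test_mask], preds, cond_a, cond_b, chance)
        )
    return _build_report("group hold-out", rows, cond_a, cond_b, cfg.priors)


# ---------------------------------------------------------------------------
# small utilities

def binomial_pvalue(errors: int, n: int, p_chance: float) -> float:
    """Lower-tail binomial probability P(X <= errors), X ~ Bin(n, p_chance)."""
    if not (0 <= errors <= n):
        raise ValueError("error count must lie in [0, n]")
    if not (0.0 < p_chance < 1.0):
        raise ValueError("chance probability must lie in (0, 1)")
    return float(stats.binom.cdf(errors, n, p_chance))


def pool_datasets(datasets) -> ErpEpochs:
    """Concatenate datasets into one group sample, preserving dataset ids."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("nothing to pool")
    first = datasets[0]
    for d in datasets[1:]:
        if (
            d.channels != first.channels
            or d.rate != first.rate
            or abs(d.t0 - first.t0) > 1e-12
            or d.samples_per_channel != first.samples_per_channel
            or d.domain != first.domain
        ):
            raise ValueError("datasets disagree on channels/rate/window")
    return ErpEpochs(
        data=np.vstack([d.data for d in datasets]),
        channels=list(first.channels),
        rate=first.rate,
        t0=first.t0,
        labels=np.concatenate([d.labels for d in datasets]),
        dataset_ids=np.concatenate([d.dataset_ids for d in datasets]),
        trial_index=np.concatenate([d.trial_index for d in datasets]),
        domain=first.domain,
    )


@dataclass
class ResourceEstimate:
    """Exact and approximate matrix-element counts with memory/time heuristics.

    Exact counts obey N_P = 2 K² N_F² (PCT plus covariance matrix) and
    N_W = K N_F N_G (the per-channel CWT block applied K times); the
    approximations are N_F ≈ 4T/S_c, N_G ≈ 3R²T/S_c, N_P ≈ 32K²T²/S_c² and
    N_W ≈ 12KR²T²/S_c².  Heuristics: 8 bytes of memory and 1 µs of processing
    per matrix element.
    """

    K: int
    T: float
    s_c: float
    R: int
    n_f: int
    n_g: int
    n_p: int
    n_w: int
    n_f_approx: float
    n_g_approx: float
    n_p_approx: float
    n_w_approx: float

    @property
    def pca_memory_bytes(self) -> int:
        return 8 * self.n_p

    @property
    def cwt_memory_bytes(self) -> int:
        return 8 * self.n_f * self.n_g  # one channel block at a time

    @property
    def pca_seconds(self) -> float:
        return 1e-6 * self.n_p

    @property
    def cwt_seconds(self) -> float:
        return 1e-6 * self.n_w

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"N_F={self.n_f} (~{self.n_f_approx:.0f})  "
            f"N_G={self.n_g} (~{self.n_g_approx:.0f})  "
            f"N_P={self.n_p} (~{self.n_p_approx:.0f})  "
            f"N_W={self.n_w} (~{self.n_w_approx:.0f})\n"
            f"PCA: ~{self.pca_memory_bytes / 2**20:.0f} MB, "
            f"~{self.pca_seconds:.0f} s/iteration; "
            f"CWT: ~{self.cwt_memory_bytes / 2**20:.0f} MB/channel, "
            f"~{self.cwt_seconds:.0f} s/scalogram"
        )


def estimate_demands(K: int, T: float, s_c: float, R: int,
                     rate: float = 500.0) -> ResourceEstimate:
    """Exact and approximate problem sizes without materializing any matrix."""
    n_f = 1 + 2 * int(math.floor(2.0 * T / s_c + 1e-9))
    n_g = grid_vertex_count(s_c, T, R)
    return ResourceEstimate(
        K=K, T=T, s_c=s_c, R=R,
        n_f=n_f, n_g=n_g,
        n_p=2 * K * K * n_f * n_f,
        n_w=K * n_f * n_g,
        n_f_approx=4.0 * T / s_c,
        n_g_approx=3.0 * R * R * T / s_c,
        n_p_approx=32.0 * K * K * T * T / (s_c * s_c),
        n_w_approx=12.0 * K * R * R * T * T / (s_c * s_c),
    )
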